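"""Coarse-grained polymer structures and ensembles.

A chromatin model is an ordered chain of beads, one bead per fixed number of
base pairs, whose order follows genomic order along a region.  Modeling
packages emit such chains in XYZ, PDB (one MODEL block per structure) or
mmCIF; here each ATOM/pseudoatom record is a bead and record order is the
genomic order — residue numbering is deliberately ignored because
coarse-grained writers disagree on it.

PDB and mmCIF parsing/writing go through :mod:`gemmi`; the multi-frame XYZ
dialect used by polymer codes (optional per-frame count header + comment
line, otherwise whitespace triplets with blank-line frame breaks) is parsed
here directly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

from .regions import GenomicRegion

__all__ = [
    "PolymerModel",
    "ModelEnsemble",
    "StructureFormatError",
    "read_structure",
    "write_structure",
]


class StructureFormatError(ValueError):
    """Raised for malformed or inconsistent structure files."""


@dataclass
class PolymerModel:
    """One polymer conformation: N ordered beads over a genomic region.

    Parameters
    ----------
    coords : (N, 3) float array
        Bead centers in arbitrary length units, ordered along the genome.
    region : GenomicRegion
        Genomic interval the chain tiles (uniformly, from region start).
    bp_per_bead : float
        Base pairs represented by one bead; ``N * bp_per_bead`` must cover
        the region (the last bead may be partial).
    label : str
        Free-text identifier, e.g. the producing method's name.
    """

    coords: np.ndarray
    region: GenomicRegion
    bp_per_bead: float
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if self.n_beads < 2:
            raise ValueError("a polymer model needs at least 2 beads")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in model")
        if self.bp_per_bead <= 0:
            raise ValueError("bp_per_bead must be positive")
        if self.n_beads * self.bp_per_bead < self.region.length():
            raise ValueError(
                f"{self.n_beads} beads at {self.bp_per_bead} bp/bead do not "
                f"cover region of length {self.region.length()}"
            )

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def contour_length(self) -> float:
        """Sum of consecutive inter-bead distances."""
        steps = np.diff(self.coords, axis=0)
        return float(np.linalg.norm(steps, axis=1).sum())

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    scale: float = 1.0) -> "PolymerModel":
        """Return a copy under an affine similarity (rotate, scale, shift)."""
        xyz = self.coords * scale
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return PolymerModel(xyz, self.region, self.bp_per_bead, self.label)


@dataclass
class ModelEnsemble:
    """An ordered set of same-shape conformations from one method.

    Order is meaningful: for annealing-style trajectories the last model is
    the physically relevant one, for equilibrium ensembles order is just
    sampling order.
    """

    models: list[PolymerModel] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble must contain at least one model")
        ref = self.models[0]
        for m in self.models[1:]:
            if m.n_beads != ref.n_beads:
                raise ValueError(
                    f"inconsistent bead counts in ensemble: "
                    f"{m.n_beads} vs {ref.n_beads}"
                )
            if m.region != ref.region or m.bp_per_bead != ref.bp_per_bead:
                raise ValueError("ensemble models must share region and resolution")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self) -> Iterator[PolymerModel]:
        return iter(self.models)

    def __getitem__(self, i: int) -> PolymerModel:
        return self.models[i]

    @property
    def n_beads(self) -> int:
        return self.models[0].n_beads

    @property
    def region(self) -> GenomicRegion:
        return self.models[0].region

    @property
    def bp_per_bead(self) -> float:
        return self.models[0].bp_per_bead


# ---------------------------------------------------------------------------
# format detection

_EXT_FORMAT = {
    ".xyz": "xyz",
    ".pdb": "pdb",
    ".ent": "pdb",
    ".cif": "cif",
    ".mmcif": "cif",
}


def _detect_format(path: Path, format: str) -> str:
    if format != "auto":
        if format not in ("xyz", "pdb", "cif"):
            raise ValueError(f"unknown structure format {format!r}")
        return format
    fmt = _EXT_FORMAT.get(path.suffix.lower())
    if fmt is None:
        raise StructureFormatError(
            f"cannot detect format from extension of {path.name!r}; "
            "pass format explicitly"
        )
    return fmt


# ---------------------------------------------------------------------------
# XYZ dialect

def _parse_xyz_frames(path: Path) -> list[np.ndarray]:
    """Parse multi-frame XYZ: count-header dialect or plain triplet lines."""
    frames: list[np.ndarray] = []
    current: list[list[float]] = []

    def flush() -> None:
        if current:
            frames.append(np.array(current, dtype=float))
            current.clear()

    lines = path.read_text().splitlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            flush()
            i += 1
            continue
        tokens = line.split()
        if len(tokens) == 1 and tokens[0].lstrip("+").isdigit():
            # count header: "<n>" then a comment line, then n bead lines
            flush()
            count = int(tokens[0])
            if count <= 0:
                raise StructureFormatError(
                    f"{path.name}:{i + 1}: non-positive bead count {count}"
                )
            if i + 1 + count >= n_lines + 1:
                raise StructureFormatError(
                    f"{path.name}:{i + 1}: frame header promises {count} beads "
                    "but file ends early"
                )
            i += 2  # skip header and comment line
            for k in range(count):
                current.append(_parse_xyz_bead(path, lines, i + k))
            i += count
            flush()
        else:
            current.append(_parse_xyz_bead(path, lines, i))
            i += 1
    flush()
    return frames


def _parse_xyz_bead(path: Path, lines: Sequence[str], idx: int) -> list[float]:
    tokens = lines[idx].split()
    # tolerate a leading element/bead symbol ("C 1.0 2.0 3.0")
    if len(tokens) == 4 and not _is_float(tokens[0]):
        tokens = tokens[1:]
    if len(tokens) != 3 or not all(_is_float(t) for t in tokens):
        raise StructureFormatError(
            f"{path.name}:{idx + 1}: expected 3 coordinates, got {lines[idx]!r}"
        )
    return [float(t) for t in tokens]


def _is_float(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _write_xyz(ensemble: ModelEnsemble, path: Path) -> None:
    with path.open("w") as fh:
        for idx, model in enumerate(ensemble):
            fh.write(f"{model.n_beads}\n")
            fh.write(f"frame {idx} {ensemble.label}\n".rstrip() + "\n")
            for x, y, z in model.coords:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# PDB / mmCIF via gemmi

def _frames_from_gemmi(path: Path, fmt: str) -> list[np.ndarray]:
    try:
        st = gemmi.read_structure(os.fspath(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path.name}: {exc}") from exc
    frames = []
    for model in st:
        xyz = [
            [atom.pos.x, atom.pos.y, atom.pos.z]
            for chain in model
            for residue in chain
            for atom in residue
        ]
        if xyz:
            frames.append(np.array(xyz, dtype=float))
    return frames


def _gemmi_structure(ensemble: ModelEnsemble) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = ensemble.label or "polymer"
    for mi, pmodel in enumerate(ensemble, start=1):
        model = gemmi.Model(mi)
        chain = gemmi.Chain("A")
        for bi, (x, y, z) in enumerate(pmodel.coords, start=1):
            res = gemmi.Residue()
            res.name = "BEA"
            res.seqid = gemmi.SeqId(bi, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


# ---------------------------------------------------------------------------
# public API

def read_structure(
    path: str | os.PathLike,
    region: GenomicRegion,
    bp_per_bead: float,
    format: str = "auto",
    label: str | None = None,
) -> ModelEnsemble:
    """Read a structure file into a :class:`ModelEnsemble`.

    One :class:`PolymerModel` is produced per structure block — each MODEL
    record in PDB, each model block in mmCIF, each frame in multi-frame XYZ.
    Bead order follows record order.

    Parameters
    ----------
    path : path-like
        Structure file in XYZ, PDB or mmCIF.
    region, bp_per_bead
        Genomic anchoring of the chain; the file formats carry no genomic
        metadata, so these must be supplied.
    format : {"auto", "xyz", "pdb", "cif"}
        ``"auto"`` detects from the file extension.
    label : str, optional
        Ensemble label; defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    if fmt == "xyz":
        frames = _parse_xyz_frames(path)
    else:
        frames = _frames_from_gemmi(path, fmt)
    if not frames:
        raise StructureFormatError(f"{path.name}: no beads found")
    counts = {f.shape[0] for f in frames}
    if len(counts) > 1:
        raise StructureFormatError(
            f"{path.name}: inconsistent bead counts across structure blocks: "
            f"{sorted(counts)}"
        )
    if label is None:
        label = path.stem
    models = [
        PolymerModel(frame, region, bp_per_bead, label=label) for frame in frames
    ]
    return ModelEnsemble(models, label=label)


def write_structure(
    ensemble: ModelEnsemble | PolymerModel,
    path: str | os.PathLike,
    format: str = "auto",
) -> None:
    """Write an ensemble (or single model) to XYZ, PDB or mmCIF.

    Round trip through :func:`read_structure` reproduces coordinates within
    format precision: 1e-3 for fixed-width PDB, 1e-6 otherwise.
    """
    if isinstance(ensemble, PolymerModel):
        ensemble = ModelEnsemble([ensemble], label=ensemble.label)
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "xyz":
        _write_xyz(ensemble, path)
        return
    st = _gemmi_structure(ensemble)
    if fmt == "pdb":
        st.write_pdb(os.fspath(path))
    else:
        doc = st.make_mmcif_document()
        doc.write_file(os.fspath(path))
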