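"""Reading and writing contact/distance matrices.

Three input routes cover the formats benchmark users actually have:

1. dense whitespace/CSV matrix plus a JSON sidecar (``<path>.json``) with
   region, bin size, kind and mask;
2. 3-column sparse text ``bin_i bin_j count`` (0-based bins, upper triangle
   or full — symmetrized on load);
3. binned-matrix HDF5 containers following the cooler single-resolution
   layout (``chroms/ bins/ pixels/``), read for a requested region at
   native bin size.

Outputs are always route 1: a dense CSV with a JSON sidecar, so results are
diff-able text.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .matrixops import SquareMatrix
from .regions import GenomicRegion, bead_count, parse_region

__all__ = [
    "write_matrix",
    "read_dense_matrix",
    "read_sparse_text",
    "read_cooler_region",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_matrix(matrix: SquareMatrix, path: str | os.PathLike) -> None:
    """Write a dense CSV plus a JSON sidecar with the matrix metadata."""
    path = Path(path)
    np.savetxt(path, matrix.values, delimiter=",", fmt="%.10g")
    meta = {
        "region": str(matrix.region),
        "bp_per_bin": matrix.bp_per_bin,
        "kind": matrix.kind,
        "label": matrix.label,
        "mask": matrix.mask.astype(int).tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_dense_matrix(
    path: str | os.PathLike,
    region: GenomicRegion | None = None,
    bp_per_bin: float | None = None,
    kind: str = "contact",
) -> SquareMatrix:
    """Read a dense whitespace/CSV matrix.

    If a JSON sidecar exists its region/bin-size/kind/mask are used;
    explicit arguments override the sidecar.
    """
    path = Path(path)
    values = np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None)
    mask = None
    label = path.stem
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if region is None:
            region = parse_region(meta["region"])
        if bp_per_bin is None:
            bp_per_bin = float(meta["bp_per_bin"])
        kind = meta.get("kind", kind)
        label = meta.get("label") or label
        if "mask" in meta:
            mask = np.asarray(meta["mask"], dtype=bool)
    if region is None or bp_per_bin is None:
        raise ValueError(
            f"{path.name}: no sidecar found; region and bp_per_bin are required"
        )
    return SquareMatrix(values, kind=kind, region=region,
                        bp_per_bin=bp_per_bin, mask=mask, label=label)


def read_sparse_text(
    path: str | os.PathLike,
    region: GenomicRegion,
    bp_per_bin: float,
    n_bins: int | None = None,
) -> SquareMatrix:
    """Read 3-column ``bin_i bin_j count`` text into a contact matrix.

    Bins are 0-based; entries may be upper-triangle only or full — the
    matrix is symmetrized by mirroring.  ``n_bins`` defaults to the bin
    count of *region* at *bp_per_bin*.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None,
                     names=["i", "j", "count"])
    if n_bins is None:
        n_bins = bead_count(region, bp_per_bin)
    i = df["i"].to_numpy(dtype=int)
    j = df["j"].to_numpy(dtype=int)
    c = df["count"].to_numpy(dtype=float)
    if i.min(initial=0) < 0 or max(i.max(initial=0), j.max(initial=0)) >= n_bins:
        raise ValueError(f"{path.name}: bin index outside [0, {n_bins})")
    m = np.zeros((n_bins, n_bins))
    np.add.at(m, (i, j), c)
    lower = np.tril(m, k=-1)
    m = np.triu(m) + np.triu(m, k=1).T + lower + lower.T
    return SquareMatrix(m, kind="contact", region=region,
                        bp_per_bin=bp_per_bin, label=path.stem)


def read_cooler_region(
    path: str | os.PathLike,
    region: GenomicRegion | str,
    group: str = "/",
) -> SquareMatrix:
    """Read one region from a cooler-layout HDF5 file at native bin size.

    Supports the single-resolution layout: ``chroms/name``, ``bins/chrom``,
    ``bins/start``, ``bins/end``, ``pixels/bin1_id``, ``pixels/bin2_id``,
    ``pixels/count``, with uniform ``bin-size``.  Balancing weights are
    ignored (raw counts are returned).
    """
    if isinstance(region, str):
        region = parse_region(region)
    with h5py.File(os.fspath(path), "r") as fh:
        grp = fh[group]
        bin_size = int(grp.attrs["bin-size"])
        chrom_names = [
            c.decode() if isinstance(c, bytes) else str(c)
            for c in grp["chroms/name"][:]
        ]
        bin_chrom_ids = grp["bins/chrom"][:].astype(int)
        bin_starts = grp["bins/start"][:].astype(int)
        bin_ends = grp["bins/end"][:].astype(int)
        try:
            chrom_id = chrom_names.index(region.chrom)
        except ValueError:
            raise KeyError(
                f"chromosome {region.chrom!r} not in container "
                f"(has {chrom_names})"
            ) from None
        sel = (
            (bin_chrom_ids == chrom_id)
            & (bin_starts >= region.start)
            & (bin_starts < region.end)
        )
        bin_ids = np.flatnonzero(sel)
        if bin_ids.size < 2:
            raise ValueError(f"region {region} covers fewer than 2 bins")
        lo, hi = int(bin_ids[0]), int(bin_ids[-1])
        if not np.array_equal(bin_ids, np.arange(lo, hi + 1)):
            raise ValueError("selected bins are not contiguous in the container")
        b1 = grp["pixels/bin1_id"][:].astype(int)
        b2 = grp["pixels/bin2_id"][:].astype(int)
        counts = grp["pixels/count"][:].astype(float)
    keep = (b1 >= lo) & (b1 <= hi) & (b2 >= lo) & (b2 <= hi)
    n = hi - lo + 1
    m = np.zeros((n, n))
    np.add.at(m, (b1[keep] - lo, b2[keep] - lo), counts[keep])
    m = np.triu(m) + np.triu(m, k=1).T  # cooler stores upper triangle
    covered = GenomicRegion(region.chrom, int(bin_starts[lo]), int(bin_ends[hi]))
    return SquareMatrix(m, kind="contact", region=covered,
                        bp_per_bin=bin_size, label=Path(path).stem)
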