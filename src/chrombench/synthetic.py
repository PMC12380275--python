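"""Synthetic ground truth: Gaussian spring-network polymers and contact maps.

Real benchmark inputs (Hi-C / ChIA-PET maps and the models built from them)
need external software; this module generates both sides with *known*
structure so every pipeline stage and metric is testable.

The polymer is a Gaussian phantom network: beads connected by harmonic
springs — a backbone chain plus loop springs between anchor pairs, the
spring analogue of CTCF-mediated loops.  Its Boltzmann distribution is an
exact zero-mean Gaussian whose per-axis precision matrix is the weighted
graph Laplacian of the spring network, so structures are sampled exactly
(no molecular dynamics, no equilibration) and moments have closed forms:

    E ||r_i - r_j||^2 = 3 * R_ij

where R_ij is the effective resistance between nodes i and j of the spring
graph (for a pure chain with unit springs, R_ij = |i - j|).  Adding a loop
spring strictly lowers the resistance, hence the mean squared distance,
between its anchors — exactly the behavior the loop constraints of
bottom-up chromatin models are meant to produce.

Contact maps are emitted from an ensemble either by capture radius (count
structures with d_ij < r_c — ligation-like) or through the power-law decay
s ~ d^(-a); optional multinomial downsampling to a target read depth
emulates the sparser, more discontinuous maps of ChIA-PET versus Hi-C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np

from .matrixops import PowerLawMap, SquareMatrix
from .regions import GenomicRegion
from .structures import ModelEnsemble, PolymerModel

__all__ = [
    "SpringNetworkSpec",
    "ContactModel",
    "BenchmarkScene",
    "spring_laplacian",
    "effective_resistance",
    "sample_ensemble",
    "emit_contacts",
    "make_benchmark_scene",
]


@dataclass(frozen=True)
class SpringNetworkSpec:
    """A harmonic bead-spring network: backbone chain plus loop springs.

    n_beads : chain length.
    backbone_strength : spring constant of each consecutive-bead spring.
    loops : (i, j, kappa) anchor pairs with loop spring constants.
    seed : RNG seed for exact Gaussian sampling.
    """

    n_beads: int
    backbone_strength: float = 1.0
    loops: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beads < 2:
            raise ValueError("need at least 2 beads")
        if self.backbone_strength <= 0:
            raise ValueError("backbone spring constant must be positive")
        loops = tuple(tuple(loop) for loop in self.loops)
        for i, j, kappa in loops:
            if not (0 <= i < j < self.n_beads):
                raise ValueError(f"loop anchors ({i}, {j}) out of range")
            if kappa <= 0:
                raise ValueError(f"loop spring constant must be positive, got {kappa}")
        object.__setattr__(self, "loops", loops)


@dataclass(frozen=True)
class ContactModel:
    """How an ensemble becomes a contact map.

    mode="capture_radius" : entry (i, j) counts structures with d_ij < r_c.
    mode="power_law" : entry proportional to the ensemble mean of d_ij^(-a).
    depth : if set, multinomial downsampling of the map to this total read
        count (upper triangle), emulating finite sequencing depth.
    """

    mode: Literal["capture_radius", "power_law"] = "capture_radius"
    r_c: float | None = None
    map: PowerLawMap | None = None
    depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode == "capture_radius":
            if self.r_c is None or self.r_c <= 0:
                raise ValueError("capture_radius mode needs r_c > 0")
            if self.map is not None:
                raise ValueError("capture_radius mode takes no power-law map")
        elif self.mode == "power_law":
            if self.map is None:
                raise ValueError("power_law mode needs a PowerLawMap")
            if self.r_c is not None:
                raise ValueError("power_law mode takes no capture radius")
        else:
            raise ValueError(f"unknown contact mode {self.mode!r}")
        if self.depth is not None and self.depth < 1:
            raise ValueError("depth must be a positive integer")


def spring_laplacian(spec: SpringNetworkSpec) -> np.ndarray:
    """Weighted graph Laplacian of the spring network (per-axis precision)."""
    n = spec.n_beads
    L = np.zeros((n, n))
    idx = np.arange(n - 1)
    L[idx, idx + 1] -= spec.backbone_strength
    L[idx + 1, idx] -= spec.backbone_strength
    for i, j, kappa in spec.loops:
        L[i, j] -= kappa
        L[j, i] -= kappa
    np.fill_diagonal(L, -L.sum(axis=1) + np.diag(L))
    return L


def effective_resistance(spec: SpringNetworkSpec) -> np.ndarray:
    """Pairwise effective resistance R_ij via the Laplacian pseudoinverse.

    Closed-form oracle for the sampler: E ||r_i - r_j||^2 = 3 R_ij.
    """
    Lp = np.linalg.pinv(spring_laplacian(spec), hermitian=True)
    diag = np.diag(Lp)
    return diag[:, None] + diag[None, :] - 2.0 * Lp


def sample_ensemble(
    spec: SpringNetworkSpec,
    n_structures: int,
    region: GenomicRegion | None = None,
    bp_per_bead: float | None = None,
    label: str = "synthetic",
) -> ModelEnsemble:
    """Draw structures exactly from the network's Gaussian distribution.

    Per coordinate axis (axes independent), coordinates follow the
    degenerate Gaussian with precision matrix L, sampled in the subspace
    orthogonal to the all-ones vector — which also centers each structure
    at the origin, removing the free translation mode.  Deterministic for a
    given ``spec.seed``.
    """
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    L = spring_laplacian(spec)
    eigval, eigvec = np.linalg.eigh(L)
    # one zero mode (translation) iff the spring graph is connected
    if eigval[1] <= eigval[-1] * 1e-12:
        raise ValueError("spring network is disconnected: precision is singular")
    lam = eigval[1:]
    V = eigvec[:, 1:]
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((n_structures, 3, lam.size))
    coords = np.einsum("nk,sxk->snx", V / np.sqrt(lam), z)  # (structures, beads, 3)
    if region is None:
        region = GenomicRegion("chrS", 0, spec.n_beads * 5000)
    if bp_per_bead is None:
        bp_per_bead = region.length() / spec.n_beads
    models = [
        PolymerModel(c, region, bp_per_bead, label=label) for c in coords
    ]
    return ModelEnsemble(models, label=label)


def emit_contacts(
    ensemble: ModelEnsemble,
    model: ContactModel,
    label: str = "contacts",
) -> SquareMatrix:
    """Turn an ensemble into a synthetic contact map (see :class:`ContactModel`)."""
    n = ensemble.n_beads
    from scipy.spatial.distance import pdist, squareform

    dists = np.stack([squareform(pdist(m.coords)) for m in ensemble])  # (S, N, N)
    off = ~np.eye(n, dtype=bool)
    if model.mode == "capture_radius":
        counts = (dists < model.r_c).sum(axis=0).astype(float)
        counts[~off] = 0.0
    else:
        with np.errstate(divide="ignore"):
            w = np.where(dists > 0, np.power(dists, -model.map.a), 0.0)
        counts = w.mean(axis=0)
        counts[~off] = 0.0
    if model.depth is not None:
        counts = _downsample(counts, model.depth, model.seed)
    return SquareMatrix(
        counts,
        kind="contact",
        region=ensemble.region,
        bp_per_bin=ensemble.bp_per_bead,
        label=label,
    )


def _downsample(counts: np.ndarray, depth: int, seed: int) -> np.ndarray:
    """Multinomial resampling of upper-triangle mass to *depth* total reads."""
    n = counts.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = counts[iu, ju]
    total = w.sum()
    if total <= 0:
        raise ValueError("cannot downsample an empty contact map")
    rng = np.random.default_rng(seed)
    reads = rng.multinomial(depth, w / total)
    out = np.zeros_like(counts)
    out[iu, ju] = reads
    out[ju, iu] = reads
    return out


class BenchmarkScene(NamedTuple):
    """A self-contained end-to-end test scene with known ground truth."""

    truth: ModelEnsemble
    hic_like: SquareMatrix
    chia_like: SquareMatrix
    spec: SpringNetworkSpec
    metadata: dict


def make_benchmark_scene(
    seed: int = 0,
    n_beads: int = 214,
    n_structures: int = 200,
    region: GenomicRegion | None = None,
) -> BenchmarkScene:
    """One spring network with 3 loops plus Hi-C-like and ChIA-PET-like maps.

    The Hi-C-like map is dense power-law contacts (smooth, deep coverage);
    the ChIA-PET-like map is capture-radius contacts downsampled to low
    read depth, so it is sparser and discontinuous, concentrated at the
    loop anchors the capture radius picks out.  All seeds derive from
    *seed* and are recorded in the metadata.
    """
    third = n_beads // 3
    loops = (
        (third // 2, third, 8.0),
        (third + third // 4, 2 * third, 8.0),
        (2 * third + third // 4, n_beads - 5, 8.0),
    )
    spec = SpringNetworkSpec(
        n_beads=n_beads, backbone_strength=1.0, loops=loops, seed=seed
    )
    truth = sample_ensemble(spec, n_structures, region=region, label="truth")
    hic_model = ContactModel(
        mode="power_law", map=PowerLawMap(a=1.0), depth=None, seed=seed + 1
    )
    hic_like = emit_contacts(truth, hic_model, label="hic_like")
    # capture radius ~ median 1-step distance: tight enough to be loop-driven
    step = np.median([
        np.linalg.norm(np.diff(m.coords, axis=0), axis=1).mean() for m in truth
    ])
    chia_model = ContactModel(
        mode="capture_radius", r_c=float(step), depth=20 * n_beads, seed=seed + 2
    )
    chia_like = emit_contacts(truth, chia_model, label="chia_like")
    metadata = {
        "seed": seed,
        "n_beads": n_beads,
        "n_structures": n_structures,
        "loops": list(map(list, loops)),
        "hic": {"mode": "power_law", "a": 1.0, "seed": seed + 1},
        "chia": {
            "mode": "capture_radius",
            "r_c": float(step),
            "depth": 20 * n_beads,
            "seed": seed + 2,
        },
    }
    return BenchmarkScene(truth, hic_like, chia_like, spec, metadata)
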