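"""Square matrices linking polymer models and experimental contact maps.

Everything downstream of structure parsing lives in one container:
a symmetric N x N matrix tagged with its kind (spatial ``distance``,
experimental ``contact`` frequency, or ``pseudodistance`` — the spatial
surrogate obtained by inverting contacts), its genomic region and bin size,
and a per-bin validity mask.  The diagonal is forced to zero in every kind
and excluded from all statistics: the dominant diagonal signal of contact
maps otherwise biases correlations.

Contacts and distances are linked by the power-law decay of chromatin
interaction frequency with spatial distance, s ~ (1/d)^a.  The exponent
``a`` is not universal and can be estimated from matched data
(:func:`chrombench.metrics.fit_exponent`); ``a = 1`` (plain reciprocal) is
the default used for validation against inverse contact maps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .regions import GenomicRegion
from .structures import ModelEnsemble, PolymerModel

__all__ = [
    "SquareMatrix",
    "PowerLawMap",
    "distance_matrix",
    "ensemble_reduce",
    "coarsen",
    "contact_to_pseudodistance",
    "distance_to_contact",
    "mask_sparse_bins",
    "default_eps",
]

MatrixKind = Literal["distance", "contact", "pseudodistance"]


@dataclass
class SquareMatrix:
    """Symmetric matrix over genomic bins with kind, region and mask.

    Parameters
    ----------
    values : (N, N) float array
        Symmetric; non-negative for every kind; zero diagonal.
    kind : {"distance", "contact", "pseudodistance"}
    region : GenomicRegion
    bp_per_bin : float
    mask : (N,) bool array
        True = bin is valid.  Masked bins are excluded from every
        downstream statistic.
    """

    values: np.ndarray
    kind: MatrixKind
    region: GenomicRegion
    bp_per_bin: float
    mask: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape != (n, n) or n < 2:
            raise ValueError(f"values must be square with N >= 2, got {self.values.shape}")
        if self.kind not in ("distance", "contact", "pseudodistance"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite matrix entries")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix not symmetric within 1e-9")
        if np.any(self.values < 0):
            raise ValueError(f"negative entries in {self.kind} matrix")
        if self.bp_per_bin <= 0:
            raise ValueError("bp_per_bin must be positive")
        # diagonal carries no pairwise information in any kind
        np.fill_diagonal(self.values, 0.0)
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ValueError("mask must be a length-N boolean vector")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Strictly-upper-triangle indices restricted to unmasked bins."""
        i, j = np.triu_indices(self.n, k=1)
        ok = self.mask[i] & self.mask[j]
        return i[ok], j[ok]

    def upper_values(self) -> np.ndarray:
        i, j = self.upper_indices()
        return self.values[i, j]

    def aligned_with(self, other: "SquareMatrix") -> bool:
        return (
            self.n == other.n
            and self.region == other.region
            and np.isclose(self.bp_per_bin, other.bp_per_bin)
        )


@dataclass(frozen=True)
class PowerLawMap:
    """The contact <-> distance transform s ~ (1/d)^a.

    a : power-law decay exponent (> 0); a = 1 is a plain reciprocal.
    eps : pseudocount added to contact frequencies before inversion, so
        zero counts map to a finite (large) pseudodistance; 0 is allowed
        only for strictly positive matrices.
    """

    a: float = 1.0
    eps: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"power-law exponent must be positive, got {self.a}")
        if self.eps < 0:
            raise ValueError("eps must be non-negative")

    def to_distance(self, s: np.ndarray) -> np.ndarray:
        """d = (s + eps)^(-1/a); strictly decreasing in s."""
        return np.power(s + self.eps, -1.0 / self.a)

    def to_contact(self, d: np.ndarray) -> np.ndarray:
        """s = d^(-a); requires strictly positive d."""
        return np.power(d, -self.a)


def default_eps(contacts: np.ndarray) -> float:
    """Default pseudocount: half the smallest positive off-diagonal entry.

    Keeps the ordering of all observed counts while making zeros finite.
    Returns 0 if the matrix has no positive off-diagonal entry.
    """
    c = np.asarray(contacts, dtype=float).copy()
    np.fill_diagonal(c, 0.0)
    pos = c[c > 0]
    return float(pos.min() / 2.0) if pos.size else 0.0


def distance_matrix(model: PolymerModel, label: str | None = None) -> SquareMatrix:
    """Pairwise Euclidean bead-bead distance matrix of one conformation."""
    d = squareform(pdist(model.coords))
    return SquareMatrix(
        d,
        kind="distance",
        region=model.region,
        bp_per_bin=model.bp_per_bead,
        label=label if label is not None else model.label,
    )


def ensemble_reduce(
    ensemble: ModelEnsemble,
    mode: Literal["final", "mean", "medoid"] = "mean",
    label: str | None = None,
) -> SquareMatrix:
    """Reduce an ensemble to one distance matrix.

    mode="final"
        Distance matrix of the last structure — for simulated-annealing
        trajectories, where only the final structure is the physically
        plausible state.
    mode="mean"
        Entrywise mean of per-structure distance matrices — for equilibrium
        ensembles of statistically equivalent structures.  Note this
        averages the *heatmaps*, not the coordinates.
    mode="medoid"
        Distance matrix of the structure minimizing the summed Frobenius
        distance to all other structures' matrices — a deterministic way to
        pick one representative model.
    """
    if mode == "final":
        out = distance_matrix(ensemble[len(ensemble) - 1])
    elif mode == "mean":
        mats = np.stack([distance_matrix(m).values for m in ensemble])
        out = SquareMatrix(
            mats.mean(axis=0),
            kind="distance",
            region=ensemble.region,
            bp_per_bin=ensemble.bp_per_bead,
        )
    elif mode == "medoid":
        mats = np.stack([distance_matrix(m).values for m in ensemble])
        # summed pairwise Frobenius distances, O(k^2) on k structures
        k = mats.shape[0]
        cost = np.zeros(k)
        for i in range(k):
            cost[i] = sum(
                np.linalg.norm(mats[i] - mats[j]) for j in range(k) if j != i
            )
        out = SquareMatrix(
            mats[int(np.argmin(cost))],
            kind="distance",
            region=ensemble.region,
            bp_per_bin=ensemble.bp_per_bead,
        )
    else:
        raise ValueError(f"unknown ensemble reduction mode {mode!r}")
    out.label = label if label is not None else ensemble.label
    return out


def coarsen(matrix: SquareMatrix, factor: int) -> SquareMatrix:
    """Merge *factor* adjacent bins into one.

    Contact matrices are block-summed (total counts conserved; a trailing
    partial block keeps edge bins).  Distance and pseudodistance matrices
    are block-averaged.  A coarse bin is valid iff any member bin is valid.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor > matrix.n:
        raise ValueError(f"factor {factor} exceeds matrix size {matrix.n}")
    if factor == 1:
        return replace(matrix, values=matrix.values.copy(), mask=matrix.mask.copy())
    n = matrix.n
    n_out = -(-n // factor)
    groups = np.arange(n) // factor
    # block sums via group indicator matrix
    ind = np.zeros((n_out, n), dtype=float)
    ind[groups, np.arange(n)] = 1.0
    sums = ind @ matrix.values @ ind.T
    if matrix.kind == "contact":
        vals = sums
    else:
        counts = ind.sum(axis=1)
        vals = sums / np.outer(counts, counts)
    mask = ind.astype(bool) @ matrix.mask
    np.fill_diagonal(vals, 0.0)
    return SquareMatrix(
        vals,
        kind=matrix.kind,
        region=matrix.region,
        bp_per_bin=matrix.bp_per_bin * factor,
        mask=mask,
        label=matrix.label,
    )


def contact_to_pseudodistance(
    matrix: SquareMatrix, map: PowerLawMap | None = None
) -> SquareMatrix:
    """Invert a contact matrix into a pseudodistance matrix.

    Off-diagonal entry (i, j) becomes ``(s_ij + eps)^(-1/a)``; the diagonal
    is 0 and the mask is propagated.  With the default ``PowerLawMap()``
    this is the plain inverse of the contact frequencies.
    """
    if matrix.kind != "contact":
        raise ValueError(f"expected a contact matrix, got kind={matrix.kind!r}")
    if map is None:
        map = PowerLawMap()
    s = matrix.values
    off = ~np.eye(matrix.n, dtype=bool)
    if map.eps == 0 and np.any(s[off] == 0):
        i, j = np.argwhere((s == 0) & off)[0]
        raise ZeroDivisionError(
            f"zero contact at bin pair ({i}, {j}) with eps=0; "
            "use a positive pseudocount (see default_eps)"
        )
    d = np.zeros_like(s)
    d[off] = map.to_distance(s[off])
    d = (d + d.T) / 2.0
    return SquareMatrix(
        d,
        kind="pseudodistance",
        region=matrix.region,
        bp_per_bin=matrix.bp_per_bin,
        mask=matrix.mask.copy(),
        label=matrix.label,
    )


def distance_to_contact(
    matrix: SquareMatrix, map: PowerLawMap | None = None
) -> SquareMatrix:
    """Map (pseudo)distances to contact frequencies via s = d^(-a)."""
    if matrix.kind not in ("distance", "pseudodistance"):
        raise ValueError(f"expected a distance-like matrix, got kind={matrix.kind!r}")
    if map is None:
        map = PowerLawMap()
    d = matrix.values
    off = ~np.eye(matrix.n, dtype=bool)
    if np.any(d[off] == 0):
        i, j = np.argwhere((d == 0) & off)[0]
        raise ZeroDivisionError(f"zero off-diagonal distance at bin pair ({i}, {j})")
    s = np.zeros_like(d)
    s[off] = map.to_contact(d[off])
    s = (s + s.T) / 2.0
    return SquareMatrix(
        s,
        kind="contact",
        region=matrix.region,
        bp_per_bin=matrix.bp_per_bin,
        mask=matrix.mask.copy(),
        label=matrix.label,
    )


def mask_sparse_bins(matrix: SquareMatrix, min_fraction: float) -> SquareMatrix:
    """Mask bins whose off-diagonal nonzero fraction is below *min_fraction*.

    Sparse rows of experimental maps produce unreliable correlations;
    masking them removes those bins from every downstream statistic without
    altering the stored values.
    """
    if matrix.kind != "contact":
        raise ValueError("sparsity masking applies to contact matrices")
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    n = matrix.n
    off = ~np.eye(n, dtype=bool)
    nonzero_frac = (matrix.values > 0).sum(axis=1, where=off) / (n - 1)
    new_mask = matrix.mask & (nonzero_frac >= min_fraction)
    return replace(matrix, values=matrix.values.copy(), mask=new_mask)
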