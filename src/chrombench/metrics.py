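"""Agreement metrics between aligned square matrices.

All statistics are computed over the strictly-upper-triangle entries whose
row and column bins are both unmasked; the diagonal is always excluded
(its dominant signal would otherwise swamp correlations).  Correlations on
constant input are reported as *undefined* with a reason, never coerced to
0 — constant strata are common near masked bins.

Spearman rank correlation is the primary model-vs-model and
model-vs-experiment metric; Pearson is provided as the common alternative;
KL divergence compares the matrices as probability distributions over bin
pairs (computed in contact space); distance-stratified Spearman scores each
window of genomic separation |i - j| separately, removing the
distance-decay dominance that makes global correlations optimistic.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrixops import PowerLawMap, SquareMatrix, distance_to_contact

__all__ = [
    "StrataSpec",
    "ComparisonResult",
    "spearman_compare",
    "pearson_compare",
    "kl_divergence",
    "stratified_spearman",
    "fit_exponent",
    "pairwise_table",
    "table_to_square",
    "AlignmentError",
    "UndefinedMetricError",
]


class AlignmentError(ValueError):
    """Two matrices do not share shape/region/bin size."""


class UndefinedMetricError(ValueError):
    """The metric is undefined on this input (e.g. constant values)."""


@dataclass(frozen=True)
class StrataSpec:
    """Genomic-separation windows for stratified correlation.

    edges : strictly increasing separation bounds in bins; stratum k covers
        separations ``edges[k] <= |i - j| < edges[k+1]``.  ``None`` means
        dyadic windows 1, 2, 4, ... up to N (spanning scales evenly in
        log-separation).
    min_pairs : minimum pair count for a stratum to be scored (default 10).
    """

    edges: tuple[int, ...] | None = None
    min_pairs: int = 10

    def __post_init__(self) -> None:
        if self.edges is not None:
            e = tuple(self.edges)
            if len(e) < 2 or any(b <= a for a, b in zip(e, e[1:])) or e[0] < 1:
                raise ValueError("edges must be strictly increasing with first >= 1")
            object.__setattr__(self, "edges", e)
        if self.min_pairs < 2:
            raise ValueError("min_pairs must be >= 2")

    def resolve_edges(self, n: int) -> tuple[int, ...]:
        if self.edges is not None:
            return self.edges
        edges = [1]
        while edges[-1] < n:
            edges.append(min(edges[-1] * 2, n))
        return tuple(edges)


@dataclass
class ComparisonResult:
    """Labeled metric values for one pair of matrices.

    global_value is None when undefined (see ``reason``); per_stratum maps
    "lo-hi" separation windows to values or None.
    """

    label_a: str
    label_b: str
    metric: str
    global_value: float | None
    n_pairs: int
    per_stratum: dict[str, float | None] = field(default_factory=dict)
    stratum_n_pairs: dict[str, int] = field(default_factory=dict)
    reason: str | None = None


def _paired_upper(A: SquareMatrix, B: SquareMatrix):
    if not A.aligned_with(B):
        raise AlignmentError(
            f"matrices not aligned: {A.n}x{A.n} {A.region} vs {B.n}x{B.n} {B.region}"
        )
    i, j = np.triu_indices(A.n, k=1)
    ok = A.mask[i] & A.mask[j] & B.mask[i] & B.mask[j]
    i, j = i[ok], j[ok]
    return A.values[i, j], B.values[i, j], j - i


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    """Correlation with explicit degeneracy handling."""
    if a.size < 3:
        raise UndefinedMetricError(f"only {a.size} usable pairs (need >= 3)")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedMetricError("constant values on one side")
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    return float(stats.pearsonr(a, b).statistic)


def _corr_compare(A: SquareMatrix, B: SquareMatrix, method: str) -> ComparisonResult:
    a, b, _ = _paired_upper(A, B)
    value = _corr(a, b, method)
    return ComparisonResult(A.label, B.label, method, value, n_pairs=a.size)


def spearman_compare(A: SquareMatrix, B: SquareMatrix) -> ComparisonResult:
    """Spearman rank correlation over shared unmasked upper-triangle entries.

    Ties get average ranks.  Being rank-based, the result is invariant
    under any strictly increasing transform of either matrix — in
    particular under the power-law contact <-> distance maps — which is why
    it is the metric of choice for matrices whose units are incomparable.
    """
    return _corr_compare(A, B, "spearman")


def pearson_compare(A: SquareMatrix, B: SquareMatrix) -> ComparisonResult:
    """Pearson linear correlation over shared unmasked upper-triangle entries."""
    return _corr_compare(A, B, "pearson")


def kl_divergence(
    A: SquareMatrix,
    B: SquareMatrix,
    direction: Literal["a_to_b", "b_to_a", "jensen_shannon"] = "a_to_b",
    smoothing: float = 0.0,
    power_law: PowerLawMap | None = None,
) -> ComparisonResult:
    """Kullback-Leibler divergence between two matrices, in nats.

    Each matrix is interpreted as an (unnormalized) distribution over bin
    pairs: distance-like matrices are first mapped to contact space through
    *power_law* (KL needs non-negative mass that decays with distance),
    then the shared unmasked upper-triangle entries plus *smoothing* are
    normalized to probability vectors.  ``jensen_shannon`` gives the
    symmetric, ln(2)-bounded variant.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")

    def as_contact(M: SquareMatrix) -> SquareMatrix:
        if M.kind == "contact":
            return M
        return distance_to_contact(M, power_law or PowerLawMap())

    a, b, _ = _paired_upper(as_contact(A), as_contact(B))
    p = a + smoothing
    q = b + smoothing
    if p.sum() == 0 or q.sum() == 0:
        raise UndefinedMetricError("zero total mass on one side")
    p = p / p.sum()
    q = q / q.sum()
    if direction == "a_to_b":
        value = _kl(p, q)
    elif direction == "b_to_a":
        value = _kl(q, p)
    elif direction == "jensen_shannon":
        m = (p + q) / 2.0
        value = 0.5 * _kl(p, m) + 0.5 * _kl(q, m)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return ComparisonResult(A.label, B.label, "kl", float(value), n_pairs=a.size)


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    if np.any((q == 0) & (p > 0)):
        raise UndefinedMetricError(
            "q has zero mass where p is positive; use smoothing > 0"
        )
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / q[nz])))


def stratified_spearman(
    A: SquareMatrix, B: SquareMatrix, strata: StrataSpec = StrataSpec()
) -> ComparisonResult:
    """Spearman correlation per window of genomic separation |i - j|.

    Strata with fewer than ``min_pairs`` usable pairs, or with constant
    values on either side, are reported as undefined (None), never as 0.
    The global Spearman over all pairs is reported alongside.
    """
    a, b, sep = _paired_upper(A, B)
    result = ComparisonResult(
        A.label, B.label, "stratified_spearman",
        global_value=None, n_pairs=a.size,
    )
    try:
        result.global_value = _corr(a, b, "spearman")
    except UndefinedMetricError as exc:
        result.reason = str(exc)
    edges = strata.resolve_edges(A.n)
    for lo, hi in zip(edges[:-1], edges[1:]):
        key = f"{lo}-{hi}"
        in_stratum = (sep >= lo) & (sep < hi)
        result.stratum_n_pairs[key] = int(in_stratum.sum())
        if in_stratum.sum() < strata.min_pairs:
            result.per_stratum[key] = None
            continue
        try:
            result.per_stratum[key] = _corr(a[in_stratum], b[in_stratum], "spearman")
        except UndefinedMetricError:
            result.per_stratum[key] = None
    return result


def fit_exponent(
    distances: SquareMatrix, contacts: SquareMatrix
) -> PowerLawMap:
    """Estimate the power-law exponent a of s ~ (1/d)^a from matched data.

    Least-squares fit of ln(s) on ln(d) over shared unmasked upper-triangle
    pairs with strictly positive values on both sides; a is minus the
    slope.  Raises if fewer than 3 usable pairs remain or the fit is
    degenerate (constant s or d).
    """
    d, s, _ = _paired_upper(distances, contacts)
    usable = (d > 0) & (s > 0)
    d, s = d[usable], s[usable]
    if d.size < 3:
        raise UndefinedMetricError(f"only {d.size} strictly positive pairs (need >= 3)")
    log_d, log_s = np.log(d), np.log(s)
    if np.ptp(log_d) == 0 or np.ptp(log_s) == 0:
        raise UndefinedMetricError("degenerate fit: constant distances or contacts")
    slope, _intercept = np.polyfit(log_d, log_s, 1)
    a = -float(slope)
    if a <= 0:
        raise UndefinedMetricError(
            f"fitted exponent {a:.3g} is not positive; no power-law decay"
        )
    from .matrixops import default_eps

    return PowerLawMap(a=a, eps=default_eps(contacts.values))


def pairwise_table(
    matrices: Sequence[SquareMatrix],
    metric: Literal["spearman", "pearson", "kl"] = "spearman",
    **kwargs,
) -> list[ComparisonResult]:
    """Score all unordered pairs of matrices with one metric.

    Per-pair errors are reported as undefined cells with reasons, so one
    degenerate matrix does not abort the whole table.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices")
    fns = {
        "spearman": spearman_compare,
        "pearson": pearson_compare,
        "kl": kl_divergence,
    }
    try:
        fn = fns[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}") from None
    results = []
    for i in range(len(matrices)):
        for j in range(i + 1, len(matrices)):
            try:
                results.append(fn(matrices[i], matrices[j], **kwargs))
            except (UndefinedMetricError, ZeroDivisionError) as exc:
                results.append(
                    ComparisonResult(
                        matrices[i].label, matrices[j].label, metric,
                        global_value=None, n_pairs=0, reason=str(exc),
                    )
                )
    return results


def table_to_square(
    results: Sequence[ComparisonResult], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Arrange pairwise results as a symmetric label x label DataFrame.

    Correlation tables get a unit diagonal; KL gets a zero diagonal.
    Undefined cells are NaN.
    """
    if labels is None:
        seen: dict[str, None] = {}
        for r in results:
            seen.setdefault(r.label_a)
            seen.setdefault(r.label_b)
        labels = list(seen)
    metric = results[0].metric if results else "spearman"
    diag = 0.0 if metric == "kl" else 1.0
    df = pd.DataFrame(np.nan, index=list(labels), columns=list(labels))
    np.fill_diagonal(df.values, diag)
    for r in results:
        v = np.nan if r.global_value is None else r.global_value
        df.loc[r.label_a, r.label_b] = v
        df.loc[r.label_b, r.label_a] = v
    return df
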