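import math

import numpy as np
import pytest

from chrombench import (
    PowerLawMap,
    StrataSpec,
    contact_to_pseudodistance,
    distance_matrix,
    distance_to_contact,
    fit_exponent,
    kl_divergence,
    pairwise_table,
    pearson_compare,
    spearman_compare,
    stratified_spearman,
    table_to_square,
)
from chrombench.metrics import UndefinedMetricError
from conftest import from_upper, square


# --- independent oracles -----------------------------------------------------

def average_ranks(x):
    """Ranks with ties averaged, by explicit enumeration (no scipy)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1  # average of 1-based positions
        i = j + 1
    return ranks


def spearman_oracle(a, b):
    """Pearson correlation of average ranks, written out longhand."""
    ra, rb = average_ranks(a), average_ranks(b)
    ra, rb = ra - ra.mean(), rb - rb.mean()
    return float((ra * rb).sum() / math.sqrt((ra**2).sum() * (rb**2).sum()))


def kl_oracle(p, q):
    p = np.asarray(p, float) / np.sum(p)
    q = np.asarray(q, float) / np.sum(q)
    return float(sum(pi * math.log(pi / qi) for pi, qi in zip(p, q) if pi > 0))


# --- Spearman / Pearson ------------------------------------------------------

class TestSpearman:
    def test_self_correlation_is_one(self):
        a = from_upper([1, 2, 3, 4, 5, 6], 4)
        assert spearman_compare(a, a).global_value == pytest.approx(1.0)

    def test_strict_reversal_is_minus_one(self):
        a = from_upper([1, 2, 3], 3)
        b = from_upper([3, 2, 1], 3)
        assert spearman_compare(a, b).global_value == pytest.approx(-1.0)

    def test_classical_rank_formula_case(self):
        """Two swapped neighbours: rho = 1 - 6*4/(6*35) per the d^2 formula."""
        a = from_upper([1, 2, 3, 4, 5, 6], 4)
        b = from_upper([2, 1, 3, 4, 6, 5], 4)
        expected = 1 - 6 * 4 / (6 * (6**2 - 1))
        got = spearman_compare(a, b).global_value
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(spearman_oracle(
            [1, 2, 3, 4, 5, 6], [2, 1, 3, 4, 6, 5]), abs=1e-12)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    @pytest.mark.parametrize("rep", range(3))
    def test_matches_brute_force_oracle_small_n(self, n, rep):
        """Random tied-value fixtures at N <= 6 agree with the hand oracle."""
        rng = np.random.default_rng(100 * n + rep)
        k = n * (n - 1) // 2
        ua = ub = np.zeros(k)
        while np.ptp(ua) == 0 or np.ptp(ub) == 0:
            ua = rng.integers(0, 4, size=k).astype(float)  # ties likely
            ub = rng.integers(0, 4, size=k).astype(float)
        got = spearman_compare(from_upper(ua, n), from_upper(ub, n)).global_value
        assert got == pytest.approx(spearman_oracle(ua, ub), abs=1e-9)

    def test_constant_input_reported_undefined(self):
        a = from_upper([1, 1, 1], 3)
        b = from_upper([1, 2, 3], 3)
        with pytest.raises(UndefinedMetricError, match="constant"):
            spearman_compare(a, b)

    def test_shape_mismatch_rejected(self):
        a = from_upper([1, 2, 3], 3)
        b = from_upper([1, 2, 3, 4, 5, 6], 4)
        from chrombench.metrics import AlignmentError
        with pytest.raises(AlignmentError):
            spearman_compare(a, b)

    def test_mask_restricts_pairs(self):
        a = from_upper(np.arange(1.0, 11.0), 5)
        b = from_upper(np.arange(10.0, 0.0, -1.0), 5)
        r = spearman_compare(a, b)
        assert r.n_pairs == 10
        a_masked = from_upper(np.arange(1.0, 11.0), 5,
                              mask=np.array([True, True, True, True, False]))
        r2 = spearman_compare(a_masked, b)
        assert r2.n_pairs == 6  # pairs among 4 unmasked bins

    @pytest.mark.parametrize("transform", [np.exp, lambda x: x**3,
                                           lambda x: 2 * x + 3])
    def test_invariant_under_increasing_transforms(self, transform):
        rng = np.random.default_rng(17)
        ua = rng.random(15)
        ub = rng.random(15)
        base = spearman_compare(from_upper(ua, 6), from_upper(ub, 6)).global_value
        warped = spearman_compare(
            from_upper(transform(ua), 6), from_upper(ub, 6)
        ).global_value
        assert warped == pytest.approx(base, abs=1e-12)

    def test_rank_preserving_power_law_round_trip(self, random_walk_model):
        """distances vs pseudodistance(contact(distances)) correlate exactly 1."""
        d = distance_matrix(random_walk_model)
        round_tripped = contact_to_pseudodistance(
            distance_to_contact(d, PowerLawMap(a=1.8)),
            PowerLawMap(a=1.8, eps=0),
        )
        assert spearman_compare(d, round_tripped).global_value == \
            pytest.approx(1.0, abs=1e-12)


class TestPearson:
    def test_self_and_affine(self):
        rng = np.random.default_rng(3)
        ua = rng.random(10)
        a = from_upper(ua, 5)
        b = from_upper(2 * ua + 3, 5)
        assert pearson_compare(a, a).global_value == pytest.approx(1.0)
        assert pearson_compare(a, b).global_value == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(13)
        ua, ub = rng.random(6), rng.random(6)
        got = pearson_compare(from_upper(ua, 4), from_upper(ub, 4)).global_value
        x, y = ua - ua.mean(), ub - ub.mean()
        expected = (x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum())
        assert got == pytest.approx(float(expected), abs=1e-12)


# --- KL ---------------------------------------------------------------------

class TestKL:
    def test_identical_matrices_zero(self):
        a = from_upper([1, 2, 3, 4, 5, 6], 4, kind="contact")
        assert kl_divergence(a, a).global_value == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_three_pair_case(self):
        """P=(1/2,1/4,1/4) vs uniform Q: ln(3/2)/2 + ln(3/4)/2 nats."""
        p = from_upper([2, 1, 1], 3, kind="contact")
        q = from_upper([1, 1, 1], 3, kind="contact")
        expected = 0.5 * math.log(3 / 2) + 0.5 * math.log(3 / 4)
        got = kl_divergence(p, q).global_value
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.0589, abs=1e-4)
        assert got == pytest.approx(kl_oracle([2, 1, 1], [1, 1, 1]), abs=1e-12)

    @pytest.mark.parametrize("rep", range(4))
    def test_matches_direct_summation_oracle(self, rep):
        rng = np.random.default_rng(rep)
        ua = rng.random(10) + 0.1
        ub = rng.random(10) + 0.1
        got = kl_divergence(
            from_upper(ua, 5, kind="contact"), from_upper(ub, 5, kind="contact")
        ).global_value
        assert got == pytest.approx(kl_oracle(ua, ub), abs=1e-9)

    def test_nonnegative(self):
        rng = np.random.default_rng(55)
        for _ in range(10):
            ua = rng.random(6) + 0.01
            ub = rng.random(6) + 0.01
            assert kl_divergence(
                from_upper(ua, 4, kind="contact"),
                from_upper(ub, 4, kind="contact"),
            ).global_value >= -1e-15

    def test_jensen_shannon_symmetric_and_bounded(self):
        a = from_upper([5, 1, 1, 1, 1, 1], 4, kind="contact")
        b = from_upper([1, 1, 1, 1, 1, 5], 4, kind="contact")
        ab = kl_divergence(a, b, direction="jensen_shannon").global_value
        ba = kl_divergence(b, a, direction="jensen_shannon").global_value
        assert ab == pytest.approx(ba, abs=1e-12)
        assert 0 <= ab <= math.log(2)

    def test_direction_asymmetry(self):
        a = from_upper([5, 1, 1], 3, kind="contact")
        b = from_upper([1, 1, 5], 3, kind="contact")
        assert kl_divergence(a, b, "a_to_b").global_value == pytest.approx(
            kl_divergence(b, a, "b_to_a").global_value, abs=1e-12
        )

    def test_zero_support_requires_smoothing(self):
        a = from_upper([1, 1, 1], 3, kind="contact")
        b = from_upper([0, 1, 1], 3, kind="contact")
        with pytest.raises(UndefinedMetricError, match="smoothing"):
            kl_divergence(a, b)
        assert kl_divergence(a, b, smoothing=0.5).global_value > 0

    def test_distance_inputs_mapped_to_contact_space(self, random_walk_model):
        """KL between a distance matrix and itself via the power law is 0."""
        d = distance_matrix(random_walk_model)
        got = kl_divergence(d, d, power_law=PowerLawMap(a=1.0))
        assert got.global_value == pytest.approx(0.0, abs=1e-15)


# --- stratified --------------------------------------------------------------

class TestStratified:
    def test_identity_every_defined_stratum_one(self):
        rng = np.random.default_rng(21)
        n = 20
        vals = rng.random((n, n))
        vals = np.triu(vals, 1)
        a = square(vals + vals.T, kind="distance")
        r = stratified_spearman(a, a, StrataSpec(min_pairs=5))
        defined = {k: v for k, v in r.per_stratum.items() if v is not None}
        assert defined and all(v == pytest.approx(1.0) for v in defined.values())

    def test_noise_near_diagonal_degrades_near_strata(self):
        """Heavy noise at separations <= 2 hurts the near stratum most."""
        rng = np.random.default_rng(31)
        n = 40
        base = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        base += rng.random((n, n)) * 0.2
        base = (base + base.T) / 2
        np.fill_diagonal(base, 0)
        a = square(base, kind="distance")
        noisy = base.copy()
        sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        near = (sep >= 1) & (sep <= 2)
        noise = rng.random((n, n)) * 50
        noise = (noise + noise.T) / 2
        noisy[near] = noise[near]
        noisy = (noisy + noisy.T) / 2
        b = square(noisy, kind="distance")
        r = stratified_spearman(a, b, StrataSpec(edges=(1, 4, n), min_pairs=5))
        near_rho = r.per_stratum[f"1-4"]
        far_rho = r.per_stratum[f"4-{n}"]
        assert near_rho < far_rho

    def test_per_stratum_matches_rank_oracle(self):
        from test_metrics import spearman_oracle  # self-import for clarity
        rng = np.random.default_rng(41)
        n = 12
        va = rng.random((n, n)); va = np.triu(va, 1); va += va.T
        vb = rng.random((n, n)); vb = np.triu(vb, 1); vb += vb.T
        a, b = square(va, kind="distance"), square(vb, kind="distance")
        r = stratified_spearman(a, b, StrataSpec(edges=(1, 3, 6, n), min_pairs=3))
        iu, ju = np.triu_indices(n, k=1)
        sepu = ju - iu
        for (lo, hi) in [(1, 3), (3, 6), (6, n)]:
            sel = (sepu >= lo) & (sepu < hi)
            expected = spearman_oracle(va[iu[sel], ju[sel]], vb[iu[sel], ju[sel]])
            assert r.per_stratum[f"{lo}-{hi}"] == pytest.approx(expected, abs=1e-9)

    def test_tied_stratum_undefined_not_zero(self):
        n = 8
        vals = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        a = square(vals, kind="distance")
        # every stratum of |i-j| has constant value in a -> all undefined
        r = stratified_spearman(a, a, StrataSpec(edges=(1, 2, 3), min_pairs=2))
        assert r.per_stratum["1-2"] is None
        assert r.per_stratum["2-3"] is None

    def test_small_strata_skipped_by_min_pairs(self):
        rng = np.random.default_rng(51)
        n = 10
        va = rng.random((n, n)); va = np.triu(va, 1); va += va.T
        a = square(va, kind="distance")
        r = stratified_spearman(a, a, StrataSpec(edges=(8, n), min_pairs=10))
        assert r.per_stratum[f"8-{n}"] is None  # only 3 pairs at sep >= 8
        assert r.stratum_n_pairs[f"8-{n}"] == 3

    def test_default_dyadic_edges(self):
        assert StrataSpec().resolve_edges(20) == (1, 2, 4, 8, 16, 20)


# --- exponent fit ------------------------------------------------------------

class TestFitExponent:
    def test_exact_power_law_recovered(self, random_walk_model):
        d = distance_matrix(random_walk_model)
        s = distance_to_contact(d, PowerLawMap(a=2.0))
        assert fit_exponent(d, s).a == pytest.approx(2.0, abs=1e-9)

    def test_noiseless_and_noisy_recovery_at_n100(self):
        rng = np.random.default_rng(61)
        n = 100
        coords = np.cumsum(rng.standard_normal((n, 3)), axis=0)
        from chrombench import GenomicRegion, PolymerModel
        d = distance_matrix(
            PolymerModel(coords, GenomicRegion("c", 0, n * 100), 100)
        )
        s_clean = distance_to_contact(d, PowerLawMap(a=1.5))
        assert fit_exponent(d, s_clean).a == pytest.approx(1.5, abs=0.1)
        noise = np.exp(rng.normal(0, 0.05, size=(n, n)))
        noise = (noise + noise.T) / 2
        noisy_vals = s_clean.values * noise
        np.fill_diagonal(noisy_vals, 0)
        s_noisy = square(noisy_vals, kind="contact", bp=100,
                         region=d.region)
        assert fit_exponent(d, s_noisy).a == pytest.approx(1.5, abs=0.1)

    def test_constant_contacts_degenerate(self):
        d = from_upper([1, 2, 3], 3, kind="distance")
        s = from_upper([1, 1, 1], 3, kind="contact")
        with pytest.raises(UndefinedMetricError, match="degenerate"):
            fit_exponent(d, s)

    def test_too_few_pairs(self):
        d = from_upper([1.0], 2, kind="distance")
        s = from_upper([1.0], 2, kind="contact")
        with pytest.raises(UndefinedMetricError):
            fit_exponent(d, s)


# --- pairwise tables ---------------------------------------------------------

class TestPairwiseTable:
    def _matrices(self, k=5, n=8):
        rng = np.random.default_rng(71)
        out = []
        for idx in range(k):
            v = rng.random((n, n))
            v = np.triu(v, 1)
            out.append(square(v + v.T, kind="distance", label=f"m{idx}"))
        return out

    def test_all_unordered_pairs_scored(self):
        mats = self._matrices()
        results = pairwise_table(mats, "spearman")
        assert len(results) == 10

    def test_each_cell_matches_direct_call(self):
        mats = self._matrices()
        results = pairwise_table(mats, "spearman")
        for r in results:
            ia = int(r.label_a[1:]); ib = int(r.label_b[1:])
            direct = spearman_compare(mats[ia], mats[ib]).global_value
            assert r.global_value == pytest.approx(direct, abs=1e-12)

    def test_square_table_symmetric_unit_diagonal(self):
        mats = self._matrices()
        df = table_to_square(pairwise_table(mats, "spearman"),
                             labels=[m.label for m in mats])
        assert np.allclose(df.values, df.values.T, equal_nan=True)
        assert np.allclose(np.diag(df.values), 1.0)

    def test_degenerate_pair_becomes_undefined_cell(self):
        mats = self._matrices(3)
        flat = from_upper(np.ones(28), 8, kind="distance")
        flat.label = "flat"
        results = pairwise_table(mats + [flat], "spearman")
        broken = [r for r in results if "flat" in (r.label_a, r.label_b)]
        assert broken and all(r.global_value is None for r in broken)
        assert all(r.reason for r in broken)

    def test_needs_two_matrices(self):
        with pytest.raises(ValueError):
            pairwise_table(self._matrices(1))
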