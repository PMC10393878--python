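"""Accuracy metric, paired statistics and the sweep harness."""

import itertools

import numpy as np
import pytest
from scipy.stats import wilcoxon as scipy_wilcoxon

from vffrcfd import (StatsError, StenosisSpec, accuracy_pct, bland_altman,
                     concordance_at_threshold, fidelity_sweep, pair_table,
                     reference_duration_contrast,
                     regression_with_slope_compare, wilcoxon_signed_rank)


class TestAccuracy:
    def test_identity_and_symmetry(self):
        assert accuracy_pct(0.80, 0.80) == 100.0
        assert accuracy_pct(0.79, 0.80) == pytest.approx(98.75)
        assert accuracy_pct(0.81, 0.80) == pytest.approx(98.75)

    def test_rejects_nonpositive_reference(self):
        with pytest.raises(StatsError):
            accuracy_pct(0.8, 0.0)

    def test_consistent_with_difference(self):
        tab = pair_table(["a", "b"], [0.8, 0.7], [0.8, 0.65])
        assert (tab["accuracy_pct"] == 100.0).tolist() == [True, False]
        assert (tab["difference"] == 0.0).tolist() == [True, False]


def brute_force_signed_rank_p(d):
    """Exhaustive two-sided p over all 2^n sign assignments (midranks)."""
    d = np.asarray(d, dtype=float)
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(len(d))
    sa = absd[order]
    i, pos = 0, 1
    while i < len(d):
        j = i
        while j + 1 < len(d) and sa[j + 1] == sa[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (pos + pos + j - i)
        pos += j - i + 1
        i = j + 1
    w_obs = ranks[d > 0].sum()
    ws = np.array([np.dot(signs, ranks) for signs in
                   itertools.product([0, 1], repeat=len(d))])
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_positive_n10_exact(self):
        w = wilcoxon_signed_rank(np.arange(1.0, 11.0))
        assert w.p_value == pytest.approx(2.0 / 2 ** 10)

    @pytest.mark.parametrize("seed,n", [(0, 8), (1, 10), (2, 12), (3, 7)])
    def test_matches_exhaustive_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(0.4, 1.0, n), 2)
        d = d[d != 0]
        w = wilcoxon_signed_rank(d)
        assert w.p_value == pytest.approx(brute_force_signed_rank_p(d),
                                          abs=1e-12)

    def test_matches_scipy_exact_and_approx(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.3, 1.0, 15)
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(
            scipy_wilcoxon(d, method="exact").pvalue)
        d = rng.normal(0.1, 1.0, 60)
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(
            scipy_wilcoxon(d, correction=True, method="approx").pvalue,
            rel=1e-9)

    def test_antisymmetric_differences(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        w = wilcoxon_signed_rank(d)
        assert w.p_value > 0.9
        assert w.median_difference == 0.0

    def test_degenerate_inputs(self):
        with pytest.raises(StatsError):
            wilcoxon_signed_rank(np.zeros(10))
        with pytest.raises(StatsError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0])

    def test_achievable_ci_levels(self):
        rng = np.random.default_rng(11)
        d = rng.normal(0.5, 1.0, 40)
        w = wilcoxon_signed_rank(d, confidence=0.95)
        # binomial order-statistic discreteness at n=40 gives exactly 96.15%
        assert w.achieved_level == pytest.approx(0.9615, abs=5e-5)
        assert w.ci_low <= w.median_difference <= w.ci_high
        assert w.hl_ci_low <= w.hl_ci_high
        assert 0.90 <= w.hl_achieved_level <= 0.99


class TestBlandAltman:
    def test_constant_differences(self):
        ba = bland_altman(np.full(8, 0.37))
        assert ba.bias == pytest.approx(0.37)
        assert ba.loa_low == pytest.approx(0.37)
        assert ba.loa_high == pytest.approx(0.37)

    def test_hand_computation(self):
        ba = bland_altman([-1.0, 0.0, 1.0])
        assert ba.bias == 0.0
        assert ba.loa_high == pytest.approx(1.96)

    def test_recomputation_on_random_fixture(self):
        rng = np.random.default_rng(40)
        d = rng.normal(0.005, 0.01, 40)
        ba = bland_altman(d)
        mean = d.sum() / len(d)
        sd = np.sqrt(((d - mean) ** 2).sum() / (len(d) - 1))
        assert ba.bias == pytest.approx(mean, rel=1e-12)
        assert ba.loa_low == pytest.approx(mean - 1.96 * sd, rel=1e-12)

    def test_insufficient_pairs(self):
        with pytest.raises(StatsError):
            bland_altman([0.1, 0.2])


class TestRegressionCompare:
    def test_perfectly_collinear_group(self):
        x = np.linspace(0, 1, 20)
        rng = np.random.default_rng(0)
        res = regression_with_slope_compare(
            {"exact": (x, 2 * x + 1),
             "noisy": (x, x + rng.normal(0, 0.1, 20))})
        row = res.per_group.loc["exact"]
        assert row["slope"] == pytest.approx(2.0)
        assert row["intercept"] == pytest.approx(1.0)
        assert row["r2"] == pytest.approx(1.0)

    def test_type_one_error_and_power(self):
        rng = np.random.default_rng(314)
        x = np.linspace(0, 1, 100)
        same, diff = 0, 0
        reps = 100
        for _ in range(reps):
            ya = 1.0 + 1.0 * x + rng.normal(0, 0.05, 100)
            yb = 0.5 + 1.0 * x + rng.normal(0, 0.05, 100)
            yc = 0.5 + 3.0 * x + rng.normal(0, 0.05, 100)
            same += regression_with_slope_compare(
                {"a": (x, ya), "b": (x, yb)}).p_value > 0.05
            diff += regression_with_slope_compare(
                {"a": (x, ya), "c": (x, yc)}).p_value < 0.001
        assert same >= 0.90 * reps
        assert diff >= 0.95 * reps

    def test_zero_variance_group(self):
        with pytest.raises(StatsError):
            regression_with_slope_compare(
                {"flat": (np.ones(10), np.arange(10.0))})


class TestConcordance:
    def test_threshold_straddle_flips_decision(self):
        r = concordance_at_threshold([0.79], [0.81])
        assert r.percent == 0.0

    def test_all_equal(self):
        v = np.linspace(0.4, 0.95, 12)
        assert concordance_at_threshold(v, v).percent == 100.0

    def test_counting(self):
        ref = [0.79, 0.78] + [0.5] * 4 + [0.9] * 4
        test = [0.81, 0.82] + [0.5] * 4 + [0.9] * 4
        r = concordance_at_threshold(ref, test, case_ids=list("abcdefghij"))
        assert r.percent == pytest.approx(80.0)
        assert set(r.discordant) == {"a", "b"}


@pytest.fixture(scope="module")
def tiny_sweep():
    specs = [
        StenosisSpec(3.0, 45.0, 9.0, 24.5, 30.0, case_id="mild"),
        StenosisSpec(3.2, 60.0, 10.0, 24.0, 30.0, case_id="moderate"),
        StenosisSpec(3.5, 35.0, 10.0, 24.0, 30.0, case_id="mild2"),
    ]
    return fidelity_sweep(specs, fidelities=(10, 50), n_min=600, n_max=3000)


class TestSweepHarness:
    def test_records_shape_and_pairing(self, tiny_sweep):
        recs = tiny_sweep.records
        assert set(recs["case_id"]) == {"mild", "moderate", "mild2"}
        assert (recs["method"] == "reference").sum() == 3
        assert tiny_sweep.n_analyzed == 3
        pairs = tiny_sweep.pairs
        assert len(pairs) == 6          # 3 cases x 2 fidelities
        assert (pairs["duration_s"] > 0).all()
        assert ((pairs["vffr_test"] > 0) & (pairs["vffr_test"] <= 1)).all()

    def test_finer_meshes_take_longer(self, tiny_sweep):
        med = tiny_sweep.summary.set_index("fidelity_percent")
        assert (med.loc[50, "median_duration_s"]
                > med.loc[10, "median_duration_s"])

    def test_reference_duration_contrast_poolings(self, tiny_sweep):
        pooled = reference_duration_contrast(tiny_sweep, "pooled")
        # the reference mesh is finer, so it always takes longer
        assert pooled.median_difference > 0
        assert pooled.n == len(tiny_sweep.pairs)
        # per-case-median pooling needs >= 5 analyzable cases
        with pytest.raises(StatsError):
            reference_duration_contrast(tiny_sweep, "case_median")
        with pytest.raises(StatsError):
            reference_duration_contrast(tiny_sweep, "bogus")

    def test_healthy_tube_accuracy_is_near_perfect(self):
        specs = [StenosisSpec(3.0, 0.0, 9.0, 24.5, 30.0, case_id="tube")]
        sw = fidelity_sweep(specs, fidelities=(10, 50), n_min=600, n_max=3000)
        assert sw.n_analyzed == 1
        assert (sw.pairs["accuracy_pct"] > 99.5).all()
        assert (sw.pairs["vffr_test"] > 0.9).all()
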