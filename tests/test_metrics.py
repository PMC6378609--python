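import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from roifinder.metrics import (
    ablation_response,
    binomial_ci_exact,
    binomial_ci_wilson,
    cycle_length,
    driver_metrics,
    evaluate_detection,
    fisher_exact,
    lvz_classify,
    percent,
)
from roifinder.roi import ROISite
from roifinder.simulate import AFDriverProfile, sample_driver_runs


def mk_site(xyz, runs):
    return ROISite("e", np.asarray(xyz, float), list(runs), 0.0, 30000.0)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def exact_ci_bisect(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact interval by bisection on the binomial CDF (no beta quantiles)."""
    alpha = 1.0 - level

    def solve(f, lo, hi):
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid):
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    low = 0.0 if k == 0 else solve(lambda p: sps.binom.sf(k - 1, n, p) < alpha / 2, 0.0, 1.0)
    high = 1.0 if k == n else solve(lambda p: sps.binom.cdf(k, n, p) >= alpha / 2, 0.0, 1.0)
    return low, high


def fisher_enumerate(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration over margin-fixed tables."""
    r1, c1, N = a + b, a + c, a + b + c + d
    rv = sps.hypergeom(N, c1, r1)
    obs = rv.pmf(a)
    xs = np.arange(max(0, c1 - (N - r1)), min(r1, c1) + 1)
    pm = rv.pmf(xs)
    return float(np.sum(pm[pm <= obs * (1 + 1e-9)]))


# ---------------------------------------------------------------------------
# driver metrics
# ---------------------------------------------------------------------------


class TestDriverMetrics:
    def test_consistency_6_of_8(self):
        hit = [mk_site([0, 0, 0], [3])]
        maps = [hit] * 6 + [[]] * 2
        m = driver_metrics(maps, [0, 0, 0])
        assert m.consistency == pytest.approx(0.75)

    def test_stability_mean_of_runs(self):
        maps = [[mk_site([0, 0, 0], [3, 3])], [mk_site([0, 0, 0], [4, 3])]]
        m = driver_metrics(maps, [0, 0, 0])
        assert m.temporal_stability == pytest.approx(3.25)
        assert m.recurrence_rate == pytest.approx(2.0)

    def test_uncovered_maps_excluded_from_denominator(self):
        maps = [[mk_site([0, 0, 0], [2])], None, None, []]
        m = driver_metrics(maps, [0, 0, 0])
        assert m.maps_covered == 2 and m.consistency == pytest.approx(0.5)

    def test_zero_maps_rejected(self):
        with pytest.raises(ValueError):
            driver_metrics([], [0, 0, 0])


class TestCycleLength:
    def test_metronomic(self):
        lats = np.arange(31) * 150.0
        assert cycle_length(lats) == pytest.approx(150.0)

    def test_alternans_mean(self):
        lats = np.cumsum([0.0] + [140.0, 160.0] * 15)
        assert cycle_length(lats) == pytest.approx(150.0)

    def test_too_few_rejected_with_count(self):
        with pytest.raises(ValueError, match="got 10"):
            cycle_length(np.arange(10) * 150.0)


class TestClinicalRules:
    @pytest.mark.parametrize(
        "pre,post,term,label",
        [
            (145.0, 180.0, False, "cl_slowing"),
            (145.0, 170.0, False, "none"),
            (145.0, 175.0, False, "cl_slowing"),  # exactly +30 ms counts
            (145.0, 120.0, True, "termination"),
        ],
    )
    def test_ablation_response(self, pre, post, term, label):
        assert ablation_response(pre, post, term) == label

    @pytest.mark.parametrize("v,expected", [(0.49, True), (0.5, False), (1.2, False)])
    def test_lvz_strict(self, v, expected):
        assert lvz_classify(v) is expected

    def test_negative_voltage_rejected(self):
        with pytest.raises(ValueError):
            lvz_classify(-0.1)


# ---------------------------------------------------------------------------
# accuracy statistics
# ---------------------------------------------------------------------------


class TestBinomialCI:
    def test_sequential_row_values(self):
        lo, hi = binomial_ci_exact(22, 30)
        assert lo == pytest.approx(0.541, abs=0.005)
        assert hi == pytest.approx(0.877, abs=0.005)
        assert (percent(lo), percent(hi)) == (54, 88)

    @pytest.mark.parametrize("k,n", [(0, 10), (10, 10), (1, 7), (22, 30), (15, 40)])
    def test_matches_bisection_oracle(self, k, n):
        got = binomial_ci_exact(k, n)
        want = exact_ci_bisect(k, n)
        assert got == pytest.approx(want, abs=1e-6)

    def test_boundaries(self):
        assert binomial_ci_exact(0, 10)[0] == 0.0
        assert binomial_ci_exact(10, 10)[1] == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci_exact(5, 3)

    def test_wilson_contains_point(self):
        lo, hi = binomial_ci_wilson(22, 30)
        assert lo < 22 / 30 < hi

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        got = binomial_ci_exact(22, 30)
        want = proportion_confint(22, 30, method="beta")
        assert got == pytest.approx(want, abs=1e-9)


class TestFisher:
    def test_termination_table_below_bound(self):
        assert fisher_exact(17, 5, 0, 8) <= 0.001

    def test_balanced_table_p_one(self):
        assert fisher_exact(5, 5, 5, 5) == pytest.approx(1.0)

    @given(
        st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)
    )
    def test_matches_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_exact(a, b, c, d) == pytest.approx(fisher_enumerate(a, b, c, d), abs=1e-9)

    def test_row_and_column_swap_symmetry(self):
        p = fisher_exact(17, 5, 0, 8)
        assert fisher_exact(0, 8, 17, 5) == pytest.approx(p)
        assert fisher_exact(5, 17, 8, 0) == pytest.approx(p)


class TestEvaluateDetection:
    def _layout(self, n_ref=30, n_hit=22, n_ctrl=50):
        refs = [[60.0 * i, 0.0, 0.0] for i in range(n_ref)]
        rois = [[60.0 * i + 3.0, 0.0, 0.0] for i in range(n_hit)]
        ctrls = [[60.0 * i + 30.0, 100.0, 0.0] for i in range(n_ctrl)]
        return rois, refs, ctrls

    def test_sequential_row_reproduced(self):
        rois, refs, ctrls = self._layout()
        res = evaluate_detection(rois, refs, ctrls)
        assert (res.tp, res.fn) == (22, 8)
        assert res.sensitivity.as_printed() == "73 (54-88)"

    def test_perfect_detection(self):
        rois, refs, ctrls = self._layout(10, 10, 50)
        res = evaluate_detection(rois, refs, ctrls)
        assert res.sensitivity.point == 1.0 and res.specificity.point == 1.0
        assert res.fp == 0

    def test_exact_10mm_is_a_miss(self):
        refs = [[0.0, 0.0, 0.0]]
        rois = [[10.0, 0.0, 0.0]]
        ctrls = [[100.0, 0.0, 0.0]]
        res = evaluate_detection(rois, refs, ctrls)
        assert res.tp == 0 and res.fn == 1 and res.fp == 1

    def test_empty_references_flagged(self):
        res = evaluate_detection([[0, 0, 0]], [], [[100.0, 0, 0]])
        assert res.sensitivity_undefined and res.sensitivity is None
        assert res.specificity is not None

    def test_controls_too_close_rejected(self):
        with pytest.raises(ValueError, match="control"):
            evaluate_detection([], [[0, 0, 0]], [[15.0, 0, 0]])

    @given(
        n_ref=st.integers(1, 8),
        n_roi=st.integers(0, 8),
        n_ctrl=st.integers(0, 8),
        seed=st.integers(0, 1000),
    )
    def test_confusion_count_invariants(self, n_ref, n_roi, n_ctrl, seed):
        rng = np.random.default_rng(seed)
        refs = rng.uniform(-200, 200, size=(n_ref, 3))
        rois = rng.uniform(-200, 200, size=(n_roi, 3))
        ctrls = rng.uniform(500, 900, size=(n_ctrl, 3))
        res = evaluate_detection(rois, refs, ctrls)
        assert res.tp + res.fn == n_ref
        assert res.fp >= 0 and res.tn >= 0 and res.tn <= n_ctrl


class TestCohortGroupDifference:
    def test_termination_profile_separates_from_slowing(self):
        """Drivers sampled at the termination profile (stability 3.6,
        recurrence 12.2) rank above cl-slowing drivers (2.7, 8.4)."""
        rng = np.random.default_rng(42)

        def cohort(recurrence, run_mean, n=20):
            stab, rec = [], []
            for _ in range(n):
                runs = sample_driver_runs(
                    AFDriverProfile(recurrence_per_30s=recurrence, run_length_mean=run_mean),
                    30000.0,
                    rng,
                )
                rec.append(len(runs))
                stab.append(np.mean([len(r) for r in runs]) if runs else 0.0)
            return np.array(stab), np.array(rec)

        stab_t, rec_t = cohort(12.2, 3.6)
        stab_s, rec_s = cohort(8.4, 2.7)
        assert sps.mannwhitneyu(stab_t, stab_s, alternative="greater").pvalue < 0.01
        assert sps.mannwhitneyu(rec_t, rec_s, alternative="greater").pvalue < 0.01
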