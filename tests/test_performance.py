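import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vbmpattern as vp
from vbmpattern.performance import (
    ConfusionCounts,
    format_permutation_p,
    performance_report,
    permutation_test,
    predicted_case_fraction,
    round_half_up_percent,
)

from conftest import make_separable_matrix

STUDY_COUNTS = ConfusionCounts(
    hits=18, misses=4, false_alarms=6, correct_rejections=21
)


def oracle_report(h, m, fa, cr):
    """Independent recomputation with plain Python and the stdlib normal
    quantile (no scipy)."""
    z = statistics.NormalDist().inv_cdf
    n_cases, n_controls = h + m, fa + cr
    clip = lambda r, n: min(max(r, 1 / (2 * n)), 1 - 1 / (2 * n))
    return {
        "accuracy": (h + cr) / (h + m + fa + cr),
        "sensitivity": h / n_cases,
        "specificity": cr / n_controls,
        "ppv": h / (h + fa) if h + fa else None,
        "npv": cr / (cr + m) if cr + m else None,
        "d_prime": z(clip(h / n_cases, n_cases)) - z(clip(fa / n_controls, n_controls)),
    }


class TestConfusionCounts:
    def test_balanced_study_layout(self):
        true = np.array(["case"] * 22 + ["control"] * 27)
        pred = np.array(
            ["case"] * 18 + ["control"] * 4 + ["case"] * 6 + ["control"] * 21
        )
        assert vp.confusion_counts(true, pred) == STUDY_COUNTS

    def test_perfect_prediction(self):
        true = np.array(["case", "control", "case"])
        c = vp.confusion_counts(true, true)
        assert (c.misses, c.false_alarms) == (0, 0)

    def test_inverted_prediction(self):
        true = np.array(["case", "control"])
        pred = np.array(["control", "case"])
        c = vp.confusion_counts(true, pred)
        assert (c.hits, c.correct_rejections) == (0, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            vp.confusion_counts(np.array(["case"]), np.array(["case", "case"]))


class TestPerformanceReport:
    def test_study_sample_metrics(self):
        rep = performance_report(STUDY_COUNTS)
        assert round_half_up_percent(rep.accuracy) == 80
        assert round_half_up_percent(rep.sensitivity) == 82
        assert round_half_up_percent(rep.specificity) == 78
        assert round_half_up_percent(rep.ppv) == 75
        assert round_half_up_percent(rep.npv) == 84
        assert rep.d_prime == pytest.approx(1.67, abs=0.005)

    def test_perfect_counts_clip_dprime(self):
        rep = performance_report(ConfusionCounts(1, 0, 0, 1))
        assert rep.accuracy == rep.sensitivity == rep.specificity == 1
        assert rep.ppv == rep.npv == 1
        assert np.isfinite(rep.d_prime)

    def test_chance_symmetry(self):
        rep = performance_report(ConfusionCounts(5, 5, 5, 5))
        assert rep.accuracy == 0.5
        assert rep.d_prime == pytest.approx(0, abs=1e-12)

    def test_undefined_ppv_reported_missing(self):
        rep = performance_report(ConfusionCounts(0, 3, 0, 3))
        assert rep.ppv is None
        assert "--" in rep.summary()

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        h=st.integers(0, 50), m=st.integers(0, 50),
        fa=st.integers(0, 50), cr=st.integers(0, 50),
    )
    def test_agrees_with_independent_oracle(self, h, m, fa, cr):
        if h + m == 0 or fa + cr == 0:
            return
        rep = performance_report(ConfusionCounts(h, m, fa, cr))
        exp = oracle_report(h, m, fa, cr)
        for key in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            got = getattr(rep, key)
            if exp[key] is None:
                assert got is None
            else:
                assert got == pytest.approx(exp[key], abs=1e-12)
        assert rep.d_prime == pytest.approx(exp["d_prime"], abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        h=st.integers(0, 40), m=st.integers(0, 40),
        fa=st.integers(0, 40), cr=st.integers(0, 40),
    )
    def test_accuracy_decomposes_over_prevalence(self, h, m, fa, cr):
        if h + m == 0 or fa + cr == 0:
            return
        rep = performance_report(ConfusionCounts(h, m, fa, cr))
        prev = (h + m) / (h + m + fa + cr)
        assert rep.accuracy == pytest.approx(
            rep.sensitivity * prev + rep.specificity * (1 - prev), abs=1e-12
        )


class TestDprime:
    def test_study_value(self):
        assert vp.dprime(18 / 22, 6 / 27, 22, 27) == pytest.approx(1.67, abs=0.005)

    def test_equal_rates_zero(self):
        assert vp.dprime(0.3, 0.3, 20, 20) == pytest.approx(0, abs=1e-12)

    def test_standard_quantile_pair(self):
        # Phi^-1(0.97725) ~ 2.00, Phi^-1(0.5) = 0
        assert vp.dprime(0.97725, 0.5, 1000, 1000) == pytest.approx(2.00, abs=0.005)

    def test_boundary_rates_clipped(self):
        d = vp.dprime(1.0, 0.0, 22, 27)
        z = statistics.NormalDist().inv_cdf
        assert d == pytest.approx(z(1 - 1 / 44) - z(1 / 54), abs=1e-9)


class TestExtrapolation:
    def test_tenfold_controls(self):
        ppv, npv = vp.extrapolate_predictive_values(18 / 22, 21 / 27, 22, 270)
        assert round_half_up_percent(ppv) == 23
        assert round_half_up_percent(npv) == 98

    def test_general_population_sample(self):
        ppv, npv = vp.extrapolate_predictive_values(0.67, 0.59, 60, 816)
        assert round_half_up_percent(ppv) == 11
        assert round_half_up_percent(npv) == 96
        frac = predicted_case_fraction(0.67, 0.59, 60, 816)
        assert round_half_up_percent(frac) == 43

    def test_perfect_rates(self):
        assert vp.extrapolate_predictive_values(1, 1, 5, 500) == (1.0, 1.0)

    def test_original_sizes_reproduce_unextrapolated_values(self):
        rep = performance_report(STUDY_COUNTS)
        ppv, npv = vp.extrapolate_predictive_values(
            rep.sensitivity, rep.specificity, 22, 27
        )
        assert ppv == pytest.approx(rep.ppv, abs=1e-12)
        assert npv == pytest.approx(rep.npv, abs=1e-12)


@pytest.fixture(scope="module")
def small_setup():
    matrix = make_separable_matrix(n_cases=5, n_controls=6, gap=0.4, seed=2)
    cfg = vp.CVConfig(
        n_iterations=20, seed=2, selection=vp.SelectionConfig(z_threshold=1.5)
    )
    return matrix, cfg


class TestPermutationTest:
    def test_p_string_bound_convention(self):
        assert format_permutation_p(0, 1000) == "< 0.001"
        assert format_permutation_p(70, 1000) == "0.07"

    def test_sentinel_observed_brackets_p(self, small_setup):
        matrix, cfg = small_setup
        hi = permutation_test(matrix, cfg, 10, seed=1, observed_accuracy=np.inf)
        lo = permutation_test(matrix, cfg, 10, seed=1, observed_accuracy=-np.inf)
        assert hi.p_value == 0 and hi.p_str == "< 0.1"
        assert lo.p_value == 1.0

    def test_strong_signal_significant(self, small_setup):
        matrix, cfg = small_setup
        res = permutation_test(matrix, cfg, n_permutations=19, seed=4)
        assert res.observed_accuracy == 1.0
        assert res.p_value <= 0.2
        assert len(res.null_accuracies) == 19

    def test_null_pvalues_roughly_uniform(self):
        # zero-effect data: the permutation p over repeated datasets
        # should not pile up at either end (coarse KS check)
        from scipy.stats import kstest

        ps = []
        for rep in range(12):
            matrix = make_separable_matrix(
                n_cases=6, n_controls=6, n_voxels=40, gap=0.0, seed=100 + rep
            )
            cfg = vp.CVConfig(
                n_iterations=15, seed=rep,
                selection=vp.SelectionConfig(z_threshold=1.5),
            )
            res = permutation_test(matrix, cfg, n_permutations=15, seed=rep)
            ps.append(res.p_value)
        assert kstest(ps, "uniform").pvalue > 0.005
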