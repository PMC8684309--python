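"""Positive-rate curves, re-ordering FPR, specificity equating, paired CIs."""

import numpy as np
import pytest

from vfprog.evaluate import (
    EvalCurves,
    default_alpha_grid,
    equate_specificity,
    fpr_curve,
    paired_difference_ci,
    positive_rate_curve,
)
from vfprog.model import ProgressionResult
from vfprog.simulate import CohortConfig, NoiseModel, generate_cohort


class TestPositiveRateCurve:
    def test_all_p_one_gives_zero_rate(self):
        grid = default_alpha_grid()
        assert np.all(positive_rate_curve(np.ones(10), grid) == 0.0)

    def test_direct_count(self):
        assert positive_rate_curve([0.01, 0.2, 0.9], [0.05])[0] == pytest.approx(1 / 3)

    def test_strict_inequality_at_alpha_zero(self):
        assert positive_rate_curve([0.0, 0.5], [0.0])[0] == 0.0

    def test_uniform_p_matches_alpha(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=10_000)
        grid = default_alpha_grid()
        rate = positive_rate_curve(p, grid)
        sd = np.sqrt(grid * (1 - grid) / 10_000)
        assert np.all(np.abs(rate - grid) < 3 * sd + 1e-12)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        rate = positive_rate_curve(rng.uniform(size=500), default_alpha_grid())
        assert np.all(np.diff(rate) >= 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            positive_rate_curve([], default_alpha_grid())


def _dummy_runner(p=1.0, status="ok"):
    def run(series):
        return ProgressionResult(
            series.series_id, "dummy", 0.0, p, np.zeros(52), np.ones(52), status
        )

    return run


class TestFprCurve:
    def test_method_returning_p_one_has_zero_fpr(self, stable_cohort_small):
        curves = fpr_curve(
            stable_cohort_small, _dummy_runner(1.0), default_alpha_grid(), seed=0
        )
        assert np.all(curves.false_positive_rate == 0.0)
        assert curves.n_excluded == 0

    def test_failed_series_are_excluded_and_counted(self, stable_cohort_small):
        flip = {"n": 0}

        def runner(series):
            flip["n"] += 1
            status = "failed" if flip["n"] % 2 else "ok"
            return _dummy_runner(0.5, status)(series)

        curves = fpr_curve(stable_cohort_small, runner, default_alpha_grid(), seed=1)
        assert curves.n_excluded == 5
        assert curves.n_series == 10

    def test_all_failures_is_an_error(self, stable_cohort_small):
        with pytest.raises(ValueError):
            fpr_curve(
                stable_cohort_small,
                _dummy_runner(status="failed"),
                default_alpha_grid(),
                seed=0,
            )


class TestEquateSpecificity:
    def test_perfectly_calibrated_method_is_identity(self):
        grid = default_alpha_grid()
        pr = np.sqrt(grid)  # any monotone curve
        a = EvalCurves(grid, positive_rate=pr)
        b = EvalCurves(grid, false_positive_rate=grid.copy())
        out, extrap = equate_specificity(a, b, grid)
        np.testing.assert_allclose(out, pr, atol=1e-12)
        assert not extrap.any()

    def test_doubled_fpr_reads_halved_alpha(self):
        # a method whose FPR is 2*alpha: PR at equated FPR 0.05 equals
        # the raw PR at alpha = 0.025
        grid = np.linspace(0.001, 0.15, 300)
        pr = grid**0.3
        a = EvalCurves(grid, positive_rate=pr)
        b = EvalCurves(grid, false_positive_rate=np.minimum(2 * grid, 1.0))
        out, _ = equate_specificity(a, b, [0.05])
        assert out[0] == pytest.approx(0.025**0.3, rel=1e-3)

    def test_extrapolation_flagged_with_boundary_value(self):
        grid = default_alpha_grid()
        a = EvalCurves(grid, positive_rate=grid.copy())
        b = EvalCurves(grid, false_positive_rate=grid.copy())
        out, extrap = equate_specificity(a, b, [0.5])
        assert extrap[0]
        assert out[0] == pytest.approx(grid[-1])

    def test_grid_mismatch_rejected(self):
        a = EvalCurves(np.array([0.01, 0.05]), positive_rate=np.array([0.1, 0.2]))
        b = EvalCurves(np.array([0.01, 0.1]), false_positive_rate=np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            equate_specificity(a, b, [0.05])

    def test_invariant_to_monotone_alpha_reparameterization(self):
        grid = default_alpha_grid()
        pr = grid**0.4
        fpr = np.minimum(1.5 * grid, 1.0)
        out1, _ = equate_specificity(
            EvalCurves(grid, positive_rate=pr),
            EvalCurves(grid, false_positive_rate=fpr),
            [0.05],
        )
        # re-index the same curves by alpha^2 (strictly monotone)
        grid2 = grid**2
        out2, _ = equate_specificity(
            EvalCurves(grid2, positive_rate=pr),
            EvalCurves(grid2, false_positive_rate=fpr),
            [0.05],
        )
        assert out1[0] == pytest.approx(out2[0], abs=1e-12)


class TestPairedDifferenceCI:
    def test_identical_methods_give_zero_difference(self):
        p = np.random.default_rng(2).uniform(size=200)
        d, lo, hi = paired_difference_ci(p, p, 0.05, seed=0)
        assert d == 0.0 and lo <= 0.0 <= hi

    def test_more_sensitive_method_detected(self):
        rng = np.random.default_rng(3)
        p_b = rng.uniform(size=500)
        p_a = p_b / 2  # method a strictly more sensitive
        d, lo, hi = paired_difference_ci(p_a, p_b, 0.05, n_boot=2000, seed=1)
        assert d > 0 and lo > 0

    def test_reproducible_ci(self):
        rng = np.random.default_rng(4)
        p_a, p_b = rng.uniform(size=300), rng.uniform(size=300)
        r1 = paired_difference_ci(p_a, p_b, 0.05, seed=7)
        r2 = paired_difference_ci(p_a, p_b, 0.05, seed=7)
        assert r1 == r2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_difference_ci([0.1], [0.1, 0.2], 0.05)


def test_poplr_fpr_calibrated_end_to_end():
    """PoPLR FPR at alpha=0.05/0.15 within binomial bands via fpr_curve."""
    from vfprog.poplr import permutation_p

    n, reps = 300, 3
    cohort = generate_cohort(
        CohortConfig(n_eyes=n, n_visits=7, noise=NoiseModel(mode="gaussian"), seed=33)
    )
    rng = np.random.default_rng(34)
    curves = fpr_curve(
        cohort,
        lambda s: permutation_p(s, n_perm=300, seed=rng),
        np.array([0.05, 0.15]),
        seed=35,
        n_repeats=reps,
    )
    from scipy import stats

    for i, alpha in enumerate((0.05, 0.15)):
        lo, hi = stats.binom.interval(0.95, n * reps, alpha)
        assert lo / (n * reps) <= curves.false_positive_rate[i] <= hi / (n * reps)
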