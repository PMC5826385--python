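import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from brainshift.calibration import (
    CalibrationResults,
    SyntheticCalibrationStudy,
    recover_stiffness,
    regress_through_origin,
    select_optimal,
)
from brainshift.datasets import reference_stiffness_sweep


class TestRegressionThroughOrigin:
    def test_identity_slope_zero_width_ci(self):
        x = np.array([0.4, 1.2, 0.9, 2.0])
        slope, lo, hi = regress_through_origin(x, x)
        assert slope == 1.0
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_hand_worked_slope(self):
        """slope = sum(xy)/sum(x^2) = 14.5/14 for the 3-point example."""
        slope, lo, hi = regress_through_origin([1, 2, 3], [1.1, 1.9, 3.2])
        assert slope == pytest.approx(14.5 / 14)
        assert lo < slope < hi

    def test_scaling_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.2, 2.0, 12)
        y = 0.8 * x + rng.normal(0, 0.1, 12)
        s1 = regress_through_origin(x, y)
        s3 = regress_through_origin(x, 3.0 * y)
        assert np.allclose(np.array(s3), 3.0 * np.array(s1), rtol=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 60))
    def test_matches_least_squares_oracle(self, seed, n):
        """The closed-form slope equals brute-force least squares restricted
        to zero intercept (and the statsmodels no-constant OLS fit)."""
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 3.0, n)
        y = rng.uniform(-1.0, 3.0, n)
        slope, lo, hi = regress_through_origin(x, y)
        lstsq = np.linalg.lstsq(x[:, None], y, rcond=None)[0][0]
        assert slope == pytest.approx(lstsq, rel=1e-10)
        fit = sm.OLS(y, x[:, None]).fit()
        assert slope == pytest.approx(fit.params[0], rel=1e-10)
        ci = fit.conf_int(alpha=0.05)
        assert lo == pytest.approx(ci[0, 0], rel=1e-8, abs=1e-10)
        assert hi == pytest.approx(ci[0, 1], rel=1e-8, abs=1e-10)

    def test_all_zero_regressor_rejected(self):
        with pytest.raises(ValueError, match="identically zero"):
            regress_through_origin(np.zeros(5), np.ones(5))

    def test_ci_coverage(self):
        """The 95% CI contains the true slope in 95% +- 2% of 10,000
        simulated no-intercept regressions with Gaussian errors."""
        rng = np.random.default_rng(42)
        n_rep, n = 10_000, 12
        true_a = 1.3
        x = rng.uniform(0.3, 2.0, (n_rep, n))
        y = true_a * x + rng.normal(0.0, 0.25, (n_rep, n))
        sxx = np.sum(x * x, axis=1)
        slope = np.sum(x * y, axis=1) / sxx
        resid = y - slope[:, None] * x
        se = np.sqrt(np.sum(resid**2, axis=1) / ((n - 1) * sxx))
        from scipy import stats

        tcrit = stats.t.ppf(0.975, n - 1)
        covered = np.abs(slope - true_a) <= tcrit * se
        assert covered.mean() == pytest.approx(0.95, abs=0.02)


class TestSelection:
    def test_reference_sweep_selects_46_133(self):
        """The published sweep's slopes and CIs select 46.133 N/m."""
        assert select_optimal(reference_stiffness_sweep()) == 46.133

    def test_sum_metric_agrees_on_reference_sweep(self):
        assert select_optimal(reference_stiffness_sweep(), metric="sum") == 46.133

    def test_single_candidate_selected(self):
        t = reference_stiffness_sweep()
        t = t[t["stiffness"].isin([4000.0, 46.133])].iloc[:2]
        assert select_optimal(t) == 46.133

    def test_empty_candidate_set_error(self):
        t = reference_stiffness_sweep()
        t = t[t["stiffness"] > 100.0]
        t = t[(t["ci_all_high"] < 1.0)]
        with pytest.raises(ValueError, match="extend the sweep grid"):
            select_optimal(t)

    def test_tie_breaks_to_stiffer(self):
        rows = []
        for k in (10.0, 20.0):
            rows.append(dict(stiffness=k, a_all=1.05, ci_all_low=0.9,
                             ci_all_high=1.2, a_sup=0.95, ci_sup_low=0.8,
                             ci_sup_high=1.1, n_all=10, n_sup=4,
                             vein_variant="post_cyclic"))
        assert select_optimal(pd.DataFrame(rows)) == 20.0

    def test_results_wrapper(self):
        res = CalibrationResults.from_table(reference_stiffness_sweep())
        assert res.selected_stiffness == 46.133
        text = res.summary()
        assert "46.133" in text and "selected stiffness" in text


@pytest.fixture(scope="module")
def small_study():
    """Compact simulation-backed calibration study shared across tests."""
    grid = (50.0, 150.0, 450.0)
    return SyntheticCalibrationStudy(
        grid, n_animals=1, n_rotations=2, n_markers=6,
        profile="circle", target_edge=6.0, seed=0,
    )


class TestRecovery:
    def test_noiseless_recovery_exact(self, small_study):
        for true_k in small_study.stiffness_grid:
            assert small_study.recover(true_k, 0.0, 1) == true_k

    def test_boundary_true_k_stays_in_grid(self, small_study):
        sel = small_study.recover(small_study.stiffness_grid[0], 0.3, 3)
        assert sel in small_study.stiffness_grid

    def test_noisy_recovery_close(self, small_study):
        grid = list(small_study.stiffness_grid)
        true_k = grid[1]
        hits = sum(
            abs(grid.index(small_study.recover(true_k, 0.1, 50 + s)) - 1) <= 1
            for s in range(10)
        )
        assert hits >= 8

    def test_recover_stiffness_requires_grid_membership(self, small_study):
        with pytest.raises(ValueError, match="member"):
            small_study.recover(77.7, 0.0, 0)

    def test_recover_stiffness_wrapper(self, small_study):
        assert recover_stiffness(150.0, 0.0, 0, study=small_study) == 150.0


class TestSweepModel:
    def test_fit_slopes_decrease_with_k(self, small_study):
        """Model slopes a(k) are monotone non-increasing in stiffness when
        the measured side is held fixed."""
        d_exp, sup = small_study.simulated(150.0)
        for e, d in zip(small_study.model.experiments,
                        np.split(d_exp, len(small_study.model.experiments))):
            e.d_exp = d
        results = small_study.model.fit()
        a = results.table["a_all"].to_numpy()
        assert np.all(np.diff(a) <= 1e-9)
        # at the generating stiffness the slope is exactly one
        at_true = results.table[results.table["stiffness"] == 150.0]
        assert at_true["a_all"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert results.selected_stiffness == 150.0

    def test_vein_sensitivity_variants(self, small_study):
        from brainshift.calibration import vein_sensitivity

        d_exp, _ = small_study.simulated(150.0)
        for e, d in zip(small_study.model.experiments,
                        np.split(d_exp, len(small_study.model.experiments))):
            e.d_exp = d
        sens = vein_sensitivity(small_study.model, 150.0)
        assert set(sens["vein_variant"]) == {"post_cyclic", "high_rate"}
        assert sens["delta_a_all"].iloc[0] == 0.0
        # veins stay slack against a stiff-ish boundary: variants agree
        assert sens["delta_a_all"].iloc[1] < 0.05
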