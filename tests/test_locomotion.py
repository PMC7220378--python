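"""Locomotion fluorescence, decay detrending, classification, regression."""

import numpy as np
import pandas as pd
import pytest

from calpharm import (
    DrugTestParams,
    classify_drug_effect,
    detrend_block,
    fit_decay,
    locomotion_fluorescence,
    regress_change_vs_baseline,
)
from calpharm.locomotion import artifact_ratio


def _trace_with_window(window_values, n=1200, rate=30.0, window=(10.0, 25.0)):
    tr = np.zeros(n)
    lo, hi = int(window[0] * rate), int(window[1] * rate)
    vals = np.asarray(window_values, dtype=float)
    reps = int(np.ceil((hi - lo) / len(vals)))
    tr[lo:hi] = np.tile(vals, reps)[: hi - lo]
    return tr


class TestLocomotionFluorescence:
    def test_constant_trace(self):
        tr = np.full(1200, 3.25)
        assert locomotion_fluorescence(tr) == pytest.approx(3.25)

    def test_sort_index_worked_example(self):
        # 101 values 0..100 in a window: (n-1)*0.75 = 75 -> percentile 75.0
        tr = np.zeros(200)
        tr[30:131] = np.arange(101)
        assert locomotion_fluorescence(tr, window=(1.0, 131 / 30), q=75, frame_rate=30.0) == 75.0

    def test_invariant_to_values_outside_window(self, rng):
        vals = rng.uniform(0, 2, size=450)
        t1 = _trace_with_window(vals)
        t2 = t1.copy()
        t2[:300] = 99.0
        t2[750:] = -99.0
        assert locomotion_fluorescence(t1) == locomotion_fluorescence(t2)

    def test_matches_numpy_linear_interpolation_oracle(self, rng):
        vals = rng.uniform(-1, 3, size=450)
        tr = _trace_with_window(vals)
        win = tr[300:750]
        # linear interpolation between order statistics at index (n-1)*q/100
        srt = np.sort(win)
        idx = (len(win) - 1) * 0.75
        lo, frac = int(np.floor(idx)), idx - int(np.floor(idx))
        oracle = srt[lo] * (1 - frac) + srt[min(lo + 1, len(win) - 1)] * frac
        assert locomotion_fluorescence(tr) == pytest.approx(oracle, abs=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            locomotion_fluorescence(np.zeros(100), window=(10.0, 10.0))


class TestFitDecay:
    def test_exact_parameter_recovery(self):
        j = np.arange(1, 7, dtype=float)
        y = 0.2 + 1.0 * np.exp(-j / 3.0)
        fit = fit_decay(y, j)
        assert fit.method == "exponential"
        assert np.max(np.abs(fit.predict(j) - y)) < 1e-6
        assert fit.A == pytest.approx(0.2, abs=1e-4)
        assert fit.B == pytest.approx(1.0, abs=1e-4)
        assert fit.C == pytest.approx(3.0, abs=1e-3)

    def test_constant_data_degenerate(self):
        fit = fit_decay(np.full(5, 0.8))
        assert fit.A == pytest.approx(0.8)
        assert fit.B == 0.0
        assert "degenerate_constant" in fit.flags

    def test_matches_profile_grid_oracle(self, rng):
        j = np.arange(1, 9, dtype=float)
        y = 0.3 + 0.7 * np.exp(-j / 2.5) + rng.normal(0, 0.02, size=len(j))
        fit = fit_decay(y, j)
        # oracle: grid over C, linear least squares in (A, B) at each C
        best_sse, best_pred = np.inf, None
        for c in np.linspace(0.2, 30.0, 3000):
            X = np.c_[np.ones_like(j), np.exp(-j / c)]
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            pred = X @ coef
            sse = np.sum((y - pred) ** 2)
            if sse < best_sse:
                best_sse, best_pred = sse, pred
        assert np.max(np.abs(fit.predict(j) - best_pred)) < 1e-4

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_decay(np.array([1.0]))
        fit = fit_decay(np.array([1.0, 0.5]))
        assert fit.method == "linear"
        assert "too_few_points" in fit.flags


class TestDetrend:
    def test_exact_curve_gives_zeros(self):
        j = np.arange(1, 7, dtype=float)
        y = 0.2 + 1.0 * np.exp(-j / 3.0)
        fit = fit_decay(y, j)
        assert np.allclose(detrend_block(y, j, fit), 0.0, atol=1e-8)

    def test_constant_offset_absorbed_into_A(self):
        j = np.arange(1, 8, dtype=float)
        y = 0.2 + 1.0 * np.exp(-j / 3.0)
        c = 0.9
        fit0, fit1 = fit_decay(y, j), fit_decay(y + c, j)
        assert fit1.A - fit0.A == pytest.approx(c, abs=1e-5)
        assert np.allclose(detrend_block(y, j, fit0), detrend_block(y + c, j, fit1), atol=1e-6)

    def test_post_drug_step_recovered(self):
        j_pre = np.arange(1, 7, dtype=float)
        j_post = np.arange(7, 13, dtype=float)
        curve = lambda j: 0.2 + 1.0 * np.exp(-j / 3.0)
        fit = fit_decay(curve(j_pre), j_pre)
        post = curve(j_post) - 0.5
        assert np.allclose(detrend_block(post, j_post, fit), -0.5, atol=1e-6)


class TestClassifyDrugEffect:
    def test_identical_constants_flagged_none(self):
        p, label, flags = classify_drug_effect(
            np.full(6, 0.4), np.full(9, 0.4), DrugTestParams(exclude_first=3)
        )
        assert p == 1.0
        assert label == "none"
        assert "zero_variance" in flags

    def test_clear_decrease(self, rng):
        pre = rng.normal(0.0, 0.01, size=6)
        post = rng.normal(-1.0, 0.01, size=11)
        p, label, _ = classify_drug_effect(pre, post)
        assert label == "decrease"
        assert p < 1e-6

    def test_exclusion_of_washin_recordings(self):
        # first three post values are wild but excluded, remainder equals pre
        pre = np.array([0.0, 0.01, -0.01, 0.0, 0.01, -0.01])
        post = np.concatenate([[5.0, 5.0, 5.0], pre[:4]])
        p, label, _ = classify_drug_effect(pre, post, DrugTestParams(exclude_first=3))
        assert label == "none"

    def test_null_type_one_rate_near_alpha(self):
        rng = np.random.default_rng(42)
        n_rois, flagged = 2000, 0
        params = DrugTestParams(exclude_first=3, alpha=0.01)
        for _ in range(n_rois):
            pre = rng.normal(0, 0.3, size=8)
            post = rng.normal(0, 0.3, size=11)
            p, label, _ = classify_drug_effect(pre, post, params)
            flagged += label != "none"
        # binomial 3-sigma band around alpha
        assert abs(flagged / n_rois - 0.01) < 3 * np.sqrt(0.01 * 0.99 / n_rois) + 1e-9

    def test_too_few_recordings_skipped(self):
        p, label, flags = classify_drug_effect(np.array([0.1]), np.zeros(9))
        assert np.isnan(p)
        assert "too_few_recordings" in flags


class TestRegression:
    def test_exact_negative_line(self):
        x = np.linspace(0, 3, 20)
        res = regress_change_vs_baseline(x, 1.0 - 0.5 * x)
        assert res.r == pytest.approx(-1.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(-0.5)

    def test_independent_data_near_zero(self, rng):
        x = rng.normal(size=5000)
        y = rng.normal(size=5000)
        res = regress_change_vs_baseline(x, y)
        assert abs(res.r) < 0.05

    def test_matches_covariance_formula_oracle(self, rng):
        x = rng.normal(1, 0.5, size=80)
        y = -0.6 * x + rng.normal(0, 0.4, size=80)
        res = regress_change_vs_baseline(x, y)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        oracle_r = cov / (x.std() * y.std())
        assert res.r == pytest.approx(oracle_r, abs=1e-12)
        assert res.r2 == pytest.approx(oracle_r**2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            regress_change_vs_baseline(np.ones(10), np.arange(10.0))


class TestArtifactRatio:
    def test_scaled_metrics(self):
        m910 = pd.Series([1.0, 2.0, 4.0], index=[1, 2, 3])
        out = artifact_ratio(0.4 * m910, m910)
        assert np.allclose(out["ratio"], 0.4)

    def test_identical_runs_and_zero_cases(self):
        m = pd.Series([1.0, 2.0], index=[1, 2])
        assert np.allclose(artifact_ratio(m, m)["ratio"], 1.0)
        assert np.allclose(artifact_ratio(0 * m, m)["ratio"], 0.0)
        out = artifact_ratio(m, 0 * m)
        assert out["ratio"].isna().all()
        assert (out["flag"] == "zero_910_metric").all()
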