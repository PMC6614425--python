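"""Hue-estimation regression and residual statistics."""

import numpy as np
import pandas as pd
import pytest

from memcolor import colorimetry as cm
from memcolor import hue_model as hm
from memcolor import pipeline, synthetic_data as sd

from conftest import noise_free_config


def _make_study(cfg):
    rng = np.random.default_rng(cfg.seed)
    catalog = sd.make_stimulus_catalog()
    measured = sd.make_measured_colors(catalog, cfg, rng)
    matches = sd.simulate_matches(catalog, measured, cfg, rng)
    ref = sd.reference_lab(measured, cfg.monitor_white, cfg.scene_white)
    return catalog, measured, matches, ref


class TestSelectTraining:
    def test_default_counts(self, study, catalog):
        *_, matches = study
        sub = hm.select_training(matches, catalog, "white")
        assert len(sub) == 7 * 20
        assert set(sub["stimulus_id"]) == {
            "lego_red", "lego_yellow", "toy_phone",
            "actor1_masked_forehead", "actor2_masked_forehead",
            "actor3_masked_forehead", "actor4_masked_forehead"}

    def test_ping_pong_ball_excluded(self, study, catalog):
        *_, matches = study
        sub = hm.select_training(matches, catalog, "LPS")
        assert "ping_pong_ball" not in set(sub["stimulus_id"])

    def test_without_masked_foreheads(self, study, catalog):
        *_, matches = study
        reduced = catalog[catalog["category"] != "masked_forehead"]
        sub = hm.select_training(matches, reduced, "white")
        assert sub["stimulus_id"].nunique() == 3

    def test_unknown_illuminant(self, study, catalog):
        *_, matches = study
        with pytest.raises(hm.ModelError):
            hm.select_training(matches, catalog, "moonlight")


class TestFit:
    def test_identity_data_gives_zero_residuals(self, catalog):
        catalog, measured, matches, ref = _make_study(noise_free_config())
        fits = pipeline.fit_models(matches, catalog, ref)
        res = hm.hue_residuals(matches, fits, ref)
        # the identity map lies in the model family; the only slack is the
        # truncated-SVD regularisation of the degenerate LPS design
        assert np.abs(res["residual"]).max() < 1e-3

    def test_lightness_slope_recovery(self, catalog):
        catalog, measured, matches, ref = _make_study(
            noise_free_config(lightness_hue_slope=0.2))
        fits = pipeline.fit_models(matches, catalog, ref)
        res = hm.hue_residuals(matches, fits, ref)
        training_ids = set(fits["white"].training_ids)
        tr = res[res["stimulus_id"].isin(training_ids)]
        # small-angle rotations are near-linear in the predictors
        assert np.abs(tr["residual"]).mean() < 1.0

    def test_ols_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        n = 40
        meas = pd.DataFrame({
            "stimulus_id": [f"s{i}" for i in range(n)],
            "illuminant": "white",
            "a": rng.normal(10, 5, n), "b": rng.normal(20, 5, n),
            "L": rng.normal(60, 10, n),
        })
        meas["chroma"] = np.hypot(meas["a"], meas["b"]) + rng.normal(0, 1, n)
        matches = meas[["stimulus_id", "illuminant"]].copy()
        matches["a"] = 0.5 * meas["a"] - 0.2 * meas["L"] + rng.normal(0, 1, n)
        matches["b"] = 0.8 * meas["b"] + 3 + rng.normal(0, 1, n)
        matches["hue"], matches["chroma"] = cm.hue_chroma(
            np.column_stack([np.zeros(n), matches["a"], matches["b"]]))
        matches["L"] = meas["L"]
        matches["participant_id"] = "P01"
        fit = hm.fit_hue_model(matches, meas)
        X = np.column_stack([np.ones(n), meas[["a", "b", "L", "chroma"]]])
        Y = matches[["a", "b"]].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ Y)
        assert np.allclose(fit.coefficients, beta, atol=1e-8)

    def test_duplicated_training_set_same_fit(self, study, catalog, reference):
        *_, matches = study
        tr = hm.select_training(matches, catalog, "white")
        f1 = hm.fit_hue_model(tr, reference)
        f2 = hm.fit_hue_model(pd.concat([tr, tr]), reference)
        assert np.allclose(f1.coefficients, f2.coefficients, atol=1e-9)

    def test_too_few_records(self, study, catalog, reference):
        *_, matches = study
        tr = hm.select_training(matches, catalog, "white").head(5)
        with pytest.raises(hm.ModelError, match=">= 10"):
            hm.fit_hue_model(tr, reference)

    def test_collinear_predictors_raise(self, reference):
        n = 20
        meas = pd.DataFrame({
            "stimulus_id": [f"s{i}" for i in range(n)],
            "illuminant": "white",
            "a": 1.0, "b": 2.0, "L": 50.0, "chroma": np.hypot(1.0, 2.0),
        })
        matches = meas.copy()
        matches["participant_id"] = "P01"
        matches["hue"] = 60.0
        with pytest.raises(hm.ModelError, match="rank"):
            hm.fit_hue_model(matches, meas)


class TestEstimate:
    def test_constant_map(self):
        fit = hm.HueModelFit(
            illuminant="white",
            coefficients=np.array([[0.0, 1.0], [0, 0], [0, 0], [0, 0], [0, 0]],
                                  dtype=float),
            training_ids=(), fit_correlation=np.nan)
        meas = pd.DataFrame({"a": [5.0, -3.0], "b": [1.0, 9.0],
                             "L": [40.0, 70.0], "chroma": [5.1, 9.5]})
        assert np.allclose(hm.estimate_hue(fit, meas), 90.0)

    def test_hand_computed_dot_product(self):
        rng = np.random.default_rng(0)
        coef = rng.normal(size=(5, 2))
        fit = hm.HueModelFit("white", coef, (), np.nan)
        meas = pd.DataFrame({"a": [4.0], "b": [-2.0], "L": [55.0],
                             "chroma": [4.47]})
        x = np.array([1.0, 4.0, -2.0, 55.0, 4.47])
        ab = x @ coef
        expected = np.degrees(np.arctan2(ab[1], ab[0])) % 360
        assert np.isclose(hm.estimate_hue(fit, meas)[0], expected, atol=1e-10)

    def test_residual_wraps_through_zero(self):
        # estimated 350°, matched 10° → residual +20°
        fit = hm.HueModelFit(
            "white",
            np.array([[np.cos(np.radians(350.0)) * 10,
                       np.sin(np.radians(350.0)) * 10],
                      [0, 0], [0, 0], [0, 0], [0, 0]]),
            (), np.nan)
        meas = pd.DataFrame({"stimulus_id": ["s0"], "illuminant": ["white"],
                             "a": [0.0], "b": [0.0], "L": [50.0],
                             "chroma": [0.0]})
        matches = pd.DataFrame({
            "participant_id": ["P01"], "stimulus_id": ["s0"],
            "illuminant": ["white"], "hue": [10.0], "chroma": [5.0],
            "L": [50.0], "a": [np.cos(np.radians(10)) * 5],
            "b": [np.sin(np.radians(10)) * 5]})
        res = hm.hue_residuals(matches, {"white": fit}, meas)
        assert np.isclose(res["residual"].iloc[0], 20.0)


class TestResidualDiagnostics:
    def test_training_residuals_centered(self, study, catalog, fitted):
        fits, res = fitted
        for illum, fit in fits.items():
            tr = res[(res["illuminant"] == illum)
                     & res["stimulus_id"].isin(fit.training_ids)]
            assert abs(tr["residual"].mean()) < 1.5

    def test_residuals_uncorrelated_with_estimate(self, fitted):
        fits, res = fitted
        for illum, fit in fits.items():
            tr = res[(res["illuminant"] == illum)
                     & res["stimulus_id"].isin(fit.training_ids)]
            r = np.corrcoef(tr["residual"], tr["estimated_hue"])[0, 1]
            assert abs(r) < 0.25

    def test_fit_correlation_positive(self, fitted):
        fits, _ = fitted
        assert fits["white"].fit_correlation > 0.5
        assert fits["LPS"].fit_correlation > 0.0


class TestBootstrap:
    def test_constant_residuals_degenerate_ci(self):
        rng = np.random.default_rng(0)
        lo, hi = hm.bootstrap_ci(np.full(50, 3.2), 200, 0.99, rng)
        assert lo == hi == pytest.approx(3.2)

    def test_normal_sample_matches_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 10000)
        lo, hi = hm.bootstrap_ci(x, 2000, 0.99, rng)
        half = 2.576 / np.sqrt(10000)
        assert np.isclose(lo, x.mean() - half, atol=0.05)
        assert np.isclose(hi, x.mean() + half, atol=0.05)

    def test_summary_structure(self, fitted, catalog):
        _, res = fitted
        rng = np.random.default_rng(0)
        out = hm.category_residual_summary(
            res, catalog, ["face_context", "illuminant"], n_boot=100, rng=rng)
        assert len(out) == 4
        assert set(out.columns) >= {"n", "mean", "ci_low", "ci_high"}

    def test_empty_group_reported(self, fitted, catalog):
        _, res = fitted
        rng = np.random.default_rng(0)
        sub = res[res["illuminant"] == "LPS"]
        out = hm.category_residual_summary(
            sub, catalog, ["category", "illuminant"], n_boot=50, rng=rng)
        # illuminant column still enumerates only observed levels
        assert (out["n"] > 0).all()

    def test_participant_bootstrap_mode(self, fitted, catalog):
        _, res = fitted
        rng = np.random.default_rng(0)
        out = hm.category_residual_summary(
            res, catalog, ["category", "illuminant"], n_boot=100, rng=rng,
            bootstrap_mode="participant")
        assert np.isfinite(out["ci_low"]).all()

    def test_unknown_grouping_key(self, fitted, catalog):
        _, res = fitted
        with pytest.raises(ValueError, match="grouping"):
            hm.category_residual_summary(res, catalog, ["actor"], n_boot=10)


class TestRecovery:
    def test_face_ci_contains_injected_delta(self, study, catalog, reference):
        cfg, catalog, _, matches = study
        mean, lo, hi = hm.pipeline_bootstrap_ci(
            matches, catalog, reference, "LPS", "face_skin",
            n_boot=300, rng=np.random.default_rng(0))
        assert lo <= cfg.delta_face <= hi
        mean_w, lo_w, hi_w = hm.pipeline_bootstrap_ci(
            matches, catalog, reference, "white", "face_skin",
            n_boot=300, rng=np.random.default_rng(0))
        assert lo_w <= 0.0 <= hi_w

    def test_monotone_in_injected_delta(self):
        means = []
        for delta in (0.0, 10.0, 20.0, 30.0, 40.0):
            cfg = sd.SimulationConfig(seed=21, delta_face=delta)
            catalog, measured, matches, ref = _make_study(cfg)
            fits = pipeline.fit_models(matches, catalog, ref)
            res = hm.hue_residuals(matches, fits, ref)
            merged = res.merge(catalog, left_on="stimulus_id", right_on="id")
            face = merged[(merged["illuminant"] == "LPS")
                          & (merged["category"] == "face_skin")]
            means.append(face["residual"].mean())
        assert np.all(np.diff(means) > 0)
        assert np.allclose(means, [0, 10, 20, 30, 40], atol=5.0)
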