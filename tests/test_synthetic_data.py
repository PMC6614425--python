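"""Synthetic study generator: catalog structure, measurement loci, matches."""

import numpy as np
import pandas as pd
import pytest

from memcolor import colorimetry as cm
from memcolor import synthetic_data as sd

from conftest import noise_free_config


class TestCatalog:
    def test_inventory_size_and_partition(self, catalog):
        assert len(catalog) == 35
        counts = catalog["category"].value_counts().to_dict()
        assert counts == {"toy": 4, "fruit": 3, "face_skin": 8, "lips": 4,
                          "body_skin": 8, "photo": 4, "masked_forehead": 4}

    def test_non_color_diagnostic_set(self, catalog):
        ids = set(catalog.loc[~catalog["color_diagnostic"], "id"])
        assert ids == {"lego_red", "lego_yellow", "toy_phone", "ping_pong_ball",
                       "actor1_masked_forehead", "actor2_masked_forehead",
                       "actor3_masked_forehead", "actor4_masked_forehead"}

    def test_context_flags(self, catalog):
        assert int(catalog["face_context"].sum()) == 16
        assert set(catalog.loc[~catalog["three_d"], "region"]) == {
            "photo", "masked_forehead"}
        assert int((~catalog["three_d"]).sum()) == 8

    def test_deterministic(self, catalog):
        pd.testing.assert_frame_equal(catalog, sd.make_stimulus_catalog())


class TestMeasuredColors:
    def test_deterministic_given_seed(self, catalog):
        cfg = sd.SimulationConfig(seed=5)
        m1 = sd.make_measured_colors(catalog, cfg, np.random.default_rng(5))
        m2 = sd.make_measured_colors(catalog, cfg, np.random.default_rng(5))
        pd.testing.assert_frame_equal(m1, m2)

    def test_complete_and_finite(self, study):
        _, catalog, measured, _ = study
        assert len(measured) == 70
        assert np.isfinite(measured[["X", "Y", "Z", "L", "a", "b"]]
                           .to_numpy()).all()
        assert (measured[["X", "Y", "Z"]].to_numpy() >= 0).all()
        chroma = np.hypot(measured["a"], measured["b"])
        assert (chroma >= 0).all()

    def test_lps_hue_spread_compressed(self, study):
        _, _, measured, _ = study
        hue, _ = cm.hue_chroma(measured[["L", "a", "b"]].to_numpy())
        df = measured.assign(hue=hue)
        spread = df.groupby("illuminant")["hue"].std()
        assert spread["LPS"] < spread["white"]

    def test_lps_shares_illuminant_chromaticity(self, study):
        # monochromatic light: every surface has the same chromaticity
        _, _, measured, _ = study
        lps = measured[measured["illuminant"] == "LPS"]
        xyz = lps[["X", "Y", "Z"]].to_numpy()
        xy = xyz[:, :2] / xyz.sum(axis=1, keepdims=True)
        assert xy.std(axis=0).max() < 0.01


class TestSimulateMatches:
    def test_noise_free_identity(self, catalog):
        cfg = noise_free_config()
        rng = np.random.default_rng(0)
        measured = sd.make_measured_colors(catalog, cfg, rng)
        matches = sd.simulate_matches(catalog, measured, cfg, rng)
        ref = sd.reference_lab(measured, cfg.monitor_white, cfg.scene_white)
        merged = matches.merge(ref, on=["stimulus_id", "illuminant"],
                               suffixes=("", "_ref"))
        assert len(merged) == 20 * 35 * 2
        assert np.allclose(
            cm.circular_diff(merged["hue"], merged["hue_ref"]), 0.0, atol=1e-6)
        assert np.allclose(merged["L"], merged["L_ref"], atol=1e-6)

    def test_noise_free_face_shift_exact(self, catalog):
        cfg = noise_free_config(delta_face=30.0)
        rng = np.random.default_rng(0)
        measured = sd.make_measured_colors(catalog, cfg, rng)
        matches = sd.simulate_matches(catalog, measured, cfg, rng)
        ref = sd.reference_lab(measured, cfg.monitor_white, cfg.scene_white)
        merged = matches.merge(ref, on=["stimulus_id", "illuminant"],
                               suffixes=("", "_ref"))
        merged = merged.merge(catalog, left_on="stimulus_id", right_on="id")
        lps_face = merged[(merged["illuminant"] == "LPS")
                          & (merged["category"] == "face_skin")]
        d = cm.circular_diff(lps_face["hue"], lps_face["hue_ref"])
        assert np.allclose(d, 30.0, atol=1e-6)
        white_face = merged[(merged["illuminant"] == "white")
                            & (merged["category"] == "face_skin")]
        assert np.allclose(
            cm.circular_diff(white_face["hue"], white_face["hue_ref"]),
            0.0, atol=1e-6)

    def test_noise_free_lightness_slope_exact(self, catalog):
        cfg = noise_free_config(lightness_hue_slope=0.2)
        rng = np.random.default_rng(0)
        measured = sd.make_measured_colors(catalog, cfg, rng)
        matches = sd.simulate_matches(catalog, measured, cfg, rng)
        ref = sd.reference_lab(measured, cfg.monitor_white, cfg.scene_white)
        ref = ref.assign(
            L_bar=ref.groupby("illuminant")["L"].transform("mean"))
        merged = matches.merge(ref, on=["stimulus_id", "illuminant"],
                               suffixes=("", "_ref"))
        expected = 0.2 * (merged["L_ref"] - merged["L_bar"])
        assert np.allclose(cm.circular_diff(merged["hue"], merged["hue_ref"]),
                           expected, atol=1e-6)

    def test_byte_identical_given_seed(self, catalog):
        cfg = sd.SimulationConfig(seed=9)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            measured = sd.make_measured_colors(catalog, cfg, rng)
            out.append(sd.simulate_matches(catalog, measured, cfg, rng))
        assert out[0].to_csv(index=False) == out[1].to_csv(index=False)

    def test_missing_measurement_is_an_error(self, catalog):
        cfg = sd.SimulationConfig(seed=0)
        rng = np.random.default_rng(0)
        measured = sd.make_measured_colors(catalog, cfg, rng)
        broken = measured[measured["stimulus_id"] != "tomato"]
        with pytest.raises(sd.DataIntegrityError, match="tomato"):
            sd.simulate_matches(catalog, broken, cfg, rng)

    def test_record_count(self, study):
        *_, matches = study
        assert len(matches) == 1400
        rgb = matches[["R", "G", "B"]].to_numpy()
        assert (rgb >= 0).all() and (rgb <= 1).all()


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"match_noise_sd": -1.0},
        {"lps_chroma_compression": 0.0},
        {"lps_chroma_compression": 1.5},
        {"photo_fraction": 2.0},
        {"lips_variance_inflation": 0.5},
        {"n_participants": 0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sd.SimulationConfig(**kwargs)


class TestDatasetIO:
    def test_round_trip(self, study, tmp_path):
        _, catalog, measured, matches = study
        sd.write_dataset(tmp_path, catalog, measured, matches)
        cat2, meas2, match2 = sd.read_dataset(tmp_path)
        pd.testing.assert_frame_equal(catalog.reset_index(drop=True), cat2)
        assert np.allclose(measured[["X", "Y", "Z"]], meas2[["X", "Y", "Z"]],
                           rtol=1e-9)
        assert np.allclose(matches[["hue", "chroma"]],
                           match2[["hue", "chroma"]], rtol=1e-9)

    def test_empty_match_table_valid(self, study, tmp_path):
        _, catalog, measured, matches = study
        sd.write_dataset(tmp_path, catalog, measured, matches.iloc[:0])
        *_, match2 = sd.read_dataset(tmp_path)
        assert len(match2) == 0

    def test_unknown_illuminant_rejected_with_row(self, study, tmp_path):
        _, catalog, measured, matches = study
        bad = matches.copy()
        bad.loc[3, "illuminant"] = "sodium"
        sd.write_dataset(tmp_path, catalog, measured, bad)
        with pytest.raises(sd.DataIntegrityError, match="row 5.*sodium"):
            sd.read_dataset(tmp_path)

    def test_out_of_gamut_rgb_rejected(self, study, tmp_path):
        _, catalog, measured, matches = study
        bad = matches.copy()
        bad.loc[0, "R"] = 1.2
        sd.write_dataset(tmp_path, catalog, measured, bad)
        with pytest.raises(sd.DataIntegrityError, match="gamut"):
            sd.read_dataset(tmp_path)
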