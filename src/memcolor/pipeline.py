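"""End-to-end orchestration: simulate → convert → fit → residuals → stats →
RSA → observer, deterministically from a config plus one seed.

The global seed is expanded through :class:`numpy.random.SeedSequence` into
independent per-stage streams (simulation, bootstrap, observer), so adding or
re-running one stage never perturbs another's draws.  All outputs are plain
CSV/JSON; a run writes its config snapshot and a manifest listing every file
with a content hash, and two runs with equal config and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import colorimetry as cm
from . import hue_model, inference_stats, observer, rsa, synthetic_data

__all__ = ["PipelineConfig", "run_all", "validate_inputs"]

logger = logging.getLogger(__name__)

#: verbal-report contingency tables (rows = female/male, cols = yes/no):
#: "face looked green or sick" and "face looked sick"
REPORT_TABLES = {
    "green_or_sick_by_sex": (10, 0, 4, 6),
    "sick_by_sex": (7, 3, 2, 8),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    n_boot: int = 1000
    ci_level: float = 0.99
    bootstrap_mode: str = "record"
    rdm_metric: str = "euclidean"


@dataclass
class ObserverConfig:
    sigma_int: float = 0.001
    grid_points: int = 4096
    grid_span: float = 6.0
    n_mc: int = 2000
    #: stimulus values for the bias curve, in prior SDs from the prior mean
    stimulus_sds: tuple[float, ...] = tuple(
        float(x) for x in np.arange(-3.0, 3.5, 0.5))
    sick_offset: float = observer.DEFAULT_SICK_OFFSET
    prior_sick: float = 0.5


@dataclass
class PipelineConfig:
    simulation: synthetic_data.SimulationConfig = field(
        default_factory=synthetic_data.SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    observer: ObserverConfig = field(default_factory=ObserverConfig)
    #: monitor model (primary matrix + gamma); None = default calibration
    calibration: cm.MonitorCalibration | None = None
    #: read matches/measured/stimuli from this directory instead of simulating
    dataset_dir: str | None = None

    @property
    def calib(self) -> cm.MonitorCalibration:
        return self.calibration or cm.default_calibration()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = synthetic_data.config_to_dict(self.simulation)
        d["observer"]["stimulus_sds"] = [float(x) for x in self.observer.stimulus_sds]
        d["calibration"] = {
            "primary_matrix": [[float(v) for v in row]
                               for row in self.calib.primary_matrix],
            "gamma": [float(g) for g in self.calib.gamma],
            "monitor_white": [float(v) for v in self.simulation.monitor_white],
            "scene_white": [float(v) for v in self.simulation.scene_white],
        }
        return d


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n")


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ("simulation", "bootstrap", "observer")
    return dict(zip(names, map(np.random.default_rng, ss.spawn(len(names)))))


def fit_models(matches: pd.DataFrame, catalog: pd.DataFrame,
               measured_ref: pd.DataFrame) -> dict[str, hue_model.HueModelFit]:
    """Per-illuminant hue-model fits on the non-diagnostic training stimuli."""
    fits = {}
    for illum in synthetic_data.ILLUMINANTS:
        training = hue_model.select_training(matches, catalog, illum)
        fits[illum] = hue_model.fit_hue_model(training, measured_ref)
    return fits


def _participant_face_body_diff(residuals: pd.DataFrame, catalog: pd.DataFrame,
                                illuminant: str) -> pd.Series:
    """Per-participant mean face-skin minus mean body-skin residual."""
    df = residuals.merge(catalog, left_on="stimulus_id", right_on="id")
    df = df[(df["illuminant"] == illuminant)
            & df["category"].isin(["face_skin", "body_skin"])]
    means = df.groupby(["participant_id", "category"])["residual"].mean().unstack()
    return (means["face_skin"] - means["body_skin"]).sort_index()


def run_stats(residuals: pd.DataFrame, catalog: pd.DataFrame) -> dict:
    """The battery of hypothesis tests on hue residuals and report tables."""
    out: dict = {}
    for name, counts in REPORT_TABLES.items():
        out[f"chi2_{name}"] = inference_stats.chi2_2x2(*counts).as_dict()

    lps = _participant_face_body_diff(residuals, catalog, "LPS")
    white = _participant_face_body_diff(residuals, catalog, "white")
    out["paired_t_face_body_lps_vs_white"] = inference_stats.paired_t(
        lps.to_numpy(), white.to_numpy()).as_dict()

    df = residuals.merge(catalog, left_on="stimulus_id", right_on="id")
    white_df = df[df["illuminant"] == "white"]
    lips = white_df.loc[white_df["category"] == "lips", "residual"]
    face = white_df.loc[white_df["category"] == "face_skin", "residual"]
    out["f_test_lips_vs_face_white"] = inference_stats.variance_f_test(
        lips.to_numpy(), face.to_numpy()).as_dict()

    skin = df[df["category"].isin(["face_skin", "body_skin"])]
    out["anova_lighting_skin_race"] = inference_stats.factorial_anova(
        skin["residual"].to_numpy(),
        {
            "lighting": skin["illuminant"].to_numpy(),
            "skin_type": skin["category"].to_numpy(),
            "race": skin["race"].to_numpy(),
        },
    ).as_dict()

    # face (cheek, forehead, photo) x 3-D (cheek, forehead, neck, hand) on
    # LPS residuals; cells have unequal numbers of regions, so residuals are
    # aggregated to one value per participant x actor x cell first
    lps_df = df[(df["illuminant"] == "LPS")
                & df["region"].isin(["cheek", "forehead", "photo",
                                     "neck", "hand", "masked_forehead"])].copy()
    lps_df["face"] = lps_df["region"].isin(["cheek", "forehead", "photo"])
    lps_df["three_d_f"] = lps_df["region"].isin(["cheek", "forehead", "neck", "hand"])
    cells = (lps_df.groupby(["participant_id", "actor", "face", "three_d_f"])
             ["residual"].mean().reset_index())
    out["anova_face_threed"] = inference_stats.factorial_anova(
        cells["residual"].to_numpy(),
        {"face": cells["face"].to_numpy(), "three_d": cells["three_d_f"].to_numpy()},
    ).as_dict()
    return out


def run_rsa(matches: pd.DataFrame, catalog: pd.DataFrame, out_dir: Path,
            metric: str = "euclidean", calib=None) -> dict:
    """RDM + MDS + dendrogram per cone-opponent component and illuminant."""
    summary = {}
    mds_frames = []
    for illum in synthetic_data.ILLUMINANTS:
        for comp in ("lm", "s"):
            mat = rsa.condition_matrix(matches, catalog, illum, comp,
                                       calib=calib)
            rdm = rsa.compute_rdm(mat, metric=metric)
            rdm.to_csv(out_dir / f"rdm_{comp}_{illum}.csv")
            mds = rsa.classical_mds(rdm, dims=1)
            mds["component"], mds["illuminant"] = comp, illum
            mds_frames.append(mds.reset_index(names="condition"))
            tree = rsa.average_linkage_tree(rdm)
            _write_json(out_dir / f"dendrogram_{comp}_{illum}.json",
                        {"conditions": list(rdm.index), "merges": [
                            {"pair": list(m["pair"]), "height": m["height"],
                             "size": m["size"]} for m in tree]})
            cut = rsa.cut_two_clusters(rdm)
            face = {c for c in rdm.index if c in ("cheek", "forehead")}
            labels = {cut[c] for c in face}
            separated = (len(labels) == 1
                         and all(cut[c] != next(iter(labels))
                                 for c in rdm.index if c not in face))
            summary[f"face_separation_{comp}_{illum}"] = bool(separated)
    pd.concat(mds_frames, ignore_index=True).to_csv(out_dir / "mds.csv", index=False)
    return summary


def run_observer(matches: pd.DataFrame, catalog: pd.DataFrame,
                 cfg: ObserverConfig, rng: np.random.Generator,
                 out_dir: Path) -> dict:
    """Health model + efficient-coding bias curve from the match data."""
    masked_ids = set(catalog.loc[catalog["category"] == "masked_forehead", "id"])
    samples = matches[(matches["illuminant"] == "LPS")
                      & matches["stimulus_id"].isin(masked_ids)]["a"].to_numpy()
    health = observer.fit_health_model(
        samples, sick_offset=cfg.sick_offset, prior_sick=cfg.prior_sick)

    grid = np.linspace(-30.0, 30.0, 601)
    post = pd.DataFrame({"a_star": grid})
    for lighting in health.healthy:
        post[f"p_sick_{lighting}"] = observer.posterior_sick(grid, health, lighting)
    post.to_csv(out_dir / "posterior_sick.csv", index=False)

    prior = health.healthy["LPS"]
    obs = observer.EfficientObserver(
        prior=observer.GaussianDensity(prior.mu, prior.sigma),
        sigma_int=cfg.sigma_int, grid_points=cfg.grid_points,
        grid_span=cfg.grid_span)
    stimuli = prior.mu + np.asarray(cfg.stimulus_sds) * prior.sigma
    curve = observer.bias_curve(obs, stimuli, n_mc=cfg.n_mc, rng=rng)
    curve.to_csv(out_dir / "observer.csv", index=False)
    neg2 = curve.iloc[(np.abs(np.asarray(cfg.stimulus_sds) + 2.0)).argmin()]
    return {
        "prior_mu": prior.mu, "prior_sigma": prior.sigma,
        "bias_at_minus_2sd": float(neg2["bias"]),
    }


def run_all(config: PipelineConfig, seed: int, out_dir) -> dict:
    """Execute the full analysis; returns the run manifest (also written)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = _stage_rngs(seed)
    manifest: dict = {"seed": seed,
                      "package_version": _pkg_version("memcolor"),
                      "config": config.to_dict(), "stages": {}, "files": []}
    stage = "simulate"
    try:
        if config.dataset_dir is not None:
            catalog, measured, matches = synthetic_data.read_dataset(config.dataset_dir)
        else:
            catalog = synthetic_data.make_stimulus_catalog()
            measured = synthetic_data.make_measured_colors(
                catalog, config.simulation, rngs["simulation"])
            matches = synthetic_data.simulate_matches(
                catalog, measured, config.simulation, rngs["simulation"],
                calib=config.calib)
        synthetic_data.write_dataset(out, catalog, measured, matches)
        manifest["stages"][stage] = {"n_stimuli": len(catalog),
                                     "n_matches": len(matches)}
        logger.info("simulate: %d stimuli, %d matches", len(catalog), len(matches))

        stage = "fit"
        measured_ref = synthetic_data.reference_lab(
            measured, config.simulation.monitor_white,
            config.simulation.scene_white)
        fits = fit_models(matches, catalog, measured_ref)
        manifest["stages"][stage] = {
            illum: {"r": f.fit_correlation, "n_training_stimuli": len(f.training_ids)}
            for illum, f in fits.items()}

        stage = "residuals"
        residuals = hue_model.hue_residuals(matches, fits, measured_ref)
        residuals.to_csv(out / "residuals.csv", index=False)
        summary = hue_model.category_residual_summary(
            residuals, catalog, ["category", "illuminant"],
            n_boot=config.analysis.n_boot, level=config.analysis.ci_level,
            rng=rngs["bootstrap"], bootstrap_mode=config.analysis.bootstrap_mode)
        summary.to_csv(out / "summary.csv", index=False)
        manifest["stages"][stage] = {"n_residuals": len(residuals)}

        stage = "stats"
        stats_out = run_stats(residuals, catalog)
        _write_json(out / "tests.json", stats_out)
        manifest["stages"][stage] = {"n_tests": len(stats_out)}

        stage = "rsa"
        manifest["stages"][stage] = run_rsa(
            matches, catalog, out, metric=config.analysis.rdm_metric,
            calib=config.calib)

        stage = "observer"
        manifest["stages"][stage] = run_observer(
            matches, catalog, config.observer, rngs["observer"], out)
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        manifest["error"] = {"stage": stage, "message": str(exc)}
        _write_json(out / "manifest.json", manifest)
        raise PipelineError(stage, str(exc)) from exc

    _write_json(out / "config.json", config.to_dict())
    files = sorted(p.name for p in out.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest["files"] = [
        {"name": name,
         "sha256": hashlib.sha256((out / name).read_bytes()).hexdigest()}
        for name in files]
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()
    _write_json(out / "manifest.json", manifest)
    return manifest


def validate_inputs(path) -> list[str]:
    """Schema, gamut and completeness checks on a dataset directory.

    Returns a list of human-readable problems; empty means valid.
    """
    problems: list[str] = []
    try:
        catalog, measured, matches = synthetic_data.read_dataset(path)
    except (synthetic_data.DataIntegrityError, FileNotFoundError) as exc:
        return [str(exc)]

    have = {(s, i) for s, i in measured[["stimulus_id", "illuminant"]]
            .itertuples(index=False)}
    for sid in catalog["id"]:
        for illum in synthetic_data.ILLUMINANTS:
            if (sid, illum) not in have:
                problems.append(f"measured.csv: no measurement for stimulus "
                                f"{sid!r} under {illum!r}")
    if len(matches):
        expected = {(s, i) for s in catalog["id"]
                    for i in synthetic_data.ILLUMINANTS}
        for pid, grp in matches.groupby("participant_id"):
            got = {(s, i) for s, i in grp[["stimulus_id", "illuminant"]]
                   .itertuples(index=False)}
            for sid, illum in sorted(expected - got):
                problems.append(f"matches.csv: participant {pid!r} missing "
                                f"stimulus {sid!r} under {illum!r}")
    return problems
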