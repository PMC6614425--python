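"""Synthetic color-matching study generator.

Emulates the structure of a color-matching experiment in which 20 observers
match 35 real-world stimuli — 4 toys, 3 fruit, and 7 skin regions of each of
4 actors — once under near-monochromatic low-pressure-sodium (LPS) light and
once under broad-band white light.  The generator produces

* a deterministic stimulus catalog with the context flags the analysis needs
  (face context, 3-D cues, color diagnosticity, actor race),
* "spectroradiometric" measurements of every stimulus under both illuminants
  (category-typical CIELAB loci under white light; a shared near-illuminant
  hue with compressed chroma spread under LPS), and
* participant matches built from the measurements by a small generative
  model: a lightness-dependent hue rotation, chroma under-estimation under
  LPS, a face-context-specific greenward hue rotation under LPS (full for
  3-D faces, a configurable fraction for photographs, absent for masked
  foreheads and body skin), race-dependent lightness shifts, a per-observer
  hue bias, and i.i.d. match noise (variance-inflated for lips).

Hue effects are injected as rotations in the L*a*b* plane of the *matching
monitor's* white point — the space in which observers set their matches and
in which the downstream residual analysis runs.  Measurements are reported
in scene-white L*a*b*, as a spectroradiometric pipeline would.

All randomness flows through a caller-supplied :class:`numpy.random.Generator`,
so a seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import colorimetry as cm

__all__ = [
    "SimulationConfig",
    "make_stimulus_catalog",
    "make_measured_colors",
    "simulate_matches",
    "generate_study",
    "write_dataset",
    "read_dataset",
]

logger = logging.getLogger(__name__)

ILLUMINANTS = ("white", "LPS")
ACTORS = (
    ("actor1", "Caucasian"),
    ("actor2", "Caucasian"),
    ("actor3", "AfricanAmerican"),
    ("actor4", "AfricanAmerican"),
)
# per-actor regions and the category each maps to
_REGION_CATEGORY = {
    "forehead": "face_skin",
    "cheek": "face_skin",
    "lips": "lips",
    "neck": "body_skin",
    "hand": "body_skin",
    "photo": "photo",
    "masked_forehead": "masked_forehead",
}

CATALOG_COLUMNS = [
    "id", "category", "region", "actor", "race",
    "face_context", "three_d", "color_diagnostic",
]
MEASURED_COLUMNS = ["stimulus_id", "illuminant", "X", "Y", "Z", "L", "a", "b"]
MATCH_COLUMNS = [
    "participant_id", "stimulus_id", "illuminant",
    "R", "G", "B", "L", "a", "b", "hue", "chroma",
]


class DataIntegrityError(ValueError):
    """Dataset violates a structural invariant (schema, completeness, gamut)."""


@dataclass
class SimulationConfig:
    """Parameters of the generative model for matches.

    Hue parameters are degrees of CIE a*b* angle; positive rotations are
    counterclockwise (from the yellowish LPS locus toward green).
    """

    seed: int = 0
    n_participants: int = 20
    #: hue rotation per L* unit of measured lightness (dark → redder,
    #: light → yellower); degrees per L* unit
    lightness_hue_slope: float = 0.2
    #: multiplicative chroma under-estimation of matches under LPS
    lps_chroma_compression: float = 0.6
    #: greenward hue rotation for face-context 3-D stimuli under LPS (deg)
    delta_face: float = 30.0
    #: fraction of delta_face applied to photographs of faces
    photo_fraction: float = 0.4
    #: lightness-match shift, +shift for Caucasian, −shift for African
    #: American skin stimuli (L* units)
    race_lightness_shift: float = 5.0
    #: SD of the per-observer hue bias (deg, shared across all matches)
    participant_sd: float = 5.0
    #: SD of i.i.d. hue noise per match (deg)
    match_noise_sd: float = 12.0
    #: SD of i.i.d. lightness noise per match (L* units)
    lightness_noise_sd: float = 3.0
    #: hue-noise *variance* multiplier for lip stimuli
    lips_variance_inflation: float = 3.0
    monitor_white: np.ndarray = field(default_factory=lambda: cm.MONITOR_WHITE_XYZ.copy())
    scene_white: np.ndarray = field(default_factory=lambda: cm.SCENE_WHITE_XYZ.copy())

    def __post_init__(self) -> None:
        for name in (
            "participant_sd", "match_noise_sd", "lightness_noise_sd",
            "photo_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.lps_chroma_compression <= 1):
            raise ValueError("lps_chroma_compression must be in (0, 1]")
        if self.photo_fraction > 1:
            raise ValueError("photo_fraction must be in [0, 1]")
        if self.lips_variance_inflation < 1:
            raise ValueError("lips_variance_inflation must be >= 1")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


def make_stimulus_catalog() -> pd.DataFrame:
    """The fixed 35-stimulus inventory: 4 toys, 3 fruit, 7 regions × 4 actors.

    Deterministic; flags follow the study design: ``face_context`` is true for
    face skin, lips and face photographs; ``three_d`` is false for photographs
    and masked foreheads; ``color_diagnostic`` is false exactly for the two
    Legos, the toy phone, the ping-pong ball, and the masked foreheads
    (arbitrary colors, or skin stripped of its shape context).
    """
    rows: list[dict] = []

    def add(id_, category, region, actor, race, face, three_d, diagnostic):
        rows.append(dict(zip(CATALOG_COLUMNS,
                             (id_, category, region, actor, race, face, three_d, diagnostic))))

    add("lego_red", "toy", "body", "none", "none", False, True, False)
    add("lego_yellow", "toy", "body", "none", "none", False, True, False)
    add("toy_phone", "toy", "body", "none", "none", False, True, False)
    add("ping_pong_ball", "toy", "body", "none", "none", False, True, False)
    add("strawberry", "fruit", "body", "none", "none", False, True, True)
    add("tomato", "fruit", "body", "none", "none", False, True, True)
    add("orange_fruit", "fruit", "body", "none", "none", False, True, True)
    for actor, race in ACTORS:
        for region, category in _REGION_CATEGORY.items():
            add(
                f"{actor}_{region}", category, region, actor, race,
                face=category in ("face_skin", "lips", "photo"),
                three_d=region not in ("photo", "masked_forehead"),
                diagnostic=category != "masked_forehead",
            )
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


# White-light loci as (L*, hue°, chroma) in the *monitor-white* L*a*b* space
# (the space in which observers set matches; defining loci there keeps the
# whole generative model inside the monitor gamut).  The stored measurement
# records are re-expressed under the scene white point.  Toys/fruit are
# saturated; skin is low-chroma orange whose lightness and chroma depend on
# race; lips are redder and slightly more chromatic.
_WHITE_LOCI = {
    "lego_red": (45.0, 28.0, 45.0),
    "lego_yellow": (80.0, 88.0, 50.0),
    "toy_phone": (62.0, 55.0, 45.0),
    "ping_pong_ball": (84.0, 70.0, 1.5),
    "strawberry": (42.0, 25.0, 42.0),
    "tomato": (46.0, 33.0, 45.0),
    "orange_fruit": (65.0, 55.0, 45.0),
}
_SKIN_BASE = {  # race -> (L*, hue°, chroma)
    "Caucasian": (68.0, 50.0, 20.0),
    "AfricanAmerican": (42.0, 52.0, 14.0),
}
_REGION_OFFSET = {  # region -> (dL, dhue, dchroma)
    "forehead": (0.0, 0.0, 0.0),
    "cheek": (-1.0, -4.0, 2.0),
    "lips": (-12.0, -18.0, 5.0),
    "neck": (-2.0, 1.0, -1.0),
    "hand": (1.0, 2.0, 0.0),
    "photo": (0.0, 0.0, 0.0),
    "masked_forehead": (0.0, 0.0, 0.0),
}
# LPS illuminant locus: near-monochromatic sodium light, yellow-orange hue.
# Under a monochromatic illuminant every surface reflects the same single
# wavelength, so all stimuli share the illuminant's *chromaticity*; only
# luminance varies.  The locus is specified as hue/chroma at a reference
# lightness; per-stimulus Lab chroma then scales with lightness implicitly.
_LPS_HUE = 71.0
_LPS_CHROMA_REF = 27.0
_LPS_L_REF = 70.0
_LPS_HUE_SD = 0.3      # spectroradiometric measurement jitter (deg)
_LPS_CHROMA_SD = 0.5   # measurement jitter at the reference lightness


def _white_locus(row: pd.Series) -> tuple[float, float, float]:
    if row["id"] in _WHITE_LOCI:
        return _WHITE_LOCI[row["id"]]
    L, h, c = _SKIN_BASE[row["race"]]
    dL, dh, dc = _REGION_OFFSET[row["region"]]
    return (L + dL, h + dh, c + dc)


def make_measured_colors(
    catalog: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Spectroradiometric-style measurements of every stimulus × illuminant.

    White-light colors sit at category-typical loci (with a small per-stimulus
    jitter).  LPS colors keep each stimulus's lightness but collapse onto the
    shared chromaticity of the monochromatic illuminant (small measurement
    jitter only), so measured hue varies far less under LPS than under white
    light and Lab chroma shrinks with lightness.  Loci are designed in
    monitor-white L*a*b*; the stored XYZ are rescaled to the scene luminance
    scale and the stored L*a*b* computed against the scene white, as a
    spectroradiometric pipeline reports them.
    """
    scale = float(config.scene_white[1]) / float(config.monitor_white[1])

    def lum(L):  # relative luminance Y for lightness L* (monitor scale)
        return float(cm.lab_to_xyz([L, 0.0, 0.0], config.monitor_white)[1])

    rows = []
    for _, stim in catalog.iterrows():
        L, h, c = _white_locus(stim)
        L += rng.normal(0.0, 1.0)
        h += rng.normal(0.0, 1.5)
        if stim["id"] != "ping_pong_ball":  # keep the ball near-achromatic
            c = max(0.5, c + rng.normal(0.0, 1.5))
        xyz_white = cm.lab_to_xyz(cm.lab_from_polar(L, h, c), config.monitor_white)

        # same chromaticity for every surface: the illuminant locus at a
        # reference lightness, luminance-scaled to this stimulus's lightness
        lab_ref = cm.lab_from_polar(
            _LPS_L_REF,
            _LPS_HUE + rng.normal(0.0, _LPS_HUE_SD),
            _LPS_CHROMA_REF + rng.normal(0.0, _LPS_CHROMA_SD),
        )
        xyz_ref = cm.lab_to_xyz(lab_ref, config.monitor_white)
        xyz_lps = xyz_ref * (lum(L) / float(xyz_ref[1]))

        for illum, xyz in (("white", xyz_white), ("LPS", xyz_lps)):
            xyz = np.asarray(xyz) * scale
            lab_scene = cm.xyz_to_lab(xyz, config.scene_white)
            rows.append(
                dict(zip(MEASURED_COLUMNS,
                         (stim["id"], illum, *xyz, *np.asarray(lab_scene)))))
    return pd.DataFrame(rows, columns=MEASURED_COLUMNS)


def reference_lab(measured: pd.DataFrame, white,
                  source_white=None) -> pd.DataFrame:
    """Measured colors re-expressed as L*a*b* under a different white point.

    The match generator and the hue-residual regression both work in the
    monitor-white L*a*b* space; this returns the measured XYZ converted there,
    with hue/chroma columns.  ``source_white`` is the white point of the
    measurement scale; when given, the XYZ are rescaled so that relative
    luminance Y/Yn is preserved across the two scales (relative colorimetry —
    spectroradiometric and monitor units are otherwise incommensurate).
    """
    xyz = measured[["X", "Y", "Z"]].to_numpy(dtype=float)
    if source_white is not None:
        xyz = xyz * (np.asarray(white, dtype=float)[1]
                     / np.asarray(source_white, dtype=float)[1])
    lab = cm.xyz_to_lab(xyz, white)
    hue, chroma = cm.hue_chroma(lab)
    out = measured[["stimulus_id", "illuminant"]].copy()
    out[["L", "a", "b"]] = lab
    out["hue"], out["chroma"] = hue, chroma
    return out


def simulate_matches(
    catalog: pd.DataFrame,
    measured: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    calib: cm.MonitorCalibration | None = None,
) -> pd.DataFrame:
    """Generate one match per participant × stimulus × illuminant.

    The matched color starts from the measured color (re-expressed in
    monitor-white L*a*b*) and is perturbed per the generative model; the
    resulting L*a*b* is driven through the monitor model to RGB (clipping to
    gamut is logged, never silent) and the recorded L*a*b*/hue/chroma are
    recomputed from the on-screen RGB, exactly as the analysis pipeline
    sees them.
    """
    calib = calib or cm.default_calibration()
    ref = reference_lab(measured, config.monitor_white, config.scene_white)
    ref = ref.merge(catalog, left_on="stimulus_id", right_on="id", how="left")
    if ref["category"].isna().any():
        missing = ref.loc[ref["category"].isna(), "stimulus_id"].iloc[0]
        raise DataIntegrityError(f"measured stimulus {missing!r} not in catalog")
    got = {(s, i) for s, i in measured[["stimulus_id", "illuminant"]].itertuples(index=False)}
    for sid in catalog["id"]:
        for illum in ILLUMINANTS:
            if (sid, illum) not in got:
                raise DataIntegrityError(f"no measurement for {sid!r} under {illum!r}")

    # mean measured lightness per illuminant (reference space) anchors the
    # lightness–hue rotation
    L_bar = ref.groupby("illuminant")["L"].transform("mean")

    participant_bias = rng.normal(0.0, config.participant_sd, config.n_participants)

    frames = []
    n_clipped = 0
    for p in range(config.n_participants):
        rot = config.lightness_hue_slope * (ref["L"] - L_bar)
        is_lps = ref["illuminant"] == "LPS"
        mult = np.where(
            ref["face_context"] & ref["three_d"], 1.0,
            np.where(ref["category"] == "photo", config.photo_fraction, 0.0))
        rot = rot + np.where(is_lps, config.delta_face * mult, 0.0)
        noise_sd = np.where(
            ref["category"] == "lips",
            config.match_noise_sd * np.sqrt(config.lips_variance_inflation),
            config.match_noise_sd)
        rot = rot + participant_bias[p] + rng.normal(0.0, 1.0, len(ref)) * noise_sd

        hue = (ref["hue"] + rot) % 360.0
        chroma = ref["chroma"] * np.where(is_lps, config.lps_chroma_compression, 1.0)
        race_shift = np.where(
            ref["race"] == "Caucasian", config.race_lightness_shift,
            np.where(ref["race"] == "AfricanAmerican", -config.race_lightness_shift, 0.0))
        L = ref["L"] + race_shift + rng.normal(0.0, config.lightness_noise_sd, len(ref))
        L = np.clip(L, 1.0, 99.0)

        lab = cm.lab_from_polar(L.to_numpy(), hue.to_numpy(), chroma.to_numpy())
        xyz = cm.lab_to_xyz(lab, config.monitor_white)
        rgb, oog = cm.xyz_to_rgb(xyz, calib, clip=True)
        n_clipped += int(oog.sum())
        # record what is actually on screen
        lab_out = cm.xyz_to_lab(cm.rgb_to_xyz(rgb, calib), config.monitor_white)
        hue_out, chroma_out = cm.hue_chroma(lab_out)
        frames.append(pd.DataFrame({
            "participant_id": f"P{p + 1:02d}",
            "stimulus_id": ref["stimulus_id"],
            "illuminant": ref["illuminant"],
            "R": rgb[:, 0], "G": rgb[:, 1], "B": rgb[:, 2],
            "L": lab_out[:, 0], "a": lab_out[:, 1], "b": lab_out[:, 2],
            "hue": hue_out, "chroma": chroma_out,
        }))
    if n_clipped:
        logger.warning("gamut clipping applied to %d of %d matches",
                       n_clipped, len(ref) * config.n_participants)
    return pd.concat(frames, ignore_index=True)[MATCH_COLUMNS]


def generate_study(
    config: SimulationConfig | None = None, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Catalog, measurements and matches for one full synthetic study."""
    config = config or SimulationConfig()
    rng = rng or np.random.default_rng(config.seed)
    catalog = make_stimulus_catalog()
    measured = make_measured_colors(catalog, config, rng)
    matches = simulate_matches(catalog, measured, config, rng)
    return catalog, measured, matches


# ---------------------------------------------------------------------------
# dataset I/O — plain CSV, lossless round trip

_FLOAT_FMT = "%.10g"


def write_dataset(path, catalog: pd.DataFrame, measured: pd.DataFrame,
                  matches: pd.DataFrame) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    catalog[CATALOG_COLUMNS].to_csv(path / "stimuli.csv", index=False)
    measured[MEASURED_COLUMNS].to_csv(path / "measured.csv", index=False,
                                      float_format=_FLOAT_FMT)
    matches[MATCH_COLUMNS].to_csv(path / "matches.csv", index=False,
                                  float_format=_FLOAT_FMT)


def _check_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise DataIntegrityError(f"{name}: missing columns {sorted(missing)}")


def read_dataset(path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read ``stimuli.csv``/``measured.csv``/``matches.csv`` with validation."""
    path = Path(path)
    catalog = pd.read_csv(path / "stimuli.csv")
    measured = pd.read_csv(path / "measured.csv")
    matches = pd.read_csv(path / "matches.csv")
    _check_columns(catalog, CATALOG_COLUMNS, "stimuli.csv")
    _check_columns(measured, MEASURED_COLUMNS, "measured.csv")
    _check_columns(matches, MATCH_COLUMNS, "matches.csv")
    for name, df in (("measured.csv", measured), ("matches.csv", matches)):
        bad = ~df["illuminant"].isin(ILLUMINANTS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataIntegrityError(
                f"{name} row {row + 2}: unknown illuminant "
                f"{df['illuminant'].iloc[row]!r}")
    if len(matches):
        rgb = matches[["R", "G", "B"]].to_numpy(dtype=float)
        bad = np.any((rgb < 0) | (rgb > 1), axis=1)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise DataIntegrityError(f"matches.csv row {row + 2}: RGB out of gamut")
    return catalog, measured, matches


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["monitor_white"] = list(map(float, d["monitor_white"]))
    d["scene_white"] = list(map(float, d["scene_white"]))
    return d
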