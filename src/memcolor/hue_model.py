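"""Hue-estimation regression and memory-color residuals.

The central statistic of the analysis: an ordinary-least-squares model of
matched color on measured color, trained only on stimuli whose color carries
no shape-specific expectation (the two Legos, the toy phone, and the masked
foreheads), then applied to all stimuli.  The signed circular difference
between each matched hue and the model's estimated hue — the hue residual —
quantifies what object knowledge contributed to the match.

Because hue is circular while lightness and chroma are linear, the model is
fit in Cartesian a*b* coordinates: the predictors are (1, measured a*,
measured b*, measured L*, measured C*) and the responses the matched
(a*, b*), fit jointly by OLS; predicted (a*, b*) are then converted back to
a hue angle.  One fit per illuminant.  Positive residuals are
counterclockwise in the a*b* plane — from the yellowish LPS locus toward
green — so the face memory-color effect under LPS light is positive.

Group residual summaries carry percentile bootstrap confidence intervals
(default 1000 resamples, 99% level), resampling residual records with
replacement; a participant-level (clustered) bootstrap is available via
``bootstrap_mode="participant"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import colorimetry as cm

__all__ = [
    "HueModelFit",
    "select_training",
    "fit_hue_model",
    "estimate_hue",
    "hue_residuals",
    "category_residual_summary",
    "bootstrap_ci",
]

PREDICTOR_NAMES = ("intercept", "a", "b", "L", "chroma")

# non-diagnostic stimuli excluded from training anyway: near-achromatic
# matches make the hue angle unstable
_TRAINING_EXCLUDE = frozenset({"ping_pong_ball"})


class ModelError(ValueError):
    """Invalid training data or model state."""


@dataclass
class HueModelFit:
    """OLS map from measured (1, a*, b*, L*, C*) to matched (a*, b*)."""

    illuminant: str
    #: (5, 2) coefficient matrix, rows per PREDICTOR_NAMES, cols (a*, b*)
    coefficients: np.ndarray
    training_ids: tuple[str, ...]
    #: Pearson r between matched and estimated hue on the training records
    fit_correlation: float


def select_training(matches: pd.DataFrame, catalog: pd.DataFrame,
                    illuminant: str) -> pd.DataFrame:
    """Matches to the non-color-diagnostic training stimuli, one illuminant.

    Training set = stimuli flagged non-diagnostic minus the ping-pong ball
    (its matches are close to achromatic, so their hue is unstable); with the
    full catalog that is the 2 Legos, the toy phone, and the 4 masked
    foreheads.
    """
    if illuminant not in set(matches["illuminant"]):
        raise ModelError(f"unknown illuminant {illuminant!r}")
    ids = set(catalog.loc[~catalog["color_diagnostic"], "id"]) - _TRAINING_EXCLUDE
    out = matches[(matches["illuminant"] == illuminant)
                  & matches["stimulus_id"].isin(ids)]
    if out.empty:
        raise ModelError(f"no training matches for illuminant {illuminant!r}")
    return out


def _design(measured_lab: pd.DataFrame) -> np.ndarray:
    X = measured_lab[["a", "b", "L", "chroma"]].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(X)), X])


def fit_hue_model(training_matches: pd.DataFrame,
                  measured_lab: pd.DataFrame,
                  rcond: float = 1e-4) -> HueModelFit:
    """Fit the measured→matched OLS model for one illuminant.

    ``measured_lab`` must carry the measured colors *in the same L*a*b* space
    as the matches* (monitor white point), with columns ``stimulus_id``,
    ``illuminant``, ``L``, ``a``, ``b``, ``chroma`` — see
    :func:`memcolor.synthetic_data.reference_lab`.

    The normal equations are solved by truncated SVD: singular values below
    ``rcond`` times the largest are discarded.  Under a near-monochromatic
    illuminant the measured colors collapse onto a one-dimensional manifold
    (a*, b* and C* all proportional, driven by lightness), leaving the design
    ill conditioned; without truncation the near-null directions acquire huge
    coefficients that amplify measurement jitter into tens of degrees of
    prediction error off the training stimuli.  Truncation keeps predictions
    on the populated manifold.  Exactly collinear predictors still raise.
    """
    illums = training_matches["illuminant"].unique()
    if len(illums) != 1:
        raise ModelError("training matches must come from a single illuminant")
    illuminant = illums[0]
    if len(training_matches) < 10:
        raise ModelError(f"need >= 10 training records, got {len(training_matches)}")

    meas = measured_lab[measured_lab["illuminant"] == illuminant]
    merged = training_matches.merge(
        meas, on="stimulus_id", suffixes=("_match", "_meas"))
    if len(merged) != len(training_matches):
        raise ModelError("missing measured color for some training stimuli")

    X = _design(merged.rename(columns={
        "a_meas": "a", "b_meas": "b", "L_meas": "L", "chroma_meas": "chroma"}))
    Y = merged[["a_match", "b_match"]].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ModelError(
            f"rank-deficient predictors (rank {rank} < {X.shape[1]}): "
            "measured a*, b*, L*, C* are collinear in the training set")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=rcond)

    pred = X @ beta
    est_hue, _ = cm.hue_chroma(pred)
    match_hue = merged["hue_match" if "hue_match" in merged else "hue"].to_numpy()
    ok = ~np.isnan(est_hue) & ~np.isnan(match_hue)
    # unwrap matched hue onto the branch nearest its estimate so that
    # red-adjacent hues (wrapping 360→0) do not wreck the correlation
    aligned = est_hue[ok] + cm.circular_diff(match_hue[ok], est_hue[ok])
    r = float(np.corrcoef(aligned, est_hue[ok])[0, 1]) if ok.sum() > 2 else np.nan
    return HueModelFit(
        illuminant=str(illuminant),
        coefficients=beta,
        training_ids=tuple(sorted(training_matches["stimulus_id"].unique())),
        fit_correlation=r,
    )


def estimate_hue(fit: HueModelFit, measured_lab: pd.DataFrame) -> np.ndarray:
    """Estimated hue angle for measured colors (NaN where predicted C* = 0)."""
    pred = _design(measured_lab) @ fit.coefficients
    hue, _ = cm.hue_chroma(pred)
    return hue


def hue_residuals(matches: pd.DataFrame, fits: dict[str, HueModelFit],
                  measured_lab: pd.DataFrame) -> pd.DataFrame:
    """Signed circular residual (matched − estimated hue) per match.

    Matches with undefined hue are dropped.  Returns columns
    participant_id, stimulus_id, illuminant, matched_hue, estimated_hue,
    residual.
    """
    frames = []
    for illuminant, fit in fits.items():
        sub = matches[matches["illuminant"] == illuminant]
        meas = measured_lab[measured_lab["illuminant"] == illuminant]
        merged = sub.merge(meas, on="stimulus_id", suffixes=("_match", "_meas"))
        est = estimate_hue(fit, merged.rename(columns={
            "a_meas": "a", "b_meas": "b", "L_meas": "L", "chroma_meas": "chroma"}))
        hue_col = "hue_match" if "hue_match" in merged else "hue"
        matched = merged[hue_col].to_numpy(dtype=float)
        ok = ~np.isnan(matched) & ~np.isnan(est)
        frames.append(pd.DataFrame({
            "participant_id": merged.loc[ok, "participant_id"].to_numpy(),
            "stimulus_id": merged.loc[ok, "stimulus_id"].to_numpy(),
            "illuminant": illuminant,
            "matched_hue": matched[ok],
            "estimated_hue": est[ok],
            "residual": cm.circular_diff(matched[ok], est[ok]),
        }))
    return pd.concat(frames, ignore_index=True)


def bootstrap_ci(values: np.ndarray, n_boot: int, level: float,
                 rng: np.random.Generator,
                 clusters: np.ndarray | None = None) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean.

    With ``clusters`` given, whole clusters (participants) are resampled with
    replacement instead of individual records.
    """
    values = np.asarray(values, dtype=float)
    alpha = (1.0 - level) / 2.0
    if clusters is None:
        idx = rng.integers(0, len(values), size=(n_boot, len(values)))
        stats = values[idx].mean(axis=1)
    else:
        uniq = np.unique(clusters)
        groups = [values[clusters == c] for c in uniq]
        stats = np.empty(n_boot)
        for i in range(n_boot):
            pick = rng.integers(0, len(uniq), size=len(uniq))
            stats[i] = np.concatenate([groups[j] for j in pick]).mean()
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def pipeline_bootstrap_ci(
    matches: pd.DataFrame,
    catalog: pd.DataFrame,
    measured_lab: pd.DataFrame,
    illuminant: str,
    category: str,
    n_boot: int = 1000,
    level: float = 0.99,
    rng: np.random.Generator | None = None,
    rcond: float = 1e-4,
) -> tuple[float, float, float]:
    """Full-pipeline bootstrap CI for a category's mean hue residual.

    Resamples *participants* with replacement and, for every replicate,
    refits the hue model on the resampled training records before averaging
    the target category's residuals.  Unlike the record-level bootstrap of
    :func:`category_residual_summary`, this propagates the uncertainty of the
    model fit itself — which is shared across all records of a category and
    therefore invisible to record resampling.  Returns
    ``(mean, ci_low, ci_high)`` where ``mean`` is the point estimate on the
    original data.
    """
    rng = rng or np.random.default_rng()
    training = select_training(matches, catalog, illuminant)
    meas = measured_lab[measured_lab["illuminant"] == illuminant]

    def _design_and_merge(records: pd.DataFrame):
        merged = records.merge(meas, on="stimulus_id", suffixes=("_match", "_meas"))
        X = _design(merged.rename(columns={
            "a_meas": "a", "b_meas": "b", "L_meas": "L", "chroma_meas": "chroma"}))
        return merged, X

    tr_merged, X_tr = _design_and_merge(training)
    Y_tr = tr_merged[["a_match", "b_match"]].to_numpy(dtype=float)
    target_ids = set(catalog.loc[catalog["category"] == category, "id"])
    target = matches[(matches["illuminant"] == illuminant)
                     & matches["stimulus_id"].isin(target_ids)]
    if target.empty:
        raise ModelError(f"no matches for category {category!r}")
    tg_merged, X_tg = _design_and_merge(target)
    hue_tg = tg_merged["hue_match"].to_numpy(dtype=float)

    participants = np.unique(matches["participant_id"])
    tr_pid = tr_merged["participant_id"].to_numpy()
    tg_pid = tg_merged["participant_id"].to_numpy()
    tr_rows = {p: np.flatnonzero(tr_pid == p) for p in participants}
    tg_rows = {p: np.flatnonzero(tg_pid == p) for p in participants}

    def _mean_residual(tr_idx: np.ndarray, tg_idx: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X_tr[tr_idx], Y_tr[tr_idx], rcond=rcond)
        est, _ = cm.hue_chroma(X_tg[tg_idx] @ beta)
        d = cm.circular_diff(hue_tg[tg_idx], est)
        return float(np.nanmean(d))

    all_tr = np.arange(len(X_tr))
    all_tg = np.arange(len(X_tg))
    point = _mean_residual(all_tr, all_tg)
    stats_ = np.empty(n_boot)
    for i in range(n_boot):
        pick = rng.choice(participants, size=len(participants), replace=True)
        tr_idx = np.concatenate([tr_rows[p] for p in pick])
        tg_idx = np.concatenate([tg_rows[p] for p in pick])
        stats_[i] = _mean_residual(tr_idx, tg_idx)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats_, [alpha, 1.0 - alpha])
    return point, float(lo), float(hi)


def category_residual_summary(
    residuals: pd.DataFrame,
    catalog: pd.DataFrame,
    grouping: list[str],
    n_boot: int = 1000,
    level: float = 0.99,
    rng: np.random.Generator | None = None,
    bootstrap_mode: str = "record",
) -> pd.DataFrame:
    """Group means of hue residuals with percentile bootstrap CIs.

    ``grouping`` may contain ``illuminant`` plus any catalog flag among
    {category, race, face_context, three_d}.  Empty groups are reported with
    n = 0 and null CI rather than dropped.
    """
    allowed = {"category", "illuminant", "race", "face_context", "three_d"}
    bad = set(grouping) - allowed
    if bad:
        raise ValueError(f"unsupported grouping keys: {sorted(bad)}")
    if bootstrap_mode not in ("record", "participant"):
        raise ValueError(f"unknown bootstrap_mode {bootstrap_mode!r}")
    rng = rng or np.random.default_rng()

    df = residuals.merge(catalog, left_on="stimulus_id", right_on="id")
    levels = [sorted(df[g].unique()) for g in grouping]
    index = pd.MultiIndex.from_product(levels, names=grouping)
    rows = []
    grouped = {
        (k if isinstance(k, tuple) else (k,)): v for k, v in df.groupby(grouping)
    }
    for key in index:
        key_t = tuple(key) if isinstance(key, tuple) else (key,)
        g = grouped.get(key_t)
        if g is None or g.empty:
            rows.append((*key_t, 0, np.nan, np.nan, np.nan))
            continue
        vals = g["residual"].to_numpy()
        clusters = (g["participant_id"].to_numpy()
                    if bootstrap_mode == "participant" else None)
        lo, hi = bootstrap_ci(vals, n_boot, level, rng, clusters)
        rows.append((*key_t, len(vals), float(vals.mean()), lo, hi))
    out = pd.DataFrame(rows, columns=[*grouping, "n", "mean", "ci_low", "ci_high"])
    out["n_boot"], out["level"] = n_boot, level
    return out
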