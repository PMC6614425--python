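"""Color-space machinery for the color-matching analysis.

Everything downstream happens in CIE 1976 L*a*b*.  Monitor RGB settings are
linearized with a per-channel gamma, mapped to CIE XYZ through the measured
primary matrix, and converted to L*a*b* relative to a reference white.  Two
reference whites are in play and must never be conflated:

* the *monitor* white point — the XYZ of the display at RGB=(1,1,1); monitor
  matches are converted with it;
* the *scene* white point — the XYZ of a white reference card under the room's
  white illuminant; spectroradiometric measurements of the stimuli are
  reported with it.

Hue is the CIE a*b* angle in degrees, counterclockwise from +a*: 0° is the
red direction, 90° yellow, 180° green.  Chroma is the (a*, b*) vector length.
A chroma of zero leaves hue undefined; that case is flagged explicitly (NaN
hue) rather than silently reported as 0°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MONITOR_WHITE_XYZ",
    "SCENE_WHITE_XYZ",
    "MonitorCalibration",
    "default_calibration",
    "linearize_rgb",
    "delinearize_rgb",
    "rgb_to_xyz",
    "xyz_to_rgb",
    "xyz_to_lab",
    "lab_to_xyz",
    "hue_chroma",
    "lab_from_polar",
    "circular_diff",
    "circular_mean",
]

# Matching-monitor white point (XYZ of RGB=(1,1,1) on the calibrated display).
MONITOR_WHITE_XYZ = np.array([87.4, 100.0, 57.7])

# White reference card under the room's broad-band white illuminant; the
# white point for spectroradiometric stimulus measurements.
SCENE_WHITE_XYZ = np.array([27.9446, 25.0000, 10.5134])

# CIELAB transfer function: cube root above the (6/29)^3 break point,
# linear segment of slope (1/3)(29/6)^2 below it.
_EPS = (6.0 / 29.0) ** 3
_KAPPA = (29.0 / 6.0) ** 2 / 3.0


class ColorimetryError(ValueError):
    """Invalid colorimetric input or configuration."""


@dataclass(frozen=True)
class MonitorCalibration:
    """Linear-RGB → XYZ primary matrix plus per-channel gamma.

    ``primary_matrix`` columns are the XYZ of the R, G, B primaries at full
    drive, so ``primary_matrix @ (1, 1, 1)`` is the monitor white point.
    """

    primary_matrix: np.ndarray
    gamma: np.ndarray = field(default_factory=lambda: np.array([2.2, 2.2, 2.2]))

    def __post_init__(self) -> None:
        m = np.asarray(self.primary_matrix, dtype=float)
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if g.size == 1:
            g = np.repeat(g, 3)
        if m.shape != (3, 3):
            raise ColorimetryError(f"primary_matrix must be 3x3, got {m.shape}")
        if g.shape != (3,) or np.any(g <= 0):
            raise ColorimetryError("gamma must be 3 positive exponents")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ColorimetryError("singular primary matrix")
        object.__setattr__(self, "primary_matrix", m)
        object.__setattr__(self, "gamma", g)

    @property
    def white_xyz(self) -> np.ndarray:
        return self.primary_matrix.sum(axis=1)

    @property
    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.primary_matrix)


def _primaries_for_white(xy_primaries: np.ndarray, white_xyz: np.ndarray) -> np.ndarray:
    """Scale primaries of given chromaticity so they sum to ``white_xyz``."""
    x, y = xy_primaries[:, 0], xy_primaries[:, 1]
    # columns: XYZ direction of each primary at unit Y
    dirs = np.stack([x / y, np.ones_like(y), (1.0 - x - y) / y])
    lum = np.linalg.solve(dirs, np.asarray(white_xyz, dtype=float))
    if np.any(lum <= 0):
        raise ColorimetryError("white point outside the primaries' gamut")
    return dirs * lum


def default_calibration(gamma: float = 2.2) -> MonitorCalibration:
    """Calibration of the study's matching monitor.

    Primary chromaticities are Rec.709-class (typical of the LCD used);
    primary luminances are solved so the full-drive white reproduces the
    measured monitor white point XYZ = (87.4, 100, 57.7) exactly.
    """
    xy = np.array([[0.640, 0.330], [0.300, 0.600], [0.150, 0.060]])
    return MonitorCalibration(_primaries_for_white(xy, MONITOR_WHITE_XYZ), np.full(3, gamma))


def linearize_rgb(rgb, calib: MonitorCalibration) -> np.ndarray:
    """Undo the display nonlinearity: channel c ↦ c**gamma, channels in [0, 1]."""
    rgb = np.asarray(rgb, dtype=float)
    if np.any(rgb < 0) or np.any(rgb > 1):
        bad = np.argwhere((rgb < 0) | (rgb > 1))
        idx = tuple(bad[0])
        raise ColorimetryError(
            f"RGB channel {'RGB'[idx[-1]]} out of [0,1]: {rgb[idx]!r}"
        )
    return rgb**calib.gamma


def delinearize_rgb(linear, calib: MonitorCalibration) -> np.ndarray:
    linear = np.clip(np.asarray(linear, dtype=float), 0.0, 1.0)
    return linear ** (1.0 / calib.gamma)


def rgb_to_xyz(rgb, calib: MonitorCalibration) -> np.ndarray:
    """Monitor RGB (possibly an (N, 3) array) → CIE XYZ."""
    lin = linearize_rgb(rgb, calib)
    return lin @ calib.primary_matrix.T


def xyz_to_rgb(xyz, calib: MonitorCalibration, clip: bool = False):
    """CIE XYZ → monitor RGB.  With ``clip=False`` out-of-gamut input raises;
    with ``clip=True`` it is clipped and a boolean out-of-gamut mask returned.
    """
    xyz = np.asarray(xyz, dtype=float)
    lin = xyz @ calib.inverse_matrix.T
    oog = np.any((lin < -1e-9) | (lin > 1 + 1e-9), axis=-1)
    if not clip:
        if np.any(oog):
            raise ColorimetryError("XYZ outside monitor gamut; pass clip=True")
        return delinearize_rgb(lin, calib)
    return delinearize_rgb(lin, calib), oog


def _f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _EPS, np.cbrt(t), _KAPPA * t + 4.0 / 29.0)


def _f_inv(u: np.ndarray) -> np.ndarray:
    return np.where(u > 6.0 / 29.0, u**3, (u - 4.0 / 29.0) / _KAPPA)


def xyz_to_lab(xyz, white) -> np.ndarray:
    """CIE XYZ → L*a*b* relative to ``white`` (an XYZ triplet, Y > 0)."""
    white = np.asarray(white, dtype=float)
    if white[1] <= 0:
        raise ColorimetryError("white point must have Y > 0")
    xyz = np.asarray(xyz, dtype=float)
    fx, fy, fz = (_f(xyz[..., i] / white[i]) for i in range(3))
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return np.stack([L, a, b], axis=-1)


def lab_to_xyz(lab, white) -> np.ndarray:
    """Inverse of :func:`xyz_to_lab`; exact round trip to numerical precision."""
    white = np.asarray(white, dtype=float)
    if white[1] <= 0:
        raise ColorimetryError("white point must have Y > 0")
    lab = np.asarray(lab, dtype=float)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    return np.stack(
        [_f_inv(fx) * white[0], _f_inv(fy) * white[1], _f_inv(fz) * white[2]],
        axis=-1,
    )


def hue_chroma(lab, chroma_tol: float = 1e-12):
    """(a*, b*) polar decomposition: hue angle in [0, 360) and chroma C*.

    Hue is NaN wherever chroma is below ``chroma_tol`` (achromatic colors have
    no defined hue and must be excluded from circular statistics).
    """
    lab = np.asarray(lab, dtype=float)
    a, b = lab[..., -2], lab[..., -1]
    chroma = np.hypot(a, b)
    hue = np.degrees(np.arctan2(b, a)) % 360.0
    hue = np.where(chroma < chroma_tol, np.nan, hue)
    return hue, chroma


def lab_from_polar(L, hue_deg, chroma) -> np.ndarray:
    """Assemble L*a*b* from lightness, hue angle (degrees) and chroma."""
    h = np.radians(np.asarray(hue_deg, dtype=float))
    return np.stack(
        np.broadcast_arrays(
            np.asarray(L, dtype=float),
            chroma * np.cos(h),
            chroma * np.sin(h),
        ),
        axis=-1,
    )


def circular_diff(h1, h2) -> np.ndarray | float:
    """Signed angular difference h1 − h2, wrapped to (−180, 180]."""
    d = (np.asarray(h1, dtype=float) - np.asarray(h2, dtype=float)) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    return d if d.ndim else float(d)


def circular_mean(hues_deg) -> float:
    """Circular mean of hue angles in degrees (NaN entries excluded)."""
    h = np.radians(np.asarray(hues_deg, dtype=float))
    h = h[~np.isnan(h)]
    if h.size == 0:
        return float("nan")
    return float(np.degrees(np.arctan2(np.sin(h).mean(), np.cos(h).mean())) % 360.0)
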