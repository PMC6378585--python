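"""Astigmatic 3D calibration: defocus curves, z lookup and persistence.

A cylindrical lens in the emission path makes the PSF elliptical away from
focus, with the x and y waists at different axial positions.  Each axis
follows the defocus model

    sigma(z) = sigma0 * sqrt(1 + ((z - c) / d)^2)

(sigma0: in-focus width, c: focal offset, d: depth scale, all nm).  Axial
position is recovered by inverting the pair of curves: we minimise the
distance between measured and calibrated widths on a square-root scale,
which de-emphasises the wide, slowly varying tails of the curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import least_squares

from .errors import (
    DegenerateCalibrationError,
    InsufficientDataError,
    SchemaError,
)

_Z_UNC_CAP_NM = 1000.0


@dataclass(frozen=True)
class DefocusCurve:
    """One axis of the astigmatic calibration."""

    sigma0_nm: float
    c_nm: float
    d_nm: float

    def __call__(self, z_nm):
        z = np.asarray(z_nm, dtype=float)
        return self.sigma0_nm * np.sqrt(1.0 + ((z - self.c_nm) / self.d_nm) ** 2)


@dataclass(frozen=True)
class AstigCalibration:
    """sigma_x(z), sigma_y(z) defocus curves with their validity range."""

    axis_x: DefocusCurve
    axis_y: DefocusCurve
    z_min_nm: float
    z_max_nm: float
    engine_tag: str = "gaussian"

    def __post_init__(self) -> None:
        for ax in (self.axis_x, self.axis_y):
            if not (ax.sigma0_nm > 0 and ax.d_nm > 0):
                raise DegenerateCalibrationError(
                    "defocus curve requires sigma0 > 0 and d > 0")
        if abs(self.axis_x.c_nm - self.axis_y.c_nm) < 1e-9:
            raise DegenerateCalibrationError(
                "focal offsets coincide; astigmatism requires c_x != c_y")
        if not self.z_min_nm < self.z_max_nm:
            raise DegenerateCalibrationError("need z_min < z_max")

    def sigmas(self, z_nm):
        return self.axis_x(z_nm), self.axis_y(z_nm)


def _fit_axis(z: np.ndarray, sig: np.ndarray) -> tuple[DefocusCurve, float]:
    def resid(p):
        s0, c, d = p
        return s0 * np.sqrt(1.0 + ((z - c) / d) ** 2) - sig

    span = z.max() - z.min()
    p0 = (float(sig.min()), float(z[np.argmin(sig)]), max(span / 2.0, 1.0))
    sol = least_squares(resid, p0, bounds=([1e-3, z.min() - span, 1e-3],
                                           [np.inf, z.max() + span, np.inf]))
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return DefocusCurve(*map(float, sol.x)), rms


def fit_calibration(bead_fits: Sequence[tuple[float, float, float]],
                    engine_tag: str = "gaussian"
                    ) -> tuple[AstigCalibration, float]:
    """Fit both defocus curves to (z_nm, sigma_x_nm, sigma_y_nm) triplets.

    Returns the calibration and the pooled residual RMS (nm).  Raises
    :class:`InsufficientDataError` for fewer than 7 distinct z positions and
    :class:`DegenerateCalibrationError` when the widths do not encode z
    (coincident foci, flat curves, or a non-monotonic width difference).
    """
    arr = np.asarray(list(bead_fits), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise InsufficientDataError("bead fits must be (z, sigma_x, sigma_y) rows")
    z, sx, sy = arr[:, 0], arr[:, 1], arr[:, 2]
    if len(np.unique(z)) < 7:
        raise InsufficientDataError(
            f"need >= 7 distinct z positions, got {len(np.unique(z))}")
    cx, rms_x = _fit_axis(z, sx)
    cy, rms_y = _fit_axis(z, sy)
    z_min, z_max = float(z.min()), float(z.max())
    # flat curves: predicted width variation must exceed fit noise floor
    grid = np.linspace(z_min, z_max, 201)
    for curve in (cx, cy):
        s = curve(grid)
        if np.ptp(s) < 1e-3 * curve.sigma0_nm:
            raise DegenerateCalibrationError(
                "widths do not vary with z; cannot calibrate")
    if abs(cx.c_nm - cy.c_nm) < 5.0:
        raise DegenerateCalibrationError(
            f"focal offsets nearly coincide ({cx.c_nm:.1f} vs {cy.c_nm:.1f} nm)")
    cal = AstigCalibration(cx, cy, z_min, z_max, engine_tag)
    diff = np.sqrt(cx(grid)) - np.sqrt(cy(grid))
    ddiff = np.diff(diff)
    if not (np.all(ddiff > 0) or np.all(ddiff < 0)):
        raise DegenerateCalibrationError(
            "width difference is not monotonic over the z range")
    return cal, float(np.hypot(rms_x, rms_y) / np.sqrt(2.0))


def z_lookup(sigma_x_nm: float, sigma_y_nm: float, cal: AstigCalibration
             ) -> tuple[float, float]:
    """Invert the calibration: widths -> (z_nm, residual).

    Minimises ``(sqrt(sx) - sqrt(sx_cal(z)))^2 + (sqrt(sy) - sqrt(sy_cal(z)))^2``
    on a 1 nm grid over the validity range, then refines the minimum with a
    parabola through the three surrounding grid points.  Out-of-range widths
    clamp to the nearest boundary (with a correspondingly large residual).
    """
    z, res = z_lookup_batch(np.atleast_1d(sigma_x_nm),
                            np.atleast_1d(sigma_y_nm), cal)
    return float(z[0]), float(res[0])


def z_lookup_batch(sigma_x_nm, sigma_y_nm, cal: AstigCalibration
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`z_lookup` over arrays of widths."""
    sx = np.sqrt(np.asarray(sigma_x_nm, dtype=float))[:, None]
    sy = np.sqrt(np.asarray(sigma_y_nm, dtype=float))[:, None]
    grid = np.arange(cal.z_min_nm, cal.z_max_nm + 0.5, 1.0)
    gx = np.sqrt(cal.axis_x(grid))[None, :]
    gy = np.sqrt(cal.axis_y(grid))[None, :]
    dist = (sx - gx) ** 2 + (sy - gy) ** 2
    idx = np.argmin(dist, axis=1)
    z_star = grid[idx]
    res = dist[np.arange(len(idx)), idx]
    # parabolic refinement where the minimum is interior
    interior = (idx > 0) & (idx < len(grid) - 1)
    if np.any(interior):
        i = idx[interior]
        rows = np.flatnonzero(interior)
        d0 = dist[rows, i - 1]
        d1 = dist[rows, i]
        d2 = dist[rows, i + 1]
        denom = d0 - 2 * d1 + d2
        shift = np.where(denom > 0, 0.5 * (d0 - d2) / np.where(denom == 0, 1, denom),
                         0.0)
        shift = np.clip(shift, -1.0, 1.0)
        z_star = z_star.astype(float)
        z_star[interior] = grid[i] + shift
        res = res.astype(float)
        res[rows] = np.where(denom > 0, d1 - 0.125 * (d0 - d2) * shift, d1)
    return np.asarray(z_star, dtype=float), np.asarray(res, dtype=float)


def z_uncertainty(sigma_x_nm, sigma_y_nm, uncertainty_xy_nm, z_star_nm,
                  cal: AstigCalibration) -> np.ndarray:
    """Axial precision from the lateral width uncertainty and curve slope.

    Propagates the width uncertainty through the calibration difference
    sigma_diff(z) = sqrt(sigma_x_cal) - sqrt(sigma_y_cal):
    ``dz = d(sqrt(sigma)) / |d sigma_diff / dz|`` evaluated at z*, capped at
    1000 nm (values far beyond the 500 nm quality filter carry no meaning).
    """
    sx = np.asarray(sigma_x_nm, dtype=float)
    sy = np.asarray(sigma_y_nm, dtype=float)
    dxy = np.asarray(uncertainty_xy_nm, dtype=float)
    z = np.asarray(z_star_nm, dtype=float)
    h = 1.0
    diff = lambda zz: np.sqrt(cal.axis_x(zz)) - np.sqrt(cal.axis_y(zz))  # noqa: E731
    slope = np.abs(diff(z + h) - diff(z - h)) / (2 * h)
    sbar = np.sqrt(sx * sy)
    d_sqrt_sigma = dxy / (2.0 * np.sqrt(sbar))
    with np.errstate(divide="ignore", invalid="ignore"):
        dz = np.where(slope > 0, d_sqrt_sigma / slope, np.inf)
    return np.minimum(dz, _Z_UNC_CAP_NM)


# ---------------------------------------------------------------------------
# persistence

_REQUIRED_AXIS_KEYS = ("sigma0_nm", "c_nm", "d_nm")


def save_calibration(cal: AstigCalibration, path) -> Path:
    path = Path(path)
    doc = {
        "axis_x": {k: float(getattr(cal.axis_x, k)) for k in _REQUIRED_AXIS_KEYS},
        "axis_y": {k: float(getattr(cal.axis_y, k)) for k in _REQUIRED_AXIS_KEYS},
        "z_min_nm": float(cal.z_min_nm),
        "z_max_nm": float(cal.z_max_nm),
        "engine_tag": cal.engine_tag,
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def load_calibration(path) -> AstigCalibration:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise SchemaError(f"calibration file {path} is not a mapping")
    for key in ("axis_x", "axis_y", "z_min_nm", "z_max_nm"):
        if key not in doc:
            raise SchemaError(f"calibration file missing key '{key}'")
    axes = {}
    for ax in ("axis_x", "axis_y"):
        for k in _REQUIRED_AXIS_KEYS:
            if k not in doc[ax]:
                raise SchemaError(f"calibration {ax} missing key '{k}'")
        axes[ax] = DefocusCurve(**{k: float(doc[ax][k])
                                   for k in _REQUIRED_AXIS_KEYS})
    return AstigCalibration(axes["axis_x"], axes["axis_y"],
                            float(doc["z_min_nm"]), float(doc["z_max_nm"]),
                            str(doc.get("engine_tag", "gaussian")))


def default_calibration(engine_tag: str = "gaussian") -> AstigCalibration:
    """Representative cylindrical-lens calibration used by the simulator.

    130 nm waists with foci offset to -200/+200 nm and a 400 nm depth scale,
    valid over -500..+500 nm — a typical astigmatic dSTORM configuration.
    """
    return AstigCalibration(
        axis_x=DefocusCurve(sigma0_nm=130.0, c_nm=-200.0, d_nm=400.0),
        axis_y=DefocusCurve(sigma0_nm=130.0, c_nm=200.0, d_nm=400.0),
        z_min_nm=-500.0, z_max_nm=500.0, engine_tag=engine_tag)
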