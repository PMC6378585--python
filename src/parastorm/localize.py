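"""Sub-pixel localization engines.

Three engines, matching the trade-offs studied in SMLM practice:

``nwls``
    Iterative fitting of the integrated (erf-based) Gaussian PSF model by
    nonlinear weighted least squares, weights ``1 / max(counts, 1)``.
``mle``
    The same PSF model fitted by Poisson maximum likelihood (minimising
    ``sum(mu - y*ln(mu))``), the statistically efficient choice at low
    photon counts.
``phasor``
    Non-iterative position estimation from the phase of the first Fourier
    coefficients of the ROI; width proxies from the coefficient magnitudes.

Both iterative engines use a Levenberg–Marquardt damped iteration (cap 50,
convergence at max relative parameter change < 1e-6).  Patch coordinates are
continuous pixels with the centre of pixel ``j`` at ``j + 0.5``; the driver
converts to nm through the camera pixel size.

Lateral precision uses the Thompson–Larson–Webb closed form

    dx^2 = (s^2 + a^2/12) / N  +  8*pi*s^4*b^2 / (a^2 * N^2)

with ``s`` the PSF width, ``a`` the pixel size, ``N`` the photon count and
``b`` the background standard deviation.  No uncertainty is reported for
phasor fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import erf

from . import calibrate as _calmod
from .detect import DetectionParams, detect_spots, extract_roi
from .errors import DegenerateInputError, DomainError
from .io_formats import (
    CameraModel,
    LocalizationTable,
    MovieHandle,
    RunLog,
    read_frames,
)

_MAX_ITER = 50
_REL_TOL = 1e-6
_FTOL = 1e-9
_SIGMA_BOUNDS_PX = (0.3, 10.0)
_MU_FLOOR = 1e-6

ENGINES = ("nwls", "mle", "phasor")


@dataclass(frozen=True)
class FitResult:
    """One fitted emitter, in patch-local pixel/photon units."""

    x_px: float
    y_px: float
    sigma_x_px: float
    sigma_y_px: float
    n_photons: float
    b_photons: float
    bkgstd_photons: float
    converged: bool
    n_iter: int
    engine: str


# ---------------------------------------------------------------------------
# initial estimate


def estimate_initial(roi: np.ndarray, sigma_prior_px: float = 1.3
                     ) -> tuple[float, float, float, float, float]:
    """Moment-based starting point ``(x, y, sigma, N, b)`` for the fitters."""
    patch = np.asarray(roi, dtype=float)
    if patch.ndim != 2 or min(patch.shape) < 5:
        raise DegenerateInputError(f"patch side must be >= 5, got {patch.shape}")
    b = float(patch.min())
    net = patch - b
    n = float(net.sum())
    if n <= 0:
        raise DegenerateInputError("patch carries no signal above its minimum")
    h, w = patch.shape
    cols = np.arange(w) + 0.5
    rows = np.arange(h) + 0.5
    x = float((net.sum(axis=0) * cols).sum() / n)
    y = float((net.sum(axis=1) * rows).sum() / n)
    return x, y, float(sigma_prior_px), n, b


# ---------------------------------------------------------------------------
# integrated Gaussian model


def _axis_profiles(n: int, mu: float, sigma: float):
    """Per-pixel integral of a unit 1D Gaussian and its mu/sigma derivatives."""
    edges = np.arange(n + 1, dtype=float)
    u = (edges - mu) / (math.sqrt(2.0) * sigma)
    e = erf(u)
    g = 0.5 * (e[1:] - e[:-1])
    t = (edges - mu) / sigma
    phi = np.exp(-np.minimum(0.5 * t * t, 700.0)) / (
        math.sqrt(2.0 * math.pi) * sigma)
    dg_dmu = -(phi[1:] - phi[:-1])
    dg_ds = -(phi[1:] * t[1:] - phi[:-1] * t[:-1])
    return g, dg_dmu, dg_ds


def _model_and_jacobian(theta: np.ndarray, shape: tuple[int, int],
                        elliptical: bool):
    h, w = shape
    if elliptical:
        x, y, sx, sy, n_ph, b = theta
    else:
        x, y, sx, n_ph, b = theta
        sy = sx
    gx, dgx_dx, dgx_dsx = _axis_profiles(w, x, sx)
    gy, dgy_dy, dgy_dsy = _axis_profiles(h, y, sy)
    spot = np.outer(gy, gx)
    mu = n_ph * spot + b
    cols = [n_ph * np.outer(gy, dgx_dx),          # d/dx
            n_ph * np.outer(dgy_dy, gx)]          # d/dy
    if elliptical:
        cols += [n_ph * np.outer(gy, dgx_dsx),    # d/dsx
                 n_ph * np.outer(dgy_dsy, gx)]    # d/dsy
    else:
        cols += [n_ph * (np.outer(gy, dgx_dsx) + np.outer(dgy_dsy, gx))]
    cols += [spot, np.ones_like(spot)]            # d/dN, d/db
    jac = np.stack([c.ravel() for c in cols], axis=1)
    return mu.ravel(), jac


def _in_bounds(theta: np.ndarray, shape: tuple[int, int], elliptical: bool
               ) -> bool:
    h, w = shape
    x, y = theta[0], theta[1]
    sigmas = theta[2:4] if elliptical else theta[2:3]
    n_ph = theta[-2]
    return bool(0.0 <= x <= w and 0.0 <= y <= h
                and np.all((sigmas >= _SIGMA_BOUNDS_PX[0])
                           & (sigmas <= _SIGMA_BOUNDS_PX[1]))
                and n_ph > 0)


def _border_ring_std(residual: np.ndarray) -> float:
    ring = np.ones(residual.shape, dtype=bool)
    ring[1:-1, 1:-1] = False
    return float(residual[ring].std())


def fit_gaussian(roi: np.ndarray, init, engine: str = "nwls",
                 elliptical: bool = False) -> FitResult:
    """Levenberg–Marquardt fit of the integrated Gaussian PSF to one ROI.

    ``init`` is the ``(x, y, sigma, N, b)`` tuple from
    :func:`estimate_initial`.  Divergence (parameters leaving the patch,
    width outside 0.3–10 px, or non-positive intensity) yields a result
    flagged ``converged=False`` rather than an exception.
    """
    if engine not in ("nwls", "mle"):
        raise ValueError(f"engine must be 'nwls' or 'mle', got {engine!r}")
    y_obs = np.asarray(roi, dtype=float).ravel()
    shape = np.asarray(roi).shape
    x0, y0, s0, n0, b0 = init
    if elliptical:
        theta = np.array([x0, y0, s0, s0, n0, b0], dtype=float)
    else:
        theta = np.array([x0, y0, s0, n0, b0], dtype=float)

    if engine == "nwls":
        wts = 1.0 / np.maximum(y_obs, 1.0)

        def cost_of(mu):
            return float(np.sum(wts * (y_obs - mu) ** 2))

        def grad_hess(mu, jac):
            r = y_obs - mu
            g = -(jac.T @ (wts * r))
            a = jac.T @ (jac * wts[:, None])
            return g, a
    else:
        def cost_of(mu):
            mu_f = np.maximum(mu, _MU_FLOOR)
            return float(np.sum(mu_f - y_obs * np.log(mu_f)))

        def grad_hess(mu, jac):
            mu_f = np.maximum(mu, _MU_FLOOR)
            g = jac.T @ (1.0 - y_obs / mu_f)
            a = jac.T @ (jac / mu_f[:, None])     # expected Fisher information
            return g, a

    mu, jac = _model_and_jacobian(theta, shape, elliptical)
    cost = cost_of(mu)
    lam = 1e-3
    converged = False
    n_iter = 0
    for n_iter in range(1, _MAX_ITER + 1):
        g, a = grad_hess(mu, jac)
        diag = np.diag(a).copy()
        diag[diag <= 0] = 1.0
        try:
            step = np.linalg.solve(a + lam * np.diag(diag), -g)
        except np.linalg.LinAlgError:
            break
        trial = theta + step
        rel = np.max(np.abs(step) / np.maximum(np.abs(theta), 1.0))
        if rel < _REL_TOL:
            # the proposed update is negligible: we are at the optimum
            # whether or not this last step would be accepted
            converged = True
            break
        sig_trial = trial[2:4] if elliptical else trial[2:3]
        if not np.all(np.isfinite(trial)) or np.any(sig_trial <= 0.05):
            lam *= 10.0
            if lam > 1e10:
                break
            continue
        mu_t, jac_t = _model_and_jacobian(trial, shape, elliptical)
        cost_t = cost_of(mu_t)
        if np.isfinite(cost_t) and cost_t <= cost:
            improvement = cost - cost_t
            theta, mu, jac, cost = trial, mu_t, jac_t, cost_t
            lam = max(lam / 3.0, 1e-12)
            # flat-likelihood stop: zero-count pixels can pull the
            # background along an asymptotically flat boundary where the
            # cost gain per step is negligible but parameter steps shrink
            # only geometrically
            if improvement <= _FTOL * (abs(cost) + 1.0):
                converged = True
                break
        else:
            lam *= 10.0
            if lam > 1e10:
                break
    if not _in_bounds(theta, shape, elliptical):
        converged = False
    if elliptical:
        x, yy, sx, sy, n_ph, b = theta
    else:
        x, yy, sx, n_ph, b = theta
        sy = sx
    resid = np.asarray(roi, dtype=float) - mu.reshape(shape)
    return FitResult(x_px=float(x), y_px=float(yy), sigma_x_px=float(sx),
                     sigma_y_px=float(sy), n_photons=float(n_ph),
                     b_photons=float(b), bkgstd_photons=_border_ring_std(resid),
                     converged=bool(converged), n_iter=n_iter, engine=engine)


# ---------------------------------------------------------------------------
# phasor engine


def _phasor_axis(total: float, coeff: complex, w: int) -> tuple[float, float]:
    mag = abs(coeff)
    if mag <= 0 or mag > total * (1.0 + 1e-12):
        raise DegenerateInputError(
            "phasor coefficient magnitude outside (0, total intensity]")
    phase = math.atan2(coeff.imag, coeff.real)
    if phase > 0:
        phase -= 2.0 * math.pi
    local = -phase * w / (2.0 * math.pi)
    # mag == total (single-pixel spot) gives a zero width proxy; keep it
    # positive so downstream geometric means stay defined
    sigma = (w / math.pi) * math.sqrt(max(math.log(total / mag), 0.0) / 2.0)
    return local, max(sigma, 1e-9)


def fit_phasor(roi: np.ndarray) -> FitResult:
    """Non-iterative phasor localization of one square ROI.

    The position comes from the phase of the first Fourier coefficient
    along each axis (after subtracting the patch minimum); the width proxy
    comes from the coefficient magnitude through the Gaussian Fourier
    transform.  Always "converged" with ``n_iter = 0``.
    """
    patch = np.asarray(roi, dtype=float)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise DegenerateInputError("phasor requires a square patch")
    w = patch.shape[0]
    if w < 5:
        raise DegenerateInputError(f"patch side must be >= 5, got {w}")
    b = float(patch.min())
    net = patch - b
    total = float(net.sum())
    if total <= 0:
        raise DegenerateInputError("patch carries no signal above its minimum")
    k = np.exp(-2j * math.pi * np.arange(w) / w)
    p_x = complex((net.sum(axis=0) * k).sum())
    p_y = complex((net.sum(axis=1) * k).sum())
    loc_x, sig_x = _phasor_axis(total, p_x, w)
    loc_y, sig_y = _phasor_axis(total, p_y, w)
    ring = np.ones(patch.shape, dtype=bool)
    ring[1:-1, 1:-1] = False
    return FitResult(x_px=loc_x + 0.5, y_px=loc_y + 0.5,
                     sigma_x_px=sig_x, sigma_y_px=sig_y,
                     n_photons=total, b_photons=b,
                     bkgstd_photons=float(net[ring].std()),
                     converged=True, n_iter=0, engine="phasor")


# ---------------------------------------------------------------------------
# precision


def thompson_uncertainty(sigma_nm: float, pixel_size_nm: float,
                         n_photons: float, bkgstd_photons: float) -> float:
    """Thompson–Larson–Webb lateral precision (nm)."""
    if n_photons <= 0:
        raise DomainError("photon count must be > 0")
    s2 = sigma_nm * sigma_nm
    a2 = pixel_size_nm * pixel_size_nm
    var = (s2 + a2 / 12.0) / n_photons + (
        8.0 * math.pi * s2 * s2 * bkgstd_photons * bkgstd_photons
        / (a2 * n_photons * n_photons))
    return math.sqrt(var)


def localization_uncertainty(fit: FitResult, camera: CameraModel
                             ) -> Optional[float]:
    """Lateral precision of one fit; ``None`` for phasor fits."""
    if fit.engine == "phasor":
        return None
    if not fit.converged:
        raise DomainError("uncertainty undefined for non-converged fits")
    a = camera.pixel_size_nm
    sigma_nm = math.sqrt(fit.sigma_x_px * fit.sigma_y_px) * a
    return thompson_uncertainty(sigma_nm, a, fit.n_photons, fit.bkgstd_photons)


# ---------------------------------------------------------------------------
# per-frame driver


def localize_frames(handle: MovieHandle, start: int = 1, stride: int = 1,
                    engine: str = "nwls",
                    detection: Optional[DetectionParams] = None,
                    calibration: Optional[_calmod.AstigCalibration] = None,
                    log: Optional[RunLog] = None,
                    sigma_prior_px: float = 1.3) -> LocalizationTable:
    """Detect and fit every candidate in the strided frame subset.

    Non-converged and degenerate fits are discarded.  With a calibration the
    Gaussian engines fit elliptical widths and each record gains z (via the
    defocus-curve lookup) and an axial uncertainty; records carry the true
    frame numbers so interleaved worker outputs can be merged by frame.
    """
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES}")
    if detection is None:
        detection = DetectionParams(
            roi_radius_px=4 if calibration is not None else 3)
    cam = handle.camera
    a = cam.pixel_size_nm
    dim = 3 if calibration is not None else 2
    records: list[dict] = []
    n_frames_seen = 0
    n_candidates = 0
    for frame, pixels in read_frames(handle, start, stride):
        n_frames_seen += 1
        for cand in detect_spots(pixels, detection, frame=frame):
            n_candidates += 1
            roi, origin = extract_roi(pixels, cand, detection.roi_radius_px, cam)
            try:
                if engine == "phasor":
                    fit = fit_phasor(roi)
                else:
                    init = estimate_initial(roi, sigma_prior_px)
                    fit = fit_gaussian(roi, init, engine,
                                       elliptical=calibration is not None)
            except DegenerateInputError:
                continue
            if not fit.converged:
                continue
            unc = localization_uncertainty(fit, cam)
            rec = {
                "id": float(len(records) + 1),
                "frame": float(frame),
                "x_nm": origin[0] + fit.x_px * a,
                "y_nm": origin[1] + fit.y_px * a,
                "sigma_nm": math.sqrt(fit.sigma_x_px * fit.sigma_y_px) * a,
                "intensity_photons": fit.n_photons,
                "offset_photons": fit.b_photons,
                "bkgstd_photons": fit.bkgstd_photons,
                "uncertainty_xy_nm": np.nan if unc is None else unc,
            }
            if calibration is not None:
                sx_nm = fit.sigma_x_px * a
                sy_nm = fit.sigma_y_px * a
                z, _res = _calmod.z_lookup(sx_nm, sy_nm, calibration)
                rec["z_nm"] = z
                rec["sigma1_nm"] = sx_nm
                rec["sigma2_nm"] = sy_nm
                if unc is None:
                    rec["uncertainty_z_nm"] = np.nan
                else:
                    rec["uncertainty_z_nm"] = float(_calmod.z_uncertainty(
                        sx_nm, sy_nm, unc, z, calibration))
            records.append(rec)
    note = (f"localize engine={engine} start={start} stride={stride} "
            f"frames={n_frames_seen} candidates={n_candidates} "
            f"kept={len(records)}")
    if log is not None:
        log.log(note)
    return LocalizationTable.from_records(records, dim=dim, provenance=[note])
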