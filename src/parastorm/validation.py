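"""Desk-scale validation experiments for the whole pipeline.

Each function simulates its own data under the study conditions the package
is designed for, runs the relevant pipeline stage(s) from scratch, and
returns the measured quantities.  They back both the acceptance test suite
and ``scripts/acceptance.py``; every experiment is deterministic given its
seed.

Problem sizes: 64x64 px fields; 500 frames for the parallel-equivalence
check, 2000 frames for load balancing and blink-decay statistics, 1000
frames for drift, 250-300 frames for the precision and 3D checks.
"""

from __future__ import annotations

import math
import tempfile
from dataclasses import replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import calibrate as _calmod
from .detect import DetectionParams
from .io_formats import LocalizationTable, open_movie
from .localize import localize_frames, thompson_uncertainty
from .parallel_engine import (
    WorkerConfig,
    contiguous_block_counts,
    plan_interleave,
    run_parallel,
)
from .postprocess import PostprocessConfig, apply_filter_chain, estimate_drift, merge_consecutive
from .simulate import (
    GroundTruth,
    SimulationConfig,
    fit_decay_rate,
    generate_ground_truth,
    render_movie,
)


def _sub_seed(seed: int, idx: int) -> int:
    return (seed * 131 + idx * 7919) % (2 ** 31)


def _workdir(workdir) -> Path:
    if workdir is None:
        return Path(tempfile.mkdtemp(prefix="parastorm_val_"))
    p = Path(workdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _isolated_event_mask(positions: np.ndarray, frames: np.ndarray,
                         min_dist_nm: float) -> np.ndarray:
    """Events whose nearest same-frame neighbour is farther than min_dist."""
    iso = np.ones(len(positions), dtype=bool)
    for f in np.unique(frames):
        sel = np.flatnonzero(frames == f)
        if len(sel) > 1:
            dd, _ = cKDTree(positions[sel]).query(positions[sel], k=2)
            iso[sel[dd[:, 1] < min_dist_nm]] = False
    return iso


def _match_events(truth: GroundTruth, table: LocalizationTable,
                  radius_nm: float, iso_dist_nm: float = 600.0):
    """Match isolated true ON events to localizations by nearest neighbour.

    Returns (lateral error array (n, 2), z pairs (true, est) or None,
    matched count, isolated count).
    """
    pos = truth.event_positions_nm()
    frames = truth.event_frames
    iso = _isolated_event_mask(pos, frames, iso_dist_nm)
    loc = table.df[["x_nm", "y_nm"]].to_numpy()
    fr = table.df["frame"].to_numpy().astype(int)
    has_z = "z_nm" in table.df.columns and table.dim == 3
    z_est = table.df["z_nm"].to_numpy() if has_z else None
    z_true = truth.emitters[truth.event_emitters, 2]
    errs, z_pairs = [], []
    matched = 0
    for f in np.unique(frames):
        te = np.flatnonzero((frames == f) & iso)
        lo = np.flatnonzero(fr == f)
        if len(te) == 0 or len(lo) == 0:
            continue
        dd, jj = cKDTree(loc[lo]).query(pos[te], k=1)
        ok = dd < radius_nm
        matched += int(ok.sum())
        errs.append(loc[lo][jj[ok]] - pos[te][ok])
        if has_z:
            z_pairs.append(np.column_stack([z_true[te][ok],
                                            z_est[lo][jj[ok]]]))
    lateral = np.vstack(errs) if errs else np.empty((0, 2))
    zp = np.vstack(z_pairs) if z_pairs else None
    return lateral, zp, matched, int(iso.sum())


# ---------------------------------------------------------------------------
# 1. parallel/serial equivalence


def parallel_equivalence(seed: int, workdir=None,
                         engines: Sequence[str] = ("nwls", "mle", "phasor"),
                         workers: Sequence[int] = (1, 2, 4, 8),
                         n_frames: int = 500) -> dict:
    """Merged raw CSVs must be byte-identical for any worker count.

    One simulated movie; for each engine the run is repeated with each W and
    the merged CSV compared byte-for-byte against the single-worker run.
    """
    wd = _workdir(workdir)
    cfg = SimulationConfig(n_frames=n_frames, n_emitters=300,
                           seed=_sub_seed(seed, 1))
    truth = generate_ground_truth(cfg)
    movie, _, _ = render_movie(truth, cfg, wd / "equiv.ome.tif")
    handle = open_movie(movie)
    identical = 0
    comparisons = 0
    per_engine: dict[str, bool] = {}
    for engine in engines:
        blobs = {}
        for w in workers:
            plan = plan_interleave(handle.n_frames, w)
            report = run_parallel(handle, plan, WorkerConfig(engine=engine),
                                  wd / f"{engine}_w{w}", processes=(w > 1),
                                  max_processes=min(w, 4))
            blobs[w] = report.merged_table_path.read_bytes()
        same = [blobs[w] == blobs[workers[0]] for w in workers[1:]]
        identical += sum(same)
        comparisons += len(same)
        per_engine[engine] = all(same)
    return {
        "identical_fraction": identical / comparisons,
        "per_engine": per_engine,
        "n_comparisons": comparisons,
        "n_frames": n_frames,
    }


# ---------------------------------------------------------------------------
# 2. load balancing under exponential decay


def load_balance(seed: int, workdir=None, n_frames: int = 2000,
                 n_workers: int = 4) -> dict:
    """Interleaved vs contiguous per-worker counts on a decaying movie.

    Decay rate p_on * p_bleach = 0.002/frame, the regime where a contiguous
    split concentrates most localizations in the first block.
    """
    wd = _workdir(workdir)
    cfg = SimulationConfig(n_frames=n_frames, n_emitters=2000, p_on=0.02,
                           p_bleach=0.1, structure="uniform",
                           seed=_sub_seed(seed, 2))
    truth = generate_ground_truth(cfg)
    movie, _, _ = render_movie(truth, cfg, wd / "decay.ome.tif")
    handle = open_movie(movie)
    plan = plan_interleave(handle.n_frames, n_workers)
    report = run_parallel(handle, plan, WorkerConfig(engine="phasor"),
                          wd / "balance", processes=False)
    inter = report.worker_counts
    contig = contiguous_block_counts(report.merged_table, n_frames, n_workers)
    return {
        "interleaved_counts": inter,
        "contiguous_counts": contig,
        "interleaved_ratio": max(inter) / min(inter),
        "contiguous_ratio": max(contig) / max(min(contig), 1),
        "n_frames": n_frames,
        "decay_rate_per_frame": cfg.p_on * cfg.p_bleach,
    }


# ---------------------------------------------------------------------------
# 3. localization precision vs the Thompson bound


def precision(seed: int, workdir=None, n_frames: int = 300) -> dict:
    """Per-axis RMSE of matched localizations against the Thompson bound.

    Default imaging regime: N = 1000 photons, sigma = 130 nm, 100 nm pixels,
    10 background photons/px (background std = sqrt(10 + read_noise^2)).
    """
    wd = _workdir(workdir)
    cfg = SimulationConfig(n_frames=n_frames, n_emitters=150, p_on=0.02,
                           p_bleach=0.0, structure="uniform",
                           photons_sd=1e-6, seed=_sub_seed(seed, 3))
    truth = generate_ground_truth(cfg)
    movie, _, _ = render_movie(truth, cfg, wd / "prec.ome.tif")
    handle = open_movie(movie)
    b_std = math.sqrt(cfg.background_photons + cfg.read_noise_e ** 2)
    bound = thompson_uncertainty(cfg.psf_sigma_nm, cfg.camera.pixel_size_nm,
                                 cfg.photons_mean, b_std)
    out = {"thompson_bound_nm": bound, "n_frames": n_frames}
    for engine in ("mle", "phasor"):
        table = localize_frames(handle, engine=engine)
        lateral, _, matched, total = _match_events(truth, table, 50.0)
        rmse = float(np.sqrt(np.mean(lateral ** 2)))
        out[f"{engine}_rmse_nm"] = rmse
        out[f"{engine}_rmse_over_bound"] = rmse / bound
        out[f"{engine}_matched_fraction"] = matched / total
    return out


def noiseless_recovery() -> dict:
    """Position error of each engine on an exact noiseless model spot."""
    from scipy.special import erf
    from .localize import estimate_initial, fit_gaussian, fit_phasor

    def spot(side, x, y, s, n, b):
        e = np.arange(side + 1.0)
        gx = 0.5 * (erf((e[1:] - x) / (np.sqrt(2) * s))
                    - erf((e[:-1] - x) / (np.sqrt(2) * s)))
        gy = 0.5 * (erf((e[1:] - y) / (np.sqrt(2) * s))
                    - erf((e[:-1] - y) / (np.sqrt(2) * s)))
        return n * np.outer(gy, gx) + b

    roi = spot(7, 3.2, 3.6, 1.3, 1000.0, 5.0)
    init = estimate_initial(roi)
    out = {}
    for engine in ("nwls", "mle"):
        fit = fit_gaussian(roi, init, engine)
        out[f"{engine}_err_px"] = float(
            max(abs(fit.x_px - 3.2), abs(fit.y_px - 3.6)))
    ph = fit_phasor(roi)
    out["phasor_err_px"] = float(max(abs(ph.x_px - 3.2), abs(ph.y_px - 3.6)))
    return out


# ---------------------------------------------------------------------------
# 4. filter contracts


def filter_contracts() -> dict:
    """Kept counts of the three quality filters on their toy tables."""
    import pandas as pd

    def base(n, dim=2):
        cols = {
            "id": np.arange(1, n + 1, dtype=float), "frame": np.ones(n),
            "x_nm": np.zeros(n), "y_nm": np.zeros(n),
            "sigma_nm": np.full(n, 130.0),
            "intensity_photons": np.full(n, 1000.0),
            "offset_photons": np.full(n, 10.0),
            "bkgstd_photons": np.full(n, 3.0),
            "uncertainty_xy_nm": np.full(n, 9.5),
        }
        if dim == 3:
            cols.update({"z_nm": np.zeros(n), "sigma1_nm": np.full(n, 130.0),
                         "sigma2_nm": np.full(n, 130.0),
                         "uncertainty_z_nm": np.full(n, 50.0)})
        return cols

    c = base(3)
    c["intensity_photons"] = np.array([0.2, 1.0, 3.5])
    t_phot = LocalizationTable(pd.DataFrame(c), 2)
    kept_phot = len(apply_filter_chain(
        t_phot, PostprocessConfig(steps=("minphot",))))

    c = base(3, dim=3)
    c["uncertainty_z_nm"] = np.array([100.0, 500.0, 501.0])
    t_z = LocalizationTable(pd.DataFrame(c), 3)
    kept_z = len(apply_filter_chain(t_z, PostprocessConfig(steps=("zunc",))))

    c = base(20)
    c["sigma_nm"] = np.arange(1.0, 21.0)
    t_sig = LocalizationTable(pd.DataFrame(c), 2)
    kept_sig = len(apply_filter_chain(
        t_sig, PostprocessConfig(steps=("sigma",))))
    return {"minphot_kept": kept_phot, "zunc_kept": kept_z,
            "sigma_kept": kept_sig}


# ---------------------------------------------------------------------------
# 5. drift recovery


def drift_recovery(seed: int, workdir=None, n_frames: int = 1000,
                   drift: tuple[float, float] = (2.0, -1.0)) -> dict:
    """Recover a linear stage drift and quantify the residual."""
    wd = _workdir(workdir)
    cfg = SimulationConfig(n_frames=n_frames, n_emitters=200, p_on=0.03,
                           p_bleach=0.0, structure="filaments",
                           drift_nm_per_frame=drift, seed=_sub_seed(seed, 5))
    truth = generate_ground_truth(cfg)
    movie, _, _ = render_movie(truth, cfg, wd / "drift.ome.tif")
    table = localize_frames(open_movie(movie), engine="phasor")
    traj = estimate_drift(table, n_bins=5, magnification=5,
                          pixel_size_nm=cfg.camera.pixel_size_nm)
    f = np.arange(1, n_frames + 1)
    est = traj.displacements_nm
    true = np.column_stack([(f - 1) * drift[0], (f - 1) * drift[1]])
    resid = est - true
    return {
        "slope_x_nm_per_frame": float(np.polyfit(f, est[:, 0], 1)[0]),
        "slope_y_nm_per_frame": float(np.polyfit(f, est[:, 1], 1)[0]),
        "true_slope_nm_per_frame": list(drift),
        "residual_rms_nm": float(np.sqrt(np.mean(resid ** 2))),
        "n_frames": n_frames,
        "n_localizations": len(table),
    }


# ---------------------------------------------------------------------------
# 6. astigmatic 3D


def z_round_trip(central_fraction: float = 0.8,
                 cal: Optional[_calmod.AstigCalibration] = None) -> dict:
    """Invert the forward defocus model across the central z range."""
    cal = cal or _calmod.default_calibration()
    span = cal.z_max_nm - cal.z_min_nm
    pad = span * (1 - central_fraction) / 2
    zs = np.linspace(cal.z_min_nm + pad, cal.z_max_nm - pad, 161)
    sx, sy = cal.sigmas(zs)
    z_back, _ = _calmod.z_lookup_batch(sx, sy, cal)
    return {"max_abs_err_nm": float(np.max(np.abs(z_back - zs))),
            "n_grid": len(zs)}


def astigmatic_3d(seed: int, workdir=None, n_frames: int = 250) -> dict:
    """z RMSE of the full astigmatic pipeline over +/-400 nm."""
    wd = _workdir(workdir)
    cal = _calmod.default_calibration()
    cfg = SimulationConfig(n_frames=n_frames, n_emitters=120, p_on=0.02,
                           p_bleach=0.0, structure="uniform", astig=cal,
                           z_range_nm=400.0, photons_sd=1e-6,
                           seed=_sub_seed(seed, 6))
    truth = generate_ground_truth(cfg)
    movie, _, _ = render_movie(truth, cfg, wd / "astig.ome.tif")
    table = localize_frames(open_movie(movie), engine="mle", calibration=cal,
                            detection=DetectionParams(roi_radius_px=4))
    _, z_pairs, matched, total = _match_events(truth, table, 100.0,
                                               iso_dist_nm=800.0)
    z_err = z_pairs[:, 1] - z_pairs[:, 0]
    return {"z_rmse_nm": float(np.sqrt(np.mean(z_err ** 2))),
            "z_bias_nm": float(np.mean(z_err)),
            "matched": matched, "isolated_events": total,
            "n_frames": n_frames}


# ---------------------------------------------------------------------------
# 7. exponential decay of localization counts


def decay_recovery(seed: int, n_frames: int = 2000,
                   n_emitters: int = 10_000) -> dict:
    """Fitted decay rate of per-frame ON-event counts vs p_on * p_bleach."""
    cfg = SimulationConfig(n_frames=n_frames, n_emitters=n_emitters,
                           p_on=0.01, p_bleach=0.5, structure="uniform",
                           seed=_sub_seed(seed, 7))
    truth = generate_ground_truth(cfg)
    rate = fit_decay_rate(truth.events_per_frame(n_frames))
    expected = cfg.p_on * cfg.p_bleach
    return {"fitted_rate_per_frame": float(rate),
            "configured_rate_per_frame": expected,
            "relative_error": float(abs(rate - expected) / expected),
            "n_events": truth.n_events}


# ---------------------------------------------------------------------------
# 8. consecutive-frame merging


def merge_run_counting(seed: int, workdir=None, k_on: int = 3,
                       n_emitters: int = 36) -> dict:
    """Each emitter stays ON for k consecutive frames: one merged record.

    Constructed (non-stochastic) blinking on a sparse grid with bright
    spots over low background, so detection is complete and the merged
    record count can be compared exactly with the number of ON runs.
    """
    wd = _workdir(workdir)
    side = int(np.ceil(np.sqrt(n_emitters)))
    coords = np.linspace(800.0, 5600.0, side)
    gx, gy = np.meshgrid(coords, coords)
    emitters = np.column_stack([gx.ravel(), gy.ravel(),
                                np.zeros(side * side)])[:n_emitters]
    n_frames = 60
    frames, eidx = [], []
    for i in range(n_emitters):
        start = 1 + (i * 7) % (n_frames - k_on)
        frames.extend(range(start, start + k_on))
        eidx.extend([i] * k_on)
    truth = GroundTruth(
        emitters=emitters,
        event_frames=np.asarray(frames, dtype=np.int64),
        event_emitters=np.asarray(eidx, dtype=np.int64),
        event_photons=np.full(len(frames), 5000.0),
        drift=np.zeros((n_frames, 2)))
    cfg = SimulationConfig(n_frames=n_frames, n_emitters=n_emitters,
                           structure="grid", background_photons=2.0,
                           read_noise_e=1.0, seed=_sub_seed(seed, 8))
    movie, _, _ = render_movie(truth, cfg, wd / "runs.ome.tif")
    table = localize_frames(open_movie(movie), engine="mle",
                            detection=DetectionParams(k_threshold=6.0))
    merged = merge_consecutive(table, radius_nm=50.0, max_gap_frames=0,
                               pixel_size_nm=cfg.camera.pixel_size_nm)
    return {"merged_records": len(merged), "true_on_runs": n_emitters,
            "raw_records": len(table), "k_on": k_on}
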