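"""Automated postprocessing of merged localization tables.

The chain mirrors the automated cleanup used on merged SMLM tables:

``minphot``
    Remove unphysical fits with intensity below one photon (records at
    exactly the threshold survive).
``sigma``
    Keep widths inside the 10th–75th intercentile range of the table as it
    stands when the step runs (linear-interpolation percentiles, inclusive
    bounds).
``zunc``
    Drop 3D records whose axial uncertainty exceeds 500 nm (exactly 500
    survives); ignored for 2D tables.
``drift``
    Fiducial-free lateral drift correction: temporal bins rendered as
    super-resolved histograms, FFT cross-correlation against the first bin,
    paraboloid sub-pixel peak, per-frame linear interpolation.
``merge``
    Combine repeat localizations of one emitter in subsequent frames into a
    single record.

Each step appends a provenance line with before/after counts; filters only
ever remove rows, never alter surviving values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .errors import ConfigError, DriftError
from .io_formats import LocalizationTable, RunLog
from .localize import thompson_uncertainty

_KNOWN_STEPS = ("minphot", "sigma", "zunc", "drift", "merge")


@dataclass(frozen=True)
class PostprocessConfig:
    """Which steps run, in which order, with which thresholds."""

    steps: tuple[str, ...] = ("minphot", "sigma", "zunc", "drift", "merge")
    min_intensity_photons: float = 1.0
    zunc_max_nm: float = 500.0
    sigma_lo_centile: float = 10.0
    sigma_hi_centile: float = 75.0
    drift_bins: int = 5
    drift_magnification: int = 5
    merge_radius_nm: float = 50.0
    merge_max_gap_frames: int = 0

    def __post_init__(self) -> None:
        unknown = [s for s in self.steps if s not in _KNOWN_STEPS]
        if unknown:
            raise ConfigError(
                f"unknown postprocessing step(s) {unknown}; "
                f"choose from {_KNOWN_STEPS}")
        if not 0 <= self.sigma_lo_centile < self.sigma_hi_centile <= 100:
            raise ConfigError("need 0 <= lo_centile < hi_centile <= 100")
        if self.drift_bins < 2:
            raise ConfigError("drift_bins must be >= 2")
        if self.merge_radius_nm <= 0 or self.drift_magnification < 1:
            raise ConfigError("radii/magnification must be positive")

    @classmethod
    def from_tokens(cls, tokens: str, **overrides) -> "PostprocessConfig":
        """Parse the launch-script style step string, e.g. 'minphot,sigma,drift'."""
        steps = tuple(t.strip() for t in tokens.split(",") if t.strip())
        return cls(steps=steps, **overrides)

    @property
    def token_string(self) -> str:
        return ",".join(self.steps)


@dataclass
class DriftTrajectory:
    """Per-frame lateral displacement (nm) relative to the first temporal bin."""

    displacements_nm: np.ndarray      # (n_frames, 2): dx, dy for frames 1..n

    def __post_init__(self) -> None:
        d = np.asarray(self.displacements_nm, dtype=float)
        if d.ndim != 2 or d.shape[1] != 2:
            raise ConfigError("displacements must be (n_frames, 2)")
        if not np.all(np.isfinite(d)):
            raise DriftError("drift trajectory contains non-finite values")
        self.displacements_nm = d

    @property
    def n_frames(self) -> int:
        return len(self.displacements_nm)

    def at(self, frames: np.ndarray) -> np.ndarray:
        idx = np.clip(np.asarray(frames, dtype=int) - 1, 0, self.n_frames - 1)
        return self.displacements_nm[idx]


# ---------------------------------------------------------------------------
# filters


def _keep(table: LocalizationTable, mask: np.ndarray, step: str
          ) -> LocalizationTable:
    before = len(table)
    df = table.df.loc[mask]
    out = table.with_df(df, f"filter {step}: kept {int(mask.sum())}/{before}")
    return out


def apply_filter_chain(table: LocalizationTable, config: PostprocessConfig,
                       pixel_size_nm: float = 100.0,
                       drift_plot_path=None,
                       log: Optional[RunLog] = None) -> LocalizationTable:
    """Apply the configured steps in order; returns a new table."""
    current = table
    for step in config.steps:
        if step == "minphot":
            vals = current.df["intensity_photons"].to_numpy()
            current = _keep(current, vals >= config.min_intensity_photons,
                            "minphot")
        elif step == "sigma":
            if len(current):
                sig = current.df["sigma_nm"].to_numpy()
                lo, hi = np.percentile(
                    sig, [config.sigma_lo_centile, config.sigma_hi_centile])
                current = _keep(current, (sig >= lo) & (sig <= hi), "sigma")
            else:
                current = _keep(current, np.zeros(0, dtype=bool), "sigma")
        elif step == "zunc":
            if current.dim == 3 and len(current):
                unc = current.df["uncertainty_z_nm"].to_numpy()
                # NaN (no uncertainty reported, e.g. phasor) is not "greater
                # than the threshold" and survives
                current = _keep(current, ~(unc > config.zunc_max_nm), "zunc")
        elif step == "drift":
            traj = estimate_drift(current, config.drift_bins,
                                  config.drift_magnification,
                                  pixel_size_nm=pixel_size_nm,
                                  plot_path=drift_plot_path)
            current = apply_drift_correction(current, traj)
        elif step == "merge":
            current = merge_consecutive(current, config.merge_radius_nm,
                                        config.merge_max_gap_frames,
                                        pixel_size_nm=pixel_size_nm)
        if log is not None and current.provenance:
            log.log(current.provenance[-1])
    return current


# ---------------------------------------------------------------------------
# drift


def _subpixel_peak(corr: np.ndarray) -> tuple[float, float]:
    """Correlation maximum with separable 3-point parabolic refinement."""
    idx = np.unravel_index(np.argmax(corr), corr.shape)
    peak = np.array(idx, dtype=float)
    for axis in (0, 1):
        i = idx[axis]
        sl = list(idx)
        sl[axis] = (i - 1) % corr.shape[axis]
        c0 = corr[tuple(sl)]
        c1 = corr[idx]
        sl[axis] = (i + 1) % corr.shape[axis]
        c2 = corr[tuple(sl)]
        denom = c0 - 2 * c1 + c2
        if denom < 0:
            peak[axis] += 0.5 * (c0 - c2) / denom
    return float(peak[0]), float(peak[1])


def _bin_histograms(x, y, frames, edges, sp):
    x_edges = np.arange(x.min() - sp, x.max() + 2 * sp, sp)
    y_edges = np.arange(y.min() - sp, y.max() + 2 * sp, sp)
    hists, centers = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (frames >= lo) & (frames < hi)
        if sel.sum() < 10:
            raise DriftError(
                f"temporal bin [{lo:.0f},{hi:.0f}) holds only "
                f"{int(sel.sum())} localizations; use fewer bins")
        h, _, _ = np.histogram2d(y[sel], x[sel], bins=[y_edges, x_edges])
        hists.append(h)
        centers.append((lo + hi - 1) / 2.0)
    return hists, np.asarray(centers)


def _bin_displacements(hists, sp, smooth_superpixels):
    """Redundant pairwise cross-correlation, least-squares consensus.

    Every bin pair (i, j) yields a relative shift; the per-bin displacements
    (relative to bin 1) are the least-squares solution of the resulting
    overdetermined linear system, which averages down single-pair peak
    errors.
    """
    n = len(hists)
    shape = hists[0].shape
    fft_shape = tuple(int(2 ** np.ceil(np.log2(2 * s))) for s in shape)
    ky = np.fft.fftfreq(fft_shape[0])[:, None]
    kx = np.fft.rfftfreq(fft_shape[1])[None, :]
    transfer = np.exp(-2.0 * np.pi ** 2 * smooth_superpixels ** 2
                      * (kx ** 2 + ky ** 2))
    spectra = [np.fft.rfft2(h, fft_shape) for h in hists]
    rows, obs = [], []
    for i in range(n):
        for j in range(i + 1, n):
            corr = np.fft.irfft2(spectra[i] * np.conj(spectra[j]) * transfer,
                                 fft_shape)
            pr, pc = _subpixel_peak(corr)
            if pr > fft_shape[0] / 2:
                pr -= fft_shape[0]
            if pc > fft_shape[1] / 2:
                pc -= fft_shape[1]
            # corr peak at +tau: bin j content sits at bin i positions - tau,
            # i.e. bin j drifted by -tau relative to bin i
            row = np.zeros(n)
            row[j], row[i] = 1.0, -1.0
            rows.append(row)
            obs.append([-pc * sp, -pr * sp])
    a = np.array(rows)[:, 1:]          # displacement of bin 1 fixed at 0
    obs = np.array(obs)
    disp = np.zeros((n, 2))
    for axis in range(2):
        disp[1:, axis] = np.linalg.lstsq(a, obs[:, axis], rcond=None)[0]
    return disp


def _interpolate_per_frame(centers, bin_disp, f_max):
    all_frames = np.arange(1, f_max + 1, dtype=float)
    disp = np.empty((f_max, 2))
    c = centers
    for axis in range(2):
        v = bin_disp[:, axis]
        d = np.interp(all_frames, c, v)
        lo_slope = (v[1] - v[0]) / (c[1] - c[0])
        hi_slope = (v[-1] - v[-2]) / (c[-1] - c[-2])
        before = all_frames < c[0]
        after = all_frames > c[-1]
        d[before] = v[0] + (all_frames[before] - c[0]) * lo_slope
        d[after] = v[-1] + (all_frames[after] - c[-1]) * hi_slope
        disp[:, axis] = d
    return disp


def estimate_drift(table: LocalizationTable, n_bins: int = 5,
                   magnification: int = 5, pixel_size_nm: float = 100.0,
                   plot_path=None, smooth_superpixels: float = 2.0,
                   n_passes: int = 2) -> DriftTrajectory:
    """Fiducial-free drift estimate by redundant cross-correlation.

    Frames split into ``n_bins`` contiguous bins; each bin is rendered as a
    2D histogram at super-pixel size ``pixel_size_nm / magnification``.
    Every bin pair is FFT cross-correlated (band-limited by a Gaussian of
    ``smooth_superpixels``, since sparse histograms produce coincidence
    noise that jitters the raw argmax by several super-pixels; sub-pixel
    peak via a 3x3 paraboloid) and the per-bin displacements are the
    least-squares consensus of all pairwise shifts.  Per-frame
    displacements interpolate linearly between bin centres, extrapolating
    the end segments linearly.  A second pass re-estimates on the corrected
    coordinates — the first pass removes the within-bin drift smear, so
    the refined peaks are much sharper — and the passes are summed.  The
    trajectory is anchored so frame 1 has zero displacement.  Also writes
    the drift-summary graph when ``plot_path`` is given.
    """
    frames = table.df["frame"].to_numpy()
    if len(np.unique(frames)) < n_bins:
        raise DriftError(
            f"table spans {len(np.unique(frames))} distinct frames; "
            f"need >= {n_bins} bins")
    f_max = int(frames.max())
    edges = np.linspace(1, f_max + 1, n_bins + 1)
    sp = pixel_size_nm / magnification
    x = table.df["x_nm"].to_numpy().copy()
    y = table.df["y_nm"].to_numpy().copy()
    fidx = frames.astype(int) - 1

    disp = np.zeros((f_max, 2))
    centers = None
    bin_disp_total = None
    for _ in range(max(n_passes, 1)):
        hists, centers = _bin_histograms(x, y, frames, edges, sp)
        bin_disp = _bin_displacements(hists, sp, smooth_superpixels)
        bin_disp_total = (bin_disp if bin_disp_total is None
                          else bin_disp_total + bin_disp)
        pass_disp = _interpolate_per_frame(centers, bin_disp, f_max)
        disp += pass_disp
        x = x - pass_disp[fidx, 0]
        y = y - pass_disp[fidx, 1]
    disp -= disp[0]                     # frame 1 anchored at (0, 0)
    bin_disp = bin_disp_total

    if plot_path is not None:
        all_frames = np.arange(1, f_max + 1)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(all_frames, disp[:, 0], label="dx")
        ax.plot(all_frames, disp[:, 1], label="dy")
        ax.plot(centers, bin_disp[:, 0] - bin_disp[0, 0], "o", color="C0")
        ax.plot(centers, bin_disp[:, 1] - bin_disp[0, 1], "o", color="C1")
        ax.set_xlabel("frame")
        ax.set_ylabel("drift [nm]")
        ax.legend()
        fig.tight_layout()
        fig.savefig(Path(plot_path), dpi=120)
        plt.close(fig)
    return DriftTrajectory(disp)


def apply_drift_correction(table: LocalizationTable, traj: DriftTrajectory
                           ) -> LocalizationTable:
    """Subtract the per-frame displacement from every localization."""
    df = table.df.copy()
    d = traj.at(df["frame"].to_numpy())
    df["x_nm"] = df["x_nm"].to_numpy() - d[:, 0]
    df["y_nm"] = df["y_nm"].to_numpy() - d[:, 1]
    return table.with_df(df, f"drift correction applied ({traj.n_frames} frames)")


# ---------------------------------------------------------------------------
# consecutive-frame merging


def merge_consecutive(table: LocalizationTable, radius_nm: float = 50.0,
                      max_gap_frames: int = 0, pixel_size_nm: float = 100.0
                      ) -> LocalizationTable:
    """Combine repeat localizations of one emitter in subsequent frames.

    Greedy chaining in frame order: a record joins the nearest open chain
    whose last frame precedes its own by 1..(1 + max_gap_frames) and whose
    photon-weighted centroid lies within ``radius_nm``.  Records in the same
    frame never merge.  The merged record keeps the first frame, sums the
    photons, photon-weights positions and widths, and recomputes the lateral
    uncertainty from the merged photon count (Thompson formula); axial
    uncertainties combine in inverse quadrature.
    """
    if len(table) == 0:
        return table.with_df(table.df, "merge: kept 0/0")
    df = table.df.sort_values(["frame", "id"], kind="stable")
    dim = table.dim
    chains: list[dict] = []
    open_idx: list[int] = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        f = int(rec["frame"])
        # retire chains that can no longer accept anything
        open_idx = [ci for ci in open_idx
                    if f - chains[ci]["last_frame"] <= 1 + max_gap_frames]
        best, best_d = None, np.inf
        for ci in open_idx:
            ch = chains[ci]
            gap = f - ch["last_frame"]
            if not 1 <= gap <= 1 + max_gap_frames:
                continue
            d = float(np.hypot(rec["x_nm"] - ch["x"], rec["y_nm"] - ch["y"]))
            if d <= radius_nm and d < best_d:
                best, best_d = ci, d
        w = max(float(rec["intensity_photons"]), 1e-12)
        if best is None:
            chains.append({
                "first_frame": f, "last_frame": f, "w": w,
                "x": rec["x_nm"], "y": rec["y_nm"],
                "sum_sigma": w * rec["sigma_nm"],
                "sum_off": w * rec["offset_photons"],
                "sum_bkg": w * rec["bkgstd_photons"],
                "sum_n": float(rec["intensity_photons"]),
                "sum_z": w * rec.get("z_nm", 0.0),
                "sum_s1": w * rec.get("sigma1_nm", 0.0),
                "sum_s2": w * rec.get("sigma2_nm", 0.0),
                "inv_uz2": _inv_sq(rec.get("uncertainty_z_nm")),
                "any_unc": np.isfinite(rec.get("uncertainty_xy_nm", np.nan)),
                "n_members": 1,
            })
            open_idx.append(len(chains) - 1)
        else:
            ch = chains[best]
            w_tot = ch["w"] + w
            ch["x"] = (ch["x"] * ch["w"] + rec["x_nm"] * w) / w_tot
            ch["y"] = (ch["y"] * ch["w"] + rec["y_nm"] * w) / w_tot
            ch["w"] = w_tot
            ch["last_frame"] = f
            ch["sum_sigma"] += w * rec["sigma_nm"]
            ch["sum_off"] += w * rec["offset_photons"]
            ch["sum_bkg"] += w * rec["bkgstd_photons"]
            ch["sum_n"] += float(rec["intensity_photons"])
            ch["sum_z"] += w * rec.get("z_nm", 0.0)
            ch["sum_s1"] += w * rec.get("sigma1_nm", 0.0)
            ch["sum_s2"] += w * rec.get("sigma2_nm", 0.0)
            ch["inv_uz2"] += _inv_sq(rec.get("uncertainty_z_nm"))
            ch["any_unc"] |= bool(
                np.isfinite(rec.get("uncertainty_xy_nm", np.nan)))
            ch["n_members"] += 1

    records = []
    for i, ch in enumerate(
            sorted(chains, key=lambda c: c["first_frame"]), start=1):
        w = ch["w"]
        sigma = ch["sum_sigma"] / w
        bkg = ch["sum_bkg"] / w
        if ch["any_unc"] and ch["sum_n"] > 0:
            unc = thompson_uncertainty(sigma, pixel_size_nm, ch["sum_n"], bkg)
        else:
            unc = np.nan
        rec = {
            "id": float(i), "frame": float(ch["first_frame"]),
            "x_nm": ch["x"], "y_nm": ch["y"], "sigma_nm": sigma,
            "intensity_photons": ch["sum_n"],
            "offset_photons": ch["sum_off"] / w,
            "bkgstd_photons": bkg, "uncertainty_xy_nm": unc,
        }
        if dim == 3:
            rec["z_nm"] = ch["sum_z"] / w
            rec["sigma1_nm"] = ch["sum_s1"] / w
            rec["sigma2_nm"] = ch["sum_s2"] / w
            rec["uncertainty_z_nm"] = (
                1.0 / np.sqrt(ch["inv_uz2"]) if ch["inv_uz2"] > 0 else np.nan)
        records.append(rec)
    out = LocalizationTable.from_records(records, dim=dim,
                                         provenance=list(table.provenance))
    out.provenance.append(
        f"merge consecutive (radius {radius_nm} nm, gap {max_gap_frames}): "
        f"{len(table)} -> {len(out)} records")
    return out


def _inv_sq(v) -> float:
    if v is None or not np.isfinite(v) or v <= 0:
        return 0.0
    return 1.0 / (float(v) ** 2)
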