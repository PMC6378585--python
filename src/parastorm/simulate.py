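"""Synthetic dSTORM movie generator with ground truth.

The generator emulates the data this pipeline is built for: sparse,
stochastically blinking emitters decorating filament-like structures
(microtubules), imaged through a Gaussian (optionally astigmatic) PSF onto a
noisy camera, with slow lateral stage drift.

Photophysics model: independently in each frame every not-yet-bleached
emitter switches ON with probability ``p_on``; after an ON event it
permanently bleaches with probability ``p_bleach``.  The expected number of
ON events per frame therefore decays geometrically with per-frame rate
``p_on * p_bleach`` — the approximately exponential fall-off of localization
counts seen in long dSTORM acquisitions.  Re-blinking within a frame,
triplet states and buffer chemistry are not modelled.

Camera model: expected photon image (integrated Gaussian PSF per event plus
uniform background) -> Poisson shot noise -> additive Gaussian read noise ->
counts via gain and baseline, clipped to uint16.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy.special import erf

from . import calibrate as _cal
from .errors import ConfigError
from .io_formats import CameraModel, format_float, write_movie

_STRUCTURES = ("uniform", "filaments", "grid")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic movie (typical dSTORM regime)."""

    width: int = 64
    height: int = 64
    n_frames: int = 200
    camera: CameraModel = field(
        default_factory=lambda: CameraModel(pixel_size_nm=100.0,
                                            photons_per_adu=0.5,
                                            baseline_adu=100.0))
    structure: str = "filaments"
    n_emitters: int = 300
    p_on: float = 0.02
    p_bleach: float = 0.1
    photons_mean: float = 1000.0
    photons_sd: float = 0.3        # log-space sigma of the lognormal
    background_photons: float = 10.0
    read_noise_e: float = 1.6
    psf_sigma_nm: float = 130.0
    astig: Optional[_cal.AstigCalibration] = None
    z_range_nm: float = 0.0
    drift_nm_per_frame: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure not in _STRUCTURES:
            raise ConfigError(f"structure must be one of {_STRUCTURES}")
        if not 0 < self.p_on <= 1:
            raise ConfigError("need 0 < p_on <= 1")
        if not 0 <= self.p_bleach <= 1:
            raise ConfigError("need 0 <= p_bleach <= 1")
        if not self.photons_mean > 0:
            raise ConfigError("photons_mean must be > 0")
        if not self.psf_sigma_nm > 0:
            raise ConfigError("psf_sigma_nm must be > 0")
        if self.z_range_nm != 0 and self.astig is None:
            raise ConfigError("z_range_nm is nonzero but no astig calibration given")


@dataclass
class GroundTruth:
    """True emitter positions, per-frame ON events and the drift track."""

    emitters: np.ndarray           # (n_emitters, 3): x_nm, y_nm, z_nm
    event_frames: np.ndarray       # (n_events,) int, 1-based
    event_emitters: np.ndarray     # (n_events,) int index into emitters
    event_photons: np.ndarray      # (n_events,) float
    drift: np.ndarray              # (n_frames, 2): cumulative dx_nm, dy_nm

    @property
    def n_events(self) -> int:
        return len(self.event_frames)

    def events_per_frame(self, n_frames: int) -> np.ndarray:
        return np.bincount(self.event_frames, minlength=n_frames + 1)[1:]

    def event_positions_nm(self) -> np.ndarray:
        """Drift-shifted true (x, y) of every event, as imaged."""
        pos = self.emitters[self.event_emitters, :2]
        return pos + self.drift[self.event_frames - 1]


# ---------------------------------------------------------------------------
# emitter placement


def _place_uniform(rng, cfg: SimulationConfig, margin_nm: float) -> np.ndarray:
    w_nm = cfg.width * cfg.camera.pixel_size_nm
    h_nm = cfg.height * cfg.camera.pixel_size_nm
    x = rng.uniform(margin_nm, w_nm - margin_nm, cfg.n_emitters)
    y = rng.uniform(margin_nm, h_nm - margin_nm, cfg.n_emitters)
    return np.column_stack([x, y])


def _place_grid(rng, cfg: SimulationConfig, margin_nm: float) -> np.ndarray:
    w_nm = cfg.width * cfg.camera.pixel_size_nm
    h_nm = cfg.height * cfg.camera.pixel_size_nm
    side = int(np.ceil(np.sqrt(cfg.n_emitters)))
    xs = np.linspace(margin_nm, w_nm - margin_nm, side)
    ys = np.linspace(margin_nm, h_nm - margin_nm, side)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])[: cfg.n_emitters]
    return pts


def _place_filaments(rng, cfg: SimulationConfig, margin_nm: float) -> np.ndarray:
    """Quadratic Bezier filaments, emitters at ~15 nm arc spacing + jitter."""
    w_nm = cfg.width * cfg.camera.pixel_size_nm
    h_nm = cfg.height * cfg.camera.pixel_size_nm
    n_curves = int(rng.integers(3, 9))
    pts = []
    for _ in range(n_curves):
        ctrl = np.column_stack([rng.uniform(0, w_nm, 3), rng.uniform(0, h_nm, 3)])
        t = np.linspace(0, 1, 400)[:, None]
        curve = ((1 - t) ** 2 * ctrl[0] + 2 * (1 - t) * t * ctrl[1]
                 + t ** 2 * ctrl[2])
        seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        n_pts = max(int(arc[-1] / 15.0), 2)
        s = np.linspace(0, arc[-1], n_pts)
        pts.append(np.column_stack([np.interp(s, arc, curve[:, 0]),
                                    np.interp(s, arc, curve[:, 1])]))
    allpts = np.vstack(pts)
    allpts = allpts + rng.normal(0.0, 10.0, allpts.shape)
    inside = ((allpts[:, 0] > margin_nm) & (allpts[:, 0] < w_nm - margin_nm)
              & (allpts[:, 1] > margin_nm) & (allpts[:, 1] < h_nm - margin_nm))
    allpts = allpts[inside]
    if len(allpts) == 0:
        return _place_uniform(rng, cfg, margin_nm)
    idx = rng.choice(len(allpts), size=cfg.n_emitters,
                     replace=len(allpts) < cfg.n_emitters)
    return allpts[idx]


def generate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw emitter positions, blinking events and the drift track.

    Deterministic for a given config (the RNG is seeded from ``config.seed``).
    ``n_emitters == 0`` yields an empty (but valid) truth.
    """
    rng = np.random.default_rng(config.seed)
    margin_nm = 5.0 * config.camera.pixel_size_nm
    if config.n_emitters == 0:
        xy = np.empty((0, 2))
    elif config.structure == "uniform":
        xy = _place_uniform(rng, config, margin_nm)
    elif config.structure == "grid":
        xy = _place_grid(rng, config, margin_nm)
    else:
        xy = _place_filaments(rng, config, margin_nm)
    if config.z_range_nm > 0:
        z = rng.uniform(-config.z_range_nm, config.z_range_nm, len(xy))
    else:
        z = np.zeros(len(xy))
    emitters = np.column_stack([xy, z]) if len(xy) else np.empty((0, 3))

    frames, eidx = [], []
    alive = np.ones(len(emitters), dtype=bool)
    for f in range(1, config.n_frames + 1):
        r = rng.random(len(emitters))
        on = alive & (r < config.p_on)
        which = np.flatnonzero(on)
        frames.append(np.full(len(which), f, dtype=np.int64))
        eidx.append(which)
        if config.p_bleach > 0 and len(which):
            bleach = rng.random(len(which)) < config.p_bleach
            alive[which[bleach]] = False
    event_frames = np.concatenate(frames) if frames else np.empty(0, np.int64)
    event_emitters = np.concatenate(eidx) if eidx else np.empty(0, np.int64)
    photons = rng.lognormal(
        np.log(config.photons_mean) - config.photons_sd ** 2 / 2.0,
        config.photons_sd, len(event_frames))

    k = np.arange(config.n_frames, dtype=float)
    drift = np.column_stack([k * config.drift_nm_per_frame[0],
                             k * config.drift_nm_per_frame[1]])
    return GroundTruth(emitters, event_frames, event_emitters, photons, drift)


# ---------------------------------------------------------------------------
# rendering


def _integrated_gaussian_1d(edges_px: np.ndarray, mu_px: float, sigma_px: float
                            ) -> np.ndarray:
    z = (edges_px - mu_px) / (np.sqrt(2.0) * sigma_px)
    e = erf(z)
    return 0.5 * (e[1:] - e[:-1])


def expected_photon_image(truth: GroundTruth, config: SimulationConfig,
                          frame: int) -> np.ndarray:
    """Noise-free expected photons per pixel for one frame (no background)."""
    a = config.camera.pixel_size_nm
    img = np.zeros((config.height, config.width))
    sel = truth.event_frames == frame
    if not np.any(sel):
        return img
    dx, dy = truth.drift[frame - 1]
    for ei, nph in zip(truth.event_emitters[sel], truth.event_photons[sel]):
        x_nm, y_nm, z_nm = truth.emitters[ei]
        x_px = (x_nm + dx) / a
        y_px = (y_nm + dy) / a
        if config.astig is not None:
            sx_nm, sy_nm = config.astig.sigmas(z_nm)
            sx, sy = sx_nm / a, sy_nm / a
        else:
            sx = sy = config.psf_sigma_nm / a
        half = 5.0 * max(sx, sy)
        c0 = max(int(np.floor(x_px - half)), 0)
        c1 = min(int(np.ceil(x_px + half)) + 1, config.width)
        r0 = max(int(np.floor(y_px - half)), 0)
        r1 = min(int(np.ceil(y_px + half)) + 1, config.height)
        if c0 >= c1 or r0 >= r1:
            continue
        gx = _integrated_gaussian_1d(np.arange(c0, c1 + 1, dtype=float), x_px, sx)
        gy = _integrated_gaussian_1d(np.arange(r0, r1 + 1, dtype=float), y_px, sy)
        img[r0:r1, c0:c1] += nph * np.outer(gy, gx)
    return img


def render_movie(truth: GroundTruth, config: SimulationConfig, out_path
                 ) -> tuple[Path, Path, Optional[Path]]:
    """Render the movie to disk.

    Writes the OME-TIFF movie (with camera sidecar), the ground-truth CSV
    (``<stem>.truth.csv``) and, in 3D mode, the calibration YAML
    (``<stem>.calibration.yaml``).  Byte-identical output for identical
    config and seed.
    """
    if config.z_range_nm != 0 and config.astig is None:
        raise ConfigError("3D rendering requires config.astig")
    out_path = Path(out_path)
    cam = config.camera
    noise_rng = np.random.default_rng([config.seed, 0xA5])
    stack = np.empty((config.n_frames, config.height, config.width), np.uint16)
    for f in range(1, config.n_frames + 1):
        expected = expected_photon_image(truth, config, f) + config.background_photons
        electrons = noise_rng.poisson(expected).astype(float)
        if config.read_noise_e > 0:
            electrons += noise_rng.normal(0.0, config.read_noise_e, electrons.shape)
        adu = np.rint(electrons / cam.photons_per_adu + cam.baseline_adu)
        stack[f - 1] = np.clip(adu, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    write_movie(out_path, stack, cam, seed=config.seed)

    stem = out_path.name
    for suf in (".ome.tiff", ".ome.tif", ".tiff", ".tif"):
        if stem.lower().endswith(suf):
            stem = stem[: -len(suf)]
            break
    truth_path = out_path.parent / f"{stem}.truth.csv"
    _write_truth_csv(truth, truth_path)
    cal_path = None
    if config.astig is not None:
        cal_path = out_path.parent / f"{stem}.calibration.yaml"
        _cal.save_calibration(config.astig, cal_path)
    return out_path, truth_path, cal_path


def simulate_movie(config: SimulationConfig, out_path
                   ) -> tuple[GroundTruth, Path, Path, Optional[Path]]:
    """Convenience: ground truth + rendered movie in one call."""
    truth = generate_ground_truth(config)
    movie, truth_csv, cal = render_movie(truth, config, out_path)
    return truth, movie, truth_csv, cal


def _write_truth_csv(truth: GroundTruth, path: Path) -> None:
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        wr = csv.writer(fh, lineterminator="\n")
        wr.writerow(["frame", "emitter", "x [nm]", "y [nm]", "z [nm]", "photons"])
        for f, e, p in zip(truth.event_frames, truth.event_emitters,
                           truth.event_photons):
            x, y, z = truth.emitters[e]
            wr.writerow([int(f), int(e), format_float(x), format_float(y),
                         format_float(z), format_float(p)])


# ---------------------------------------------------------------------------
# decay-rate estimation (validation of the blinking model)


def fit_decay_rate(counts_per_frame: np.ndarray, n_bins: int = 40) -> float:
    """Exponential decay rate (per frame) of a per-frame count series.

    Bins the series, then fits log(mean count) vs. frame by least squares
    weighted by the bin totals (approximate Poisson weighting).  Returns the
    positive rate lambda of ``counts ~ exp(-lambda * frame)``.
    """
    counts = np.asarray(counts_per_frame, dtype=float)
    n = len(counts)
    edges = np.linspace(0, n, min(n_bins, n) + 1).astype(int)
    centers, means, weights = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        m = counts[lo:hi].mean()
        if m > 0:
            centers.append((lo + hi) / 2.0)
            means.append(m)
            weights.append(counts[lo:hi].sum())
    if len(means) < 3:
        raise ConfigError("too few populated bins to fit a decay rate")
    coef = np.polyfit(np.asarray(centers), np.log(np.asarray(means)), 1,
                      w=np.sqrt(np.asarray(weights)))
    return float(-coef[0])


# ---------------------------------------------------------------------------
# YAML config round trip (CLI `simulate` subcommand)


def config_from_yaml(path) -> SimulationConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    cam = doc.pop("camera", None)
    astig = doc.pop("astig", None)
    kwargs = dict(doc)
    if cam is not None:
        kwargs["camera"] = CameraModel(**cam)
    if astig:
        if isinstance(astig, str) and astig != "default":
            kwargs["astig"] = _cal.load_calibration(astig)
        else:
            kwargs["astig"] = _cal.default_calibration()
    if "drift_nm_per_frame" in kwargs:
        kwargs["drift_nm_per_frame"] = tuple(kwargs["drift_nm_per_frame"])
    try:
        return SimulationConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"bad simulation config: {exc}") from exc


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
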