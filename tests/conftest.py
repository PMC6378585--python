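"""Shared fixtures: synthetic movies and noiseless PSF patches.

Expensive simulations are session-scoped so several tests can share one
rendered movie.  All randomness is seeded; every fixture is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import erf

from parastorm.io_formats import CameraModel, open_movie
from parastorm.simulate import SimulationConfig, generate_ground_truth, render_movie


def make_spot(side: int, x: float, y: float, sx: float, sy: float,
              n_photons: float, b: float) -> np.ndarray:
    """Noiseless integrated-Gaussian patch (the generative model itself)."""
    e = np.arange(side + 1, dtype=float)
    gx = 0.5 * (erf((e[1:] - x) / (np.sqrt(2) * sx))
                - erf((e[:-1] - x) / (np.sqrt(2) * sx)))
    gy = 0.5 * (erf((e[1:] - y) / (np.sqrt(2) * sy))
                - erf((e[:-1] - y) / (np.sqrt(2) * sy)))
    return n_photons * np.outer(gy, gx) + b


@pytest.fixture(scope="session")
def default_camera() -> CameraModel:
    return CameraModel(pixel_size_nm=100.0, photons_per_adu=0.5,
                       baseline_adu=100.0)


@pytest.fixture(scope="session")
def small_movie(tmp_path_factory):
    """13-frame filament movie with ground truth (fast, for I/O tests)."""
    cfg = SimulationConfig(n_frames=13, n_emitters=50, seed=3)
    truth = generate_ground_truth(cfg)
    out = tmp_path_factory.mktemp("small") / "small.ome.tif"
    movie, truth_csv, _ = render_movie(truth, cfg, out)
    return cfg, truth, movie


@pytest.fixture(scope="session")
def medium_movie(tmp_path_factory):
    """60-frame filament movie used by the parallel-engine tests."""
    cfg = SimulationConfig(n_frames=60, n_emitters=120, seed=7)
    truth = generate_ground_truth(cfg)
    out = tmp_path_factory.mktemp("medium") / "medium.ome.tif"
    movie, _, _ = render_movie(truth, cfg, out)
    return cfg, truth, movie


@pytest.fixture(scope="session")
def sparse_movie(tmp_path_factory):
    """Well-separated emitters at fixed photon count (precision tests)."""
    cfg = SimulationConfig(n_frames=80, n_emitters=100, p_on=0.02,
                           p_bleach=0.0, structure="uniform",
                           photons_sd=1e-6, seed=21)
    truth = generate_ground_truth(cfg)
    out = tmp_path_factory.mktemp("sparse") / "sparse.ome.tif"
    movie, _, _ = render_movie(truth, cfg, out)
    return cfg, truth, movie


@pytest.fixture(scope="session")
def medium_handle(medium_movie):
    _, _, movie = medium_movie
    return open_movie(movie)
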