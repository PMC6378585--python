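"""Per-frame spot candidate detection.

A difference-of-Gaussians band-pass (sigma 1.0 / 1.6 px by default,
approximating the wavelet front-end common in SMLM software) followed by
strict 8-neighbourhood local-maximum selection against a robust threshold:
``k * 1.4826 * MAD`` of the filtered frame.  Candidates too close to the
border to support a full fitting ROI are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import BoundsError, ConfigError
from .io_formats import CameraModel


@dataclass(frozen=True)
class DetectionParams:
    dog_sigma1_px: float = 1.0
    dog_sigma2_px: float = 1.6
    k_threshold: float = 3.0
    roi_radius_px: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.dog_sigma1_px < self.dog_sigma2_px:
            raise ConfigError("need 0 < dog_sigma1_px < dog_sigma2_px")
        if not self.k_threshold > 0:
            raise ConfigError("k_threshold must be > 0")
        if self.roi_radius_px < 2:
            raise ConfigError("roi_radius_px must be >= 2")


@dataclass(frozen=True)
class Candidate:
    frame: int
    row_px: int
    col_px: int
    peak_value: float


def band_pass(frame_pixels: np.ndarray, params: DetectionParams) -> np.ndarray:
    img = np.asarray(frame_pixels, dtype=float)
    return (ndimage.gaussian_filter(img, params.dog_sigma1_px)
            - ndimage.gaussian_filter(img, params.dog_sigma2_px))


def detect_spots(frame_pixels: np.ndarray, params: DetectionParams,
                 frame: int = 0) -> list[Candidate]:
    """Find candidate emitters in one raw frame (counts).

    Returns candidates in row-major order.  A pixel is a candidate when its
    band-passed value exceeds the robust threshold and is >= all 8
    neighbours; on exact plateau ties only the first pixel in row-major
    order is kept.  Candidates within ``roi_radius_px`` of the border are
    dropped so a full ROI can always be extracted.
    """
    img = np.asarray(frame_pixels, dtype=float)
    r = params.roi_radius_px
    if img.shape[0] < 2 * r + 1 or img.shape[1] < 2 * r + 1:
        raise BoundsError(f"frame {img.shape} too small for ROI radius {r}")
    filt = band_pass(img, params)
    mad = np.median(np.abs(filt - np.median(filt)))
    thr = params.k_threshold * 1.4826 * mad
    local_max = filt == ndimage.maximum_filter(filt, size=3, mode="nearest")
    mask = local_max & (filt > thr)
    mask[:r, :] = mask[-r:, :] = False
    mask[:, :r] = mask[:, -r:] = False
    rows, cols = np.nonzero(mask)
    out: list[Candidate] = []
    h, w = filt.shape
    for i, j in zip(rows, cols):       # row-major order from nonzero
        v = filt[i, j]
        tie_earlier = False
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w and filt[ni, nj] == v:
                    if (ni, nj) < (i, j):
                        tie_earlier = True
        if not tie_earlier:
            out.append(Candidate(frame=frame, row_px=int(i), col_px=int(j),
                                 peak_value=float(v)))
    return out


def extract_roi(frame_pixels: np.ndarray, cand: Candidate, radius: int,
                camera: CameraModel) -> tuple[np.ndarray, tuple[float, float]]:
    """Cut a (2r+1)^2 patch around a candidate, converted to photons.

    Returns ``(patch, origin_nm)`` where ``origin_nm`` is the world (x, y)
    of the outer corner of the patch's (0, 0) pixel.
    """
    img = np.asarray(frame_pixels)
    h, w = img.shape
    i, j = cand.row_px, cand.col_px
    if not (radius <= i < h - radius and radius <= j < w - radius):
        raise BoundsError(
            f"candidate at ({i},{j}) too close to border for radius {radius}")
    patch = camera.adu_to_photons(
        img[i - radius:i + radius + 1, j - radius:j + radius + 1])
    a = camera.pixel_size_nm
    origin = ((j - radius) * a, (i - radius) * a)
    return patch, origin
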