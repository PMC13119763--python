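"""Detection of the white registration disks in visible-light images.

The registration hardware presents 10 mm white disks on matte-black strips.
Detection scores every pixel by the contrast between a disk-shaped
neighbourhood of the expected marker radius and the surrounding ring
(``S = mu_disk - mu_ring``), after removing slowly varying illumination
with a large-scale Gaussian background subtraction.  Local maxima of the
score are validated geometrically: an adaptive (Otsu) segmentation around
each candidate must yield a component whose area is consistent with the
expected disk, whose circularity ``4*pi*A/P^2`` is high, and whose axis
ratio is close to unity.  Centres are component centroids (sub-pixel);
the radius follows from the equivalent-disk area and doubles as a spatial
scale (the physical marker diameter is known).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "MarkerDetection",
    "VisMarkerConfig",
    "subtract_illumination",
    "disk_ring_score",
    "detect_vis_markers",
    "to_grayscale",
]


@dataclass
class MarkerDetection:
    """Sub-pixel marker centre with size and detection score."""

    x: float
    y: float
    radius_px: float
    score: float
    modality: Literal["VIS", "LWIR"]

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")


@dataclass
class VisMarkerConfig:
    r: float = 5.0              # expected disk radius, px
    w: float = 5.0              # ring width, px
    sigma_bg: float = 25.0      # background-subtraction scale (>= 4r)
    score_threshold: float | None = None   # None -> 5 x robust MAD of S
    score_mad_factor: float = 5.0
    circularity_min: float = 0.7
    axis_ratio_min: float = 0.75
    area_alpha_min: float = 0.4
    area_alpha_max: float = 2.5


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Standard luma conversion for RGB input; float64 output."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        image = (0.299 * image[..., 0] + 0.587 * image[..., 1]
                 + 0.114 * image[..., 2])
    return image


def subtract_illumination(gray: np.ndarray, sigma_bg: float) -> np.ndarray:
    """Remove the slowly varying illumination component.

    A large-scale Gaussian estimate of the background is subtracted; small
    bright structures (the markers) survive essentially unchanged when
    ``sigma_bg`` is at least ~4x the marker radius.
    """
    gray = np.asarray(gray, dtype=np.float64)
    return gray - gaussian_filter(gray, sigma=sigma_bg, mode="nearest")


def _disk_mask(radius: float) -> np.ndarray:
    n = int(np.ceil(radius))
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    return (xx * xx + yy * yy) <= radius * radius


def disk_ring_score(image: np.ndarray, r: float, w: float) -> np.ndarray:
    """Disk-minus-ring mean-contrast score at every pixel.

    ``S(x, y) = mean(image over disk of radius r) - mean(image over the
    annulus r < d <= r + w)``.  Pixels whose ring exits the image are NaN.
    """
    if r <= 0 or w <= 0:
        raise ValueError("r and w must be positive")
    image = np.asarray(image, dtype=np.float64)
    outer = _disk_mask(r + w)
    n = outer.shape[0] // 2
    inner = np.zeros_like(outer)
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    inner[(xx * xx + yy * yy) <= r * r] = True
    ring = outer & ~inner

    disk_k = inner.astype(np.float64) / inner.sum()
    ring_k = ring.astype(np.float64) / ring.sum()
    S = (fftconvolve(image, disk_k[::-1, ::-1], mode="same")
         - fftconvolve(image, ring_k[::-1, ::-1], mode="same"))
    S[:n, :] = np.nan
    S[-n:, :] = np.nan
    S[:, :n] = np.nan
    S[:, -n:] = np.nan
    return S


def detect_vis_markers(image: np.ndarray,
                       cfg: VisMarkerConfig | None = None,
                       valid_mask: np.ndarray | None = None
                       ) -> list[MarkerDetection]:
    """Detect white marker disks in a (possibly RGB) visible image.

    Pipeline: grayscale -> illumination subtraction -> disk/ring score ->
    non-maximum suppression at radius r -> per-candidate Otsu segmentation
    in a (4r)^2 region of interest -> area / circularity / axis-ratio
    validation.  Returns possibly empty list.
    """
    cfg = cfg or VisMarkerConfig()
    gray = to_grayscale(image)
    flat = subtract_illumination(gray, cfg.sigma_bg)
    S = disk_ring_score(flat, cfg.r, cfg.w)
    if valid_mask is not None:
        S = np.where(valid_mask, S, np.nan)

    finite = S[np.isfinite(S)]
    if finite.size == 0:
        return []
    if cfg.score_threshold is None:
        mad = np.median(np.abs(finite - np.median(finite)))
        thr = cfg.score_mad_factor * 1.4826 * max(mad, 1e-12)
    else:
        thr = cfg.score_threshold

    S_filled = np.where(np.isfinite(S), S, -np.inf)
    peaks = peak_local_max(S_filled, min_distance=max(int(round(cfg.r)), 1),
                           threshold_abs=thr)

    half = int(round(2 * cfg.r))
    area_lo = cfg.area_alpha_min * np.pi * cfg.r ** 2
    area_hi = cfg.area_alpha_max * np.pi * cfg.r ** 2
    detections: list[MarkerDetection] = []
    for py, px in peaks:
        y0, y1 = max(py - half, 0), min(py + half + 1, flat.shape[0])
        x0, x1 = max(px - half, 0), min(px + half + 1, flat.shape[1])
        roi = flat[y0:y1, x0:x1]
        if roi.size < 4 or np.ptp(roi) <= 0:
            continue
        try:
            t = threshold_otsu(roi)
        except ValueError:
            continue
        binary = roi >= t
        lab = label(binary, connectivity=2)
        comp_id = lab[py - y0, px - x0]
        if comp_id == 0:
            continue
        props = [p for p in regionprops(lab) if p.label == comp_id][0]
        A = props.area
        if not (area_lo <= A <= area_hi):
            continue
        P = props.perimeter
        if 4.0 * np.pi * A / (P ** 2 + 1e-9) < cfg.circularity_min:
            continue
        if props.axis_major_length > 0 and \
                props.axis_minor_length / props.axis_major_length < cfg.axis_ratio_min:
            continue
        cy, cx = props.centroid
        detections.append(MarkerDetection(
            x=float(cx + x0), y=float(cy + y0),
            radius_px=float(np.sqrt(A / np.pi)),
            score=float(S[py, px]), modality="VIS"))

    # NMS can leave two candidate peaks on one disk; keep the best per site
    detections.sort(key=lambda d: -d.score)
    kept: list[MarkerDetection] = []
    for d in detections:
        if all((d.x - k.x) ** 2 + (d.y - k.y) ** 2 > cfg.r ** 2 for k in kept):
            kept.append(d)
    return kept
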