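"""Detection of thermal-hill marker imprints in LWIR temperature images.

A heated registration marker leaves a diffuse, single-peaked warm imprint
("thermal hill") of roughly 10-15 px diameter in the 160x120 temperature
image.  The detector separates hills from the large-scale anatomical
background with a grayscale morphological opening (disk structuring element
about twice the expected marker radius), thresholds the resulting relief at
a minimum temperature excess, cleans the binary mask (area opening, small
closing, hole filling), filters connected components by area, circularity
and peak relief, and localises each retained hill with a relief-weighted
barycentre - sub-pixel accurate and robust to diffuse boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.measure import label, regionprops
from skimage.morphology import (closing, disk, opening,
                                remove_small_objects, reconstruction, erosion)

from .marker_vis import MarkerDetection

__all__ = [
    "ReliefDecomposition",
    "ComponentFilterConfig",
    "morphological_background",
    "threshold_and_clean",
    "filter_components",
    "weighted_barycenter",
    "detect_lwir_markers",
]


@dataclass
class ReliefDecomposition:
    """Background / relief split of a temperature image (degC)."""

    background: np.ndarray
    relief: np.ndarray
    se_radius: int


@dataclass
class ComponentFilterConfig:
    """Thresholds for hill selection; defaults follow the 10-15 px imprint."""

    dTmin: float = 2.0          # minimum relief, degC
    rmin: float = 5.0           # px (diameter 10)
    rmax: float = 7.5           # px (diameter 15)
    alpha_min: float = 0.4      # area slack below pi*rmin^2
    alpha_max: float = 2.5      # area slack above pi*rmax^2
    tau_circ: float = 0.20      # permissive circularity for diffuse hills
    area_min0: int = 20         # speckle area opening, px
    close_radius: int = 2       # closing disk radius, px
    eps_perimeter: float = 1e-9

    @property
    def area_min(self) -> float:
        return self.alpha_min * np.pi * self.rmin ** 2

    @property
    def area_max(self) -> float:
        return self.alpha_max * np.pi * self.rmax ** 2

    @property
    def se_radius(self) -> int:
        # structuring element about twice the expected marker radius
        return int(round(2 * 0.5 * (self.rmin + self.rmax)))


def morphological_background(T: np.ndarray, se_radius: int,
                             use_reconstruction: bool = False
                             ) -> ReliefDecomposition:
    """Estimate the large-scale thermal background by grayscale opening.

    The disk-shaped erosion flattens structures smaller than the element,
    the dilation restores the scale of what survives; the relief
    ``T - opening`` is non-negative everywhere (anti-extensivity).
    ``use_reconstruction`` switches to opening-by-reconstruction, which
    restores large structures more faithfully at the cost of keeping any
    small bump connected to them.
    """
    T = np.asarray(T, dtype=np.float64)
    se = disk(se_radius)
    if use_reconstruction:
        bg = reconstruction(erosion(T, se), T, method="dilation")
    else:
        bg = opening(T, se)
    return ReliefDecomposition(background=bg, relief=T - bg, se_radius=se_radius)


def threshold_and_clean(relief: np.ndarray,
                        cfg: ComponentFilterConfig) -> np.ndarray:
    """Hard-threshold the relief and clean the mask.

    Order: relief >= dTmin -> area opening (remove components below
    ``area_min0`` px) -> closing with a small disk -> hole filling.
    """
    mask = np.asarray(relief, dtype=np.float64) >= cfg.dTmin
    # area opening: drop components strictly smaller than area_min0
    mask = remove_small_objects(mask, max_size=cfg.area_min0 - 1, connectivity=2)
    mask = closing(mask, disk(cfg.close_radius))
    return binary_fill_holes(mask)


def filter_components(mask: np.ndarray, relief: np.ndarray,
                      cfg: ComponentFilterConfig) -> list:
    """Retain plausibly marker-like components (8-connectivity).

    Keeps components with area in ``[alpha_min*pi*rmin^2,
    alpha_max*pi*rmax^2]``, circularity ``4*pi*A/(P^2 + eps)`` of at least
    ``tau_circ``, and peak relief of at least ``dTmin``.  Returns skimage
    regionprops of the survivors (measured on the relief image).
    """
    lab = label(np.asarray(mask, dtype=bool), connectivity=2)
    relief = np.asarray(relief, dtype=np.float64)
    kept = []
    for p in regionprops(lab, intensity_image=relief):
        A = p.area
        if not (cfg.area_min <= A <= cfg.area_max):
            continue
        P = p.perimeter
        if 4.0 * np.pi * A / (P ** 2 + cfg.eps_perimeter) < cfg.tau_circ:
            continue
        if p.intensity_max < cfg.dTmin:
            continue
        kept.append(p)
    return kept


def weighted_barycenter(component, relief: np.ndarray,
                        weight_floor: float = 0.0) -> tuple[float, float]:
    """Relief-weighted centroid (x, y) of one connected component.

    Pixels near the hill summit dominate, which keeps the estimate stable
    under diffuse boundaries and moderate anisotropy.  ``weight_floor``
    subtracts a baseline from the weights (clipped at zero): relief below
    the detection threshold is indistinguishable from residual background,
    so weighting by the *excess* above the floor suppresses the pull of
    rim pixels sitting on a sloping background.  Falls back to the
    unweighted centroid with a warning if all weights vanish.
    """
    coords = component.coords  # (row, col)
    w = np.asarray(relief, dtype=np.float64)[coords[:, 0], coords[:, 1]]
    if weight_floor > 0.0:
        w = np.maximum(w - weight_floor, 0.0)
    wsum = w.sum()
    if wsum <= 0:
        warnings.warn("all-zero relief weights; falling back to unweighted centroid",
                      RuntimeWarning, stacklevel=2)
        return float(coords[:, 1].mean()), float(coords[:, 0].mean())
    x = float((coords[:, 1] * w).sum() / wsum)
    y = float((coords[:, 0] * w).sum() / wsum)
    return x, y


def detect_lwir_markers(T: np.ndarray,
                        cfg: ComponentFilterConfig | None = None,
                        use_reconstruction: bool = False
                        ) -> list[MarkerDetection]:
    """Full thermal-hill detection chain on a (vignette-corrected) image.

    Composition of background removal, thresholding/cleaning, component
    filtering and weighted barycentres; the equivalent diameter of every
    retained component must fall in the expected [2*rmin, 2*rmax] band.
    """
    cfg = cfg or ComponentFilterConfig()
    T = np.asarray(getattr(T, "values", T), dtype=np.float64)
    dec = morphological_background(T, cfg.se_radius,
                                   use_reconstruction=use_reconstruction)
    mask = threshold_and_clean(dec.relief, cfg)
    detections: list[MarkerDetection] = []
    for comp in filter_components(mask, dec.relief, cfg):
        d_eq = 2.0 * np.sqrt(comp.area / np.pi)
        if not (2.0 * cfg.rmin <= d_eq <= 2.0 * cfg.rmax):
            continue
        x, y = weighted_barycenter(comp, dec.relief, weight_floor=cfg.dTmin)
        detections.append(MarkerDetection(
            x=x, y=y, radius_px=float(d_eq / 2.0),
            score=float(comp.intensity_max), modality="LWIR"))
    return detections
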