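"""VIS -> LWIR registration, fusion for display, and the physical scale.

The matched marker centres define an anamorphosis that warps the visible
image onto the (untouched) LWIR temperature grid.  The default family is
affine, matching the matcher's model; projective and degree-2 polynomial
fits are available for scenes with residual perspective.  Since the
physical marker diameter is known (10 mm), the median detected radius also
yields the mm-per-pixel scale of either modality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from skimage import transform as sktransform
from skimage.filters import sobel

from .marker_vis import MarkerDetection

__all__ = [
    "FittedTransform",
    "fit_transform",
    "warp_vis_to_lwir",
    "fuse_overlay",
    "mm_per_pixel",
]

_MIN_PAIRS = {"affine": 3, "projective": 4, "poly2": 6}


@dataclass
class FittedTransform:
    """A fitted VIS->LWIR coordinate map with per-pair residuals."""

    family: Literal["affine", "projective", "poly2"]
    forward: sktransform._geometric._GeometricTransform   # VIS -> LWIR
    inverse: sktransform._geometric._GeometricTransform   # LWIR -> VIS
    residuals: np.ndarray

    def __call__(self, vis_pts: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(vis_pts, dtype=np.float64))

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.residuals ** 2)))

    def to_json(self, path) -> None:
        if self.family == "affine":
            coeffs = self.forward.params.tolist()
        elif self.family == "projective":
            coeffs = self.forward.params.tolist()
        else:
            coeffs = self.forward.params.tolist()
        Path(path).write_text(json.dumps(
            {"family": self.family, "coefficients": coeffs,
             "residual_rms": self.rms}, indent=2))


def fit_transform(vis_pts: np.ndarray, lwir_pts: np.ndarray,
                  family: Literal["affine", "projective", "poly2"] = "affine"
                  ) -> FittedTransform:
    """Least-squares fit of a VIS->LWIR map in the chosen family.

    ``vis_pts`` and ``lwir_pts`` are matched (N, 2) centre arrays, e.g.
    extracted from a :class:`~thermafoot.matching.CorrespondenceSet`.
    Requires 3 / 4 / 6 pairs for affine / projective / poly2.
    """
    vis = np.asarray(vis_pts, dtype=np.float64)
    lwir = np.asarray(lwir_pts, dtype=np.float64)
    if family not in _MIN_PAIRS:
        raise ValueError(f"unknown family {family!r}")
    if len(vis) < _MIN_PAIRS[family]:
        raise ValueError(
            f"{family} fit needs >= {_MIN_PAIRS[family]} pairs, got {len(vis)}")

    cls = {"affine": sktransform.AffineTransform,
           "projective": sktransform.ProjectiveTransform,
           "poly2": sktransform.PolynomialTransform}[family]
    kw = {"order": 2} if family == "poly2" else {}
    fwd = cls.from_estimate(vis, lwir, **kw)
    # polynomial transforms have no analytic inverse: fit the reverse map
    inv = cls.from_estimate(lwir, vis, **kw)
    if not fwd or not inv:
        raise ValueError("transform estimation failed (degenerate points)")
    residuals = np.linalg.norm(fwd(vis) - lwir, axis=1)
    return FittedTransform(family=family, forward=fwd, inverse=inv,
                           residuals=residuals)


def warp_vis_to_lwir(vis_image: np.ndarray, transform: FittedTransform,
                     lwir_shape: tuple[int, int]
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-mapped bilinear warp of the VIS image onto the LWIR grid.

    Returns ``(warped, valid_mask)``; pixels mapping outside the VIS domain
    are zero and flagged invalid.  The LWIR raster itself is never touched
    (the registration is designed to leave the thermal data unmodified).
    """
    vis = np.asarray(vis_image, dtype=np.float64)
    h, w = lwir_shape

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    src = transform.inverse(np.column_stack([xx.ravel(), yy.ravel()]))
    if not np.all(np.isfinite(src)):
        raise ValueError("transform is not invertible on the target domain")
    sx = src[:, 0].reshape(h, w)
    sy = src[:, 1].reshape(h, w)
    eps = 1e-6   # tolerate pure round-off at the domain edge
    valid = ((sx >= -eps) & (sx <= vis.shape[1] - 1 + eps)
             & (sy >= -eps) & (sy <= vis.shape[0] - 1 + eps))
    sx = np.clip(sx, 0, vis.shape[1] - 1)
    sy = np.clip(sy, 0, vis.shape[0] - 1)

    from scipy.ndimage import map_coordinates

    def _sample(ch):
        out = map_coordinates(ch, [sy, sx], order=1, mode="constant", cval=0.0)
        out[~valid] = 0.0
        return out

    if vis.ndim == 2:
        warped = _sample(vis)
    else:
        warped = np.dstack([_sample(vis[..., c]) for c in range(vis.shape[2])])
    return warped, valid


def fuse_overlay(T, warped_vis: np.ndarray,
                 mode: Literal["edges", "alpha"] = "edges",
                 alpha: float = 0.5, cmap: str = "inferno",
                 t_range: tuple[float, float] | None = None) -> np.ndarray:
    """Blend the temperature map with the warped VIS image for display.

    Pure visualisation: the stored temperature raster is never altered.
    ``edges`` superimposes the VIS edge magnitude on a temperature
    colormap; ``alpha`` blends the two renderings linearly.
    Returns an RGB float image in [0, 1].
    """
    import matplotlib as mpl

    values = np.asarray(getattr(T, "values", T), dtype=np.float64)
    lo, hi = t_range if t_range is not None else (values.min(), values.max())
    norm = np.clip((values - lo) / max(hi - lo, 1e-12), 0.0, 1.0)
    thermal_rgb = mpl.colormaps[cmap](norm)[..., :3]

    vis = np.asarray(warped_vis, dtype=np.float64)
    if vis.ndim == 3:
        vis = vis.mean(axis=2)
    vmax = vis.max() if vis.max() > 0 else 1.0
    vis_norm = vis / vmax

    if mode == "edges":
        edges = sobel(vis_norm)
        emax = edges.max() if edges.max() > 0 else 1.0
        e = (edges / emax)[..., None]
        fused = thermal_rgb * (1.0 - alpha * e) + alpha * e
    elif mode == "alpha":
        fused = (1.0 - alpha) * thermal_rgb + alpha * vis_norm[..., None]
    else:
        raise ValueError(f"unknown fusion mode {mode!r}")
    return np.clip(fused, 0.0, 1.0)


def mm_per_pixel(detections: Sequence[MarkerDetection],
                 true_diameter_mm: float = 10.0) -> float:
    """Physical scale from the known marker diameter.

    Uses the median detected diameter of the modality's markers; the
    10 mm registration disks double as an in-image length reference.
    """
    if len(detections) == 0:
        raise ValueError("cannot derive a scale from zero detections")
    diam_px = np.median([2.0 * d.radius_px for d in detections])
    return float(true_diameter_mm / diam_px)
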