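"""Lens-distortion correction for the VIS and LWIR cameras.

Intrinsics (focal lengths, principal point, radial k1..k3 and tangential
p1, p2 coefficients of the Brown-Conrady model) are supplied from any
standard planar-calibration toolbox as a JSON file; only the *application*
of the model is implemented here.  For the LWIR camera, calibration images
are acquired with a heated-wire grid: a single resistive wire stretched into
a checkerboard-like lattice and warmed by a weak current, which renders the
grid with high contrast against the background — the planar calibration
itself is then identical to the visible-light procedure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["CameraIntrinsics", "undistort", "distort_points", "undistort_points"]


@dataclass
class CameraIntrinsics:
    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "CameraIntrinsics":
        return cls(**json.loads(Path(path).read_text()))


def _apply_distortion(x: np.ndarray, y: np.ndarray, intr: CameraIntrinsics):
    """Brown-Conrady forward model on normalised coordinates."""
    r2 = x * x + y * y
    radial = 1.0 + intr.k1 * r2 + intr.k2 * r2 * r2 + intr.k3 * r2 ** 3
    xd = x * radial + 2.0 * intr.p1 * x * y + intr.p2 * (r2 + 2.0 * x * x)
    yd = y * radial + intr.p1 * (r2 + 2.0 * y * y) + 2.0 * intr.p2 * x * y
    return xd, yd


def distort_points(pts: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Map ideal (undistorted) pixel coordinates to distorted ones.

    ``pts`` is (N, 2) as (x, y) columns.
    """
    pts = np.asarray(pts, dtype=np.float64)
    x = (pts[:, 0] - intr.cx) / intr.fx
    y = (pts[:, 1] - intr.cy) / intr.fy
    xd, yd = _apply_distortion(x, y, intr)
    return np.column_stack([xd * intr.fx + intr.cx, yd * intr.fy + intr.cy])


def undistort_points(pts: np.ndarray, intr: CameraIntrinsics,
                     iters: int = 20) -> np.ndarray:
    """Invert the distortion model by fixed-point iteration on normalised coords."""
    pts = np.asarray(pts, dtype=np.float64)
    xd = (pts[:, 0] - intr.cx) / intr.fx
    yd = (pts[:, 1] - intr.cy) / intr.fy
    x, y = xd.copy(), yd.copy()
    for _ in range(iters):
        xt, yt = _apply_distortion(x, y, intr)
        x += xd - xt
        y += yd - yt
    return np.column_stack([x * intr.fx + intr.cx, y * intr.fy + intr.cy])


def undistort(image: np.ndarray, intr: CameraIntrinsics
              ) -> tuple[np.ndarray, np.ndarray]:
    """Unwarp an image with bilinear resampling.

    Returns ``(undistorted, valid_mask)``: for every output pixel the
    distortion model gives the source location in the input image; pixels
    sampling outside the source are zeroed and marked invalid in the mask,
    which downstream detection uses to ignore them.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape[:2] != (intr.height, intr.width):
        raise ValueError(
            f"image shape {image.shape[:2]} does not match intrinsics "
            f"({intr.height}, {intr.width})")
    yy, xx = np.mgrid[0:intr.height, 0:intr.width].astype(np.float64)
    x = (xx - intr.cx) / intr.fx
    y = (yy - intr.cy) / intr.fy
    xd, yd = _apply_distortion(x, y, intr)
    src_x = xd * intr.fx + intr.cx
    src_y = yd * intr.fy + intr.cy
    eps = 1e-6   # tolerate pure round-off at the domain edge
    valid = ((src_x >= -eps) & (src_x <= intr.width - 1 + eps)
             & (src_y >= -eps) & (src_y <= intr.height - 1 + eps))
    src_x = np.clip(src_x, 0, intr.width - 1)
    src_y = np.clip(src_y, 0, intr.height - 1)

    def _sample(channel):
        out = map_coordinates(channel, [src_y, src_x], order=1,
                              mode="constant", cval=0.0)
        out[~valid] = 0.0
        return out

    if image.ndim == 2:
        result = _sample(image)
    else:
        result = np.dstack([_sample(image[..., c])
                            for c in range(image.shape[2])])
    return result, valid
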