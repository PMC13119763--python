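"""Synthetic scenes with known ground truth for every pipeline stage.

Everything the processing chain consumes can be generated here with its
truth recorded: smooth multiplicative gain fields, flat-field stacks with
detector-realistic noise, Planck-consistent radiometric scenes, bimodal
(VIS + LWIR) coplanar-marker scenes with a small stereo baseline, and
radiometric JPEG containers.

The bimodal scene emulates the bedside geometry: a 160x120 LWIR
microbolometer (54 x 42 degree field of view) and a higher-resolution
visible camera with nearly parallel axes view a marker plane at the 0.5 m
protocol distance.  Markers are 10 mm disks; in the visible image they
render as white anti-aliased disks on matte-black strips, in the thermal
image as diffuse Gaussian "hills" a few degrees above the local
background, sized so their imprints span 10-15 LWIR pixels.  Because both
cameras are fronto-parallel to the marker plane, the exact plane-induced
VIS -> LWIR map is an (axis-aligned) affine transform, recorded in the
truth record together with all centres and the physical scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .flir_io import AcquisitionMeta, RadiometricFrame, write_radiometric_jpeg
from .matching import Affine2D
from .radiometry import RadiometricParams, planck_forward
from .vignetting import FlatFieldSequence, GainField

__all__ = [
    "CameraModel",
    "SceneTruth",
    "make_gain",
    "counts_noise_sd",
    "make_flat_stack",
    "smooth_temperature_field",
    "render_counts",
    "make_bimodal_scene",
    "write_fixture_container",
    "registration_error_mm",
]

#: protocol working distance, m
WORKING_DISTANCE_M = 0.5
#: stereo baseline between the VIS and LWIR lenses, m
DEFAULT_BASELINE_M = 0.012
#: physical marker diameter, m
MARKER_DIAMETER_M = 0.010
#: detector thermal-noise floor (NETD), kelvin
DEFAULT_NETD_K = 0.070


@dataclass
class CameraModel:
    """Fronto-parallel pinhole camera looking down +Z at the marker plane."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    baseline_x: float = 0.0   # lens offset in world X, m
    baseline_y: float = 0.0

    @classmethod
    def from_fov(cls, width: int, height: int, fov_x_deg: float,
                 fov_y_deg: float, baseline_x: float = 0.0,
                 baseline_y: float = 0.0) -> "CameraModel":
        fx = (width / 2.0) / np.tan(np.radians(fov_x_deg / 2.0))
        fy = (height / 2.0) / np.tan(np.radians(fov_y_deg / 2.0))
        return cls(fx=fx, fy=fy, cx=(width - 1) / 2.0, cy=(height - 1) / 2.0,
                   width=width, height=height,
                   baseline_x=baseline_x, baseline_y=baseline_y)

    def project(self, world: np.ndarray, Z0: float = WORKING_DISTANCE_M
                ) -> np.ndarray:
        """Project world points (X, Y[, z_offset]) in metres to pixels.

        ``z_offset`` moves a point off the marker plane toward the camera.
        """
        world = np.atleast_2d(np.asarray(world, dtype=np.float64))
        z = world[:, 2] if world.shape[1] > 2 else np.zeros(len(world))
        Z = Z0 - z
        u = self.fx * (world[:, 0] - self.baseline_x) / Z + self.cx
        v = self.fy * (world[:, 1] - self.baseline_y) / Z + self.cy
        return np.column_stack([u, v])


def _lwir_camera() -> CameraModel:
    return CameraModel.from_fov(160, 120, 54.0, 42.0)


def _vis_camera(baseline_m: float = DEFAULT_BASELINE_M) -> CameraModel:
    # 640x480 stands in for the 5 MP sensor at desk scale
    return CameraModel.from_fov(640, 480, 71.5, 56.0, baseline_x=baseline_m)


@dataclass
class SceneTruth:
    """Everything the simulator knows about a rendered bimodal scene."""

    gain: GainField | None
    T_map: np.ndarray
    ir_centers: np.ndarray
    vis_centers: np.ndarray
    vis_to_lwir: Affine2D
    params: RadiometricParams
    seed: int
    lwir_cam: CameraModel
    vis_cam: CameraModel
    marker_world: np.ndarray
    hill_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def mm_per_px_lwir(self) -> tuple[float, float]:
        Z0 = WORKING_DISTANCE_M
        return (1000.0 * Z0 / self.lwir_cam.fx, 1000.0 * Z0 / self.lwir_cam.fy)

    def lwir_delta_to_mm(self, delta_px: np.ndarray) -> np.ndarray:
        """Convert LWIR pixel displacement vectors to millimetres."""
        mx, my = self.mm_per_px_lwir
        d = np.atleast_2d(np.asarray(delta_px, dtype=np.float64))
        return np.hypot(d[:, 0] * mx, d[:, 1] * my)


def make_gain(shape: tuple[int, int] = (120, 160), model: str = "tilt+radial",
              amplitude: float = 0.1, seed: int = 0) -> GainField:
    """Smooth positive gain-field truth: planar tilt plus a radial quartic.

    ``amplitude`` bounds the relative deviation from unity, so the max/min
    ratio is at most (1 + a) / (1 - a); the field is normalised to unit
    median.  Deterministic per seed.
    """
    if model != "tilt+radial":
        raise ValueError(f"unknown gain model {model!r}")
    if not (0.0 <= amplitude < 0.5):
        raise ValueError("amplitude must be in [0, 0.5)")
    h, w = shape
    rng = np.random.default_rng(seed)
    yn, xn = np.mgrid[0:h, 0:w].astype(np.float64)
    xn = 2.0 * xn / (w - 1) - 1.0
    yn = 2.0 * yn / (h - 1) - 1.0
    rn2 = 0.5 * (xn * xn + yn * yn)
    a, b, c = rng.uniform(-1.0, 1.0, size=3)
    raw = a * xn + b * yn + c * (2.0 * rn2 ** 2 - 1.0)
    peak = np.abs(raw).max()
    if peak > 0:
        raw = raw / peak
    values = 1.0 + amplitude * raw
    values /= np.median(values)
    return GainField(values=np.maximum(values, 1e-6), epoch=0.0,
                     normalizer="median", meta={"model": model,
                                                "amplitude": amplitude,
                                                "seed": seed})


def counts_noise_sd(params: RadiometricParams, T_C: float,
                    netd_K: float = DEFAULT_NETD_K) -> float:
    """Counts-domain noise SD equivalent to a given NETD at temperature T_C.

    Uses the local slope of the forward Planck chain (central difference).
    """
    dT = 0.05
    slope = (planck_forward(T_C + dT, params)
             - planck_forward(T_C - dT, params)) / (2.0 * dT)
    return float(netd_K * slope)


def make_flat_stack(gain: GainField, level_counts: float | None = None,
                    noise_sd_counts: float | None = None, Nk: int = 16,
                    seed: int = 0, epoch: float = 0.0,
                    params: RadiometricParams | None = None,
                    flat_temp_C: float = 23.0,
                    netd_K: float = DEFAULT_NETD_K) -> FlatFieldSequence:
    """Flat-field stack: gain x uniform level + i.i.d. Gaussian noise.

    The level defaults to the forward-model counts of a cardboard target
    at ``flat_temp_C``; the noise defaults to the NETD-equivalent counts
    noise at that temperature.
    """
    if Nk < 1:
        raise ValueError("Nk must be >= 1")
    params = params or RadiometricParams()
    if level_counts is None:
        level_counts = planck_forward(flat_temp_C, params)
    if noise_sd_counts is None:
        noise_sd_counts = counts_noise_sd(params, flat_temp_C, netd_K)
    rng = np.random.default_rng(seed)
    frames = []
    for n in range(Nk):
        counts = gain.values * level_counts
        if noise_sd_counts > 0:
            counts = counts + rng.normal(0.0, noise_sd_counts, size=gain.shape)
        frames.append(RadiometricFrame(counts=np.maximum(counts, 0.0),
                                       timestamp=epoch + n))
    return FlatFieldSequence(frames=frames, epoch=epoch)


def smooth_temperature_field(shape: tuple[int, int] = (120, 160),
                             t_min: float = 28.0, t_max: float = 35.0,
                             smooth_sigma: float = 12.0,
                             seed: int = 0) -> np.ndarray:
    """Smooth random temperature map spanning exactly [t_min, t_max] degC."""
    rng = np.random.default_rng(seed)
    raw = gaussian_filter(rng.normal(size=shape), smooth_sigma, mode="nearest")
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        return np.full(shape, 0.5 * (t_min + t_max))
    return t_min + (t_max - t_min) * (raw - lo) / (hi - lo)


def render_counts(T_map: np.ndarray, params: RadiometricParams,
                  gain: GainField | None = None,
                  noise_sd_counts: float | None = None,
                  netd_K: float = DEFAULT_NETD_K,
                  seed: int = 0) -> RadiometricFrame:
    """Render a temperature map to raw detector counts.

    Forward Planck chain, then the multiplicative vignetting gain, then
    NETD-equivalent Gaussian noise (pass ``noise_sd_counts=0`` to disable).
    """
    counts = planck_forward(T_map, params)
    if gain is not None:
        counts = counts * gain.values
    if noise_sd_counts is None:
        noise_sd_counts = counts_noise_sd(params, float(np.mean(T_map)), netd_K)
    if noise_sd_counts > 0:
        rng = np.random.default_rng(seed)
        counts = counts + rng.normal(0.0, noise_sd_counts, size=counts.shape)
    return RadiometricFrame(counts=np.maximum(counts, 0.0))


def _marker_layout(n_markers: int, rng: np.random.Generator) -> np.ndarray:
    """World (X, Y) marker positions, m.

    A roughly rectangular ring around the feet, the way hand-placed marker
    strips end up in practice: each strip sits a couple of centimetres off
    the nominal grid (fixed irregular offsets), plus a few millimetres of
    per-session jitter.  The irregularity matters: it makes the arrangement
    genuinely asymmetric, so a mirrored image admits no relabelled
    look-alike correspondence.
    """
    hw, hh = 0.17, 0.12
    base = [(-hw, -hh), (0.0, -hh), (hw, -hh), (hw, 0.0),
            (hw, hh), (0.0, hh), (-hw, hh), (-hw, 0.0)]
    offsets = [(0.000, 0.012), (0.028, -0.014), (-0.016, 0.009),
               (0.020, 0.026), (-0.034, -0.010), (0.014, 0.018),
               (0.024, -0.021), (-0.012, 0.030)]
    if n_markers > len(base):
        extra = [(-hw / 2, -hh), (hw / 2, hh), (-hw / 2, hh), (hw / 2, -hh)]
        base = base + extra
        offsets = offsets + [(0.010, 0.005), (-0.020, 0.012),
                             (0.016, -0.008), (-0.006, -0.024)]
    pts = (np.array(base[:n_markers], dtype=np.float64)
           + np.array(offsets[:n_markers], dtype=np.float64))
    return pts + rng.uniform(-0.006, 0.006, size=pts.shape)


def _render_vis_image(vis_centers: np.ndarray, disk_radius_px: float,
                      shape: tuple[int, int], rng: np.random.Generator,
                      strip_half_px: int = 14,
                      illumination_gradient: float = 20.0) -> np.ndarray:
    """White anti-aliased disks on matte-black strips over a gray scene."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    img = np.full(shape, 110.0)
    img += illumination_gradient * (xx / max(w - 1, 1) - 0.5)
    for cx, cy in vis_centers:
        x0, x1 = int(cx) - strip_half_px, int(cx) + strip_half_px + 1
        y0, y1 = int(cy) - strip_half_px, int(cy) + strip_half_px + 1
        img[max(y0, 0):y1, max(x0, 0):x1] = 30.0
    for cx, cy in vis_centers:
        dist = np.hypot(xx - cx, yy - cy)
        coverage = np.clip(disk_radius_px + 0.5 - dist, 0.0, 1.0)
        img = img + (230.0 - img) * coverage
    img += rng.normal(0.0, 1.5, size=shape)
    return np.clip(img, 0.0, 255.0)


def _render_temperature_map(ir_centers: np.ndarray, amps: np.ndarray,
                            shape: tuple[int, int],
                            hill_sigma_px: float = 4.5,
                            ambient_C: float = 23.0,
                            gradient_C: float = 0.0) -> np.ndarray:
    """Ambient field + warm foot-shaped blobs + marker thermal hills."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    T = np.full(shape, ambient_C)
    T += gradient_C * (xx / max(w - 1, 1) - 0.5)
    # two broad anisotropic blobs standing in for the feet (peaks ~31 degC)
    for fx0 in (-0.17, 0.17):
        cx = (w - 1) / 2.0 + fx0 * w
        cy = (h - 1) / 2.0
        T += 8.0 * np.exp(-((xx - cx) ** 2 / (2 * 20.0 ** 2)
                            + (yy - cy) ** 2 / (2 * 38.0 ** 2)))
    for (cx, cy), amp in zip(ir_centers, amps):
        T += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                          / (2 * hill_sigma_px ** 2))
    return T


def _plane_affine(vis_cam: CameraModel, lwir_cam: CameraModel,
                  Z0: float = WORKING_DISTANCE_M) -> Affine2D:
    """Exact VIS -> LWIR map induced by the marker plane (fronto-parallel)."""
    sx = lwir_cam.fx / vis_cam.fx
    sy = lwir_cam.fy / vis_cam.fy
    tx = (lwir_cam.cx - sx * vis_cam.cx
          + lwir_cam.fx * (vis_cam.baseline_x - lwir_cam.baseline_x) / Z0)
    ty = (lwir_cam.cy - sy * vis_cam.cy
          + lwir_cam.fy * (vis_cam.baseline_y - lwir_cam.baseline_y) / Z0)
    return Affine2D(linear=np.diag([sx, sy]), translation=[tx, ty])


def make_bimodal_scene(n_markers: int = 8, layout: str = "ring",
                       parallax_offset_m: float = 0.0, seed: int = 0,
                       gain: GainField | None = None,
                       noise: bool = True,
                       params: RadiometricParams | None = None,
                       baseline_m: float = DEFAULT_BASELINE_M,
                       mirror_vis: bool = False
                       ) -> tuple[np.ndarray, RadiometricFrame, SceneTruth]:
    """Render a coplanar-marker scene in both modalities with full truth.

    ``parallax_offset_m`` lifts the markers off the sole plane toward the
    camera (the truth transform stays the plane-induced one, so off-plane
    markers show the parallax mapping error the registration warns about).
    ``mirror_vis`` flips the visible image left-right, producing the
    physically impossible configuration the matcher must reject.
    """
    if n_markers < 3:
        raise ValueError("need at least 3 markers")
    if layout != "ring":
        raise ValueError(f"unknown layout {layout!r}")
    params = params or RadiometricParams()
    rng = np.random.default_rng(seed)
    lwir_cam = _lwir_camera()
    vis_cam = _vis_camera(baseline_m)

    world_xy = _marker_layout(n_markers, rng)
    world = np.column_stack([world_xy,
                             np.full(n_markers, parallax_offset_m)])
    ir_centers = lwir_cam.project(world)
    vis_centers = vis_cam.project(world)

    disk_radius_px = vis_cam.fx * (MARKER_DIAMETER_M / 2.0) / WORKING_DISTANCE_M
    vis_image = _render_vis_image(vis_centers, disk_radius_px,
                                  (vis_cam.height, vis_cam.width), rng)
    if mirror_vis:
        vis_image = vis_image[:, ::-1].copy()
        vis_centers = vis_centers.copy()
        vis_centers[:, 0] = (vis_cam.width - 1) - vis_centers[:, 0]

    # resistor hills run several degrees above ambient; amplitudes are set
    # so the >= 2 degC relief imprint spans 10-15 LWIR px even where the
    # warm foot background overlaps the marker ring
    amps = rng.uniform(6.0, 9.0, size=n_markers)
    T_map = _render_temperature_map(ir_centers, amps,
                                    (lwir_cam.height, lwir_cam.width))
    frame = render_counts(T_map, params, gain=gain,
                          noise_sd_counts=None if noise else 0.0,
                          seed=int(rng.integers(2**31)))

    truth = SceneTruth(gain=gain, T_map=T_map, ir_centers=ir_centers,
                       vis_centers=vis_centers,
                       vis_to_lwir=_plane_affine(vis_cam, lwir_cam),
                       params=params, seed=seed, lwir_cam=lwir_cam,
                       vis_cam=vis_cam, marker_world=world,
                       hill_amplitudes=amps)
    return vis_image, frame, truth


def write_fixture_container(frame: RadiometricFrame, vis: np.ndarray,
                            params: RadiometricParams, path,
                            meta: AcquisitionMeta | None = None,
                            dialect: str = "raw", byte_swapped: bool = False,
                            omit_payload: bool = False) -> None:
    """Write the scene as a radiometric JPEG container.

    Counts are rounded to the 16-bit payload grid.  ``omit_payload`` writes
    a plain JPEG (the decoder's non-radiometric negative fixture).
    """
    meta = meta or AcquisitionMeta(air_temp_C=params.Ta_C,
                                   rel_humidity=params.RH,
                                   distance_m=params.do)
    if omit_payload:
        from PIL import Image
        v = np.asarray(vis)
        if v.dtype != np.uint8:
            v = np.clip(v, 0, 255).astype(np.uint8)
        Image.fromarray(v).save(path, format="JPEG")
        return
    counts = np.clip(np.round(frame.counts), 0, 0xFFFF)
    write_radiometric_jpeg(path, counts, vis, params, meta,
                           dialect=dialect, byte_swapped=byte_swapped)


def registration_error_mm(truth: SceneTruth, fitted, n_grid: int = 15,
                          markers_world_z: float | None = None) -> float:
    """Mean mapping error (mm) over a grid inside the marker convex hull.

    Compares the fitted VIS->LWIR map with the scene's exact plane-induced
    transform on test points sampled inside the convex hull of the true
    visible marker centres, converted to millimetres with the known scale.
    """
    from scipy.spatial import Delaunay

    hull_pts = truth.vis_centers
    tri = Delaunay(hull_pts)
    x0, y0 = hull_pts.min(axis=0)
    x1, y1 = hull_pts.max(axis=0)
    gx, gy = np.meshgrid(np.linspace(x0, x1, n_grid),
                         np.linspace(y0, y1, n_grid))
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    inside = tri.find_simplex(grid) >= 0
    grid = grid[inside]
    mapped = np.asarray(fitted(grid), dtype=np.float64)
    true = truth.vis_to_lwir(grid)
    return float(np.mean(truth.lwir_delta_to_mm(mapped - true)))
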