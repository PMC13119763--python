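"""Flat-field vignetting correction in the radiometric domain.

Vignetting of an uncooled LWIR camera (optics transmission, angular
response, detector non-uniformity) is multiplicative in radiance space:
``R = G * R_star`` with a slowly varying positive gain field ``G(x, y, t)``.
The gain is estimated from flat-field stacks (camera pressed against
cardboard) acquired at several epochs: pixelwise median -> quantile clamp ->
Gaussian smoothing -> normalisation to unit central tendency.  Epochs are
combined into a pixelwise-median master gain when the inter-epoch log-gain
RMS says the pattern is stable, and interpolated geometrically in time
otherwise.  Correction is elementwise division, performed *before* the
non-linear Planck inversion so that the multiplicative structure is
preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .flir_io import RadiometricFrame

__all__ = [
    "FlatFieldSequence",
    "GainField",
    "GainStabilityReport",
    "robust_flat",
    "build_gain",
    "master_gain",
    "stability_report",
    "interpolate_gain",
    "apply_gain_correction",
    "select_gain",
]

DEFAULT_FLOOR = 1e-6
DEFAULT_QLO = 0.02
DEFAULT_QHI = 0.98
DEFAULT_SIGMA = 4.0
#: max off-diagonal inter-epoch RMS below which the master gain is used
MASTER_RMS_THRESHOLD = 0.01


@dataclass
class FlatFieldSequence:
    """A stack of flat-field frames acquired at one epoch."""

    frames: list[RadiometricFrame]
    epoch: float = 0.0

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("flat-field sequence must contain at least one frame")
        shapes = {f.counts.shape for f in self.frames}
        if len(shapes) != 1:
            raise ValueError(f"flat-field frames have mixed shapes: {shapes}")

    def stack(self) -> np.ndarray:
        return np.stack([f.counts for f in self.frames])


@dataclass
class GainField:
    """Positive multiplicative gain field, nominally of unit central tendency."""

    values: np.ndarray
    epoch: float = 0.0
    normalizer: Literal["mean", "median"] = "median"
    floor: float = DEFAULT_FLOOR
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(~np.isfinite(self.values)) or np.any(self.values < self.floor):
            raise ValueError("gain values must be finite and >= floor")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def central_tendency(self) -> float:
        f = np.median if self.normalizer == "median" else np.mean
        return float(f(self.values))

    def to_tiff(self, path) -> None:
        import tifffile
        tifffile.imwrite(path, self.values.astype(np.float32))
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(json.dumps({
            "epoch": self.epoch, "normalizer": self.normalizer,
            "floor": self.floor, **self.meta}, indent=2))

    @classmethod
    def from_tiff(cls, path) -> "GainField":
        import tifffile
        values = tifffile.imread(path).astype(np.float64)
        sidecar = Path(path).with_suffix(".json")
        kw = {}
        if sidecar.exists():
            d = json.loads(sidecar.read_text())
            kw = {k: d[k] for k in ("epoch", "normalizer", "floor") if k in d}
        return cls(values=values, **kw)


@dataclass
class GainStabilityReport:
    """Pairwise inter-epoch log-gain RMS discrepancies."""

    rms: np.ndarray
    epochs: list[float]

    @property
    def max_offdiag(self) -> float:
        if self.rms.shape[0] < 2:
            return 0.0
        mask = ~np.eye(self.rms.shape[0], dtype=bool)
        return float(self.rms[mask].max())

    def master_is_safe(self, threshold: float = MASTER_RMS_THRESHOLD) -> bool:
        return self.max_offdiag <= threshold


def robust_flat(seq: FlatFieldSequence, qlo: float = DEFAULT_QLO,
                qhi: float = DEFAULT_QHI, clamp: bool = True) -> np.ndarray:
    """Pixelwise median over the stack, then symmetric quantile clamp.

    The median suppresses hot pixels and transient reflections; the clamp
    (default [0.02, 0.98] quantiles of the median image over all pixels)
    removes rare residual artefacts.  Pass ``clamp=False`` to disable.
    """
    if not (0.0 <= qlo < qhi <= 1.0):
        raise ValueError(f"need 0 <= qlo < qhi <= 1, got ({qlo}, {qhi})")
    flat = np.median(seq.stack(), axis=0)
    if clamp:
        lo, hi = np.quantile(flat, [qlo, qhi])
        flat = np.clip(flat, lo, hi)
    return flat


def build_gain(flat: np.ndarray, sigma: float = DEFAULT_SIGMA,
               normalizer: Literal["mean", "median"] = "median",
               floor: float = DEFAULT_FLOOR, epoch: float = 0.0) -> GainField:
    """Gaussian-smooth a flat image and normalise it to a unit-level gain.

    ``sigma`` of 3-6 px preserves the spatial structure of the vignetting
    while suppressing residual noise.  Replicate padding avoids artificial
    darkening at the borders.  The result is divided by its mean or median
    and floored at ``floor``.
    """
    flat = np.asarray(flat, dtype=np.float64)
    if np.any(flat <= 0):
        raise ValueError("flat image must be strictly positive after clamping")
    smooth = gaussian_filter(flat, sigma=sigma, mode="nearest")
    ref = np.median(smooth) if normalizer == "median" else np.mean(smooth)
    values = np.maximum(smooth / ref, floor)
    return GainField(values=values, epoch=epoch, normalizer=normalizer,
                     floor=floor, meta={"sigma": sigma})


def master_gain(gains: Sequence[GainField]) -> GainField:
    """Pixelwise median across epoch gains (re-floored)."""
    if len(gains) < 1:
        raise ValueError("need at least one gain field")
    shapes = {g.shape for g in gains}
    if len(shapes) != 1:
        raise ValueError(f"gain fields have mixed shapes: {shapes}")
    g0 = gains[0]
    values = np.maximum(np.median(np.stack([g.values for g in gains]), axis=0),
                        g0.floor)
    return GainField(values=values, epoch=float(np.median([g.epoch for g in gains])),
                     normalizer=g0.normalizer, floor=g0.floor,
                     meta={"n_epochs": len(gains)})


def stability_report(gains: Sequence[GainField]) -> GainStabilityReport:
    """RMS over pixels of log(G_i / G_j) for every epoch pair."""
    if len(gains) < 2:
        raise ValueError("need at least two gain fields")
    shapes = {g.shape for g in gains}
    if len(shapes) != 1:
        raise ValueError(f"gain fields have mixed shapes: {shapes}")
    logs = [np.log(g.values) for g in gains]
    K = len(gains)
    rms = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            rms[i, j] = rms[j, i] = float(np.sqrt(np.mean((logs[i] - logs[j]) ** 2)))
    return GainStabilityReport(rms=rms, epochs=[g.epoch for g in gains])


def interpolate_gain(gj: GainField, gj1: GainField, t: float) -> GainField:
    """Geometric (log-domain) interpolation between two epoch gains at time t.

    ``G(t) = Gj^(1-w) * Gj1^w`` with ``w = (t - tj) / (tj1 - tj)``; no
    extrapolation outside [tj, tj1].
    """
    if not (gj.epoch <= t <= gj1.epoch):
        raise ValueError(f"t={t} outside epoch interval [{gj.epoch}, {gj1.epoch}]")
    if gj.shape != gj1.shape:
        raise ValueError("gain shapes differ")
    span = gj1.epoch - gj.epoch
    w = 0.0 if span == 0 else (t - gj.epoch) / span
    values = np.exp((1.0 - w) * np.log(gj.values) + w * np.log(gj1.values))
    return GainField(values=np.maximum(values, gj.floor), epoch=t,
                     normalizer=gj.normalizer, floor=gj.floor,
                     meta={"interpolated": True, "w": w})


def apply_gain_correction(frame: RadiometricFrame, gain: GainField) -> RadiometricFrame:
    """Elementwise division by the gain field; metadata propagated."""
    if frame.counts.shape != gain.shape:
        raise ValueError(
            f"frame shape {frame.counts.shape} != gain shape {gain.shape}")
    return RadiometricFrame(counts=frame.counts / gain.values,
                            timestamp=frame.timestamp, camera_id=frame.camera_id)


def select_gain(gains: Sequence[GainField], t: float,
                threshold: float = MASTER_RMS_THRESHOLD
                ) -> tuple[GainField, str]:
    """Master gain when epochs are stable, geometric interpolation otherwise.

    Returns the chosen gain plus a tag ("master" or "interpolated") for
    provenance logging.
    """
    if len(gains) == 1:
        return gains[0], "single-epoch"
    report = stability_report(gains)
    if report.master_is_safe(threshold):
        return master_gain(gains), "master"
    ordered = sorted(gains, key=lambda g: g.epoch)
    for gj, gj1 in zip(ordered, ordered[1:]):
        if gj.epoch <= t <= gj1.epoch:
            return interpolate_gain(gj, gj1, t), "interpolated"
    raise ValueError(f"t={t} outside the calibrated epoch range; no extrapolation")
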