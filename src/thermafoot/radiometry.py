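"""Radiometric counts ↔ temperature conversion for calibrated LWIR cameras.

The camera reports a radiometric signal that is related to scene temperature
through a calibrated Planck-law parameterisation (constants ``PB, PR1, PR2,
PO, PF`` stored in the image metadata) combined with an emissivity,
window-transmission and atmospheric model.  The chain implemented here is
the classical one used for consumer radiometric cameras (Minkina & Dudzik):

1. water-vapour pressure from air temperature and relative humidity,
2. atmospheric transmission ``tau`` along the camera-object path,
3. path radiances (atmosphere, optics window, reflected ambient),
4. object radiance from the vignette-corrected counts,
5. Planck inversion to temperature in degrees Celsius.

The exact algebraic forward model (temperature -> counts) is also provided;
it is the basis of the synthetic-scene simulator and of round-trip tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

__all__ = [
    "RadiometricParams",
    "TemperatureImage",
    "water_vapour_pressure",
    "atm_transmission",
    "path_radiances",
    "counts_to_object_radiance",
    "planck_invert",
    "planck_forward",
    "frame_to_temperature",
]

_ZERO_C_IN_K = 273.15


@dataclass
class RadiometricParams:
    """Planck calibration constants plus emissivity, optics and atmosphere.

    Defaults correspond to a typical low-cost uncooled microbolometer camera
    under the bedside acquisition protocol (0.5 m working distance, skin
    emissivity 0.98, unity window transmission).
    """

    PB: float = 1428.0
    PR1: float = 17096.453
    PR2: float = 0.046642
    PO: float = -1385.0
    PF: float = 1.0
    emissivity: float = 0.98
    Wt: float = 1.0
    Xatm: float = 1.9
    alpha1: float = 0.006569
    alpha2: float = 0.01262
    beta1: float = -0.002276
    beta2: float = -0.00667
    do: float = 0.5
    Ta_C: float = 22.4
    Tw_K: float | None = None
    Tr_K: float | None = None
    RH: float = 0.58
    atm_formula: Literal["sqrt", "linear"] = "sqrt"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.PB <= 0 or self.PR1 <= 0 or self.PR2 <= 0:
            raise ValueError("Planck constants PB, PR1, PR2 must be positive")
        if not (0.0 < self.emissivity <= 1.0):
            raise ValueError(f"emissivity must be in (0, 1], got {self.emissivity}")
        if not (0.0 < self.Wt <= 1.0):
            raise ValueError(f"window transmission must be in (0, 1], got {self.Wt}")
        if not (0.0 <= self.RH <= 1.0):
            raise ValueError(f"relative humidity must be in [0, 1], got {self.RH}")
        if self.do < 0:
            raise ValueError("distance must be >= 0")
        # Reflected / window temperatures default to ambient (standard
        # reflected-temperature practice when the metadata does not say).
        if self.Tw_K is None:
            self.Tw_K = self.Ta_C + _ZERO_C_IN_K
        if self.Tr_K is None:
            self.Tr_K = self.Ta_C + _ZERO_C_IN_K

    @property
    def Ta_K(self) -> float:
        return self.Ta_C + _ZERO_C_IN_K

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RadiometricParams":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RadiometricParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class TemperatureImage:
    """A temperature raster in degrees Celsius with its conversion context."""

    values: np.ndarray
    params: RadiometricParams
    vignette_corrected: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def plausible(self, lo: float = -40.0, hi: float = 150.0) -> bool:
        return bool(np.all(np.isfinite(self.values)) and
                    np.all((self.values >= lo) & (self.values <= hi)))


def water_vapour_pressure(Ta_C: float, RH: float) -> float:
    """Water-vapour pressure from air temperature (degC) and RH fraction.

    Cubic-exponential empirical fit; the air temperature enters in Celsius.
    """
    if not (0.0 <= RH <= 1.0):
        raise ValueError(f"relative humidity must be in [0, 1], got {RH}")
    Ta = float(Ta_C)
    return RH * np.exp(1.5587 + 0.06939 * Ta - 0.00027816 * Ta**2
                       + 0.00000068455 * Ta**3)


def atm_transmission(params: RadiometricParams, Wp: float) -> float:
    """Two-component exponential atmospheric transmission over ``params.do``.

    Default form uses sqrt(distance) and sqrt(Wp) attenuation exponents;
    ``params.atm_formula == "linear"`` switches to the literal linear-path
    variant.  Result is clamped into (0, 1].
    """
    d = params.do
    if params.atm_formula == "sqrt":
        e1 = np.exp(-np.sqrt(d) * (params.alpha1 + params.beta1 * np.sqrt(Wp)))
        e2 = np.exp(-np.sqrt(d) * (params.alpha2 + params.beta2 * np.sqrt(Wp)))
    else:
        e1 = np.exp(-d * (params.alpha1 + params.beta1 * Wp))
        e2 = np.exp(-d * (params.alpha2 + params.beta2 * Wp))
    tau = params.Xatm * e1 + (1.0 - params.Xatm) * e2
    return float(np.clip(tau, np.finfo(float).tiny, 1.0))


def _planck_radiance(T_K: float, p: RadiometricParams) -> float:
    """Camera-unit radiance of a blackbody at T_K under the calibration."""
    return p.PR1 / (p.PR2 * (np.exp(p.PB / T_K) - p.PF)) - p.PO


def path_radiances(params: RadiometricParams, tau: float) -> tuple[float, float, float]:
    """Radiance contributions of atmosphere, optics window and reflection.

    Returns ``(Ratm, Ropt, Rrefl)`` in camera radiance units; the ambient,
    window and reflected temperatures enter in kelvin.
    """
    eps, Wt = params.emissivity, params.Wt
    if tau <= 0.0 or eps <= 0.0:
        raise ValueError("tau and emissivity must be positive (singular configuration)")
    Ratm = (1.0 - tau) / (eps * tau) * _planck_radiance(params.Ta_K, params)
    Ropt = (1.0 - Wt) / (eps * tau * Wt) * _planck_radiance(params.Tw_K, params)
    Rrefl = (1.0 - eps) / eps * _planck_radiance(params.Tr_K, params)
    return float(Ratm), float(Ropt), float(Rrefl)


def counts_to_object_radiance(counts, params: RadiometricParams, tau: float):
    """Object radiance from vignette-corrected counts (elementwise affine)."""
    eps, Wt = params.emissivity, params.Wt
    denom = eps * tau * Wt
    if denom == 0.0:
        raise ValueError("emissivity * tau * Wt must be nonzero")
    Ratm, Ropt, Rrefl = path_radiances(params, tau)
    return np.asarray(counts, dtype=np.float64) / denom - Ratm - Ropt - Rrefl


class RadianceRangeError(ValueError):
    """Raised when a radiance maps outside the invertible Planck domain."""

    def __init__(self, n_bad: int, where=None):
        self.n_bad = n_bad
        self.where = where
        super().__init__(
            f"{n_bad} pixel(s) have object radiance outside the invertible "
            "range (log argument <= 1); check gain correction and parameters")


def planck_invert(Robject, params: RadiometricParams):
    """Invert the Planck parameterisation: object radiance -> temperature degC.

    Raises :class:`RadianceRangeError` identifying offending pixels when the
    logarithm argument is <= 1 (temperature would be non-positive kelvin).
    """
    R = np.asarray(Robject, dtype=np.float64)
    arg = params.PR1 / (params.PR2 * (R + params.PO)) + params.PF
    bad = ~(arg > 1.0)
    if np.any(bad):
        raise RadianceRangeError(int(np.count_nonzero(bad)),
                                 where=np.argwhere(np.atleast_1d(bad)))
    T = params.PB / np.log(arg) - _ZERO_C_IN_K
    if np.ndim(Robject) == 0:
        return float(T)
    return T


def planck_forward(T_C, params: RadiometricParams, tau: float | None = None):
    """Exact forward model: scene temperature degC -> radiometric counts.

    Algebraic inverse of the correction/inversion chain, used by the
    synthetic-scene generator and round-trip tests.
    """
    if tau is None:
        Wp = water_vapour_pressure(params.Ta_C, params.RH)
        tau = atm_transmission(params, Wp)
    T_K = np.asarray(T_C, dtype=np.float64) + _ZERO_C_IN_K
    Robject = params.PR1 / (params.PR2 * (np.exp(params.PB / T_K) - params.PF)) - params.PO
    Ratm, Ropt, Rrefl = path_radiances(params, tau)
    counts = params.emissivity * tau * params.Wt * (Robject + Ratm + Ropt + Rrefl)
    if np.ndim(T_C) == 0:
        return float(counts)
    return counts


def counts_to_temperature(counts, params: RadiometricParams):
    """Full inversion chain on already-corrected counts."""
    Wp = water_vapour_pressure(params.Ta_C, params.RH)
    tau = atm_transmission(params, Wp)
    Robject = counts_to_object_radiance(counts, params, tau)
    return planck_invert(Robject, params)


def frame_to_temperature(frame, gain, params: RadiometricParams) -> TemperatureImage:
    """Vignette-correct a radiometric frame and convert it to temperature.

    ``frame`` is a :class:`~thermafoot.flir_io.RadiometricFrame` (or bare
    array), ``gain`` a :class:`~thermafoot.vignetting.GainField` (or ``None``
    to skip correction).
    """
    from .vignetting import apply_gain_correction

    if gain is not None:
        frame = apply_gain_correction(frame, gain)
    counts = getattr(frame, "counts", frame)
    T = counts_to_temperature(counts, params)
    return TemperatureImage(values=T, params=params,
                            vignette_corrected=gain is not None)
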