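"""Drought activity factors gamma_SM.

The drought activity factor scales standard-condition isoprene emission
for water stress.  Two mechanisms act in opposite directions: stomatal
closure raises leaf temperature, stimulating emission under mild-to-
moderate drought, while severe drought cuts the photosynthetic substrate
supply and suppresses it.

The PDS (parameterized drought stress) response captures both as a
product of two logistic curves in a normalized drought index (1 =
unstressed, 0 = severe drought):

    gamma_sm  = gamma_sm_max * gamma_sub * gamma_lt
    gamma_sub = 1 / (1 + b1 * exp(a1 * (x - 0.2)))
    gamma_lt  = 1/gamma_sm_max
                + (1 - 1/gamma_sm_max) / (1 + b2 * exp(a2 * (1.3 - x)))

With the default parameters the curve is ~1 at x = 1, peaks at ~1.27
around x ~ 0.7 and collapses toward 0 under severe drought.

The EDS (explicit drought stress) response is a three-branch function of
the land-model water stress function beta_t, using Vcmax as the substrate
proxy under severe drought.  Legacy soil-moisture formulations (linear
ramps over the wilting point, a power-law ramp, and a Gompertz-type curve
in soil water availability) are included for comparison.

All functions are pure and vectorized over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PDSParams:
    """Shape parameters of the PDS drought response curve.

    ``a1``/``b1`` shape the substrate-supply logistic, ``a2``/``b2`` the
    leaf-temperature logistic, and ``gamma_sm_max`` is the ceiling of the
    combined response (1.4 = at most a 40% leaf-temperature enhancement).
    Defaults are the values calibrated against the MOFLUX 2012 drought
    season canopy fluxes.
    """

    a1: float = -7.45
    a2: float = -28.76
    b1: float = 3.26
    b2: float = 2.35e6
    gamma_sm_max: float = 1.4

    def __post_init__(self) -> None:
        if self.gamma_sm_max < 1.0:
            raise ValueError("gamma_sm_max must be >= 1")
        if self.b1 <= 0 or self.b2 <= 0:
            raise ValueError("b1 and b2 must be positive")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.a1, self.a2, self.b1, self.b2, self.gamma_sm_max)


@dataclass(frozen=True)
class EDSInputs:
    """Inputs of the explicit (beta_t/Vcmax-driven) drought response."""

    beta_t: float
    vcmax: float = 37.0   # umol m^-2 s^-1
    alpha: float = 37.0   # empirical Vcmax scale

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta_t <= 1.0:
            raise ValueError("beta_t must be in [0, 1]")
        if self.vcmax < 0:
            raise ValueError("vcmax must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class LegacySMParams:
    """Thresholds of the legacy soil-moisture drought formulations.

    ``delta_theta1`` is the ramp width above the wilting point: 0.06 for
    the v2 form, 0.04 for v2.1, 0.07 for the power-law form.
    ``theta_max`` is only used for soil water availability (SWA).
    """

    theta_w: float = 0.23       # wilting point, m^3 m^-3
    delta_theta1: float = 0.04  # ramp width, m^3 m^-3
    theta_max: float = 0.47     # maximum observed SWC, m^3 m^-3 (for SWA)
    exponent: float = 0.4       # power-law ramp exponent

    def __post_init__(self) -> None:
        if self.theta_w < 0:
            raise ValueError("theta_w must be >= 0")
        if self.delta_theta1 <= 0:
            raise ValueError("delta_theta1 must be positive")
        if self.theta_max <= self.theta_w:
            raise ValueError("theta_max must exceed theta_w")

    @property
    def theta_c(self) -> float:
        """Critical soil moisture theta_w + delta_theta1."""
        return self.theta_w + self.delta_theta1


def _check_index(index: np.ndarray) -> np.ndarray:
    index = np.asarray(index, dtype=float)
    if np.any((index < 0.0) | (index > 1.3)):
        raise ValueError("drought index outside [0, 1.3]")
    return index


def gamma_sub(index, p: PDSParams = PDSParams()):
    """Substrate-supply component of the PDS response.

    Logistic in the normalized index, in (0, 1); non-decreasing for
    a1 < 0.  Near 1 when unstressed, dropping once the index falls below
    roughly 0.7.
    """
    index = _check_index(index)
    out = 1.0 / (1.0 + p.b1 * np.exp(p.a1 * (index - 0.2)))
    return float(out) if out.ndim == 0 else out


def gamma_lt(index, p: PDSParams = PDSParams()):
    """Leaf-temperature stimulation component of the PDS response.

    Bounded in [1/gamma_sm_max, 1]; non-increasing in the index for
    a2 < 0, so multiplied by gamma_sm_max it rises toward the ceiling as
    drought develops (stomatal closure warms the leaf).
    """
    index = _check_index(index)
    inv = 1.0 / p.gamma_sm_max
    out = inv + (1.0 - inv) / (1.0 + p.b2 * np.exp(p.a2 * (1.3 - index)))
    return float(out) if out.ndim == 0 else out


def gamma_sm_pds(index, p: PDSParams = PDSParams(), clip: bool = True):
    """PDS drought activity factor: gamma_sm_max * gamma_sub * gamma_lt.

    ~1 when unstressed (index = 1), a single interior maximum (~1.27 with
    defaults) under moderate drought, collapsing toward 0 under severe
    drought.  ``clip=True`` clips the index into [0, 1] first (the
    normalized-index convention); with ``clip=False`` the extended domain
    up to 1.3 is allowed.
    """
    index = np.asarray(index, dtype=float)
    if clip:
        index = np.clip(index, 0.0, 1.0)
    out = p.gamma_sm_max * gamma_sub(index, p) * gamma_lt(index, p)
    return float(out) if np.ndim(out) == 0 else out


def gamma_sm_eds(inp: EDSInputs) -> float:
    """Explicit (beta_t/Vcmax-driven) drought activity factor.

    1 for beta_t >= 0.6 (mild/moderate drought leaves emission untouched);
    Vcmax/alpha, clipped to [0, 1], for 0 < beta_t < 0.6; 0 at beta_t = 0.
    The jump at beta_t = 0.6 is a feature of the formulation, not smoothed.
    """
    if inp.beta_t >= 0.6:
        return 1.0
    if inp.beta_t == 0.0:
        return 0.0
    return float(np.clip(inp.vcmax / inp.alpha, 0.0, 1.0))


def gamma_sm_megan2(theta, p: LegacySMParams = LegacySMParams()):
    """Legacy linear-ramp soil-moisture response (MEGAN v2 / v2.1).

    0 below the wilting point, (theta - theta_w)/delta_theta1 on the ramp,
    1 above theta_c = theta_w + delta_theta1.  Use delta_theta1 = 0.06 for
    the v2 constants, 0.04 for v2.1.
    """
    theta = np.asarray(theta, dtype=float)
    out = np.clip((theta - p.theta_w) / p.delta_theta1, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def gamma_sm_otularbi(theta, p: LegacySMParams | None = None):
    """Power-law soil-moisture ramp: ((theta-theta_w)/(theta_c-theta_w))^0.4.

    Defaults to the published ramp width delta_theta1 = 0.07.
    """
    if p is None:
        p = LegacySMParams(delta_theta1=0.07)
    theta = np.asarray(theta, dtype=float)
    frac = np.clip((theta - p.theta_w) / (p.theta_c - p.theta_w), 0.0, 1.0)
    out = frac**p.exponent
    return float(out) if out.ndim == 0 else out


def gamma_sm_bonn(swa, rescale: bool = False):
    """Gompertz-type response to soil water availability.

    gamma_sm = exp(-exp(0.056 * e * (-2.3 - SWA) + 1))

    Implemented exactly as published; note it evaluates to ~0.19 at
    SWA = 1, well short of 1 under no stress.  ``rescale=True`` divides by
    the value at SWA = 1 so unstressed soil maps to 1, for side-by-side
    comparison with the other algorithms.
    """
    swa = np.asarray(swa, dtype=float)
    out = np.exp(-np.exp(0.056 * np.e * (-2.3 - swa) + 1.0))
    if rescale:
        out = out / np.exp(-np.exp(0.056 * np.e * (-3.3) + 1.0))
    return float(out) if out.ndim == 0 else out


def swa_from_theta(theta, p: LegacySMParams = LegacySMParams(), clip: bool = False):
    """Soil water availability: SWC normalized between wilting point and maximum.

    SWA = (theta - theta_w) / (theta_max - theta_w); 0 at the wilting
    point, 1 at the maximum.  Out-of-range soil moisture maps outside
    [0, 1] unless ``clip=True``.
    """
    theta = np.asarray(theta, dtype=float)
    out = (theta - p.theta_w) / (p.theta_max - p.theta_w)
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out
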