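"""Canopy-scale isoprene emission as a product of activity factors.

The canopy flux follows the MEGAN framework:

    F = epsilon * LAI * gamma_P * gamma_T * gamma_A * gamma_SM * gamma_C

with epsilon the standardized emission factor (mg m^-2 h^-1), LAI the leaf
area index, and dimensionless activity factors for light, temperature,
leaf age, drought and CO2 inhibition.  The drought factor gamma_SM is
pluggable — any of the algorithms in :mod:`isodrought.gamma` — while the
light and temperature responses use the canonical MEGAN v2.1 isoprene
forms, normalized so that standard conditions (PPFD = 1000 umol m^-2
s^-1, leaf at 303 K with a 297 K past-temperature history) give a factor
near 1.

The temperature response depends on the running means of leaf temperature
over the past 24 hours and the past 10 days: a warm preceding period
raises both the optimum temperature and the attainable maximum, so the
same instantaneous leaf temperature emits more after warm days.  In this
offline driver leaf temperature is approximated by air temperature plus a
configurable constant offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from isodrought.gamma import (
    LegacySMParams,
    PDSParams,
    gamma_sm_bonn,
    gamma_sm_megan2,
    gamma_sm_otularbi,
    gamma_sm_pds,
    swa_from_theta,
)
from isodrought.met import DroughtIndex

#: drought algorithm choices accepted by run_timeseries
DROUGHT_ALGORITHMS = ("none", "pds", "eds", "megan2", "megan21", "otularbi", "bonn")


@dataclass(frozen=True)
class EmissionConfig:
    """Emission factor, canopy state and response-curve constants.

    ``epsilon`` defaults to the canopy-scale isoprene emission factor of
    10 mg m^-2 h^-1 (a leaf-scale factor of 2.45 mg m^-2 h^-1 is the
    offline v3.2 alternative when a canopy environment model supplies the
    scaling).  ``gamma_age`` and ``gamma_co2`` default to 1 (constant
    canopy age structure and fixed CO2).
    """

    epsilon: float = 10.0       # emission factor, mg m^-2 h^-1
    lai: float = 1.0            # leaf area index, m^2 m^-2
    gamma_age: float = 1.0
    gamma_co2: float = 1.0
    # temperature response (MEGAN v2.1 isoprene constants)
    ct1: float = 95.0
    ct2: float = 230.0
    eopt_scale: float = 2.034
    # light response
    light_alpha: float = 0.004
    light_cp: float = 1.21
    # offline leaf-temperature approximation: t_leaf = t_air + offset (K)
    leaf_air_offset: float = 0.0
    # EDS inputs when driven by a beta_t index series
    vcmax: float = 37.0         # umol m^-2 s^-1
    eds_alpha: float = 37.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.lai < 0 or self.gamma_age < 0 or self.gamma_co2 < 0:
            raise ValueError("lai and activity factors must be >= 0")


@dataclass(frozen=True)
class ActivityFactors:
    """Per-timestep activity factor bundle entering the flux product."""

    gamma_p: float
    gamma_t: float
    gamma_sm: float
    gamma_a: float = 1.0
    gamma_c: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gamma_p", "gamma_t", "gamma_sm", "gamma_a", "gamma_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class BallBerryInputs:
    """Inputs of the Ball-Berry stomatal conductance relation."""

    m: float              # PFT slope
    a_n: float            # net photosynthesis, umol m^-2 s^-1
    c_s: float            # CO2 partial pressure at the leaf surface, Pa
    p_atm: float          # atmospheric pressure, Pa
    h_s: float            # leaf-surface relative humidity, fraction
    b: float              # minimum conductance, umol m^-2 s^-1
    beta_t: float = 1.0   # water stress function

    def __post_init__(self) -> None:
        if self.c_s <= 0:
            raise ValueError("c_s must be positive")
        if self.p_atm <= 0:
            raise ValueError("p_atm must be positive")
        if not 0.0 <= self.h_s <= 1.0:
            raise ValueError("h_s must be in [0, 1]")
        if not 0.0 <= self.beta_t <= 1.0:
            raise ValueError("beta_t must be in [0, 1]")


def gamma_temperature(t_leaf, t24, t240, cfg: EmissionConfig = EmissionConfig()):
    """Temperature activity factor (MEGAN v2.1 isoprene form).

    Parameters are leaf temperature and the running means of leaf
    temperature over the past 24 h and 240 h, all in kelvin.  The optimum
    temperature T_opt = 313 + 0.6 (t240 - 297) and the peak value
    E_opt = 2.034 exp(0.05 (t24 - 297)) exp(0.05 (t240 - 297)) shift with
    the past-temperature history; the response has a single interior
    maximum at T_opt.
    """
    t_leaf = np.asarray(t_leaf, dtype=float)
    t24 = np.asarray(t24, dtype=float)
    t240 = np.asarray(t240, dtype=float)
    if np.any((t_leaf <= 240.0) | (t_leaf >= 330.0)):
        raise ValueError("t_leaf outside the physical range (240, 330) K")

    t_opt = 313.0 + 0.6 * (t240 - 297.0)
    e_opt = (
        cfg.eopt_scale
        * np.exp(0.05 * (t24 - 297.0))
        * np.exp(0.05 * (t240 - 297.0))
    )
    x = (1.0 / t_opt - 1.0 / t_leaf) / 0.00831
    out = (
        e_opt
        * cfg.ct2
        * np.exp(cfg.ct1 * x)
        / (cfg.ct2 - cfg.ct1 * (1.0 - np.exp(cfg.ct2 * x)))
    )
    return float(out) if out.ndim == 0 else out


def gamma_light(ppfd, cfg: EmissionConfig = EmissionConfig()):
    """Light activity factor: saturating response to PPFD.

    gamma_P = C_P * alpha * Q / sqrt(1 + alpha^2 Q^2); zero in the dark,
    monotone and saturating in PPFD (umol m^-2 s^-1).
    """
    q = np.asarray(ppfd, dtype=float)
    if np.any(q < 0):
        raise ValueError("ppfd must be >= 0")
    a = cfg.light_alpha
    out = cfg.light_cp * a * q / np.sqrt(1.0 + a * a * q * q)
    return float(out) if out.ndim == 0 else out


def canopy_flux(af: ActivityFactors, cfg: EmissionConfig = EmissionConfig()) -> float:
    """Canopy isoprene flux (mg m^-2 h^-1): epsilon * LAI * product of factors."""
    return (
        cfg.epsilon
        * cfg.lai
        * af.gamma_p
        * af.gamma_t
        * af.gamma_a
        * af.gamma_sm
        * af.gamma_c
    )


def ball_berry_gs(inp: BallBerryInputs) -> float:
    """Ball-Berry stomatal conductance g_s (umol m^-2 s^-1).

    g_s = m * A_n * h_s / (C_s / P_atm) + b * beta_t

    The water stress function throttles the minimum-conductance intercept;
    drought therefore closes stomata, which in a coupled canopy model
    raises leaf temperature.  Provided as a leaf-level utility — the
    offline emission driver does not simulate the leaf energy balance.
    """
    gs = inp.m * inp.a_n * inp.h_s / (inp.c_s / inp.p_atm) + inp.b * inp.beta_t
    return float(max(gs, 0.0))


def _past_mean(series: pd.Series, window: str) -> pd.Series:
    """Causal time-based running mean (includes the current sample)."""
    return series.rolling(window, min_periods=1).mean()


def _drought_factor(
    algorithm: str,
    met: pd.DataFrame,
    index: DroughtIndex | None,
    cfg: EmissionConfig,
    pds_params: PDSParams,
    sm_params: LegacySMParams,
) -> np.ndarray:
    n = len(met)
    if algorithm == "none":
        return np.ones(n)
    if algorithm in ("pds", "eds"):
        if index is None:
            raise ValueError(f"algorithm {algorithm!r} needs a drought index series")
        idx = index.for_day(met.index)
        if np.any(~np.isfinite(idx)):
            raise ValueError("drought index does not cover all run days")
        if algorithm == "pds":
            return np.asarray(gamma_sm_pds(idx, pds_params))
        # EDS: the index series is interpreted as beta_t
        mid = np.clip(cfg.vcmax / cfg.eds_alpha, 0.0, 1.0)
        return np.where(idx >= 0.6, 1.0, np.where(idx == 0.0, 0.0, mid))
    if "theta" not in met.columns or met["theta"].isna().all():
        raise ValueError(f"algorithm {algorithm!r} needs soil moisture (theta)")
    theta = met["theta"].to_numpy()
    if algorithm == "megan2":
        p = LegacySMParams(
            theta_w=sm_params.theta_w, delta_theta1=0.06, theta_max=sm_params.theta_max
        )
        return np.asarray(gamma_sm_megan2(theta, p))
    if algorithm == "megan21":
        p = LegacySMParams(
            theta_w=sm_params.theta_w, delta_theta1=0.04, theta_max=sm_params.theta_max
        )
        return np.asarray(gamma_sm_megan2(theta, p))
    if algorithm == "otularbi":
        p = LegacySMParams(
            theta_w=sm_params.theta_w, delta_theta1=0.07, theta_max=sm_params.theta_max
        )
        return np.asarray(gamma_sm_otularbi(theta, p))
    if algorithm == "bonn":
        return np.asarray(gamma_sm_bonn(swa_from_theta(theta, sm_params)))
    raise ValueError(
        f"unknown drought algorithm {algorithm!r}; choose from {DROUGHT_ALGORITHMS}"
    )


def run_timeseries(
    met: pd.DataFrame,
    index: DroughtIndex | None = None,
    cfg: EmissionConfig = EmissionConfig(),
    algorithm: str = "pds",
    pds_params: PDSParams = PDSParams(),
    sm_params: LegacySMParams = LegacySMParams(),
) -> pd.DataFrame:
    """Run the emission model over a met series with a chosen drought algorithm.

    Parameters
    ----------
    met
        Met series (``DatetimeIndex``, canonical columns); ``ppfd`` and
        ``t_air`` drive the light and temperature responses, ``theta``
        the soil-moisture algorithms.
    index
        Daily drought index, broadcast to every timestep of its calendar
        day.  Interpreted as normalized f_PET for ``"pds"``, as beta_t
        for ``"eds"``.  Unused by the soil-moisture algorithms.
    algorithm
        One of ``DROUGHT_ALGORITHMS``; ``"none"`` fixes gamma_SM = 1.

    Returns
    -------
    DataFrame indexed like ``met`` with columns ``gamma_p``, ``gamma_t``,
    ``gamma_sm`` and ``flux_mg_m2_h``.

    Notes
    -----
    The 24 h / 240 h past-temperature means are causal (current and past
    samples only; expanding at the start of the series), so future data
    can never change the current flux.
    """
    if not isinstance(met.index, pd.DatetimeIndex):
        raise TypeError("met must have a DatetimeIndex")

    t_leaf = met["t_air"] + 273.15 + cfg.leaf_air_offset
    t24 = _past_mean(t_leaf, "24h")
    t240 = _past_mean(t_leaf, "240h")

    g_p = np.asarray(gamma_light(met["ppfd"].to_numpy(), cfg))
    g_t = np.asarray(
        gamma_temperature(t_leaf.to_numpy(), t24.to_numpy(), t240.to_numpy(), cfg)
    )
    g_sm = _drought_factor(algorithm, met, index, cfg, pds_params, sm_params)

    flux = cfg.epsilon * cfg.lai * cfg.gamma_age * cfg.gamma_co2 * g_p * g_t * g_sm
    return pd.DataFrame(
        {"gamma_p": g_p, "gamma_t": g_t, "gamma_sm": g_sm, "flux_mg_m2_h": flux},
        index=met.index,
    )
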