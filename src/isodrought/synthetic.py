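"""Deterministic synthetic forcing for a growing season with a drought.

The generator emulates the structure of a mid-latitude deciduous-forest
flux-tower record over a growing season containing a drought episode:
diurnal shortwave and PPFD with a solar-like shape, a diurnal air
temperature cycle elevated while the drought deepens, declining soil
moisture and air humidity, and a latent heat flux constructed so that the
daily ET/PET ratio follows a prescribed drought-index trajectory (1
before and after the episode, ramping down to a prescribed minimum and
back).  Running the f_PET pipeline on the generated series therefore
recovers the prescribed trajectory up to smoothing error, which makes
every downstream module testable without any external data.

All outputs are pure functions of (spec, seed).  The generator makes no
claim to weather realism beyond what the pipeline's filters and running
means need; it does not reproduce any measured site values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from isodrought.emission import EmissionConfig, run_timeseries
from isodrought.gamma import PDSParams, gamma_sm_pds
from isodrought.met import (
    DroughtIndex,
    latent_heat_of_vaporization,
    pet_penman_monteith,
    saturation_vapor_pressure,
    W_TO_MJ_DAY,
)


@dataclass(frozen=True)
class ScenarioSpec:
    """A synthetic growing-season scenario.

    The drought window ramps the daily drought index from 1 down to
    ``depth`` over ``ramp_days``, holds it, and ramps back (a trapezoid).
    ``drought_warming`` is the extra afternoon warmth (degC) at full
    drought depth; ``noise_sigma`` is the multiplicative lognormal sigma
    applied to pseudo-observed fluxes.
    """

    start: str = "2012-06-01"
    end: str = "2012-09-01"          # exclusive
    timestep_min: int = 30
    drought_start: str = "2012-07-10"
    drought_end: str = "2012-08-09"  # exclusive
    depth: float = 0.3               # minimum daily index during the drought
    ramp_days: int = 7
    t_mean: float = 24.0             # daily mean air temperature, degC
    t_amp: float = 7.0               # diurnal half-amplitude, degC
    drought_warming: float = 5.0     # extra warmth at full depth, degC
    sw_max: float = 900.0            # clear-sky noon shortwave, W m^-2
    noise_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("depth must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        run = (pd.Timestamp(self.start), pd.Timestamp(self.end))
        win = (pd.Timestamp(self.drought_start), pd.Timestamp(self.drought_end))
        if not (run[0] <= win[0] <= win[1] <= run[1]):
            raise ValueError("drought window must lie inside the run window")


def index_trajectory(spec: ScenarioSpec) -> pd.Series:
    """The prescribed daily drought-index trajectory (trapezoid ramp)."""
    days = pd.date_range(spec.start, spec.end, freq="D", inclusive="left")
    d0, d1 = pd.Timestamp(spec.drought_start), pd.Timestamp(spec.drought_end)
    f = np.ones(len(days))
    for i, day in enumerate(days):
        if d0 <= day < d1:
            into = (day - d0).days
            until = (d1 - day).days
            ramp = min(into / spec.ramp_days, until / spec.ramp_days, 1.0)
            f[i] = 1.0 - (1.0 - spec.depth) * ramp
    return pd.Series(f, index=days)


def generate_met(spec: ScenarioSpec) -> pd.DataFrame:
    """Generate a half-hourly met series realizing the scenario.

    The latent heat flux is back-computed from the sample's own
    Penman-Monteith PET so that ET/PET equals the day's prescribed index
    (plus small seeded within-day scatter, capped at 1 so ET <= PET on
    sunny samples).
    """
    rng = np.random.default_rng(spec.seed)
    ts = pd.date_range(
        spec.start, spec.end, freq=f"{spec.timestep_min}min", inclusive="left"
    )
    hour = ts.hour + ts.minute / 60.0
    f_day = index_trajectory(spec).reindex(ts.normalize()).to_numpy()

    # solar-like diurnal shortwave: daylight 06-18 local, noon peak
    elev = np.sin(np.pi * (hour - 6.0) / 12.0)
    sw_in = spec.sw_max * np.clip(elev, 0.0, None)
    ppfd = 2.1 * sw_in  # umol m^-2 s^-1 per W m^-2, broadband-to-PAR rule of thumb

    # diurnal temperature peaking mid-afternoon, warmer under drought
    warm = spec.drought_warming * (1.0 - f_day)
    t_air = spec.t_mean + warm + spec.t_amp * np.cos(2 * np.pi * (hour - 15.0) / 24.0)

    r_n = 0.7 * sw_in - 30.0
    g_soil = 0.1 * r_n
    u2 = np.full(len(ts), 2.0)
    rh = 0.40 + 0.30 * f_day  # drier air as the drought deepens
    e_a = rh * saturation_vapor_pressure(t_air)

    pet = pet_penman_monteith(t_air, r_n * W_TO_MJ_DAY, g_soil * W_TO_MJ_DAY, u2, e_a)
    f_sample = np.clip(f_day * (1.0 + 0.02 * rng.standard_normal(len(ts))), 0.0, 1.0)
    et = f_sample * pet
    le = et * latent_heat_of_vaporization(t_air) / W_TO_MJ_DAY

    theta = 0.21 + (0.40 - 0.21) * f_day  # m^3 m^-3, tracking the index

    return pd.DataFrame(
        {
            "t_air": t_air,
            "sw_in": sw_in,
            "r_n": r_n,
            "g_soil": g_soil,
            "u2": u2,
            "e_a": e_a,
            "le": le,
            "ppfd": ppfd,
            "theta": theta,
        },
        index=ts,
    )


def generate_pseudo_obs(
    met: pd.DataFrame,
    index: DroughtIndex,
    cfg: EmissionConfig = EmissionConfig(),
    true_params: PDSParams = PDSParams(),
    noise_sigma: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Pseudo-observed fluxes for exercising the calibration procedure.

    ``f_mod`` is the drought-free model run; ``f_obs`` multiplies it by
    the PDS response at the day's index and by mean-one lognormal noise.
    Returns a DataFrame with columns ``f_obs``, ``f_mod`` and ``index``.
    """
    rng = np.random.default_rng(seed)
    run = run_timeseries(met, index=None, cfg=cfg, algorithm="none")
    f_mod = run["flux_mg_m2_h"].to_numpy()
    idx = index.for_day(met.index)
    noise = np.exp(
        noise_sigma * rng.standard_normal(len(f_mod)) - noise_sigma**2 / 2.0
    )
    f_obs = f_mod * np.asarray(gamma_sm_pds(idx, true_params)) * noise
    return pd.DataFrame(
        {"f_obs": f_obs, "f_mod": f_mod, "index": idx}, index=met.index
    )
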