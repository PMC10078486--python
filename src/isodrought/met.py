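"""Meteorological indicators: evapotranspiration, the f_PET drought index,
and the soil-profile water stress function.

The drought indicator used by the offline (PDS) emission path is the ratio
f_PET = ET/PET of actual to potential evapotranspiration, computed from
half-hourly (or hourly) eddy-flux tower meteorology.  ET comes from the
measured latent heat flux; PET is the Penman-Monteith reference
evapotranspiration evaluated per sample.  The ratio is retained only on
relatively sunny samples (incoming shortwave above a threshold, 500 W m^-2
by default), aggregated to a daily value, smoothed with a 7-day running
mean and min/max-normalized to [0, 1] (1 = unstressed).

The online (EDS) path is driven instead by the land-model water stress
function beta_t, a root-distribution-weighted sum of per-layer wilting
factors; that computation is provided here as well from soil matric
potential profiles.

Energy fluxes arrive in W m^-2 and are converted to MJ m^-2 day^-1
(x 0.0864) before the evapotranspiration equations so that ET and PET
share mm day^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: W m^-2 -> MJ m^-2 day^-1
W_TO_MJ_DAY = 0.0864

#: default sunny-sample filter on incoming shortwave, W m^-2
DEFAULT_SW_THRESHOLD = 500.0

#: default smoothing window for the daily index, days
DEFAULT_SMOOTHING_DAYS = 7

#: PET below this floor (mm day^-1) makes the ET/PET ratio unusable
DEFAULT_PET_FLOOR = 0.05

#: canonical internal column names for a met series
MET_COLUMNS = (
    "t_air",    # air temperature, degC
    "sw_in",    # incoming shortwave, W m^-2
    "r_n",      # net radiation, W m^-2
    "g_soil",   # soil heat flux, W m^-2
    "u2",       # wind speed at 2 m, m s^-1
    "e_a",      # actual vapor pressure, kPa
    "le",       # latent heat flux, W m^-2
    "ppfd",     # photosynthetic photon flux density, umol m^-2 s^-1
    "theta",    # volumetric soil moisture, m^3 m^-3 (optional)
)


# ---------------------------------------------------------------------------
# drought index container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DroughtIndex:
    """A daily drought index series.

    Parameters
    ----------
    values
        Daily index values with a ``DatetimeIndex`` of calendar dates.
        After normalization every value lies in [0, 1], with 1 meaning
        no water stress.  Missing days carry NaN.
    source
        Provenance tag: ``"f_pet"``, ``"beta_t"``, ``"esi"`` or
        ``"custom"``.
    raw
        The unsmoothed daily series the index was derived from, when the
        pipeline produced one (otherwise identical to ``values``).
    normalized
        Whether :func:`normalize_index` has been applied.
    """

    values: pd.Series
    source: str = "custom"
    raw: pd.Series | None = field(default=None, repr=False)
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.source not in ("f_pet", "beta_t", "esi", "custom"):
            raise ValueError(f"unknown index source {self.source!r}")
        if not isinstance(self.values.index, pd.DatetimeIndex):
            raise TypeError("DroughtIndex.values must have a DatetimeIndex")
        if self.normalized:
            finite = self.values.dropna()
            if len(finite) and ((finite < 0).any() or (finite > 1).any()):
                raise ValueError("normalized index values must lie in [0, 1]")

    def for_day(self, timestamps: pd.DatetimeIndex) -> np.ndarray:
        """Broadcast the daily index onto sub-daily timestamps by calendar day."""
        daily = self.values.copy()
        daily.index = daily.index.normalize()
        return daily.reindex(timestamps.normalize()).to_numpy()


# ---------------------------------------------------------------------------
# soil profile types (CLM-style water stress)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SoilLayer:
    """One soil layer entering the water stress function.

    Matric potentials are in mm of suction head and negative under
    tension (the usual land-model sign convention): ``psi_c < psi_o <= 0``
    with ``psi_c`` the potential at full stomatal closure and ``psi_o``
    at full opening.
    """

    psi: float            # soil matric potential, mm (negative under tension)
    theta_ice: float      # volumetric ice content, m^3 m^-3
    theta_sat: float      # saturated volumetric water content, m^3 m^-3
    root_fraction: float  # fraction of roots in this layer

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_ice <= self.theta_sat:
            raise ValueError("need 0 <= theta_ice <= theta_sat")
        if not 0.0 <= self.root_fraction <= 1.0:
            raise ValueError("root_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SoilProfile:
    """A soil column plus the PFT closure/opening potentials."""

    layers: tuple[SoilLayer, ...]
    psi_c: float  # potential at full stomatal closure, mm
    psi_o: float  # potential at full stomatal opening, mm

    def __post_init__(self) -> None:
        if self.psi_c == self.psi_o:
            raise ValueError("degenerate PFT parameters: psi_c == psi_o")
        if not self.psi_c < self.psi_o <= 0.0:
            raise ValueError("expected psi_c < psi_o <= 0 (negative under tension)")
        total = sum(l.root_fraction for l in self.layers)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"root fractions sum to {total}, expected 1")


# ---------------------------------------------------------------------------
# evapotranspiration primitives
# ---------------------------------------------------------------------------

def latent_heat_of_vaporization(t_air):
    """Latent heat of vaporization (MJ kg^-1) at air temperature ``t_air`` (degC).

    lambda = 2.501 - 0.00237 * T; strictly decreasing in temperature.
    """
    t_air = np.asarray(t_air, dtype=float)
    if not np.all(np.isfinite(t_air)):
        raise ValueError("non-finite air temperature")
    out = 2.501 - 0.00237 * t_air
    return float(out) if out.ndim == 0 else out


def et_from_le(le, t_air):
    """Evapotranspiration (mm day^-1) from latent heat flux.

    ``le`` must already be in MJ m^-2 day^-1 (multiply W m^-2 by 0.0864).
    """
    le = np.asarray(le, dtype=float)
    out = le / latent_heat_of_vaporization(t_air)
    return float(out) if out.ndim == 0 else out


def saturation_vapor_pressure(t_air):
    """Saturation vapor pressure e_s (kPa) — Tetens form, FAO-56 constants."""
    t_air = np.asarray(t_air, dtype=float)
    out = 0.6108 * np.exp(17.27 * t_air / (t_air + 237.3))
    return float(out) if out.ndim == 0 else out


def svp_slope(t_air):
    """Slope of the saturation vapor pressure curve (kPa degC^-1) at ``t_air``."""
    t_air = np.asarray(t_air, dtype=float)
    out = 4098.0 * saturation_vapor_pressure(t_air) / (t_air + 237.3) ** 2
    return float(out) if out.ndim == 0 else out


def psychrometric_constant(p_atm=101.325):
    """Psychrometric constant gamma (kPa degC^-1) at pressure ``p_atm`` (kPa)."""
    p_atm = np.asarray(p_atm, dtype=float)
    if np.any(p_atm <= 0):
        raise ValueError("p_atm must be positive")
    out = 0.000665 * p_atm
    return float(out) if out.ndim == 0 else out


def pet_penman_monteith(t_air, r_n, g_soil, u2, e_a, p_atm=101.325):
    """Penman-Monteith reference (potential) evapotranspiration, mm day^-1.

    PET = [0.408 Delta (Rn - G) + gamma (37/(T+273.15)) u2 (e_s - e_a)]
          / [Delta + gamma (1 + 0.34 u2)]

    with the sub-daily aerodynamic coefficient 37/(T+273.15).  ``r_n`` and
    ``g_soil`` are in MJ m^-2 day^-1; temperatures in degC; pressures in
    kPa.  The vapor pressure deficit is clipped at zero (a supersaturated
    sample exerts no evaporative demand) and so is the result.
    """
    t_air = np.asarray(t_air, dtype=float)
    r_n = np.asarray(r_n, dtype=float)
    g_soil = np.asarray(g_soil, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    e_a = np.asarray(e_a, dtype=float)

    delta = svp_slope(t_air)
    gam = psychrometric_constant(p_atm)
    vpd = np.clip(saturation_vapor_pressure(t_air) - e_a, 0.0, None)
    num = 0.408 * delta * (r_n - g_soil) + gam * (37.0 / (t_air + 273.15)) * u2 * vpd
    den = delta + gam * (1.0 + 0.34 * u2)
    out = np.clip(num / den, 0.0, None)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# the f_PET pipeline
# ---------------------------------------------------------------------------

def fpet_daily(
    met: pd.DataFrame,
    sw_threshold: float = DEFAULT_SW_THRESHOLD,
    smoothing_days: int = DEFAULT_SMOOTHING_DAYS,
    pet_floor: float = DEFAULT_PET_FLOOR,
    p_atm: float = 101.325,
) -> DroughtIndex:
    """Daily (unnormalized) f_PET = ET/PET drought indicator from met data.

    Parameters
    ----------
    met
        Met series with a ``DatetimeIndex`` and the columns of
        ``MET_COLUMNS`` (``theta`` optional).  Missing values are NaN.
    sw_threshold
        Only samples with incoming shortwave above this (W m^-2) enter the
        ratio — the "relatively sunny" filter.
    smoothing_days
        Window of the centered running mean applied to the daily series
        (shrinking at the edges).
    pet_floor
        Samples whose PET falls below this (mm day^-1) are treated as
        missing; the ratio is unstable there.

    Returns
    -------
    DroughtIndex
        ``raw`` holds the unsmoothed daily means, ``values`` the smoothed
        series.  Days with no retained sunny sample are NaN in ``raw``;
        the running mean bridges them where neighbors exist.

    Notes
    -----
    Per-sample ratios are computed only where the shortwave filter passes;
    within each day the filtered/missing samples are implicitly filled
    with the mean of that day's retained ratios, so the daily value is the
    mean over retained samples.
    """
    if not isinstance(met.index, pd.DatetimeIndex):
        raise TypeError("met must have a DatetimeIndex")
    n_days = met.index.normalize().nunique()
    if n_days < smoothing_days:
        raise ValueError(
            f"series covers {n_days} days, need at least {smoothing_days}"
        )

    et = et_from_le(met["le"].to_numpy() * W_TO_MJ_DAY, met["t_air"].to_numpy())
    pet = pet_penman_monteith(
        met["t_air"].to_numpy(),
        met["r_n"].to_numpy() * W_TO_MJ_DAY,
        met["g_soil"].to_numpy() * W_TO_MJ_DAY,
        met["u2"].to_numpy(),
        met["e_a"].to_numpy(),
        p_atm=p_atm,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(pet >= pet_floor, et / pet, np.nan)
    sunny = met["sw_in"].to_numpy() > sw_threshold
    f = np.where(sunny, f, np.nan)

    if not np.any(np.isfinite(f)):
        raise ValueError("no sunny retained samples in the whole series")

    daily = pd.Series(f, index=met.index).groupby(met.index.normalize()).mean()
    smoothed = daily.rolling(smoothing_days, center=True, min_periods=1).mean()
    return DroughtIndex(values=smoothed, source="f_pet", raw=daily)


def normalize_index(
    index: DroughtIndex, lo: float, hi: float, clip: bool = True
) -> DroughtIndex:
    """Min/max-normalize a drought index to [0, 1].

    ``value <- (raw - lo) / (hi - lo)``, clipped to [0, 1] unless
    ``clip=False`` (some downstream response curves tolerate indices
    slightly above 1).  Idempotent with ``lo=0, hi=1`` on an
    already-normalized series.
    """
    if hi <= lo:
        raise ValueError(f"invalid bounds: hi={hi} must exceed lo={lo}")
    scaled = (index.values - lo) / (hi - lo)
    if clip:
        scaled = scaled.clip(0.0, 1.0)
    return replace(index, values=scaled, normalized=clip)


def reference_percentile_bound(history: pd.Series | DroughtIndex, q: float = 95.0) -> float:
    """Upper normalization bound from a reference history of smoothed index values.

    Returns the ``q``-th percentile (linear interpolation between order
    statistics) of the unnormalized smoothed series — e.g. the 95th
    percentile of a multi-year f_PET record serves as the ``hi`` bound of
    :func:`normalize_index`.
    """
    values = history.values if isinstance(history, DroughtIndex) else history
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no reference data: history is empty")
    if not 0.0 < q < 100.0:
        raise ValueError("percentile q must be in (0, 100)")
    return float(np.percentile(values, q))


# ---------------------------------------------------------------------------
# CLM-style water stress function
# ---------------------------------------------------------------------------

def wilting_factor(layer: SoilLayer, psi_c: float, psi_o: float) -> float:
    """Per-layer wilting factor in [0, 1].

    w = [(psi_c - psi) / (psi_c - psi_o)] * [(theta_sat - theta_ice) / theta_sat]

    1 when the layer is at the stomata-open potential with no ice, 0 at the
    closure potential or when the layer is fully frozen.
    """
    if psi_c == psi_o:
        raise ValueError("degenerate PFT parameters: psi_c == psi_o")
    w = (psi_c - layer.psi) / (psi_c - psi_o)
    w *= (layer.theta_sat - layer.theta_ice) / layer.theta_sat
    return float(np.clip(w, 0.0, 1.0))


def beta_t(profile: SoilProfile) -> float:
    """Root-weighted water stress function beta_t = sum_i w_i r_i, in [0, 1]."""
    total = sum(
        wilting_factor(layer, profile.psi_c, profile.psi_o) * layer.root_fraction
        for layer in profile.layers
    )
    return float(np.clip(total, 0.0, 1.0))
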