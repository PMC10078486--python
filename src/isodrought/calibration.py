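"""Calibration of the PDS drought response from paired flux observations.

The drought activity factor can be observed at canopy scale as the ratio
of the measured isoprene flux to a drought-free model run:

    gamma_sm_obs = F_obs / F_mod

Ratios are formed only where the drought-free modeled flux exceeds a
floor (nights and dawn make the ratio unstable), grouped into bins of the
normalized drought index (0.05 wide by default), averaged per bin, and
normalized by the mean of the bin nearest index = 1 so that the
no-drought bin is exactly 1.  The five PDS curve parameters are then
fitted to the normalized bin means by nonlinear least squares.

The parameterization is not fully identifiable — (b1, a1) and (b2, a2)
trade off against the fixed offsets in the logistic arguments — so fit
quality is judged on the fitted curve, not on raw parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from isodrought.gamma import PDSParams, gamma_sm_pds

#: default floor on the drought-free modeled flux for ratio formation,
#: mg m^-2 h^-1
DEFAULT_FMOD_FLOOR = 0.5


@dataclass
class CalibrationResult:
    """Binned observed activity ratios and (after fitting) the PDS curve.

    ``bin_mean`` is normalized so the bin nearest index = 1 equals 1
    exactly; empty bins are absent from the arrays.  ``bin_mean_index``
    is the mean observed index of each bin's samples — the abscissa used
    for fitting, which avoids the bias of attributing a bin's mean ratio
    to its geometric center.  After :func:`fit_pds`, ``params`` holds the
    fitted :class:`PDSParams`, ``param_ci`` the per-parameter 95%
    confidence half-widths, and ``curve_index``/``curve_gamma`` a dense
    evaluation of the fitted curve for plotting.
    """

    bin_centers: np.ndarray
    bin_mean_index: np.ndarray
    bin_mean: np.ndarray
    bin_lower_quartile: np.ndarray
    bin_upper_quartile: np.ndarray
    bin_count: np.ndarray
    normalization: float
    params: PDSParams | None = None
    param_ci: dict[str, float] | None = None
    curve_index: np.ndarray | None = field(default=None, repr=False)
    curve_gamma: np.ndarray | None = field(default=None, repr=False)
    rmse: float | None = None
    converged: bool | None = None
    message: str = ""


def gamma_sm_obs(
    pairs: pd.DataFrame, fmod_floor: float = DEFAULT_FMOD_FLOOR
) -> pd.DataFrame:
    """Observed drought activity ratios F_obs / F_mod.

    ``pairs`` needs columns ``f_obs``, ``f_mod`` and ``index`` (the
    normalized drought index of each sample's day).  Samples with
    ``f_mod`` at or below ``fmod_floor`` are dropped, never divided.

    Returns a DataFrame with columns ``index`` and ``ratio`` on the
    retained samples.
    """
    keep = pairs["f_mod"] > fmod_floor
    keep &= np.isfinite(pairs["f_obs"]) & np.isfinite(pairs["index"])
    if not keep.any():
        raise ValueError("no usable pairs: all modeled fluxes at or below the floor")
    out = pd.DataFrame(
        {
            "index": pairs.loc[keep, "index"],
            "ratio": pairs.loc[keep, "f_obs"] / pairs.loc[keep, "f_mod"],
        }
    )
    return out


def bin_and_normalize(
    ratios: pd.DataFrame, bin_width: float = 0.05
) -> CalibrationResult:
    """Bin observed ratios by drought index and normalize to the no-drought bin.

    Bins tile [0, 1] with the given width; per-bin means and quartiles are
    computed, empty bins dropped, and every bin mean divided by the mean
    of the highest-index retained bin (nearest "no drought") so that bin
    equals 1 exactly.
    """
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2
    which = np.clip(
        np.digitize(ratios["index"].to_numpy(), edges) - 1, 0, len(centers) - 1
    )
    grouped = pd.DataFrame(
        {
            "bin": which,
            "ratio": ratios["ratio"].to_numpy(),
            "index": ratios["index"].to_numpy(),
        }
    ).groupby("bin")
    stats = grouped["ratio"].agg(
        mean="mean",
        lower=lambda s: s.quantile(0.25),
        upper=lambda s: s.quantile(0.75),
        count="count",
    )
    stats["mean_index"] = grouped["index"].mean()
    if len(stats) < 2:
        raise ValueError("insufficient index spread: fewer than 2 non-empty bins")

    norm = float(stats["mean"].iloc[-1])  # highest-index retained bin
    return CalibrationResult(
        bin_centers=centers[stats.index.to_numpy()],
        bin_mean_index=stats["mean_index"].to_numpy(),
        bin_mean=stats["mean"].to_numpy() / norm,
        bin_lower_quartile=stats["lower"].to_numpy() / norm,
        bin_upper_quartile=stats["upper"].to_numpy() / norm,
        bin_count=stats["count"].to_numpy(),
        normalization=norm,
    )


def _pds_params(a1, a2, b1, log10_b2, gamma_max) -> PDSParams:
    return PDSParams(a1=a1, a2=a2, b1=b1, b2=10.0**log10_b2, gamma_sm_max=gamma_max)


def fit_pds(
    binned: CalibrationResult,
    init: PDSParams = PDSParams(),
    weighted: bool = False,
) -> CalibrationResult:
    """Fit the five PDS curve parameters to normalized bin means.

    The model prediction is normalized at the reference (no-drought) bin
    exactly as the data is — the fit compares
    ``gamma(x; p) / gamma(x_ref; p)`` with the normalized bin means — so
    the first-bin normalization introduces no scale bias into the
    recovered curve.  Unweighted nonlinear least squares by default;
    ``weighted=True`` weights each bin by the inverse of its
    interquartile range.  b2 spans many orders of magnitude and is fitted
    on a log10 scale for conditioning.  95% confidence half-widths come
    from the estimated parameter covariance (first-order).
    Non-convergence is reported in ``converged``/``message``, never
    silent.
    """
    if len(binned.bin_centers) < 5:
        raise ValueError("need at least 5 non-empty bins to fit 5 parameters")

    x = binned.bin_mean_index
    y = binned.bin_mean
    x_ref = float(x[-1])

    def _model(x, a1, a2, b1, log10_b2, gamma_max):
        p = _pds_params(a1, a2, b1, log10_b2, gamma_max)
        return gamma_sm_pds(x, p) / gamma_sm_pds(x_ref, p)

    sigma = None
    if weighted:
        iqr = binned.bin_upper_quartile - binned.bin_lower_quartile
        sigma = np.clip(iqr, np.max(iqr) * 1e-3 + 1e-12, None)

    p0 = [init.a1, init.a2, init.b1, np.log10(init.b2), init.gamma_sm_max]
    bounds = ([-60.0, -60.0, 1e-6, 0.0, 1.0], [0.0, 0.0, 1e3, 12.0, 3.0])
    p0 = np.clip(p0, bounds[0], bounds[1])

    try:
        popt, pcov = curve_fit(
            _model, x, y, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
        )
        converged = True
        message = "fit converged"
    except RuntimeError as exc:  # scipy raises on exhausted iterations
        binned.converged = False
        binned.message = f"fit did not converge: {exc}"
        return binned

    params = PDSParams(
        a1=popt[0], a2=popt[1], b1=popt[2], b2=10.0 ** popt[3], gamma_sm_max=popt[4]
    )
    stderr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    ci = dict(zip(("a1", "a2", "b1", "log10_b2", "gamma_sm_max"), 1.96 * stderr))

    grid = np.linspace(0.0, 1.0, 501)
    binned.params = params
    binned.param_ci = ci
    binned.curve_index = grid
    binned.curve_gamma = np.asarray(gamma_sm_pds(grid, params))
    binned.rmse = float(np.sqrt(np.mean((_model(x, *popt) - y) ** 2)))
    binned.converged = converged
    binned.message = message
    return binned


def fit_metrics(obs, mod) -> dict[str, float]:
    """Model evaluation statistics: mean bias, mean error, RMSE and R^2.

    MB = mean(mod - obs); ME = mean(|mod - obs|);
    RMSE = sqrt(mean((mod - obs)^2)); R^2 = squared Pearson correlation
    (NaN when either series is constant).
    """
    obs = np.asarray(obs, dtype=float)
    mod = np.asarray(mod, dtype=float)
    if obs.shape != mod.shape:
        raise ValueError("obs and mod must be aligned and equal length")
    if obs.size < 2:
        raise ValueError("insufficient data: need at least 2 samples")
    diff = mod - obs
    if np.std(obs) == 0 or np.std(mod) == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(obs, mod)[0, 1] ** 2)
    return {
        "MB": float(np.mean(diff)),
        "ME": float(np.mean(np.abs(diff))),
        "RMSE": float(np.sqrt(np.mean(diff**2))),
        "R2": r2,
    }


def daytime_running_mean(
    flux: pd.Series, daytime: pd.Series | None = None, window: int = 9
) -> pd.Series:
    """Centered running mean of hourly flux over daytime samples only.

    Night samples are removed before averaging and never appear in the
    output; the window is applied within each calendar day's daytime
    block (shrinking at block edges), matching the common presentation of
    daytime flux time series as a 9-hour running average.

    ``daytime`` is a boolean mask aligned with ``flux``; by default all
    samples are treated as daytime.
    """
    if daytime is not None:
        flux = flux[daytime.to_numpy()]
    day = flux.index.normalize()
    return flux.groupby(day).transform(
        lambda block: block.rolling(window, center=True, min_periods=1).mean()
    )
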