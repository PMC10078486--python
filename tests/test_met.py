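"""Evapotranspiration primitives, the f_PET pipeline, and the water stress
function."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isodrought import (
    DroughtIndex,
    SoilLayer,
    SoilProfile,
    beta_t,
    et_from_le,
    fpet_daily,
    latent_heat_of_vaporization,
    normalize_index,
    pet_penman_monteith,
    psychrometric_constant,
    reference_percentile_bound,
    saturation_vapor_pressure,
    svp_slope,
    wilting_factor,
)
from isodrought.met import W_TO_MJ_DAY


class TestLatentHeat:
    @pytest.mark.parametrize(
        "t_air, expected",
        [(0.0, 2.501), (20.0, 2.4536), (-10.0, 2.5247)],
    )
    def test_values(self, t_air, expected):
        assert latent_heat_of_vaporization(t_air) == pytest.approx(expected)

    def test_strictly_decreasing(self):
        t = np.linspace(-40, 50, 200)
        lam = latent_heat_of_vaporization(t)
        assert np.all(np.diff(lam) < 0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            latent_heat_of_vaporization(float("nan"))


class TestEtFromLe:
    @pytest.mark.parametrize(
        "le, t_air, expected",
        [(2.501, 0.0, 1.0), (0.0, 20.0, 0.0), (12.268, 20.0, 5.0)],
    )
    def test_values(self, le, t_air, expected):
        assert et_from_le(le, t_air) == pytest.approx(expected, rel=1e-4)

    @given(
        le=st.floats(-30, 30),
        t_air=st.floats(-30, 45),
        c=st.floats(0.1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_in_le_at_fixed_temperature(self, le, t_air, c):
        assert et_from_le(c * le, t_air) == pytest.approx(
            c * et_from_le(le, t_air), rel=1e-12, abs=1e-12
        )


class TestVaporPressure:
    def test_tetens_at_20(self):
        assert saturation_vapor_pressure(20.0) == pytest.approx(2.3383, abs=1e-3)

    def test_slope_at_20(self):
        assert svp_slope(20.0) == pytest.approx(0.14474, abs=1e-4)

    def test_slope_matches_finite_difference(self):
        # the conventional 4098 numerator rounds the exact 17.27 * 237.3,
        # so agreement with the true derivative is ~4e-5 relative
        t = np.linspace(-10, 45, 56)
        h = 1e-5
        fd = (saturation_vapor_pressure(t + h) - saturation_vapor_pressure(t - h)) / (2 * h)
        assert np.allclose(svp_slope(t), fd, rtol=1e-4)

    def test_psychrometric_constant(self):
        assert psychrometric_constant(101.325) == pytest.approx(0.0674, abs=1e-4)
        with pytest.raises(ValueError):
            psychrometric_constant(-1.0)

    def test_es_strictly_increasing(self):
        t = np.linspace(-30, 50, 300)
        assert np.all(np.diff(saturation_vapor_pressure(t)) > 0)


class TestPenmanMonteith:
    def test_zero_when_no_energy_and_no_deficit(self):
        e_s = saturation_vapor_pressure(25.0)
        assert pet_penman_monteith(25.0, 1.0, 1.0, 2.0, e_s) == 0.0

    def test_windless_radiative_case(self):
        # 0.408 * Delta * (Rn - G) / (Delta + gamma) with the wind terms zeroed
        assert pet_penman_monteith(25.0, 2.0, 0.0, 0.0, 1.8) == pytest.approx(
            0.6013, abs=1e-3
        )

    def test_hourly_reference_case(self):
        # frozen from an independent transcription of the FAO-56-style form
        assert pet_penman_monteith(25.0, 2.0, 0.0, 2.0, 1.8) == pytest.approx(
            0.58579, abs=1e-4
        )

    def test_increasing_in_available_energy(self):
        rn = np.linspace(0.5, 4.0, 30)
        pet = pet_penman_monteith(25.0, rn, 0.0, 2.0, 1.8)
        assert np.all(np.diff(pet) > 0)

    def test_supersaturation_clipped(self):
        # e_a above e_s must not produce negative evaporative demand
        assert pet_penman_monteith(10.0, 0.0, 0.0, 3.0, 5.0) == 0.0


def _flat_met(n_days, f_by_day, sw=800.0):
    """Met frame with constant conditions whose ET/PET is f per day."""
    ts = pd.date_range("2012-06-01", periods=n_days * 48, freq="30min")
    t_air = np.full(len(ts), 25.0)
    e_a = np.full(len(ts), 1.8)
    pet = pet_penman_monteith(25.0, 2.0 / W_TO_MJ_DAY * W_TO_MJ_DAY, 0.0, 2.0, 1.8)
    f = np.repeat(np.asarray(f_by_day, dtype=float), 48)
    le = f * pet * latent_heat_of_vaporization(25.0) / W_TO_MJ_DAY
    return pd.DataFrame(
        {
            "t_air": t_air,
            "sw_in": np.full(len(ts), sw),
            "r_n": np.full(len(ts), 2.0 / W_TO_MJ_DAY),
            "g_soil": np.zeros(len(ts)),
            "u2": np.full(len(ts), 2.0),
            "e_a": e_a,
            "le": le,
            "ppfd": np.full(len(ts), 1500.0),
            "theta": np.full(len(ts), 0.3),
        },
        index=ts,
    )


class TestFpetDaily:
    def test_constant_ratio_gives_unit_index(self):
        met = _flat_met(10, [1.0] * 10)
        idx = fpet_daily(met)
        assert np.allclose(idx.values.to_numpy(), 1.0, atol=1e-9)

    def test_step_series_smoothing(self):
        # ET/PET steps 1.0 -> 0.5 at day 8 of 14; brute-force centered
        # 7-day running mean crosses 0.75 between days 7 and 9
        met = _flat_met(14, [1.0] * 7 + [0.5] * 7)
        idx = fpet_daily(met)
        daily = np.array([1.0] * 7 + [0.5] * 7)
        brute = np.array(
            [daily[max(0, i - 3) : i + 4].mean() for i in range(14)]
        )
        assert np.allclose(idx.values.to_numpy(), brute, atol=1e-9)
        smoothed = idx.values.to_numpy()
        assert smoothed[6] > 0.75 > smoothed[8]

    def test_overcast_day_is_missing_before_smoothing(self):
        met = _flat_met(10, [1.0] * 10)
        day3 = met.index.normalize() == pd.Timestamp("2012-06-03")
        met.loc[day3, "sw_in"] = 100.0  # below the 500 W m^-2 filter
        idx = fpet_daily(met)
        assert np.isnan(idx.raw.loc["2012-06-03"])
        # the running mean bridges the gap from neighboring days
        assert idx.values.loc["2012-06-03"] == pytest.approx(1.0)

    def test_no_sunny_data_anywhere_raises(self):
        met = _flat_met(10, [1.0] * 10, sw=100.0)
        with pytest.raises(ValueError, match="sunny"):
            fpet_daily(met)

    def test_too_short_series_raises(self):
        met = _flat_met(3, [1.0] * 3)
        with pytest.raises(ValueError, match="days"):
            fpet_daily(met)


class TestNormalizeIndex:
    def _index(self, values):
        dates = pd.date_range("2012-06-01", periods=len(values), freq="D")
        return DroughtIndex(values=pd.Series(values, index=dates), source="custom")

    @pytest.mark.parametrize(
        "raw, lo, hi, expected",
        [
            (0.82, 0.0, 0.82, 1.0),
            (-3.5, -3.5, -0.5, 0.0),
            (1.2, 0.0, 1.0, 1.0),  # clipped
            (0.41, 0.0, 0.82, 0.5),
        ],
    )
    def test_bounds(self, raw, lo, hi, expected):
        out = normalize_index(self._index([raw]), lo, hi)
        assert out.values.iloc[0] == pytest.approx(expected)

    def test_invalid_bounds_raise(self):
        with pytest.raises(ValueError, match="bounds"):
            normalize_index(self._index([0.5]), 1.0, 0.0)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_bounded(self, values):
        once = normalize_index(self._index(values), -2.0, 3.0)
        twice = normalize_index(once, 0.0, 1.0)
        assert np.all((once.values >= 0) & (once.values <= 1))
        assert np.allclose(once.values, twice.values)


class TestReferencePercentile:
    @pytest.mark.parametrize(
        "history, q, expected",
        [
            ([0.82] * 5, 95.0, 0.82),
            (np.arange(0.0, 1.0001, 0.01), 95.0, 0.95),
            ([0.2, 0.4, 0.6], 50.0, 0.4),
        ],
    )
    def test_values(self, history, q, expected):
        bound = reference_percentile_bound(pd.Series(history), q)
        assert bound == pytest.approx(expected)

    def test_empty_history_raises(self):
        with pytest.raises(ValueError, match="empty"):
            reference_percentile_bound(pd.Series([], dtype=float))


class TestWaterStress:
    def _layer(self, psi, root, theta_ice=0.0):
        return SoilLayer(psi=psi, theta_ice=theta_ice, theta_sat=0.45, root_fraction=root)

    def test_open_and_closed_extremes(self):
        psi_c, psi_o = -255000.0, -66000.0
        assert wilting_factor(self._layer(psi_o, 1.0), psi_c, psi_o) == 1.0
        assert wilting_factor(self._layer(psi_c, 1.0), psi_c, psi_o) == 0.0

    def test_two_layer_weighted_sum(self):
        psi_c, psi_o = -255000.0, -66000.0
        profile = SoilProfile(
            layers=(self._layer(psi_o, 0.25), self._layer(psi_c, 0.75)),
            psi_c=psi_c,
            psi_o=psi_o,
        )
        assert beta_t(profile) == pytest.approx(0.25)

    def test_ice_scales_wilting_factor(self):
        psi_c, psi_o = -255000.0, -66000.0
        layer = self._layer(psi_o, 1.0, theta_ice=0.225)  # half of saturation frozen
        assert wilting_factor(layer, psi_c, psi_o) == pytest.approx(0.5)

    def test_degenerate_pft_parameters_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            wilting_factor(self._layer(-1000.0, 1.0), -5000.0, -5000.0)

    def test_root_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SoilProfile(
                layers=(self._layer(-1000.0, 0.5),), psi_c=-255000.0, psi_o=-66000.0
            )

    @given(
        psis=st.lists(st.floats(-300000, -1000), min_size=2, max_size=5),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=50, deadline=None)
    def test_beta_t_is_convex_combination(self, psis, seed):
        rng = np.random.default_rng(seed)
        roots = rng.dirichlet(np.ones(len(psis)))
        psi_c, psi_o = -255000.0, -66000.0
        layers = tuple(
            SoilLayer(psi=p, theta_ice=0.0, theta_sat=0.45, root_fraction=r)
            for p, r in zip(psis, roots)
        )
        profile = SoilProfile(layers=layers, psi_c=psi_c, psi_o=psi_o)
        ws = [wilting_factor(l, psi_c, psi_o) for l in layers]
        bt = beta_t(profile)
        assert min(ws) - 1e-12 <= bt <= max(ws) + 1e-12
        assert 0.0 <= bt <= 1.0
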