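"""CASA core: APAR, stress scalars, monthly/seasonal NPP, analytic limits."""

import numpy as np
import pytest

from cropnpp import casa
from cropnpp.casa import (MeteoGrid, StressParams, actual_lue, compute_apar,
                          estimate_topt, monthly_npp, season_npp,
                          temp_stress_high, temp_stress_low, thornthwaite_pet,
                          water_stress)
from cropnpp.errors import (MissingMonthError, NegativePrecipitationError,
                            ShapeMismatchError)
from cropnpp.grids import Grid


def G(v, shape=(3, 3), **kw):
    return Grid(np.full(shape, float(v)), **kw)


class TestApar:
    def test_direct_product(self):
        apar = compute_apar(G(100.0), G(0.5))
        np.testing.assert_allclose(apar.values, 25.0)

    def test_zero_fpar_and_linearity(self):
        assert compute_apar(G(100.0), G(0.0)).values.max() == 0.0
        a1 = compute_apar(G(100.0), G(0.3)).values
        a2 = compute_apar(G(200.0), G(0.3)).values
        np.testing.assert_allclose(a2, 2 * a1)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeMismatchError):
            compute_apar(G(100.0, (2, 2)), G(0.5, (3, 3)))


class TestStressScalars:
    def test_te1_quadratic_values(self):
        assert temp_stress_low(20.0) == pytest.approx(1.0)
        assert temp_stress_low(0.0) == pytest.approx(0.8)

    def test_te1_frozen_month_rule(self):
        te1 = temp_stress_low(G(20.0), temp=G(-15.0))
        np.testing.assert_allclose(te1, 0.0)

    def test_te2_at_topt(self):
        # 1.1814 / ((1+e^-2)(1+e^-3)) by direct arithmetic
        want = 1.1814 / ((1 + np.exp(-2)) * (1 + np.exp(-3)))
        np.testing.assert_allclose(temp_stress_high(G(20.0), 20.0), want)
        assert want == pytest.approx(0.9914, abs=2e-4)

    def test_te2_cold_limit_and_brute_force(self):
        assert temp_stress_high(G(-80.0), 20.0).max() < 1e-6
        topt, t = 18.0, np.linspace(-30, 50, 161)
        got = temp_stress_high(Grid(t[None, :]), topt)[0]
        want = np.clip(1.1814 / ((1 + np.exp(0.2 * (topt - 10 - t)))
                                 * (1 + np.exp(0.3 * (-topt - 10 + t)))), 0, 1)
        np.testing.assert_allclose(got, want)

    def test_water_stress_bounds_and_monotonicity(self):
        pet = np.full((3, 3), 80.0)
        assert water_stress(G(200.0), pet) == pytest.approx(1.0)  # EET=PET
        assert water_stress(G(0.0), pet) == pytest.approx(0.5)  # EET=0
        w = [water_stress(G(p), pet)[0, 0] for p in (0, 20, 40, 60, 80, 120)]
        assert (np.diff(w) >= 0).all() and w[-1] == 1.0

    def test_water_stress_zero_pet_and_negative_precip(self):
        assert water_stress(G(10.0), np.zeros((3, 3))) == pytest.approx(1.0)
        with pytest.raises(NegativePrecipitationError):
            water_stress(G(-5.0), np.full((3, 3), 10.0))

    def test_actual_lue_multiplicative(self):
        p = StressParams(topt=20.0, epsilon_max=0.389)
        assert actual_lue(1.0, 1.0, 1.0, p) == pytest.approx(0.389)
        assert actual_lue(0.0, 1.0, 1.0, p) == 0.0
        full = actual_lue(0.9, 0.8, 1.0, p)
        half = actual_lue(0.9, 0.8, 0.5, p)
        assert half == pytest.approx(full / 2)


class TestNpp:
    def test_monthly_product(self):
        npp = monthly_npp(G(25.0), 0.389)
        np.testing.assert_allclose(npp.values, 9.725)
        assert monthly_npp(G(25.0), 0.0).values.max() == 0.0

    def test_npp_linear_in_fpar(self):
        sol = G(300.0)
        n1 = monthly_npp(compute_apar(sol, G(0.2)), 0.3).values
        n2 = monthly_npp(compute_apar(sol, G(0.4)), 0.3).values
        np.testing.assert_allclose(n2, 2 * n1)

    def test_season_sum_and_permutation(self):
        monthly = {m: G(10.0) for m in range(4, 11)}
        total = season_npp(monthly)
        np.testing.assert_allclose(total.values, 70.0)
        perm = season_npp(monthly, season=(10, 4, 7, 5, 6, 9, 8))
        np.testing.assert_allclose(perm.values, total.values)

    def test_season_strict_masking_policy(self):
        monthly = {m: G(10.0) for m in range(4, 11)}
        masked = G(10.0)
        masked.mask[0, 0] = True
        monthly[7] = masked
        strict = season_npp(monthly, policy="strict")
        assert strict.mask[0, 0] and not strict.mask[1, 1]
        partial = season_npp(monthly, policy="partial")
        assert not partial.mask[0, 0]
        assert partial.values[0, 0] == pytest.approx(60.0)

    def test_missing_month_error_names_it(self):
        with pytest.raises(MissingMonthError, match="7"):
            season_npp({m: G(1.0) for m in (4, 5, 6, 8, 9, 10)})

    def test_analytic_limit_no_stress(self, rng):
        # with all stress scalars 1: NPP = 0.5 * emax * SOL * FPAR exactly
        sol = Grid(rng.uniform(100, 600, (5, 5)))
        fpar = Grid(rng.uniform(0, 1, (5, 5)))
        apar = compute_apar(sol, fpar)
        eps = actual_lue(1.0, 1.0, 1.0, StressParams(epsilon_max=0.389))
        npp = monthly_npp(apar, eps)
        np.testing.assert_allclose(npp.values,
                                   0.5 * 0.389 * sol.values * fpar.values)


class TestTopt:
    def test_peak_month_temperature(self):
        ndvi = {6: G(0.3), 7: G(0.8), 8: G(0.5)}
        temp = {6: G(18.0), 7: G(24.0), 8: G(22.0)}
        np.testing.assert_allclose(estimate_topt(ndvi, temp).values, 24.0)

    def test_constant_series_takes_earliest(self):
        ndvi = {5: G(0.4), 6: G(0.4)}
        temp = {5: G(15.0), 6: G(20.0)}
        np.testing.assert_allclose(estimate_topt(ndvi, temp).values, 15.0)

    def test_single_month(self):
        out = estimate_topt({7: G(0.6)}, {7: G(23.0)})
        np.testing.assert_allclose(out.values, 23.0)


class TestThornthwaite:
    def test_pet_zero_below_freezing_and_positive_in_summer(self):
        temps = {m: G(v) for m, v in zip(range(1, 13),
                 [-8, -5, 2, 10, 17, 22, 25, 24, 18, 10, 2, -6])}
        pet = thornthwaite_pet(temps)
        assert pet[1].max() == 0.0
        assert pet[7].min() > 50.0  # warm-month demand is substantial
        assert pet[7].min() > pet[5].max()  # hotter month, higher demand


def test_run_casa_monotone_in_fpar(small_scene):
    truth = small_scene
    lo = {m: g.with_values(g.values * 0.5) for m, g in truth.fpar.items()}
    npp_lo = casa.run_casa(lo, truth.meteo, truth.stress_params)
    assert (npp_lo.annual.values <= truth.npp.annual.values + 1e-12).all()
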