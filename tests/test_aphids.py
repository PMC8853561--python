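"""Aphid sub-model: development, feeding, reproduction, mortality, fluxes."""

from dataclasses import replace as dreplace

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize

import elatosim as es
from elatosim.aphids import AphidParams, AphidState, aphid_odes

BENIGN = dict(lai_per_stem=30.0, conc_c=0.4, conc_n=0.06, n_stems=0.25)


@pytest.fixture(scope="module")
def p():
    return AphidParams()


def weather(t_air=14.0):
    return es.WeatherInstant(t_air, 10.0, 0.8, 1e7, 3.0, 4.0, 350.0)


def integrate_aphids(counts, t_air, p, days, h=0.05, host=BENIGN):
    """Fixed-host integration of the ten-stage system (python RK4)."""
    w = weather(t_air)

    def fun(t, y):
        da, _ = aphid_odes(AphidState(np.maximum(y, 0.0)), w,
                           host["lai_per_stem"], host["conc_c"],
                           host["conc_n"], host["n_stems"], p)
        return da

    y = np.asarray(counts, dtype=float)
    out = [y.copy()]
    t = 0.0
    for _ in range(int(days / h)):
        y = es.rk4_step(fun, t, y, h)
        t += h
        out.append(y.copy())
    return np.array(out)


class TestDevelopment:
    def test_zero_at_and_below_base(self, p):
        assert es.development_rate(p.t_base, 1, p) == 0.0
        assert es.development_rate(p.t_base - 5.0, 2, p) == 0.0

    def test_degree_day_identity_in_linear_region(self, p):
        for instar in range(1, 5):
            K = p.thermal_k[instar - 1]
            assert es.development_rate(p.t_base + 7.0, instar, p) == \
                pytest.approx(7.0 / K)

    def test_zero_above_ceiling(self, p):
        assert es.development_rate(p.t_ceil_dev + 1.0, 1, p) == 0.0

    def test_declines_between_optimum_and_ceiling(self, p):
        mid = 0.5 * (p.t_opt_dev + p.t_ceil_dev)
        assert 0 < es.development_rate(mid, 1, p) < \
            es.development_rate(p.t_opt_dev, 1, p)

    def test_invalid_instar(self, p):
        with pytest.raises(ValueError):
            es.development_rate(10.0, 5, p)

    def test_cohort_transit_time_matches_degree_day_sum(self):
        """A nymph pulse reaches the adult class with mean delay sum(K_j)/dT.

        Oracle: the mean transit time through a chain of exponential stages
        is the sum of the stage means, K_j / (T - T_base) each.
        """
        p = AphidParams(mort_base=(0.0,) * 10, c_cold=0.0, m_starv=0.0,
                        fec_max=0.0, emig_rate=0.0)
        t_air = p.t_base + 10.0
        counts = np.zeros(10)
        counts[0] = 1.0
        h = 0.05
        traj = integrate_aphids(counts, t_air, p, days=120.0, h=h)
        adults = traj[:, 4]
        arrivals = np.diff(adults)          # all flow ends in the adult bin
        t_mid = (np.arange(arrivals.size) + 0.5) * h
        mean_delay = float((t_mid * arrivals).sum() / arrivals.sum())
        expected = sum(p.thermal_k) / 10.0
        assert adults[-1] == pytest.approx(1.0, abs=1e-3)
        assert mean_delay == pytest.approx(expected, rel=0.02)


class TestIntake:
    def test_zero_substrate_zero_intake(self, p):
        assert es.per_capita_intake(0.0, 0.0, 10.0, p) == (0.0, 0.0)

    def test_crowding_asymptote(self, p):
        c0, _ = es.per_capita_intake(0.4, 0.05, 0.0, p)
        c_inf, _ = es.per_capita_intake(0.4, 0.05, 1e9, p)
        assert c_inf < 1e-6 * c0

    def test_half_at_crowding_scale(self, p):
        c0, _ = es.per_capita_intake(0.4, 0.05, 0.0, p)
        c_half, _ = es.per_capita_intake(0.4, 0.05, p.crowd_half, p)
        assert c_half == pytest.approx(0.5 * c0)

    def test_intake_ratio_follows_phloem_stoichiometry(self, p):
        c, n = es.per_capita_intake(0.4, 0.05, 10.0, p)
        assert n / c == pytest.approx(0.05 / 0.4)

    def test_negative_inputs_rejected(self, p):
        with pytest.raises(ValueError):
            es.per_capita_intake(-0.1, 0.0, 0.0, p)


class TestFecundity:
    def test_starvation_stops_reproduction(self, p):
        assert es.fecundity(0.0, p.t_opt_fec, p) == 0.0

    def test_saturates_to_maximum(self, p):
        assert es.fecundity(1e-3, p.t_opt_fec, p) == pytest.approx(
            p.fec_max, rel=1e-4)

    def test_temperature_unimodal(self, p):
        f = [es.fecundity(1e-3, t, p) for t in (p.t_min_fec - 1,
                                                p.t_opt_fec, p.t_max_fec + 1)]
        assert f[0] == 0.0 and f[2] == 0.0 and f[1] > 0


class TestAlateFraction:
    def test_uncrowded_well_fed_minimum(self, p):
        assert es.alate_fraction(0.0, 1.0, p) == pytest.approx(0.0)

    def test_crowded_asymptote(self, p):
        assert es.alate_fraction(1e12, 1.0, p) == pytest.approx(1.0, abs=1e-6)

    def test_half_at_induction_point(self, p):
        assert es.alate_fraction(p.alate_half, 1.0, p) == pytest.approx(0.5)

    @given(c=st.floats(0, 1e5), food=st.floats(0, 1))
    def test_bounds_and_monotonicity(self, c, food):
        p = AphidParams()
        phi = es.alate_fraction(c, food, p)
        assert 0.0 <= phi <= 1.0
        assert es.alate_fraction(c * 2 + 1, food, p) >= phi - 1e-12
        assert es.alate_fraction(c, food * 0.5, p) >= phi - 1e-12


class TestMortality:
    def test_baseline_only_when_warm_and_fed(self, p):
        for stage in range(1, 11):
            assert es.mortality_rate(10.0, stage, 1.0, p) == \
                pytest.approx(p.mort_base[stage - 1])

    def test_cold_term_is_quadratic(self, p):
        base = p.mort_base[0]
        m5 = es.mortality_rate(p.t_cold - 5.0, 1, 1.0, p) - base
        m10 = es.mortality_rate(p.t_cold - 10.0, 1, 1.0, p) - base
        assert m10 / m5 == pytest.approx(4.0)

    def test_sustained_deep_cold_kills_population(self, p):
        """Constant deep winter: the population collapses below 1e-6 of peak."""
        counts = np.full(10, 100.0)
        traj = integrate_aphids(counts, p.t_cold - 10.0, p, days=90.0, h=0.05)
        assert traj[-1].sum() < 1e-6 * traj[0].sum()

    def test_invalid_ratio(self, p):
        with pytest.raises(ValueError):
            es.mortality_rate(10.0, 1, 1.5, p)


class TestAphidOdes:
    def test_extinction_is_absorbing(self, p):
        da, fx = aphid_odes(AphidState(), weather(), **BENIGN, p=p)
        assert np.all(da == 0.0)
        assert fx.uptake_c == 0.0 and fx.corpse_c == 0.0

    def test_lone_starving_adult_declines_without_births(self, p):
        counts = np.zeros(10)
        counts[4] = 1.0
        da, fx = aphid_odes(AphidState(counts), weather(),
                            lai_per_stem=30.0, conc_c=0.0, conc_n=0.0,
                            n_stems=0.25, p=p)
        assert da[4] < 0.0          # starvation + baseline mortality
        assert da[0] == 0.0 and da[5] == 0.0   # no births
        assert fx.uptake_c == 0.0

    @given(st.lists(st.floats(0.0, 1e4), min_size=10, max_size=10),
           st.floats(-5.0, 30.0))
    def test_carbon_and_nitrogen_routing_close(self, counts, t_air):
        """uptake = respiration + honeydew + growth (C); uptake = excreted +
        growth (N); and the biomass derivative equals growth - corpse - emig."""
        p = AphidParams()
        a = AphidState(np.array(counts))
        da, fx = aphid_odes(a, weather(t_air), **BENIGN, p=p)
        assert fx.uptake_c == pytest.approx(
            fx.respiration_c + fx.honeydew_c + fx.growth_c, rel=1e-9, abs=1e-30)
        assert fx.uptake_n == pytest.approx(
            fx.excreted_n + fx.growth_n, rel=1e-9, abs=1e-30)
        masses = p.stage_mass_c()
        db_area = float(da @ masses) * BENIGN["n_stems"]
        assert db_area == pytest.approx(
            fx.growth_c - fx.corpse_c - fx.emigration_c, rel=1e-9, abs=1e-25)

    def test_background_immigration_rescues_empty_population(self):
        p = AphidParams(immigration=0.05)
        da, fx = aphid_odes(AphidState(), weather(), **BENIGN, p=p)
        assert da[0] == pytest.approx(0.05)       # apterous instar-1 arrivals
        assert fx.immigration_c == pytest.approx(
            0.05 * p.mass_frac[0] * p.mc_adult * BENIGN["n_stems"])

    def test_non_finite_state_rejected(self, p):
        counts = np.zeros(10)
        a = AphidState(counts)
        a.counts[0] = np.nan   # bypass constructor validation
        with pytest.raises(FloatingPointError):
            aphid_odes(a, weather(), **BENIGN, p=p)

    def test_plateau_matches_fixed_point_solve(self, p):
        """Constant benign environment: the crowding-capped plateau of the
        integrated system equals an algebraic root of the same stage ODEs."""
        counts = np.zeros(10)
        counts[4] = 1.0
        traj = integrate_aphids(counts, 14.0, p, days=2500.0, h=0.1)
        plateau = traj[-1]
        # independent route: Newton root-find on the derivative field
        w = weather(14.0)

        def f(y):
            da, _ = aphid_odes(AphidState(np.maximum(y, 0.0)), w,
                               **BENIGN, p=p)
            return da

        sol = optimize.root(f, plateau * 1.3, method="hybr", tol=1e-12)
        assert sol.success
        assert np.all(sol.x > 0)
        assert plateau.sum() == pytest.approx(sol.x.sum(), rel=1e-3)

    def test_nitrogen_poor_phloem_lowers_plateau(self, p):
        counts = np.zeros(10)
        counts[4] = 1.0
        rich = integrate_aphids(counts, 14.0, p, days=2000.0, h=0.1,
                                host=BENIGN)[-1].sum()
        poor_host = dict(BENIGN, conc_n=BENIGN["conc_n"] / 2)
        poor = integrate_aphids(counts, 14.0, p, days=2000.0, h=0.1,
                                host=poor_host)[-1].sum()
        assert poor < rich


class TestInoculate:
    def test_zero_density_is_identity(self, p):
        a = AphidState()
        assert np.all(es.inoculate(a, 0.0).counts == a.counts)

    def test_density_lands_in_apterous_adults(self):
        out = es.inoculate(AphidState(), 2.5)
        assert out.counts[4] == 2.5
        assert out.total == 2.5

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            es.inoculate(AphidState(), -1.0)


class TestManagementKill:
    def test_zero_fraction_no_kill(self, p):
        a = es.inoculate(AphidState(), 10.0)
        out, kc, kn = es.management_kill(a, 0.0, 0.25, p)
        assert kc == 0.0 and np.all(out.counts == a.counts)

    def test_full_removal_kills_all_per_area_biomass(self, p):
        a = es.inoculate(AphidState(), 10.0)
        out, kc, kn = es.management_kill(a, 1.0, 0.25, p)
        assert kc == pytest.approx(0.25 * a.biomass_c(p))
        assert kn == pytest.approx(kc * p.nc_body)

    def test_partial_removal_keeps_per_stem_state(self, p):
        a = es.inoculate(AphidState(), 10.0)
        out, kc, kn = es.management_kill(a, 0.45, 0.25, p)
        assert np.all(out.counts == a.counts)       # per-stem load unchanged
        assert kc == pytest.approx(0.45 * 0.25 * a.biomass_c(p))
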