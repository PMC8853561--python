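"""Integrator, event handling, spin-up, determinism and the mass audit."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import elatosim as es
from elatosim.engine import (
    IntegrationError, Trajectory, integrate_fixed, mass_balance_audit,
    run_rotation, spin_up,
)
from elatosim.stand import ManagementSchedule, StandParams, StandState, \
    planting_state

TOY_SCHEDULE = ManagementSchedule(thinnings=((1, 0.3),), clearfell_year=2)
AMBIENT = es.ScenarioDelta(0.0, 350.0)


def toy_cfg(**kw):
    base = dict(maxt=1.0 / 12.0, rotation_years=2, spinup_tol=1e9,
                spinup_max_rotations=3)
    base.update(kw)
    return es.SimConfig(**base)


class TestRk4:
    def test_zero_derivative_system(self):
        y = es.rk4_step(lambda t, y: np.zeros_like(y), 0.0,
                        np.array([1.0, -2.0]), 0.1)
        assert np.all(y == np.array([1.0, -2.0]))

    def test_exponential_decay_oracle(self):
        """dx/dt = -x over 1 d at h=0.02 matches exp(-1) to < 1e-8."""
        y = integrate_fixed(lambda t, y: -y, 0.0, np.array([1.0]), 0.02, 50)
        assert abs(y[0] - np.exp(-1.0)) / np.exp(-1.0) < 1e-8

    def test_config_validation(self):
        with pytest.raises(ValueError):
            es.SimConfig(maxt=0.3)            # does not divide 1 d
        with pytest.raises(ValueError):
            es.SimConfig(maxt=1 / 24, output_cadence=1 / 48)
        with pytest.raises(ValueError):
            es.SimConfig(rotation_years=0)


class TestDeterminism:
    def test_identical_configs_bitwise_identical(self):
        init = planting_state(TOY_SCHEDULE, StandParams(), StandState())
        cfg = toy_cfg(aphids_on=True)
        a = run_rotation(init, AMBIENT, cfg, schedule=TOY_SCHEDULE)
        b = run_rotation(init, AMBIENT, cfg, schedule=TOY_SCHEDULE)
        assert a.data.equals(b.data)

    def test_aphid_switch_off_equals_empty_population_run(self):
        """Switch-off (aphid code path never entered) is bit-identical to
        running the aphid machinery on a zero population."""
        init = planting_state(TOY_SCHEDULE, StandParams(), StandState())
        off = run_rotation(init, AMBIENT, toy_cfg(aphids_on=False),
                           schedule=TOY_SCHEDULE)
        empty = run_rotation(init, AMBIENT,
                             toy_cfg(aphids_on=True, inoculum=0.0),
                             schedule=TOY_SCHEDULE)
        stand_cols = [c for c in off.data.columns
                      if not c.startswith(("ap_", "al_"))
                      and c not in ("rho_aph", "aphid_biomass_c")]
        for col in stand_cols:
            assert (off.data[col].to_numpy() ==
                    empty.data[col].to_numpy()).all(), col


class TestEvents:
    def test_thinning_total_independent_of_step(self):
        init = planting_state(TOY_SCHEDULE, StandParams(), StandState())
        ends = {}
        for maxt in (1.0 / 12.0, 1.0 / 24.0):
            tr = run_rotation(init, AMBIENT, toy_cfg(maxt=maxt),
                              schedule=TOY_SCHEDULE)
            ends[maxt] = tr.data["n_stems"].iloc[-1]
        assert ends[1 / 12] == pytest.approx(ends[1 / 24], rel=1e-3)

    def test_removal_completes_in_one_day(self):
        init = planting_state(TOY_SCHEDULE, StandParams(), StandState())
        tr = run_rotation(init, AMBIENT, toy_cfg(), schedule=TOY_SCHEDULE)
        d = tr.data
        n_before = d["n_stems"].iloc[364]
        n_after = d["n_stems"].iloc[366]
        assert n_before == pytest.approx(0.25)
        assert n_after == pytest.approx(0.25 * 0.7, rel=1e-6)
        later = d["n_stems"].iloc[366:].to_numpy()
        assert np.allclose(later, later[0])


class TestExternalForcing:
    def test_tabulated_forcing_reproduces_parametric_run(self):
        """Driving the engine with a one-year forcing table generated from
        the default climate reproduces the parametric run closely (the only
        difference is linear interpolation between table rows)."""
        from elatosim.climate import generate_forcing
        table = generate_forcing(es.SeasonalDriverSpec(), steps_per_day=12)
        init = planting_state(TOY_SCHEDULE, StandParams(), StandState())
        a = run_rotation(init, AMBIENT, toy_cfg(), schedule=TOY_SCHEDULE)
        b = run_rotation(init, AMBIENT, toy_cfg(), schedule=TOY_SCHEDULE,
                         forcing=table)
        for col in ("c_fol", "c_wood", "c_le"):
            assert b.data[col].iloc[-1] == pytest.approx(
                a.data[col].iloc[-1], rel=0.05), col

    def test_scenario_delta_applies_on_top_of_table(self):
        from elatosim.climate import generate_forcing
        table = generate_forcing(es.SeasonalDriverSpec(), steps_per_day=12)
        init = planting_state(TOY_SCHEDULE, StandParams(), StandState())
        warm = run_rotation(init, es.ScenarioDelta(3.0, 700.0), toy_cfg(),
                            schedule=TOY_SCHEDULE, forcing=table)
        base = run_rotation(init, AMBIENT, toy_cfg(),
                            schedule=TOY_SCHEDULE, forcing=table)
        assert warm.data["T_air"].mean() == pytest.approx(
            base.data["T_air"].mean() + 3.0, abs=0.01)
        assert (warm.data["CO2"] == 700.0).all()

    def test_non_uniform_forcing_rejected(self):
        import pandas as pd
        bad = pd.DataFrame({
            "time": [0.0, 0.5, 2.0], "T_air": 10.0, "T_soil": 8.0,
            "RH": 0.8, "PAR": 0.0, "wind": 3.0, "rain": 4.0, "CO2": 350.0})
        init = planting_state(TOY_SCHEDULE, StandParams(), StandState())
        with pytest.raises(ValueError):
            run_rotation(init, AMBIENT, toy_cfg(), schedule=TOY_SCHEDULE,
                         forcing=bad)


class TestSpinUp:
    def test_degenerate_tolerance_returns_after_first_rotation(self):
        state, n_rot = spin_up(AMBIENT, toy_cfg(spinup_tol=1e12),
                               schedule=TOY_SCHEDULE)
        assert n_rot == 1
        assert state.n_stems == TOY_SCHEDULE.planting_density

    def test_already_converged_input_verifies_in_one_rotation(self):
        cfg = toy_cfg(spinup_tol=0.1, spinup_max_rotations=40)
        state, _ = spin_up(AMBIENT, cfg, schedule=TOY_SCHEDULE)
        again, n_rot = spin_up(AMBIENT, cfg, schedule=TOY_SCHEDULE,
                               initial=state)
        assert n_rot == 1

    def test_non_convergence_raises(self):
        with pytest.raises(IntegrationError):
            spin_up(AMBIENT, toy_cfg(spinup_tol=1e-16, spinup_max_rotations=2),
                    schedule=TOY_SCHEDULE)


class TestImmigration:
    def test_background_influx_establishes_population_and_closes_budget(self):
        from elatosim.aphids import AphidParams
        from elatosim.engine import mass_balance_audit as audit
        ap = AphidParams(immigration=0.05)
        init = planting_state(TOY_SCHEDULE, StandParams(), StandState())
        tr = run_rotation(init, AMBIENT, toy_cfg(aphids_on=True, inoculum=0.0),
                          schedule=TOY_SCHEDULE, aphid_p=ap)
        assert tr.data["rho_aph"].iloc[-1] > 0.0
        c_err, n_err = audit(tr)
        assert c_err < 1e-9 and n_err < 1e-9


class TestFailureModes:
    def test_stiff_blowup_reports_integration_failure(self):
        # a pathological turnover rate makes RK4 unstable -> material
        # negativity must be reported, not silently clamped
        bad = StandParams(s_fol=1.0e3)
        init = planting_state(TOY_SCHEDULE, bad, StandState())
        with pytest.raises(IntegrationError):
            run_rotation(init, AMBIENT, toy_cfg(), stand_p=bad,
                         schedule=TOY_SCHEDULE)


class TestMassBalanceAudit:
    def test_closed_toy_trajectory_audits_to_zero(self):
        n = 50
        data = pd.DataFrame({
            "time": np.arange(n, dtype=float),
            "total_c": np.full(n, 12.5),
            "total_n": np.full(n, 0.7),
            "cum_photosynthesis": 0.0, "cum_plant_resp": 0.0,
            "cum_soil_resp": 0.0, "cum_aphid_resp": 0.0,
            "cum_harvest_c": 0.0, "cum_harvest_n": 0.0,
            "cum_emigration_c": 0.0, "cum_emigration_n": 0.0,
            "cum_n_deposition": 0.0, "cum_n_leaching": 0.0,
        })
        tr = Trajectory(data=data, scenario=AMBIENT, config=toy_cfg())
        c_err, n_err = mass_balance_audit(tr)
        assert c_err == 0.0 and n_err == 0.0

    def test_audit_detects_corrupted_flux_routing(self):
        init = planting_state(TOY_SCHEDULE, StandParams(), StandState())
        tr = run_rotation(init, AMBIENT, toy_cfg(aphids_on=True),
                          schedule=TOY_SCHEDULE)
        c0, _ = mass_balance_audit(tr)
        assert c0 < 1e-9
        broken = tr.data.copy()
        broken["cum_soil_resp"] = broken["cum_soil_resp"] + \
            np.linspace(0.0, 0.5, len(broken))
        tr_bad = Trajectory(data=broken, scenario=AMBIENT, config=tr.config)
        c1, _ = mass_balance_audit(tr_bad)
        assert c1 > 1e-6

    def test_trajectory_time_axis(self):
        init = planting_state(TOY_SCHEDULE, StandParams(), StandState())
        tr = run_rotation(init, AMBIENT, toy_cfg(), schedule=TOY_SCHEDULE)
        t = tr.time
        assert np.all(np.diff(t) > 0)
        assert t[0] == 0.0 and t[-1] == pytest.approx(2 * 365.0)
        assert np.isfinite(tr.data.to_numpy(dtype=float)).all()
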