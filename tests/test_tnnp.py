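"""Myocyte ionic model: current assembly, integration, HF remodeling."""

import dataclasses

import numpy as np
import pytest

from cardiomef.tnnp import (CellParams, CellState, HfModifiers, StimulusSpec,
                            compute_ionic_currents, euler_step, apply_hf,
                            equilibrate, run_paced_cell, InvalidStateError,
                            ParameterError, CURRENT_NAMES)
from cardiomef.sac import SacParams
from conftest import apd_at_threshold


def zero_conductance_params():
    zeros = {n: 0.0 for n in ("g_na", "g_k1", "g_to", "g_kr", "g_ks", "g_pk",
                              "g_cal", "k_naca", "p_nak", "g_pca", "g_bna",
                              "g_bca")}
    return CellParams(**zeros)


class TestCurrentAssembly:
    def test_all_conductances_off_gives_zero_total(self):
        cur = compute_ionic_currents(CellState(), zero_conductance_params(), i_sac=0.0)
        assert cur["I_ion"] == 0.0
        for name in CURRENT_NAMES:
            assert cur[name] == 0.0

    def test_component_sum_equals_total_for_random_states(self, cell_params):
        rng = np.random.default_rng(42)
        for _ in range(100):
            st = CellState(
                vm=float(rng.uniform(-95, 45)),
                m=float(rng.uniform(0, 1)), h=float(rng.uniform(0, 1)),
                j=float(rng.uniform(0, 1)), xr1=float(rng.uniform(0, 1)),
                xr2=float(rng.uniform(0, 1)), xs=float(rng.uniform(0, 1)),
                r=float(rng.uniform(0, 1)), s=float(rng.uniform(0, 1)),
                d=float(rng.uniform(0, 1)), f=float(rng.uniform(0, 1)),
                fca=float(rng.uniform(0, 1)), g=float(rng.uniform(0, 1)),
                nai=float(rng.uniform(5, 20)), ki=float(rng.uniform(120, 150)),
                cai=float(rng.uniform(1e-5, 1e-3)),
                casr=float(rng.uniform(0.1, 5.0)))
            isac = float(rng.uniform(-2, 2))
            cur = compute_ionic_currents(st, cell_params, i_sac=isac)
            total = sum(cur[name] for name in CURRENT_NAMES)
            assert cur["I_ion"] == pytest.approx(total, abs=1e-12)

    def test_total_current_vanishes_at_converged_rest(self, cell_params, rest_state):
        cur = compute_ionic_currents(rest_state, cell_params)
        assert abs(cur["I_ion"]) < 0.01

    def test_nonfinite_state_names_offending_variable(self, cell_params):
        st = CellState(cai=float("nan"))
        with pytest.raises(InvalidStateError, match="Cai"):
            compute_ionic_currents(st, cell_params)


class TestEulerStep:
    def test_pure_stimulus_advances_voltage_by_hand_arithmetic(self):
        # Iion forced to 0 via zero conductances: dVm = +Istim*dt = 52*0.02
        st = CellState()
        out = euler_step(st, zero_conductance_params(), istim=52.0, dt=0.02)
        assert out.vm - st.vm == pytest.approx(1.04, abs=1e-12)

    def test_rest_is_a_fixed_point(self, cell_params, rest_state):
        out = euler_step(rest_state, cell_params, istim=0.0, dt=0.02)
        assert abs(out.vm - rest_state.vm) < 1e-4

    def test_rest_drift_rate_below_threshold(self, cell_params, rest_state):
        out = euler_step(rest_state, cell_params, dt=0.02)
        assert abs(out.vm - rest_state.vm) / 0.02 < 1e-3  # mV/ms

    def test_nonpositive_dt_rejected(self, cell_params, rest_state):
        with pytest.raises(ParameterError):
            euler_step(rest_state, cell_params, dt=0.0)

    def test_time_advances(self, cell_params, rest_state):
        out = euler_step(rest_state, cell_params, dt=0.02)
        assert out.t == pytest.approx(rest_state.t + 0.02)


class TestRestingStability:
    def test_unstimulated_cell_stays_at_rest_for_5s(self, cell_params, rest_state):
        later = equilibrate(cell_params, None, 1.0, duration=5000.0,
                            initial_state=rest_state)
        assert abs(later.vm - rest_state.vm) < 0.1

    def test_resting_potential_in_published_range(self, rest_state):
        assert -88.0 < rest_state.vm < -85.0


class TestPacedRuns:
    def test_ap_morphology_matches_published_m_cell(self, control_ap):
        vm = control_ap.vm
        assert 25.0 < vm.max() < 45.0       # overshoot
        rest, peak = vm[0], vm.max()
        v90 = peak - 0.9 * (peak - rest)
        idx = np.where(vm > v90)[0]
        apd90 = control_ap.t[idx[-1]] - control_ap.t[idx[0]]
        assert 320.0 < apd90 < 350.0        # M-cell APD90 class (~336 ms)

    def test_gate_bounds_and_positive_concentrations_over_10s_pacing(
            self, cell_params, rest_state):
        st = rest_state
        stim = StimulusSpec(period=1000.0)
        for _ in range(10):
            tr = run_paced_cell(cell_params, stim, duration=1000.0,
                                initial_state=st, record_stride=1.0)
            st = tr.final_state
            for g in ("m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f",
                      "fca", "g"):
                assert 0.0 <= getattr(st, g) <= 1.0
            for c in ("nai", "ki", "cai", "casr"):
                assert getattr(st, c) > 0.0

    def test_dt_halving_changes_apd_by_less_than_1ms(self, cell_params, rest_state):
        apds = []
        for dt in (0.02, 0.01, 0.005):
            tr = run_paced_cell(cell_params, StimulusSpec(), duration=600.0,
                                dt=dt, initial_state=rest_state,
                                record_stride=0.1)
            apds.append(apd_at_threshold(tr.t, tr.vm))
        assert abs(apds[1] - apds[0]) < 1.0
        assert abs(apds[2] - apds[1]) < 1.0
        # monotone approach to the fine-step limit
        assert (apds[1] - apds[0]) * (apds[2] - apds[1]) >= 0.0

    def test_sac_disabled_recovers_unmodified_model(self, cell_params, rest_state):
        base = run_paced_cell(cell_params, StimulusSpec(), sac_config=None,
                              duration=500.0, initial_state=rest_state)
        off = run_paced_cell(cell_params, StimulusSpec(),
                             sac_config=SacParams.disabled(), lam=1.3,
                             duration=500.0, initial_state=rest_state)
        assert np.max(np.abs(base.vm - off.vm)) < 1e-12

    def test_traces_share_time_grid_across_stretch(self, cell_params, rest_state):
        sac = SacParams()
        t_grids = []
        for lam in (1.0, 1.2):
            tr = run_paced_cell(cell_params, StimulusSpec(), sac_config=sac,
                                lam=lam, duration=300.0,
                                initial_state=rest_state)
            t_grids.append(tr.t)
        np.testing.assert_array_equal(t_grids[0], t_grids[1])


class TestHeartFailure:
    def test_identity_modifiers_leave_params_bit_identical(self, cell_params):
        assert apply_hf(cell_params, HfModifiers()) == cell_params

    def test_exactly_six_currents_are_remodeled(self, cell_params):
        mods = HfModifiers(f_ito=0.25, f_iks=0.2, f_ik1=0.4, f_ina=0.6,
                           f_ical=0.88, f_inaca=1.65)
        hf = apply_hf(cell_params, mods)
        changed = {f.name for f in dataclasses.fields(CellParams)
                   if getattr(hf, f.name) != getattr(cell_params, f.name)}
        assert changed == {"g_to", "g_ks", "g_k1", "g_na", "g_cal", "k_naca"}
        assert hf.g_to == pytest.approx(cell_params.g_to * 0.25)
        assert hf.k_naca == pytest.approx(cell_params.k_naca * 1.65)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ParameterError):
            HfModifiers(f_ik1=0.0)
        with pytest.raises(ParameterError):
            HfModifiers(f_ina=-0.5)

    def test_hf_prolongs_1hz_action_potential(self, cell_params):
        from cardiomef.config import default_hf_modifiers
        hf_params = apply_hf(cell_params, default_hf_modifiers())
        apds = {}
        for name, p in (("control", cell_params), ("hf", hf_params)):
            rest = equilibrate(p, duration=4000.0)
            tr = run_paced_cell(p, StimulusSpec(period=1000.0), duration=6000.0,
                                initial_state=rest, record_stride=0.1)
            k0 = int(5000.0 / 0.1)
            apds[name] = apd_at_threshold(tr.t[k0:], tr.vm[k0:])
        assert apds["hf"] > apds["control"]
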