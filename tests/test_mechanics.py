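import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pleurasim import mechanics as M
from pleurasim.patient_model import build_patient
from pleurasim.units import KPA_PER_CMH2O


class TestHydrostatics:
    def test_zero_depth_returns_apex_pressure(self):
        assert M.hydrostatic_ppl(-0.5, 0.0, 1.0) == pytest.approx(-0.5)

    def test_ten_cm_of_water_column(self):
        # -0.5 + 10 * 0.0981 kPa
        assert M.hydrostatic_ppl(-0.5, 10.0, 1.0) == pytest.approx(0.4807, abs=5e-4)

    @given(st.floats(0.1, 30.0))
    def test_linear_in_depth(self, d):
        one = M.hydrostatic_ppl(0.0, d, 1.0)
        two = M.hydrostatic_ppl(0.0, 2 * d, 1.0)
        assert two == pytest.approx(2 * one)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            M.hydrostatic_ppl(0.0, -1.0, 1.0)


class TestFluidSurface:
    def test_empty_and_half_full(self, default_params):
        p = default_params
        assert M.fluid_surface_level(0.0, p) == 0.0
        # uniform prism: half the capacity fills to half the height
        half = M.fluid_surface_level(p.hemithorax_capacity / 2, p)
        assert half == pytest.approx(p.lung_height / 2)

    @given(a=st.floats(0.0, 3.4), b=st.floats(0.0, 3.4))
    def test_monotone_in_volume(self, default_params, a, b):
        la = M.fluid_surface_level(a, default_params)
        lb = M.fluid_surface_level(b, default_params)
        assert (la <= lb) == (a <= b) or math.isclose(la, lb)

    def test_overfill_rejected(self, default_params):
        with pytest.raises(ValueError):
            M.fluid_surface_level(10.0, default_params)


class TestRecruitmentHysteresis:
    def hand_automaton(self, seq, p_close, p_open, start):
        """Scalar hysteresis oracle, stepped by hand."""
        state, out = start, []
        for p in seq:
            if state and p < p_close:
                state = False
            elif not state and p > p_open:
                state = True
            out.append(state)
        return out

    @given(st.lists(st.floats(-0.5, 0.8), min_size=1, max_size=50),
           st.booleans())
    def test_matches_scalar_oracle(self, seq, start):
        flags = np.array([start])
        expected = self.hand_automaton(seq, 0.0, 0.3, start)
        got = []
        for p in seq:
            flags = M.hysteresis_step(flags, np.array([p]), 0.0, 0.3)
            got.append(bool(flags[0]))
        assert got == expected

    def test_fixed_point_and_threshold(self):
        flags = np.array([True, True, False])
        gate = np.array([1.0, -0.1, 0.1])     # >> open, below close, inside band
        new = M.hysteresis_step(flags, gate, 0.0, 0.3)
        assert new.tolist() == [True, False, False]


class TestMuscleDriver:
    def test_rest_length_full_transmission(self, default_params):
        d = M.DriveState(2.0)
        t_peak = default_params.Ti    # waveform maximum
        p_i, p_c, p_rc, phase = M.muscle_driver(t_peak - 1e-9, default_params, d)
        assert M.force_length_factor(0.0, default_params) == 1.0
        expected = 2.0 * (1 - default_params.rc_share)
        # the smooth inversion-direction factor is ~1 (tanh(3)) at rest length
        assert p_i == pytest.approx(expected, rel=1e-2)
        assert p_rc == pytest.approx(2.0 * default_params.rc_share, rel=1e-6)
        assert phase == "insp"

    def test_inverted_hemidiaphragm_paradoxical_and_floored(self, default_params):
        p = default_params
        d = M.DriveState(2.0)
        # displacement deep enough to reach both the inversion and the floor
        deep = (1 - p.di_phi_floor) * p.di_phi_span + 1.0
        p_i, p_c, _, _ = M.muscle_driver(p.Ti - 1e-9, p, d, x_di=(deep, 0.0))
        full = 2.0 * (1 - p.rc_share)
        assert p_i < 0, "contraction of an inverted dome must act expiratory"
        assert abs(p_i) == pytest.approx(full * p.di_phi_floor, rel=1e-3)
        assert p_c == pytest.approx(full, rel=1e-2)

    def test_end_expiration_pressures_vanish(self, default_params):
        p_i, p_c, p_rc, phase = M.muscle_driver(
            default_params.T_breath - 1e-6, default_params, M.DriveState(3.0))
        assert abs(p_i) < 1e-2 and abs(p_c) < 1e-2 and abs(p_rc) < 1e-2
        assert phase == "exp"


class TestEquilibriumAndDerivatives:
    def test_relaxed_state_is_a_fixed_point(self, small_params):
        state = M.Engine(small_params).static_state(0.0)
        d = M.derivatives(state, small_params.T_breath - 1e-9, small_params,
                          M.DriveState(0.0))
        assert np.max(np.abs(d["dV_alv"])) < 1e-6
        assert np.max(np.abs(d["dx_di"])) < 1e-6
        assert d["Q_mouth"] == pytest.approx(0.0, abs=1e-8)

    def test_flows_match_independent_network_solve(self, small_params):
        """Brute-force nodal solution of the airway resistance network."""
        p = small_params
        eng = M.Engine(p)
        state = eng.static_state(0.0)
        state.V_alv *= 0.97          # deflate both lungs -> inspiratory inflow
        d = M.derivatives(state, p.T_breath - 1e-9, p, M.DriveState(0.0))
        P = d["P_pl_top"]

        # oracle: solve [P_car, P_mb_i, P_mb_c] from Kirchhoff current law
        N = p.n_layers
        g_layer = []
        srcs = []
        for s in range(2):
            R = (p.R_small * N * (1 + p.collapse_beta * np.maximum(
                0, (eng.V_half - state.V_alv[s]) / eng.V_half))
                + p.R_par * N)
            g_layer.append(1.0 / R)
            srcs.append(P[s] + eng.recoil(state.V_alv[s]))
        A = np.zeros((3, 3))
        b = np.zeros(3)
        A[0, 0] = 1 / p.R_tr + 1 / p.R_mb_ipsi + 1 / p.R_mb_contra
        A[0, 1] = -1 / p.R_mb_ipsi
        A[0, 2] = -1 / p.R_mb_contra
        for k, (g, src, rmb) in enumerate(
                zip(g_layer, srcs, (p.R_mb_ipsi, p.R_mb_contra)), start=1):
            A[k, 0] = -1 / rmb
            A[k, k] = 1 / rmb + g.sum()
            b[k] = (g * src).sum()
        x = np.linalg.solve(A, b)
        q_i = (x[0] - x[1]) / p.R_mb_ipsi
        q_c = (x[0] - x[2]) / p.R_mb_contra
        assert d["Q_mb"][M.IPSI] == pytest.approx(q_i, rel=1e-9)
        assert d["Q_mb"][M.CONTRA] == pytest.approx(q_c, rel=1e-9)
        assert d["Q_mouth"] == pytest.approx(q_i + q_c, rel=1e-9)

    def test_effusion_routes_inspiratory_flow_contralaterally(self, stiff_run_3l):
        _, rec, _ = stiff_run_3l
        sl = rec.breath_slices()[-1]
        insp = rec.phase[sl] == "insp"
        v_i = np.trapezoid(np.maximum(rec.Q_mb_ipsi[sl][insp], 0), rec.t[sl][insp])
        v_c = np.trapezoid(np.maximum(rec.Q_mb_contra[sl][insp], 0), rec.t[sl][insp])
        assert v_c > 5 * v_i


class TestSingleCompartmentLimit:
    def test_step_response_matches_rc_closed_form(self):
        """One layer per lung, frozen rib cage, constant diaphragm drive:
        the network reduces exactly to a first-order RC relaxation."""
        p = build_patient("default", {"n_layers": 1, "R_rc": 1e6})
        eng = M.Engine(p)
        state = eng.static_state(0.0)
        D = 0.005   # kPa, small enough to stay in the linear range

        out, samples = eng.integrate(
            state, 1.2, drive_fn=lambda t: (D, 0.0),
            record_from=0.0, dt_out=0.01, phase_fn=lambda t: "")
        t = np.array([s[0] for s in samples])
        v_tot = np.array([s[6] + s[7] for s in samples])
        s_sim = (v_tot - v_tot[0]) / 2.0     # per-side displacement

        V0 = state.V_alv.sum(axis=1)[0]
        C_L = p.lung_Vmax * p.lung_k * math.exp(
            -p.lung_k * eng.recoil(np.array([V0]))[0])
        C_eff = 1.0 / (1.0 / C_L + 2.0 / p.C_ab + 1.0 / p.C_di_ipsi)
        R_x = 2 * p.R_tr + p.R_mb_ipsi + p.R_small + p.R_par
        tau = (p.R_ab + R_x) * C_eff
        s_ref = C_eff * D * (1.0 - np.exp(-t / tau))
        err = np.max(np.abs(s_sim - s_ref)) / (C_eff * D)
        assert err < 0.005, f"RC step response deviates {err:.2%} from closed form"


class TestConservationAndContract:
    def test_flow_continuity_at_carina(self, stiff_run_3l):
        _, rec, _ = stiff_run_3l
        resid = rec.Q_mouth - (rec.Q_mb_ipsi + rec.Q_mb_contra)
        assert np.max(np.abs(resid)) < 1e-12

    def test_cycle_volume_conservation(self, baseline_run, stiff_run_3l):
        for _, rec, _ in (baseline_run, stiff_run_3l):
            sl = rec.breath_slices()[-1]
            net = np.trapezoid(rec.Q_mouth[sl], rec.t[sl])
            vt = M.tidal_volume(rec)
            assert abs(net) <= 1e-3 * vt

    def test_mediastinal_pressure_volume_contract(self, stiff_run_3l,
                                                  compliant_run_3l):
        for params, rec, _ in (stiff_run_3l, compliant_run_3l):
            resid = (rec.P_pl_ipsi - rec.P_pl_contra) - rec.V_med / params.C_med
            assert np.max(np.abs(resid)) < 1e-9

    def test_mediastinal_coupling_limits_and_monotonicity(self):
        """Large C_med transmits pressure (|dP| -> 0); small C_med blocks
        volume (|V_med| -> 0); both monotone across the sweep."""
        dps, vms = [], []
        for f in (0.2, 0.5, 1.0, 2.0, 5.0):
            p = build_patient("default", {"n_layers": 20})
            p = p.with_updates(C_med=p.C_med * f)
            rec, _ = M.simulate_breaths(p, 3.0, n_breaths=1)
            dps.append(np.max(np.abs(rec.P_pl_ipsi - rec.P_pl_contra)))
            vms.append(np.max(np.abs(rec.V_med)))
        assert all(np.diff(dps) < 0), f"|dP| not decreasing in C_med: {dps}"
        assert all(np.diff(vms) > 0), f"|V_med| not increasing in C_med: {vms}"

    def test_hydrostatic_consistency_under_fluid(self, stiff_run_3l):
        params, _, state = stiff_run_3l
        eng = M.Engine(params)
        z_f = M.fluid_surface_level(state.V_pf, params)
        deepest_center = eng.z_center[0]
        expected = KPA_PER_CMH2O * params.rho_f * (z_f - deepest_center)
        hyd, _ = eng.hydro_offsets(state.V_pf)
        assert hyd[0] == pytest.approx(expected, rel=1e-12)


class TestSimulateBreaths:
    def test_vt_controller_hits_target(self, baseline_run):
        params, rec, _ = baseline_run
        assert M.tidal_volume(rec) == pytest.approx(params.VT_target, rel=0.02)

    def test_apical_layers_survive_large_effusion(self, stiff_run_3l):
        _, _, state = stiff_run_3l
        n = state.open.shape[1]
        assert state.open[M.IPSI, -max(1, n // 20):].all(), \
            "apical ipsilateral layers should stay open at 3 L"
        assert not state.open[M.IPSI, : n // 2].any(), \
            "dependent (submerged) layers should be collapsed"
        assert state.open[M.CONTRA].all()

    def test_invalid_breath_count(self, small_params):
        with pytest.raises(ValueError):
            M.simulate_breaths(small_params, 0.0, n_breaths=0)


class TestDriveController:
    def test_deterministic(self, small_params):
        a = M.adapt_drive_to_vt(small_params, 0.0)
        b = M.adapt_drive_to_vt(small_params, 0.0)
        assert a.amp == b.amp

    def test_effusion_demands_greater_drive(self, small_params):
        a0 = M.adapt_drive_to_vt(small_params, 0.0)
        a3 = M.adapt_drive_to_vt(small_params, 3.0)
        assert a3.amp > a0.amp

    def test_unreachable_target_reports_best(self, small_params):
        p = small_params.with_updates(VT_target=10.0)
        with pytest.raises(M.SimulationError, match="best"):
            M.adapt_drive_to_vt(p, 0.0)


class TestRecordingRoundTrip:
    def test_csv_round_trip(self, tmp_path, small_params):
        import pandas as pd

        rec, _ = M.simulate_breaths(small_params, 0.0, n_breaths=1)
        path = tmp_path / "rec.csv"
        rec.to_csv(path)
        back = M.BreathRecording.from_dataframe(pd.read_csv(path),
                                                rec.T_breath, rec.n_breaths)
        np.testing.assert_allclose(back.P_pl_ipsi, rec.P_pl_ipsi, rtol=1e-12)
        np.testing.assert_allclose(back.Q_mouth, rec.Q_mouth, rtol=1e-12)
        assert list(back.phase) == list(rec.phase)
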