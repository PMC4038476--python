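"""Simulator tests: analytic step responses, session phenomenology, cohorts."""

import math

import numpy as np
import pytest

from touchzap import (
    CircuitParams,
    PulseTrain,
    SessionScenario,
    SpikeShape,
    StepProtocol,
    scenario_for,
    simulate_session,
    simulate_step_response,
)
from touchzap.circuit import (
    CohortConfig,
    Dist,
    seal_rate_for_delay,
    simulate_cohort,
)

from oracles import ode_step_voltage


class TestStepResponse:
    def test_steady_state_is_ohms_law(self):
        # R_a_eff = 0, R_in = 100 MOhm, I = -0.1 nA -> V_ss = -80 mV exactly
        p = CircuitParams(R_in=100, tau_m=10, E_rest=-70, tau_e=0.0, bridge_error=0.0)
        tr = simulate_step_response(p, StepProtocol(0.25, 0.5, -0.1))
        i = int(round(0.74 * tr.sampling_rate))
        assert tr.voltage[i] == pytest.approx(-80.0, abs=1e-6)

    def test_two_exponential_value_matches_closed_form_and_ode(self):
        # 20 MOhm residual (tau_e 0.1 ms) + 100 MOhm cell (tau_m 10 ms),
        # I = -0.1 nA: at onset + 0.5 ms the closed form gives
        # -70 - 2(1-e^-5) - 10(1-e^-0.05) = -72.4742 mV
        p = CircuitParams(R_in=100, tau_m=10, E_rest=-70, tau_e=0.1, bridge_error=20.0)
        proto = StepProtocol(0.25, 0.5, -0.1)
        tr = simulate_step_response(p, proto)
        i = int(round((0.25 + 0.0005) * tr.sampling_rate))
        expected = -70 - 2 * (1 - math.exp(-5)) - 10 * (1 - math.exp(-0.05))
        assert expected == pytest.approx(-72.4742, abs=5e-4)
        assert tr.voltage[i] == pytest.approx(expected, abs=1e-9)
        v_ode = ode_step_voltage(p, proto, tr.times[i - 1: i + 2])
        assert tr.voltage[i] == pytest.approx(v_ode[1], abs=1e-4)

    def test_zero_current_gives_flat_trace_at_rest(self):
        p = CircuitParams(E_rest=-70, tau_e=0.0)
        tr = simulate_step_response(p, StepProtocol(0.25, 0.5, 0.0))
        assert np.allclose(tr.voltage, -70.0)
        assert np.allclose(tr.current, 0.0)

    def test_current_channel_reproduces_command_exactly(self, neuron_params, step):
        tr = simulate_step_response(neuron_params, step)
        on = (tr.times >= step.onset_s) & (tr.times < step.onset_s + step.duration_s)
        assert np.all(tr.current[on] == step.amplitude_na)
        assert np.all(tr.current[~on] == 0.0)

    def test_deterministic_under_seed(self, neuron_params, step):
        import dataclasses
        noisy = dataclasses.replace(neuron_params, noise_rms=1.0)
        a = simulate_step_response(noisy, step, seed=7)
        b = simulate_step_response(noisy, step, seed=7)
        assert np.array_equal(a.voltage, b.voltage)

    def test_errors(self, neuron_params):
        with pytest.raises(ValueError, match="200 ms"):
            simulate_step_response(neuron_params, StepProtocol(0.25, 0.15, -0.1))
        with pytest.raises(ValueError, match="non-uniform"):
            simulate_step_response(neuron_params, StepProtocol(0.25, 0.5, -0.1),
                                   sampling_rate=np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="tau_e"):
            simulate_step_response(neuron_params, StepProtocol(0.25, 0.5, -0.1),
                                   sampling_rate=1000.0)

    def test_spiking_response_contains_stereotyped_spikes(self):
        p = CircuitParams(R_in=100, tau_m=10, E_rest=-70, tau_e=0.0)
        spike = SpikeShape(threshold_mv=-50, peak_mv=11, dvdt_max=230)
        tr = simulate_step_response(p, StepProtocol(0.25, 0.5, 0.4), spike=spike)
        assert tr.voltage.max() == pytest.approx(11.0, abs=0.5)
        sub = simulate_step_response(p, StepProtocol(0.25, 0.5, 0.1), spike=spike)
        assert sub.voltage.max() < -50  # subthreshold drive stays passive


class TestCircuitParamInvariants:
    @pytest.mark.parametrize("kwargs", [
        dict(R_e=-1.0), dict(R_in=0.0), dict(tau_e=2.0, tau_m=1.0),
        dict(V_bd=-50.0), dict(noise_rms=-0.1), dict(bridge_error=-2.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CircuitParams(**kwargs)


class TestSession:
    def test_zap_fires_at_breakdown_resistance(self):
        # V_bd = -333 mV at -1.11 nA -> total resistance 300 MOhm at the zap
        p = CircuitParams(V_bd=-333.0)
        log = simulate_session(p, scenario_for("TZ", p, t_zap_s=2.5), seed=0)
        zaps = [e for e in log.truth_events if e.kind == "zap"]
        assert len(zaps) == 1
        r_at_zap = zaps[0].value / -1.11
        assert r_at_zap == pytest.approx(300.0, rel=0.02)
        # true V_zap within one sample of the breakdown threshold
        assert -338.0 < zaps[0].value <= -333.0

    def test_bath_phase_resistance_is_electrode_only(self):
        p = CircuitParams(R_e=6.0)
        log = simulate_session(p, SessionScenario(endpoint="FAIL"), seed=0)
        assert log.truth_events == []
        # deflection of each pulse ~ -1.11 * 6 = -6.66 mV
        i = int(round(0.54 * log.sampling_rate))  # plateau of some pulse
        assert log.voltage[i] == pytest.approx(-6.66, abs=0.05)

    def test_tzs_truth_sequence_ordered(self):
        p = CircuitParams()
        sc = scenario_for("TZS", p, t_zap_s=2.0, n_zaps=2)
        log = simulate_session(p, sc, seed=0)
        kinds = [e.kind for e in log.truth_events]
        assert kinds == ["touch", "zap", "zap", "reseal", "suction_break"]
        times = [e.time_s for e in log.truth_events]
        assert times == sorted(times)

    def test_second_zap_offset_is_respected(self):
        p = CircuitParams(R_in=56.0, R_a=35.0)
        sc = scenario_for("TZ", p, t_zap_s=2.0, n_zaps=2, second_zap_offset_mv=120.0)
        log = simulate_session(p, sc, seed=0)
        zaps = [e for e in log.truth_events if e.kind == "zap"]
        assert len(zaps) == 2
        assert 100.0 <= zaps[1].value - zaps[0].value <= 150.0

    def test_unreachable_breakdown_raises(self):
        p = CircuitParams(V_bd=-3000.0)  # needs a seal beyond the 2 GOhm ceiling
        with pytest.raises(ValueError, match="unreachable"):
            simulate_session(p, SessionScenario(endpoint="TZ", seal_rate_mohm_s=100.0),
                             seed=0)

    def test_scenario_invariants(self):
        with pytest.raises(ValueError):
            SessionScenario(endpoint="TS", n_zaps=1)
        with pytest.raises(ValueError):
            SessionScenario(endpoint="TZS", reseal=False)
        with pytest.raises(ValueError):
            SessionScenario(endpoint="TZ", touch_time_s=3.0, release_time_s=2.0)
        with pytest.raises(ValueError):
            SessionScenario(second_zap_offset_mv=80.0)

    def test_seal_rate_solver_hits_requested_delay(self):
        p = CircuitParams(V_bd=-333.0)
        rate = seal_rate_for_delay(p, 2.5)
        sc = SessionScenario(endpoint="TZ", seal_rate_mohm_s=rate)
        log = simulate_session(p, sc, seed=0)
        zap = [e for e in log.truth_events if e.kind == "zap"][0]
        # zap relative to pressure release at 2.0 s
        assert zap.time_s - 2.0 == pytest.approx(2.5, abs=0.15)


class TestCohort:
    def test_reproducible_under_seed(self):
        cfg = CohortConfig(n_cells=4)
        a = simulate_cohort(cfg, seed=5)
        b = simulate_cohort(cfg, seed=5)
        assert a.truth.equals(b.truth)
        assert np.array_equal(a.cells[0].session.voltage, b.cells[0].session.voltage)
        assert np.array_equal(a.cells[-1].traces[0].voltage, b.cells[-1].traces[0].voltage)

    def test_endpoint_mix_within_binomial_bounds(self):
        cfg = CohortConfig(n_cells=1000, glia_fraction=0.0, sessions=False, n_traces=0)
        cfg.neuron.spike = None
        cohort = simulate_cohort(cfg, seed=0)
        counts = cohort.truth.endpoint.value_counts()
        for ep, frac in zip(("TZ", "TZS", "TS"), (0.48, 0.40, 0.12)):
            sd = math.sqrt(1000 * frac * (1 - frac))
            assert abs(counts.get(ep, 0) - 1000 * frac) < 3 * sd

    def test_glia_tau_below_classifier_criterion_by_construction(self):
        cfg = CohortConfig(n_cells=40, glia_fraction=1.0, sessions=False, n_traces=0)
        cohort = simulate_cohort(cfg, seed=1)
        assert (cohort.truth.tau_m < 5.0).all()
        assert (cohort.truth.cell_class == "glia").all()

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="SD"):
            Dist(10.0, -1.0)
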