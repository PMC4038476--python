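"""Electrode + cell equivalent-circuit simulator.

Synthesizes single current-step sweeps (two-exponential responses: a fast
electrode component and a slower membrane component), full approach-and-access
session logs driven by a pulse train (touch, spontaneous seal formation,
electroporation "zap", reseal, suction), and whole cohorts of cells with
parameters drawn from configurable distributions.  Every synthetic object
carries its ground truth, so all downstream analysis stages can be validated
against known values.

The electrode artifact is modeled as a single fast exponential (tau_e); seal
growth as an exponential approach toward a 2 GOhm ceiling; spiking neurons as
leaky integrate-and-fire with a stereotyped piecewise-linear spike waveform of
configurable peak and maximum dV/dt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal

from .core import (
    Annotation,
    CurrentClampTrace,
    Event,
    PulseTrain,
    SessionLog,
    StepProtocol,
)

ENDPOINTS = ("TZ", "TZS", "TS", "FAIL")

#: seal resistance ceiling for the exponential growth model (MOhm); a formed
#: gigaseal is on the order of a few GOhm
SEAL_CEILING_MOHM = 2000.0


@dataclass(frozen=True)
class CircuitParams:
    """Ground-truth electrode/seal/cell equivalent-circuit parameters.

    Resistances in MOhm, time constants in ms, voltages in mV.
    ``bridge_error`` is the uncompensated access resistance presented to the
    analyst (the residual left by the amplifier's bridge circuit); the step
    response contains an artifact ``I * bridge_error`` with time constant
    ``tau_e``, while ``R_a`` is the full (true) access resistance.
    """

    R_e: float = 6.0
    tau_e: float = 0.15
    R_a: float = 35.0
    R_in: float = 100.0
    tau_m: float = 10.0
    E_rest: float = -70.0
    V_bd: float = -330.0
    noise_rms: float = 0.0
    bridge_error: float = 0.0

    def __post_init__(self):
        if self.R_e <= 0 or self.R_a <= 0 or self.R_in <= 0:
            raise ValueError("R_e, R_a and R_in must be positive")
        if self.tau_e < 0 or self.noise_rms < 0:
            raise ValueError("tau_e and noise_rms must be non-negative")
        if self.tau_e > 0 and self.tau_m > 0 and not self.tau_e < self.tau_m:
            raise ValueError("electrode time constant must be faster than the membrane (tau_e < tau_m)")
        if self.V_bd >= -100.0:
            raise ValueError("breakdown voltage V_bd must be below -100 mV")
        if self.bridge_error < 0:
            raise ValueError("bridge_error must be non-negative")


@dataclass(frozen=True)
class SpikeShape:
    """Stereotyped action-potential waveform for the integrate-and-fire model.

    The spike rises linearly from threshold to ``peak_mv`` at exactly
    ``dvdt_max`` mV/ms, then falls linearly to ``reset_mv`` over the rest of
    ``width_ms``.  Sufficient to exercise spike detection and dV/dt / peak
    metrics; no biophysical channel model is implied.
    """

    threshold_mv: float = -50.0
    peak_mv: float = 11.0
    dvdt_max: float = 230.0
    width_ms: float = 2.0
    reset_mv: float = -60.0

    def __post_init__(self):
        if self.peak_mv <= self.threshold_mv:
            raise ValueError("spike peak must exceed threshold")
        if self.dvdt_max <= 0 or self.width_ms <= 0:
            raise ValueError("dvdt_max and width_ms must be positive")
        rise = (self.peak_mv - self.threshold_mv) / self.dvdt_max
        if rise >= self.width_ms:
            raise ValueError("rise time implied by dvdt_max exceeds spike width")


def bessel_lowpass(voltage: np.ndarray, sampling_rate: float, cutoff_hz: float) -> np.ndarray:
    """Causal 4th-order Bessel low-pass, emulating the acquisition filter."""
    nyq = sampling_rate / 2.0
    if cutoff_hz >= nyq:
        return np.asarray(voltage, dtype=float).copy()
    sos = signal.bessel(4, cutoff_hz / nyq, btype="low", output="sos", norm="mag")
    return signal.sosfilt(sos, voltage)


def _charging(t: np.ndarray, r_fast: float, tau_e_s: float, r_mem: float, tau_m_s: float) -> np.ndarray:
    """Step-response resistance profile r(t) (MOhm) for t >= 0, 0 for t < 0."""
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    if r_fast:
        out[pos] += r_fast * (1.0 - np.exp(-tp / tau_e_s)) if tau_e_s > 0 else r_fast
    if r_mem:
        out[pos] += r_mem * (1.0 - np.exp(-tp / tau_m_s)) if tau_m_s > 0 else r_mem
    return out


def simulate_step_response(
    params: CircuitParams,
    protocol: StepProtocol,
    sampling_rate: float = 40_000.0,
    seed: Optional[int] = None,
    *,
    spike: Optional[SpikeShape] = None,
    tail_s: float = 0.25,
    filter_cutoff_hz: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    meta: Optional[dict] = None,
) -> CurrentClampTrace:
    """Simulate one current-step sweep.

    The noiseless voltage after onset is the analytic piecewise-linear-circuit
    solution ``E_rest + I*bridge_error*(1-exp(-t/tau_e)) + I*R_in*(1-exp(-t/tau_m))``
    (superposed with the mirrored off-step), plus Gaussian noise of sd
    ``noise_rms``.  The current channel reproduces the command exactly.

    With ``spike`` given and a sufficiently depolarizing step, the membrane
    component follows a leaky integrate-and-fire trajectory with stereotyped
    spike waveforms pasted at threshold crossings.

    Raises if the sampling request is non-uniform, if the sampling interval
    cannot resolve the electrode time constant (dt > tau_e/2), or if the step
    is shorter than 200 ms (the steady-state window would be undefined).
    """
    if np.ndim(sampling_rate) != 0:
        raise ValueError("non-uniform sampling is not supported; pass a scalar sampling rate")
    sampling_rate = float(sampling_rate)
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    dt = 1.0 / sampling_rate
    tau_e_s = params.tau_e * 1e-3
    tau_m_s = params.tau_m * 1e-3
    if tau_e_s > 0 and dt > tau_e_s / 2.0:
        raise ValueError(
            f"sampling interval {dt * 1e3:.3f} ms cannot resolve the electrode time constant "
            f"{params.tau_e:.3f} ms (need dt <= tau_e/2, or tau_e = 0)"
        )
    if protocol.duration_s < 0.2:
        raise ValueError(
            "step duration must be >= 200 ms so the steady-state window "
            "[onset+100 ms, onset+200 ms) exists"
        )

    n = int(round((protocol.onset_s + protocol.duration_s + tail_s) * sampling_rate))
    t = np.arange(n) * dt
    amp = protocol.amplitude_na
    onset, offset = protocol.onset_s, protocol.onset_s + protocol.duration_s

    current = np.where((t >= onset) & (t < offset), amp, 0.0)
    # electrode artifact (the residual the analyst sees)
    artifact = amp * (
        _charging(t - onset, params.bridge_error, tau_e_s, 0.0, 0.0)
        - _charging(t - offset, params.bridge_error, tau_e_s, 0.0, 0.0)
    )

    if spike is None or amp * params.R_in + params.E_rest <= spike.threshold_mv:
        membrane = params.E_rest + amp * (
            _charging(t - onset, 0.0, 0.0, params.R_in, tau_m_s)
            - _charging(t - offset, 0.0, 0.0, params.R_in, tau_m_s)
        )
    else:
        membrane = _lif_membrane(params, spike, t, onset, offset, amp, tau_m_s)

    voltage = membrane + artifact
    if params.noise_rms > 0:
        r = rng if rng is not None else np.random.default_rng(seed)
        voltage = voltage + r.normal(0.0, params.noise_rms, size=n)
    if filter_cutoff_hz is not None:
        voltage = bessel_lowpass(voltage, sampling_rate, filter_cutoff_hz)

    m = {"filter_cutoff_hz": filter_cutoff_hz, "tip_offset_mv": -14.0, "tip_offset_applied": True}
    if meta:
        m.update(meta)
    return CurrentClampTrace(sampling_rate, voltage, current, protocol, m)


def _lif_membrane(params, spike, t, onset, offset, amp, tau_m_s):
    """Leaky integrate-and-fire membrane trajectory with pasted spike waveforms."""
    v = np.empty_like(t)
    e, target = params.E_rest, params.E_rest + amp * params.R_in
    v[t < onset] = e
    rise_s = (spike.peak_mv - spike.threshold_mv) / spike.dvdt_max * 1e-3
    width_s = spike.width_ms * 1e-3
    fall_s = width_s - rise_s

    seg_t0, v0 = onset, e
    while seg_t0 < offset:
        # analytic time to threshold from v0 under constant drive
        if target <= spike.threshold_mv or v0 >= target:
            t_cross = offset
        else:
            ratio = (target - v0) / (target - spike.threshold_mv)
            t_cross = seg_t0 + tau_m_s * math.log(ratio) if ratio > 1 else seg_t0
        t_cross = min(t_cross, offset)
        seg = (t >= seg_t0) & (t < t_cross)
        v[seg] = target + (v0 - target) * np.exp(-(t[seg] - seg_t0) / tau_m_s)
        if t_cross >= offset:
            v0 = target + (v0 - target) * math.exp(-(offset - seg_t0) / tau_m_s)
            break
        # paste spike: linear rise at dvdt_max, then linear fall to reset
        sp_end = t_cross + width_s
        seg = (t >= t_cross) & (t < min(sp_end, offset))
        ts = t[seg] - t_cross
        v[seg] = np.where(
            ts < rise_s,
            spike.threshold_mv + spike.dvdt_max * 1e3 * ts,
            spike.peak_mv - (spike.peak_mv - spike.reset_mv) * (ts - rise_s) / fall_s,
        )
        seg_t0, v0 = sp_end, spike.reset_mv
        if seg_t0 >= offset:
            break
    # off-step relaxation back to rest
    seg = t >= offset
    v[seg] = e + (v0 - e) * np.exp(-(t[seg] - offset) / tau_m_s)
    return v


# ---------------------------------------------------------------------------
# session simulation


@dataclass
class SessionScenario:
    """Script of one approach-and-access attempt.

    Endpoints: TZ (zap only), TZS (zap, reseal, then suction), TS (no zap,
    seal formed slowly, access by suction), FAIL (no cell contact).
    ``seal_rate_mohm_s`` is the initial slope of the exponential seal growth;
    ``artifact_frac`` injects a sinusoidal (cardiac/movement-like) fractional
    modulation of the electrode resistance.
    """

    endpoint: str = "TZ"
    touch_time_s: float = 1.5
    release_time_s: float = 2.0
    seal_rate_mohm_s: float = 110.0
    n_zaps: int = 1
    second_zap_offset_mv: float = 120.0
    reseal: bool = False
    reseal_delay_s: float = 1.5
    reseal_rate_mohm_s: float = 250.0
    suction_time_s: Optional[float] = None
    duration_s: Optional[float] = None
    delta_r_touch: float = 0.5
    artifact_frac: float = 0.0
    artifact_freq_hz: float = 2.0
    pulse_train: PulseTrain = field(default_factory=PulseTrain)
    seal_ceiling: float = SEAL_CEILING_MOHM
    post_zap1_frac: float = 0.5
    reduced_amplitude_na: float = -0.111

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}")
        if self.endpoint in ("TZ", "TZS") and self.n_zaps not in (1, 2):
            raise ValueError("TZ/TZS scenarios require n_zaps of 1 or 2")
        if self.endpoint == "TS" and self.n_zaps != 0:
            raise ValueError("TS scenarios imply n_zaps = 0")
        if self.endpoint == "TZS" and not self.reseal:
            raise ValueError("TZS scenarios imply reseal")
        if self.endpoint != "FAIL" and not self.touch_time_s < self.release_time_s:
            raise ValueError("touch_time must precede release_time")
        if not 0 <= self.artifact_frac < 1:
            raise ValueError("artifact_frac must be in [0, 1)")
        if self.seal_rate_mohm_s <= 0 or self.seal_ceiling <= 0:
            raise ValueError("seal growth rate and ceiling must be positive")
        if not 100.0 <= self.second_zap_offset_mv <= 150.0:
            raise ValueError("second zap offset must lie in [100, 150] mV")


def seal_rate_for_delay(
    params: CircuitParams,
    delay_s: float,
    amplitude_na: float = -1.11,
    ceiling: float = SEAL_CEILING_MOHM,
    delta_r_touch: float = 0.5,
) -> float:
    """Initial seal-growth slope (MOhm/s) such that the pulse envelope reaches
    the breakdown voltage ``delay_s`` seconds after pressure release."""
    r_needed = abs(params.V_bd / amplitude_na) - params.R_e - delta_r_touch
    if r_needed <= 0:
        raise ValueError("breakdown voltage already exceeded at the bare electrode resistance")
    if r_needed >= ceiling:
        raise ValueError(
            f"breakdown requires a seal of {r_needed:.0f} MOhm, above the {ceiling:.0f} MOhm ceiling"
        )
    tau = -delay_s / math.log1p(-r_needed / ceiling)
    return ceiling / tau


class _SessionState:
    """Mutable rendering state shared across pulse segments."""

    __slots__ = ("phase", "v_fast", "v_mem", "seal_base", "seal_t0", "seal_tau", "zaps_done", "v_zap1", "access_time", "amp")

    def __init__(self, amp):
        self.phase = "bath"  # bath | on_cell | sealing | whole_cell | resealing
        self.v_fast = 0.0
        self.v_mem = 0.0
        self.seal_base = 0.0
        self.seal_t0 = 0.0
        self.seal_tau = 1.0
        self.zaps_done = 0
        self.v_zap1 = None
        self.access_time = None
        self.amp = amp


def simulate_session(
    params: CircuitParams,
    scenario: SessionScenario,
    sampling_rate: float = 5000.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SessionLog:
    """Simulate a full session log of an approach-and-access attempt.

    Per pulse, the plateau deflection equals the command amplitude times the
    total instantaneous resistance: R_e in the bath, plus a few hundred kOhm
    after the touch, plus the continuously growing seal resistance after
    pressure release.  A zap fires at the first sample whose voltage reaches
    the breakdown threshold (V_bd for the first zap; 100-150 mV less
    hyperpolarized for a second zap), so the true zap voltage matches the
    threshold within one sample of envelope growth.  After final access the
    electrode sees the whole-cell load (R_e + R_a fast, plus R_in charging
    with tau_m), the command is reduced to a small monitoring amplitude, and
    the DC level shifts toward E_rest.  Ground truth (touch, zaps with true
    V_zap, reseal, suction_break) is attached as ``truth_events``;
    experimenter actions as ``annotations``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pt = scenario.pulse_train
    amp_full = pt.amplitude_na
    if amp_full == 0:
        raise ValueError("pulse amplitude must be non-zero")
    ceiling = scenario.seal_ceiling
    tau_seal = ceiling / scenario.seal_rate_mohm_s
    fail = scenario.endpoint == "FAIL"
    touch, release = scenario.touch_time_s, scenario.release_time_s

    # when will the growing seal reach breakdown? (duration default and error check)
    r_bd = abs(params.V_bd / amp_full)
    s_needed = r_bd - params.R_e - scenario.delta_r_touch
    t_zap_expect = None
    if scenario.endpoint in ("TZ", "TZS"):
        if s_needed >= ceiling:
            raise ValueError(
                f"breakdown voltage {params.V_bd:.0f} mV needs {s_needed:.0f} MOhm of seal, "
                f"unreachable below the {ceiling:.0f} MOhm ceiling"
            )
        t_zap_expect = release - tau_seal * math.log1p(-s_needed / ceiling)

    suction = scenario.suction_time_s
    if scenario.endpoint == "TZS" and suction is None:
        suction = t_zap_expect + 6.5
    if scenario.endpoint == "TS" and suction is None:
        suction = release + 12.0

    duration = scenario.duration_s
    if duration is None:
        if fail:
            duration = 8.0
        elif scenario.endpoint == "TZ":
            duration = t_zap_expect + 5.0
        else:
            duration = suction + 3.0
    if t_zap_expect is not None and t_zap_expect > duration:
        raise ValueError(
            f"seal cannot reach the breakdown voltage {params.V_bd:.0f} mV within the "
            f"{duration:.1f} s log (expected crossing at {t_zap_expect:.1f} s)"
        )

    dt = 1.0 / float(sampling_rate)
    n = int(round(duration * sampling_rate))
    voltage = np.zeros(n)
    current = np.zeros(n)
    tau_e_s = max(params.tau_e * 1e-3, dt / 4.0)
    tau_m_s = max(params.tau_m * 1e-3, dt / 4.0)
    alpha_e = math.exp(-dt / tau_e_s)
    alpha_m = math.exp(-dt / tau_m_s)

    truth: list[Event] = []
    annotations: list[Annotation] = []
    if not fail:
        truth.append(Event(touch, "touch", scenario.delta_r_touch))
        annotations.append(Annotation(release, "pressure_release"))
    if suction is not None and suction < duration:
        annotations.append(Annotation(suction, "suction"))

    period, on_w = pt.period_s, pt.on_width_s
    st = _SessionState(amp_full)
    reduce_next = False
    reseal_t0 = None
    ts_reductions = 0
    final_zap_target = scenario.n_zaps if scenario.endpoint in ("TZ", "TZS") else 0

    def seal_at(times):
        return ceiling - (ceiling - st.seal_base) * np.exp(-(times - st.seal_t0) / st.seal_tau)

    def r_fast_env(times, base_r):
        """Fast-component resistance seen by the electrode at ``times``."""
        r = np.full_like(np.asarray(times, dtype=float), base_r)
        if scenario.artifact_frac:
            r = r * (1.0 + scenario.artifact_frac * np.sin(2 * math.pi * scenario.artifact_freq_hz * np.asarray(times)))
        return r

    k = 0
    t_k = pt.start_s
    while t_k < duration:
        i0 = int(round(t_k / dt))
        i_on = min(int(round((t_k + on_w) / dt)), n)
        i_end = min(int(round((t_k + period) / dt)), n)
        if i0 >= n:
            break

        # ---- phase transitions evaluated at pulse start
        if not fail:
            if st.phase == "bath" and t_k >= touch:
                st.phase = "on_cell"
            if st.phase == "on_cell" and t_k >= release:
                st.phase = "sealing"
                st.seal_base, st.seal_t0, st.seal_tau = 0.0, release, tau_seal
            if reseal_t0 is not None and st.phase == "whole_cell" and t_k >= reseal_t0:
                st.phase = "resealing"
                st.seal_base, st.seal_t0 = 0.0, reseal_t0
                st.seal_tau = ceiling / scenario.reseal_rate_mohm_s
                reseal_t0 = None
            if suction is not None and t_k >= suction and st.phase in ("sealing", "resealing"):
                if st.phase == "sealing":  # TS access by suction
                    st.access_time = suction
                    reduce_next = True
                st.phase = "whole_cell"
                truth.append(Event(suction, "suction_break", params.R_e + params.R_a))
                suction = None
        if reduce_next:
            st.amp = scenario.reduced_amplitude_na
            annotations.append(Annotation(max(0.0, min(t_k, duration - dt)), "current_change", f"{st.amp:g} nA"))
            reduce_next = False

        # ---- render the on-phase
        seg = np.arange(i0, i_on)
        ts_abs = seg * dt
        if seg.size:
            decay_e = alpha_e ** np.arange(1, seg.size + 1)
            decay_m = alpha_m ** np.arange(1, seg.size + 1)
            if st.phase in ("bath", "on_cell"):
                base_r = params.R_e + (scenario.delta_r_touch if st.phase == "on_cell" else 0.0)
                target = st.amp * r_fast_env(ts_abs, base_r)
                # TS-style amplitude reduction to avoid huge deflections
                voltage[seg] = target + (st.v_fast - target[0]) * decay_e
                st.v_fast = voltage[seg][-1]
                st.v_mem *= decay_m[-1]
                current[seg] = st.amp
            elif st.phase in ("sealing", "resealing"):
                extra = params.R_a if st.phase == "resealing" else scenario.delta_r_touch
                r_env = r_fast_env(ts_abs, params.R_e) + extra + seal_at(ts_abs)
                if st.phase == "sealing" and not fail and abs(st.amp * r_env[0]) > 140.0 and scenario.endpoint == "TS" and ts_reductions < 3:
                    st.amp *= 0.1
                    ts_reductions += 1
                    annotations.append(Annotation(max(0.0, min(t_k, duration - dt)), "current_change", f"{st.amp:g} nA"))
                target = st.amp * r_env
                v = target + (st.v_fast - target[0]) * decay_e
                zap_thr = None
                if (
                    st.phase == "sealing"
                    and st.zaps_done < final_zap_target
                    and st.amp == amp_full
                ):
                    zap_thr = params.V_bd if st.zaps_done == 0 else st.v_zap1 + scenario.second_zap_offset_mv
                j = None
                if zap_thr is not None:
                    hits = np.nonzero(v <= zap_thr)[0]
                    if hits.size:
                        j = int(hits[0])
                if j is None:
                    voltage[seg] = v
                    current[seg] = st.amp
                    st.v_fast = v[-1]
                    st.v_mem *= decay_m[-1]
                else:
                    # electroporation at sample j: record, collapse, re-render rest
                    voltage[seg[: j + 1]] = v[: j + 1]
                    current[seg] = st.amp
                    t_zap = ts_abs[j]
                    v_zap = v[j]
                    truth.append(Event(t_zap, "zap", v_zap))
                    st.zaps_done += 1
                    st.v_fast = v[j]
                    if st.zaps_done == 1:
                        st.v_zap1 = v_zap
                    if st.zaps_done < final_zap_target:
                        # partial access; seal collapses and regrows
                        st.seal_base = max(
                            0.0, scenario.post_zap1_frac * (abs(v_zap / st.amp) - params.R_e) - scenario.delta_r_touch
                        )
                        st.seal_t0 = t_zap
                        rest = seg[j + 1:]
                        if rest.size:
                            r_env2 = r_fast_env(rest * dt, params.R_e) + scenario.delta_r_touch + seal_at(rest * dt)
                            target2 = st.amp * r_env2
                            d_e = alpha_e ** np.arange(1, rest.size + 1)
                            voltage[rest] = target2 + (st.v_fast - target2[0]) * d_e
                            st.v_fast = voltage[rest][-1]
                    else:
                        st.phase = "whole_cell"
                        st.access_time = t_zap
                        reduce_next = True
                        if scenario.reseal:
                            reseal_t0 = t_zap + scenario.reseal_delay_s
                            truth.append(Event(reseal_t0, "reseal", None))
                        rest = seg[j + 1:]
                        if rest.size:
                            tf = st.amp * (params.R_e + params.R_a)
                            tm = st.amp * params.R_in
                            d_e = alpha_e ** np.arange(1, rest.size + 1)
                            d_m = alpha_m ** np.arange(1, rest.size + 1)
                            vf = tf + (st.v_fast - tf) * d_e
                            vm = tm + (st.v_mem - tm) * d_m
                            voltage[rest] = vf + vm
                            st.v_fast, st.v_mem = vf[-1], vm[-1]
            else:  # whole_cell
                tf = st.amp * (r_fast_env(ts_abs, params.R_e)[0] + params.R_a)
                tm = st.amp * params.R_in
                vf = tf + (st.v_fast - tf) * decay_e
                vm = tm + (st.v_mem - tm) * decay_m
                voltage[seg] = vf + vm
                current[seg] = st.amp
                st.v_fast, st.v_mem = vf[-1], vm[-1]

        # ---- render the off-phase (relaxation)
        seg = np.arange(i_on, i_end)
        if seg.size:
            decay_e = alpha_e ** np.arange(1, seg.size + 1)
            decay_m = alpha_m ** np.arange(1, seg.size + 1)
            voltage[seg] = st.v_fast * decay_e + st.v_mem * decay_m
            st.v_fast *= decay_e[-1]
            st.v_mem *= decay_m[-1]

        k += 1
        t_k = pt.start_s + k * period

    # DC shift toward E_rest once whole-cell access is established; settles
    # on the membrane time scale so it does not bleed into later pulses
    if st.access_time is not None:
        tvec = np.arange(n) * dt
        rel = tvec - st.access_time
        tau_dc = max(tau_m_s, 0.01)
        voltage += np.where(rel >= 0, params.E_rest * -np.expm1(-np.maximum(rel, 0.0) / tau_dc), 0.0)

    if params.noise_rms > 0:
        voltage += rng.normal(0.0, params.noise_rms, size=n)

    truth.sort(key=lambda e: e.time_s)
    annotations = sorted((a for a in annotations if a.time_s <= duration), key=lambda a: a.time_s)
    return SessionLog(
        sampling_rate=float(sampling_rate),
        voltage=voltage,
        current=current,
        pulse_train=pt,
        annotations=annotations,
        truth_events=truth,
        meta={"endpoint_true": scenario.endpoint, "E_rest": params.E_rest, "V_bd": params.V_bd},
    )


def scenario_for(
    endpoint: str,
    params: CircuitParams,
    t_zap_s: float = 2.5,
    n_zaps: int = 1,
    pulse_train: Optional[PulseTrain] = None,
    **kwargs,
) -> SessionScenario:
    """Build a consistent scenario for an endpoint, with the seal growth rate
    chosen so the zap (when any) fires ``t_zap_s`` seconds after release."""
    pt = pulse_train if pulse_train is not None else PulseTrain()
    base = dict(endpoint=endpoint, pulse_train=pt)
    if endpoint in ("TZ", "TZS"):
        rate = seal_rate_for_delay(
            params, t_zap_s, pt.amplitude_na,
            kwargs.get("seal_ceiling", SEAL_CEILING_MOHM),
            kwargs.get("delta_r_touch", 0.5),
        )
        base.update(seal_rate_mohm_s=rate, n_zaps=n_zaps, reseal=endpoint == "TZS")
    elif endpoint == "TS":
        base.update(seal_rate_mohm_s=kwargs.pop("seal_rate_mohm_s", 60.0), n_zaps=0)
    elif endpoint == "FAIL":
        base.update(n_zaps=0)
    base.update(kwargs)
    return SessionScenario(**base)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class Dist:
    """Truncated-normal parameter distribution (mean, sd, [lo, hi])."""

    mean: float
    sd: float
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("distribution SD must be non-negative")

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return float(np.clip(self.mean, self.lo, self.hi))
        for _ in range(1000):
            x = rng.normal(self.mean, self.sd)
            if self.lo <= x <= self.hi:
                return float(x)
        return float(np.clip(self.mean, self.lo, self.hi))


@dataclass
class CellTypeConfig:
    """Per-cell-type parameter distributions for cohort synthesis.

    Defaults reproduce the in vivo cohort summaries shipped with the package
    (see :mod:`touchzap.reference`): electrode resistance ~6 MOhm, neuron
    R_in 56 +/- 31 MOhm with tau_m 9.8 +/- 5.2 ms, breakdown voltages near
    -330 mV, zap delays averaging 2.6 s.  T_zap is sampled lognormally: the
    delay distribution is right-skewed, and matching the published median and
    mean reproduces the published SD almost exactly.
    """

    R_e: Dist = field(default_factory=lambda: Dist(6.0, 0.73, 4.0, 8.0))
    R_a: Dist = field(default_factory=lambda: Dist(35.0, 18.0, 8.0, 120.0))
    R_in: Dist = field(default_factory=lambda: Dist(56.0, 31.0, 15.0, 250.0))
    tau_m: Dist = field(default_factory=lambda: Dist(9.8, 5.2, 5.0, 28.0))
    E_rest: Dist = field(default_factory=lambda: Dist(-76.0, 7.5, -100.0, -55.0))
    V_bd: Dist = field(default_factory=lambda: Dist(-330.0, 53.0, -520.0, -180.0))
    bridge_error: Dist = field(default_factory=lambda: Dist(4.0, 2.0, 0.5, 12.0))
    ra_drift: Dist = field(default_factory=lambda: Dist(1.3, 1.5, -3.0, 6.0))
    depth_um: Dist = field(default_factory=lambda: Dist(874.0, 345.0, 100.0, 2000.0))
    t_zap_median_s: float = 2.1
    t_zap_sigma: float = 0.654
    tau_e: float = 0.15
    noise_rms: float = 0.5
    endpoint_mix: tuple = (0.48, 0.40, 0.12)
    spike: Optional[SpikeShape] = field(default_factory=SpikeShape)
    spike_dvdt: Dist = field(default_factory=lambda: Dist(230.0, 85.0, 80.0, 500.0))
    spike_peak: Dist = field(default_factory=lambda: Dist(11.0, 9.3, -20.0, 40.0))


def glia_type_config() -> CellTypeConfig:
    """Glial-cell distributions: no spikes, fast tau_m (< 5 ms by construction)."""
    return CellTypeConfig(
        R_e=Dist(6.4, 0.58, 4.0, 8.0),
        R_a=Dist(53.0, 26.0, 8.0, 140.0),
        R_in=Dist(90.0, 62.0, 15.0, 280.0),
        tau_m=Dist(1.5, 2.9, 0.4, 4.9),
        E_rest=Dist(-76.0, 13.0, -110.0, -45.0),
        V_bd=Dist(-350.0, 64.0, -560.0, -180.0),
        ra_drift=Dist(1.7, 1.5, -3.0, 7.0),
        t_zap_median_s=3.2,
        t_zap_sigma=0.738,
        endpoint_mix=(0.61, 0.24, 0.15),
        spike=None,
    )


@dataclass
class CohortConfig:
    """Cohort synthesis configuration: cell-type mix, endpoint mix, sizes."""

    n_cells: int = 20
    glia_fraction: float = 0.27
    neuron: CellTypeConfig = field(default_factory=CellTypeConfig)
    glia: CellTypeConfig = field(default_factory=glia_type_config)
    session_sampling_rate: float = 5000.0
    trace_sampling_rate: float = 40_000.0
    n_traces: int = 5
    rat_fraction: float = 0.42
    sessions: bool = True
    two_zap_fraction: float = 0.75

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("cohort needs at least one cell")
        if not 0 <= self.glia_fraction <= 1:
            raise ValueError("glia_fraction must be within [0, 1]")


@dataclass
class CellSim:
    """One simulated cell: ground truth, session log and IV step traces."""

    cell_id: str
    cell_class: str
    endpoint: str
    params: CircuitParams
    session: Optional[SessionLog]
    traces: list
    truth: dict


@dataclass
class Cohort:
    cells: list
    truth: "object"  # pandas DataFrame

    @property
    def sessions(self):
        return [c.session for c in self.cells if c.session is not None]


def simulate_cohort(config: CohortConfig, seed: Optional[int] = None) -> Cohort:
    """Simulate a cohort of cells (sessions + IV traces + ground-truth table).

    Reproducible given ``seed``; the ground-truth table records every sampled
    parameter.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    cells = []
    rows = []
    for i in range(config.n_cells):
        cell_id = f"cell_{i:04d}"
        is_glia = rng.random() < config.glia_fraction
        ctype = config.glia if is_glia else config.neuron
        cls = "glia" if is_glia else "neuron"
        species = "rat" if rng.random() < config.rat_fraction else "cat"
        params = CircuitParams(
            R_e=ctype.R_e.draw(rng),
            tau_e=ctype.tau_e,
            R_a=ctype.R_a.draw(rng),
            R_in=ctype.R_in.draw(rng),
            tau_m=ctype.tau_m.draw(rng),
            E_rest=ctype.E_rest.draw(rng),
            V_bd=ctype.V_bd.draw(rng),
            noise_rms=ctype.noise_rms,
            bridge_error=ctype.bridge_error.draw(rng),
        )
        mix = np.asarray(ctype.endpoint_mix, dtype=float)
        endpoint = ("TZ", "TZS", "TS")[int(rng.choice(3, p=mix / mix.sum()))]
        t_zap = float(np.exp(rng.normal(math.log(ctype.t_zap_median_s), ctype.t_zap_sigma)))
        t_zap = min(max(t_zap, 0.4), 20.0)
        n_zaps = 0 if endpoint == "TS" else (2 if rng.random() < config.two_zap_fraction else 1)
        depth = ctype.depth_um.draw(rng)
        drift = ctype.ra_drift.draw(rng)

        session = None
        if config.sessions:
            scenario = scenario_for(endpoint, params, t_zap_s=t_zap, n_zaps=max(n_zaps, 1) if endpoint != "TS" else 0)
            session = simulate_session(params, scenario, config.session_sampling_rate, rng=rng)
            session.meta["cell_id"] = cell_id

        spike = None
        if ctype.spike is not None:
            spike = replace(
                ctype.spike,
                dvdt_max=ctype.spike_dvdt.draw(rng),
                peak_mv=ctype.spike_peak.draw(rng),
                threshold_mv=params.E_rest + 22.0,
                reset_mv=params.E_rest + 8.0,
            )

        traces = _cell_traces(params, spike, config, cell_id, species, depth, drift, rng)

        zaps = [e for e in (session.truth_events if session else []) if e.kind == "zap"]
        truth = dict(
            cell_id=cell_id, species=species, cell_class=cls, endpoint=endpoint,
            R_e=params.R_e, R_a=params.R_a, R_in=params.R_in, tau_m=params.tau_m,
            tau_e=params.tau_e, E_rest=params.E_rest, V_bd=params.V_bd,
            bridge_error=params.bridge_error, ra_drift_mohm_min=drift,
            depth_um=depth, n_zaps=len(zaps),
            V_zap_true=zaps[0].value if zaps else np.nan,
            T_zap_true=(zaps[0].time_s - 2.0) if zaps else np.nan,
            spike_dvdt_true=spike.dvdt_max if spike else np.nan,
            spike_peak_true=spike.peak_mv if spike else np.nan,
        )
        cells.append(CellSim(cell_id, cls, endpoint, params, session, traces, truth))
        rows.append(truth)
    return Cohort(cells, pd.DataFrame(rows))


def _cell_traces(params, spike, config, cell_id, species, depth, drift, rng):
    """Subthreshold step sweeps (plus one suprathreshold sweep for spiking
    cells), spread over the recording so the access-resistance trend is
    estimable.

    The bridge is recompensated before each sweep (as in the emulated
    protocol, where R_a is re-estimated and compensated several times during
    the first minutes): every sweep carries a fresh residual around the
    cell's ``bridge_error``, while the bridge *setting* stored in the sweep
    metadata follows the drifting true access resistance, so setting +
    fitted residual recovers R_a(t) and its trend.
    """
    traces = []
    amp = -round(min(0.35, max(0.04, 8.0 / (params.R_in + params.bridge_error))), 3)
    for j in range(config.n_traces):
        t_rec_min = 0.5 + 0.8 * j  # minutes into the recording
        residual = float(np.clip(rng.normal(params.bridge_error, 1.0), 0.3, 15.0))
        r_a_now = max(params.R_a + drift * t_rec_min, residual + 1.0)
        p = replace(params, bridge_error=residual)
        protocol = StepProtocol(onset_s=0.25, duration_s=0.5, amplitude_na=amp)
        meta = dict(
            cell_id=cell_id, species=species, depth_um=depth,
            bridge_setting_mohm=r_a_now - residual, rec_time_s=t_rec_min * 60.0,
            protocol_role="iv",
        )
        traces.append(
            simulate_step_response(p, protocol, config.trace_sampling_rate, rng=rng, meta=meta)
        )
    if spike is not None:
        amp_supra = round((spike.threshold_mv - params.E_rest + 25.0) / params.R_in, 3)
        protocol = StepProtocol(onset_s=0.25, duration_s=0.5, amplitude_na=amp_supra)
        meta = dict(
            cell_id=cell_id, species=species, depth_um=depth,
            bridge_setting_mohm=params.R_a - params.bridge_error, rec_time_s=30.0,
            protocol_role="suprathreshold",
        )
        traces.append(
            simulate_step_response(
                params, protocol, config.trace_sampling_rate, rng=rng, spike=spike, meta=meta
            )
        )
    return traces


__all__ = [
    "CircuitParams",
    "SpikeShape",
    "SessionScenario",
    "CellTypeConfig",
    "CohortConfig",
    "CellSim",
    "Cohort",
    "Dist",
    "ENDPOINTS",
    "SEAL_CEILING_MOHM",
    "bessel_lowpass",
    "glia_type_config",
    "seal_rate_for_delay",
    "scenario_for",
    "simulate_step_response",
    "simulate_session",
    "simulate_cohort",
]
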