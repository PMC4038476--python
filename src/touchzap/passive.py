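"""Passive-parameter extraction from current-step responses.

Implements an off-line heuristic modeled on the visual bridge-balance
procedure: the fast electrode artifact is discounted by ignoring the first
part of the response rather than fitting it, the steady state is measured in
a fixed late window, and the membrane charging is fit as a single exponential
in two passes of log-linear regression.  Per trace this yields the resting
potential V_rest, steady state V_ss, pre-step voltage V_O, membrane time
constant tau0, the residual access-resistance compensation error R_a_error,
and the input resistance R_in; per cell, trace results are averaged and the
access-resistance trend over the recording is estimated by ordinary least
squares.

The approach assumes tau_e is one to two orders of magnitude below tau_m, so
estimates for very fast cells (glia with tau_m under ~1 ms) carry a
documented bias; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import CurrentClampTrace, StepProtocol


class TraceRejected(ValueError):
    """Raised when a sweep fails the acceptance screen; ``reason`` names why."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"trace rejected ({reason})" + (f": {detail}" if detail else ""))


@dataclass
class FitConfig:
    """Tunable windows and thresholds of the passive-fit heuristic.

    The steady-state window, the 0.5 ms first-pass start, the 0.3 stop
    fraction and the 20 %-of-tau second-pass start define the heuristic
    itself; minimum point counts and the spike/sag screen thresholds are
    implementation choices exposed here.
    """

    baseline_min_s: float = 0.05
    baseline_window_s: float = 0.05
    ss_start_s: float = 0.100
    ss_stop_s: float = 0.200
    v_o_window_s: float = 0.002
    v_o_min_points: int = 8
    tau_first_start_s: float = 0.0005
    tau_stop_frac: float = 0.3
    tau_second_start_frac: float = 0.2
    min_log_points: int = 10
    max_nonpositive_frac: float = 0.2
    max_deflection_mv: float = 10.0
    min_deflection_snr: float = 5.0
    spike_dvdt_mv_ms: float = 10.0
    spike_amp_mv: float = 20.0
    sag_tol_mv: float = 2.0


@dataclass
class PassiveFitResult:
    """Per-trace passive parameters with fit diagnostics."""

    V_rest: float
    V_ss: float
    V_O: float
    tau0: float  # ms
    tau0_first_pass: float  # ms
    R_a_error: float  # MOhm
    R_in: float  # MOhm
    fit_window: Tuple[float, float]
    n_points: int
    r2_log_fit: float
    amplitude_na: float = float("nan")
    bridge_setting_mohm: Optional[float] = None
    rec_time_s: Optional[float] = None

    @property
    def polarity(self) -> str:
        return "depolarizing" if self.amplitude_na > 0 else "hyperpolarizing"

    @property
    def R_a_total(self) -> float:
        """Total access-resistance estimate: on-line bridge setting plus the
        off-line residual error (the residual alone when no setting is known)."""
        if self.bridge_setting_mohm is None:
            return self.R_a_error
        return self.bridge_setting_mohm + self.R_a_error


@dataclass
class CellPassive:
    """Cell-level passive parameters: unweighted means of accepted traces."""

    V_rest: float
    V_ss: float
    tau0: float
    R_a_error: float
    R_in: float
    R_a_mean: float
    dRa_dt: float  # MOhm/min
    n_traces: int
    results: List[PassiveFitResult] = field(default_factory=list)
    rejections: List[Tuple[str, str]] = field(default_factory=list)


def _window_has_spike(v: np.ndarray, dt: float, config: FitConfig) -> bool:
    if v.size < 3:
        return False
    dvdt = np.diff(v) / (dt * 1e3)  # mV/ms
    return bool(
        np.max(dvdt) > config.spike_dvdt_mv_ms
        and np.max(v) - np.median(v) > config.spike_amp_mv
    )


def estimate_v_rest(
    traces: Sequence[CurrentClampTrace],
    config: FitConfig = FitConfig(),
) -> float:
    """Resting potential: mean over pre-stimulus baseline windows, excluding
    windows that contain spontaneous spikes.

    Requires at least one trace with >= 50 ms of pre-stimulus baseline;
    raises if every window is rejected.
    """
    if isinstance(traces, CurrentClampTrace):
        traces = [traces]
    accepted = []
    usable = False
    for trace in traces:
        protocol = trace.protocol
        if not isinstance(protocol, StepProtocol):
            raise ValueError("v_rest estimation requires traces with a step protocol")
        n_base = int(round(protocol.onset_s * trace.sampling_rate))
        if n_base * trace.dt < config.baseline_min_s:
            continue
        usable = True
        win = max(int(round(config.baseline_window_s * trace.sampling_rate)), 8)
        baseline = trace.voltage[:n_base]
        for start in range(0, n_base - win + 1, win):
            seg = baseline[start:start + win]
            if not _window_has_spike(seg, trace.dt, config):
                accepted.append(seg)
    if not usable:
        raise ValueError("no trace provides the minimum 50 ms pre-stimulus baseline")
    if not accepted:
        raise ValueError("all baseline windows rejected (spiking activity)")
    return float(np.mean(np.concatenate(accepted)))


def estimate_v_ss(trace: CurrentClampTrace, protocol: Optional[StepProtocol] = None,
                  config: FitConfig = FitConfig()) -> float:
    """Steady-state voltage: average over [onset+100 ms, onset+200 ms)."""
    protocol = protocol or trace.protocol
    if protocol.duration_s < config.ss_stop_s:
        raise ValueError("step shorter than 200 ms: steady-state window undefined")
    i0 = int(round((protocol.onset_s + config.ss_start_s) * trace.sampling_rate))
    i1 = int(round((protocol.onset_s + config.ss_stop_s) * trace.sampling_rate))
    return float(np.mean(trace.voltage[i0:i1]))


def estimate_v_o(trace: CurrentClampTrace, onset_s: Optional[float] = None,
                 config: FitConfig = FitConfig()) -> float:
    """Voltage just before the step: cubic least-squares fit over the 2 ms
    preceding onset, evaluated at onset (absorbs rapid membrane fluctuation)."""
    if onset_s is None:
        onset_s = trace.protocol.onset_s
    i1 = int(round(onset_s * trace.sampling_rate))
    i0 = int(round((onset_s - config.v_o_window_s) * trace.sampling_rate))
    if i0 < 0:
        raise ValueError("fewer than 2 ms of pre-onset data for the V_O fit")
    if i1 - i0 < config.v_o_min_points:
        raise ValueError(f"V_O window holds fewer than {config.v_o_min_points} samples")
    t = (np.arange(i0, i1) * trace.dt) - onset_s
    coef = np.polynomial.polynomial.polyfit(t, trace.voltage[i0:i1], 3)
    return float(coef[0])  # polynomial evaluated at t = 0 (onset)


@dataclass
class TauFit:
    tau0_first: float
    tau0: float
    window: Tuple[float, float]
    n_points: int
    r2: float
    v_fit_onset: float  # single-exponential fit extrapolated to stimulus onset


def _log_linear_pass(t_rel, vprime, start_s, threshold, config):
    """One log-linear regression pass over [start_s, first crossing of
    vprime <= threshold); returns (tau_s, intercept_at_onset, n, r2, stop_s)."""
    after = t_rel >= start_s
    crossing = np.nonzero(after & (vprime <= threshold))[0]
    if crossing.size == 0:
        raise ValueError("stop criterion never reached: V' did not decay to 0.3 of the deflection")
    stop_idx = crossing[0]
    start_idx = int(np.argmax(after))
    # very fast cells can cross the stop threshold before the window opens;
    # extend the stop so the regression keeps its minimum point count (the
    # resulting estimate is biased for tau_m near tau_e, and documented so)
    stop_idx = max(stop_idx, min(start_idx + config.min_log_points, t_rel.size))
    sel = after & (np.arange(t_rel.size) < stop_idx)
    idx = np.nonzero(sel)[0]
    if idx.size == 0:
        raise ValueError("empty fit window (stop crossing precedes the start)")
    v_win = vprime[idx]
    positive = v_win > 0
    if np.count_nonzero(~positive) > config.max_nonpositive_frac * v_win.size:
        raise ValueError("more than 20% of V' samples non-positive in the fit window")
    idx = idx[positive]
    if idx.size < config.min_log_points:
        raise ValueError(
            f"fewer than {config.min_log_points} usable points for the log-linear fit"
        )
    res = stats.linregress(t_rel[idx], np.log(vprime[idx]))
    if res.slope >= 0:
        raise ValueError("non-decaying V': log-linear slope is not negative")
    tau_s = -1.0 / res.slope
    return tau_s, res.intercept, idx.size, float(res.rvalue**2), float(t_rel[stop_idx])


def fit_tau(
    trace: CurrentClampTrace,
    protocol: Optional[StepProtocol] = None,
    v_rest: Optional[float] = None,
    v_ss: Optional[float] = None,
    config: FitConfig = FitConfig(),
) -> TauFit:
    """Two-pass log-linear estimate of the membrane time constant.

    V' = (V_ss - V) for depolarizing steps, (V - V_ss) for hyperpolarizing
    ones.  Pass one regresses ln V' on t from 0.5 ms after onset (by then most
    of the electrode artifact has decayed) until V' first reaches
    0.3 |V_ss - V_rest|; pass two restarts the window at onset + 0.2 tau_first
    to better isolate the cell component.  The pass-two line extrapolated to
    onset gives the fitted response start used for the R_a error.
    """
    protocol = protocol or trace.protocol
    if v_rest is None:
        v_rest = estimate_v_rest([trace], config)
    if v_ss is None:
        v_ss = estimate_v_ss(trace, protocol, config)

    i_on = int(round(protocol.onset_s * trace.sampling_rate))
    n_base = i_on
    noise_sd = float(np.std(trace.voltage[:n_base])) if n_base > 1 else 0.0
    deflection = v_ss - v_rest
    if abs(deflection) <= config.min_deflection_snr * noise_sd:
        raise ValueError(
            f"deflection {deflection:.2f} mV below {config.min_deflection_snr}x the noise floor"
        )

    i_off = int(round((protocol.onset_s + protocol.duration_s) * trace.sampling_rate))
    v = trace.voltage[i_on:i_off]
    t_rel = np.arange(v.size) * trace.dt
    depol = protocol.amplitude_na > 0
    vprime = (v_ss - v) if depol else (v - v_ss)
    threshold = config.tau_stop_frac * abs(deflection)

    tau1_s, _, _, _, _ = _log_linear_pass(t_rel, vprime, config.tau_first_start_s, threshold, config)
    start2 = config.tau_second_start_frac * tau1_s
    tau2_s, intercept, n_pts, r2, stop_s = _log_linear_pass(t_rel, vprime, start2, threshold, config)

    vprime_onset = math.exp(intercept)
    v_fit_onset = (v_ss - vprime_onset) if depol else (v_ss + vprime_onset)
    return TauFit(
        tau0_first=tau1_s * 1e3,
        tau0=tau2_s * 1e3,
        window=(protocol.onset_s + start2, protocol.onset_s + stop_s),
        n_points=n_pts,
        r2=r2,
        v_fit_onset=v_fit_onset,
    )


def _screen(trace, protocol, v_rest, v_ss, tau1_ms, config):
    """Acceptance screen: steady state within +/-10 mV of rest, no spikes
    during the step, no sag.  Raises TraceRejected with a named reason."""
    if abs(v_ss - v_rest) > config.max_deflection_mv:
        raise TraceRejected(
            "deflection", f"steady state {v_ss - v_rest:+.1f} mV from rest exceeds "
            f"+/-{config.max_deflection_mv:g} mV"
        )
    i_on = int(round(protocol.onset_s * trace.sampling_rate))
    i_off = int(round((protocol.onset_s + protocol.duration_s) * trace.sampling_rate))
    v = trace.voltage[i_on:i_off]
    dvdt = np.diff(v) / (trace.dt * 1e3)
    envelope_top = max(v_rest, v_ss) + config.spike_amp_mv
    if np.any((dvdt > config.spike_dvdt_mv_ms) & (v[1:] > envelope_top)):
        raise TraceRejected("spike", "action potential during the step")
    # sag: non-monotonic approach, deviating beyond V_ss after 3 tau then
    # relaxing; judged on a 5 ms-smoothed trace so noise extremes over the
    # long late window cannot mimic a sag
    i_sag = i_on + int(round(3 * tau1_ms * 1e-3 * trace.sampling_rate))
    if i_sag < i_off - 2:
        late = trace.voltage[i_sag:i_off]
        win = max(int(round(5e-3 * trace.sampling_rate)), 1)
        if late.size > 2 * win:
            kernel = np.ones(win) / win
            late = np.convolve(late, kernel, mode="valid")
        if protocol.amplitude_na < 0:
            overshoot = v_ss - np.min(late)
            recovers = late[-1] > np.min(late) + config.sag_tol_mv / 2
        else:
            overshoot = np.max(late) - v_ss
            recovers = late[-1] < np.max(late) - config.sag_tol_mv / 2
        if overshoot > config.sag_tol_mv and recovers:
            raise TraceRejected("sag", f"non-monotonic approach ({overshoot:.1f} mV beyond V_ss)")


def fit_step_response(
    trace: CurrentClampTrace,
    protocol: Optional[StepProtocol] = None,
    v_rest: Optional[float] = None,
    config: FitConfig = FitConfig(),
) -> PassiveFitResult:
    """Full per-trace passive fit.

    The single-exponential fit extrapolated to onset is compared with the
    pre-step voltage V_O; the difference divided by the step amplitude is the
    on-line R_a compensation error.  V_ss adjusted by that error then gives
    R_in = (V_ss_adj - V_rest) / I.

    Raises :class:`TraceRejected` (with a named reason) when the sweep fails
    the acceptance screen.
    """
    protocol = protocol or trace.protocol
    if protocol is None or not isinstance(protocol, StepProtocol):
        raise ValueError("fit_step_response requires a step protocol")
    amp = protocol.amplitude_na
    if amp == 0:
        raise ValueError("zero stimulus amplitude: passive parameters undefined")
    if v_rest is None:
        v_rest = estimate_v_rest([trace], config)
    v_ss = estimate_v_ss(trace, protocol, config)
    v_o = estimate_v_o(trace, protocol.onset_s, config)
    tau = fit_tau(trace, protocol, v_rest, v_ss, config)
    _screen(trace, protocol, v_rest, v_ss, tau.tau0_first, config)

    r_a_error = (tau.v_fit_onset - v_o) / amp
    v_ss_adj = v_ss - amp * r_a_error
    r_in = (v_ss_adj - v_rest) / amp
    meta = trace.meta or {}
    return PassiveFitResult(
        V_rest=v_rest,
        V_ss=v_ss,
        V_O=v_o,
        tau0=tau.tau0,
        tau0_first_pass=tau.tau0_first,
        R_a_error=r_a_error,
        R_in=r_in,
        fit_window=tau.window,
        n_points=tau.n_points,
        r2_log_fit=tau.r2,
        amplitude_na=amp,
        bridge_setting_mohm=meta.get("bridge_setting_mohm"),
        rec_time_s=meta.get("rec_time_s"),
    )


def ra_trend(estimates: Sequence[Tuple[float, float]]) -> Tuple[float, float]:
    """Mean access resistance and its drift from (time_s, R_a) estimates.

    Ordinary least squares over time; the reported mean is the regression
    value at the mean time, which for OLS equals the arithmetic mean.  One
    point returns (value, nan); identical times with >= 2 points make the
    slope undefined and raise.
    """
    pts = list(estimates)
    if not pts:
        raise ValueError("no access-resistance estimates")
    t = np.asarray([p[0] for p in pts], dtype=float)
    r = np.asarray([p[1] for p in pts], dtype=float)
    if len(pts) == 1:
        return float(r[0]), float("nan")
    if np.ptp(t) == 0:
        raise ValueError("all estimates share one timestamp: slope undefined")
    res = stats.linregress(t, r)
    return float(np.mean(r)), float(res.slope * 60.0)  # MOhm/min


def aggregate_cell(results: Sequence[PassiveFitResult],
                   rejections: Sequence[Tuple[str, str]] = ()) -> CellPassive:
    """Cell-level values: unweighted means of the accepted traces' linear
    parameters, plus the access-resistance trend when times are recorded."""
    results = list(results)
    if not results:
        raise ValueError("zero accepted traces: cell parameters undefined")
    timed = [(res.rec_time_s, res.R_a_total) for res in results if res.rec_time_s is not None]
    if len(timed) >= 2 and np.ptp([t for t, _ in timed]) > 0:
        ra_mean, dra = ra_trend(timed)
    else:
        ra_mean = float(np.mean([res.R_a_total for res in results]))
        dra = float("nan")
    return CellPassive(
        V_rest=float(np.mean([r.V_rest for r in results])),
        V_ss=float(np.mean([r.V_ss for r in results])),
        tau0=float(np.mean([r.tau0 for r in results])),
        R_a_error=float(np.mean([r.R_a_error for r in results])),
        R_in=float(np.mean([r.R_in for r in results])),
        R_a_mean=ra_mean,
        dRa_dt=dra,
        n_traces=len(results),
        results=results,
        rejections=list(rejections),
    )


def fit_cell(traces: Sequence[CurrentClampTrace], config: FitConfig = FitConfig()) -> CellPassive:
    """Fit every sweep of one cell, pooling the accepted ones.

    V_rest is estimated jointly across all baselines first, then each sweep
    is fit against it; sweeps failing the screen are collected as
    (reason, detail) in ``rejections``.
    """
    traces = [tr for tr in traces if isinstance(tr.protocol, StepProtocol)]
    if not traces:
        raise ValueError("no step-protocol traces supplied")
    v_rest = estimate_v_rest(traces, config)
    accepted, rejections = [], []
    for tr in traces:
        try:
            accepted.append(fit_step_response(tr, v_rest=v_rest, config=config))
        except TraceRejected as exc:
            rejections.append((exc.reason, str(exc)))
        except ValueError as exc:
            rejections.append(("fit_error", str(exc)))
    if not accepted:
        raise ValueError(
            "zero accepted traces for this cell; rejections: "
            + "; ".join(r for r, _ in rejections)
        )
    return aggregate_cell(accepted, rejections)


__all__ = [
    "FitConfig",
    "PassiveFitResult",
    "CellPassive",
    "TauFit",
    "TraceRejected",
    "estimate_v_rest",
    "estimate_v_ss",
    "estimate_v_o",
    "fit_tau",
    "fit_step_response",
    "ra_trend",
    "aggregate_cell",
    "fit_cell",
]
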