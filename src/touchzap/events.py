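"""Per-pulse resistance tracking and access-event detection.

From a session log driven by the impedance-monitoring pulse train, this
module measures one total-resistance estimate per pulse, detects the touch
(small sustained resistance increase on cell contact), zaps (abrupt
resistance drops at strongly hyperpolarized pulse peaks, i.e. membrane
electroporation), resealing, and suction breaks (experimenter-annotated,
corroborated by the resistance trace), then classifies the session endpoint
as TZ, TZS, TS or FAIL.

Detection thresholds are qualitative in origin and live in
:class:`DetectionConfig`, not in code.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np

from .core import Annotation, Event, SessionLog


@dataclass
class DetectionConfig:
    """Thresholds for touch/zap/reseal/suction detection."""

    plateau_frac: float = 0.25          # last fraction of the on-phase averaged per pulse
    baseline_frac: float = 0.50         # last fraction of the preceding off-phase
    min_pulse_amp_na: float = 0.005     # below this a pulse carries no resistance information
    touch_baseline_pulses: int = 10
    touch_frac: float = 0.05            # relative rise over rolling baseline
    touch_sustain_pulses: int = 3
    unstable_frac: float = 0.20         # peak-to-peak-equivalent fluctuation that aborts
    zap_drop_frac: float = 0.40         # between-consecutive-pulses resistance drop
    zap_dc_shift_mv: float = 15.0       # DC shift toward E_rest corroborating a small drop
    zap_dc_min_drop_frac: float = 0.10  # minimum drop when DC-corroborated
    zap_peak_mv: float = -150.0         # pulse peak must be at least this hyperpolarized
    zap_full_amp_na: float = 1.0        # zaps only at (near) full monitoring amplitude
    zap_min_separation_s: float = 0.25  # distinct zaps cannot share a drop window
    max_zaps: int = 2
    reseal_growth_factor: float = 3.0   # growth over the post-zap level
    reseal_sustain_s: float = 1.0
    suction_corroborate_s: float = 0.5  # resistance drop must corroborate the annotation
    suction_drop_frac: float = 0.2


@dataclass
class ResistanceSeries:
    """One total-resistance estimate per monitoring pulse."""

    times: np.ndarray          # pulse start times (s)
    r_total: np.ndarray        # MOhm
    amplitude: np.ndarray      # per-pulse command deflection (nA)
    peak_mv: np.ndarray        # most hyperpolarized sample within the on-phase
    base_mv: np.ndarray = None  # off-phase baseline (DC) level per pulse

    def __post_init__(self):
        if self.base_mv is None:
            self.base_mv = np.zeros_like(np.asarray(self.times, dtype=float))

    def __len__(self):
        return self.times.size


@dataclass
class EndpointCall:
    """Endpoint classification of one session."""

    endpoint: str
    events: List[Event] = field(default_factory=list)
    T_zap: Optional[float] = None
    V_zap: Optional[float] = None
    reason: str = ""
    flags: Set[str] = field(default_factory=set)

    @property
    def zaps(self) -> List[Event]:
        return [e for e in self.events if e.kind == "zap"]


def pulse_resistance_series(log: SessionLog, config: DetectionConfig = DetectionConfig()) -> ResistanceSeries:
    """Per-pulse total resistance: (plateau - baseline deflection) / amplitude.

    The plateau is averaged over the last 25% of each on-phase and referenced
    to the last 25% of the preceding off-phase; the command deflection is
    measured from the current channel, so amplitude changes during the
    session are handled per pulse.  Raises when the log carries no pulse
    train or the command amplitude is zero throughout.
    """
    pt = log.pulse_train
    if pt is None:
        raise ValueError("session log carries no pulse-train annotation")
    n = log.voltage.size
    if n == 0:
        return ResistanceSeries(np.empty(0), np.empty(0), np.empty(0), np.empty(0), np.empty(0))
    dt = log.dt
    period, on_w = pt.period_s, pt.on_width_s
    times, r_tot, amps, peaks, bases = [], [], [], [], []
    any_nonzero = False
    k = 0
    while True:
        t_k = pt.start_s + k * period
        i0 = int(round(t_k / dt))
        i_on = int(round((t_k + on_w) / dt))
        if i_on > n or (pt.stop_s is not None and t_k >= pt.stop_s):
            break
        plat0 = i_on - max(int(round((i_on - i0) * config.plateau_frac)), 1)
        v_plat = float(np.mean(log.voltage[plat0:i_on]))
        i_plat = float(np.mean(log.current[plat0:i_on]))
        if k == 0:
            j0, j1 = i_on, min(int(round((t_k + period) / dt)), n)
            j0 = j1 - max(int(round((j1 - j0) * config.baseline_frac)), 1)
        else:
            j1 = i0
            j0 = j1 - max(int(round((period - on_w) / dt * config.baseline_frac)), 1)
        if j0 < 0 or j1 > n or j1 <= j0:
            break
        v_base = float(np.mean(log.voltage[j0:j1]))
        i_base = float(np.mean(log.current[j0:j1]))
        amp = i_plat - i_base
        if abs(amp) >= config.min_pulse_amp_na:
            any_nonzero = True
            times.append(t_k)
            r_tot.append((v_plat - v_base) / amp)
            amps.append(amp)
            peaks.append(float(np.min(log.voltage[i0:i_on])))
            bases.append(v_base)
        k += 1
    if k > 0 and not any_nonzero:
        raise ValueError("pulse amplitude is zero throughout: resistance undefined")
    return ResistanceSeries(np.asarray(times), np.asarray(r_tot), np.asarray(amps),
                            np.asarray(peaks), np.asarray(bases))


def detect_touch(
    series: ResistanceSeries,
    config: DetectionConfig = DetectionConfig(),
) -> Tuple[Optional[Event], Set[str]]:
    """First sustained resistance increase over the rolling baseline.

    The touch is called at the first pulse whose resistance exceeds the
    rolling-median baseline by >= 5%, sustained for >= 3 pulses; the recorded
    value is the median resistance rise.  If the baseline fluctuates by more
    than ~20% peak-to-peak (cardiac/movement artifact, blocked tip), the
    attempt is flagged "unstable" instead and no touch is returned.

    Returns ``(event_or_None, quality_flags)``; requires >= 10 baseline
    pulses.
    """
    nb = config.touch_baseline_pulses
    if len(series) < nb + config.touch_sustain_pulses:
        raise ValueError(f"need at least {nb} baseline pulses before touch detection")
    r = series.r_total
    flags: Set[str] = set()
    touch = None
    k_touch = len(series)
    for k in range(nb, len(series) - config.touch_sustain_pulses + 1):
        window = r[k - nb:k]
        med = float(np.median(window))
        if med <= 0:
            continue
        threshold = med * (1.0 + config.touch_frac)
        run = r[k:k + config.touch_sustain_pulses]
        if np.all(run >= threshold):
            touch = Event(float(series.times[k]), "touch", float(np.median(run) - med))
            k_touch = k
            break
    # electrode stability over the pre-touch stretch: a persistent
    # (cardiac/movement) oscillation is judged by its sd-based peak-to-peak
    # equivalent (2*sqrt(2)*sd for a sinusoid), on a median-of-3 smoothed
    # series whose ~0.8x attenuation of slow artifacts is undone, so that
    # isolated noisy pulses do not mimic an artifact
    seg = r[:k_touch]
    med = float(np.median(seg)) if seg.size else 0.0
    if seg.size >= nb and med > 0:
        rel = seg / med - 1.0
        smooth = np.array([np.median(rel[max(j - 1, 0):j + 2]) for j in range(rel.size)])
        pp_equiv = 2.0 * math.sqrt(2.0) * float(np.std(smooth)) / 0.81
        if pp_equiv >= config.unstable_frac:
            flags.add("unstable")
            return None, flags
    return touch, flags


def detect_zaps(
    log: SessionLog,
    series: ResistanceSeries,
    config: DetectionConfig = DetectionConfig(),
) -> List[Event]:
    """Electroporation events: abrupt drops in per-pulse resistance.

    A zap is a >= 40% drop between consecutive pulses while the monitoring
    command is at (near) full amplitude and the pulse peak is at least
    -150 mV.  A smaller drop (>= 10%) also counts when the off-phase DC
    level shifts by >= 15 mV toward the cell's resting potential right after
    it -- the signature of whole-cell access in a cell whose input
    resistance is close to the seal resistance at breakdown.  V_zap is the
    most hyperpolarized voltage sample over the pulse pair spanning the drop
    (electroporation may truncate the second pulse of the pair mid-rise, in
    which case the extreme lives there rather than in the preceding pulse).
    Drops within 0.5 s of a suction annotation belong to the suction, not to
    a zap.  Up to two zaps are reported.
    """
    out: List[Event] = []
    suctions = [a.time_s for a in log.annotations_of("suction")]
    r = series.r_total
    dt = log.dt
    pt = log.pulse_train
    k = 0
    while k < len(series) - 1 and len(out) < config.max_zaps:
        if r[k] <= 0 or abs(series.amplitude[k]) < config.zap_full_amp_na:
            k += 1
            continue
        if out and series.times[k] < out[-1].time_s + config.zap_min_separation_s:
            k += 1
            continue
        def dc_shift_after(j):
            look = series.base_mv[j + 1:j + 4]
            if look.size == 0:
                return 0.0
            return float(np.min(look) - series.base_mv[max(k - 1, 0)])

        def is_drop(frac, j):
            if frac >= config.zap_drop_frac:
                return True
            return (frac >= config.zap_dc_min_drop_frac
                    and dc_shift_after(j) <= -config.zap_dc_shift_mv)

        # electroporation inside a plateau window leaves one mixed-value
        # pulse; allow the drop to complete over two pulses in that case
        span = None
        if is_drop((r[k] - r[k + 1]) / r[k], k + 1):
            span = k + 1
        elif (
            k + 2 < len(series)
            and r[k + 1] < r[k]
            and is_drop((r[k] - r[k + 2]) / r[k], k + 2)
        ):
            span = k + 2
        if span is None:
            k += 1
            continue
        if float(np.min(series.peak_mv[k:span + 1])) > config.zap_peak_mv:
            k += 1
            continue
        t_pair0 = series.times[k]
        t_pair1 = series.times[span] + pt.on_width_s
        if any(t_pair0 - config.suction_corroborate_s <= s <= t_pair1 + config.suction_corroborate_s
               for s in suctions):
            k = span
            continue
        i0 = int(round(t_pair0 / dt))
        i1 = min(int(round(t_pair1 / dt)), log.voltage.size)
        j = int(np.argmin(log.voltage[i0:i1]))
        out.append(Event(float((i0 + j) * dt), "zap", float(log.voltage[i0 + j])))
        k = span
    return out


def detect_reseal(
    series: ResistanceSeries,
    zaps: Sequence[Event],
    config: DetectionConfig = DetectionConfig(),
    before_s: Optional[float] = None,
) -> Optional[Event]:
    """Post-zap seal reformation: resistance growth to >= 3x the post-zap
    level, sustained for >= 1 s (before ``before_s`` when given)."""
    if not zaps:
        return None
    t_last = max(e.time_s for e in zaps)
    after = series.times > t_last
    if before_s is not None:
        after &= series.times < before_s - 1e-9
    idx = np.nonzero(after)[0]
    if idx.size < 3:
        return None
    # reference level: settled whole-cell resistance, measured over a window
    # that skips the immediate post-zap transient (second-zap regrowth, DC
    # settling) and is robust to the start of resealing itself
    ref = (series.times > t_last + 0.5) & (series.times <= t_last + 2.5)
    if before_s is not None:
        ref &= series.times < before_s - 1e-9
    level = float(np.median(series.r_total[ref])) if np.any(ref) else float(
        np.median(series.r_total[idx[:5]])
    )
    if level <= 0:
        return None
    period = float(np.median(np.diff(series.times))) if len(series) > 1 else 0.1
    sustain = max(int(round(config.reseal_sustain_s / period)), 1)
    threshold = config.reseal_growth_factor * level
    above = series.r_total[idx] >= threshold
    for j in range(above.size - sustain + 1):
        if np.all(above[j:j + sustain]):
            k = idx[j]
            return Event(float(series.times[k]), "reseal", float(series.r_total[k]))
    return None


def detect_suction_break(
    log: SessionLog,
    series: ResistanceSeries,
    config: DetectionConfig = DetectionConfig(),
) -> Optional[Event]:
    """Suction-driven access: taken from the experimenter annotation, kept
    only when a resistance drop corroborates it within 0.5 s."""
    for ann in log.annotations_of("suction"):
        t = ann.time_s
        before = series.r_total[(series.times >= t - 1.0) & (series.times < t)]
        after = series.r_total[(series.times > t) & (series.times <= t + 1.0)]
        if before.size == 0 or after.size == 0:
            continue
        r0, r1 = float(np.median(before)), float(np.median(after))
        if r0 > 0 and (r0 - r1) / r0 >= config.suction_drop_frac:
            return Event(t, "suction_break", r1)
    return None


def measure_zap_timing(events: Sequence[Event], annotations: Sequence[Annotation]) -> Optional[float]:
    """Zap delay T_zap: time from pressure release to the first zap.

    Returns None when the session has no zap; raises when the release
    annotation is missing or follows the zap (ordering violation).
    """
    zaps = sorted((e for e in events if e.kind == "zap"), key=lambda e: e.time_s)
    if not zaps:
        return None
    releases = [a.time_s for a in annotations if a.kind == "pressure_release"]
    if not releases:
        raise ValueError("no pressure_release annotation: T_zap undefined")
    release = min(releases)
    if zaps[0].time_s < release:
        raise ValueError("ordering: first zap precedes the pressure release")
    return zaps[0].time_s - release


def classify_endpoint(
    events: Sequence[Event],
    annotations: Sequence[Annotation] = (),
) -> EndpointCall:
    """Classify the access endpoint from the time-ordered event list.

    TZ: zap(s), no reseal, no suction break.  TZS: zap, then reseal, then
    suction break.  TS: no zap, a seal (touch) followed by a suction break.
    Everything else, including contradictory orderings, is FAIL with a named
    reason.
    """
    evs = sorted(events, key=lambda e: e.time_s)
    touches = [e for e in evs if e.kind == "touch"]
    zaps = [e for e in evs if e.kind == "zap"]
    reseals = [e for e in evs if e.kind == "reseal"]
    suctions = [e for e in evs if e.kind == "suction_break"]

    t_zap = None
    if zaps and any(a.kind == "pressure_release" for a in annotations):
        try:
            t_zap = measure_zap_timing(evs, annotations)
        except ValueError:
            t_zap = None
    v_zap = zaps[0].value if zaps else None

    def call(endpoint, reason=""):
        return EndpointCall(endpoint, evs, t_zap, v_zap, reason)

    if suctions and touches and suctions[0].time_s < touches[0].time_s:
        return call("FAIL", "contradictory sequence: suction break precedes the touch")
    if suctions and not touches and not zaps:
        return call("FAIL", "suction break without a preceding seal")
    if zaps:
        if not reseals and not suctions:
            return call("TZ")
        if reseals and suctions and zaps[0].time_s < reseals[0].time_s < suctions[0].time_s:
            return call("TZS")
        return call("FAIL", "zap followed by an inconsistent reseal/suction sequence")
    if suctions and touches:
        return call("TS")
    if touches:
        return call("FAIL", "touch without whole-cell access")
    return call("FAIL", "no cell contact detected")


def analyze_session(log: SessionLog, config: DetectionConfig = DetectionConfig()) -> EndpointCall:
    """Full detection pipeline for one session log.

    Builds the per-pulse resistance series, detects touch, zaps, reseal and
    suction break, classifies the endpoint, and attaches quality flags
    ("unstable" for >= 20% baseline fluctuation, which aborts the attempt).
    The detected events are also appended to ``log.events``.
    """
    series = pulse_resistance_series(log, config)
    touch, flags = detect_touch(series, config)
    events: List[Event] = []
    if touch is not None:
        events.append(touch)
    if "unstable" not in flags:
        zaps = detect_zaps(log, series, config)
        events.extend(zaps)
        suction = detect_suction_break(log, series, config)
        reseal = detect_reseal(series, zaps, config,
                               before_s=suction.time_s if suction else None)
        if reseal is not None:
            events.append(reseal)
        if suction is not None:
            events.append(suction)
    call = classify_endpoint(events, log.annotations)
    call.flags |= flags
    if "unstable" in flags:
        call.reason = (call.reason + "; " if call.reason else "") + "attempt aborted: unstable electrode resistance"
    log.events = sorted(events, key=lambda e: e.time_s)
    return call


__all__ = [
    "DetectionConfig",
    "ResistanceSeries",
    "EndpointCall",
    "pulse_resistance_series",
    "detect_touch",
    "detect_zaps",
    "detect_reseal",
    "detect_suction_break",
    "measure_zap_timing",
    "classify_endpoint",
    "analyze_session",
]
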