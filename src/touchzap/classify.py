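"""Cell classification (neuron / glia / unclassified), spike metrics, and
recording-quality rules.

A cell is a neuron when any current-evoked action potential reaches 50 mV in
amplitude measured from rest; a cell with no spikes and a membrane time
constant under 5 ms is a putative glial cell; everything else is left
unclassified.  The four-way firing-pattern taxonomy (regular-spiking,
fast-spiking, intrinsic-bursting, chattering) is an external label carried
through, never computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Set, Tuple

import numpy as np

from .core import CurrentClampTrace, StepProtocol
from .passive import CellPassive

QC_FLAGS = frozenset({"high_Ra", "Ra_drift", "Vrest_drift", "movement", "excluded_Rin"})


@dataclass
class ClassifyConfig:
    """Spike-detection and classification thresholds.

    Only the 50 mV amplitude criterion and the 5 ms glial time-constant bound
    define the classification; the crossing threshold and refractory period
    are implementation choices for locating spikes.
    """

    spike_threshold_above_rest_mv: float = 20.0
    refractory_ms: float = 1.0
    neuron_spike_amp_mv: float = 50.0
    glia_tau_max_ms: float = 5.0


@dataclass
class QCConfig:
    high_ra_mohm: float = 50.0
    ra_drift_factor: float = 1.5
    vrest_drift_mv: float = 20.0
    rin_exclude_mohm: float = 500_000.0  # 500 GOhm
    movement_artifact_mv: float = 5.0


@dataclass
class CellRecord:
    """One recorded cell: the row type of cohort tables."""

    cell_id: str
    species: str = ""
    cell_class: str = "unclassified"
    firing_label: str = ""  # external taxonomy, supplied not computed
    passive: Optional[CellPassive] = None
    spike_dvdt_max: float = float("nan")
    spike_v_peak: float = float("nan")
    endpoint: str = ""
    qc_flags: Set[str] = field(default_factory=set)
    duration_min: float = float("nan")
    depth_um: float = float("nan")

    def __post_init__(self):
        unknown = self.qc_flags - QC_FLAGS
        if unknown:
            raise ValueError(f"unknown qc flags: {sorted(unknown)}")

    def to_row(self) -> dict:
        p = self.passive
        return dict(
            cell_id=self.cell_id,
            species=self.species,
            cell_class=self.cell_class,
            firing_label=self.firing_label,
            endpoint=self.endpoint,
            V_rest=p.V_rest if p else float("nan"),
            tau0=p.tau0 if p else float("nan"),
            R_in=p.R_in if p else float("nan"),
            R_a=p.R_a_mean if p else float("nan"),
            R_a_error=p.R_a_error if p else float("nan"),
            dRa_dt=p.dRa_dt if p else float("nan"),
            n_traces=p.n_traces if p else 0,
            spike_dvdt_max=self.spike_dvdt_max,
            spike_v_peak=self.spike_v_peak,
            qc_flags="|".join(sorted(self.qc_flags)),
            duration_min=self.duration_min,
            depth_um=self.depth_um,
        )


def detect_spikes(
    trace: CurrentClampTrace,
    v_rest: float,
    config: ClassifyConfig = ClassifyConfig(),
    window: Optional[Tuple[float, float]] = None,
) -> np.ndarray:
    """Spike peak indices: upward crossings of V_rest + 20 mV with a 1 ms
    refractory period; the peak is the sample maximum of each suprathreshold
    excursion.  ``window`` restricts the search to a time interval."""
    v = trace.voltage
    thr = v_rest + config.spike_threshold_above_rest_mv
    above = v > thr
    if window is not None:
        i0 = int(round(window[0] * trace.sampling_rate))
        i1 = int(round(window[1] * trace.sampling_rate))
        mask = np.zeros(v.size, dtype=bool)
        mask[i0:i1] = True
        above &= mask
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    refractory = int(round(config.refractory_ms * 1e-3 * trace.sampling_rate))
    # crossings whose excursions fall within one refractory period belong to
    # one spike (noise chatters around the threshold just before the upstroke)
    peaks = []
    group_start = None
    group_end = -np.inf
    for c in crossings:
        end = c
        while end < v.size and above[end]:
            end += 1
        if group_start is not None and c - group_end < refractory:
            group_end = max(group_end, end)
            continue
        if group_start is not None:
            peaks.append(group_start + int(np.argmax(v[group_start:group_end])))
        group_start, group_end = c, end
    if group_start is not None:
        peaks.append(group_start + int(np.argmax(v[group_start:group_end])))
    return np.asarray(peaks, dtype=int)


def spike_metrics(
    trace: CurrentClampTrace,
    protocol: Optional[StepProtocol] = None,
    v_rest: Optional[float] = None,
    config: ClassifyConfig = ClassifyConfig(),
) -> Tuple[float, float]:
    """Maximum depolarization rate (mV/ms) and absolute peak voltage (mV) of
    current-evoked action potentials, averaged over the detected spikes.

    The derivative is the per-sample finite difference within a +/-2 ms
    window around each spike peak.  Raises when the step evokes no spike.
    """
    protocol = protocol or trace.protocol
    if v_rest is None:
        base = trace.voltage[: int(round(protocol.onset_s * trace.sampling_rate))]
        v_rest = float(np.mean(base))
    window = (protocol.onset_s, protocol.onset_s + protocol.duration_s)
    peaks = detect_spikes(trace, v_rest, config, window)
    if peaks.size == 0:
        raise ValueError("no current-evoked spikes in this sweep")
    half = int(round(2e-3 * trace.sampling_rate))
    dvdt_list, peak_list = [], []
    for p in peaks:
        lo, hi = max(p - half, 1), min(p + half, trace.voltage.size)
        seg = trace.voltage[lo - 1:hi]
        dvdt = np.diff(seg) * trace.sampling_rate / 1e3
        dvdt_list.append(float(np.max(dvdt)))
        peak_list.append(float(trace.voltage[p]))
    return float(np.mean(dvdt_list)), float(np.mean(peak_list))


def classify_cell(
    traces: Sequence[CurrentClampTrace],
    passive: CellPassive,
    config: ClassifyConfig = ClassifyConfig(),
) -> str:
    """neuron / glia / unclassified from evoked spikes and tau0.

    Neuron: any current-evoked spike of >= 50 mV amplitude from rest.
    Glia: no spikes anywhere and tau0 < 5 ms.  Otherwise unclassified.
    """
    steps = [tr for tr in traces if isinstance(tr.protocol, StepProtocol)]
    if not steps:
        raise ValueError("classification requires at least one step-protocol trace")
    any_spike = False
    for tr in steps:
        pr = tr.protocol
        peaks = detect_spikes(tr, passive.V_rest, config,
                              (pr.onset_s, pr.onset_s + pr.duration_s))
        if peaks.size == 0:
            continue
        any_spike = True
        amp = float(np.max(tr.voltage[peaks])) - passive.V_rest
        if amp >= config.neuron_spike_amp_mv:
            return "neuron"
    if not any_spike and passive.tau0 < config.glia_tau_max_ms:
        return "glia"
    return "unclassified"


def qc_evaluate(
    ra_series: Sequence[float] = (),
    vrest_series: Sequence[float] = (),
    r_in: Optional[float] = None,
    movement_artifact_mv: Optional[float] = None,
    config: QCConfig = QCConfig(),
) -> Set[str]:
    """Recording-quality flags from time-ordered R_a and V_rest series.

    high_Ra: initial R_a above 50 MOhm (recording abandoned after one IV
    protocol).  Ra_drift: any estimate above 1.5x the initial value.
    Vrest_drift: resting potential strayed more than ~20 mV.  excluded_Rin:
    input resistance above 500 GOhm (non-physiological seal remnant).
    Flags are monotone: later, worse samples only ever add flags.
    """
    flags: Set[str] = set()
    ra = list(ra_series)
    if ra:
        if ra[0] > config.high_ra_mohm:
            flags.add("high_Ra")
        if any(x > config.ra_drift_factor * ra[0] for x in ra[1:]):
            flags.add("Ra_drift")
    vr = list(vrest_series)
    if vr and any(abs(x - vr[0]) > config.vrest_drift_mv for x in vr[1:]):
        flags.add("Vrest_drift")
    if r_in is not None and r_in > config.rin_exclude_mohm:
        flags.add("excluded_Rin")
    if movement_artifact_mv is not None and movement_artifact_mv > config.movement_artifact_mv:
        flags.add("movement")
    return flags


def corrected_depth(depth_um: float, angle_deg: float) -> float:
    """Cortical depth corrected for the oblique electrode trajectory
    (depth x cos(angle)).  Reported as a helper only; the raw trajectory
    length is what gets stored."""
    return depth_um * math.cos(math.radians(angle_deg))


__all__ = [
    "QC_FLAGS",
    "ClassifyConfig",
    "QCConfig",
    "CellRecord",
    "detect_spikes",
    "spike_metrics",
    "classify_cell",
    "qc_evaluate",
    "corrected_depth",
]
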