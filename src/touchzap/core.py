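"""Core containers for current-clamp recordings and session logs.

Unit conventions used throughout the package: time in seconds, voltage in
mV, current in nA, resistance in MOhm (so V = I*R holds in mV = nA*MOhm),
time constants in ms where the field convention is ms (tau_e, tau_m).
Sample intervals are half-open [t, t + dt).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

#: closed set of detected-event kinds
EVENT_KINDS = frozenset({"touch", "zap", "reseal", "suction_break"})

#: closed set of experimenter-annotation kinds
ANNOTATION_KINDS = frozenset({"pressure_release", "suction", "current_change", "note"})


@dataclass(frozen=True)
class StepProtocol:
    """A square current step for passive-parameter (IV) protocols.

    The 0.5 s default duration leaves a 100-200 ms post-onset window for the
    steady-state estimate and a long tail for the charging fit.
    """

    onset_s: float
    duration_s: float = 0.5
    amplitude_na: float = -0.1
    inter_sweep_s: float = 1.0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("step duration must be positive")
        if self.onset_s <= 0:
            raise ValueError("step onset must be positive (a pre-stimulus baseline is required)")


@dataclass(frozen=True)
class PulseTrain:
    """Square pulse train used to monitor electrode impedance during the
    approach: 10 Hz, 50% duty cycle, alternating between 0 and -1.11 nA."""

    frequency_hz: float = 10.0
    duty: float = 0.5
    amplitude_na: float = -1.11
    start_s: float = 0.0
    stop_s: Optional[float] = None

    def __post_init__(self):
        if self.frequency_hz <= 0 or not (0 < self.duty < 1):
            raise ValueError("pulse train requires frequency > 0 and 0 < duty < 1")

    @property
    def period_s(self) -> float:
        return 1.0 / self.frequency_hz

    @property
    def on_width_s(self) -> float:
        return self.duty / self.frequency_hz


Protocol = Union[StepProtocol, PulseTrain]


@dataclass(frozen=True)
class Event:
    """A detected (or ground-truth) event in a session log.

    ``value`` is kind-specific: resistance increase in MOhm for a touch,
    peak hyperpolarization V_zap in mV for a zap, post-drop resistance in
    MOhm for reseal/suction_break.
    """

    time_s: float
    kind: str
    value: Optional[float] = None

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected one of {sorted(EVENT_KINDS)}")
        if self.kind == "zap":
            if self.value is None:
                raise ValueError("zap events must carry a V_zap value")
            if self.value >= 0:
                raise ValueError("zap events must carry V_zap < 0 (mV)")


@dataclass(frozen=True)
class Annotation:
    """An experimenter annotation (time-stamped action or note)."""

    time_s: float
    kind: str
    value: str = ""

    def __post_init__(self):
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(
                f"unknown annotation kind {self.kind!r}; expected one of {sorted(ANNOTATION_KINDS)}"
            )


@dataclass
class CurrentClampTrace:
    """One sampled current-clamp sweep: voltage (mV) and command current (nA).

    ``meta`` carries acquisition metadata: filter_cutoff_hz, tip_offset_mv,
    tip_offset_applied, bridge_setting_mohm, depth_um, species, cell_id.
    """

    sampling_rate: float
    voltage: np.ndarray
    current: np.ndarray
    protocol: Optional[Protocol] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.voltage.shape != self.current.shape:
            raise ValueError("voltage and current must have equal length")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.voltage.size) * self.dt

    @property
    def duration_s(self) -> float:
        return self.voltage.size * self.dt

    def copy(self) -> "CurrentClampTrace":
        return CurrentClampTrace(
            self.sampling_rate,
            self.voltage.copy(),
            self.current.copy(),
            self.protocol,
            dict(self.meta),
        )


@dataclass
class SessionLog:
    """Continuous voltage/current log of one approach-and-access attempt.

    ``annotations`` are experimenter actions (pressure release, suction,
    current changes); ``events`` holds detected events; ``truth_events``
    holds the simulator's ground truth when the log is synthetic.
    """

    sampling_rate: float
    voltage: np.ndarray
    current: np.ndarray
    pulse_train: Optional[PulseTrain] = None
    annotations: list = field(default_factory=list)
    events: list = field(default_factory=list)
    truth_events: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.voltage.shape != self.current.shape:
            raise ValueError("voltage and current must have equal length")
        span = self.duration_s
        for ann in self.annotations:
            if not (0.0 <= ann.time_s <= span):
                raise ValueError(f"annotation at {ann.time_s} s outside log span [0, {span:.3f}] s")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.voltage.size) * self.dt

    @property
    def duration_s(self) -> float:
        return self.voltage.size * self.dt

    def annotations_of(self, kind: str) -> list:
        return [a for a in self.annotations if a.kind == kind]


__all__ = [
    "EVENT_KINDS",
    "ANNOTATION_KINDS",
    "StepProtocol",
    "PulseTrain",
    "Event",
    "Annotation",
    "CurrentClampTrace",
    "SessionLog",
    "replace",
]
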