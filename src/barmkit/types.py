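"""Core data containers shared across the simulation and analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

CHANNELS = ("h", "v", "t")


@dataclass
class EyeTraceBlock:
    """One experimental block of binocular 3D eye-position data.

    Attributes
    ----------
    time : array of s, strictly increasing, uniform at 1/sampling_rate
    left, right : dict channel -> array of deg ('h', 'v', 't'); samples that
        are invalid in the video modality are NaN
    valid_left, valid_right : boolean per sample
    phase_label : per-sample experimental phase, one of dark1/flow1/dark2/flow2
    stimulus_state : per-sample, one of off/flow_cw/flow_ccw/blanked
    modality : 'video' or 'coil'
    """

    time: np.ndarray
    left: dict
    right: dict
    valid_left: np.ndarray
    valid_right: np.ndarray
    phase_label: np.ndarray
    stimulus_state: np.ndarray
    modality: str
    sampling_rate: float

    def __post_init__(self):
        n = len(self.time)
        arrays = [self.valid_left, self.valid_right, self.phase_label, self.stimulus_state]
        arrays += [self.left[c] for c in CHANNELS] + [self.right[c] for c in CHANNELS]
        if any(len(a) != n for a in arrays):
            raise ValueError("all per-sample arrays must share the time axis length")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def eye(self, which: str) -> dict:
        if which == "left":
            return self.left
        if which == "right":
            return self.right
        raise ValueError(f"unknown eye {which!r}")

    def phase_mask(self, phase: str) -> np.ndarray:
        """Boolean mask of samples in the given phase; 'flow' matches both."""
        if phase == "flow":
            return (self.phase_label == "flow1") | (self.phase_label == "flow2")
        if phase == "dark":
            return (self.phase_label == "dark1") | (self.phase_label == "dark2")
        return self.phase_label == phase

    def index_at_time(self, t: float) -> int:
        return int(round((t - self.time[0]) * self.sampling_rate))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "eyeL_h": self.left["h"],
                "eyeL_v": self.left["v"],
                "eyeL_t": self.left["t"],
                "eyeR_h": self.right["h"],
                "eyeR_v": self.right["v"],
                "eyeR_t": self.right["t"],
                "valid_L": self.valid_left.astype(int),
                "valid_R": self.valid_right.astype(int),
                "phase": self.phase_label,
                "stimulus_state": self.stimulus_state,
            }
        )


@dataclass
class BlinkRecord:
    """Ground-truth description of one simulated blink."""

    onset_time: float
    offset_time: float
    phase: str
    #: pre-blink latent torsion at blink onset (the quantity the gain acts on)
    torsion_at_onset: float
    #: commanded resetting displacement, gain * torsion_at_onset + noise
    commanded_shift: float
    #: effective gain that was applied (phase gain x within-phase modulation)
    gain_applied: float
    #: latent torsion at the safety read times (140 ms before onset,
    #: 200 ms after offset); their difference is what a noiseless
    #: measurement recovers exactly
    torsion_at_pre_read: float
    torsion_at_post_read: float
    h_shift: float = 0.0
    v_shift: float = 0.0
    #: torsion change from the end of the preceding fast phase to blink onset
    preceding_slow_amplitude: Optional[float] = None
    comp1_amplitude: float = 0.0
    comp1_peak_latency: float = 0.0  # s after onset
    comp2_latency: float = 0.0  # s after comp1 peak

    @property
    def duration(self) -> float:
        return self.offset_time - self.onset_time

    @property
    def true_shift(self) -> float:
        """Latent torsional shift between the safety read times."""
        return self.torsion_at_post_read - self.torsion_at_pre_read


@dataclass
class FastPhaseRecord:
    onset_time: float
    offset_time: float
    amplitude: float  # signed torsional displacement
    preceding_slow_amplitude: float
    torsion_at_onset: float
    phase: str


@dataclass
class GroundTruthLog:
    """Event log written by the generator; the oracle for every stage."""

    blinks: list = field(default_factory=list)
    fast_phases: list = field(default_factory=list)
    blanks: list = field(default_factory=list)  # (onset, duration) tuples
    gains_by_phase: dict = field(default_factory=dict)
    plateau: float = 0.0
    slow_phase_velocity: float = 0.0
    flow_direction: str = "cw"

    def check_within(self, t0: float, t1: float) -> None:
        for b in self.blinks:
            if not (t0 <= b.onset_time and b.offset_time <= t1):
                raise ValueError("blink event outside block time range")
        for f in self.fast_phases:
            if not (t0 <= f.onset_time and f.offset_time <= t1):
                raise ValueError("fast-phase event outside block time range")
        for onset, dur in self.blanks:
            if not (t0 <= onset and onset + dur <= t1):
                raise ValueError("blank event outside block time range")


@dataclass
class BlinkEvent:
    """A detected blink: a maximal binocular dropout run with safety reads."""

    onset_index: int
    offset_index: int
    onset_time: float
    offset_time: float
    duration_ms: float
    pre_position: Optional[tuple]  # (h, v, t) at 140 ms before onset
    post_position: Optional[tuple]  # (h, v, t) at 200 ms after offset
    phase_label: str
    eye: str = "right"
    usable: bool = True
    #: sample indices at which the pre/post positions were read
    pre_index: Optional[int] = None
    post_index: Optional[int] = None


@dataclass
class NystagmusPhase:
    kind: str  # 'slow' or 'fast'
    onset_index: int
    offset_index: int
    onset_time: float
    offset_time: float
    torsional_amplitude: float  # position at offset - position at onset
    pre_shift_position: float  # torsion at onset
    direction: int  # sign of the amplitude
    phase_label: str
    peak_velocity: Optional[float] = None  # deg/s, fast phases only
    preceding_slow_amplitude: Optional[float] = None  # fast phases only

    @property
    def duration(self) -> float:
        return self.offset_time - self.onset_time

    @property
    def mean_speed(self) -> float:
        """Mean unsigned torsional velocity over the interval."""
        return abs(self.torsional_amplitude) / self.duration


@dataclass
class BarmMeasurement:
    torsional_shift: float
    h_shift: float
    v_shift: float
    pre_blink_position: tuple  # (h, v, t)
    preceding_slow_amplitude: Optional[float]
    phase_label: str
    flow_direction: str
    blink_duration_ms: float
    first_of_phase: bool = False

    @property
    def pre_blink_torsion(self) -> float:
        return self.pre_blink_position[2]


@dataclass
class CoilBlinkComponents:
    comp1_peak_time: float  # ms from blink onset
    comp1_torsional_amplitude: float  # deg, signed (extorsional positive)
    comp1_hv_displacement: tuple  # (h, v) deg
    comp2_peak_velocity_time: Optional[float]  # ms after comp1 peak
    comp2_amplitude: Optional[float]  # deg, signed net torsional displacement
    comp2_peak_velocity: Optional[float]  # deg/s, signed
    merged: bool = False
    usable: bool = True
    phase_label: str = ""
    #: True when no further movement occurs between the end of the second
    #: component and the post-blink safety read, i.e. a video-style pre/post
    #: measurement of this blink is uncontaminated
    clean_read: bool = True


def blinks_to_frame(blinks) -> pd.DataFrame:
    rows = []
    for b in blinks:
        rows.append(
            {
                "onset_index": b.onset_index,
                "offset_index": b.offset_index,
                "onset_time": b.onset_time,
                "offset_time": b.offset_time,
                "duration_ms": b.duration_ms,
                "phase": b.phase_label,
                "usable": b.usable,
                "pre_h": b.pre_position[0] if b.pre_position else np.nan,
                "pre_v": b.pre_position[1] if b.pre_position else np.nan,
                "pre_t": b.pre_position[2] if b.pre_position else np.nan,
                "post_h": b.post_position[0] if b.post_position else np.nan,
                "post_v": b.post_position[1] if b.post_position else np.nan,
                "post_t": b.post_position[2] if b.post_position else np.nan,
            }
        )
    return pd.DataFrame(rows)


def measurements_to_frame(measurements) -> pd.DataFrame:
    rows = []
    for m in measurements:
        rows.append(
            {
                "torsional_shift": m.torsional_shift,
                "h_shift": m.h_shift,
                "v_shift": m.v_shift,
                "pre_blink_torsion": m.pre_blink_torsion,
                "pre_blink_h": m.pre_blink_position[0],
                "pre_blink_v": m.pre_blink_position[1],
                "preceding_slow_amplitude": (
                    np.nan
                    if m.preceding_slow_amplitude is None
                    else m.preceding_slow_amplitude
                ),
                "phase": m.phase_label,
                "flow_direction": m.flow_direction,
                "blink_duration_ms": m.blink_duration_ms,
                "first_of_phase": m.first_of_phase,
            }
        )
    return pd.DataFrame(rows)
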