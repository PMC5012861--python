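"""Generative parameterization of a simulated experimental block.

All angles are in degrees, times in seconds unless a field name says ``ms``.
The sign convention follows the camera's view of the subject: positive torsion
is clockwise, which for the right eye is extorsion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

VALID_SAMPLING_RATES = (50, 100, 200)
PHASE_NAMES = ("dark1", "flow1", "dark2", "flow2")

#: Internal integration rate of the latent eye-state simulation (Hz).  The
#: video modality is decimated from this grid, the coil modality uses it as is.
LATENT_RATE = 200


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic oculomotor-trace generator.

    The defaults encode the study conditions: a four-phase block
    (darkness 180 s / rotary optic flow 270 s / darkness 180 s / flow 270 s),
    30 deg/s rotary flow, slow phases near 2.95 deg/s, a torsional build-up
    whose drive saturates at a 3-8 deg plateau, spontaneous blinks at
    15-20/min lasting ~300 ms, and blink-associated resetting movements
    whose torsional shift is a phase-dependent linear gain on the pre-blink
    torsion (dark ~-0.26/-0.28, optic flow ~-0.62).
    """

    # -- acquisition -------------------------------------------------------
    sampling_rate: int = 50
    phase_durations: tuple[float, float, float, float] = (180.0, 270.0, 180.0, 270.0)

    # -- optokinetic stimulus and slow phases ------------------------------
    flow_speed: float = 30.0
    flow_direction: str = "cw"  # 'cw' or 'ccw'; cw drives torsion positive
    slow_phase_velocity_mean: float = 2.95
    slow_phase_velocity_sd: float = 0.7
    #: within-block variability of the slow-phase drive: an OU modulation of
    #: the instantaneous slow-phase velocity (deg/s sd, time constant s)
    slow_velocity_wander_sd: float = 1.45
    slow_velocity_wander_tau: float = 2.5

    # -- torsional build-up / plateau --------------------------------------
    #: admissible range of the per-block drive plateau (deg); the plateau is
    #: the torsion at which slow-phase drift and fast-phase resetting balance.
    plateau_range: tuple[float, float] = (3.0, 8.0)
    #: exponential scale of the per-block plateau draw above plateau_range[0];
    #: plateaus cluster at the low end of the range ("up to 8 deg").
    plateau_exp_scale: float = 1.8
    #: time constant (s) of the within-phase build-up of the optokinetic
    #: adaptation state (ramps the plateau and the BARM gain from phase onset).
    buildup_time_constant: float = 90.0

    # -- fast phases (tOKN resetting saccades) ------------------------------
    fast_phase_slowamp_gain: float = 0.33
    fast_phase_position_gain: float = 0.21  # weak relative to the clusters
    fast_phase_amp_intercept: float = 1.15
    #: multiplicative lognormal dispersion of fast-phase amplitude
    fast_phase_amp_noise_sigma: float = 0.55
    fast_phase_main_seq_slope: float = 31.5  # (deg/s)/deg, minimum-jerk peak
    #: hazard exponent of the position-dependent fast-phase trigger rate,
    #: rate = r0 * (torsion/plateau)**q; small q = sluggish position feedback
    fast_phase_rate_exponent: float = 0.4
    #: overall multiplier on the trigger hazard.  Values > 1 make resetting
    #: outpace the drive below the plateau, so the torsion operates below it.
    fast_phase_rate_scale: float = 3.55
    #: slow multiplicative burstiness of the trigger rate (lognormal OU,
    #: stationary sigma of log-rate; time constant s).  Real nystagmus shows
    #: waxing-and-waning fast-phase frequency; this disperses slow-phase
    #: amplitudes well beyond the exponential-interval baseline.
    fast_phase_rate_burst_sigma: float = 0.3
    fast_phase_rate_burst_tau: float = 10.0
    fast_phase_refractory: float = 0.10  # s, no retrigger after a fast phase
    fast_phase_min_amplitude: float = 0.8

    # -- blinks and BARMs ---------------------------------------------------
    blink_rate: float = 17.5  # events / min, within the 15-20 range
    blink_duration_mean: float = 300.0  # ms
    blink_duration_sd: float = 50.0  # ms
    #: torsional resetting gain applied at a blink, per experimental phase;
    #: 'flow' covers both optic-flow phases
    barm_gain_by_phase: Mapping[str, float] = field(
        default_factory=lambda: {"dark1": -0.26, "flow": -0.62, "dark2": -0.28}
    )
    barm_noise_sd: float = 0.55
    #: within-flow-phase modulation of the BARM gain by the adaptation state:
    #: effective gain = gain * (start + (asym - start) * (1 - exp(-t/tau)))
    #: with tau = buildup_time_constant.  Early-phase blinks (low torsion)
    #: therefore carry a smaller effective gain.
    flow_gain_ramp_start: float = 0.15
    flow_gain_ramp_asymptote: float = 2.05
    #: softening scale (deg) of the flow-phase resetting response: the
    #: commanded shift is gain * T*|T|/(|T| + softzone), i.e. resetting is
    #: sub-proportional for torsion below ~softzone and linear above it
    barm_softzone: float = 1.5
    #: horizontal/vertical resetting gain (qualitative; not printed)
    hv_barm_gain: float = -0.2

    # -- coil blink kinematics ---------------------------------------------
    comp1_amplitude_mean: float = 1.14  # deg, always extorsional (positive)
    comp1_amplitude_sd: float = 0.47
    comp1_peak_latency_mean: float = 127.0  # ms after blink onset
    comp1_peak_latency_sd: float = 35.0
    comp2_latency_mean: float = 73.0  # ms after comp1 velocity peak
    comp2_latency_sd: float = 22.0
    comp2_main_seq_slope: float = 18.6  # (deg/s)/deg
    #: subject-S case: comp1 and comp2 temporally merged (comp2 latency ~ 0)
    merged_components: bool = False

    # -- dark-phase dynamics ------------------------------------------------
    dark_drift_time_constant: float = 80.0  # s, decay of torsion toward zero
    #: diffusion of the slow spontaneous torsional wander (deg/sqrt(s));
    #: together with the dark time constant and the blink resets this yields
    #: a dark-phase torsional standard deviation near the observed ~1.6 deg
    torsion_wander_sd: float = 0.6
    #: multiplier on the torsional wander during optic-flow phases: with a
    #: visual anchor the spontaneous drift is weaker than in darkness
    flow_wander_factor: float = 0.4
    hv_wander_sd: float = 0.12
    hv_time_constant: float = 10.0

    # -- observation noise (deg) -------------------------------------------
    #: slow drift component (H, V, T); dominated by head translation for H/V
    video_noise_drift: tuple[float, float, float] = (4.75, 6.3, 0.38)
    video_noise_white: tuple[float, float, float] = (0.7, 0.9, 0.10)
    video_drift_time_constant: float = 45.0
    coil_noise_white: tuple[float, float, float] = (0.29, 0.29, 0.115)
    #: rate (events/min) of single-eye pupil-detection artifacts (1-3 samples)
    eye_artifact_rate: float = 2.0

    # -- stimulus blanking (afference-hypothesis control) -------------------
    blanks_enabled: bool = False
    blank_durations: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)  # s
    blank_interval_peak: float = 5.0  # s, mode of the half-sine gap density
    blank_interval_width: float = 5.0  # s, half-width; support = [0, 2*peak]

    seed: int = 0

    # ----------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate not in VALID_SAMPLING_RATES:
            raise ValueError(
                f"sampling_rate must be one of {VALID_SAMPLING_RATES}, "
                f"got {self.sampling_rate}"
            )
        if self.flow_direction not in ("cw", "ccw"):
            raise ValueError("flow_direction must be 'cw' or 'ccw'")
        if len(self.phase_durations) != 4 or any(d <= 0 for d in self.phase_durations):
            raise ValueError("phase_durations must be four positive durations")
        lo, hi = self.plateau_range
        if not lo < hi:
            raise ValueError("plateau_range must satisfy lo < hi")
        if lo <= 0:
            raise ValueError("plateau_range must be positive")
        for name in ("dark1", "flow", "dark2"):
            g = self.barm_gain_by_phase.get(name)
            if g is None:
                raise ValueError(f"barm_gain_by_phase missing entry '{name}'")
            if not (-1.0 < g <= 0.0):
                raise ValueError(f"barm_gain_by_phase['{name}'] must lie in (-1, 0]")
        positive = {
            "slow_phase_velocity_mean": self.slow_phase_velocity_mean,
            "blink_rate": self.blink_rate,
            "blink_duration_mean": self.blink_duration_mean,
            "dark_drift_time_constant": self.dark_drift_time_constant,
            "buildup_time_constant": self.buildup_time_constant,
            "fast_phase_main_seq_slope": self.fast_phase_main_seq_slope,
            "comp2_main_seq_slope": self.comp2_main_seq_slope,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        nonneg = {
            "flow_speed": self.flow_speed,
            "slow_phase_velocity_sd": self.slow_phase_velocity_sd,
            "barm_noise_sd": self.barm_noise_sd,
            "blink_duration_sd": self.blink_duration_sd,
            "torsion_wander_sd": self.torsion_wander_sd,
            "fast_phase_amp_noise_sigma": self.fast_phase_amp_noise_sigma,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if self.blanks_enabled and len(self.blank_durations) == 0:
            raise ValueError("blank_durations must not be empty when blanks are enabled")
        if any(d <= 0 for d in self.blank_durations):
            raise ValueError("blank_durations must be strictly positive")

    # ----------------------------------------------------------------------
    @property
    def direction_sign(self) -> int:
        """+1 for clockwise flow (drives torsion positive), -1 for ccw."""
        return 1 if self.flow_direction == "cw" else -1

    @property
    def block_duration(self) -> float:
        return float(sum(self.phase_durations))

    def phase_edges(self) -> list[tuple[str, float, float]]:
        """(name, start, end) of the four phases, in order."""
        edges = []
        t = 0.0
        for name, dur in zip(PHASE_NAMES, self.phase_durations):
            edges.append((name, t, t + dur))
            t += dur
        return edges

    def barm_gain(self, phase: str) -> float:
        key = "flow" if phase.startswith("flow") else phase
        return float(self.barm_gain_by_phase[key])

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["barm_gain_by_phase"] = dict(d["barm_gain_by_phase"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        kwargs = dict(d)
        for key in (
            "phase_durations",
            "plateau_range",
            "video_noise_drift",
            "video_noise_white",
            "coil_noise_white",
            "blank_durations",
        ):
            if key in kwargs and isinstance(kwargs[key], Sequence):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
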