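"""Per-event measurement of resetting movements and their kinematics.

This module turns detected events into the quantities the statistical layer
works with: BARM shifts across blinks (post minus pre position at the safety
times), fast-phase shifts, the two-component decomposition of coil-recorded
blink movements, main-sequence (amplitude vs peak velocity) fits, and the
stimulus-blanking control measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from barmkit.detect import torsional_velocity
from barmkit.simulate import safety_offsets
from barmkit.types import (
    BarmMeasurement,
    BlinkEvent,
    CoilBlinkComponents,
    EyeTraceBlock,
    NystagmusPhase,
)


def _flow_direction_of(block: EyeTraceBlock) -> str:
    if (block.stimulus_state == "flow_cw").any():
        return "cw"
    if (block.stimulus_state == "flow_ccw").any():
        return "ccw"
    return "none"


def measure_barms(block: EyeTraceBlock, blinks, phases) -> list[BarmMeasurement]:
    """One measurement per usable blink.

    The torsional/horizontal/vertical shifts are post minus pre position at
    the safety read times.  The preceding slow-phase amplitude is the
    torsion change from the end of the last fast phase of the same
    experimental phase to the pre-blink read; blinks with no preceding fast
    phase in their experimental phase are flagged ``first_of_phase``.
    """
    flow_dir = _flow_direction_of(block)
    fast_ends = sorted(
        (p.offset_time, p.offset_index, p.phase_label)
        for p in phases
        if p.kind == "fast"
    )
    eye = blinks[0].eye if blinks else "right"
    if eye == "mean":
        tors = 0.5 * (block.left["t"] + block.right["t"])
    else:
        tors = block.eye(eye)["t"]

    out = []
    for b in blinks:
        if not b.usable:
            continue
        pre = b.pre_position
        post = b.post_position
        prev = [e for e in fast_ends if e[0] < b.onset_time and e[2] == b.phase_label]
        other_onsets = [o.onset_time for o in blinks if o is not b]
        if prev:
            t_end, j, _ = prev[-1]
            # the stretch from the fast-phase end to this blink must not be
            # interrupted by another blink (whose reset would contaminate it)
            clean = not any(t_end < t < b.onset_time for t in other_onsets)
            slow_amp = float(pre[2] - tors[j]) if clean else None
            first = False
        else:
            slow_amp = None
            first = True
        out.append(
            BarmMeasurement(
                torsional_shift=float(post[2] - pre[2]),
                h_shift=float(post[0] - pre[0]),
                v_shift=float(post[1] - pre[1]),
                pre_blink_position=tuple(float(v) for v in pre),
                preceding_slow_amplitude=slow_amp,
                phase_label=b.phase_label,
                flow_direction=flow_dir,
                blink_duration_ms=b.duration_ms,
                first_of_phase=first,
            )
        )
    return out


@dataclass
class FastPhaseShift:
    """A fast phase expressed in the same terms as a BARM measurement."""

    torsional_shift: float
    pre_shift_position: float
    preceding_slow_amplitude: Optional[float]
    peak_velocity: float
    phase_label: str
    flow_direction: str


def measure_fast_phase_shifts(phases, flow_direction: str = "cw") -> list[FastPhaseShift]:
    """Torsional shift, pre-shift position and preceding slow amplitude per fast phase."""
    out = []
    for p in phases:
        if p.kind != "fast":
            continue
        out.append(
            FastPhaseShift(
                torsional_shift=float(p.torsional_amplitude),
                pre_shift_position=float(p.pre_shift_position),
                preceding_slow_amplitude=p.preceding_slow_amplitude,
                peak_velocity=float(p.peak_velocity),
                phase_label=p.phase_label,
                flow_direction=flow_direction,
            )
        )
    return out


def decompose_coil_blink(
    coil_block: EyeTraceBlock,
    blink_window: tuple[float, float],
    eye: str = "right",
    velocity_floor: float = 9.0,
    comp2_search_ms: tuple[float, float] = (15.0, 175.0),
) -> CoilBlinkComponents:
    """Two-component decomposition of a coil-recorded blink movement.

    Component 1 is the first extorsional (positive) torsional-velocity peak
    after blink onset that rises above `velocity_floor` (deg/s).  Component
    2 is the subsequent velocity extremum whose sign matches the net
    resetting direction across the blink, searched `comp2_search_ms` after
    the comp1 peak; its amplitude is integrated from the velocity partition
    at the point of minimal speed between the two peaks.  Peak velocities
    are re-estimated with a narrow (25 ms) derivative window so that the
    main-sequence values are not flattened by the detection smoothing.
    When no second extremum rises above the floor the movement is flagged
    merged (a small reset, or the merged-components case).
    """
    onset, offset = blink_window
    fs = coil_block.sampling_rate
    n = len(coil_block)
    x = coil_block.eye(eye)["t"]
    i_on = int(round(onset * fs))
    unusable = CoilBlinkComponents(
        np.nan, np.nan, (np.nan, np.nan), None, None, None, usable=False
    )
    if not (0 <= i_on < n):
        return unusable

    lo = max(i_on - int(0.15 * fs), 0)
    hi = min(i_on + int(0.60 * fs), n)
    if hi - lo < int(0.4 * fs):
        return unusable
    vel = torsional_velocity(x[lo:hi], fs, window_ms=55.0)
    vel_sharp = torsional_velocity(x[lo:hi], fs, window_ms=25.0)
    # comp1 is a 3D movement with a stereotyped extorsional/nasal/downward
    # direction; projecting the 3D velocity onto that direction suppresses
    # the purely torsional resetting component when both share the
    # extorsional sign
    vel_h = torsional_velocity(coil_block.eye(eye)["h"][lo:hi], fs, window_ms=55.0)
    vel_v = torsional_velocity(coil_block.eye(eye)["v"][lo:hi], fs, window_ms=55.0)
    comp1_proj = vel - 0.7 * vel_h - 0.5 * vel_v
    t_ms = (np.arange(lo, hi) - i_on) * 1000.0 / fs  # ms from blink onset

    half = max(int(0.015 * fs), 1)  # local-max neighbourhood, ~15 ms

    def _lobe_centroid_ms(signal, times, ipk):
        """Time of a velocity-lobe peak as the centroid of its upper part."""
        sgn = 1.0 if signal[ipk] >= 0 else -1.0
        s = sgn * signal
        thr = 0.75 * s[ipk]
        a = ipk
        while a > 0 and s[a - 1] >= thr:
            a -= 1
        b = ipk
        while b < len(s) - 1 and s[b + 1] >= thr:
            b += 1
        w = s[a : b + 1]
        return float(np.sum(w * times[a : b + 1]) / np.sum(w))

    def local_peaks(signal, sel, floor):
        idxs = np.where(sel)[0]
        out = []
        for j in idxs:
            a, b = max(j - half, 0), min(j + half + 1, len(signal))
            if signal[j] >= signal[a:b].max() and signal[j] > floor:
                out.append(j)
        return out

    # comp1: first prominent positive peak in 30..260 ms after onset; its
    # stereotyped ~20 deg/s peak velocity warrants a higher floor than the
    # (possibly small) resetting component
    p1 = local_peaks(comp1_proj, (t_ms > 30.0) & (t_ms < 260.0), 2.0 * velocity_floor)
    if not p1:
        return unusable
    # refine to the true maximum of the hump (the first local peak can sit
    # on the rising shoulder when noise is present), then take the centroid
    # of the upper part of the lobe -- robust against noise on a flat top
    j = p1[0]
    a, b = max(j - int(0.010 * fs), 0), min(j + int(0.035 * fs) + 1, len(comp1_proj))
    i1 = int(a + np.argmax(comp1_proj[a:b]))
    comp1_time_ms = _lobe_centroid_ms(comp1_proj, t_ms, i1)

    # comp1 amplitude: excursion from onset to the first velocity zero
    # crossing after its peak (capped at 60 ms so a same-sign resetting
    # component cannot leak in)
    cap = min(i1 + int(0.06 * fs), len(vel) - 1)
    after = np.where((np.arange(len(vel)) > i1) & (np.arange(len(vel)) <= cap) & (vel < 0))[0]
    i1_end = int(after[0]) if len(after) else cap
    base = max(i_on, lo)
    comp1_amp = float(x[lo + i1_end] - x[base])
    hdisp = float(coil_block.eye(eye)["h"][lo + i1_end] - coil_block.eye(eye)["h"][base])
    vdisp = float(coil_block.eye(eye)["v"][lo + i1_end] - coil_block.eye(eye)["v"][base])

    # net resetting direction: position well after the blink vs before it
    j_pre = max(i_on - int(0.14 * fs), 0)
    j_post = min(i_on + int(0.50 * fs), n - 1)
    net = x[j_post] - x[j_pre]
    reset_sign = float(np.sign(net)) if net != 0 else 0.0

    lo_ms, hi_ms = comp2_search_ms
    sel2 = (t_ms > comp1_time_ms + lo_ms) & (t_ms < comp1_time_ms + hi_ms)
    i2 = None
    if reset_sign != 0 and sel2.any():
        cand = local_peaks(vel * reset_sign, sel2, velocity_floor)
        if cand:
            i2 = max(cand, key=lambda j: vel[j] * reset_sign)
    if i2 is None:
        return CoilBlinkComponents(
            comp1_peak_time=comp1_time_ms,
            comp1_torsional_amplitude=comp1_amp,
            comp1_hv_displacement=(hdisp, vdisp),
            comp2_peak_velocity_time=None,
            comp2_amplitude=None,
            comp2_peak_velocity=None,
            merged=True,
            usable=True,
            phase_label=str(coil_block.phase_label[i_on]),
        )

    # partition at the point of minimal speed between the two peaks
    between = np.arange(min(i1, i2), max(i1, i2) + 1)
    boundary = int(between[int(np.argmin(np.abs(vel[between])))])
    # comp2 support: the minimum-jerk lobe is symmetric about its velocity
    # peak, so the displacement is complete ~60 ms after it; reading there
    # keeps resumed nystagmus and drift out of the amplitude
    end = min(i2 + int(0.06 * fs), len(vel) - 1)

    n_win = hi - lo

    def pos_at(j):
        j = int(np.clip(j, 0, n_win - 1))
        a, b = max(j - 1, 0), min(j + 2, n_win)
        return float(np.mean(x[lo + a : lo + b]))

    comp2_amp = pos_at(end) - pos_at(boundary)
    # Is the remainder of the video read window free of *additional*
    # movement?  Between the end of comp2 and the post read we expect only
    # the comp1 return (net -comp1 amplitude, at lid reopening) plus the
    # resumed slow-phase drift; a larger budget means another saccade fell
    # inside the read window and a video pre/post measurement of this blink
    # would be contaminated.
    j_end_read = min(int(round((offset - onset + 0.20) * fs)) + (i_on - lo), n_win - 2)
    stim = str(coil_block.stimulus_state[i_on])
    direction = 1 if stim == "flow_cw" else -1 if stim == "flow_ccw" else 0
    quiet = True
    if j_end_read > end + 2:
        budget = pos_at(j_end_read) - pos_at(end) + comp1_amp - 2.95 * 0.20 * direction
        quiet = bool(abs(budget) < 0.5)
    # same check for the 140 ms window before blink onset
    j_on = i_on - lo
    budget_pre = pos_at(j_on) - pos_at(j_on - int(0.14 * fs)) - 2.95 * 0.14 * direction
    quiet = quiet and bool(abs(budget_pre) < 0.45)
    if abs(comp2_amp) < 0.3 or np.sign(comp2_amp) != reset_sign:
        # too small to be a genuine resetting lobe -- treat as unresolved
        return CoilBlinkComponents(
            comp1_peak_time=comp1_time_ms,
            comp1_torsional_amplitude=comp1_amp,
            comp1_hv_displacement=(hdisp, vdisp),
            comp2_peak_velocity_time=None,
            comp2_amplitude=None,
            comp2_peak_velocity=None,
            merged=True,
            usable=True,
            phase_label=str(coil_block.phase_label[i_on]),
        )
    # refine the peak-velocity estimate with the narrow window
    a, b = max(i2 - 2, 0), min(i2 + 3, len(vel_sharp))
    peak_vel = float(vel_sharp[a:b][np.argmax(np.abs(vel_sharp[a:b]))])
    comp2_time_ms = _lobe_centroid_ms(vel, t_ms, i2)
    return CoilBlinkComponents(
        comp1_peak_time=comp1_time_ms,
        comp1_torsional_amplitude=comp1_amp,
        comp1_hv_displacement=(hdisp, vdisp),
        comp2_peak_velocity_time=float(comp2_time_ms - comp1_time_ms),
        comp2_amplitude=comp2_amp,
        comp2_peak_velocity=peak_vel,
        merged=False,
        usable=True,
        phase_label=str(coil_block.phase_label[i_on]),
        clean_read=quiet,
    )


@dataclass
class MainSequenceFit:
    class_label: str
    slope: float  # (deg/s)/deg on |amplitude|
    intercept: float  # deg/s
    r: float
    n: int


@dataclass
class MainSequenceComparison:
    offset_shift: float  # mean vertical offset of A relative to B at matched amplitudes
    wilcoxon_p: float  # rank-sum test on amplitude-normalised peak velocities
    median_normalized_a: float
    median_normalized_b: float


def main_sequence(amplitudes, peak_velocities, class_label: str) -> MainSequenceFit:
    """Least-squares main-sequence fit of peak velocity on \\|amplitude\\|."""
    a = np.abs(np.asarray(amplitudes, dtype=float))
    v = np.abs(np.asarray(peak_velocities, dtype=float))
    ok = np.isfinite(a) & np.isfinite(v)
    a, v = a[ok], v[ok]
    if len(a) < 3:
        raise ValueError("main-sequence fit requires at least 3 events")
    if np.ptp(a) == 0:
        raise ValueError("degenerate amplitude spread; no fit")
    res = sps.linregress(a, v)
    return MainSequenceFit(
        class_label=class_label,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n=len(a),
    )


def compare_main_sequences(fit_a, fit_b, samples_a, samples_b) -> MainSequenceComparison:
    """Compare two movement classes on the amplitude--peak-velocity plane.

    Reports (i) the mean vertical offset between the two regression lines
    over the pooled amplitude range and (ii) a Wilcoxon rank-sum test on the
    per-event amplitude-normalised peak velocities (peak velocity divided by
    \\|amplitude\\|).
    """
    amp_a, vel_a = (np.abs(np.asarray(s, dtype=float)) for s in samples_a)
    amp_b, vel_b = (np.abs(np.asarray(s, dtype=float)) for s in samples_b)
    grid = np.linspace(
        min(amp_a.min(), amp_b.min()), max(amp_a.max(), amp_b.max()), 50
    )
    offset = float(
        np.mean((fit_a.slope * grid + fit_a.intercept) - (fit_b.slope * grid + fit_b.intercept))
    )
    norm_a = vel_a / np.where(amp_a > 0, amp_a, np.nan)
    norm_b = vel_b / np.where(amp_b > 0, amp_b, np.nan)
    norm_a = norm_a[np.isfinite(norm_a)]
    norm_b = norm_b[np.isfinite(norm_b)]
    # Wilcoxon rank-sum via the Mann-Whitney U statistic; exact for small
    # untied samples, normal approximation otherwise
    stat = sps.mannwhitneyu(norm_a, norm_b, alternative="two-sided", method="auto")
    return MainSequenceComparison(
        offset_shift=offset,
        wilcoxon_p=float(stat.pvalue),
        median_normalized_a=float(np.median(norm_a)),
        median_normalized_b=float(np.median(norm_b)),
    )


@dataclass
class BlankShift:
    torsional_shift: float
    pre_blank_torsion: float
    blank_duration_ms: float
    phase_label: str


def measure_blank_shifts(block: EyeTraceBlock, blanks, eye: str = "right",
                         phases=None, blinks=None) -> list[BlankShift]:
    """Apply the blink measurement convention to stimulus-blanking events.

    Each blank (an interruption of the optic flow with no lid closure) is
    read exactly like a real blink: torsion 140 ms before onset and 200 ms
    after offset.  Blanks whose reads leave the block or fall on invalid
    samples are skipped; if segmented `phases` (or detected `blinks`) are
    supplied, blanks whose read window contains a nystagmus fast phase (or a
    real blink, whose own resetting movement would leak in) are also
    skipped, so the measurement isolates the effect of the blank itself.
    """
    fs = block.sampling_rate
    n_pre, n_post = safety_offsets(fs)
    n = len(block)
    tors = block.eye(eye)["t"]
    fast_spans = (
        [(p.onset_time, p.offset_time) for p in phases if p.kind == "fast"]
        if phases is not None
        else []
    )
    if blinks is not None:
        fast_spans += [(b.onset_time, b.offset_time) for b in blinks]
    out = []
    for onset, dur in blanks:
        i0 = int(np.ceil(onset * fs - 1e-9))
        i1 = int(np.floor((onset + dur) * fs + 1e-9))
        pre_i, post_i = i0 - n_pre, i1 + n_post
        if not (0 <= pre_i < n and 0 <= post_i < n):
            continue
        if np.isnan(tors[pre_i]) or np.isnan(tors[post_i]):
            continue
        t_lo, t_hi = pre_i / fs, post_i / fs
        if any(a < t_hi and b > t_lo for a, b in fast_spans):
            continue
        out.append(
            BlankShift(
                torsional_shift=float(tors[post_i] - tors[pre_i]),
                pre_blank_torsion=float(tors[pre_i]),
                blank_duration_ms=float(dur * 1000.0),
                phase_label=str(block.phase_label[i0]) if i0 < n else "",
            )
        )
    return out
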