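"""Blink detection and slow/fast-phase segmentation of torsional traces.

Blinks are identified purely from the per-sample validity flags: a maximal
run of samples that are invalid in *both* eyes is a blink, while single-eye
dropouts are rejected as pupil-detection artifacts.  Eye positions around a
blink are only trusted outside a temporal safety margin (140 ms before
onset, 200 ms after offset -- 7 and 10 frames at 50 Hz), because the pupil
detector is unreliable while the lid still covers part of the pupil.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import savgol_filter

from barmkit.simulate import safety_offsets
from barmkit.types import BlinkEvent, EyeTraceBlock, NystagmusPhase


def reference_torsion(block: EyeTraceBlock) -> EyeTraceBlock:
    """Re-reference all channels to their mean over the first darkness phase.

    The mean position during fixation in darkness I defines zero torsion
    (and the zero horizontal/vertical positions); every sample of every
    channel is shifted accordingly, per eye.
    """
    dark1 = block.phase_label == "dark1"
    out_eyes = {}
    for eye_name, valid in (("left", block.valid_left), ("right", block.valid_right)):
        chans = block.eye(eye_name)
        ok = dark1 & valid & ~np.isnan(chans["t"])
        if not ok.any():
            raise ValueError(f"no valid dark1 samples in {eye_name} eye; cannot reference")
        out_eyes[eye_name] = {ch: chans[ch] - np.nanmean(chans[ch][ok]) for ch in ("h", "v", "t")}
    return EyeTraceBlock(
        time=block.time,
        left=out_eyes["left"],
        right=out_eyes["right"],
        valid_left=block.valid_left,
        valid_right=block.valid_right,
        phase_label=block.phase_label,
        stimulus_state=block.stimulus_state,
        modality=block.modality,
        sampling_rate=block.sampling_rate,
    )


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs; stop is inclusive."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    stops = list(np.where(d == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask) - 1)
    return list(zip(starts, stops))


def detect_blinks(block: EyeTraceBlock, eye: str = "right") -> list[BlinkEvent]:
    """Detect blinks as maximal binocular dropout runs.

    A run of samples invalid in both eyes is one blink; runs invalid in only
    one eye are pupil-detection artifacts and yield no event.  Pre/post
    positions are read exactly at the safety times (140 ms before onset,
    200 ms after offset).  Blinks whose safety reads would leave the block,
    fall on an invalid sample, or collide with a neighbouring blink's safety
    window are flagged unusable.

    Parameters
    ----------
    eye : 'right' (default), 'left' or 'mean' -- which eye's channels are
        read for the pre/post positions.
    """
    if block.valid_left is None or block.valid_right is None:
        raise ValueError("block has no validity flags")
    n = len(block)
    if n == 0:
        return []
    fs = block.sampling_rate
    n_pre, n_post = safety_offsets(fs)
    both_invalid = ~block.valid_left & ~block.valid_right
    spans = _runs(both_invalid)

    def read_position(i):
        if not (0 <= i < n):
            return None
        if not (block.valid_left[i] and block.valid_right[i]):
            return None
        if eye == "mean":
            vals = tuple(
                0.5 * (block.left[ch][i] + block.right[ch][i]) for ch in ("h", "v", "t")
            )
        else:
            chans = block.eye(eye)
            vals = tuple(chans[ch][i] for ch in ("h", "v", "t"))
        if any(np.isnan(v) for v in vals):
            return None
        return vals

    events = []
    for k, (i0, i1) in enumerate(spans):
        pre_i = i0 - n_pre
        post_i = i1 + n_post
        pre = read_position(pre_i)
        post = read_position(post_i)
        usable = pre is not None and post is not None
        # collision with the neighbouring blink's safety window
        if k > 0 and pre_i <= spans[k - 1][1] + n_post:
            usable = False
        if k + 1 < len(spans) and post_i >= spans[k + 1][0] - n_pre:
            usable = False
        onset_t = block.time[i0]
        offset_t = block.time[i1]
        events.append(
            BlinkEvent(
                onset_index=i0,
                offset_index=i1,
                onset_time=float(onset_t),
                offset_time=float(offset_t),
                duration_ms=float((offset_t - onset_t) * 1000.0),
                pre_position=pre,
                post_position=post,
                phase_label=str(block.phase_label[i0]),
                eye=eye,
                usable=usable,
                pre_index=pre_i if pre is not None else None,
                post_index=post_i if post is not None else None,
            )
        )
    return events


def blink_safety_mask(block: EyeTraceBlock, blinks) -> np.ndarray:
    """Boolean mask covering every blink plus its safety margins."""
    n = len(block)
    fs = block.sampling_rate
    n_pre, n_post = safety_offsets(fs)
    mask = np.zeros(n, dtype=bool)
    for b in blinks:
        mask[max(b.onset_index - n_pre, 0) : min(b.offset_index + n_post + 1, n)] = True
    return mask


def torsional_velocity(
    x: np.ndarray, fs: float, window_ms: float = 100.0, polyorder: int = 2
) -> np.ndarray:
    """Smoothed torsional velocity (deg/s) via a local-polynomial derivative.

    Savitzky-Golay with a window of ~100 ms (5 samples at 50 Hz), the
    differentiation scheme used throughout the package.  NaNs are carried
    through by linear interpolation before filtering.
    """
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        idx = np.arange(len(x))
        ok = ~np.isnan(x)
        if ok.sum() < 2:
            return np.zeros_like(x)
        x = np.interp(idx, idx[ok], x[ok])
    window = int(round(window_ms / 1000.0 * fs))
    window = max(window | 1, polyorder + 2 | 1)  # odd, > polyorder
    if len(x) <= window:
        return np.gradient(x) * fs
    return savgol_filter(x, window, polyorder, deriv=1, delta=1.0 / fs)


def segment_nystagmus(
    block: EyeTraceBlock,
    blinks,
    eye: str = "right",
    fast_threshold: float = 10.0,
    min_fast_duration_s: float = 0.02,
    velocity_window_ms: float = 60.0,
    off_threshold_ratio: float = 0.3,
) -> list[NystagmusPhase]:
    """Segment the torsional trace into slow and fast nystagmus phases.

    Torsional velocity is estimated with a smoothed local-polynomial
    derivative; contiguous runs with \\|velocity\\| above `fast_threshold`
    (deg/s) whose direction is opposite to the optic flow (or opposite to
    the local slow drift in darkness) and which last at least
    `min_fast_duration_s` are fast phases.  The intervals between fast
    phases -- outside blink safety windows and within a single experimental
    phase -- are slow phases.
    """
    n = len(block)
    if n == 0:
        return []
    fs = block.sampling_rate
    if eye == "mean":
        x = 0.5 * (block.left["t"] + block.right["t"])
    else:
        x = block.eye(eye)["t"]
    vel = torsional_velocity(x, fs, velocity_window_ms)
    masked = blink_safety_mask(block, blinks)
    usable = ~masked & ~np.isnan(x)
    if not usable.any():
        warnings.warn("no usable samples; block cannot be segmented")
        return []

    # per-sample expected fast-phase direction: opposite the flow during
    # stimulation, opposite the local (strongly smoothed) drift in darkness
    flow_dir = np.zeros(n)
    flow_dir[block.stimulus_state == "flow_cw"] = 1.0
    flow_dir[block.stimulus_state == "flow_ccw"] = -1.0
    dark = flow_dir == 0
    if dark.any():
        slow_est = torsional_velocity(x, fs, window_ms=1000.0)
        flow_dir[dark] = np.sign(slow_est[dark])

    fast_cand = usable & (np.abs(vel) > fast_threshold) & (vel * flow_dir < 0)
    min_len = max(int(round(min_fast_duration_s * fs)), 1)
    # dual-threshold expansion: grow each supra-threshold run outward while
    # the velocity stays above a fraction of the threshold in the same
    # direction, so onset/offset capture the sub-threshold tails
    low = off_threshold_ratio * fast_threshold
    low_cand = usable & (np.abs(vel) > low) & (vel * flow_dir < 0)

    interp = x.copy()
    if np.isnan(interp).any():
        ok = ~np.isnan(interp)
        interp = np.interp(np.arange(n), np.arange(n)[ok], x[ok])

    fast_spans = []
    for i0, i1 in _runs(fast_cand):
        if i1 - i0 + 1 < min_len:
            continue
        while i0 > 0 and low_cand[i0 - 1]:
            i0 -= 1
        while i1 < n - 1 and low_cand[i1 + 1]:
            i1 += 1
        if fast_spans and i0 <= fast_spans[-1][1]:
            fast_spans[-1] = (fast_spans[-1][0], max(i1, fast_spans[-1][1]))
        else:
            fast_spans.append((i0, i1))

    phases: list[NystagmusPhase] = []
    # segments of contiguous usable samples within one experimental phase
    seg_mask = usable.copy()
    for i0, i1 in _runs(seg_mask):
        seg_fast = [(a, b) for a, b in fast_spans if a >= i0 and b <= i1]
        # split by experimental phase boundaries
        bounds = [i0]
        for j in range(i0 + 1, i1 + 1):
            if block.phase_label[j] != block.phase_label[j - 1]:
                bounds.append(j)
        bounds.append(i1 + 1)
        for s0, s1 in zip(bounds[:-1], bounds[1:]):
            sub_fast = [(a, b) for a, b in seg_fast if a >= s0 and b < s1]
            cursor = s0
            # a preceding slow amplitude is only defined when the slow phase
            # starts at an actual fast-phase end, not at a blink-mask or
            # phase boundary (there the true onset is unobservable)
            cursor_is_fast_end = False
            prev_slow_amp = None
            for a, b in sub_fast:
                if a > cursor + 1:
                    amp = interp[a] - interp[cursor]
                    phases.append(
                        NystagmusPhase(
                            kind="slow",
                            onset_index=cursor,
                            offset_index=a,
                            onset_time=float(block.time[cursor]),
                            offset_time=float(block.time[a]),
                            torsional_amplitude=float(amp),
                            pre_shift_position=float(interp[cursor]),
                            direction=int(np.sign(amp)) if amp else 0,
                            phase_label=str(block.phase_label[cursor]),
                        )
                    )
                    prev_slow_amp = float(amp) if cursor_is_fast_end else None
                famp = interp[b] - interp[a]
                if famp == 0.0:
                    continue  # degenerate single-sample crossing, no event
                phases.append(
                    NystagmusPhase(
                        kind="fast",
                        onset_index=a,
                        offset_index=b,
                        onset_time=float(block.time[a]),
                        offset_time=float(block.time[b]),
                        torsional_amplitude=float(famp),
                        pre_shift_position=float(interp[a]),
                        direction=int(np.sign(famp)) if famp else 0,
                        phase_label=str(block.phase_label[a]),
                        peak_velocity=float(np.max(np.abs(vel[a : b + 1]))),
                        preceding_slow_amplitude=prev_slow_amp,
                    )
                )
                cursor = b
                cursor_is_fast_end = True
            if s1 - 1 > cursor + 1:
                amp = interp[s1 - 1] - interp[cursor]
                phases.append(
                    NystagmusPhase(
                        kind="slow",
                        onset_index=cursor,
                        offset_index=s1 - 1,
                        onset_time=float(block.time[cursor]),
                        offset_time=float(block.time[s1 - 1]),
                        torsional_amplitude=float(amp),
                        pre_shift_position=float(interp[cursor]),
                        direction=int(np.sign(amp)) if amp else 0,
                        phase_label=str(block.phase_label[cursor]),
                    )
                )
    return phases
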