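"""Generative model of four-phase optokinetic blocks with blinks and BARMs.

The latent eye state is integrated on a fixed 200 Hz grid and then observed
in one of two modalities: ``video`` (decimated to the configured sampling
rate, with bilateral sample dropouts during blinks and camera noise) or
``coil`` (full 200 Hz, no dropouts, with the two-component blink kinematics
rendered explicitly).

Latent torsional dynamics
-------------------------
* **Slow phases.** During optic-flow phases the torsion drifts at the
  block's slow-phase velocity (~2.95 deg/s) in the flow direction.  The
  drive is suspended while the lids are closed (blinks) and while the
  stimulus is blanked.
* **Fast phases.** Resetting saccades are triggered by a position-dependent
  hazard ``r(T) = r_eq * (T/plateau)^q`` opposite to the flow.  Their
  amplitude follows the preceding slow-phase amplitude (regression gain
  ~0.33) with a weak position term and large multiplicative variability.
  Rate feedback (not amplitude feedback) is what stabilises the torsion at
  the drive plateau, so the amplitude--position correlation stays weak.
* **Plateau and build-up.** The per-block plateau is the torsion at which
  slow drift and fast-phase resetting balance; it builds up from phase
  onset with a ~60 s time constant, which makes the early part of each flow
  phase a low-torsion regime.
* **Blinks and BARMs.** Blinks follow a gamma renewal process.  At each
  blink the resetting displacement ``gain_eff * T_pre + noise`` is applied
  with the second component's minimum-jerk time course; in flow phases the
  effective gain ramps up with the same adaptation state as the plateau.
* **Darkness.** Torsion relaxes exponentially toward zero and wanders
  slowly; blinks still reset it with the (smaller) dark-phase gains.
"""

from __future__ import annotations

import math

import numpy as np

from barmkit.config import LATENT_RATE, SimulationConfig
from barmkit.types import BlinkRecord, EyeTraceBlock, FastPhaseRecord, GroundTruthLog

_DT = 1.0 / LATENT_RATE

# peak-velocity factor of a minimum-jerk displacement: v_max = 1.875 * A / D
_MINJERK_PEAK = 1.875


def minimum_jerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on u in [0, 1] (0 -> 1)."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def minimum_jerk_bump(u: np.ndarray) -> np.ndarray:
    """Smooth out-and-back bump on [0, 1] peaking at u = 0.5 (0 -> 1 -> 0).

    Built from two minimum-jerk half-movements; velocity extrema at
    u = 0.25 and u = 0.75.
    """
    u = np.clip(u, 0.0, 1.0)
    out = np.where(u <= 0.5, minimum_jerk(2 * u), 1.0 - minimum_jerk(2 * u - 1.0))
    return out


def sample_halfsine_gaps(rng: np.random.Generator, size: int, peak: float, width: float) -> np.ndarray:
    """Inter-event gaps from a half-sine density peaking at `peak`.

    The density is sin-shaped on [peak - width, peak + width]; with the
    defaults (5 s, 5 s) the support is 0..10 s.  Sampling is by inverse
    transform of the analytic CDF.
    """
    a = peak - width
    span = 2.0 * width
    u = rng.uniform(0.0, 1.0, size)
    return a + (span / math.pi) * np.arccos(1.0 - 2.0 * u)


def schedule_blanks(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Draw stimulus-blanking intervals for the optic-flow phases.

    Returns a list of ``(onset_time, duration)`` tuples.  Gap lengths between
    successive blanks follow the half-sine density; durations are drawn
    uniformly from ``config.blank_durations``.
    """
    if len(config.blank_durations) == 0:
        raise ValueError("blank_durations must not be empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    durations = np.asarray(config.blank_durations, dtype=float)
    blanks = []
    for name, t0, t1 in config.phase_edges():
        if not name.startswith("flow"):
            continue
        t = t0
        while True:
            gap = float(
                sample_halfsine_gaps(rng, 1, config.blank_interval_peak, config.blank_interval_width)[0]
            )
            dur = float(rng.choice(durations))
            onset = t + gap
            if onset + dur >= t1 - 0.5:
                break
            blanks.append((onset, dur))
            t = onset + dur
    return blanks


def _sample_blink_times(rng, config, total):
    """Gamma(shape 2) renewal process at the configured mean rate."""
    mean_gap = 60.0 / config.blink_rate
    times = []
    t = float(rng.gamma(2.0, mean_gap / 2.0))
    margin = 2.0
    while True:
        dur = float(np.clip(rng.normal(config.blink_duration_mean, config.blink_duration_sd), 150.0, 500.0)) / 1000.0
        if t + dur > total - margin:
            break
        if t > margin:
            times.append((t, dur))
        t += dur + float(rng.gamma(2.0, mean_gap / 2.0))
    return times


def simulate_block(config: SimulationConfig, seed: int | None = None):
    """Simulate one experimental block in the video modality.

    Returns ``(block, log)`` where `block` is the observed
    :class:`~barmkit.types.EyeTraceBlock` and `log` the
    :class:`~barmkit.types.GroundTruthLog` of every latent event.  The
    latent 200 Hz state is stashed on the block (``block._latent``) for
    :func:`render_coil`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    total = config.block_duration
    n = int(round(total * LATENT_RATE))
    direction = config.direction_sign

    # per-block draws
    lo, hi = config.plateau_range
    plateau = float(min(lo + rng.exponential(config.plateau_exp_scale), hi))
    v_slow = float(
        max(rng.normal(config.slow_phase_velocity_mean, config.slow_phase_velocity_sd), 0.0)
    )
    # hazard level at which fast-phase resetting balances the slow drift
    denom = config.fast_phase_amp_intercept + config.fast_phase_position_gain * plateau
    r_eq = (
        config.fast_phase_rate_scale
        * (1.0 - config.fast_phase_slowamp_gain)
        * v_slow
        / max(denom, 1e-6)
    )

    # per-sample phase id (0..3) and adaptation ramp
    phase_id = np.zeros(n, dtype=np.int8)
    ramp = np.zeros(n, dtype=float)
    edges = config.phase_edges()
    tgrid = np.arange(n) * _DT
    for k, (name, t0, t1) in enumerate(edges):
        sel = (tgrid >= t0) & (tgrid < t1)
        phase_id[sel] = k
        if name.startswith("flow"):
            ramp[sel] = 1.0 - np.exp(-(tgrid[sel] - t0) / config.buildup_time_constant)
    gain_ramp = config.flow_gain_ramp_start + (
        config.flow_gain_ramp_asymptote - config.flow_gain_ramp_start
    ) * ramp

    blinks = _sample_blink_times(rng, config, total)
    blanks = schedule_blanks(config, rng) if config.blanks_enabled else []

    # pre-draw per-step randomness
    xi = rng.standard_normal(n)
    xi_h = rng.standard_normal(n)
    xi_v = rng.standard_normal(n)
    uhaz = rng.random(n)

    wander = config.torsion_wander_sd * math.sqrt(_DT)
    wander_flow = wander * config.flow_wander_factor
    hv_wander = config.hv_wander_sd * math.sqrt(_DT)
    tau_dark = config.dark_drift_time_constant
    tau_hv = config.hv_time_constant
    q = config.fast_phase_rate_exponent
    d2 = _MINJERK_PEAK / config.comp2_main_seq_slope  # comp2 duration, s
    dfast = _MINJERK_PEAK / config.fast_phase_main_seq_slope

    # suspension mask for the optokinetic drive (blinks + blanks)
    suspended = np.zeros(n, dtype=bool)
    for onset, dur in blinks:
        i0 = int(onset * LATENT_RATE)
        i1 = min(int((onset + dur) * LATENT_RATE) + 1, n)
        suspended[i0:i1] = True
    blanked = np.zeros(n, dtype=bool)
    for onset, dur in blanks:
        i0 = int(onset * LATENT_RATE)
        i1 = min(int((onset + dur) * LATENT_RATE) + 1, n)
        blanked[i0:i1] = True
    suspended |= blanked

    T = np.zeros(n, dtype=float)
    H = np.zeros(n, dtype=float)
    V = np.zeros(n, dtype=float)

    flow_phase = (phase_id == 1) | (phase_id == 3)
    log = GroundTruthLog(
        gains_by_phase=dict(config.barm_gain_by_phase),
        plateau=plateau,
        slow_phase_velocity=v_slow,
        flow_direction=config.flow_direction,
    )

    # movement events applied as instantaneous steps during integration and
    # smoothed into minimum-jerk ramps afterwards: (index, dT, dH, dV, duration)
    steps: list[tuple[int, float, float, float, float]] = []
    pending: list[tuple[int, float, float, float]] = []  # scheduled BARM steps

    blink_iter = iter(blinks)
    next_blink = next(blink_iter, None)
    refract_until = -1.0
    t_last_reset = 0.0
    last_fast_phase = -1  # phase id of the most recent fast phase
    blink_records = []
    fast_records = []

    t_cur = 0.0
    h_cur = 0.0
    v_cur = 0.0
    # OU modulation of the slow-phase drive velocity
    v_mod = 0.0
    tau_v = config.slow_velocity_wander_tau
    v_mod_scale = config.slow_velocity_wander_sd * math.sqrt(2.0 * _DT / tau_v)
    xi_v_mod = rng.standard_normal(n)
    # lognormal OU burstiness of the fast-phase trigger rate
    burst = 0.0
    sig_b = config.fast_phase_rate_burst_sigma
    tau_b = config.fast_phase_rate_burst_tau
    burst_scale = sig_b * math.sqrt(2.0 * _DT / tau_b)
    xi_burst = rng.standard_normal(n) if sig_b > 0 else None
    for i in range(n):
        t = i * _DT
        ph = phase_id[i]
        in_flow = ph == 1 or ph == 3

        # blink onset
        if next_blink is not None and t >= next_blink[0]:
            onset, dur = next_blink
            name = edges[ph][0]
            g_eff = config.barm_gain(name) * (gain_ramp[i] if in_flow else 1.0)
            if in_flow and config.barm_softzone > 0:
                resp = t_cur * abs(t_cur) / (abs(t_cur) + config.barm_softzone)
            else:
                resp = t_cur
            shift = g_eff * resp + config.barm_noise_sd * rng.standard_normal()
            dh = config.hv_barm_gain * h_cur - 0.25 + 0.1 * rng.standard_normal()
            dv = config.hv_barm_gain * v_cur - 0.20 + 0.1 * rng.standard_normal()
            lat1 = np.clip(rng.normal(config.comp1_peak_latency_mean, config.comp1_peak_latency_sd), 60.0, 0.45 * dur * 1000.0) / 1000.0
            if config.merged_components:
                lat2 = 0.005
            else:
                lat2 = float(np.clip(rng.normal(config.comp2_latency_mean, config.comp2_latency_sd), 25.0, 160.0)) / 1000.0
            comp1_amp = float(max(rng.normal(config.comp1_amplitude_mean, config.comp1_amplitude_sd), 0.1))
            apply_idx = int(round((onset + lat1 + lat2 - 0.5 * d2) / _DT))
            pending.append((apply_idx, shift, dh, dv))
            rec = BlinkRecord(
                onset_time=onset,
                offset_time=onset + dur,
                phase=name,
                torsion_at_onset=t_cur,
                commanded_shift=shift,
                gain_applied=g_eff,
                torsion_at_pre_read=np.nan,
                torsion_at_post_read=np.nan,
                h_shift=dh,
                v_shift=dv,
                preceding_slow_amplitude=(t_cur - t_last_reset) if last_fast_phase == ph else None,
                comp1_amplitude=comp1_amp,
                comp1_peak_latency=float(lat1),
                comp2_latency=float(lat2),
            )
            blink_records.append(rec)
            next_blink = next(blink_iter, None)

        # scheduled BARM displacement (second component)
        if pending and i >= pending[0][0]:
            _, sdt, sdh, sdv = pending.pop(0)
            t_cur += sdt
            h_cur += sdh
            v_cur += sdv
            steps.append((i, sdt, sdh, sdv, d2))
            t_last_reset = t_cur

        # optokinetic fast phase
        if (
            in_flow
            and not suspended[i]
            and t >= refract_until
            and t < total - 0.5
            and direction * t_cur > 0.05
        ):
            p_now = max(plateau * ramp[i], 0.05)
            rate = r_eq * (direction * t_cur / p_now) ** q
            if sig_b > 0:
                rate *= math.exp(burst - 0.5 * sig_b * sig_b)
            if uhaz[i] < rate * _DT:
                s = t_cur - t_last_reset
                base = (
                    config.fast_phase_amp_intercept
                    + config.fast_phase_slowamp_gain * abs(s)
                    + config.fast_phase_position_gain * direction * t_cur
                )
                sig = config.fast_phase_amp_noise_sigma
                amp = max(base, config.fast_phase_min_amplitude) * float(
                    rng.lognormal(-0.5 * sig * sig, sig)
                )
                amp = max(amp, config.fast_phase_min_amplitude)
                a_signed = -direction * amp
                fast_records.append(
                    FastPhaseRecord(
                        onset_time=t,
                        offset_time=t + dfast,
                        amplitude=a_signed,
                        preceding_slow_amplitude=s,
                        torsion_at_onset=t_cur,
                        phase=edges[ph][0],
                    )
                )
                t_cur += a_signed
                steps.append((i, a_signed, 0.0, 0.0, dfast))
                t_last_reset = t_cur
                last_fast_phase = ph
                refract_until = t + dfast + config.fast_phase_refractory

        # continuous dynamics
        if in_flow:
            if not suspended[i]:
                t_cur += direction * max(v_slow + v_mod, 0.0) * _DT
            t_cur += wander_flow * xi[i]
            v_mod += -v_mod * _DT / tau_v + v_mod_scale * xi_v_mod[i]
            if sig_b > 0:
                burst += -burst * _DT / tau_b + burst_scale * xi_burst[i]
        else:
            t_cur += -t_cur * _DT / tau_dark + wander * xi[i]
        h_cur += -h_cur * _DT / tau_hv + hv_wander * xi_h[i]
        v_cur += -v_cur * _DT / tau_hv + hv_wander * xi_v[i]

        T[i] = t_cur
        H[i] = h_cur
        V[i] = v_cur

    # smooth the instantaneous steps into minimum-jerk ramps
    for idx, sdt, sdh, sdv, dur_s in steps:
        w = int(round(dur_s / _DT))
        end = min(idx + w, n)
        if end <= idx:
            continue
        u = (np.arange(idx, end) - idx) / max(w, 1)
        ramp_left = 1.0 - minimum_jerk(u)
        T[idx:end] -= sdt * ramp_left
        if sdh or sdv:
            H[idx:end] -= sdh * ramp_left
            V[idx:end] -= sdv * ramp_left

    latent = {"t": T, "h": H, "v": V, "phase_id": phase_id, "blanked": blanked}
    log.blinks = blink_records
    log.fast_phases = fast_records
    log.blanks = list(blanks)

    block = _render_video(config, latent, log, rng)
    _log_safety_reads(config, latent, log)
    log.check_within(0.0, total)
    return block, log


def _video_sample_span(onset: float, offset: float, fs: float):
    """First/last video sample index covered by [onset, offset]."""
    i0 = int(math.ceil(onset * fs - 1e-9))
    i1 = int(math.floor(offset * fs + 1e-9))
    return i0, i1


def safety_offsets(fs: float) -> tuple[int, int]:
    """Safety margins in samples: 140 ms before onset, 200 ms after offset.

    At 50 Hz these are the 7 and 10 frames of the video-oculography
    convention; at other rates the same absolute times are used.
    """
    return int(round(0.140 * fs)), int(round(0.200 * fs))


def _log_safety_reads(config, latent, log):
    fs = config.sampling_rate
    m = LATENT_RATE // fs
    n_pre, n_post = safety_offsets(fs)
    n_lat = len(latent["t"])
    for rec in log.blinks:
        i0, i1 = _video_sample_span(rec.onset_time, rec.offset_time, fs)
        pre_idx = (i0 - n_pre) * m
        post_idx = (i1 + n_post) * m
        if 0 <= pre_idx < n_lat:
            rec.torsion_at_pre_read = float(latent["t"][pre_idx])
        if 0 <= post_idx < n_lat:
            rec.torsion_at_post_read = float(latent["t"][post_idx])


def _ou_noise(rng, n, sd, tau, fs):
    """Exact stationary Ornstein-Uhlenbeck samples (drift noise)."""
    if sd == 0:
        return np.zeros(n)
    a = math.exp(-1.0 / (tau * fs))
    b = sd * math.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = sd * rng.standard_normal()
    eps = rng.standard_normal(n)
    for i in range(1, n):
        x[i] = a * x[i - 1] + b * eps[i]
    return x


def _render_video(config, latent, log, rng):
    fs = config.sampling_rate
    m = LATENT_RATE // fs
    n_lat = len(latent["t"])
    n = n_lat // m
    idx = np.arange(n) * m
    time = np.arange(n) / fs

    phase_names = np.array([name for name, _, _ in config.phase_edges()])
    phase_label = phase_names[latent["phase_id"][idx]]
    stim = np.where(
        (latent["phase_id"][idx] == 1) | (latent["phase_id"][idx] == 3),
        "flow_cw" if config.flow_direction == "cw" else "flow_ccw",
        "off",
    )
    stim = np.where(latent["blanked"][idx], "blanked", stim)

    eyes = {}
    for eye in ("left", "right"):
        chans = {}
        for ch, drift_sd, white_sd in zip(
            ("h", "v", "t"), config.video_noise_drift, config.video_noise_white
        ):
            base = latent[ch][idx]
            offset = 0.3 * rng.standard_normal()  # constant per-eye bias
            drift = _ou_noise(rng, n, drift_sd, config.video_drift_time_constant, fs)
            white = white_sd * rng.standard_normal(n)
            chans[ch] = base + offset + drift + white
        eyes[eye] = chans

    valid_left = np.ones(n, dtype=bool)
    valid_right = np.ones(n, dtype=bool)
    for rec in log.blinks:
        i0, i1 = _video_sample_span(rec.onset_time, rec.offset_time, fs)
        i0 = max(i0, 0)
        i1 = min(i1, n - 1)
        valid_left[i0 : i1 + 1] = False
        valid_right[i0 : i1 + 1] = False

    # occasional single-eye pupil-detection artifacts, away from blinks
    n_art = rng.poisson(config.eye_artifact_rate * config.block_duration / 60.0)
    blink_spans = [(r.onset_time - 0.5, r.offset_time + 0.5) for r in log.blinks]
    for _ in range(n_art):
        t_art = rng.uniform(1.0, config.block_duration - 1.0)
        if any(a <= t_art <= b for a, b in blink_spans):
            continue
        j0 = int(t_art * fs)
        j1 = min(j0 + int(rng.integers(1, 4)), n)
        if rng.random() < 0.5:
            valid_left[j0:j1] = False
        else:
            valid_right[j0:j1] = False

    for eye, valid in (("left", valid_left), ("right", valid_right)):
        for ch in ("h", "v", "t"):
            eyes[eye][ch][~valid] = np.nan

    block = EyeTraceBlock(
        time=time,
        left=eyes["left"],
        right=eyes["right"],
        valid_left=valid_left,
        valid_right=valid_right,
        phase_label=phase_label,
        stimulus_state=stim,
        modality="video",
        sampling_rate=float(fs),
    )
    block._latent = latent  # kept for render_coil
    return block


def render_coil(block: EyeTraceBlock, log: GroundTruthLog, config: SimulationConfig,
                seed: int | None = None) -> EyeTraceBlock:
    """Render the search-coil observation of the same latent run.

    The coil trace is sampled at 200 Hz with no dropouts.  At each blink the
    stereotyped first component -- an extorsional/nasal/downward out-and-back
    transient whose velocity peaks ``comp1_peak_latency`` after blink onset --
    is added on top of the latent state, which already carries the second
    component (the resetting displacement logged as the BARM shift).
    """
    if block.modality != "video":
        raise ValueError("render_coil expects the video-modality block of the run")
    latent = getattr(block, "_latent", None)
    if latent is None:
        raise ValueError(
            "block carries no latent state; render_coil must be applied to a "
            "block produced by simulate_block in this session"
        )
    n = len(latent["t"])
    log.check_within(0.0, n * _DT)
    rng = np.random.default_rng((config.seed if seed is None else seed) + 0x5EED)

    T = latent["t"].copy()
    H = latent["h"].copy()
    V = latent["v"].copy()
    tgrid = np.arange(n) * _DT

    for rec in log.blinks:
        amp = rec.comp1_amplitude
        # Out-hold-return transient.  The outgoing half lasts ~105 ms per
        # 1.14 deg of amplitude, so its peak velocity (~20 deg/s) does not
        # grow with amplitude -- comp1 has no main sequence.  The eye then
        # stays deviated while the lid is closed and returns over 150 ms as
        # the lid reopens, i.e. after the resetting component has run off.
        rise = max(0.105 * amp / 1.14, 0.04)
        t_out = rec.onset_time + rec.comp1_peak_latency - 0.5 * rise
        t_back = max(rec.offset_time, t_out + rise)
        back = 0.15
        i0 = max(int(t_out / _DT), 0)
        i_mid = min(int((t_out + rise) / _DT), n)
        i_hold = min(int(t_back / _DT), n)
        i1 = min(int((t_back + back) / _DT), n)
        if i_mid > i0:
            u = (tgrid[i0:i_mid] - t_out) / rise
            bump_out = minimum_jerk(u)
            for arr, scale in ((T, 1.0), (H, -0.7), (V, -0.5)):
                arr[i0:i_mid] += scale * amp * bump_out
        if i_hold > i_mid:
            for arr, scale in ((T, 1.0), (H, -0.7), (V, -0.5)):
                arr[i_mid:i_hold] += scale * amp
        if i1 > i_hold:
            u = (tgrid[i_hold:i1] - t_back) / back
            bump_back = 1.0 - minimum_jerk(u)
            for arr, scale in ((T, 1.0), (H, -0.7), (V, -0.5)):
                arr[i_hold:i1] += scale * amp * bump_back

    phase_names = np.array([name for name, _, _ in config.phase_edges()])
    phase_label = phase_names[latent["phase_id"]]
    stim = np.where(
        (latent["phase_id"] == 1) | (latent["phase_id"] == 3),
        "flow_cw" if config.flow_direction == "cw" else "flow_ccw",
        "off",
    )
    stim = np.where(latent["blanked"], "blanked", stim)

    eyes = {}
    for eye in ("left", "right"):
        chans = {}
        for ch, arr, sd in zip(("h", "v", "t"), (H, V, T), config.coil_noise_white):
            chans[ch] = arr + sd * rng.standard_normal(n)
        eyes[eye] = chans

    coil = EyeTraceBlock(
        time=tgrid.copy(),
        left=eyes["left"],
        right=eyes["right"],
        valid_left=np.ones(n, dtype=bool),
        valid_right=np.ones(n, dtype=bool),
        phase_label=phase_label,
        stimulus_state=stim,
        modality="coil",
        sampling_rate=float(LATENT_RATE),
    )
    return coil
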