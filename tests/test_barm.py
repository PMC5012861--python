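"""Event-measurement layer: BARM shifts, coil decomposition, main sequence."""

import itertools

import numpy as np
import pytest

from barmkit import SimulationConfig, render_coil, simulate_block
from barmkit.barm import (
    compare_main_sequences,
    decompose_coil_blink,
    main_sequence,
    measure_barms,
    measure_blank_shifts,
    measure_fast_phase_shifts,
)
from barmkit.detect import detect_blinks, reference_torsion, segment_nystagmus
from barmkit.simulate import minimum_jerk
from barmkit.types import EyeTraceBlock
from tests.conftest import make_trace_block


class TestMeasureBarms:
    def test_shift_arithmetic_on_constructed_trace(self):
        """pre 4.0 / post 1.52 across a 300 ms gap -> shift -2.48."""
        n = 300
        tors = np.where(np.arange(n) < 150, 4.0, 1.52)
        valid = np.ones(n, dtype=bool)
        valid[150:165] = False
        block = make_trace_block(tors, valid_left=valid.copy(), valid_right=valid.copy())
        blinks = detect_blinks(block)
        (m,) = measure_barms(block, blinks, [])
        assert m.torsional_shift == pytest.approx(-2.48)
        assert m.pre_blink_torsion == pytest.approx(4.0)
        assert m.first_of_phase  # no fast phase precedes it

    def test_zero_gain_zero_position_gives_zero_shift(self):
        n = 300
        tors = np.zeros(n)
        valid = np.ones(n, dtype=bool)
        valid[150:165] = False
        block = make_trace_block(tors, valid_left=valid.copy(), valid_right=valid.copy())
        (m,) = measure_barms(block, detect_blinks(block), [])
        assert m.torsional_shift == 0.0

    def test_noiseless_measured_equals_logged(self, noiseless_config):
        """Measured shifts equal the ground-truth log shifts exactly."""
        block, log = simulate_block(noiseless_config)
        ref = reference_torsion(block)
        blinks = detect_blinks(ref)
        ms = measure_barms(ref, blinks, [])
        usable = [b for b in blinks if b.usable]
        assert len(ms) == len(usable)
        logged = {round(r.onset_time, 4): r for r in log.blinks}
        fs = ref.sampling_rate
        checked = 0
        for b, m in zip(usable, ms):
            rec = min(log.blinks, key=lambda r: abs(r.onset_time - b.onset_time))
            if not np.isfinite(rec.torsion_at_pre_read):
                continue
            assert m.torsional_shift == pytest.approx(rec.true_shift, abs=1e-9)
            checked += 1
        assert checked > 10


class TestFastPhaseShifts:
    def test_definitional_fields(self):
        n = 400
        tors = np.zeros(n)
        v = 3.0 / 50
        cur = 0.0
        for i in range(1, n):
            cur += v
            if i == 200:
                cur -= 2.0
            tors[i] = cur
        block = make_trace_block(tors)
        phases = segment_nystagmus(block, [])
        shifts = measure_fast_phase_shifts(phases, "cw")
        assert len(shifts) == 1
        s = shifts[0]
        assert s.torsional_shift == pytest.approx(-2.0, abs=0.3)
        assert s.pre_shift_position == pytest.approx(tors[199], abs=0.3)


def _two_bump_coil_block(peak1_ms=110.0, peak2_ms=180.0, amp1=1.2, amp2=-2.0, fs=200.0):
    """Coil-style trace with two minimum-jerk lobes at known peak times."""
    n = int(2.0 * fs)
    t = np.arange(n) / fs
    onset = 0.8
    x = np.zeros(n)
    h = np.zeros(n)
    v = np.zeros(n)
    # lobe 1: a brisk 140 ms outgoing movement whose velocity peaks at
    # onset + peak1
    d1 = 0.14
    u1 = np.clip((t - (onset + peak1_ms / 1000.0 - d1 / 2)) / d1, 0, 1)
    x = x + amp1 * minimum_jerk(u1)
    h = h - 0.7 * amp1 * minimum_jerk(u1)
    v = v - 0.5 * amp1 * minimum_jerk(u1)
    # lobe 2: displacement amp2 with velocity peak at onset+peak2
    d2 = 0.1
    u2 = np.clip((t - (onset + peak2_ms / 1000.0 - d2 / 2)) / d2, 0, 1)
    x = x + amp2 * minimum_jerk(u2)
    ones = np.ones(n, dtype=bool)
    chans = lambda: {"h": h.copy(), "v": v.copy(), "t": x.copy()}
    block = EyeTraceBlock(
        time=t,
        left=chans(),
        right=chans(),
        valid_left=ones.copy(),
        valid_right=ones.copy(),
        phase_label=np.array(["flow1"] * n, dtype=object),
        stimulus_state=np.array(["flow_cw"] * n, dtype=object),
        modality="coil",
        sampling_rate=fs,
    )
    return block, onset


class TestCoilDecomposition:
    def test_constructed_two_bump_profile_recovered(self):
        """Peaks built at +110 and +180 ms -> comp1 110 ms, latency 70 ms."""
        block, onset = _two_bump_coil_block()
        comp = decompose_coil_blink(block, (onset, onset + 0.3))
        assert comp.usable and not comp.merged
        assert comp.comp1_peak_time == pytest.approx(110.0, abs=12.0)
        assert comp.comp2_peak_velocity_time == pytest.approx(70.0, abs=15.0)
        assert comp.comp2_amplitude == pytest.approx(-2.0, abs=0.4)

    def test_zero_reset_flagged_merged(self):
        block, onset = _two_bump_coil_block(amp2=0.0)
        comp = decompose_coil_blink(block, (onset, onset + 0.3))
        assert comp.usable and comp.merged
        assert comp.comp2_amplitude is None

    def test_window_outside_trace_unusable(self):
        block, _ = _two_bump_coil_block()
        comp = decompose_coil_blink(block, (5.0, 5.3))
        assert not comp.usable

    def test_comp1_direction_unchanged_by_flow_direction(self, short_config):
        """comp1 stays extorsional (positive) for CW and CCW stimulation."""
        for direction in ("cw", "ccw"):
            cfg = short_config.replace(flow_direction=direction)
            block, log = simulate_block(cfg)
            coil = render_coil(block, log, cfg)
            amps = []
            for rec in log.blinks:
                c = decompose_coil_blink(coil, (rec.onset_time, rec.offset_time))
                if c.usable:
                    amps.append(c.comp1_torsional_amplitude)
            # extorsional on average and in the large majority of blinks,
            # regardless of stimulus direction
            assert np.mean(amps) > 0.5
            assert np.mean(np.sign(amps)) > 0.7

    def test_merged_components_case(self, short_config):
        """With the merged-components flag the second component is no longer
        temporally separable, so most blinks are flagged merged."""
        cfg = short_config.replace(merged_components=True)
        block, log = simulate_block(cfg)
        coil = render_coil(block, log, cfg)
        flags = []
        for rec in log.blinks:
            c = decompose_coil_blink(coil, (rec.onset_time, rec.offset_time))
            if c.usable:
                flags.append(c.merged)
        assert len(flags) > 20
        assert np.mean(flags) > 0.6

    def test_comp2_tracks_video_style_shift(self):
        """comp2 amplitude correlates strongly with the pre/post shift."""
        cfg = SimulationConfig(seed=77, flow_direction="cw")
        block, log = simulate_block(cfg)
        coil = render_coil(block, log, cfg)
        pairs = []
        for rec in log.blinks:
            if not rec.phase.startswith("flow"):
                continue
            c = decompose_coil_blink(coil, (rec.onset_time, rec.offset_time))
            if c.usable and not c.merged and c.clean_read and np.isfinite(rec.torsion_at_pre_read):
                pairs.append((c.comp2_amplitude, rec.true_shift))
        assert len(pairs) > 20
        a, b = np.array(pairs).T
        assert np.corrcoef(a, b)[0, 1] > 0.85


class TestMainSequence:
    def test_exact_linear_relation(self):
        amps = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
        fit = main_sequence(amps, 30.0 * amps, "fast_phase")
        assert fit.slope == pytest.approx(30.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r == pytest.approx(1.0)

    def test_too_few_or_degenerate_events_rejected(self):
        with pytest.raises(ValueError):
            main_sequence([1.0, 2.0], [30.0, 60.0], "x")
        with pytest.raises(ValueError):
            main_sequence([2.0, 2.0, 2.0], [50.0, 60.0, 55.0], "x")

    def test_wilcoxon_matches_exact_permutation_oracle(self):
        """Rank-sum p for {10,11,12} vs {20,21,22} equals brute force."""
        a = np.array([10.0, 11.0, 12.0])
        b = np.array([20.0, 21.0, 22.0])
        fit_a = main_sequence([1, 2, 3], a, "a")
        fit_b = main_sequence([1, 2, 3], b, "b")
        cmpres = compare_main_sequences(fit_a, fit_b, ([1, 2, 3], a), ([1, 2, 3], b))
        # exact permutation distribution of the rank-sum statistic
        pooled = np.concatenate([a / np.array([1, 2, 3]), b / np.array([1, 2, 3])])
        ranks = pooled.argsort().argsort() + 1
        observed = ranks[:3].sum()
        stats = [
            sum(np.asarray(c))
            for c in itertools.combinations(ranks, 3)
        ]
        mean_stat = np.mean(stats)
        p_exact = np.mean([abs(s - mean_stat) >= abs(observed - mean_stat) - 1e-9 for s in stats])
        assert cmpres.wilcoxon_p == pytest.approx(p_exact, abs=0.02)


class TestBlankShifts:
    def test_noiseless_blank_shift_is_window_drift_only(self, noiseless_config):
        """With no resets at blanks, the shift equals the drive accrued in
        the read windows (the blank itself contributes nothing)."""
        cfg = noiseless_config.replace(
            blanks_enabled=True, blink_rate=1e-6, fast_phase_rate_scale=1e-6
        )
        block, log = simulate_block(cfg)
        ref_shifts = measure_blank_shifts(block, log.blanks)
        assert len(ref_shifts) > 10
        # drive runs only outside the blank: 140 ms pre + 200 ms post windows
        expected = cfg.slow_phase_velocity_mean * 0.34
        shifts = np.array([s.torsional_shift for s in ref_shifts])
        assert np.abs(shifts - expected).max() < 0.25

    def test_blanks_with_fast_phase_in_window_are_excluded(self, short_config):
        cfg = short_config.replace(blanks_enabled=True)
        block, log = simulate_block(cfg)
        ref = reference_torsion(block)
        blinks = detect_blinks(ref)
        phases = segment_nystagmus(ref, blinks)
        with_excl = measure_blank_shifts(ref, log.blanks, phases=phases, blinks=blinks)
        without = measure_blank_shifts(ref, log.blanks)
        assert 0 < len(with_excl) < len(without)
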