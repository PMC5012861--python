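"""End-to-end study runner: simulate -> detect -> measure -> statistics.

A *study* is a balanced set of simulated blocks (half clockwise, half
counterclockwise optic flow) analysed exactly like the recordings they
emulate: blinks from validity flags, nystagmus segmentation, per-event
measurement, then the regression/bootstrap layer.  :func:`run_study` returns
everything in one :class:`StudyResult`; :func:`run_pipeline` is the
file-based orchestration used by the command line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from barmkit.barm import (
    compare_main_sequences,
    decompose_coil_blink,
    main_sequence,
    measure_barms,
    measure_blank_shifts,
    measure_fast_phase_shifts,
)
from barmkit.config import SimulationConfig
from barmkit.detect import detect_blinks, reference_torsion, segment_nystagmus
from barmkit.simulate import render_coil, simulate_block
from barmkit.stats import (
    bootstrap_correlations,
    fit_2d_regression,
    fit_shift_regression,
    pooled_vs_split,
)
from barmkit.types import measurements_to_frame

logger = logging.getLogger("barmkit")

FLOW = ("flow1", "flow2")


def derive_seeds(seed: int, n: int) -> list[int]:
    """Independent per-block seeds (< 2**31) from one master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def analyze_block(block, eye: str = "right", fast_threshold: float = 10.0,
                  velocity_window_ms: float = 60.0):
    """Reference, detect and measure one block; returns a dict of results."""
    ref = reference_torsion(block)
    blinks = detect_blinks(ref, eye=eye)
    phases = segment_nystagmus(
        ref, blinks, eye=eye, fast_threshold=fast_threshold,
        velocity_window_ms=velocity_window_ms,
    )
    flow_dir = "cw" if (ref.stimulus_state == "flow_cw").any() else "ccw"
    barms = measure_barms(ref, blinks, phases)
    fasts = measure_fast_phase_shifts(phases, flow_direction=flow_dir)
    return {
        "block": ref,
        "blinks": blinks,
        "phases": phases,
        "barms": barms,
        "fast_shifts": fasts,
        "flow_direction": flow_dir,
    }


def fast_shifts_to_frame(fasts) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "torsional_shift": f.torsional_shift,
                "pre_shift_position": f.pre_shift_position,
                "preceding_slow_amplitude": (
                    np.nan if f.preceding_slow_amplitude is None else f.preceding_slow_amplitude
                ),
                "peak_velocity": f.peak_velocity,
                "phase": f.phase_label,
                "flow_direction": f.flow_direction,
            }
            for f in fasts
        ]
    )


@dataclass
class StudyResult:
    config: SimulationConfig
    n_blocks: int
    seed: int
    barms: pd.DataFrame = None  # all usable BARM measurements
    fast_shifts: pd.DataFrame = None
    slow_phases: pd.DataFrame = None
    coil_components: pd.DataFrame = None
    coil_fast: pd.DataFrame = None
    blank_shifts: pd.DataFrame = None
    logs: list = field(default_factory=list)
    analyses: list = field(default_factory=list)

    # -- convenience selections -------------------------------------------
    def barms_in(self, phase: str) -> pd.DataFrame:
        if phase == "flow":
            return self.barms[self.barms["phase"].isin(FLOW)]
        return self.barms[self.barms["phase"] == phase]

    def fast_in_flow(self) -> pd.DataFrame:
        return self.fast_shifts[self.fast_shifts["phase"].isin(FLOW)]

    # -- headline statistics ----------------------------------------------
    def table1(self) -> pd.DataFrame:
        """Phase-wise BARM regressions, full and constrained range (6 rows)."""
        rows = []
        for phase in ("dark1", "flow", "dark2"):
            for limits in (None, (-2.0, 2.0)):
                fit = fit_shift_regression(
                    self.barms_in(phase), "pre_shift_position", range_limits=limits
                )
                rows.append(
                    {
                        "phase": phase,
                        "range": "full" if limits is None else "-2..2",
                        "slope": fit.slope,
                        "r": fit.r,
                        "p": fit.p,
                        "n": fit.n,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self, bootstrap_reps: int = 1000, bootstrap_n: int = 400) -> dict:
        """All headline quantities of the study, computed from the events."""
        out: dict = {}
        flow_barms = self.barms_in("flow")
        out["barm_slope_flow"] = fit_shift_regression(flow_barms, "pre_shift_position").slope
        out["barm_r_flow"] = fit_shift_regression(flow_barms, "pre_shift_position").r
        out["barm_slope_dark1"] = fit_shift_regression(self.barms_in("dark1"), "pre_shift_position").slope
        out["barm_slope_dark2"] = fit_shift_regression(self.barms_in("dark2"), "pre_shift_position").slope
        out["barm_slope_flow_restricted"] = fit_shift_regression(
            flow_barms, "pre_shift_position", range_limits=(-2.0, 2.0)
        ).slope
        out["barm_mean_amplitude_flow"] = float(np.mean(np.abs(flow_barms["torsional_shift"])))
        out["barm_mean_amplitude_dark1"] = float(
            np.mean(np.abs(self.barms_in("dark1")["torsional_shift"]))
        )

        fasts = self.fast_in_flow()
        fit_slowamp = fit_shift_regression(
            fasts, "preceding_slow_amplitude", direction_scope="mean_of_split"
        )
        out["fast_r_slowamp"] = fit_slowamp.r
        split_slopes = [
            fit_shift_regression(fasts, "preceding_slow_amplitude", direction_scope=d).slope
            for d in ("cw", "ccw")
        ]
        out["fast_slope_slowamp_mag"] = float(np.mean(np.abs(split_slopes)))
        out["fast_r_position"] = fit_shift_regression(
            fasts, "pre_shift_position", direction_scope="mean_of_split"
        ).r

        cmp_barm = pooled_vs_split(flow_barms, "pre_shift_position", "barm")
        fasts_s = fasts.dropna(subset=["preceding_slow_amplitude"])
        cmp_fast = pooled_vs_split(fasts_s, "preceding_slow_amplitude", "fast_phase")
        cmp_fast_pos = pooled_vs_split(fasts, "pre_shift_position", "fast_phase")
        out["pooled_split_slope_diff_barm"] = cmp_barm.slope_difference
        out["pooled_split_slope_diff_fast"] = cmp_fast.slope_difference
        out["pooled_split_offset_diff_fast"] = cmp_fast.offset_difference
        out["pooled_split_offset_diff_barm"] = cmp_barm.offset_difference
        out["pooled_split_slope_diff_fast_position"] = cmp_fast_pos.slope_difference
        out["pooled_split_offset_diff_fast_position"] = cmp_fast_pos.offset_difference

        slow = self.slow_phases
        slow_flow = slow[slow["phase"].isin(FLOW) & (slow["duration"] >= 0.4)]
        out["slow_phase_velocity"] = float(np.mean(slow_flow["mean_speed"]))

        pools = {
            "fast_vs_slowamp": (
                fasts["preceding_slow_amplitude"], fasts["torsional_shift"],
            ),
            "fast_vs_position": (
                fasts["pre_shift_position"], fasts["torsional_shift"],
            ),
            "barm_vs_slowamp": (
                flow_barms["preceding_slow_amplitude"], flow_barms["torsional_shift"],
            ),
            "barm_vs_position": (
                flow_barms["pre_blink_torsion"], flow_barms["torsional_shift"],
            ),
        }
        boots = bootstrap_correlations(
            pools, sample_size=bootstrap_n, reps=bootstrap_reps, seed=self.seed
        )
        for b in boots:
            out[f"bootstrap_{b.relation}_mean_r"] = b.mean_r
            out[f"bootstrap_{b.relation}_ci_width"] = b.ci95[1] - b.ci95[0]

        r2_barm = fit_2d_regression(flow_barms, "barm", reps=200, seed=self.seed)
        r2_fast = fit_2d_regression(fasts, "fast_phase", reps=200, seed=self.seed)
        out["regression2d_barm_a"] = r2_barm.a
        out["regression2d_barm_b"] = r2_barm.b
        out["regression2d_fast_a"] = r2_fast.a
        out["regression2d_fast_b"] = r2_fast.b

        if self.coil_components is not None and len(self.coil_components):
            cc = self.coil_components
            resolved = cc[~cc["merged"] & cc["usable"]]
            out["comp2_latency_ms"] = float(np.mean(resolved["comp2_peak_velocity_time"]))
            out["comp1_amplitude"] = float(np.mean(cc[cc["usable"]]["comp1_torsional_amplitude"]))
            flow_cc = resolved[resolved["phase"].isin(FLOW)]
            if len(flow_cc) >= 3 and self.coil_fast is not None and len(self.coil_fast) >= 3:
                ms_comp2 = main_sequence(
                    flow_cc["comp2_amplitude"], flow_cc["comp2_peak_velocity"], "barm_comp2"
                )
                out["comp2_main_seq_slope"] = ms_comp2.slope
                ms_fast = main_sequence(
                    self.coil_fast["amplitude"], self.coil_fast["peak_velocity"], "fast_phase"
                )
                out["fast_main_seq_slope"] = ms_fast.slope
                comparison = compare_main_sequences(
                    ms_comp2,
                    ms_fast,
                    (flow_cc["comp2_amplitude"], flow_cc["comp2_peak_velocity"]),
                    (self.coil_fast["amplitude"], self.coil_fast["peak_velocity"]),
                )
                out["main_seq_wilcoxon_p"] = comparison.wilcoxon_p
                out["main_seq_offset_shift"] = comparison.offset_shift

        if self.blank_shifts is not None and len(self.blank_shifts):
            bs = self.blank_shifts
            # per-block fits averaged, as for per-subject analysis: removes
            # between-block covariance of drive speed and torsion level
            slopes = []
            for _, grp in bs.groupby("block"):
                if len(grp) >= 10:
                    fit = fit_shift_regression(
                        grp.rename(columns={"pre_blank_torsion": "pre_shift_position"}),
                        "pre_shift_position",
                    )
                    if fit.ok:
                        slopes.append(fit.slope)
            out["blank_slope_position"] = float(np.mean(slopes)) if slopes else np.nan
            from scipy.stats import pearsonr

            r, p = pearsonr(bs["blank_duration_ms"], bs["torsional_shift"])
            out["blank_r_duration"] = float(r)
            out["blank_p_duration"] = float(p)
        return out


def run_study(
    config: SimulationConfig | None = None,
    n_blocks: int = 16,
    seed: int = 0,
    coil_blocks: int = 4,
    blank_blocks: int = 0,
    eye: str = "right",
    fast_threshold: float = 10.0,
    keep_blocks: bool = False,
) -> StudyResult:
    """Simulate and analyse a balanced study.

    `n_blocks` blocks are simulated with alternating flow direction (equal
    numbers clockwise and counterclockwise).  The first `coil_blocks` blocks
    are additionally rendered in the coil modality and every blink
    decomposed into its two components.  If `blank_blocks` > 0, that many
    extra blocks with stimulus blanking are simulated and measured with the
    blank-control convention.
    """
    if n_blocks <= 0:
        raise ValueError("n_blocks must be positive")
    if config is None:
        config = SimulationConfig()
    seeds = derive_seeds(seed, n_blocks + max(blank_blocks, 0))

    barm_frames, fast_frames, slow_rows, coil_rows, coil_fast_rows = [], [], [], [], []
    logs, analyses = [], []
    for i in range(n_blocks):
        direction = "cw" if i % 2 == 0 else "ccw"
        cfg = config.replace(flow_direction=direction, seed=seeds[i])
        block, log = simulate_block(cfg)
        res = analyze_block(block, eye=eye, fast_threshold=fast_threshold)
        logs.append(log)
        if keep_blocks:
            analyses.append(res)

        bf = measurements_to_frame(res["barms"])
        if len(bf):
            bf["block"] = i
            barm_frames.append(bf)
        ff = fast_shifts_to_frame(res["fast_shifts"])
        if len(ff):
            ff["block"] = i
            fast_frames.append(ff)
        for p in res["phases"]:
            if p.kind == "slow" and p.duration > 0:
                slow_rows.append(
                    {
                        "block": i,
                        "phase": p.phase_label,
                        "duration": p.duration,
                        "amplitude": p.torsional_amplitude,
                        "mean_speed": p.mean_speed,
                    }
                )

        if i < coil_blocks:
            coil = render_coil(block, log, cfg)
            # fast-phase kinematics from the coil trace (narrow derivative
            # window: 200 Hz resolves the ~60 ms fast-phase profile)
            coil_ref = reference_torsion(coil)
            stubs = _blink_stubs(log, coil.sampling_rate, len(coil))
            coil_phases = segment_nystagmus(
                coil_ref, stubs, fast_threshold=fast_threshold, velocity_window_ms=25.0
            )
            for p in coil_phases:
                if p.kind == "fast" and p.phase_label in FLOW:
                    coil_fast_rows.append(
                        {
                            "block": i,
                            "amplitude": p.torsional_amplitude,
                            "peak_velocity": p.peak_velocity,
                            "flow_direction": direction,
                        }
                    )
            for rec in log.blinks:
                comp = decompose_coil_blink(coil, (rec.onset_time, rec.offset_time))
                coil_rows.append(
                    {
                        "block": i,
                        "phase": rec.phase,
                        "flow_direction": direction,
                        "comp1_peak_time": comp.comp1_peak_time,
                        "comp1_torsional_amplitude": comp.comp1_torsional_amplitude,
                        "comp2_peak_velocity_time": comp.comp2_peak_velocity_time,
                        "comp2_amplitude": comp.comp2_amplitude,
                        "comp2_peak_velocity": comp.comp2_peak_velocity,
                        "merged": comp.merged,
                        "usable": comp.usable,
                        "clean_read": comp.clean_read,
                        "true_shift": rec.true_shift,
                    }
                )
        logger.info("block %d (%s): analysed", i, direction)

    blank_rows = []
    for j in range(blank_blocks):
        direction = "cw" if j % 2 == 0 else "ccw"
        cfg = config.replace(
            flow_direction=direction, seed=seeds[n_blocks + j], blanks_enabled=True
        )
        block, log = simulate_block(cfg)
        res = analyze_block(block, eye=eye, fast_threshold=fast_threshold)
        ref = res["block"]
        for s in measure_blank_shifts(
            ref, log.blanks, phases=res["phases"], blinks=res["blinks"]
        ):
            blank_rows.append(
                {
                    "block": j,
                    "torsional_shift": s.torsional_shift,
                    "pre_blank_torsion": s.pre_blank_torsion,
                    "blank_duration_ms": s.blank_duration_ms,
                    "phase": s.phase_label,
                    "flow_direction": direction,
                }
            )

    result = StudyResult(config=config, n_blocks=n_blocks, seed=seed, logs=logs, analyses=analyses)
    result.barms = (
        pd.concat(barm_frames, ignore_index=True) if barm_frames else pd.DataFrame()
    )
    result.fast_shifts = (
        pd.concat(fast_frames, ignore_index=True) if fast_frames else pd.DataFrame()
    )
    result.slow_phases = pd.DataFrame(slow_rows)
    result.coil_components = pd.DataFrame(coil_rows)
    result.coil_fast = pd.DataFrame(coil_fast_rows)
    result.blank_shifts = pd.DataFrame(blank_rows)
    return result


def _blink_stubs(log, fs, n):
    """Minimal blink events (for safety masking) from the ground-truth log."""
    from barmkit.types import BlinkEvent

    stubs = []
    for rec in log.blinks:
        i0 = int(np.ceil(rec.onset_time * fs - 1e-9))
        i1 = min(int(np.floor(rec.offset_time * fs + 1e-9)), n - 1)
        stubs.append(
            BlinkEvent(
                onset_index=i0,
                offset_index=i1,
                onset_time=rec.onset_time,
                offset_time=rec.offset_time,
                duration_ms=rec.duration * 1000.0,
                pre_position=None,
                post_position=None,
                phase_label=rec.phase,
                usable=False,
            )
        )
    return stubs


def run_pipeline(config_path, out_dir, seed: int = 0) -> dict:
    """File-based end-to-end run driven by a YAML study configuration.

    The configuration file may contain a ``simulation`` section (fields of
    :class:`SimulationConfig`) plus study-level keys ``n_blocks``,
    ``coil_blocks``, ``blank_blocks``, ``fast_threshold``, ``eye``.  Writes
    event tables, the phase-wise regression summary, the cluster-diagnostic
    and bootstrap reports, and a reproducibility manifest into `out_dir`.
    """
    import json

    import yaml

    from barmkit.io import write_manifest

    with open(config_path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_cfg = SimulationConfig.from_dict(raw.get("simulation", {}))
    n_blocks = int(raw.get("n_blocks", 16))
    if n_blocks <= 0:
        raise ValueError("n_blocks must be positive")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    study = run_study(
        sim_cfg,
        n_blocks=n_blocks,
        seed=seed,
        coil_blocks=int(raw.get("coil_blocks", min(4, n_blocks))),
        blank_blocks=int(raw.get("blank_blocks", 0)),
        eye=raw.get("eye", "right"),
        fast_threshold=float(raw.get("fast_threshold", 10.0)),
    )
    files = []

    def save(df, name):
        p = out_dir / name
        df.to_csv(p, index=False)
        files.append(p)

    save(study.barms, "barm_measurements.csv")
    save(study.fast_shifts, "fast_phase_shifts.csv")
    save(study.slow_phases, "slow_phases.csv")
    if len(study.coil_components):
        save(study.coil_components, "coil_components.csv")
    if len(study.blank_shifts):
        save(study.blank_shifts, "blank_shifts.csv")
    save(study.table1(), "regression_summary.csv")

    summary = study.summary()
    p = out_dir / "summary.json"
    with open(p, "w") as fh:
        json.dump({k: (None if v != v else v) for k, v in summary.items()}, fh, indent=1)
    files.append(p)
    return write_manifest(out_dir / "manifest.json", sim_cfg, seed, files)
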