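# barmkit

Simulation and analysis of **blink-associated resetting movements (BARMs)**
— torsional eye movements, yoked to blinks, that return the eye toward zero
torsion — and of the torsional optokinetic nystagmus (tOKN) they are
embedded in.

When a large visual pattern rotates about the line of sight, the eyes
follow it with slow torsional phases (~3 deg/s) interrupted by resetting
fast phases, and torsion builds up over tens of seconds. Video-oculography
loses the eye during every blink (~300 ms, 15–20 times per minute), but
comparing the eye position just before and just after each blink reveals a
distinct resetting movement: its torsional shift is a negative, phase-
dependent linear function of the pre-blink torsion,

    shift = g_phase · T_pre + ε,     g ≈ −0.26 (darkness) … −0.62 (optic flow),

whereas optokinetic fast phases instead track the amplitude of the
preceding slow phase (regression gain ≈ 0.33) and split into two clusters
by flow direction. Search-coil recordings, which see through the closed
lid, decompose the blink movement into a stereotyped extorsional transient
(component 1, no main sequence) followed ~73 ms later by the resetting
component proper (component 2), a slow saccade with its own
amplitude–peak-velocity main sequence (~18.6 vs ~31.5 (deg/s)/deg for fast
phases). Blanking the stimulus for blink-like durations resets nothing, so
the movement is tied to the blink itself, not to the interruption of
vision.

The package provides, as a library:

- `barmkit.simulate` — a generative model of the four-phase experimental
  block (darkness 180 s / 30 deg/s rotary flow 270 s / darkness / flow) in
  video and search-coil modalities, with a ground-truth event log;
- `barmkit.detect` — zero-torsion referencing, blink detection from
  validity flags with 140/200 ms safety reads, slow/fast-phase
  segmentation;
- `barmkit.barm` — per-event measurement: BARM and fast-phase shifts, the
  two-component coil decomposition, main-sequence fits, blank controls;
- `barmkit.stats` — the regression layer: phase-wise and range-restricted
  fits, the pooled-vs-direction-split cluster diagnostic, bootstrap
  correlation intervals, the two-predictor regression;
- `barmkit.pipeline` — the end-to-end study runner;
- a thin `barmkit` command line (`simulate`, `detect`, `barm`, `stats`,
  `run`) over the same functions.

The model, its parameters and the measurement conventions are documented
in [`docs/methods.md`](docs/methods.md).

## Worked example

```python
from barmkit import SimulationConfig
from barmkit.pipeline import run_study

study = run_study(SimulationConfig(), n_blocks=8, seed=1, coil_blocks=2, blank_blocks=1)
print(study.table1())
```

(`examples/04_full_study_statistics.py`; every example script in
`examples/` runs in seconds.) Output:

```
phase range  slope      r     p    n
dark1  full -0.305 -0.600 0.000  372
dark1 -2..2 -0.301 -0.409 0.000  294
 flow  full -0.638 -0.817 0.000 1096
 flow -2..2 -0.471 -0.445 0.000  790
dark2  full -0.253 -0.576 0.000  381
dark2 -2..2 -0.183 -0.254 0.000  243

fast-phase shift vs preceding slow amplitude: r = -0.38, |slope| = 0.38
pooled-vs-split slope difference: BARMs +0.013, fast phases -0.425
blank control: shift-vs-position slope -0.044 (duration correlation p = 0.24)
```

Reading the numbers: each blink gives back ~64% of the standing torsional
deviation during optic flow and ~25–30% in darkness (the regression
slopes); restricting the analysis to pre-blink torsion within ±2 deg
shrinks the flow-phase slope toward −0.47 (the resetting gain is modulated
by the adaptation state and is sub-proportional near zero). Fast phases
behave differently on every axis: their size follows the preceding slow
phase, and pooling the two flow directions changes their fit drastically
(slope difference −0.43) while it barely changes the BARM fit (+0.01) —
BARMs form one continuous cluster through zero, fast phases two. Blanking
the stimulus produces no position-dependent shift.

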