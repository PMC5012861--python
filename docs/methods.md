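# Models and methods

`barmkit` simulates and analyses torsional eye-position recordings from a
four-phase optokinetic experiment — fixation in darkness (180 s), rotary
optic flow (270 s), darkness again (180 s), flow again (270 s) — in order to
study the blink-associated resetting movement (BARM): a saccade-like
torsional eye movement, yoked to blinks, whose amplitude is proportional to
the eye's pre-blink deviation from zero torsion. Because the human
recordings the design is based on are not publicly distributed, the package
pairs every analysis stage with a generative model whose ground truth is
known, so each stage can be validated end to end.

## Latent oculomotor model

The latent eye state (torsion T, horizontal H, vertical V; degrees) is
integrated at 200 Hz. Positive torsion is clockwise in the camera's view,
which for the right eye is extorsion.

**Slow phases.** During optic flow, torsion drifts in the flow direction at
the slow-phase velocity — per-block mean drawn from N(2.95, 0.7) deg/s (the
across-subject dispersion of slow-phase velocity is large) and modulated
within a block by an Ornstein-Uhlenbeck process (sd 1.45 deg/s, τ = 2.5 s).
The drive is suspended whenever the lids are closed (blinks) or the
stimulus is blanked.

**Fast phases.** Optokinetic fast phases are triggered by a
position-dependent hazard, `rate = r0 · (|T|/plateau)^q` with q = 0.4, and
a slow lognormal "burstiness" modulation (σ = 0.3, τ = 10 s) reflecting the
waxing and waning of nystagmus frequency. Their amplitude follows the
preceding slow-phase amplitude with gain 0.33, plus a weak position term
(0.21) and multiplicative lognormal variability (σ = 0.55); each executes
as a minimum-jerk displacement whose peak velocity is 31.5 (deg/s)/deg of
amplitude (hence a fixed ~60 ms duration). Position feedback therefore
acts mainly through the *rate* of fast phases, not their amplitude — which
is what keeps the amplitude–position correlation weak, as observed, while
still stabilising torsion. The per-block `plateau` parameter (drawn from
3–8 deg, clustered at the low end) scales the hazard: it is the level at
which resetting would balance the drive. With blinks removing ~60% of the
standing torsion every 3–4 s, the eye *operates* well below that level
(around 2 deg); the 3–8 deg band is expressed in the upper envelope of the
torsional excursions rather than as a sustained plateau. A sustained
plateau at 3–8 deg is arithmetically incompatible with a mean resetting
amplitude of 1.34 deg under a −0.62 gain, so this is a deliberate model
commitment, not an oversight.

**Blinks and BARMs.** Blinks follow a gamma(2) renewal process at 17.5/min
with N(300, 50) ms durations. At each blink a resetting displacement

    shift = gain_phase · m(t) · f(T_pre) + ε,   ε ~ N(0, 0.55²)

is executed with the second component's minimum-jerk time course. The
phase gains are −0.26 (darkness I), −0.62 (optic flow), −0.28 (darkness
II). In flow phases the gain is modulated twice, both forms of the gain
modulation the restricted-range analysis implies: `m(t)` ramps with the
optokinetic adaptation state (0.15 → 2.05 of the base gain, τ = 90 s, the
same time constant as the torsional build-up), and `f(T) = T·|T|/(|T| +
1.5)` makes resetting sub-proportional below ~1.5 deg. Together these
reproduce the full-range slope of −0.62 *and* the shallower slope (−0.43)
when the analysis is restricted to pre-blink torsion in ±2 deg. We
verified that observation-noise dilution alone cannot produce the
restricted-range shrinkage without simultaneously corrupting the
pooled-vs-split agreement and the full-range slope, so the gain-modulation
account is load-bearing, not decorative.

**Darkness.** Torsion relaxes exponentially toward zero (τ = 80 s, so the
return is usually incomplete within 180 s) and wanders slowly (0.6
deg/√s); with the blink resets this yields the observed ~1.6 deg
dark-phase torsional standard deviation. Under optic flow the wander is
0.4× smaller (the stimulus provides a visual anchor). H/V are small OU
processes with their own resetting gain (−0.2, qualitative).

## Observation models

**Video-oculography** (default 50 Hz, decimated from the latent grid): adds
a per-eye constant bias, slow drift (OU, τ = 45 s; sd 4.75/6.3/0.38 deg for
H/V/T — horizontal and vertical drift dominated by head translation, as in
the hardware this emulates) and white noise (0.7/0.9/0.10 deg). During
blinks all six channels of both eyes are invalid (NaN); occasional 1–3
sample single-eye dropouts emulate pupil-detection artifacts.

**Search coil** (200 Hz, no dropouts): the latent state plus, at every
blink, the stereotyped first component — an extorsional/nasal/downward
minimum-jerk excursion (amplitude N(1.14, 0.47) deg, always extorsional,
velocity peak 127 ± 35 ms after blink onset) that is held while the lid is
closed and returns over 150 ms at reopening. Its outgoing duration scales
with amplitude (~105 ms per 1.14 deg), so its peak velocity (~20 deg/s)
does not grow with amplitude: component 1 has no main sequence. The
second component — the resetting displacement itself — peaks 73 ± 22 ms
after the component-1 peak with peak velocity 18.6 (deg/s)/deg. White
coil noise (0.29/0.29/0.115 deg) is added. The `merged_components` flag
reproduces the subject whose two components could not be separated (the
component-2 latency collapses to ~0).

## Detection and measurement conventions

* Zero torsion is the mean over valid samples of the first darkness phase;
  all channels are re-referenced to their darkness-I means.
* A blink is a maximal run of samples invalid in both eyes; single-eye
  runs are artifacts. Positions around a blink are read exactly 140 ms
  before onset and 200 ms after offset (7 and 10 frames at 50 Hz); blinks
  whose reads leave the block or collide with a neighbouring blink's
  window are excluded rather than imputed.
* Torsional velocity is a Savitzky–Golay first derivative (quadratic,
  5 samples at 50 Hz; 25–55 ms windows on 200 Hz coil traces). Fast
  phases are runs with |velocity| > 10 deg/s opposite the flow (opposite
  the local drift in darkness) lasting at least one sample, grown outward
  while the velocity stays above 0.3× the threshold (dual-threshold
  hysteresis); this matters because a 60 ms fast phase crosses threshold
  for only 1–2 samples at 50 Hz.
* A preceding slow-phase amplitude is only attached when the slow phase
  starts at an observed fast-phase end; slow stretches that begin at a
  blink mask or phase boundary (where the true onset is hidden) yield
  none, and BARM preceding amplitudes additionally require no intervening
  blink. Slow-phase velocity statistics use slow phases ≥ 0.4 s — shorter
  inter-saccadic snippets carry more boundary noise than signal.
* The coil decomposition times component 1 on the 3D velocity projected
  onto its stereotyped direction (t − 0.7·h − 0.5·v), which suppresses a
  same-signed resetting component; peak times are lobe centroids (robust
  to noise on a flat top); component 2 is the subsequent velocity
  extremum of the net resetting sign within 15–175 ms, its amplitude the
  displacement from the minimum-speed partition point to 60 ms past its
  peak. Events with no resolvable second lobe (small resets, or the
  merged case) are flagged. A `clean_read` flag marks blinks whose
  140/200 ms read windows contain no *other* movement, judged from the
  coil trace; only those support a clean video-vs-coil comparison.
* Blank-control shifts use the identical 140/200 ms convention; blanks
  whose windows contain a fast phase or a real blink are excluded, and the
  regression against pre-blank torsion is fitted per block and averaged
  (as per-subject analysis would), removing between-block covariance of
  drive speed and torsion level.

## Statistical layer

Ordinary least squares with Pearson correlations and two-sided p-values
throughout (p < 0.05, no multiple-testing correction — per-pool
reporting). BARM shifts are fitted pooled over both flow directions; fast
phases per direction with the mean of the two fits reported. The cluster
diagnostic compares the pooled fit with the direction-split fits: the
slope difference is pooled slope minus the mean of the split slopes, the
offset difference the mean absolute intercept discrepancy (degrees).
Bootstrap correlations are percentile-based, 400 events with replacement,
1000 repetitions. The two-predictor regression (shift on slow-phase
amplitude and position) uses one model for BARMs and two direction-split
models for fast phases, with bootstrap coefficient intervals. The
main-sequence comparison tests amplitude-normalised peak velocities with
the Wilcoxon rank-sum (Mann–Whitney U, exact for small untied samples).

## What the synthetic data do and do not establish

The generator's defaults were calibrated once so that the full pipeline
(simulate → detect → measure → fit) reproduces the study's headline
statistics at a 16-block balanced design; they are not re-tuned per run.
Passing tests therefore show that the *analysis chain* recovers the
phenomena a generator of this structure embeds — proportional,
direction-continuous blink resetting dissociated from slow-amplitude-driven,
direction-clustered fast phases — at realistic noise, sampling and event
rates. They cannot show that real eyes obey this particular latent model:
lid kinematics, pupil-edge failure modes at blink boundaries, torsional
cross-talk of video trackers, and any dependence of blink rate on the
stimulus are not modeled. Two deliberate simplifications are visible in
the numbers: measured main-sequence slopes read ~10% below their generative
values (differentiation attenuates 60–100 ms velocity peaks), and the
dark-phase regression slopes carry ~0.03 of systematic offset from wander
accrued inside the read windows — both are properties any real
implementation of these conventions would share.

## Problem sizes

Default analyses use 16–48 blocks of 900 s (one block simulates in ~0.6 s);
the acceptance script runs 48 blocks with 8 coil-rendered blocks in about
half a minute, and the test suite completes in well under a minute.
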