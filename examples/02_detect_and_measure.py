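"""Run blink detection, nystagmus segmentation and BARM measurement.

Simulates a block, re-references torsion to the darkness-I mean, detects
blinks from the validity flags, segments slow/fast nystagmus phases, and
prints the measured blink shifts against the generator's ground truth.
"""
import numpy as np

from barmkit import SimulationConfig, simulate_block
from barmkit.barm import measure_barms
from barmkit.detect import detect_blinks, reference_torsion, segment_nystagmus

block, truth = simulate_block(SimulationConfig(seed=7))
ref = reference_torsion(block)
blinks = detect_blinks(ref)
phases = segment_nystagmus(ref, blinks)
barms = measure_barms(ref, blinks, phases)

fast = [p for p in phases if p.kind == "fast"]
print(f"detected {len(blinks)} blinks "
      f"({sum(b.usable for b in blinks)} usable) and {len(fast)} fast phases")
flow = [m for m in barms if m.phase_label.startswith("flow")]
shifts = np.array([m.torsional_shift for m in flow])
pre = np.array([m.pre_blink_torsion for m in flow])
slope = np.polyfit(pre, shifts, 1)[0]
print(f"optic-flow blinks: mean |shift| {np.abs(shifts).mean():.2f} deg; "
      f"shift-vs-position slope {slope:+.2f}")
print("The slope near -0.6 is the signature of the resetting movement: the")
print("eye gives back ~60% of its torsional deviation at every blink.")
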