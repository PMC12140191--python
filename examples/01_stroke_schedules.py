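"""Sample brush-stroke schedules for the pairing phase.

Strokes are delivered at truncated-exponential inter-onset intervals within
[0.6, 2.0] s.  Synchronous pairing applies one train to both the hidden real
forelimb (tactile) and the visible artificial limb (visual); asynchronous
pairing draws the two trains independently, decoupling what the mouse feels
from what it sees.
"""

import numpy as np

from pawshift import sample_stroke_schedule

sync = sample_stroke_schedule(120.0, 0.6, 2.0, mode="synchronous", seed=1)
asyn = sample_stroke_schedule(120.0, 0.6, 2.0, mode="asynchronous", seed=1)

iv = np.diff(sync.visual_onsets)
print(f"synchronous train : {len(sync.visual_onsets)} strokes, "
      f"intervals {iv.min():.3f}-{iv.max():.3f} s (mean {iv.mean():.3f} s)")
print(f"  visual == tactile: {sync.synchronous}")
print(f"asynchronous train: visual {len(asyn.visual_onsets)} / "
      f"tactile {len(asyn.tactile_onsets)} strokes, independent trains")
print(f"stroke duration {sync.stroke_duration * 1000:.0f} ms, "
      f"sweep {sync.sweep_distance:.0f} mm")
print()
print("Each 120 s pairing delivers ~100 strokes; in the synchronous condition")
print("the two brushes always coincide, which is the condition expected to")
print("induce embodiment of the artificial limb.")
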