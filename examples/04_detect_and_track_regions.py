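"""Detecting and tracking the high-risk regions over a minute in bed.

Simulates 60 seconds of a static supine patient, detects the head,
shoulders, sacrum and heels in every frame via gradient zero-crossing
maxima, and tracks each region's mean interface pressure over time —
the quantity whose accumulation drives pressure-injury risk.
"""

import numpy as np

from presscope import default_scene_spec, generate_sequence, track_regions
from presscope.regions import tracks_to_table

seq, truth = generate_sequence(default_scene_spec("supine", seed=5), n_frames=60)
tracks = track_regions(seq, "supine")

print(f"{'region':16s} {'frames':>6s} {'gaps':>4s} {'mean mmHg':>10s} {'sd':>5s}")
for t in sorted(tracks, key=lambda t: t.label):
    p = np.asarray(t.mean_pressures)
    print(f"{t.label:16s} {len(t):6d} {len(t.gaps):4d} {p.mean():10.1f} {p.std():5.2f}")

df = tracks_to_table(tracks)
print(f"\ntidy table: {len(df)} rows, columns {list(df.columns)}")
print(df.head(3).to_string(index=False))
print("\nEach region is re-identified in every frame (no gaps) and its mean")
print("pressure stays steady - the sacrum and heels carry the highest load,")
print("matching their status as the primary pressure-injury sites.")
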