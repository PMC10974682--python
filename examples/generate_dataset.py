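"""Generate a synthetic skeleton-activity dataset and write it as CSV.

Builds five activity classes over a 25-joint stick figure: two defined by
static pose geometry, two by movement dynamics (arm-leg coordination and
movement waveform), one by both.  The CSV has one row per frame — 50 joint
coordinates plus the class label in the last column — exactly the layout the
loader reads back.
"""

import numpy as np

from parnet import SynthSpec, write_dataset

spec = SynthSpec(n_classes=5, n_sequences_per_class=20,
                 frames_per_sequence=60, seed=7)
table = write_dataset(spec, "scratch_dataset.csv", "scratch_dataset.yaml")

counts = np.bincount(table.labels)
print(f"wrote scratch_dataset.csv: {table.n_frames} frames x "
      f"{table.features.shape[1]} coordinates, {table.n_classes} classes")
print(f"frames per class: {counts.tolist()}")
print(f"signal mix: {spec.signal_mix}")
# Each class contributes 20 recordings of 60 frames; recordings never share
# a window later because the loader tracks recording boundaries.
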