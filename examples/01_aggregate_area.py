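"""Measure sheet-aggregate areas on a synthetic micrograph.

Generates a micrograph with five bright aggregates over Gaussian background
noise (10% of the aggregate contrast), measures each one with the adaptive
threshold T = (max − min) − 1.5σ computed from its own masked region, and
compares the recovered nm² areas with the generator's ground truth.
"""

import numpy as np

from capsheet import ThresholdParams, measure_all
from capsheet.synthetic_data import MicrographSpec, gen_aggregate_micrograph

spec = MicrographSpec(seed=7)  # 512 px, 3.21 Å/px, 5 disks, noise sd 10
image, mask, truth = gen_aggregate_micrograph(spec)
table = measure_all(image, mask, ThresholdParams(kappa=1.5))

print(table.to_string(index=False))
errors = np.abs(table["area_nm2"].to_numpy() - truth.areas_nm2) / truth.areas_nm2
print(f"\nmedian relative error vs ground truth: {np.median(errors):.2%}")
print("Each row is one aggregate: its per-region threshold (in intensity "
      "units), the pixels passing it, and the area in nm² at 3.21 Å/px; "
      "the error line shows how closely thresholding recovers the true "
      "footprint under noise.")
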