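"""Detect the broad 2.5–3.2 Å mineral band in a diffraction exposure pair.

Generates a matched target/background pair of low-dose selected-area
electron diffraction patterns — both carry the vitreous-ice rings at 3.71 Å
and 2.15 Å, only the target carries a 10% mineral band at 2.85 Å — then runs
the full analysis: beam centering, radial averaging, normalization on
q = 0.094–0.113 Å⁻¹, background division, and band scoring.
"""

import numpy as np

from capsheet import analyze_pair
from capsheet.synthetic_data import (DEFAULT_MINERAL_BAND, DiffractionSpec,
                                     gen_diffraction_pair)

spec = DiffractionSpec(mineral_band=DEFAULT_MINERAL_BAND, poisson_noise=True,
                       seed=11)
target, background, truth = gen_diffraction_pair(spec)
ratio, detection = analyze_pair(target, background)

at_ice = ratio.ratio[np.argmin(np.abs(ratio.d - 3.71))]
print(f"ratio at the 3.71 Å ice position : {at_ice:.3f}  (≈1: ice dampened)")
print(f"band score over d = 2.5–3.2 Å    : {detection.score:.4f}")
print(f"detection threshold (3σ null)    : {detection.threshold:.4f}")
print(f"band detected                    : {detection.detected}")
print("The score is the mean excess of the target/background ratio over a "
      "linear baseline fitted beside the band; scores above the "
      "null-calibrated threshold indicate octacalcium-phosphate-like "
      "mineral in the selected area.")
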