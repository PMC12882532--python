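# capsheet

Quantitative analysis of calcium-phosphate (CaP) sheet-aggregates in
cryo-EM data. Cultured neurons can precipitate mitochondria-sized,
sheet-forming CaP aggregates with an octacalcium-phosphate-like (OCP-like)
ultrastructure; characterizing them requires three measurements that this
package implements as a tested, reusable pipeline:

1. **Aggregate area** (`capsheet.area_quant`): each segmented aggregate is
   thresholded adaptively at

   `T = (max − min) − κ·σ`

   where max, min and the population standard deviation σ are computed over
   that aggregate's masked region alone (κ = 1.5 by default). Pixels pass
   when their min-shifted value meets T, and the passing count converts to
   nm² through the pixel size (3.21 Å/px by default). Condition groups are
   compared with pairwise two-sided Wilcoxon rank-sum tests under
   Benjamini–Hochberg (BH) correction.

2. **Diffraction band detection** (`capsheet.diffraction_profile`): low-dose
   selected-area electron diffraction (LDSAED) images are centered via the
   centrosymmetric autoconvolution peak, radially averaged into
   one-pixel-radius bins, normalized by the mean intensity over
   q = 0.094–0.113 Å⁻¹, and divided by a matched background exposure to
   dampen the vitreous-ice rings at d ≈ 3.71 and 2.15 Å (d = 1/q). The broad
   OCP-like band spanning d ≈ 2.5–3.2 Å is scored as the mean excess of the
   ratio over a linear baseline fitted on flanking windows, with a detection
   cutoff calibrated at 3σ of the null-score distribution.

3. **Marker colocalization** (`capsheet.stats_compare`): the 2×2 table of
   aggregate location (intracellular/extracellular) × mitochondrial-marker
   status is analyzed with a two-sided Fisher's exact test, the sample odds
   ratio ad/(bc), and a Woolf (log-odds normal) or conditional-exact 95% CI.

Every stage is exercisable end-to-end on ground-truthed synthetic data
(`capsheet.synthetic_data`), so the pipeline's recovery properties —
exactness on clean inputs, error under noise, detection power and false
positive rate — are measurable without any microscope data.

## Worked example

`python examples/02_diffraction_band.py` builds a matched target/background
LDSAED pair — both with ice rings and Poisson counting noise, the target
additionally carrying a 10%-amplitude mineral band at 2.85 Å — and runs the
full analysis:

```
ratio at the 3.71 Å ice position : 1.010  (≈1: ice dampened)
band score over d = 2.5–3.2 Å    : 0.0638
detection threshold (3σ null)    : 0.0145
band detected                    : True
```

Background division leaves the ice position at ≈1 (non-specific scattering
cancels), while the injected band produces a score four times the
null-calibrated cutoff. `python examples/03_colocalization.py` analyzes the
observed location × marker counts (28/18 extracellular +/−, 33/3
intracellular +/−):

```
extracellular marker-positive : 61%  (n=46)
intracellular marker-positive : 92%  (n=36)
odds ratio                    : 0.141
two-sided Fisher p            : 0.001883
```

i.e. extracellular aggregates are markedly less likely to carry the
mitochondrial marker than intracellular ones.

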