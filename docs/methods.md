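# Methods

This note documents the models, parameter choices and numerical conventions
behind `capsheet`, and what the synthetic-data tests do and do not show
about real data.

## Adaptive-threshold area measurement

Each aggregate is measured inside its own segmentation-mask region. With
region intensities v, the threshold is

    T = (max(v) − min(v)) − κ·σ(v),        κ = 1.5 by default,

where σ is the **population** standard deviation (the formula reads as a
descriptive statistic of the region, not an estimator). A pixel counts when
its min-shifted value satisfies `v − min(v) ≥ T`. Design choices, made
where the procedure is genuinely underdetermined:

- **Min-shift comparison.** T is a range-derived level; comparing it
  against raw values would make the measurement depend on the arbitrary
  intensity offset of the detector. Comparing min-shifted values makes the
  rule exactly invariant under `v → v + c`, which tests assert.
- **Ties pass** (`≥`): deterministic and monotone — raising κ lowers T and
  can only add pixels, never remove them.
- **All passing pixels count**, regardless of connectivity: the output is
  one area per aggregate with no component-selection rule. Both this and
  raw-vs-shifted comparison are configuration-visible rather than hidden.
- **Degenerate uniform regions** give T = 0 and count every pixel; a
  warning is logged since this usually indicates a mask over flat
  background.
- **Polarity.** Measurement assumes density-positive (bright) aggregates;
  `invert=True` negates intensities first for dark-aggregate images.

Areas convert as `area_nm2 = count · (pixel_size_Å / 10)²`; the default
pixel size is 3.21 Å/px, the acquisition setting of the area-measurement
protocol. Groups are summarized by median and interquartile range and
compared pairwise with two-sided Wilcoxon rank-sum tests, BH-adjusted
across all pairs, starred at p < 0.05 / 0.01 / 0.001 (strict inequalities).

## LDSAED radial profiling and band detection

Calibration uses the Nyquist spatial frequency at the detector edge
(1.75 Å⁻¹ for the 670 mm camera geometry, which is carried as metadata
only): `q_per_pixel = nyquist_q / (N/2)` for an N×N image.

- **Centering.** Diffuse powder-like patterns are centrosymmetric, so the
  autoconvolution `C(s) = Σᵢ I(i)·I(s−i)` peaks at s = 2·center. A coarse
  centroid of the brightest 0.1% of pixels (the central beam) restricts the
  search; the peak is interpolated parabolically per axis. On synthetic
  patterns with Poisson noise this recovers injected offsets up to 8 px
  with sub-0.1 px error.
- **Radial averaging.** One-pixel-radius bins by rounded distance; bins
  with q < 0.03 Å⁻¹ (beam-saturated) or q > 0.95·Nyquist (corner
  undersampling) are dropped. A brute-force per-pixel grouping oracle
  checks bin means exactly.
- **Normalization** is division by the mean intensity over
  q = 0.094–0.113 Å⁻¹, a featureless low-q reference band. Division (vs
  subtraction) makes profiles scale-free so target/background ratios are
  dimensionless.
- **Background ratio.** Per-bin target/background after normalization;
  bins with background below 10⁻⁶ of the (unit) band mean are flagged
  invalid. Shared features — the diffuse scattering envelope and the
  vitreous-ice rings at 3.71/2.15 Å — cancel toward 1.
- **Band score.** A linear baseline in q is fitted over the flank windows
  d ∈ [2.30, 2.45] and [3.40, 3.60] Å (placed between the band and the two
  ice positions); the score is the mean baseline-subtracted ratio over
  d ∈ [2.5, 3.2] Å. The detection criterion itself (flanks, linear
  baseline, 3σ-null cutoff) is this package's construction — the band was
  originally identified visually — and every piece is configurable.
- **Threshold calibration.** The default cutoff 0.0145 is 3× the standard
  deviation of scores over 200 seeded background-only pairs at the
  generator's default acquisition settings (`calibrate_band_threshold`
  recomputes it). At the default 0.10 band amplitude the noise-free score
  is ≈0.062, giving large detection margin; measured operating
  characteristics on noisy replicates are ~100% power with 0 false
  positives in 200 + 200 trials.

## Synthetic-data generators

The generators emulate the statistical structure the analyses consume, not
the image physics.

- **Micrographs** (512 px², 3.21 Å/px): disk/ellipse/fibrous aggregates of
  uniform intensity 100 (arbitrary density units) placed without overlap,
  over Gaussian background noise of sd 10 (10% of contrast — a
  conservative noise level for high-contrast electron-dense aggregates),
  optional Poisson resampling. Fibrous texture is additive sinusoidal
  striping inside the footprint; ground truth is always the footprint,
  since the measurement targets total aggregate area, not individual
  sheets. Masks are footprints dilated by 6 px, emulating the generous
  hand-drawn segmentations the measurement expects: the region then
  contains both aggregate and nearby background, which is what makes the
  range-based threshold informative. With the margin set to 0 the mask is
  footprint-exact and mask pixels equal ground-truth counts.
- **Diffraction pairs** (512 px², Nyquist 1.75 Å⁻¹): noise-free intensity
  `I(q) = A·e^(−kq)·[1 + Σ ampᵢ·G(q; 1/dᵢ, wᵢ) + band(q)]` with A = 1000
  expected counts, k = 8 Å, Gaussian rings of unit peak height; ring and
  band amplitudes are dimensionless fractions of the local envelope. Ice
  rings default to (3.71 Å, 0.30, 0.015 Å⁻¹) and (2.15 Å, 0.15,
  0.025 Å⁻¹) — broad and diffuse, as for amorphous ice; the mineral band
  to (2.85 Å, 0.10, 0.035 Å⁻¹) so it spans roughly 2.5–3.2 Å. Target and
  background share envelope, rings and true center; only the target
  carries the band. Poisson noise, when enabled, draws independently for
  the two exposures from one seeded stream. The exponential envelope and
  Gaussian ring shapes are deliberate minimal parameterizations of a
  monotone diffuse background and "broad diffuse rings"; the true noise
  statistics of the detector are not claimed.
- **Colocalization counts**: independent binomial draws per location group
  (intracellular drawn first), defaults n = 36/46 at p = 0.92/0.61.
- **Area groups**: log-normal samples `median·exp(N(0, log_sd²))` at the
  four reported condition medians (99,318 / 88,134 / 66,782 / 56,475 nm²;
  n = 107/100/94/94). log_sd defaults to 0.8, a right-skew typical of
  size distributions and wide enough that only well-separated medians are
  reliably significant at these sample sizes.

What passing tests show: the estimators are exact on clean inputs, robust
at the stated noise levels, and correctly calibrated as statistical tests.
What they do not show: robustness to structured backgrounds (cellular
material, carbon film edges), segmentation error, detector artifacts,
astigmatic or elliptically distorted diffraction patterns, or
non-radially-symmetric crystalline texture — none of which the generators
model.

## Statistics

- **Fisher's exact test** uses the probability-mass two-sided rule (sum of
  margin-fixed tables no more probable than observed), the dominant
  convention; the reported odds ratio is the sample cross-product ad/(bc)
  (∞ when only bc = 0, undefined when both products vanish). The default
  95% CI is the Woolf log-odds normal interval (method-tagged, undefined
  with empty cells); a conditional-exact interval obtained by inverting
  noncentral hypergeometric tail tests is available and matches R's
  `fisher.test` to ~4 decimals.
- **Wilcoxon rank-sum** uses the exact permutation distribution when the
  smaller sample has ≤ 10 observations and the pooled data are tie-free,
  otherwise the normal approximation with tie-corrected variance and
  continuity correction; the branch taken is recorded. Null calibration
  over 2,000 simulations gives a type-I rate within 0.05 ± 0.01.
- **BH adjustment** is the standard step-up (`p₍ᵢ₎·m/i`, cumulative
  minimum from the top, capped at 1, returned in input order). Note the
  adjustment is not idempotent in general — re-adjusting adjusted values
  re-inflates them by m/i — so only the definitional form and monotonicity
  are guaranteed.

## Numerical and I/O conventions

Arrays are (row, col), 0-based, origin top-left; the geometric center of an
N×N image is ((N−1)/2, (N−1)/2). MRC2014 files are written little-endian,
mode 2 (float32) for intensities and mode 6 (uint16) for masks, pixel size
in the cell dimensions and the Nyquist frequency in a `NYQUIST_Q=` header
label; a file's own calibration always wins over flags and defaults, which
apply (with a warning) only when the file carries none. Problem sizes in
the validation runs — 512² diffraction images, 256² recovery micrographs,
200-replicate operating characteristics, 2,000-replicate null calibration
— were chosen as the smallest scales at which the measured rates are
stable to within the asserted tolerances.

## Known limitations

Masks are inputs: no segmentation is provided. No CTF/defocus/dose image
formation, no 3D tomogram simulation, no crystal indexing or powder-pattern
simulation from unit cells, no multi-frame movie handling. The band
detector assumes an isotropic pattern; strongly textured (spotty) patterns
would need azimuthal analysis.
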