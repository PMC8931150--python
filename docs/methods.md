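# Methods

## Dosage model

An X-linked target gene in an X0/XX species has copy number k = 1 in
males and k = 2 in females; an autosomal single-copy reference gene has
k = 2 in both. Both quantification backends estimate the ratio
`CNV = 2 · q_target / q_reference`, where q is a per-gene template
quantity; the factor 2 anchors the scale so that CNV is the target's
absolute copy number per diploid genome.

## ddPCR quantification

Droplet partitioning follows the standard Poisson occupancy model:
with N accepted droplets and a negative fraction f, the mean occupancy is
λ = −ln f and the concentration c = λ/v with droplet volume v.
Implementation notes:

- **Droplet volume** defaults to 0.85 nL, a common vendor constant, and
  is configurable per well. Absolute concentrations scale with 1/v, but
  the CNV ratio is volume-free, so sexing is insensitive to this choice.
- **QC**: wells with fewer than 10,000 accepted droplets are excluded
  (configurable). Replicate wells for the same specimen × gene are pooled
  by summing droplet counts before inversion, which is the maximum-
  likelihood combination under the Poisson model.
- **Degenerate wells**: an all-positive well saturates the model (λ
  diverges) and raises a saturation error rather than returning a capped
  value; an empty well raises. Inputs are already-thresholded counts —
  "rain" (intermediate-amplitude droplets) is upstream of this package.

## qPCR quantification

A dilution series (default 20, 10, 5, 2.5, 1.25 ng) is fitted by
ordinary least squares of Ct on log₁₀(input). The slope gives the
amplification factor `E = 10^(−1/slope)`; percent efficiency is
`(E − 1)·100`. In the Pfaffl ratio the **factor** form (≈2) is the
exponent base — percent values are converted via `E = 1 + E%/100`,
because the formula requires the per-cycle multiplication factor.

- **Slope rule**: raw-Ct quantification proceeds only when
  |slope_target − slope_reference| ≤ 0.1 (reported to 3 d.p.). A failing
  pair raises unless explicitly overridden, and the override is logged.
- **Technical replicates** are aggregated by the arithmetic mean of Ct.
  A replicate SD above 0.5 cycles, or any missing replicate, sets an
  outlier flag; a specimen × gene with no amplifying replicate at all is
  an error naming the specimen and gene.
- **ΔCt sign**: ΔCt = (calibrator mean Ct) − (sample mean Ct). Against a
  male calibrator a female's target ΔCt is ≈ +1 cycle, so her CNV is
  ≈ E^1 ≈ 2. The calibrator's own CNV is set to exactly 1.0 rather than
  recomputed, avoiding spurious ±1-ulp noise around the anchor.
- **Calibrator selection**: with known sexes, one male is drawn uniformly
  per run under the caller's seed (matching the one-random-male-per-run
  protocol). With unknown sexes (larval cohorts) the putative male is the
  specimen **maximising** mean Ct_target − mean Ct_reference: a
  single-copy target crosses threshold about one cycle later than the
  two-copy reference-scaled expectation. Ties break lexicographically so
  the choice is deterministic. This works whenever the run contains at
  least one true male, which is the normal situation for field-collected
  broods; an all-female run silently calibrates on a female and would
  halve every CNV, which is why cohort-level bimodality should be checked
  (below).
- **Runs are independent**: each run gets its own calibrator and CNVs are
  never compared across runs through a universal calibrator. Run-level
  Ct offsets (plate, instrument, master-mix batch) cancel exactly in the
  calibrator-relative difference.

## Sex calling

Threshold 1.5 — the midpoint of the expected modes 1 and 2 — separates
males from females; a value exactly at threshold is ambiguous. Calls
outside ±0.5 of the expected mode are still made but flagged
out-of-band (field collections contain such values and they were
morphologically confirmed correct calls). Biological replicates that
disagree produce an ambiguous call with a conflict flag rather than a
majority vote: in a diagnostic context a silent vote can hide an
extraction or labelling error.

## Validation statistics

- **Descriptive summaries** per called sex: mean, sample SD (n−1),
  t-based 95% CI half-width, min/max, CV. Cohort summaries with two
  biological replicates are computed over per-specimen means.
- **Bimodality amplitude** BA = (A_s − A_v)/A_s on a fixed-width
  histogram, where A_s is the smaller of the two tallest local-maximum
  bins and A_v the minimum bin between them; < 2 local maxima scores 0.
  Bin width 0.1 over [0, 3] suits copy numbers clustering at 1 and 2.
  No standard binning exists for this statistic, so BA values are
  comparable within this package but not across software; here BA > 0 is
  a qualitative gate that the cohort actually separated into two modes
  before thresholding is trusted.
- **Replicate agreement**: paired t-test on per-specimen replicate pairs
  (two-sided; identical vectors are rejected as degenerate rather than
  returning an infinite statistic), with Shapiro–Wilk (Royston AS R94,
  via scipy) confirming normality of the differences.
- **Truth association**: phi coefficient of the 2×2 confusion table,
  p-value from χ² = nΦ² on 1 df; any zero margin is an error, not a NaN.
- **Sex ratio**: Pearson's uncorrected χ² against 1:1, df = 1.
- Two-sided p-values throughout; no multiple-testing correction is
  applied (the battery is descriptive, not a screening procedure).

## Synthetic data generator

The forward model mirrors what the pipeline inverts:

- qPCR: `Ct = y_int + slope · log₁₀(input_ng · k/2) + run_effect + ε`,
  run_effect ~ N(0, sd_run) shared by **every well of a run** (both
  genes), ε ~ N(0, sd_tech) independent per technical replicate. Cts
  beyond the 40-cycle limit are censored as non-amplifying. Defaults:
  curves (−3.324, 38.476) and (−3.341, 36.528) for target/reference —
  a well-optimised ~100%-efficiency assay — 20 ng input, triplicates,
  sd_tech = 0.15 cycles, sd_run = 1.0 cycles.
- ddPCR: true concentration proportional to copy number (300 copies/µL
  per haploid copy by default, a mid-range loading), droplet counts
  `n_pos ~ Binomial(N, 1 − e^{−cv})` with N = 17,000 droplets of
  0.85 nL.

With sd_tech = 0.15 the simulated qPCR copy-number SD is ≈ 0.24 for
females and ≈ 0.12 for males — the dispersion regime of large
multi-run field collections — while sd_run only shifts whole plates and
cancels in calibration. All draws come from `numpy.random.default_rng`
under a single config seed; identical seeds give identical cohorts,
tables, and droplet counts.

**What the generator does not emulate**: PCR inhibition and
DNA-quality gradients between specimens, droplet rain, pipetting-volume
error, primer-site polymorphisms, and cross-run efficiency drift. Tests
passing on synthetic data therefore demonstrate that the estimators
invert the assumed measurement model and tolerate its stated noise — not
that any particular wet-lab protocol achieves that noise.

## Problem sizes

The simulation-based checks use a 448-adult cohort split over 28 runs
(16 specimens per run, the scale of a multi-plate field study) averaged
over 20 seeds, 200-draw Poisson round trips at 17,000 droplets, and
20-specimen noise-free cohorts for exactness checks. These sizes give
sub-second, fully deterministic runs while keeping Monte-Carlo standard
errors well below the tolerances being asserted.

## Known limitations

- The threshold caller assumes exactly two dosage classes (1 vs 2
  copies); duplications of the target (CNV > 2) would be called female
  and only the out-of-band flag would hint otherwise.
- Putative-male calibration fails silently on an all-female run (every
  CNV halves); the BA > 0 gate and the out-of-band flags are the
  intended tripwires.
- Reported ddPCR concentrations depend linearly on the configured
  droplet volume; only ratios are portable across instruments.
- The bimodality amplitude depends on binning (see above) and is not
  comparable to values computed with other bin choices.
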