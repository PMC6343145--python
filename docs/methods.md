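# Methods

## Scope and model

`dilongqc` implements the chemometric core of a UHPLC-DAD quality-control
assay for Guang Dilong (*Pheretima aspergillum*): simulation of 260 nm
detector traces, peak processing, chromatographic fingerprinting with
correlation similarity, six-nucleoside calibration and quantitation,
single-laboratory validation statistics, and adenosine-based adulterant
classification. Everything downstream of the simulator is
instrument-agnostic and applies unchanged to imported two-column
time/intensity CSV traces.

## Chromatogram simulator

A trace on the grid 0–16 min at 0.01 min steps is

    y(t) = drift(t) + Σ_k h_k · exp(−(t − r_k)² / 2σ²) + ε(t)

- **Peak areas.** For analyte *k* at injected concentration *c* (µg/mL),
  the true area (mAU·min) follows the assay's calibration line
  `A_k = a_k c + b_k`, clipped at zero; a zero concentration emits no
  peak at all (so blank injections are exactly flat). The peak height is
  `h_k = A_k / (σ√(2π))`. Reusing the published lines as the
  instrument's true response makes quantitation round-trips exact by
  construction, which is what the content fixtures exploit.
- **Retention times.** Inosine elutes at 9.35 min (the assay's reference
  peak). The remaining nominal RTs (3.20, 4.60, 6.10, 11.20, 13.40 min)
  are package constants chosen inside the gradient window in the
  observed elution order; their exact values are immaterial to every
  statistic computed here. Each injection jitters every RT by
  N(0, 0.01 min).
- **Peak width.** σ = 0.05 min, a typical sub-2-µm-column width; the
  non-goal of asymmetric (exponentially modified Gaussian) tailing is
  deliberate — symmetric peaks suffice for area-based statistics.
- **Noise and drift.** White Gaussian noise (SD 0.05 mAU) plus one slow
  sinusoidal drift cycle (amplitude 0.2 mAU, random phase). These are
  small relative to analyte peaks (hundreds of mAU), matching a modern
  DAD at 260 nm on a clean extract.
- **Determinism.** Every generator is a pure function of its inputs and
  a seed; batch-level functions derive per-injection seeds by
  `SeedSequence.spawn`, so studies are reproducible element-wise.

## Study simulation

The default design reproduces the surveyed market roster: batches 1–22
authentic *P. aspergillum*, 23–31 *A. obscuritoporus*, 32–42 *M. magna*
(the 9/11 adulterant split follows the survey's source table). Per
batch, dry-weight contents are drawn **log-uniformly** within the
per-species min–max content ranges observed in the published survey;
the survey states no between-batch distribution, and log-uniform spans
the printed variability (up to ~20-fold per analyte) without asserting
more. Adenosine is exactly zero for the authentic species — its absence
is the marker the classifier relies on.

Contents convert to extract concentrations through the preparation
(1.0 g into 20 mL): `c = content / 20`. When an analyte's implied
concentration exceeds its linear range (high-inosine batches routinely
do), the smallest integer dilution bringing it in range is applied
*per analyte* and recorded in the ground truth; quantitation multiplies
it back. The assay description is silent on dilution, so this rule is a
declared package choice that keeps every injected concentration inside
the calibrated range.

## Signal processing

- **Baseline.** Morphological opening (rolling minimum then maximum,
  window 1.0 min) of a lightly pre-smoothed copy, polished with a
  rolling mean, subtracted from the raw trace. Opening follows offsets,
  ramps and slow drift essentially exactly while removing peaks narrower
  than the window; pre-smoothing stops the erosion from tracking noise
  minima (residual offset well under one noise SD).
- **Detection.** Apex candidates are local maxima of a Gaussian-smoothed
  copy (σ 0.02 min) above max(min_height, 3×noise floor); smoothing
  suppresses single-sample noise spikes, and apexes are refined to the
  raw-trace maximum. The noise floor is estimated robustly as
  1.4826·median(|Δy|)/√2, which is exactly zero on noiseless traces.
- **Integration.** Bounds at the flanking valley between adjacent apexes
  or where the signal falls below 1% of the peak height, whichever comes
  first; area by trapezoid between bounds. The 1% cut truncates a
  Gaussian at ±3.03σ, so integrated areas systematically read ~0.25%
  low. This bias cancels in RSDs, nearly cancels in recoveries, and is
  well inside the 1% area tolerance used throughout; it is the price of
  not assuming a peak shape at integration time.
- **S/N convention.** Height over the standard deviation (n−1) of the
  baseline-corrected signal, either the global robust estimate
  (detection) or a user-chosen peak-free window (`estimate_snr`). The
  assay does not define its convention; this is the simplest testable
  one. Noiseless traces report infinity.
- **Analyte assignment.** Nearest reference RT within ±0.10 min, one
  peak per analyte (nearest wins). The tolerance is 10× the grid step
  and ≫ the RT jitter, yet ≪ the 1.2 min minimum inter-analyte spacing;
  reference RTs closer than twice the tolerance are rejected as
  ambiguous configuration.

## Fingerprinting

Common peaks are formed by single-linkage agglomeration of apex RTs
along the time axis, merging while the inter-cluster gap is ≤ 0.10 min
and capping the cluster diameter at twice that; ties break toward the
earlier-eluting pair. No time warping is applied: the simulated jitter
(0.01 min SD) is far below the tolerance, so cluster assignment alone
realizes retention-time normalization.

The reference peak defaults to the highest-mean-area peak among those
present in every batch — on any realistic content draw this is inosine
(its content floor exceeds every other analyte's ceiling in area terms),
reproducing the 9.35 min reference. A `fixed-rt:<t>` strategy is
available for externally imposed references. RRT and RPA are per-batch
ratios to the reference peak's RT and area.

The similarity index is, by default, the Pearson correlation between a
batch's full baseline-corrected trace and the mean fusion vector
(pointwise mean of the set). The alternative reading — correlating the
few-dimensional common-peak area vectors — is provided
(`peak_vector_similarity`) but not default: full-trace correlation is
stable for fingerprints with as few as five peaks. Characteristic peaks
are those with prevalence ≥ 0.9 across batches.

## Quantitation

OLS (area on concentration) with Pearson *r* — the assay reports the
correlation coefficient, not R². Inversion is `x = (y − b)/a` with
range enforcement; sub-blank areas clamp to zero with a warning and
below-range/above-range values either raise or, with extrapolation
enabled, warn. LOD/LOQ interpolate the measured (concentration, S/N)
series linearly at S/N 3 and 10, extrapolating through the origin below
the lowest point (no interpolation rule is stated by the assay; linear
is the minimal choice and makes LOQ/LOD = 10/3 exact for linear-through-
origin responses). Per-batch content reporting flags each analyte
`nd` (S/N < 3 or no peak), `below_loq` (3 ≤ S/N < 10, value reported,
not censored) or `ok`.

## Validation statistics

All RSDs use the sample (n−1) standard deviation. The simulated battery
mirrors the assay's replicate design: intra-day precision on 6 replicate
injections (RSD of peak areas), inter-day precision as the RSD of day
means over 3 consecutive days (the assay's aggregation is unstated;
day-means over 3 values matches its n = 3), repeatability on 6
independently prepared solutions and stability on 5 timed re-injections
(both as content RSDs), and recovery by standard addition — spike ≈ the
sample's own amount, 3 spiked replicates, recovery
`(found − original)/spiked × 100%`. The test sample's contents are those
of the survey's repeatability batch (No. 23), whose extract sits inside
every linear range. Under the default noise model the simulated RSDs are
of order 0.01–0.1% — comfortably below the assay's ≤ 2.84% acceptance —
because the simulator models detector noise but not the injection-volume
and preparation variability that dominate real replicate scatter; the
validation machinery is exercised, not the instrument's error budget.

## Classification

A batch is *adulterant* iff adenosine is detected (S/N ≥ 3) —
presence, not quantifiability, is the criterion, because authentic
material contains none at all. Similarity below the floor (default 0.80,
just under the weakest authentic batch observed, 0.811) adds a
fingerprint-atypical warning without overturning the verdict: the marker
is chemical, the fingerprint is corroborative.

## Problem sizes and determinism of reported numbers

The acceptance script simulates 22 authentic batches for the similarity
floor, 6-level calibration series for all six analytes, the full
validation battery (39 injections) for recovery, and a 3-copy noiseless
mutual-pattern fixture for reference-peak selection; it completes in
seconds. The test suite additionally sweeps 100 seeded 22-batch studies
for the similarity-floor property and 20 seeded 42-batch studies for
end-to-end classification accuracy.

## Known limitations

- Symmetric Gaussian peaks; no tailing, co-elution, or carryover, so
  the valley-splitting integration path is rarely exercised hard.
- Single-wavelength traces only; no DAD spectral peak-purity modelling.
- The noise model understates real replicate variability (see above);
  simulated RSDs should not be read as the instrument's.
- Content distributions within species are a declared stand-in
  (log-uniform over observed ranges), not an empirical fit.
- The linear ranges used are the calibration table's values; the
  coarser rounding printed elsewhere in the assay description refers to
  the same series.
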