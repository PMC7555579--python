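# Methods

This note documents the models, conventions and numerical choices behind
`wbdwi`, and what the synthetic phantom validation does and does not show.

## Signal model and ADC mapping

DWI magnitude signal is modelled as mono-exponential in the b-value,
`S(b) = S₀ exp(−b·ADC)`. With the acquired pair b = 50 / 800 s/mm² the map
is `ADC = ln(S₅₀/S₈₀₀)/750`, reported in 10⁻⁶ mm²/s so that typical values
read 600–1000 for hypercellular lymphoma, ~1600 for soft tissue, ~3000 for
free water. b = 50 is used as the true low b-value rather than idealized to
b = 0; using a small nonzero b suppresses the perfusion (IVIM) contribution
to the decay estimate. Voxels with a nonpositive signal at either b-value
carry no information and are marked invalid and excluded from all
histograms. Negative ADC values (possible under noise when S₈₀₀ > S₅₀) are
retained by default and only summarized per volume; clipping is available
as a configuration switch since vendor behavior differs. The mapping is
scale-invariant (a global intensity rescale of both b-volumes leaves ADC
unchanged) and exactly inverts the generator's signal model on noiseless
phantoms; both properties are tested. A precomputed (scanner-side) ADC map
can be ingested instead of recomputing.

## Threshold segmentation

A voxel enters the mask when its b800 intensity is at least
`th/100 × reference`. Commercial implementations do not publish what the
percentage is relative to; we define the reference as the **99.9th
percentile of strictly positive voxel intensities** ("robust maximum") so a
single hot voxel cannot move every mask, with `max` and `mean + k·sd`
selectable alternatives. The reference is per volume (per timepoint):
each acquisition has its own arbitrary intensity scale, so a per-patient
global reference would couple timepoints through scanner gain. The mask is
used completely unedited — no morphology, hole filling, connected-component
filtering or organ exclusion — which is precisely the procedure variant
under study; hyperintense organs are therefore *supposed* to contaminate
the mask. Masks are nested by construction: mask(th₂) ⊆ mask(th₁) for
th₂ ≥ th₁, so DV(th) is non-increasing.

## Features

Per mask: DV = voxel count × voxel volume / 1000 (cm³, pure voxel counting,
no partial-volume interpolation), plus eight first-order statistics of the
valid masked ADC values:

| statistic | convention |
|---|---|
| mean, median | arithmetic; percentile-based median |
| SD | sample SD, n−1 denominator (needs n ≥ 2) |
| 5th / 95th percentile | linear interpolation between order statistics |
| skewness | Fisher–Pearson g₁, population moments, no bias correction (n ≥ 3) |
| excess kurtosis | Fisher g₂ (normal → 0), no bias correction (n ≥ 4) |
| entropy | Shannon, base 2, 1024 bins fixed over [0, 4000]×10⁻⁶ mm²/s |

Entropy uses a **fixed** range with out-of-range values clamped into the
edge bins, so values are comparable across patients and timepoints and
bounded by log₂(1024) = 10 bits. A 256-bin convention is ruled out by
published whole-body entropy values around 8.3–8.5 bits, which exceed
log₂(256) = 8. Statistics that are undefined for a mask (too few voxels, or
zero spread for the standardized moments) are carried as NaN and surfaced
in the completeness report rather than silently dropped. All eight
statistics are verified against an independent direct-formula oracle to
≤ 10⁻⁹ relative error.

Percentage changes are `Δf⁰ᵀ = 100(fᵀ − f⁰)/f⁰` (T = 1, 2) and
`Δf¹² = 100(f² − f¹)/f¹`; a zero denominator yields a flagged missing
record.

## Statistics

Group comparison is CMR vs PMR at the relevant timepoint; stable and
progressive patients are excluded. Four comparison modes restrict which
feature sets may be used: `predict_interim` (baseline features only),
`predict_eot` (baseline, interim, Δ⁰¹), `assess_interim` (interim, Δ⁰¹),
`assess_eot` (end-of-treatment, Δ⁰², Δ¹²).

* **Normality gate**: Lilliefors-corrected Kolmogorov–Smirnov per group
  (the correction is required because mean and SD are estimated from the
  sample). Groups with n < 4 or zero variance are treated as non-normal;
  the rank test is then the safe default at these sizes.
* **Location test**: Welch t-test when both groups pass the gate, otherwise
  two-sided Mann–Whitney U — exact by full null enumeration when the
  combined n ≤ 14 and the data are tie-free (the regime of small clinical
  cohorts), tie-corrected normal approximation otherwise. The exact p is
  verified against a brute-force permutation oracle over all rank patterns
  with n₁, n₂ ≤ 5.
* **ROC**: built only for features with p < 0.05, mirroring the two-stage
  reporting convention of small exploratory studies. The positive class is
  PMR (poor response); orientation is flipped per feature so AUC ≥ 0.5 and
  is always reported, because whether PMR lies above (DV) or below (ADC
  percentiles) the CMR group genuinely varies by feature. AUC is computed
  as the concordant-pair fraction and equals U/(n₁n₂) identically. The
  operating cutoff maximizes Youden's J = sens + spec − 1 over midpoints
  between consecutive distinct scores (so cutoffs are in feature units and
  classify identically to any point in the same gap); ties are broken
  toward higher specificity, then toward the more conservative cutoff.
  Accuracy is (TP+TN)/N — the prevalence-weighted mean of sensitivity and
  specificity; displayed values are rounded to integer percent, unrounded
  values kept.
* No multiple-testing correction is applied to the significance gate
  (matching the single-threshold convention this analysis replicates);
  Benjamini–Hochberg q-values are printed as a clearly supplementary
  column.

Under a null cohort (no group effect) the measured per-feature type-I error
is ≈ 0.05–0.06, inside the [0.02, 0.09] calibration band the test suite
enforces over ≥ 1000 simulated features.

## Phantom generator

The phantom is a stylized torso, not an anatomical atlas: an
elliptic-cylinder soft-tissue body in air, a brain, two kidneys, a spleen,
and a vertical bone-marrow stripe — exactly the confounders an unedited
threshold mask picks up. Defaults (S₀ in arbitrary units, ADC in
10⁻⁶ mm²/s): background 300/1600±200, brain 900/800±100, kidneys
950/1800±150, spleen 850/850±100, marrow 500/600±100, lesions
1000/900±150. Voxelwise ADC is drawn once per phantom from the region's
normal distribution (negative draws clipped to zero); S(50) and S(800)
follow the mono-exponential model; independent Rician noise
(`√((S+n₁)² + n₂²)`, nᵢ ~ N(0, σ²)) is applied per b-value volume, matching
magnitude-MR statistics — the sample mean of the noisy lesion signal agrees
with the analytic Rician mean to <2 % and its bias is <3 % at SNR ≥ 5
(tested). Default grid 96×96×220 at 2×2×5 mm (~2 M voxels); default
σ = 10 gives lesion b800 SNR ≈ 50.

Longitudinal response scenarios scale each lesion between timepoints:
volume factors applied to radii as cube roots, ADC factors multiplying the
lesion ADC mean and SD, and marrow S₀ raised ×1.6 at T1/T2 (chemotherapy-
activated marrow). Defaults, chosen once as order-of-magnitude responder
biology since no quantitative effect sizes are established: CMR volume
→ 25 %/5 % at T1/T2 with ADC ×1.30/×1.45; PMR volume → 70 %/50 % with ADC
×1.05/×1.10. Cohort simulation randomizes per patient a bulky disease load
(3–6 lesions, semi-axes 15–35 mm, clamped on desk-scale grids so lesions
fit) with lesion ADC mean ~ N(900, 60) and SD ~ U(120, 180); partial
responders are given a ×1.6 higher baseline lesion volume, consistent with
the observation that baseline disease load predicts poorer response.

### What the phantom shows — and what it does not

Passing tests demonstrate internal correctness (segmentation, features,
statistics, determinism) and recoverability of ground truth under the
pipeline's own assumptions: at SNR 50 the masked lesion ADC mean is
recovered within 2 % and DV within 10 % of truth at ≥ 4× lesion/background
contrast. They do **not** demonstrate clinical validity: the phantom has no
susceptibility or motion artifacts, no station-boundary intensity steps, no
inter-timepoint misregistration, and its organ set and intensity scales are
stylized.

One mixture effect deserves note. The responder signature replicated by the
effect-direction test — complete responders show a larger T0→T1 *increase*
in masked ADC SD and 95th percentile than partial responders — holds
reliably in the phantom only at lesion-dominated thresholds (≈ 40–60 %). At
low thresholds the mask is dominated by background tissue (ADC ≈ 1600):
responder lesions shrinking and drifting *toward* the background ADC make
the masked distribution more homogeneous, which reverses the sign of
ΔADCsd. In real whole-body data the corresponding statistics were reported
across thresholds down to 5 %; the stylized tissue composition, not the
pipeline, limits the phantom here. The effect-direction test therefore
asserts the invariant at the 40 % threshold.

## Problem sizes and determinism

The test suite runs desk-scale grids (24³–48×48×80) for pipeline tests and
full-size ~2 M-voxel phantoms (20 seeds) for the parameter-recovery suite;
statistical calibration uses ≥ 1000 feature-level simulations, which
exercises the identical code path the image-level pipeline feeds. All
randomness flows from explicit seeds through `numpy.random.default_rng`;
two runs on the same inputs and configuration produce byte-identical
feature tables and reports, which the suite checks end to end.

## Known limitations

* Threshold-reference and entropy-binning conventions of proprietary tools
  are unrecoverable from the literature; ours are explicit, logged in every
  run, and configurable — results depend on them.
* Percentage thresholds are relative to a per-volume robust maximum, so DV
  values are comparable across timepoints only under similar global
  intensity distributions.
* No registration or resampling: all volumes of one patient/timepoint must
  share a grid.
* Exact Mann–Whitney inference switches to the asymptotic tie-corrected
  form whenever ties occur, even in tiny samples.
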