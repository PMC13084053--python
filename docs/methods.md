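# Methods

This note documents the models and procedures implemented in `ewingsign`,
the assumptions behind the synthetic cohort generator, the numerical choices
made where the design was genuinely open, and the limits of what the test
suite can show about real data.

## Problem setting

Ewing sarcoma (EwS) and CIC-rearranged sarcoma are fusion-driven cancers with
very low mutational burden, which makes mutation-based liquid biopsy
insensitive. The package implements a multimodal cell-free DNA (cfDNA)
analysis instead: a methylation-based ensemble classifier (EwingSign) over
300-bp genome windows, global and regional fragmentomic statistics, and an
integration layer that converts the four modality values — copy-number tumor
fraction (ichorTF), short-fragment proportion (p100–150), binding-site
coverage dip area, and the classifier's cancer score — into per-sample
positivity calls, detection metrics and longitudinal lead times.

## Window-level methylation profiles

Fragments are retained when MAPQ ≥ 10, length ∈ [70, 1000] bp and reference
span ≥ 30 bp (the span predicate never bites given the 70-bp floor but is
kept explicit). Each retained fragment increments exactly one window — the
one containing its midpoint, `floor((start+end)/2)`; off-grid midpoints are
tallied as *unassigned*, never silently dropped. NRPM (normalised reads per
million) is `counts / (cn × total_valid) × 10⁶` with an optional per-window
copy-number correction and deliberately **no** TMM normalisation.

Beta-values (methylation on a 0–1 scale) are obtained by a **linear anchor
calibration**: beta = clip(NRPM / ref, 0, 1), where `ref` is the median NRPM
over a supplied set of consistently hypermethylated (calibration) windows.
This is a transparent stand-in for enrichment-signal calibration: it maps
the hyperstable set to beta = 1, is monotone in signal, and is invariant to
uniform depth rescaling. Library QC follows the same spirit: relH is the
rate of CpG sites covered per fragment base divided by the genome CpG
density, and the hyperstable fraction is the share of fragment midpoints in
the calibration regions; a library passes when relH > 2.5 **and** the
hyperstable fraction > 0.4 (both thresholds configurable).

Tissue methylation-array profiles enter the same representation through
`array_to_profile`: counts proportional to `beta_w / Σbeta` at a chosen
depth, multinomially sampled or deterministically rounded
(largest-remainder, so counts always sum exactly to the depth).

## DMR selection

Per ensemble split, each window is tested with a two-sided Welch t-test
(configurable to Mann–Whitney) in three pairwise comparisons: EwS tissue vs
training NCCs, CIC tissue vs training NCCs, EwS vs CIC. Benjamini–Hochberg
adjustment is applied per comparison across its tested windows. A window
becomes a feature when it is significant (q < 0.05) in **all three**
comparisons, its median beta over the NCC training samples is ≤ 0.25
(cancer markers must be silent in control plasma), and it ranks in the top
200 by its minimum absolute Δβ (group-mean difference) across the
comparisons; rank ties break by ascending window id for determinism.
Windows constant in both groups with equal means receive p = 1; windows
with missing betas are skipped and reported.

## In-silico mixtures

Mixing operates on depth-normalised count proportions,
`p_w = f·t_w + (1−f)·c_w`, rescaled to a common depth — the only convention
under which `f` is interpretable as the tumor fraction of the result.
Training augmentation builds 7400 EwS+NCC and 2200 CIC+NCC mixtures at `f`
uniform in 0.005–0.1 and 10,000 NCC+NCC mixtures at proportions 0.15–0.5
(defaults; pairing uniform at random and reproducible under the mixture-set
seed).
Training mixtures are **multinomially thinned** to the target depth by
default: mixed real fragment counts carry sampling noise, and training on
noise-free expected counts lets gradient boosting learn margins so thin that
held-out samples with ordinary per-sample variance cross them. The
evaluation dilution series — every tumor × every control × 26 fixed
proportions spanning 0.001–0.05 (evenly spaced) — uses expectation mode, as
a systematic dilution grid should be deterministic.

## The EwingSign classifier

The NCC training cohort (83 samples by default) is split 75:25 into
train/validation 25 times (ceil rule: 63/20). Each split selects its own
top-200 DMR feature set against its own training NCCs, regenerates its own
mixture set, and trains 100 XGBoost sub-classifiers
(`multi:softprob`, 200 trees, row subsampling 0.5, 20 of the 200 features
considered per split node — the "mtry" mapping). Each sub-classifier sees
only mixtures generated from a fresh random 80% of the tissue arrays and
80% of the split's training NCCs. Prediction averages class probabilities
over sub-classifiers, then over ensembles, and renormalises to sum to one.
A sample is assigned the class whose score exceeds 0.5 (necessarily unique);
otherwise it is *unclassified*. The cancer score is s_EwS + s_CIC, and the
cancer call for integration is cancer score > 0.5. Unclassified samples
count as negative in detection metrics but keep their label in reports.

The scaled-down configuration used by the property suite and the acceptance
script (3 ensembles × 10 sub-classifiers, mixture counts scaled 1:25) keeps
a training run under a minute on one CPU while preserving the architecture;
cohort sizes stay at the study layout (37 EwS / 10 CIC arrays, 83 + 24
NCCs).

## Fragmentomics

* **p100–150** — proportion of retained fragments with length in
  [100, 150] bp, inclusive; the denominator is all retained 70–1000 bp
  fragments. Positivity threshold = the maximum over the reference NCC
  cohort; a sample is positive strictly above it. Optional uniform
  downsampling (without replacement, seeded) precedes the statistic.
* **5-Mb fragmentation profile** — per bin, `log2((short/long) / median bin
  ratio)` with short = 100–150 bp and long = 151–220 bp by default; bins
  with no long fragments get a missing score and are excluded from the
  Pearson correlation against a median reference NCC profile (per-bin median
  of short/long ratios).
* **Dip area** — the coverage profile is aligned at region centers, binned
  (500-bp bins over ±5000 bp by default); the baseline is the mean of the
  outer 20% of bins split across the two flanks, and the dip area sums
  (coverage − baseline) × bin width over the core bins. Negative = central
  depletion, i.e. inferred factor occupancy / open chromatin in the tissue
  of origin. This replaces a trained bias-correction model with flank-
  baseline geometry; the contract is the sign, monotonicity in tumor
  fraction and ≈0 for controls — not numeric parity with any external tool.
  The positivity threshold is the lower bound of a normal-theory 95%
  prediction interval over reference NCC dip areas,
  `mean − t_{0.975, n−1}·sd·√(1 + 1/n)`; positive strictly below.

## Integration

ichorTF is consumed as an external value: positive at ≥ 0.03 (values below
the limit of detection are negative), and *missing means not evaluable*,
never an implicit negative. Combination uses the union rule over the
evaluable subset of modalities, with the count of positive modalities
retained for longitudinal displays; non-evaluable modalities are excluded
from the union rather than imputed. AUC is computed as the rank statistic
P(cancer score > control score) with ties at 0.5. Lead time is
`clinical_relapse_day − day` of the **latest** pre-relapse sample with at
least one positive modality (the conservative choice), or none. Reported
percentages round half away from zero at one decimal; machine outputs keep
full precision.

## The synthetic cohort generator

The generator defines the conditions every test runs under, so its
assumptions matter:

* **Window identity.** Each window has a base methylation level μ_w drawn
  once per cohort (background Beta(0.6, 6); calibration windows
  Beta(40, 2) ≈ 0.95); individual samples scatter around μ_w with a beta
  distribution of concentration 50 (sd ≈ 0.05 at intermediate levels). This
  mirrors real methylomes, where unmethylated windows are consistently
  unmethylated across individuals.
* **Planted classes.** Three disjoint window sets of size `n_dmr_per_pair`
  (100 by default, among 2000 windows): EwS-signature, CIC-signature and
  shared-tumor. Signature windows put the signature class at Beta(8, 1.5)
  (≈0.85), NCC at a low level with head-room (uniform 0.12–0.2), and the
  *other* tumor class 0.1 **below** NCC — tumor DMRs run in both
  directions, and this keeps each class's evidence directionally consistent
  at any tumor fraction while making the window significant in all three
  pairwise comparisons. Shared-tumor windows are hypermethylated in both
  tumor classes at one shared level and act as a negative control for the
  three-way-intersection filter (they differ in only two comparisons).
  Planted windows keep NCC μ ≤ 0.2, so the median NCC beta stays under the
  DMR filter's 0.25 cap by construction.
* **Fragments.** Lengths are a two-component truncated normal: control mode
  166 bp (mono-nucleosomal), tumor mode 145 bp, sd 15 bp, support
  [70, 1000]; a fragment is tumor-derived with probability f. These values
  put the control p100–150 near 0.15 and a high-fraction sample near 0.2 —
  the range the modality operates in. The 10.4-bp nucleosome ladder
  periodicity, GC bias and chromosomal position effects are *not* modelled.
* **Coverage dips.** The aligned coverage profile is 1 − f·d·g(x) + noise
  with dip depth d = 0.6 and a Gaussian bump g of width 1000 bp; noise
  shrinks with the √ of the number of averaged regions (sd 0.01 per region).
  At f ≈ 0.1 this yields dip areas near −150 coverage·bp, the scale real
  binding-site analyses report.
* **Trajectories.** Patients (23 EwS + 3 CIC) get diagnosis (f uniform
  0.05–0.3), first-line treatment (0–0.01), and — for a 40% relapse
  fraction — relapse (0.05–0.3) and treatment-after-relapse (0–0.05)
  timepoints at days 0/90/270/360; 24 controls have f = 0. ichorTF is the
  true f plus N(0, 0.01) noise, floored at 0, because copy-number
  estimation itself is out of scope.

What passing tests therefore show: the pipeline recovers planted signal,
orders statistics correctly in tumor fraction, and keeps control
specificity under the stated thresholds *under these generative
assumptions*. They do not demonstrate performance on real cfDNA, where
enrichment bias, GC effects, copy-number alterations and biological
covariance between windows all exist and none is modelled here.

## Numerical choices and degenerate inputs

* Largest-remainder rounding everywhere integer counts must sum to an exact
  depth; ties broken by stable sort order.
* Zero-variance windows with equal means get p = 1 (variance compared with
  tolerance 1e-12 to absorb float cancellation); with unequal means, p = 0.
* Calibration failure (zero median calibration signal) is an error, never a
  silent fallback.
* Strict inequalities at every positivity threshold (a value equal to the
  threshold is negative), matching the "exceeds" phrasing of the rules.
* All randomness flows through `numpy.random.default_rng` seeds; every
  generator, split, subset draw and training run is reproducible bit-for-bit
  under a fixed seed (XGBoost runs single-threaded with fixed
  `random_state`).

## Problem sizes

The default synthetic cohort uses 2000 windows of 300 bp, depth 20,000
fragments per methylation profile, 20,000 fragments per sample for
fragmentomics (100,000 for the monotonicity measurements), and the
scaled-down 3 × 10 ensemble with 296/88/400 mixtures per split. A full
pipeline run (simulate → train → predict → fragmentome → integrate)
completes in well under a minute on one CPU; the full acceptance script in
about one minute.

## Known limitations

* The linear anchor calibration is a simplification of enrichment-model
  calibration; absolute beta values are only as meaningful as the
  calibration set.
* The dip statistic omits mappability/GC/copy-number bias correction; on
  real data those corrections are load-bearing.
* The classifier's behaviour on profiles far outside the training mixture
  range (tumor fractions ≫ 0.1) relies on tree extrapolation; scores remain
  correct on the synthetic design but saturate rather than calibrate.
* Evaluation-mixture and training-mixture pairing combinatorics are uniform
  at random; no stratification by source quality is attempted.
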