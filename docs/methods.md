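# Methods

`fluidprint` re-implements, as a reusable and tested pipeline, a
¹H-NMR metabolic-fingerprinting workflow for biofluids (urine, plasma,
cerebrospinal fluid) in a three-class clinical setting: healthy controls
versus a severe (G12.0, spinal muscular atrophy type I) and a mild-to-
moderate (G12.1, type II/III) patient group. This note records the models,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic benchmark does and does not demonstrate.

## Synthetic cohorts

Patient spectra for this clinical setting are not publicly deposited, so
the package ships a first-class cohort simulator. It emulates the
*structure* of the real data, not its biology:

* **Concentrations.** Per sample, each metabolite concentration is drawn
  log-normally around `base_concentration x fold_change`; the log-scale SD
  (`log_sd`, default 0.25) reflects that biofluid concentrations are
  positive and right-skewed. Fold-changes are multiplicative per
  (class, metabolite) and default to 1 (HEALTHY always 1).
* **Spectra.** Intensity is a sum of unit-area Lorentzian multiplets
  (absorption lineshape; NMR lines are Lorentzian to first order and the
  choice is immaterial at bucket resolution) scaled by concentration, plus
  i.i.d. Gaussian noise (`noise_sd`, default 0.05 intensity units). The
  default axis is 0–10 ppm with 9,000 points (~0.0011 ppm spacing), fine
  enough that a 0.01-ppm bucket averages ≥ 9 grid points.
* **Spot-urine dilution.** A global multiplicative factor drawn uniformly
  from (0.3, 3.0) multiplies both the urine spectrum and the raw
  concentration table (creatinine included), so both the minimum-baseline
  spectral scaling and the creatinine normalization downstream are
  necessary and testable.
* **Artifacts.** A broad residual-water hump (4.5–5.5 ppm, all fluids) and
  sharp EDTA peaks (3.04–3.31 and 3.59–3.66 ppm, plasma) with randomized
  amplitudes. Artifact lineshapes are windowed by a raised cosine confined
  to their exclusion interval (with a 0.005-ppm guard band): this makes
  bucket tables built with the standard exclusions *exactly* invariant to
  artifact amplitude, which turns the exclusion logic into a sharply
  testable contract instead of an approximate one. Real artifacts have
  Lorentzian tails; this idealization is deliberate.
* **Bundled library.** Thirty metabolites with literature-plausible
  chemical shifts and typical urine/plasma/CSF concentrations. Positions
  are documented in `library.py`; they need to be mutually distinct, not
  spectroscopically exact, because all analysis happens at bucket level.

The demo effect sizes shift energy-metabolism and amino-acid metabolites
(creatine, citrate, glucose, alanine, glutamine, lactate) moderately
between severity classes. They are calibration knobs for the benchmark:
nothing in this package estimates the real disease effect sizes, and real
effects in this domain are reported to lie within one standard deviation of
group overlap.

What passing tests show: the pipeline recovers injected multiplicative
signal, is calibrated under the null, and respects its bucketing/scaling
contracts. What they do not show: performance on real spectra with peak
shifts (pH, ionic strength), baseline drift, protein background envelopes,
or real inter-subject covariance structure — none of which are simulated.

## Bucketing dialects

Per fluid: urine — minimum-baseline scaling on 1.0–4.3 ppm, 0.01-ppm bins
over 0.8–9.0, exclusion 4.5–6.5; CSF — concentration scale, 0.02-ppm bins
over 0.8–4.55, exclusion 4.5–6.5; plasma — concentration scale, 0.01-ppm
bins over 0.3–10, exclusions 3.04–3.31, 3.59–3.66, 4.5–5.5. Retained bin
counts are 620 (urine), 836 (plasma) and 185 (CSF).

Numerical conventions, each chosen once and stated here:

* **"Minimum baseline scale"** has no standard definition; it is
  implemented as: subtract the 5th-percentile intensity within the scaling
  region (a baseline floor; percentile configurable), then divide the whole
  spectrum by the integral of the floored signal over the region, making
  that integral 1. Any global dilution factor then cancels exactly, which
  is the operation's stated purpose. Whether the original analysis used an
  integral or a vector norm is unknowable; the integral form is the
  documented choice.
* **Bins** are left-closed/right-open `[low + k·w, low + (k+1)·w)` on an
  ascending ppm grid; a trailing partial bin is dropped (the CSF range
  0.8–4.55 is not a multiple of 0.02; "consecutive bins of equal width"
  wins over padding). Columns are reported in ascending ppm order
  regardless of the display convention.
* **Bin values** are trapezoidal integrals with exact (piecewise-quadratic
  antiderivative) evaluation at bin edges, so the sum of bins telescopes to
  the range integral to machine precision and results are robust to grid
  resolution.
* **Exclusion rule:** a bin is removed if its interval has nonzero-length
  overlap (> 1e-9 ppm) with any exclusion interval — guaranteeing zero
  artifact leakage; a bin merely touching an exclusion endpoint is kept.
  The 4.5–4.55 ppm sliver of the CSF range falls inside the water exclusion
  and is removed.

## Classification (PCA/CA/k-NN with MCCV)

The chain: mean-center bucket columns (no unit-variance scaling — buckets
share one intensity scale and variance scaling would inflate noise bins);
PCA by SVD, retaining the smallest number of components whose cumulative
explained variance reaches a threshold (default 0.95, capped at
min(n−1, bins)); canonical discriminant analysis in PC space by the
generalized eigenproblem `B a = λ W a` of between- vs within-class scatter,
directions normalized to unit pooled within-class variance; discriminant
dimension chosen by sequential MANOVA tests on residual Wilks' Λ via the
Bartlett chi-square approximation at level α (default 0.05) — at least one
dimension is kept for classification even when no test rejects (flagged by
a warning), since assignment needs a coordinate.

Two assignment rules are implemented: nearest class center in canonical
space (the default, matching the workflow's stated prediction rule) and
k-NN among training projections (default k = 5). Ties are broken by
lexicographic class-label order and flagged. Basis vectors have their
largest-magnitude coefficient made positive for reproducible output signs.
When the within-class scatter is ill-conditioned (condition number > 1e10,
common when bins ≫ samples before PCA), it is ridge-regularized by
`1e-6 · trace(W)/dim · I` with a warning.

Monte-Carlo cross-validation draws stratified random splits (default 500
iterations, 20% held out; both unstated in the original workflow and
surfaced as explicit knobs), refits the *entire* chain — centering, PCA,
CA — on each training portion, and pools held-out truth × assignment
counts into the confusion matrix. Fold-local refitting is the defensible
reading of "embedded" validation: no statistic of the held-out samples
ever enters the model.

On small two-class problems with all components retained, the chain is
algebraically Fisher LDA; the test suite checks projections (up to
sign/scale) and assignments against an independently coded LDA oracle.

A calibration caveat stated once: pooled MCCV counts are *not* independent
Bernoulli draws — the same sample is re-split many times — so chance-level
checks in the tests use the number of independent samples for their
standard errors, not the pooled count.

## Univariate screening

Each retained bin is tested with the tie-corrected Kruskal-Wallis H
(chi-square tail, groups − 1 df; all-identical data returns H = 0, p = 1
as a no-information case). Summaries per group are the median and the
5–95% percentile band with linear-interpolation quantiles (conventions
differ at small n, so the choice is fixed here). No multiple-testing
correction is applied by default, mirroring the per-bin p < 0.05
highlighting convention of this workflow; Benjamini–Hochberg is available
(`adjust="bh"`) and off by default. Screening is per bin; aggregating
adjacent bins into regions is a documented possible extension, not
implemented.

## Quantitative enrichment analysis

Normalization: urine concentrations are expressed per mol creatinine
(ratio to the same sample's creatinine × 1000; the creatinine column is
consumed), then every fluid is autoscaled per metabolite (mean 0, SD 1,
sample SD). Zero-variance metabolites are dropped with a warning.

For a metabolite set with member matrix X (samples × m, scaled) and a
centered two-level outcome z, the global test statistic is

    Q = zᵀ X Xᵀ z / (m · zᵀz/n),

the linear-model set-association statistic. The p-value comes from an
outcome-permutation null (default 1,999 permutations, add-one estimator)
rather than the asymptotic distribution: exact at any n, assumption-free,
and seeded. The enrichment ratio is defined as Q_observed / E[Q_null]
(mean of the permutation draws) so that 1 means "no enrichment"; this is a
first-principles stand-in for dot-size ratios produced by enrichment web
tools, and may deviate from their internal definition. Three-class designs
are analyzed pairwise; the default contrast is G12.0 vs G12.1. Sets with
fewer than 2 measured members (name matching case-insensitive after
punctuation stripping) are skipped with a warning.

Pathway sets ship as a GMT fixture (`data/kegg_synthetic.gmt`): a
constructed, synthetic KEGG-style library whose member lists draw on the
bundled 30-metabolite panel, plus decoy sets. No live database is queried.
Heatmap ordering uses Euclidean distances between metabolite columns and
average-linkage leaf order; Venn overlaps are exact inclusion–exclusion
region counts over three collections.

## Baseline statistics

Numeric variables are gated by per-group Shapiro–Wilk at α = 0.05:
normal → mean ± SD with a t-test (two groups); otherwise median (IQR) with
Mann–Whitney U (two groups) or Kruskal–Wallis (more). Mann–Whitney uses the
exact null for small tie-free samples (total n ≤ 16) and a tie-corrected
normal approximation otherwise, *without* continuity correction so that
identical samples give a two-sided p of exactly 1. Because the "W" reported
by different software may be U, its complement n_x·n_y − U, or the rank
sum, all three are returned, labeled.

## Problem sizes used in the shipped checks

The acceptance script and calibration tests run: 10 zero-effect cohorts of
15 samples/class (60 MCCV iterations each) for the chance-level check; 25
zero-effect cohorts of 16/class for the per-bin type-I rate (620 bins
each); 200 replicate two-class null cohorts (199 permutations each) for
permutation-p uniformity; and one strong-signal cohort (fold 5 up in
G12.0, fold 5 down in G12.1, on the five citrate-cycle metabolites; low
noise: log_sd 0.05, noise_sd 0.002) for signal recovery. These sizes were
chosen so each check's standard error is well inside its acceptance band.

## Known limitations

* No peak alignment, phasing, baseline correction or reference
  deconvolution: spectra are assumed processed and calibrated upstream.
* The simulator omits peak-position jitter, protein background and
  lipoprotein envelopes; classifier accuracy on synthetic cohorts is not a
  forecast of clinical accuracy.
* JCAMP-DX ingestion is not implemented; the exchange format is CSV.
* MANOVA dimension selection relies on the Bartlett approximation, which
  is asymptotic; at very small n the selected dimension is noisy (the
  classifier then falls back to one canonical coordinate).
* Lipoprotein subclass data are out of scope throughout, as in the
  workflow this package follows.
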