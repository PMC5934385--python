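# Methods

This note documents the statistical models implemented in `ssri_pgx`,
the defaults chosen where the study design left the choice open, and
what the synthetic cohort does and does not emulate.

## Phenotype model

An observed visit scores all 21 HRSD items; a visit is missing as a
whole (the all-or-none convention of the study's missing-data table).
Outcome definitions, with the boundary conventions used throughout:

| outcome | favorable (coded 1) | boundary |
|---|---|---|
| remitted | week-8 total ≤ 7 | total = 7 remits |
| response (binary) | %ΔHRSD ≤ −50% | exactly −50% responds |
| response (continuous) | %ΔHRSD = (w8 − bl)/bl | signed fraction |
| stem-depressed | week-8 item 1 ≤ 2 | item 1 = 3 is unfavorable |

The study's 1/2 coding (favorable category = 2) is carried in
`study_code_*` columns and round-trips losslessly with the favorable
0/1 encoding, which is what enters every regression; effect signs
therefore refer to the favorable outcome.

## Multiple imputation

Missing follow-up totals are imputed by chained equations at the
totals level (not the 21 items jointly): each of w2/w4/w8 is regressed
on the other three totals plus age and sex over the originally observed
rows, with proper Bayesian draws — σ² from its scaled inverse-χ²
posterior, coefficients from N(β̂, σ²(XᵀX)⁻¹), plus a residual draw —
cycled 10 times per imputation. Imputed totals are rounded and clipped
to [0, 66]; the week-8 depressed-mood item is re-derived from the
imputed total through the same severity-binning rule the generator
uses, so stem-depressed stays consistent with the total. Defaults:
m = 30 imputations, 10 interior cycles, both configurable. Observed
cells are preserved bit-exactly across all m datasets.

Downstream per-variant estimates are pooled with Rubin's rules on the
coefficient scale (never by averaging p-values): T = W̄ + (1 + 1/m)B,
with the small-m Student-t reference df = (m−1)(1 + W̄/((1+1/m)B))².
Gene-based permutation tests, whose empirical p has no standard pooled
form, run on the first completed dataset; with the study's light
missingness (92% complete cases) the between-imputation variation in
the empirical p is small relative to its Monte-Carlo error.

## Quality control

Sample stage, in order: (1) plates with pass rate not strictly greater
than 0.97 are removed; (2) per-sample inbreeding F = 1 − obs_het /
Σ 2p(1−p); (3) IBS(i,j) = mean over shared non-missing markers of
(2 − |dᵢ − dⱼ|)/2, pairs above 0.9 lose the member with the lower call
rate (tie: lexicographically later id) — the threshold is a
conventional duplicate/first-degree screen, the study names no number;
(4) classical MDS on 1 − IBS, flagging samples more than 6 SD (root of
summed axis variances) from the 2-D centroid.

Marker stage, in order, each removal labeled with the first failing
rule: Hardy–Weinberg exact p < 10⁻⁴ (computed in all analyzed samples),
missing rate > 5%, MAF < 0.05 (computed on non-missing calls, folded).
The HWE test is the standard conditional exact test: given the allele
counts, the two-sided p sums the probabilities of all same-parity
heterozygote counts no more probable than the observed table;
implemented in log-gamma space and verified against exact-fraction
enumeration for every table with n ≤ 50.

## Single-marker and gene-based association

Single-marker fits use statsmodels OLS/Logit with a 1-df Wald test on
the dosage term; missing dosages are dropped per marker. Constant
covariates raise rather than being silently dropped; perfect separation
is flagged with a missing p.

The gene-based test aggregates markers within ±50 kb of the gene body
(flank boundaries inclusive). Markers with p < 0.1 are sorted by
ascending p (ties: position, then id) and greedily accepted when their
r² with every accepted marker is < 0.5; the set statistic is the mean
squared Wald z over the retained markers — the study does not state the
aggregation functional, and the mean-χ² convention of standard
set-based testing toolkits is adopted. No cap on the retained count by
default (`set_max` exposes one). Permutations shuffle the
(phenotype, covariate) rows jointly against the genotype rows and redo
the entire pipeline, selection and pruning included; empty selections
score 0, keeping the null exchangeable, and an empty *observed*
selection reports a missing empirical p.

Implementation note: the joint shuffle is applied as the algebraically
identical inverse permutation of genotype rows, so the inter-marker r²
matrix (permutation-invariant) is computed once, and the per-replicate
1-df statistics are computed in closed form — exact OLS partial t-tests
for linear outcomes, Rao score tests against the once-fitted
covariate-only null for logistic outcomes. Observed and permuted data
use the same code path. The linear route is identical to statsmodels
to 1e-8; the logistic score statistic is asymptotically equivalent to
the Wald statistic and tracks it to a few percent at n = 400.

## Meta- versus mega-analysis

Per-site p-values combine through the inverse-Gamma model: each pᵢ maps
to the Gamma(α, 1) upper-tail quantile and the sum refers to
Gamma(kα, 1); α = 1 is Fisher's method (X = −2Σ ln pᵢ ~ χ²(2k), and for
k = 2 the closed form e^(−X/2)(1 + X/2)). Fisher's method is
direction-blind, so cross-site effect-direction concordance is reported
as a separate column. The mega-analysis refits each marker on the
concatenated sample; the site indicator is off by default (mirroring a
naive pooled analysis) and switchable. Gene-level meta-analysis
combines per-site empirical p-values with the same combiner.

Published validation: of the headline variants in the source study's
summary table, four have combined p-values that are arithmetically
consistent with their printed two-significant-figure site p-values
under Fisher's method; these four are shipped as reference records and
reproduce to printed precision. Three rows of that table do not
reproduce from their printed inputs under any shape α close to 1 and
are excluded from validation rather than "corrected".

The effective number of tests Meff is a greedy position-ordered r²
pruning at r² ≥ 0.8 — a stand-in with one interpretable parameter for
the block-based LD-adjusted correction the study cites without
parameters; the adjusted 0.05/Meff threshold is reported alongside the
study's fixed tiers (variant 5×10⁻⁴/5×10⁻³, gene 10⁻²/5×10⁻²; a unit is
reported when either analysis reaches the suggestive tier and flagged
when both reach significance).

## Synthetic cohort

The generator reproduces the design quantities of the study, not its
genetic results:

* **Sites and demographics** — 268 + 187 subjects by largest-remainder
  rounding; age ~ N(43.7, 12²) truncated to [18, 80]; 71.3% female;
  96-well plates filled consecutively within site.
* **Genotypes** — per gene, a latent AR(1) Gaussian vector (default
  ρ = 0.7) thresholded at the Hardy–Weinberg genotype quantiles of each
  variant's target MAF (drawn U(0.08, 0.5)); 20 variants per gene by
  default, evenly spaced over hg19-scale gene spans. The copula gives
  direct control of MAF and LD without haplotype pools, which is all
  the pruning/permutation machinery needs; it produces no phase,
  no recombination structure and no population stratification.
* **HRSD trajectories** — baseline totals truncated-normal(22.5, 5²) on
  [14, 52]; week-8 percentage change −0.44 + Σβ·g + N(0, 0.22²)
  (matching the published response mean/SD of roughly −0.44/0.22 and a
  ≈ 39% responder rate), improvement accruing linearly across visits
  with N(0, 1.5²) per-visit rounding noise. Item 1 bins a latent
  severity 4·total/32 with N(0, 0.5²) noise, clipped to [0, min(4,
  total)]; the remaining 20 items share the remainder multinomially.
  Effects on binary outcomes convert a favorable log-odds β to a latent
  percent-change shift via the logistic-threshold factor σ·√3/π. The
  published remitted rate (33%) is higher than the generator's (~13%):
  with independent baseline and improvement draws the week-8 total
  cannot match the published remission rate and the response mean/SD
  simultaneously; the response distribution was prioritized because two
  of the four outcomes derive from it.
* **Missingness** — each subject draws one of the eight published
  patterns with probabilities (394, 10, 10, 10, 1, 2, 0, 1)/428;
  baseline is never masked. This is missing-completely-at-random by
  construction; the real cohort's dropout mechanism is unknown.
* **Case-control** — control genotypes at the base MAF; case allele
  frequencies tilted to qe^β/(1 + q(e^β − 1)) for a per-allele log-OR β.

All randomness flows from one master seed through `SeedSequence`
substreams; every generator, and the full pipeline, is bit-reproducible
for a fixed seed. Passing tests therefore demonstrate the machinery's
correctness and calibration under this idealized design — clean
genotypes, MCAR dropout, homogeneous ancestry — not robustness to the
artifacts (batch effects, relatedness, stratification) the QC stage
exists to catch; those paths are exercised with constructed fixtures.

## Problem sizes and numerical choices

The demonstration configuration runs the design at desk scale:
20 variants per gene (the study's imputed panel had ~160 per gene),
R = 1000 permutations and m = 10 imputations (study defaults: 50 000
and 30, both single configuration knobs). Calibration checks in the
test suite and acceptance script use 500 null datasets at R = 2000,
and the ranking check uses 20 seeded replicates of a reduced profile
(continuous response, pooled-sample gene tests, m = 2).

Degenerate inputs: monomorphic markers are excluded from engines and
flagged `monomorphic` in scans; genes whose observed selection is empty
report a missing empirical p with `n_selected = 0`; imputation requires
baseline observed for every subject (the generator guarantees it, the
panel container enforces it). Near-singular denominators in the
permutation engines (a dosage column in the covariate span) score 0
rather than propagating NaN. Empirical p-values are bounded below by
1/(R+1); two seeds at R = 50 000 differ by well under the reporting
precision.

## Known limitations

* Genotype imputation against a reference panel, chip-intensity
  processing, eQTL annotation and haplotype analyses are out of scope.
* The logistic permutation route uses score rather than Wald
  statistics; at n in the hundreds the difference is a few percent of
  the statistic and does not affect rank-based selection at p < 0.1
  except at the margin.
* Gene-level meta-analysis combines empirical p-values as if
  continuous; with R = 50 000 the discreteness (granularity 2×10⁻⁵) is
  negligible at the gene tiers.
* The Meff pruning stand-in is not the cited block-based estimator;
  with the default AR(1) ρ = 0.7 adjacent-marker dosage r² (~0.4) sits
  below the 0.8 block threshold, so Meff equals the marker count on the
  demonstration cohort.
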