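# ssri-pgx

A candidate-gene pharmacogenetic analysis pipeline for antidepressant
treatment response in a two-site clinical cohort.

Patients with major depressive disorder are assessed with the 21-item
Hamilton Rating Scale for Depression (HRSD) at baseline and weeks 2, 4
and 8 of SSRI treatment. Four treatment-response outcomes are derived
per subject:

* **remitted** — week-8 total ≤ 7;
* **response (%ΔHRSD, continuous)** — (week-8 − baseline) / baseline;
* **response (binary)** — %ΔHRSD ≤ −50%;
* **stem-depressed** — week-8 depressed-mood item ≥ 3.

Each minor-allele dosage g ∈ {0, 1, 2} over ten neurotrophic- and
serotonin-pathway candidate genes (*BDNF*, *NGFR*, *NTRK2*, *MTOR*,
*VEGFA*, *S100A10*, *SERPINE1*, *ARHGAP33*, *GSK3B*, *CREB1*) is tested
under the additive 1-df model

    y ~ β₀ + β_g · g + β_age · age + β_sex · sex

by least squares (continuous outcome) or maximum-likelihood logistic
regression (binary outcomes). Around the single-marker scan the
pipeline implements:

* **quality control** — plate pass rate > 97%, inbreeding/IBS kinship
  screening, classical-MDS outlier detection, Hardy–Weinberg exact test
  (p < 10⁻⁴), missingness (> 5%) and MAF (< 0.05) marker filters;
* **multiple imputation** — chained-equation imputation of missing
  follow-up totals (m = 30 by default) with Rubin's rules for pooling;
* **gene-based tests** — markers within ±50 kb of a gene with p < 0.1
  are greedily LD-pruned (r² < 0.5) and aggregated as the mean squared
  Wald z; significance comes from permutations of the
  (phenotype, covariate) rows against the genotypes, with
  empirical p = (1 + #{S_perm ≥ S_obs}) / (R + 1), R = 50 000 by default;
* **meta- vs mega-analysis** — per-site p-values are combined with the
  inverse-Gamma model (shape α; α = 1 is Fisher's method,
  X = −2 Σ ln pᵢ ~ χ²(2k)), contrasted with a single regression on the
  pooled sample; fixed significance tiers (variant: 5×10⁻⁴ / 5×10⁻³;
  gene: 10⁻² / 5×10⁻²) are reported alongside an LD-adjusted
  0.05 / Meff threshold.

Because the original cohort data are not public, the package ships a
synthetic-data generator that emulates the study design: two sites
(268 + 187 subjects), Gaussian-copula genotypes with AR(1) LD blocks,
HRSD trajectories honoring the baseline ≥ 14 inclusion rule, and the
published 8-pattern missing-data mixture (complete-case rate 394/428).

## Worked example

The numbered scripts under `analysis/` run the demonstration cohort —
455 subjects, 10 genes × 20 variants, one causal *VEGFA* variant with a
+0.08 per-allele effect on %ΔHRSD — end to end:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_quality_control.py
python analysis/03_phenotypes_imputation.py
python analysis/04_single_marker_scan.py
python analysis/05_gene_permutation_tests.py
python analysis/06_meta_mega_analysis.py
python analysis/07_published_meta_validation.py
```

Representative output (seed 0):

```
complete cases: 422/455 (92.75%)
mega-analysis top markers:
                   maf    effect        se             p
VEGFA_snp010  0.295604  0.085021  0.016246  1.675987e-07
VEGFA_snp009  0.264835  0.077255  0.017377  8.794210e-06

combined 200 markers across ['NHRI', 'TVGH']
                    meta_p        mega_p    meta_tier    mega_tier  both_significant
VEGFA_snp010  1.559728e-07  1.675987e-07  significant  significant              True
```

The causal variant is recovered with an effect estimate (0.085 ± 0.016)
matching the injected +0.08, reaches the significant tier in both the
Fisher meta-analysis and the pooled mega-analysis, and drives *VEGFA*
to the top of the gene-based ranking. Script 07 checks the Fisher
combiner against the published two-site records: combining the printed
per-site p-values reproduces the printed combined p-values to within
rounding of the two-significant-figure inputs (e.g. 0.027 and 0.019
combine to 0.0044).

The same pipeline is available as a CLI (`ssri-pgx simulate | qc |
derive-pheno | assoc | gene-test | meta | run`); see `ssri-pgx --help`.

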