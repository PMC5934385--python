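"""End-to-end orchestration of the candidate-gene pipeline.

Stage order mirrors the study: simulate (or load) the two-site cohort ->
sample QC -> marker QC -> phenotype derivation with multiple imputation
-> per-site and pooled single-marker scans (Rubin-pooled over
imputations) -> gene-based permutation tests -> Fisher meta-analysis vs
mega-analysis -> significance tiers. Every stage logs its in/out counts
and the whole run is deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, genetest, meta, phenotypes, qc, simulate
from .config import RunConfig
from .containers import GenotypeMatrix, HRSDPanel
from .io import write_tsv

log = logging.getLogger("ssri_pgx")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineResult:
    config: RunConfig
    samples: pd.DataFrame
    genotypes: GenotypeMatrix
    qc_report: qc.QCReport
    panel: HRSDPanel
    imputation: phenotypes.ImputationResult
    phenotype_tables: list[pd.DataFrame]
    site_scans: dict[str, dict[str, pd.DataFrame]]  # outcome -> site -> table
    mega_scans: dict[str, pd.DataFrame]
    variant_meta: dict[str, pd.DataFrame]  # outcome -> combined + tiers
    gene_results: dict[str, dict[str, list[genetest.GeneTestResult]]]
    gene_meta: dict[str, pd.DataFrame]
    meff: int
    thresholds: dict[str, float]
    counts: dict[str, int] = field(default_factory=dict)


def _simulate_stage(cfg: RunConfig):
    genes = [
        simulate.GeneModel(
            g.name, g.chrom, g.start, g.end,
            n_variants=cfg.variants_per_gene, block_rho=cfg.block_rho,
        )
        for g in simulate.default_gene_models()
    ]
    ss = np.random.SeedSequence(cfg.seed)
    s_geno, s_pheno, s_miss, s_meta, s_mi = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    )
    samples = simulate.assign_sites_and_plates(
        cfg.n_samples, cfg.site_fractions, cfg.plate_size, seed=s_meta
    )
    gm = simulate.simulate_genotypes(
        cfg.n_samples, genes, seed=s_geno, maf_by_variant=cfg.maf_overrides or None
    )
    gm = GenotypeMatrix(
        gm.dosages.set_axis(samples.index, axis=0), gm.variants
    )
    panel = simulate.simulate_hrsd(samples, gm, cfg.effect_specs(), seed=s_pheno)
    panel = simulate.inject_missingness(panel, seed=s_miss)
    gene_table = pd.DataFrame(
        [(g.name, g.chrom, g.start, g.end) for g in genes],
        columns=["gene", "chrom", "start", "end"],
    ).set_index("gene")
    return samples, gm, panel, gene_table, s_mi


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    counts: dict[str, int] = {}

    # -- stage: simulate -------------------------------------------------
    try:
        samples, gm_raw, panel_raw, gene_table, seed_mi = _simulate_stage(cfg)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("simulate", "generation_failed", str(exc)) from exc
    counts["samples_in"] = len(samples)
    counts["markers_in"] = gm_raw.n_variants
    log.info("simulated %d samples x %d markers", len(samples), gm_raw.n_variants)

    # -- stage: sample QC -------------------------------------------------
    try:
        gm, report = qc.run_sample_qc(
            gm_raw, samples,
            plate_min_rate=cfg.plate_pass_rate,
            kinship_ibs=cfg.kinship_ibs,
            mds_k_sd=cfg.mds_k_sd,
        )
    except Exception as exc:
        raise PipelineError("sample_qc", "qc_failed", str(exc)) from exc
    by_rule: dict[str, int] = {}
    for _, reason in report.removed_samples:
        by_rule[reason] = by_rule.get(reason, 0) + 1
    for rule, n in by_rule.items():
        counts[f"samples_removed_{rule}"] = n
        log.info("sample QC removed %d samples by rule %s", n, rule)
    samples = samples.loc[gm.sample_ids]

    # -- stage: marker QC -------------------------------------------------
    try:
        gm, report = qc.run_marker_qc(
            gm, report, hwe_p=cfg.hwe_p, max_missing=cfg.max_missing, min_maf=cfg.min_maf
        )
    except Exception as exc:
        raise PipelineError("marker_qc", "qc_failed", str(exc)) from exc
    by_rule = {}
    for _, reason in report.removed_markers:
        by_rule[reason] = by_rule.get(reason, 0) + 1
    for rule, n in by_rule.items():
        counts[f"markers_removed_{rule}"] = n
        log.info("marker QC removed %d markers by rule %s", n, rule)
    counts["markers_retained"] = gm.n_variants
    counts["samples_retained"] = gm.n_samples

    # -- stage: phenotypes + MI -------------------------------------------
    panel = HRSDPanel(
        panel_raw.data[panel_raw.data["subject_id"].isin(gm.sample_ids)].reset_index(
            drop=True
        )
    )
    for pat, n in phenotypes.observed_pattern_counts(panel):
        log.info("missingness pattern %s: %d subjects", pat, n)
    try:
        imputation = phenotypes.multiple_impute(
            panel, samples, m=cfg.imputation_m, n_iter=cfg.imputation_iter, seed=seed_mi
        )
    except Exception as exc:
        raise PipelineError("imputation", "mi_failed", str(exc)) from exc
    pheno_tables = [phenotypes.derive_phenotypes(c) for c in imputation.completed]

    covariates = samples[["age", "sex"]]
    sites = samples["site"]
    site_names = list(dict.fromkeys(sites))

    # -- stage: single-marker scans ---------------------------------------
    site_scans: dict[str, dict[str, pd.DataFrame]] = {}
    mega_scans: dict[str, pd.DataFrame] = {}
    variant_meta: dict[str, pd.DataFrame] = {}
    for outcome in cfg.outcomes:
        per_site = {}
        for s in site_names:
            ids = sites.index[sites == s]
            per_site[s] = assoc.scan_mi(
                gm, pheno_tables, outcome, covariates, samples=ids, site=s
            )
        mega = assoc.scan_mi(gm, pheno_tables, outcome, covariates, site="mega")
        site_scans[outcome] = per_site
        mega_scans[outcome] = mega
        combined = meta.combine_sites(per_site, mega, outcome, alpha=cfg.fisher_alpha)
        variant_meta[outcome] = meta.classify_significance(
            combined.dropna(subset=["meta_p", "mega_p"]), level="variant"
        )
        log.info("scanned outcome %s over %d markers", outcome, len(mega))

    # -- stage: gene tests -------------------------------------------------
    members = genetest.map_variants_to_genes(gm.variants, gene_table, flank=cfg.flank)
    gene_results: dict[str, dict[str, list[genetest.GeneTestResult]]] = {}
    gene_meta: dict[str, pd.DataFrame] = {}
    # first completed dataset carries the gene-based tests (see methods)
    pheno_first = pheno_tables[0]
    gene_seed = int(np.random.SeedSequence(cfg.seed + 1).generate_state(1)[0] % (2**31))
    for outcome in cfg.outcomes:
        per_scope: dict[str, list[genetest.GeneTestResult]] = {}
        scopes = (
            ["mega"] if cfg.gene_test_scope == "mega" else [*site_names, "mega"]
        )
        for scope in scopes:
            ids = sites.index if scope == "mega" else sites.index[sites == scope]
            sub = gm.subset(samples=ids)
            res = genetest.gene_scan(
                sub, members, pheno_first.loc[ids], outcome, covariates.loc[ids],
                R=cfg.permutations, seed=gene_seed,
                p_threshold=cfg.set_p_threshold, r2_threshold=cfg.prune_r2,
                set_max=cfg.set_max,
            )
            per_scope[scope] = res
            for r in res:
                log.info(
                    "gene test %s/%s/%s: n_selected=%d empirical_p=%s",
                    outcome, scope, r.gene, r.n_selected, r.empirical_p,
                )
        gene_results[outcome] = per_scope

        if cfg.gene_test_scope == "all":
            rows = []
            by_gene = {
                scope: {r.gene: r for r in per_scope[scope]} for scope in per_scope
            }
            for gname in by_gene["mega"]:
                site_ps = [
                    by_gene[s][gname].empirical_p
                    for s in site_names
                    if gname in by_gene[s]
                ]
                mega_p = by_gene["mega"][gname].empirical_p
                finite = [p for p in site_ps if np.isfinite(p)]
                if len(finite) == len(site_ps) and site_ps:
                    _, meta_p = meta.fisher_combine(site_ps, alpha=cfg.fisher_alpha)
                else:
                    meta_p = np.nan
                rows.append(
                    {
                        "gene": gname,
                        "outcome": outcome,
                        "meta_p": meta_p,
                        "mega_p": mega_p,
                        "prop_significant": by_gene["mega"][gname].prop_significant,
                        "n_selected": by_gene["mega"][gname].n_selected,
                    }
                )
            tab = pd.DataFrame(rows).set_index("gene")
            ok = tab[["meta_p", "mega_p"]].notna().all(axis=1)
            gene_meta[outcome] = meta.classify_significance(tab[ok], level="gene")

    # -- stage: multiple-testing landscape ---------------------------------
    meff, thresholds = meta.effective_tests(gm, r2_block=cfg.meff_r2)
    log.info("effective number of tests Meff=%d", meff)

    return PipelineResult(
        config=cfg,
        samples=samples,
        genotypes=gm,
        qc_report=report,
        panel=panel,
        imputation=imputation,
        phenotype_tables=pheno_tables,
        site_scans=site_scans,
        mega_scans=mega_scans,
        variant_meta=variant_meta,
        gene_results=gene_results,
        gene_meta=gene_meta,
        meff=meff,
        thresholds=thresholds,
        counts=counts,
    )


def write_outputs(result: PipelineResult, out_dir) -> None:
    """Serialize the result bundle as hash-stamped TSVs plus metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = result.config.hash()
    (out / "run_config.json").write_text(result.config.to_json())
    write_tsv(result.samples, out / "samples.tsv", h)
    for outcome, tab in result.variant_meta.items():
        write_tsv(tab, out / f"variants_{outcome}.tsv", h)
    for outcome, tab in result.gene_meta.items():
        write_tsv(tab, out / f"genes_{outcome}.tsv", h)
    counts = pd.Series(result.counts, name="count").to_frame()
    counts.index.name = "stage"
    write_tsv(counts, out / "stage_counts.tsv", h)
    thr = pd.Series(result.thresholds, name="value").to_frame()
    thr.index.name = "threshold"
    write_tsv(thr, out / "thresholds.tsv", h)
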