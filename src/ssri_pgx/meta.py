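"""Fisher/inverse-Gamma meta-analysis, pooled mega-analysis and
significance tiers.

Two ways of combining the two clinical sites are implemented and
contrasted:

* **meta-analysis** — per-site p-values are combined with the
  inverse-Gamma family: each p maps to the upper-tail quantile of a
  Gamma(alpha, 1) law and the sum is referred to Gamma(k * alpha, 1).
  Shape alpha = 1 recovers Fisher's method, X = -2 sum(ln p) ~ chi2(2k);
  for k = 2 the tail has the closed form e^(-X/2) (1 + X/2).
* **mega-analysis** — a single regression on the concatenated two-site
  sample (site indicator covariate optional, off by default).

Fisher's method is direction-blind, so effect-direction concordance
across sites is reported as a separate column rather than folded into
the combined statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix

#: Fixed significance tiers: (significant, suggestive) p cutoffs.
VARIANT_TIERS = (5e-4, 5e-3)
GENE_TIERS = (1e-2, 5e-2)


def fisher_combine(p_values, alpha: float = 1.0) -> tuple[float, float]:
    """Combine independent p-values with the inverse-Gamma model.

    Returns ``(X, meta_p)`` where ``X = 2 * sum(Gamma(alpha,1) upper-tail
    quantiles)``; for alpha = 1 this is Fisher's X = -2 sum(ln p) with a
    chi-square 2k-df tail. With a single p-value and alpha = 1 the
    combined p equals the input exactly.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if alpha <= 0:
        raise ValueError("shape alpha must be positive")
    k = p.size
    s = stats.gamma.isf(p, alpha).sum()
    meta_p = float(stats.gamma.sf(s, k * alpha))
    return float(2.0 * s), meta_p


def fisher_closed_form_k2(x: float) -> float:
    """Closed-form chi2(4 df) upper tail e^(-X/2) (1 + X/2) for k = 2."""
    return float(np.exp(-x / 2.0) * (1.0 + x / 2.0))


def mega_scan(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    outcome: str,
    covariates: pd.DataFrame,
    sites: pd.Series,
    *,
    include_site_covariate: bool = False,
) -> pd.DataFrame:
    """Single per-marker regression on the pooled two-site sample.

    ``sites`` labels every sample; with ``include_site_covariate`` the
    model gains site indicator columns (off by default, mirroring a naive
    pooled analysis).
    """
    from .assoc import scan

    sites = sites.reindex(genotypes.sample_ids)
    if sites.isna().any():
        missing = sites.index[sites.isna()].tolist()
        raise ValueError(f"site label missing for samples: {missing[:5]}")
    cov = covariates.loc[genotypes.sample_ids, ["age", "sex"]].copy()
    if include_site_covariate:
        dummies = pd.get_dummies(sites, prefix="site", drop_first=True, dtype=float)
        cov = pd.concat([cov, dummies], axis=1)
        result = _scan_with_cov(genotypes, phenotypes, outcome, cov)
        return result
    return scan(genotypes, phenotypes, outcome, cov, site="mega")


def _scan_with_cov(genotypes, phenotypes, outcome, cov):
    # scan() restricts covariates to age+sex; inline variant for extra columns
    from .assoc import AssocResult, MonomorphicVariantError, fit_additive, _results_frame
    from .phenotypes import OUTCOME_FAMILY

    family = OUTCOME_FAMILY[outcome]
    gm = genotypes.sorted_by_position()
    y = phenotypes.loc[gm.sample_ids, outcome]
    results = []
    for vid in gm.variant_ids:
        try:
            res = fit_additive(
                gm.dosages[vid], y, cov.loc[gm.sample_ids], family,
                variant_id=str(vid), outcome_name=outcome, site="mega",
            )
        except MonomorphicVariantError:
            res = AssocResult(
                str(vid), outcome, "mega", gm.n_samples, float(gm.maf()[vid]),
                np.nan, np.nan, np.nan, np.nan, family, note="monomorphic",
            )
        results.append(res)
    return _results_frame(results)


def effective_tests(
    genotypes: GenotypeMatrix, r2_block: float = 0.8
) -> tuple[int, dict[str, float]]:
    """LD-adjusted effective test count via greedy r^2 pruning.

    Walking markers in (chrom, pos) order, a marker becomes a new
    independent representative unless its r^2 with an already-retained
    representative is >= ``r2_block``. Meff is the number of
    representatives; the adjusted threshold is 0.05 / Meff, reported
    alongside the study's fixed tiers.
    """
    if genotypes.n_variants == 0:
        raise ValueError("empty marker set")
    gm = genotypes.sorted_by_position()
    vals = gm.dosages.to_numpy(dtype=float)
    filled = np.where(np.isnan(vals), np.nanmean(vals, axis=0), vals)
    sd = filled.std(axis=0)
    corr = np.corrcoef(filled[:, sd > 0], rowvar=False)
    r2 = np.atleast_2d(corr) ** 2
    ids = [v for v, s in zip(gm.variant_ids, sd) if s > 0]
    kept: list[int] = []
    for j in range(len(ids)):
        if all(r2[j, k] < r2_block for k in kept):
            kept.append(j)
    meff = max(len(kept), 1)
    thresholds = {
        "meff": float(meff),
        "adjusted_alpha": 0.05 / meff,
        "variant_significant": VARIANT_TIERS[0],
        "variant_suggestive": VARIANT_TIERS[1],
        "gene_significant": GENE_TIERS[0],
        "gene_suggestive": GENE_TIERS[1],
    }
    return meff, thresholds


def _tier(p: float, significant: float, suggestive: float) -> str:
    if not np.isfinite(p):
        raise ValueError("missing p-value")
    if p < significant:
        return "significant"
    if p < suggestive:
        return "suggestive"
    return "none"


def classify_significance(
    results: pd.DataFrame, level: str = "variant"
) -> pd.DataFrame:
    """Label meta and mega p-values with significance tiers.

    ``results`` needs columns ``meta_p`` and ``mega_p``. A unit is
    ``reported`` when either analysis reaches at least the suggestive
    tier, and flagged ``both_significant`` when both reach the
    significant tier (the criterion used for headline variants).
    """
    if level == "variant":
        sig, sugg = VARIANT_TIERS
    elif level == "gene":
        sig, sugg = GENE_TIERS
    else:
        raise ValueError(f"unknown level {level!r}")
    out = results.copy()
    out["meta_tier"] = [_tier(p, sig, sugg) for p in results["meta_p"]]
    out["mega_tier"] = [_tier(p, sig, sugg) for p in results["mega_p"]]
    out["reported"] = (out["meta_tier"] != "none") | (out["mega_tier"] != "none")
    out["both_significant"] = (out["meta_tier"] == "significant") & (
        out["mega_tier"] == "significant"
    )
    return out


@dataclass
class MetaRecord:
    """One combined unit (variant or gene) across the two sites."""

    unit_id: str
    outcome: str
    site_p: list[float]
    statistic: float
    meta_p: float
    mega_p: float
    direction_concordant: bool | None = None


def combine_sites(
    site_tables: dict[str, pd.DataFrame],
    mega_table: pd.DataFrame,
    outcome: str,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Per-variant Fisher combination of site scans plus the mega scan.

    Variants with a missing p in any site (monomorphic, separation) get a
    missing meta p. Effect-direction concordance across sites is recorded
    but does not enter the combination.
    """
    names = list(site_tables)
    idx = mega_table.index
    rows = []
    for vid in idx:
        ps, effs = [], []
        for s in names:
            tab = site_tables[s]
            ps.append(tab.loc[vid, "p"] if vid in tab.index else np.nan)
            effs.append(tab.loc[vid, "effect"] if vid in tab.index else np.nan)
        ps_arr = np.asarray(ps, dtype=float)
        if np.isfinite(ps_arr).all():
            x, meta_p = fisher_combine(ps_arr, alpha=alpha)
        else:
            x, meta_p = np.nan, np.nan
        effs_arr = np.asarray(effs, dtype=float)
        concordant = (
            bool((np.sign(effs_arr) == np.sign(effs_arr[0])).all())
            if np.isfinite(effs_arr).all()
            else None
        )
        row = {
            "variant_id": vid,
            "outcome": outcome,
            "statistic": x,
            "meta_p": meta_p,
            "mega_p": mega_table.loc[vid, "p"],
            "direction_concordant": concordant,
        }
        for s, p, e in zip(names, ps, effs):
            row[f"p_{s}"] = p
            row[f"effect_{s}"] = e
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant_id")
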