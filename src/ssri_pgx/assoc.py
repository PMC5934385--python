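"""Per-variant additive association scans.

Each marker's minor-allele dosage (0/1/2) enters a linear (continuous
outcome) or logistic (binary outcome) regression adjusted for sex and
age; the dosage coefficient is tested with a 1-df Wald test. Binary
outcomes use the favorable 0/1 encoding, so a positive log-odds ratio
means the minor allele favors remission/response. Samples with a missing
dosage or outcome are dropped per marker (complete-case per test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .containers import GenotypeMatrix
from .phenotypes import OUTCOME_FAMILY
from .published import SITE_SIZES  # noqa: F401  (documented site labels)


class MonomorphicVariantError(ValueError):
    """Raised when a dosage vector has zero variance among usable samples."""


class HarmonizationError(ValueError):
    """Raised when two genotype sources disagree on variant definitions."""


@dataclass
class AssocResult:
    variant_id: str
    outcome: str
    site: str
    n: int
    maf: float
    effect: float
    se: float
    zstat: float
    p: float
    family: str
    note: str = ""

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.effect)) if self.family == "logistic" else np.nan


def fit_additive(
    dosage,
    outcome,
    covariates: pd.DataFrame | None,
    family: str,
    *,
    variant_id: str = "",
    outcome_name: str = "",
    site: str = "pooled",
) -> AssocResult:
    """Fit one additive single-marker model and Wald-test the dosage term.

    ``family`` is ``"linear"`` (least squares) or ``"logistic"`` (ML).
    Raises :class:`MonomorphicVariantError` for a constant dosage and
    ``ValueError`` for a constant covariate column; perfect separation is
    flagged in ``note`` with a missing p-value rather than raised.
    """
    if family not in ("linear", "logistic"):
        raise ValueError(f"unknown family {family!r}")
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if covariates is not None:
        c = covariates.to_numpy(dtype=float)
        cov_names = list(covariates.columns)
    else:
        c = np.empty((len(g), 0))
        cov_names = []

    usable = ~np.isnan(g) & ~np.isnan(y) & ~np.isnan(c).any(axis=1)
    g, y, c = g[usable], y[usable], c[usable]
    n = int(usable.sum())
    if n == 0:
        raise ValueError("no usable samples")
    if np.nanvar(g) == 0:
        raise MonomorphicVariantError(f"monomorphic dosage for {variant_id or 'variant'}")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant")
    for j, name in enumerate(cov_names):
        if np.ptp(c[:, j]) == 0:
            raise ValueError(f"covariate {name!r} is constant; drop it explicitly")

    x = np.column_stack([np.ones(n), g, c])
    maf = float(min(g.mean() / 2.0, 1.0 - g.mean() / 2.0))
    note = ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            if family == "linear":
                fit = sm.OLS(y, x).fit()
            else:
                fit = sm.Logit(y, x).fit(disp=0, maxiter=100)
        effect = float(fit.params[1])
        se = float(fit.bse[1])
        z = effect / se if se > 0 else np.nan
        p = float(fit.pvalues[1])
        if family == "logistic" and (not np.isfinite(se) or se > 1e4):
            note, p, z = "separation", np.nan, np.nan
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        effect, se, z, p, note = np.nan, np.nan, np.nan, np.nan, "separation"
    return AssocResult(
        variant_id=variant_id,
        outcome=outcome_name,
        site=site,
        n=n,
        maf=maf,
        effect=effect,
        se=se,
        zstat=z,
        p=p,
        family=family,
        note=note,
    )


def _results_frame(results: list[AssocResult]) -> pd.DataFrame:
    frame = pd.DataFrame([r.__dict__ for r in results])
    return frame.set_index("variant_id") if len(frame) else frame


def scan(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    outcome: str,
    covariates: pd.DataFrame,
    *,
    samples=None,
    site: str = "pooled",
) -> pd.DataFrame:
    """Additive scan of every marker against one outcome.

    ``samples`` optionally restricts the scan (e.g. to one site). Markers
    are reported in (chrom, pos) order; monomorphic or separated markers
    are kept in the output with a ``note`` and missing p.
    """
    if outcome not in OUTCOME_FAMILY:
        raise KeyError(f"unknown outcome {outcome!r}")
    family = OUTCOME_FAMILY[outcome]
    gm = genotypes.sorted_by_position()
    if samples is not None:
        gm = gm.subset(samples=samples)
    ids = list(gm.sample_ids)
    y = phenotypes.loc[ids, outcome]
    cov = covariates.loc[ids, ["age", "sex"]]

    results = []
    for vid in gm.variant_ids:
        try:
            res = fit_additive(
                gm.dosages[vid],
                y,
                cov,
                family,
                variant_id=str(vid),
                outcome_name=outcome,
                site=site,
            )
        except MonomorphicVariantError:
            res = AssocResult(
                str(vid), outcome, site, len(ids), float(gm.maf()[vid]),
                np.nan, np.nan, np.nan, np.nan, family, note="monomorphic",
            )
        results.append(res)
    return _results_frame(results)


def scan_mi(
    genotypes: GenotypeMatrix,
    phenotype_tables: list[pd.DataFrame],
    outcome: str,
    covariates: pd.DataFrame,
    *,
    samples=None,
    site: str = "pooled",
) -> pd.DataFrame:
    """Scan each completed (imputed) dataset and pool with Rubin's rules.

    ``phenotype_tables`` holds one derived-outcome table per imputation.
    Markers failing in any imputation (monomorphic/separation) carry a
    note and a missing pooled p.
    """
    from .phenotypes import pool_rubin

    per_imp = [
        scan(genotypes, tab, outcome, covariates, samples=samples, site=site)
        for tab in phenotype_tables
    ]
    base = per_imp[0].copy()
    for vid in base.index:
        effs = np.array([t.loc[vid, "effect"] for t in per_imp], dtype=float)
        ses = np.array([t.loc[vid, "se"] for t in per_imp], dtype=float)
        if not (np.isfinite(effs).all() and np.isfinite(ses).all()):
            base.loc[vid, ["effect", "se", "zstat", "p"]] = np.nan
            base.loc[vid, "note"] = base.loc[vid, "note"] or "mi_unstable"
            continue
        pooled = pool_rubin(effs, ses)
        base.loc[vid, "effect"] = pooled.estimate
        base.loc[vid, "se"] = pooled.se
        base.loc[vid, "zstat"] = pooled.estimate / pooled.se if pooled.se > 0 else np.nan
        base.loc[vid, "p"] = pooled.p
    return base


def harmonize(
    cases: GenotypeMatrix, controls: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Check that two genotype sources define the shared variants identically.

    Requires equal chrom/pos and, when present, equal ref/alt allele
    labels; a flipped REF/ALT coding raises :class:`HarmonizationError`.
    """
    shared = cases.variant_ids.intersection(controls.variant_ids)
    if len(shared) == 0:
        raise HarmonizationError("no shared variants between the two sources")
    cols = ["chrom", "pos"] + [
        c for c in ("ref", "alt") if c in cases.variants.columns and c in controls.variants.columns
    ]
    a = cases.variants.loc[shared, cols]
    b = controls.variants.loc[shared, cols]
    neq = (a != b).any(axis=1)
    if neq.any():
        bad = shared[neq].tolist()
        raise HarmonizationError(f"variant definition mismatch (allele coding?): {bad[:5]}")
    return cases.subset(variants=shared), controls.subset(variants=shared)


def case_control_scan(
    cases: GenotypeMatrix,
    controls: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Logistic scan of case/control status on dosage.

    The two sources are harmonized first; covariates are optional because
    control panels often lack the clinical metadata of the case cohort.
    """
    cases, controls = harmonize(cases, controls)
    dosages = pd.concat([cases.dosages, controls.dosages])
    gm = GenotypeMatrix(dosages, cases.variants.copy()).sorted_by_position()
    y = pd.Series(
        np.r_[np.ones(cases.n_samples), np.zeros(controls.n_samples)],
        index=dosages.index,
    )
    cov = covariates.loc[dosages.index] if covariates is not None else None

    results = []
    for vid in gm.variant_ids:
        try:
            res = fit_additive(
                gm.dosages[vid], y, cov, "logistic",
                variant_id=str(vid), outcome_name="case_status", site="case_control",
            )
        except MonomorphicVariantError:
            res = AssocResult(
                str(vid), "case_status", "case_control", gm.n_samples,
                float(gm.maf()[vid]), np.nan, np.nan, np.nan, np.nan,
                "logistic", note="monomorphic",
            )
        results.append(res)
    return _results_frame(results)
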