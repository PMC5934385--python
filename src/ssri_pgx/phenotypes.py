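"""Treatment-response phenotypes and multiple imputation.

Four outcomes are derived from the HRSD panel:

* ``remitted`` — week-8 total <= 7;
* ``response_pct`` — %dHRSD = (week-8 - baseline) / baseline, a signed
  fraction (improvement is negative);
* ``response_binary`` — %dHRSD <= -50%;
* ``stem_depressed`` — week-8 depressed-mood item (item 1) dichotomized
  at >= 3 (moderately-severe/severe).

The study's 1/2 coding (1 = unfavorable, 2 = favorable for remitted and
response; for stem-depressed, 1 = moderately-severe/severe) is carried
alongside a favorable-outcome 0/1 recode (1 = remitted / responder /
mood <= 2), which is what enters the regressions.

Missing follow-ups are handled by chained-equation multiple imputation on
the timepoint totals (plus item 1 at week 8), with Rubin's rules for
pooling downstream estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import HRSDPanel, HRSD_TOTAL_MAX, TIMEPOINTS
from .simulate import MissingnessPattern, item1_from_total

OUTCOMES = ("remitted", "response_binary", "response_pct", "stem_depressed")

#: Regression family per outcome.
OUTCOME_FAMILY = {
    "remitted": "logistic",
    "response_binary": "logistic",
    "response_pct": "linear",
    "stem_depressed": "logistic",
    "case_status": "logistic",
}


# ---------------------------------------------------------------------------
# elementary derivations
# ---------------------------------------------------------------------------

def total_score(items) -> int:
    """Sum the 21 item scores at one observed timepoint.

    Raises if any item is missing: an observed visit scores all items.
    """
    arr = np.asarray(items, dtype=float)
    if arr.shape != (21,):
        raise ValueError("expected exactly 21 item scores")
    if np.isnan(arr).any():
        raise ValueError("missing item at an observed timepoint")
    return int(arr.sum())


def derive_remitted(week8_total: float) -> int:
    """1 if remitted (week-8 total <= 7) else 0."""
    if week8_total < 0:
        raise ValueError("total score cannot be negative")
    return int(week8_total <= 7)


def percent_change(baseline_total: float, week8_total: float) -> float:
    """%dHRSD as a signed fraction; negative means improvement."""
    if baseline_total == 0:
        raise ValueError("baseline total must be nonzero")
    return (week8_total - baseline_total) / baseline_total


def derive_response(response_pct: float) -> int:
    """1 if responder (%dHRSD <= -50%) else 0; exactly -50% responds."""
    if not np.isfinite(response_pct):
        raise ValueError("response_pct must be finite")
    return int(response_pct <= -0.5)


def derive_stem_depressed(week8_item1: float) -> int:
    """Favorable recode of the depressed-mood item: 1 if score <= 2.

    The study's 1/2 code assigns 1 to scores >= 3 (moderately-severe or
    severe) and 2 otherwise; the favorable 0/1 recode maps code 2 -> 1.
    """
    if not 0 <= week8_item1 <= 4:
        raise ValueError("item-1 score must lie in 0-4")
    return int(week8_item1 <= 2)


def favorable_to_study_code(favorable: int) -> int:
    """Favorable 0/1 -> study 1/2 code (favorable category is 2)."""
    if favorable not in (0, 1):
        raise ValueError("favorable code must be 0 or 1")
    return 2 if favorable else 1


def study_code_to_favorable(code: int) -> int:
    if code not in (1, 2):
        raise ValueError("study code must be 1 or 2")
    return 1 if code == 2 else 0


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

def derive_phenotypes(completed: pd.DataFrame) -> pd.DataFrame:
    """Build the four-outcome table from a completed totals table.

    ``completed`` is indexed by subject with columns ``total_bl``,
    ``total_w8`` and ``item1_w8`` (no missing values). Returns favorable
    0/1 outcomes plus the study's 1/2 codes.
    """
    for col in ("total_bl", "total_w8", "item1_w8"):
        if col not in completed.columns:
            raise ValueError(f"completed table lacks column {col!r}")
        if completed[col].isna().any():
            raise ValueError(f"column {col!r} still has missing values")
    pct = (completed["total_w8"] - completed["total_bl"]) / completed["total_bl"]
    out = pd.DataFrame(index=completed.index)
    out["response_pct"] = pct
    out["remitted"] = (completed["total_w8"] <= 7).astype(int)
    out["response_binary"] = (pct <= -0.5).astype(int)
    out["stem_depressed"] = (completed["item1_w8"] <= 2).astype(int)
    for name in ("remitted", "response_binary", "stem_depressed"):
        out[f"study_code_{name}"] = out[name].map({1: 2, 0: 1})
    return out


def panel_to_completed(panel: HRSDPanel) -> pd.DataFrame:
    """Totals + week-8 item 1 for a fully observed panel."""
    totals = panel.totals()
    if totals.isna().any(axis=None):
        raise ValueError("panel has missing timepoints; impute first")
    out = totals.rename(columns={tp: f"total_{tp}" for tp in TIMEPOINTS})
    out["item1_w8"] = panel.item(1)["w8"]
    return out


# ---------------------------------------------------------------------------
# missing-data bookkeeping
# ---------------------------------------------------------------------------

def missingness_bookkeeping(
    pattern_counts: list[tuple[tuple[bool, bool, bool, bool], int]],
) -> dict:
    """Summarize a pattern-count table.

    Returns the complete-case count/fraction and the number of missing
    observations per follow-up timepoint.
    """
    n = sum(c for _, c in pattern_counts)
    if n == 0:
        raise ValueError("empty pattern table")
    for obs, _ in pattern_counts:
        if not obs[0]:
            raise ValueError("baseline must be observed in every pattern")
    complete = sum(c for obs, c in pattern_counts if all(obs))
    missing_per_tp = {
        tp: sum(c for obs, c in pattern_counts if not obs[k])
        for k, tp in enumerate(TIMEPOINTS)
    }
    return {
        "n": n,
        "complete_cases": complete,
        "complete_case_fraction": complete / n,
        "missing_per_timepoint": missing_per_tp,
    }


def observed_pattern_counts(panel: HRSDPanel) -> list[tuple[tuple[bool, ...], int]]:
    """Tabulate the observed/missing patterns present in a panel."""
    mask = panel.observed_mask()
    patterns = mask.apply(lambda row: tuple(bool(v) for v in row), axis=1)
    counts = patterns.value_counts()
    return [(pat, int(cnt)) for pat, cnt in counts.items()]


# ---------------------------------------------------------------------------
# multiple imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationResult:
    """m completed datasets from chained-equation imputation.

    ``completed`` holds one DataFrame per imputation, indexed by subject,
    with columns ``total_bl`` .. ``total_w8`` and ``item1_w8``. Observed
    cells are identical across imputations; only imputed cells vary.
    """

    completed: list[pd.DataFrame]
    seed: int
    n_iter: int

    @property
    def m(self) -> int:
        return len(self.completed)


def _draw_regression_imputation(
    rng: np.random.Generator,
    x_obs: np.ndarray,
    y_obs: np.ndarray,
    x_mis: np.ndarray,
) -> np.ndarray:
    """Proper (Bayesian) normal-linear imputation draw.

    Draws sigma^2 from its scaled inverse-chi-square posterior and the
    coefficients from their conditional normal before predicting the
    missing rows with added residual noise.
    """
    n_obs, p = x_obs.shape
    beta_hat, _, rank, _ = np.linalg.lstsq(x_obs, y_obs, rcond=None)
    resid = y_obs - x_obs @ beta_hat
    df = max(n_obs - rank, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(df)
    xtx_inv = np.linalg.pinv(x_obs.T @ x_obs)
    cov = sigma2 * xtx_inv
    # symmetrize for Cholesky stability
    cov = (cov + cov.T) / 2.0 + 1e-10 * np.eye(p)
    beta = beta_hat + np.linalg.cholesky(cov) @ rng.standard_normal(p)
    return x_mis @ beta + rng.normal(0.0, np.sqrt(sigma2), size=len(x_mis))


def multiple_impute(
    panel: HRSDPanel,
    covariates: pd.DataFrame,
    m: int = 30,
    n_iter: int = 10,
    seed: int = 0,
) -> ImputationResult:
    """Chained-equation imputation of missing timepoint totals.

    For each of ``m`` replicates, missing follow-up totals are imputed by
    sequential regression on the other timepoint totals plus age and sex,
    with parameter and residual draws (proper imputation), cycled
    ``n_iter`` times. Imputed totals are rounded and clipped to
    [0, 66]; week-8 item 1 is imputed consistently with the imputed total
    via the same severity-binning rule the generator uses.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    for col in ("age", "sex"):
        if col not in covariates.columns:
            raise ValueError(f"covariates lack column {col!r}")

    totals = panel.totals()
    item1 = panel.item(1)
    subjects = totals.index
    cov = covariates.reindex(subjects)[["age", "sex"]].to_numpy(dtype=float)
    if np.isnan(cov).any():
        raise ValueError("covariates missing for some subjects")

    t_orig = totals.to_numpy(dtype=float)  # columns bl, w2, w4, w8
    obs_mask = ~np.isnan(t_orig)
    if not obs_mask[:, 0].all():
        raise ValueError("baseline must be observed for every subject")

    follow_cols = [k for k in range(1, 4) if (~obs_mask[:, k]).any()]
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(m)

    completed: list[pd.DataFrame] = []
    for child in streams:
        rng = np.random.default_rng(child)
        t = t_orig.copy()
        # mean initialization of missing cells
        for k in range(1, 4):
            if (~obs_mask[:, k]).any():
                t[~obs_mask[:, k], k] = np.nanmean(t_orig[:, k])
        for _ in range(n_iter if follow_cols else 0):
            for k in follow_cols:
                others = [c for c in range(4) if c != k]
                design = np.column_stack(
                    [np.ones(len(subjects)), t[:, others], cov]
                )
                obs = obs_mask[:, k]
                t[~obs, k] = _draw_regression_imputation(
                    rng, design[obs], t[obs, k], design[~obs]
                )
        t_final = t.copy()
        for k in follow_cols:
            mis = ~obs_mask[:, k]
            t_final[mis, k] = np.clip(np.round(t[mis, k]), 0, HRSD_TOTAL_MAX)
        # restore observed cells bit-exactly
        t_final[obs_mask] = t_orig[obs_mask]

        frame = pd.DataFrame(
            t_final, index=subjects, columns=[f"total_{tp}" for tp in TIMEPOINTS]
        )
        i1 = item1["w8"].to_numpy(dtype=float).copy()
        mis8 = ~obs_mask[:, 3]
        if mis8.any():
            i1[mis8] = item1_from_total(t_final[mis8, 3], rng)
        frame["item1_w8"] = i1
        completed.append(frame)

    return ImputationResult(completed=completed, seed=seed, n_iter=n_iter)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

@dataclass
class PooledEstimate:
    estimate: float
    se: float
    p: float
    df: float
    m: int


def pool_rubin(estimates, standard_errors) -> PooledEstimate:
    """Pool per-imputation estimates with Rubin's rules.

    Total variance = mean within-imputation variance plus
    (1 + 1/m) times the between-imputation variance; the Wald p-value
    uses the small-m Student-t reference with
    df = (m - 1) (1 + W / ((1 + 1/m) B))^2.
    """
    q = np.asarray(estimates, dtype=float)
    se = np.asarray(standard_errors, dtype=float)
    if q.size < 2:
        raise ValueError("need at least 2 imputations to pool")
    if not np.isfinite(q).all() or not np.isfinite(se).all():
        raise ValueError("non-finite estimate or standard error")
    m = q.size
    qbar = q.mean()
    w = (se**2).mean()
    b = q.var(ddof=1)
    total = w + (1.0 + 1.0 / m) * b
    se_pool = np.sqrt(total)
    if b == 0 or total == 0:
        df = np.inf
        p = 2.0 * stats.norm.sf(abs(qbar) / se_pool) if se_pool > 0 else 1.0
    else:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
        p = 2.0 * stats.t.sf(abs(qbar) / se_pool, df)
    return PooledEstimate(float(qbar), float(se_pool), float(p), float(df), m)
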