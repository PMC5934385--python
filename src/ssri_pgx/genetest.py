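"""Gene-based set tests with LD pruning and permutation empirical p-values.

A gene's marker set is every QC-passing variant within +/-50 kb of the
gene body. The observed test: fit each member's 1-df additive model,
keep markers with p < 0.1, greedily prune so every retained pair has
r^2 < 0.5 (best p first), and aggregate the mean squared Wald z over the
retained markers. Significance comes from permutations that jointly
shuffle the (phenotype, covariate) rows against the genotype rows and
redo the whole pipeline — selection and pruning included — with

    empirical p = (1 + #{perm statistic >= observed}) / (R + 1).

Because a joint shuffle of (phenotype, covariates) against genotypes is
algebraically identical to applying the inverse permutation to the
genotype rows, the engine permutes genotype rows against fixed
(phenotype, covariates); this preserves both the genotype LD structure
and the covariate-outcome association in every replicate, and lets the
inter-marker r^2 matrix (permutation-invariant) be computed once.

For throughput the engine computes its 1-df statistics in closed form:
exact OLS partial t-tests for linear outcomes and Rao score tests for
logistic outcomes (the covariate-only null is fitted once; its MLE is
unchanged by genotype permutation). Observed and permuted statistics use
the same code path, keeping the permutation null exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import GenotypeMatrix

DEFAULT_FLANK = 50_000
DEFAULT_SET_P = 0.1
DEFAULT_PRUNE_R2 = 0.5
DEFAULT_PERMUTATIONS = 50_000


# ---------------------------------------------------------------------------
# gene mapping and LD
# ---------------------------------------------------------------------------

def map_variants_to_genes(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
) -> dict[str, list[str]]:
    """Assign each variant to every gene whose flanked interval contains it.

    ``variants`` needs columns chrom/pos (1-based); ``genes`` is indexed
    by gene name with 1-based inclusive chrom/start/end. Flank boundaries
    are inclusive: a variant exactly ``flank`` bases upstream of the start
    is a member. Multi-assignment is allowed for overlapping genes.
    """
    mapping: dict[str, list[str]] = {}
    for name, row in genes.iterrows():
        if row["start"] > row["end"]:
            raise ValueError(f"malformed interval for gene {name!r}")
        lo, hi = row["start"] - flank, row["end"] + flank
        hit = (
            (variants["chrom"].astype(str) == str(row["chrom"]))
            & (variants["pos"] >= lo)
            & (variants["pos"] <= hi)
        )
        mapping[str(name)] = [str(v) for v in variants.index[hit]]
    return mapping


def ld_r2(dosages_a, dosages_b) -> float:
    """Squared sample correlation between two dosage vectors (composite LD)."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        raise ValueError("need at least 2 shared non-missing samples")
    a, b = a[ok], b[ok]
    if a.var() == 0 or b.var() == 0:
        raise ValueError("zero dosage variance")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_r2_matrix(dosages: pd.DataFrame) -> pd.DataFrame:
    """Pairwise r^2 for a complete (no-missing) dosage block."""
    vals = dosages.to_numpy(dtype=float)
    if np.isnan(vals).any():
        corr = dosages.corr()  # pairwise-complete fallback
    else:
        with np.errstate(invalid="ignore"):
            corr = pd.DataFrame(
                np.corrcoef(vals, rowvar=False),
                index=dosages.columns,
                columns=dosages.columns,
            )
    return corr**2


# ---------------------------------------------------------------------------
# selection, pruning, aggregation
# ---------------------------------------------------------------------------

def select_and_prune(
    p_values: pd.Series,
    positions: pd.Series,
    r2: pd.DataFrame,
    p_threshold: float = DEFAULT_SET_P,
    r2_threshold: float = DEFAULT_PRUNE_R2,
    set_max: int | None = None,
) -> list[str]:
    """Greedy LD pruning of sub-threshold markers.

    Keeps markers with p strictly < ``p_threshold``, sorts them by
    ascending p (ties: position, then id), and accepts a marker iff its
    r^2 with every already-accepted marker is strictly < ``r2_threshold``.
    An empty result is valid.
    """
    cand = p_values.index[p_values < p_threshold]
    order = sorted(
        cand, key=lambda v: (p_values[v], positions.get(v, np.inf), str(v))
    )
    retained: list[str] = []
    for vid in order:
        if set_max is not None and len(retained) >= set_max:
            break
        if all(r2.loc[vid, kept] < r2_threshold for kept in retained):
            retained.append(str(vid))
    return retained


def set_statistic(z_scores) -> float:
    """Mean squared Wald z over the retained markers."""
    z = np.asarray(z_scores, dtype=float)
    if z.size == 0:
        raise ValueError("set statistic undefined for an empty set")
    return float(np.mean(z**2))


def proportion_significant(p_values, alpha: float = 0.05) -> float:
    """#(p < alpha) / #markers over all mapped markers (pre-pruning)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty gene")
    return float((p < alpha).sum() / p.size)


# ---------------------------------------------------------------------------
# fast 1-df statistics (shared by observed data and permutations)
# ---------------------------------------------------------------------------

@dataclass
class _LinearEngine:
    """Exact OLS partial t-tests for the dosage term, vectorized."""

    y: np.ndarray
    C: np.ndarray  # covariate block incl. intercept

    def __post_init__(self) -> None:
        self.n = len(self.y)
        self.q, _ = np.linalg.qr(self.C)
        self.ytil = self.y - self.q @ (self.q.T @ self.y)
        self.yss = float(self.ytil @ self.ytil)
        self.df = self.n - self.C.shape[1] - 1

    def stats(self, G: np.ndarray) -> np.ndarray:
        """Squared t statistic per column of a complete dosage block."""
        a = self.q.T @ G
        num = G.T @ self.ytil
        gss = (G * G).sum(axis=0) - (a * a).sum(axis=0)
        return self._t2(num, gss)

    def stats_permuted(self, G: np.ndarray, perms: np.ndarray) -> np.ndarray:
        """Squared t for each (permutation, marker) pair; perms is (R, n)."""
        Gp = G[perms]  # (R, n, m)
        num = np.einsum("rnm,n->rm", Gp, self.ytil)
        a = np.tensordot(Gp, self.q, axes=([1], [0]))  # (R, m, p)
        gss = (G * G).sum(axis=0)[None, :] - (a * a).sum(axis=2)
        return self._t2(num, gss)

    def _t2(self, num, gss):
        gss = np.where(gss <= 1e-12, np.nan, gss)
        rss = self.yss - num**2 / gss
        rss = np.where(rss <= 0, np.nan, rss)
        t2 = num**2 * self.df / (gss * rss)
        return np.nan_to_num(t2, nan=0.0)

    def crit(self, p_threshold: float) -> float:
        return float(stats.f.isf(p_threshold, 1, self.df))

    def p_from_stat(self, t2) -> np.ndarray:
        return stats.f.sf(t2, 1, self.df)


@dataclass
class _LogisticEngine:
    """Rao score tests against the covariate-only logistic null."""

    y: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        self.n = len(self.y)
        null = sm.Logit(self.y, self.C).fit(disp=0, maxiter=100)
        phat = np.clip(null.predict(), 1e-10, 1 - 1e-10)
        self.w = phat * (1.0 - phat)
        self.resid = self.y - phat  # orthogonal to C at the null MLE
        self.sqrt_w = np.sqrt(self.w)
        self.qw, _ = np.linalg.qr(self.C * self.sqrt_w[:, None])

    def stats(self, G: np.ndarray) -> np.ndarray:
        u = G.T @ self.resid
        gw = G * self.sqrt_w[:, None]
        b = self.qw.T @ gw
        v = (gw * gw).sum(axis=0) - (b * b).sum(axis=0)
        return self._z2(u, v)

    def stats_permuted(self, G: np.ndarray, perms: np.ndarray) -> np.ndarray:
        Gp = G[perms]
        u = np.einsum("rnm,n->rm", Gp, self.resid)
        gw2 = np.einsum("rnm,n->rm", Gp * Gp, self.w)
        b = np.tensordot(Gp * self.sqrt_w[None, :, None], self.qw, axes=([1], [0]))
        v = gw2 - (b * b).sum(axis=2)
        return self._z2(u, v)

    @staticmethod
    def _z2(u, v):
        v = np.where(v <= 1e-12, np.nan, v)
        return np.nan_to_num(u**2 / v, nan=0.0)

    def crit(self, p_threshold: float) -> float:
        return float(stats.chi2.isf(p_threshold, 1))

    def p_from_stat(self, z2) -> np.ndarray:
        return stats.chi2.sf(z2, 1)


def make_engine(y: np.ndarray, C: np.ndarray, family: str):
    if family == "linear":
        return _LinearEngine(y, C)
    if family == "logistic":
        return _LogisticEngine(y, C)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# permutation gene test
# ---------------------------------------------------------------------------

@dataclass
class GeneTestResult:
    gene: str
    outcome: str
    n_total: int
    n_selected: int
    selected: list[str]
    statistic: float
    empirical_p: float
    R: int
    p_values: pd.Series
    prop_significant: float
    null_statistics: np.ndarray | None = field(default=None, repr=False)


def _prune_indices(
    stat_row: np.ndarray,
    crit: float,
    r2: np.ndarray,
    positions: np.ndarray,
    r2_threshold: float,
    set_max: int | None,
) -> list[int]:
    """Greedy pruning on statistic scale (larger stat == smaller p)."""
    cand = np.flatnonzero(stat_row > crit)
    if cand.size == 0:
        return []
    order = cand[np.lexsort((cand, positions[cand], -stat_row[cand]))]
    kept: list[int] = []
    for j in order:
        if set_max is not None and len(kept) >= set_max:
            break
        if all(r2[j, k] < r2_threshold for k in kept):
            kept.append(int(j))
    return kept


def permutation_gene_p(
    gene_dosages: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame,
    family: str,
    *,
    gene: str = "",
    outcome: str = "",
    positions: pd.Series | None = None,
    R: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    p_threshold: float = DEFAULT_SET_P,
    r2_threshold: float = DEFAULT_PRUNE_R2,
    set_max: int | None = None,
    keep_null: bool = False,
    chunk: int = 256,
) -> GeneTestResult:
    """Empirical gene p-value from R phenotype permutations.

    Rows with a missing outcome, covariate or any missing member dosage
    are dropped first (the engine needs a complete block). Permutations
    with an empty post-pruning selection contribute statistic 0, keeping
    the null exchangeable. An empty *observed* selection yields a missing
    empirical p with ``n_selected = 0``.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    ids = y.index
    G_df = gene_dosages.loc[ids]
    cov = covariates.loc[ids, ["age", "sex"]]
    ok = (
        y.notna().to_numpy()
        & cov.notna().all(axis=1).to_numpy()
        & G_df.notna().all(axis=1).to_numpy()
    )
    G = G_df.to_numpy(dtype=float)[ok]
    yv = y.to_numpy(dtype=float)[ok]
    C = np.column_stack([np.ones(ok.sum()), cov.to_numpy(dtype=float)[ok]])
    m = G.shape[1]
    if m == 0:
        raise ValueError(f"gene {gene!r} has no member variants")
    variant_ids = list(G_df.columns)
    if positions is None:
        pos = np.arange(m, dtype=float)
    else:
        pos = positions.reindex(variant_ids).to_numpy(dtype=float)

    # drop monomorphic members (their statistic is undefined and
    # permutation-invariant)
    poly = G.std(axis=0) > 0
    mono_ids = [v for v, keep in zip(variant_ids, poly) if not keep]
    G, pos = G[:, poly], pos[poly]
    variant_ids = [v for v, keep in zip(variant_ids, poly) if keep]
    m = G.shape[1]

    engine = make_engine(yv, C, family)
    crit = engine.crit(p_threshold)
    r2 = np.corrcoef(G, rowvar=False) ** 2 if m > 1 else np.ones((1, 1))
    r2 = np.atleast_2d(r2)

    obs_stats = engine.stats(G)
    obs_p = pd.Series(engine.p_from_stat(obs_stats), index=variant_ids)
    kept_idx = _prune_indices(obs_stats, crit, r2, pos, r2_threshold, set_max)
    selected = [variant_ids[j] for j in kept_idx]
    observed = float(np.mean(obs_stats[kept_idx])) if kept_idx else np.nan

    all_p = pd.concat([obs_p, pd.Series(np.nan, index=mono_ids)])
    prop = proportion_significant(obs_p.to_numpy()) if m else np.nan

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    null_stats = np.empty(R)
    done = 0
    while done < R:
        r = min(chunk, R - done)
        perms = np.argsort(rng.random((r, len(yv))), axis=1)
        stat_block = engine.stats_permuted(G, perms)
        for i in range(r):
            kept = _prune_indices(stat_block[i], crit, r2, pos, r2_threshold, set_max)
            null_stats[done + i] = np.mean(stat_block[i][kept]) if kept else 0.0
        done += r

    if kept_idx:
        emp_p = float((1 + (null_stats >= observed).sum()) / (R + 1))
    else:
        emp_p = np.nan

    return GeneTestResult(
        gene=gene,
        outcome=outcome,
        n_total=len(G_df.columns),
        n_selected=len(selected),
        selected=selected,
        statistic=observed,
        empirical_p=emp_p,
        R=R,
        p_values=all_p,
        prop_significant=prop,
        null_statistics=null_stats if keep_null else None,
    )


def gene_scan(
    genotypes: GenotypeMatrix,
    gene_members: Mapping[str, Sequence[str]],
    phenotypes: pd.DataFrame,
    outcome: str,
    covariates: pd.DataFrame,
    *,
    family: str | None = None,
    R: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    **kwargs,
) -> list[GeneTestResult]:
    """Run the permutation gene test for every gene with members."""
    from .phenotypes import OUTCOME_FAMILY

    fam = family or OUTCOME_FAMILY[outcome]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(gene_members))
    results = []
    y = phenotypes[outcome]
    for (gene, members), child in zip(gene_members.items(), children):
        if not members:
            continue
        res = permutation_gene_p(
            genotypes.dosages[list(members)],
            y,
            covariates,
            fam,
            gene=gene,
            outcome=outcome,
            positions=genotypes.variants["pos"],
            R=R,
            seed=int(child.generate_state(1)[0] % (2**31)),
            **kwargs,
        )
        results.append(res)
    return results
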