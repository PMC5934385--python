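"""Sample- and marker-level genotype quality control.

The sample stage mirrors standard chip-QC practice: per-plate call-rate
screening, inbreeding coefficients, identity-by-state (IBS) kinship
screening, and classical-MDS outlier detection on the IBS distance
matrix. The marker stage applies, in order, a Hardy-Weinberg exact test
(p < 1e-4), a missing-call-rate filter (> 5%) and a minor-allele-frequency
filter (< 0.05); each removed marker is labeled with the first rule it
failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import GenotypeMatrix


@dataclass
class QCReport:
    """Bookkeeping for one QC pass."""

    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_markers: list[tuple[str, str]] = field(default_factory=list)
    plate_rates: pd.Series | None = None
    inbreeding: pd.Series | None = None
    mds_coords: pd.DataFrame | None = None

    def removed_sample_ids(self) -> list[str]:
        return [s for s, _ in self.removed_samples]

    def removed_marker_ids(self) -> list[str]:
        return [v for v, _ in self.removed_markers]


# ---------------------------------------------------------------------------
# sample-level QC
# ---------------------------------------------------------------------------

def plate_pass_rate(genotypes: GenotypeMatrix, plates: pd.Series) -> pd.Series:
    """Fraction of non-missing genotype calls per plate."""
    plates = plates.reindex(genotypes.sample_ids)
    if plates.isna().any():
        missing = plates.index[plates.isna()].tolist()
        raise ValueError(f"samples without a plate id: {missing[:5]}")
    called = genotypes.dosages.notna().sum(axis=1)
    total = genotypes.n_variants
    grouped = called.groupby(plates)
    sizes = grouped.size()
    if (sizes == 0).any():
        raise ValueError("plate with zero samples")
    return grouped.sum() / (sizes * total)


def filter_plates(
    genotypes: GenotypeMatrix, plates: pd.Series, min_rate: float = 0.97
) -> tuple[pd.Series, list[tuple[str, str]]]:
    """Flag samples on plates whose pass rate is not strictly > ``min_rate``."""
    rates = plate_pass_rate(genotypes, plates)
    failing = set(rates.index[rates <= min_rate])
    plates = plates.reindex(genotypes.sample_ids)
    removed = [
        (str(sid), "plate_pass_rate")
        for sid in genotypes.sample_ids
        if plates[sid] in failing
    ]
    return rates, removed


def inbreeding_coefficient(
    genotypes: GenotypeMatrix, freqs: pd.Series | None = None
) -> pd.Series:
    """Per-sample F = 1 - observed_het / expected_het.

    Expected heterozygosity sums 2 p (1 - p) over each sample's
    non-missing markers; monomorphic markers (MAF 0) are excluded.
    ``freqs`` (counted-allele frequency per marker) defaults to the
    frequencies estimated from the given samples.
    """
    if freqs is None:
        freqs = genotypes.allele_freq()
    freqs = freqs.reindex(genotypes.variant_ids)
    poly = (freqs > 0) & (freqs < 1)
    d = genotypes.dosages.loc[:, poly.to_numpy()]
    p = freqs[poly].to_numpy()
    het_w = 2.0 * p * (1.0 - p)

    obs = (d == 1).to_numpy()
    nonmiss = d.notna().to_numpy()
    obs_het = obs.sum(axis=1).astype(float)
    exp_het = nonmiss @ het_w
    if (exp_het == 0).any():
        bad = genotypes.sample_ids[exp_het == 0].tolist()
        raise ValueError(f"samples with zero usable markers: {bad[:5]}")
    return pd.Series(1.0 - obs_het / exp_het, index=genotypes.sample_ids, name="F")


def ibs_matrix(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise identity-by-state similarity in [0, 1].

    IBS(i, j) = mean over shared non-missing markers of (2 - |d_i - d_j|)/2.
    """
    if genotypes.n_samples < 2:
        raise ValueError("IBS needs at least 2 samples")
    d = genotypes.dosages.to_numpy()
    mask = ~np.isnan(d)
    # indicator decomposition: |a-b| = (a0 b1 + a1 b0 + a1 b2 + a2 b1) + 2 (a0 b2 + a2 b0)
    a0 = ((d == 0) & mask).astype(np.float64)
    a1 = ((d == 1) & mask).astype(np.float64)
    a2 = ((d == 2) & mask).astype(np.float64)
    one_step = a0 @ a1.T + a1 @ a0.T + a1 @ a2.T + a2 @ a1.T
    two_step = a0 @ a2.T + a2 @ a0.T
    shared = mask.astype(np.float64) @ mask.astype(np.float64).T
    if (shared == 0).any():
        raise ValueError("sample pair with no shared non-missing markers")
    sim = 1.0 - (one_step + 2.0 * two_step) / (2.0 * shared)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=genotypes.sample_ids, columns=genotypes.sample_ids)


def kinship_flags(
    ibs: pd.DataFrame,
    call_rates: pd.Series,
    threshold: float = 0.9,
) -> list[tuple[str, str]]:
    """Remove one member of each pair with IBS above ``threshold``.

    Pairs are processed in decreasing IBS order; within a pair the member
    with the lower call rate is removed (tie: the lexicographically later
    id). A sample already removed is skipped in later pairs.
    """
    ids = ibs.index
    sim = ibs.to_numpy()
    iu, ju = np.triu_indices(len(ids), k=1)
    hot = sim[iu, ju] > threshold
    order = np.argsort(-sim[iu, ju][hot], kind="stable")
    removed: list[tuple[str, str]] = []
    gone: set[str] = set()
    for k in order:
        a, b = str(ids[iu[hot][k]]), str(ids[ju[hot][k]])
        if a in gone or b in gone:
            continue
        ca, cb = call_rates.get(a, 0.0), call_rates.get(b, 0.0)
        if ca < cb:
            victim = a
        elif cb < ca:
            victim = b
        else:
            victim = max(a, b)
        gone.add(victim)
        removed.append((victim, "kinship"))
    return removed


def classical_mds(distance: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (metric) MDS via eigendecomposition of the double-centered
    squared-distance matrix; returns an n x k coordinate matrix."""
    n = distance.shape[0]
    d2 = distance**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)


def mds_outliers(
    ibs: pd.DataFrame, k_sd: float = 6.0
) -> tuple[list[str], pd.DataFrame]:
    """Flag samples far from the centroid of the first two MDS axes.

    Distance = 1 - IBS; a sample is an outlier when its Euclidean distance
    from the centroid exceeds ``k_sd`` times the overall per-axis spread
    (sqrt of the summed axis variances).
    """
    sim = ibs.to_numpy()
    if not np.allclose(sim, sim.T, atol=1e-10):
        raise ValueError("IBS matrix must be symmetric")
    coords = classical_mds(1.0 - sim, k=2)
    centered = coords - coords.mean(axis=0)
    r = np.sqrt((centered**2).sum(axis=1))
    scale = np.sqrt(centered.var(axis=0).sum())
    if scale == 0:
        flags = np.zeros(len(r), dtype=bool)
    else:
        flags = r > k_sd * scale
    coord_df = pd.DataFrame(coords, index=ibs.index, columns=["mds1", "mds2"])
    return [str(s) for s in ibs.index[flags]], coord_df


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=100_000)
def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test from genotype counts.

    Conditions on the allele counts: p is the summed probability of every
    attainable heterozygote count (same parity, same allele totals) whose
    conditional probability does not exceed that of the observed table.
    Returns a p-value in (0, 1].
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one sample required")
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)

    def log_prob(het: int) -> float:
        hom_min = (n_minor - het) // 2
        hom_maj = n - het - hom_min
        return (
            gammaln(n + 1)
            - gammaln(hom_min + 1)
            - gammaln(het + 1)
            - gammaln(hom_maj + 1)
            + het * np.log(2.0)
            + gammaln(n_minor + 1)
            + gammaln(2 * n - n_minor + 1)
            - gammaln(2 * n + 1)
        )

    hets = range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    logs = np.array([log_prob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[list(hets).index(n_het)]
    p = probs[probs <= obs * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# marker-level QC
# ---------------------------------------------------------------------------

def marker_qc(
    genotypes: GenotypeMatrix,
    *,
    hwe_p: float = 1e-4,
    max_missing: float = 0.05,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """Apply the marker filters in order: HWE, missingness, MAF.

    Removes markers with exact-HWE p < ``hwe_p``, missing rate strictly
    > ``max_missing`` or MAF strictly < ``min_maf``; each removal carries
    the first failing rule. Idempotent on its own output.
    """
    if genotypes.n_variants == 0:
        raise ValueError("empty genotype table")
    d = genotypes.dosages
    removed: list[tuple[str, str]] = []
    keep: list[str] = []
    miss = genotypes.missing_rate_variants()
    maf = genotypes.maf()
    for vid in genotypes.variant_ids:
        col = d[vid].dropna()
        counts = col.value_counts()
        table = (int(counts.get(0.0, 0)), int(counts.get(1.0, 0)), int(counts.get(2.0, 0)))
        if len(col) > 0 and hwe_exact(*table) < hwe_p:
            removed.append((str(vid), "hwe"))
        elif miss[vid] > max_missing:
            removed.append((str(vid), "missingness"))
        elif maf[vid] < min_maf or np.isnan(maf[vid]):
            removed.append((str(vid), "maf"))
        else:
            keep.append(vid)
    return genotypes.subset(variants=keep), removed


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_sample_qc(
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    *,
    plate_min_rate: float = 0.97,
    kinship_ibs: float = 0.9,
    mds_k_sd: float = 6.0,
) -> tuple[GenotypeMatrix, QCReport]:
    """Plate filter, then IBS kinship screen, then MDS outliers."""
    report = QCReport()
    rates, plate_removed = filter_plates(
        genotypes, samples["plate"], min_rate=plate_min_rate
    )
    report.plate_rates = rates
    report.removed_samples.extend(plate_removed)
    kept = [s for s in genotypes.sample_ids if s not in set(report.removed_sample_ids())]
    gm = genotypes.subset(samples=kept)

    report.inbreeding = inbreeding_coefficient(gm)
    ibs = ibs_matrix(gm)
    kin_removed = kinship_flags(ibs, gm.call_rate_samples(), threshold=kinship_ibs)
    report.removed_samples.extend(kin_removed)
    kept = [s for s in gm.sample_ids if s not in {v for v, _ in kin_removed}]
    gm = gm.subset(samples=kept)

    outliers, coords = mds_outliers(ibs.loc[kept, kept], k_sd=mds_k_sd)
    report.mds_coords = coords
    report.removed_samples.extend((s, "mds_outlier") for s in outliers)
    kept = [s for s in gm.sample_ids if s not in set(outliers)]
    return gm.subset(samples=kept), report


def run_marker_qc(
    genotypes: GenotypeMatrix,
    report: QCReport | None = None,
    **kwargs,
) -> tuple[GenotypeMatrix, QCReport]:
    report = report or QCReport()
    gm, removed = marker_qc(genotypes, **kwargs)
    report.removed_markers.extend(removed)
    return gm, report
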