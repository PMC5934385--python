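"""Synthetic two-site cohort generator.

Emulates the statistical structure the downstream analysis assumes:

* LD-block genotypes over candidate genes via a Gaussian copula — per gene,
  a latent AR(1) normal vector is thresholded at Hardy-Weinberg genotype
  quantiles for each variant's target minor allele frequency, giving
  dosages in {0, 1, 2} with tunable within-gene LD (``block_rho``).
* Longitudinal 21-item HRSD trajectories with the study's inclusion rule
  (baseline total >= 14), a subject-level linear improvement whose week-8
  percentage change carries optional per-allele genetic effects, and a
  depressed-mood item (item 1) monotonically coupled to the concurrent
  total so the stem-depressed outcome is derivable.
* The published missing-data pattern mixture (baseline always observed).

All randomness flows from a single seed through per-operation
``numpy.random.SeedSequence`` substreams, so every generator is
deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, HRSDPanel, ITEM_COLUMNS, TIMEPOINTS, HRSD_TOTAL_MAX
from .published import (
    FEMALE_FRACTION,
    MEAN_AGE,
    MISSINGNESS_N,
    MISSINGNESS_PATTERN_COUNTS,
    SITE_SIZES,
)

#: Outcomes an injected genetic effect may act on.
EFFECT_OUTCOMES = (
    "remitted",
    "response_binary",
    "response_pct",
    "stem_depressed",
    "case_status",
)


@dataclass(frozen=True)
class GeneModel:
    """A candidate gene and the LD block simulated for it.

    ``start``/``end`` are 1-based inclusive base-pair positions;
    ``block_rho`` is the AR(1) correlation of the latent Gaussian and
    controls within-gene LD; variant target MAFs are drawn uniformly from
    ``maf_range`` (both ends in (0, 0.5]).
    """

    name: str
    chrom: str
    start: int
    end: int
    n_variants: int = 20
    block_rho: float = 0.7
    maf_range: tuple[float, float] = (0.08, 0.5)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name}: start must be < end")
        if self.n_variants < 1:
            raise ValueError(f"{self.name}: n_variants must be >= 1")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError(f"{self.name}: block_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"{self.name}: maf_range must lie within (0, 0.5]")


@dataclass(frozen=True)
class EffectSpec:
    """A per-allele genetic effect injected into the phenotype model.

    ``beta`` acts on the outcome's continuous scale for ``response_pct``
    (units: signed fraction of baseline per allele) and on the favorable
    log-odds scale for the binary outcomes.
    """

    variant_id: str
    outcome: str
    beta: float

    def __post_init__(self) -> None:
        if self.outcome not in EFFECT_OUTCOMES:
            raise ValueError(
                f"unknown outcome {self.outcome!r}; expected one of {EFFECT_OUTCOMES}"
            )


@dataclass(frozen=True)
class MissingnessPattern:
    """One observed/missing pattern over (baseline, w2, w4, w8)."""

    observed: tuple[bool, bool, bool, bool]
    probability: float

    def __post_init__(self) -> None:
        if len(self.observed) != 4:
            raise ValueError("pattern must cover the four timepoints")
        if not self.observed[0]:
            raise ValueError("baseline is never missing")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


def default_gene_models() -> list[GeneModel]:
    """The ten candidate genes of the study design, with hg19-scale spans."""
    spans = [
        ("BDNF", "11", 27_654_893, 27_722_058),
        ("NGFR", "17", 47_572_655, 47_592_382),
        ("NTRK2", "9", 87_283_466, 87_638_505),
        ("MTOR", "1", 11_166_588, 11_322_614),
        ("VEGFA", "6", 43_737_946, 43_754_224),
        ("S100A10", "1", 151_955_391, 151_966_866),
        ("SERPINE1", "7", 100_770_370, 100_782_547),
        ("ARHGAP33", "19", 36_276_667, 36_290_969),
        ("GSK3B", "3", 119_540_800, 119_813_264),
        ("CREB1", "2", 208_394_616, 208_470_284),
    ]
    return [GeneModel(name, chrom, s, e) for name, chrom, s, e in spans]


def default_missingness_mix() -> list[MissingnessPattern]:
    """The published 8-pattern missing-data mixture (N = 428)."""
    return [
        MissingnessPattern(obs, n / MISSINGNESS_N)
        for obs, n in MISSINGNESS_PATTERN_COUNTS
    ]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _gene_positions(gene: GeneModel) -> np.ndarray:
    pos = np.round(np.linspace(gene.start, gene.end, gene.n_variants)).astype(np.int64)
    # guard against collisions in very short genes
    pos = np.maximum.accumulate(pos + np.arange(gene.n_variants) * 0)
    for j in range(1, pos.size):
        if pos[j] <= pos[j - 1]:
            pos[j] = pos[j - 1] + 1
    return pos


def simulate_genotypes(
    n_samples: int,
    genes: Sequence[GeneModel] | None = None,
    seed: int = 0,
    *,
    maf_by_variant: Mapping[str, float] | None = None,
) -> GenotypeMatrix:
    """Draw copula genotypes with AR(1) within-gene LD.

    For each gene, latent standard normals with AR(1) correlation
    ``block_rho`` are thresholded at the Hardy-Weinberg genotype-probability
    quantiles of each variant's target MAF, so marginal genotype
    frequencies converge to (1-q)^2, 2q(1-q), q^2.

    ``maf_by_variant`` overrides the drawn target MAF for named variants
    (used, e.g., to pin the causal variant of the demo, or to tilt case
    allele frequencies in the case-control generator).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    genes = list(default_gene_models() if genes is None else genes)

    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(genes))

    dosage_cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for gene, child in zip(genes, streams):
        rng = np.random.default_rng(child)
        m = gene.n_variants
        lo, hi = gene.maf_range
        mafs = rng.uniform(lo, hi, size=m)
        ids = [f"{gene.name}_snp{j + 1:03d}" for j in range(m)]
        if maf_by_variant:
            for j, vid in enumerate(ids):
                if vid in maf_by_variant:
                    q = float(maf_by_variant[vid])
                    if not 0.0 < q < 1.0:
                        raise ValueError(f"override MAF for {vid} must lie in (0,1)")
                    mafs[j] = q
        rho = gene.block_rho
        z = rng.standard_normal((n_samples, m))
        if rho > 0:
            scale = math.sqrt(1.0 - rho * rho)
            for j in range(1, m):
                z[:, j] = rho * z[:, j - 1] + scale * z[:, j]
        # HWE genotype-probability thresholds for the minor-allele count
        p0 = (1.0 - mafs) ** 2
        c0 = stats.norm.ppf(p0)
        c1 = stats.norm.ppf(p0 + 2.0 * mafs * (1.0 - mafs))
        dos = (z > c0).astype(np.float64) + (z > c1)
        positions = _gene_positions(gene)
        for j, vid in enumerate(ids):
            dosage_cols[vid] = dos[:, j]
            meta_rows.append(
                {
                    "variant_id": vid,
                    "chrom": gene.chrom,
                    "pos": int(positions[j]),
                    "ref": "A",
                    "alt": "C",
                    "gene": gene.name,
                    "target_maf": float(mafs[j]),
                }
            )

    sample_ids = pd.Index([f"S{i + 1:05d}" for i in range(n_samples)], name="sample_id")
    dosages = pd.DataFrame(dosage_cols, index=sample_ids)
    variants = pd.DataFrame(meta_rows).set_index("variant_id")
    return GenotypeMatrix(dosages, variants)


def simulate_case_control(
    n_cases: int,
    n_controls: int,
    genes: Sequence[GeneModel] | None = None,
    effects: Iterable[EffectSpec] = (),
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.Series]:
    """Draw case and control genotypes sharing a variant panel.

    Effects with outcome ``case_status`` (``beta`` = per-allele log odds
    ratio) tilt the case allele frequency to
    ``q' = q e^beta / (1 + q (e^beta - 1))`` — the allele-level logistic
    enrichment — while controls keep the base frequency.
    """
    genes = list(default_gene_models() if genes is None else genes)
    effects = list(effects)
    for e in effects:
        if e.outcome != "case_status":
            raise ValueError("case-control generator accepts only case_status effects")

    controls = simulate_genotypes(n_controls, genes, seed=seed)
    base_maf = controls.variants["target_maf"]
    overrides = {}
    for e in effects:
        if e.variant_id not in base_maf.index:
            raise KeyError(f"effect references unknown variant {e.variant_id!r}")
        q = base_maf[e.variant_id]
        eb = math.exp(e.beta)
        overrides[e.variant_id] = q * eb / (1.0 + q * (eb - 1.0))
    # reuse the same base MAFs for cases so the only difference is the tilt
    maf_map = dict(base_maf)
    maf_map.update(overrides)
    cases = simulate_genotypes(n_cases, genes, seed=seed + 1, maf_by_variant=maf_map)

    case_ids = [f"CASE_{i}" for i in cases.sample_ids]
    ctrl_ids = [f"CTRL_{i}" for i in controls.sample_ids]
    dosages = pd.concat(
        [
            cases.dosages.set_axis(case_ids, axis=0),
            controls.dosages.set_axis(ctrl_ids, axis=0),
        ]
    )
    dosages.index.name = "sample_id"
    status = pd.Series(
        [1] * n_cases + [0] * n_controls, index=dosages.index, name="case_status"
    )
    return GenotypeMatrix(dosages, cases.variants.copy()), status


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------

def assign_sites_and_plates(
    n_samples: int,
    site_fractions: Mapping[str, float] | None = None,
    plate_size: int = 96,
    seed: int = 0,
    *,
    age_mean: float = MEAN_AGE,
    age_sd: float = 12.0,
    age_range: tuple[float, float] = (18.0, 80.0),
    female_fraction: float = FEMALE_FRACTION,
) -> pd.DataFrame:
    """Build the per-sample metadata table (site, plate, sex, age, status).

    Site counts follow largest-remainder rounding of ``site_fractions``
    (default: the 268/455 vs 187/455 two-site split); plates fill
    consecutively within site. ``sex`` is coded 1 = female, 0 = male.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if plate_size < 1:
        raise ValueError("plate_size must be >= 1")
    if site_fractions is None:
        total = sum(SITE_SIZES.values())
        site_fractions = {k: v / total for k, v in SITE_SIZES.items()}
    fracs = dict(site_fractions)
    if abs(sum(fracs.values()) - 1.0) > 1e-9:
        raise ValueError("site fractions must sum to 1")

    # largest-remainder apportionment
    raw = {k: f * n_samples for k, f in fracs.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n_samples - sum(counts.values())
    for k in sorted(fracs, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    a, b = (age_range[0] - age_mean) / age_sd, (age_range[1] - age_mean) / age_sd
    rows = []
    i = 0
    for site, n_site in counts.items():
        ages = stats.truncnorm.rvs(a, b, loc=age_mean, scale=age_sd, size=n_site, random_state=rng)
        sexes = rng.binomial(1, female_fraction, size=n_site)
        for j in range(n_site):
            rows.append(
                {
                    "subject_id": f"S{i + 1:05d}",
                    "site": site,
                    "plate": f"{site}_P{j // plate_size + 1:02d}",
                    "sex": int(sexes[j]),
                    "age": float(ages[j]),
                    "status": "case",
                }
            )
            i += 1
    return pd.DataFrame(rows).set_index("subject_id")


# ---------------------------------------------------------------------------
# HRSD trajectories
# ---------------------------------------------------------------------------

def item1_from_total(
    totals: np.ndarray,
    rng: np.random.Generator,
    *,
    shift: np.ndarray | float = 0.0,
    noise_sd: float = 0.5,
) -> np.ndarray:
    """Bin a latent severity proportional to the total into item 1 (0-4).

    The latent is ``4 * total / 32`` plus optional shift and Gaussian
    noise, rounded and clipped to [0, min(4, total)] so item 1 never
    exceeds the concurrent total (monotone coupling up to noise).
    """
    totals = np.asarray(totals, dtype=float)
    latent = 4.0 * totals / 32.0 + shift
    if noise_sd > 0:
        latent = latent + rng.normal(0.0, noise_sd, size=totals.shape)
    item1 = np.clip(np.round(latent), 0, 4)
    return np.minimum(item1, totals)


# latent-shift conversion from a favorable log-odds beta to percent-change
# units under a logistic threshold approximation: sd * sqrt(3) / pi
_LOGIT_SCALE = math.sqrt(3.0) / math.pi


def simulate_hrsd(
    samples: pd.DataFrame,
    genotypes: GenotypeMatrix | None = None,
    effects: Iterable[EffectSpec] = (),
    seed: int = 0,
    *,
    baseline_mean: float = 22.5,
    baseline_sd: float = 5.0,
    baseline_min: int = 14,
    baseline_max: int = 52,
    mean_pct_change: float = -0.44,
    pct_sd: float = 0.22,
    visit_sd: float = 1.5,
    item1_noise_sd: float = 0.5,
) -> HRSDPanel:
    """Simulate complete 4-visit HRSD panels for the given samples.

    Baseline totals are truncated normal with a floor at the study's
    inclusion criterion (total >= 14). Each subject's week-8 percentage
    change is ``mean_pct_change`` plus per-allele genetic effects plus
    Gaussian noise, and improvement accrues linearly over the 8 weeks
    with per-visit rounding noise. Item 1 is binned from the concurrent
    total; the remaining 20 items share the remainder multinomially.
    """
    effects = list(effects)
    for e in effects:
        if e.outcome == "case_status":
            continue
        if genotypes is None or e.variant_id not in genotypes.variant_ids:
            raise KeyError(f"effect references unknown variant {e.variant_id!r}")
    for col in ("sex", "age", "site"):
        if col not in samples.columns:
            raise ValueError(f"sample table lacks required column {col!r}")

    n = len(samples)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    a = (baseline_min - baseline_mean) / baseline_sd
    b = (baseline_max - baseline_mean) / baseline_sd
    t0 = np.round(
        stats.truncnorm.rvs(a, b, loc=baseline_mean, scale=baseline_sd, size=n, random_state=rng)
    )
    t0 = np.clip(t0, baseline_min, baseline_max)

    pct8 = np.full(n, mean_pct_change, dtype=float)
    item1_shift = np.zeros(n)
    for e in effects:
        if e.outcome == "case_status":
            continue
        g = genotypes.dosages[e.variant_id].reindex(samples.index).to_numpy()
        if np.isnan(g).any():
            raise ValueError(f"missing dosages for effect variant {e.variant_id!r}")
        if e.outcome == "response_pct":
            pct8 += e.beta * g
        elif e.outcome in ("remitted", "response_binary"):
            # favorable log-odds -> latent percent-change shift
            pct8 -= e.beta * g * pct_sd * _LOGIT_SCALE
        elif e.outcome == "stem_depressed":
            item1_shift -= e.beta * g * 0.5
    if pct_sd > 0:
        pct8 = pct8 + rng.normal(0.0, pct_sd, size=n)
    pct8 = np.clip(pct8, -0.95, 0.6)

    rows = []
    week_of = {"bl": 0, "w2": 2, "w4": 4, "w8": 8}
    totals_by_tp = {}
    for tp in TIMEPOINTS:
        w = week_of[tp]
        if tp == "bl":
            tw = t0.copy()
        else:
            tw = t0 * (1.0 + pct8 * w / 8.0)
            if visit_sd > 0:
                tw = tw + rng.normal(0.0, visit_sd, size=n)
            tw = np.clip(np.round(tw), 0, HRSD_TOTAL_MAX)
        totals_by_tp[tp] = tw

    for tp in TIMEPOINTS:
        tw = totals_by_tp[tp]
        shift = item1_shift if tp == "w8" else 0.0
        i1 = item1_from_total(tw, rng, shift=shift, noise_sd=item1_noise_sd)
        rest = (tw - i1).astype(np.int64)
        other = rng.multinomial(rest, np.full(20, 1.0 / 20.0))
        block = np.column_stack([i1, other]).astype(float)
        for k, sid in enumerate(samples.index):
            rows.append((sid, tp, *block[k]))

    data = pd.DataFrame(rows, columns=["subject_id", "timepoint", *ITEM_COLUMNS])
    return HRSDPanel(data)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def inject_missingness(
    panel: HRSDPanel,
    mix: Sequence[MissingnessPattern] | None = None,
    seed: int = 0,
) -> HRSDPanel:
    """Mask follow-up visits according to a pattern mixture.

    Each subject draws one pattern multinomially; masked timepoints have
    all 21 items set to missing. Observed values are never altered and
    baseline is never masked (enforced by :class:`MissingnessPattern`).
    """
    mix = list(default_missingness_mix() if mix is None else mix)
    probs = np.array([p.probability for p in mix])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("pattern probabilities must sum to 1")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    subjects = panel.subjects
    choice = rng.choice(len(mix), size=len(subjects), p=probs)
    pattern_by_subject = {sid: mix[c].observed for sid, c in zip(subjects, choice)}

    data = panel.data.copy()
    tp_index = {tp: k for k, tp in enumerate(TIMEPOINTS)}
    mask = np.array(
        [
            not pattern_by_subject[sid][tp_index[tp]]
            for sid, tp in zip(data["subject_id"], data["timepoint"])
        ]
    )
    data.loc[mask, list(ITEM_COLUMNS)] = np.nan
    return HRSDPanel(data)
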