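"""Run configuration: every numeric constant of the pipeline in one place.

A :class:`RunConfig` is validated on construction, serialized verbatim
into every output's metadata block via its hash, and fully round-trips
through JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from .simulate import EffectSpec


@dataclass
class RunConfig:
    seed: int = 0

    # cohort / simulation
    n_samples: int = 455
    site_fractions: dict[str, float] = field(
        default_factory=lambda: {"NHRI": 268 / 455, "TVGH": 187 / 455}
    )
    plate_size: int = 96
    variants_per_gene: int = 20
    block_rho: float = 0.7
    effects: list[dict] = field(default_factory=list)
    maf_overrides: dict[str, float] = field(default_factory=dict)

    # QC cutoffs
    plate_pass_rate: float = 0.97
    kinship_ibs: float = 0.9
    mds_k_sd: float = 6.0
    hwe_p: float = 1e-4
    max_missing: float = 0.05
    min_maf: float = 0.05

    # phenotypes / imputation
    imputation_m: int = 30
    imputation_iter: int = 10
    outcomes: list[str] = field(
        default_factory=lambda: [
            "remitted",
            "response_binary",
            "response_pct",
            "stem_depressed",
        ]
    )

    # gene tests
    flank: int = 50_000
    set_p_threshold: float = 0.1
    prune_r2: float = 0.5
    permutations: int = 50_000
    set_max: int | None = None
    gene_test_scope: str = "all"  # "all" = per-site + mega, "mega" = pooled only

    # meta / mega
    fisher_alpha: float = 1.0
    include_site_covariate: bool = False
    meff_r2: float = 0.8

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            (self.n_samples >= 2, "n_samples must be >= 2"),
            (abs(sum(self.site_fractions.values()) - 1.0) < 1e-9, "site fractions must sum to 1"),
            (self.plate_size >= 1, "plate_size must be >= 1"),
            (0.0 < self.plate_pass_rate < 1.0, "plate_pass_rate must lie in (0,1)"),
            (0.0 < self.kinship_ibs <= 1.0, "kinship_ibs must lie in (0,1]"),
            (self.mds_k_sd > 0, "mds_k_sd must be positive"),
            (0.0 < self.hwe_p < 1.0, "hwe_p must lie in (0,1)"),
            (0.0 <= self.max_missing < 1.0, "max_missing must lie in [0,1)"),
            (0.0 <= self.min_maf <= 0.5, "min_maf must lie in [0,0.5]"),
            (self.imputation_m >= 2, "imputation_m must be >= 2"),
            (self.imputation_iter >= 1, "imputation_iter must be >= 1"),
            (self.flank >= 0, "flank must be non-negative"),
            (0.0 < self.set_p_threshold <= 1.0, "set_p_threshold must lie in (0,1]"),
            (0.0 < self.prune_r2 <= 1.0, "prune_r2 must lie in (0,1]"),
            (self.permutations >= 1, "permutations must be >= 1"),
            (self.fisher_alpha > 0, "fisher_alpha must be positive"),
            (0.0 < self.meff_r2 <= 1.0, "meff_r2 must lie in (0,1]"),
            (self.gene_test_scope in ("all", "mega"), "gene_test_scope must be 'all' or 'mega'"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid configuration: {msg}")
        from .phenotypes import OUTCOME_FAMILY

        for o in self.outcomes:
            if o not in OUTCOME_FAMILY:
                raise ValueError(f"invalid configuration: unknown outcome {o!r}")

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    def effect_specs(self) -> list[EffectSpec]:
        return [EffectSpec(**e) for e in self.effects]


def demo_config(seed: int = 0) -> RunConfig:
    """The in-repo demonstration: the two-site cohort, ten candidate
    genes, and one causal VEGFA variant with a per-allele effect of
    +0.08 on the week-8 percentage change.

    Permutations and imputations are scaled to desk hardware (R = 1000,
    m = 10); both are single knobs on :class:`RunConfig`.
    """
    return RunConfig(
        seed=seed,
        effects=[{"variant_id": "VEGFA_snp010", "outcome": "response_pct", "beta": 0.08}],
        maf_overrides={"VEGFA_snp010": 0.3},
        imputation_m=10,
        permutations=1000,
    )


def ranking_config(seed: int = 0) -> RunConfig:
    """Reduced demo profile used to replicate the causal-gene ranking:
    continuous response only, pooled-sample gene tests, minimal
    imputation. Identical generator and effect settings to
    :func:`demo_config`."""
    cfg = demo_config(seed)
    cfg.outcomes = ["response_pct"]
    cfg.gene_test_scope = "mega"
    cfg.imputation_m = 2
    cfg.validate()
    return cfg
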