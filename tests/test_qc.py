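"""Quality control: plate rates, inbreeding, IBS/kinship, MDS outliers,
the Hardy-Weinberg exact test and marker filters."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from ssri_pgx import simulate_genotypes, GeneModel
from ssri_pgx.qc import (
    classical_mds,
    filter_plates,
    hwe_exact,
    ibs_matrix,
    inbreeding_coefficient,
    kinship_flags,
    marker_qc,
    mds_outliers,
    plate_pass_rate,
)

from conftest import make_genotype_matrix


def hwe_enumeration_oracle(n_hom_ref, n_het, n_hom_alt):
    """Exact-arithmetic enumeration of the conditional HWE test.

    P(het | allele counts) computed with integer combinatorics
    (arrangements x 2^het over the total), independent of the log-gamma
    implementation under test.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)

    def weight(het):
        hom_min = (n_minor - het) // 2
        hom_maj = n - het - hom_min
        return Fraction(
            math.factorial(n)
            * 2**het,
            math.factorial(hom_min) * math.factorial(het) * math.factorial(hom_maj),
        )

    hets = list(range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2))
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


class TestPlates:
    def test_complete_plate_retained(self):
        gm = make_genotype_matrix(np.zeros((4, 10)) + 1)
        plates = pd.Series("P1", index=gm.sample_ids)
        rates, removed = filter_plates(gm, plates)
        assert rates["P1"] == 1.0 and removed == []

    def test_rate_arithmetic_and_removal(self):
        """40 missing calls out of 1000 gives rate 0.96 and removal."""
        d = np.ones((10, 100))
        d[0, :40] = np.nan
        gm = make_genotype_matrix(d)
        plates = pd.Series("P1", index=gm.sample_ids)
        rates, removed = filter_plates(gm, plates)
        assert rates["P1"] == pytest.approx(0.96)
        assert len(removed) == 10

    def test_exact_boundary_is_removed(self):
        """Retention requires rate strictly greater than 0.97."""
        d = np.ones((1, 100))
        d[0, :3] = np.nan  # rate exactly 0.97
        gm = make_genotype_matrix(d)
        plates = pd.Series("P1", index=gm.sample_ids)
        _, removed = filter_plates(gm, plates)
        assert len(removed) == 1

    def test_missing_plate_id_rejected(self):
        gm = make_genotype_matrix(np.ones((2, 5)))
        plates = pd.Series({"S001": "P1"})
        with pytest.raises(ValueError):
            plate_pass_rate(gm, plates)


class TestInbreeding:
    def test_three_marker_toy_matches_direct_formula(self):
        """F on a hand-built 3-marker sample equals 1 - obs/exp by hand."""
        d = np.array([[1.0, 1.0, 0.0], [0.0, 2.0, 2.0]])
        gm = make_genotype_matrix(d)
        freqs = gm.allele_freq()  # (0.25, 0.75, 0.5)
        f = inbreeding_coefficient(gm, freqs)
        exp_het = float((2 * freqs * (1 - freqs)).sum())
        assert f.iloc[0] == pytest.approx(1 - 2 / exp_het)
        assert f.iloc[1] == pytest.approx(1.0)

    def test_fully_homozygous_sample_is_one(self):
        d = np.array([[0.0, 2.0, 0.0, 2.0], [1.0, 1.0, 1.0, 1.0]])
        gm = make_genotype_matrix(d)
        freqs = pd.Series(0.5, index=gm.variant_ids)
        f = inbreeding_coefficient(gm, freqs)
        assert f.iloc[0] == pytest.approx(1.0)

    def test_random_mating_mean_near_zero(self):
        gm = simulate_genotypes(
            2000, [GeneModel("G", "1", 1, 10**6, n_variants=200, block_rho=0.0)],
            seed=21,
        )
        f = inbreeding_coefficient(gm)
        se = f.std(ddof=1) / np.sqrt(len(f))
        assert abs(f.mean()) < 3 * max(se, 1e-3)


class TestIBS:
    def test_duplicate_sample_detected_and_removed(self):
        base = np.random.default_rng(0).integers(0, 3, size=(5, 50)).astype(float)
        d = np.vstack([base, base[0]])
        gm = make_genotype_matrix(d)
        ibs = ibs_matrix(gm)
        assert ibs.iloc[0, 5] == pytest.approx(1.0)
        removed = kinship_flags(ibs, gm.call_rate_samples(), threshold=0.9)
        assert len(removed) == 1 and removed[0][1] == "kinship"

    def test_opposite_homozygotes_have_zero_ibs(self):
        gm = make_genotype_matrix(np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0]]))
        assert ibs_matrix(gm).iloc[0, 1] == pytest.approx(0.0)

    def test_unrelated_pair_matches_enumeration_oracle(self):
        """Mean IBS of an unrelated pair sits within 3 SE of the value from
        brute-force summation over the 9 HWE genotype pairs."""
        q = 0.3
        probs = {0: (1 - q) ** 2, 1: 2 * q * (1 - q), 2: q**2}
        expect = sum(
            probs[a] * probs[b] * (2 - abs(a - b)) / 2
            for a in probs for b in probs
        )
        var = sum(
            probs[a] * probs[b] * ((2 - abs(a - b)) / 2 - expect) ** 2
            for a in probs for b in probs
        )
        m = 10_000
        gm = simulate_genotypes(
            2, [GeneModel("G", "1", 1, 10**7, n_variants=m, block_rho=0.0,
                          maf_range=(q, q))],
            seed=22,
        )
        obs = ibs_matrix(gm).iloc[0, 1]
        assert abs(obs - expect) < 3 * np.sqrt(var / m)

    def test_kinship_tiebreak_prefers_higher_call_rate(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, size=(4, 60)).astype(float)
        d = np.vstack([base, base[0]])
        d[4, :10] = np.nan  # duplicate has the lower call rate
        gm = make_genotype_matrix(d)
        removed = kinship_flags(ibs_matrix(gm), gm.call_rate_samples())
        assert removed == [("S005", "kinship")]


class TestMDS:
    def test_homogeneous_cohort_has_no_outliers(self):
        gm = simulate_genotypes(
            100, [GeneModel("G", "1", 1, 10**6, n_variants=300, block_rho=0.0)],
            seed=23,
        )
        outliers, coords = mds_outliers(ibs_matrix(gm), k_sd=6.0)
        assert outliers == []
        assert coords.shape == (100, 2)

    def test_constructed_outlier_is_flagged(self):
        """One sample at IBS 0.5 to a tight 0.73-similar cluster stands out."""
        n = 100
        sim = np.full((n, n), 0.73)
        rng = np.random.default_rng(2)
        noise = rng.normal(0, 0.005, size=(n, n))
        sim += (noise + noise.T) / 2
        np.fill_diagonal(sim, 1.0)
        sim[0, 1:] = 0.5
        sim[1:, 0] = 0.5
        ids = [f"S{i:03d}" for i in range(n)]
        outliers, _ = mds_outliers(pd.DataFrame(sim, index=ids, columns=ids), k_sd=6.0)
        assert outliers == ["S000"]

    def test_asymmetric_input_rejected(self):
        bad = pd.DataFrame([[1.0, 0.2], [0.4, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            mds_outliers(bad)

    def test_mds_reconstructs_planar_distances(self):
        """Classical MDS recovers pairwise distances of 2-D points exactly."""
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(20, 2))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords = classical_mds(dist, k=2)
        rec = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.abs(rec - dist).max() < 1e-8


class TestHWEExact:
    def test_monomorphic_marker_is_one(self):
        assert hwe_exact(10, 0, 0) == 1.0
        assert hwe_exact(0, 0, 7) == 1.0

    def test_four_het_table_matches_enumeration(self):
        """(0 hom-ref, 4 het, 0 hom-alt): enumeration over het in {0,2,4}."""
        assert hwe_exact(0, 4, 0) == pytest.approx(hwe_enumeration_oracle(0, 4, 0))

    @pytest.mark.parametrize("n", [5, 11, 20])
    def test_matches_exact_fraction_oracle(self, n):
        for n_minor in range(0, n + 1):
            for het in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
                hom_min = (n_minor - het) // 2
                hom_maj = n - het - hom_min
                got = hwe_exact(hom_maj, het, hom_min)
                want = hwe_enumeration_oracle(hom_maj, het, hom_min)
                assert got == pytest.approx(want, rel=1e-9), (n, n_minor, het)

    def test_distribution_sums_to_one(self):
        """The conditional het-count probabilities form a distribution."""
        for n, n_minor in [(50, 17), (50, 50), (33, 8)]:
            hets = range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
            weights = []
            for het in hets:
                hom_min = (n_minor - het) // 2
                hom_maj = n - het - hom_min
                weights.append(
                    Fraction(math.factorial(n) * 2**het,
                             math.factorial(hom_min) * math.factorial(het)
                             * math.factorial(hom_maj))
                )
            probs = [w / sum(weights) for w in weights]
            assert float(sum(probs)) == pytest.approx(1.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact(-1, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact(0, 0, 0)


class TestMarkerQC:
    def test_missingness_rule_and_label(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 2, size=(100, 1)).astype(float) + rng.integers(0, 2, (100, 1))
        d[:6, 0] = np.nan  # 6% missing
        gm = make_genotype_matrix(d)
        _, removed = marker_qc(gm)
        assert removed == [("v1", "missingness")]

    def test_maf_boundary_is_retained(self):
        """MAF exactly 0.05 passes the strictly-smaller-than filter."""
        d = np.zeros((100, 1))
        d[:10, 0] = 1.0  # allele freq 0.05 exactly
        gm = make_genotype_matrix(d)
        kept, removed = marker_qc(gm)
        assert kept.n_variants == 1 and removed == []

    def test_hwe_rule_fires_first(self):
        d = np.ones((100, 1))  # all heterozygous: gross HWE violation
        d[:6, 0] = np.nan
        gm = make_genotype_matrix(d)
        _, removed = marker_qc(gm)
        assert removed == [("v1", "hwe")]

    def test_null_markers_rarely_fail_hwe(self):
        """The exact test at 1e-4 removes (far) fewer than 0.5% of
        Hardy-Weinberg markers."""
        gm = simulate_genotypes(
            300, [GeneModel("G", "1", 1, 10**7, n_variants=1000, block_rho=0.0)],
            seed=24,
        )
        _, removed = marker_qc(gm, min_maf=0.0)
        n_hwe = sum(1 for _, r in removed if r == "hwe")
        assert n_hwe <= 4

    def test_idempotent(self):
        gm = simulate_genotypes(
            200, [GeneModel("G", "1", 1, 10**6, n_variants=50, block_rho=0.3)],
            seed=25,
        )
        kept, _ = marker_qc(gm)
        kept2, removed2 = marker_qc(kept)
        assert removed2 == []
        pd.testing.assert_frame_equal(kept.dosages, kept2.dosages)
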