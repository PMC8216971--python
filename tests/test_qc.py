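import math
from fractions import Fraction

import numpy as np
import pytest

from provscan.core_io import MISSING, EmptyDatasetError, GenotypeDataset, LocusInfo
from provscan.qc import (
    QcConfig,
    QcReport,
    het_deficit,
    hwe_exact_test,
    ibd_kinship,
    ld_prune,
    neutral_subset,
    run_qc,
    sample_filters,
    site_filters,
)
from provscan.simulate import SimConfig, linked_locus_pairs, simulate_genotypes


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration of the conditional heterozygote distribution."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0
    rare = min(n_A, n_a)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        if hom_common < 0:
            continue
        # P(h) ∝ n! / (hom_rare! h! hom_common!) * 2^h (conditional on allele counts)
        probs[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(hom_rare) * math.factorial(h) * math.factorial(hom_common),
        )
    total = sum(probs.values())
    obs = probs[n_Aa] / total
    return float(sum(p for p in probs.values() if Fraction(p, total) <= obs) / total)


class TestHweExact:
    def test_two_het_individuals(self):
        # counts (0, 2, 0): configurations {2 het} and {1 hom each}; p = 1
        assert hwe_exact_test(0, 2, 0) == pytest.approx(hwe_enumeration_oracle(0, 2, 0))
        assert hwe_exact_test(0, 2, 0) == pytest.approx(1.0)

    def test_monomorphic(self):
        assert hwe_exact_test(5, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_exhaustive_small_n(self):
        """Match the rational enumeration oracle for every config with n <= 12."""
        for n in range(1, 13):
            for n_AA in range(n + 1):
                for n_Aa in range(n - n_AA + 1):
                    n_aa = n - n_AA - n_Aa
                    assert hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
                        hwe_enumeration_oracle(n_AA, n_Aa, n_aa), abs=1e-12
                    ), (n_AA, n_Aa, n_aa)

    def test_random_counts_up_to_50(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(1, 51))
            n_AA = int(rng.integers(0, n + 1))
            n_Aa = int(rng.integers(0, n - n_AA + 1))
            n_aa = n - n_AA - n_Aa
            assert hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
                hwe_enumeration_oracle(n_AA, n_Aa, n_aa), abs=1e-10
            )

    def test_negative_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 1)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


def _dataset_from_matrix(dosage, scaffold="s1"):
    dosage = np.asarray(dosage, dtype=np.int16)
    n, m = dosage.shape
    loci = [LocusInfo(f"l{j}", scaffold, 10 * (j + 1), "A", "C") for j in range(m)]
    samples = [f"p{i % 2}_{i}" for i in range(n)]
    prov = {s: s.split("_")[0] for s in samples}
    return GenotypeDataset(samples, loci, dosage, prov)


class TestSiteFilters:
    def test_maf_boundary_retained(self):
        ds = _dataset_from_matrix([[0], [0], [0], [1]])  # MAF = 0.125
        out, report = site_filters(ds, QcConfig(maf_min=0.05, site_callrate_min=0.5))
        assert out.n_loci == 1

    def test_low_callrate_removed(self):
        col = [[0]] * 94 + [[MISSING]] * 6  # call rate 0.94 < 0.95
        good = [[1] if i % 2 else [0] for i in range(100)]
        dosage = np.hstack([np.array(col), np.array(good)])
        ds = _dataset_from_matrix(dosage)
        out, report = site_filters(ds, QcConfig())
        assert out.n_loci == 1
        assert report.stages[0].n_removed == 1

    def test_engineered_fixture_counts(self):
        rng = np.random.default_rng(1)
        cols = []
        # 13 good loci
        for _ in range(13):
            cols.append(rng.integers(0, 2, size=40) + rng.integers(0, 2, size=40))
        # 4 rare loci (MAF < 0.05), 3 low call rate
        for _ in range(4):
            c = np.zeros(40, int)
            c[0] = 1
            cols.append(c)
        for _ in range(3):
            c = rng.integers(0, 3, size=40)
            c[:3] = MISSING
            cols.append(c)
        ds = _dataset_from_matrix(np.column_stack(cols))
        out, report = site_filters(ds, QcConfig())
        assert out.n_loci == 13
        assert report.stages[0].n_removed == 7

    def test_all_removed_errors(self):
        ds = _dataset_from_matrix([[0], [0], [0], [0]])
        with pytest.raises(EmptyDatasetError):
            site_filters(ds, QcConfig())


class TestLdPrune:
    def test_duplicate_locus_one_copy(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 1])
        ds = _dataset_from_matrix(np.column_stack([col, col]))
        kept = ld_prune(ds, QcConfig())
        assert kept == ["l0"]

    def test_uncorrelated_all_retained(self):
        rng = np.random.default_rng(2)
        dosage = rng.binomial(2, 0.5, size=(500, 10))
        ds = _dataset_from_matrix(dosage)
        cfg = QcConfig(ld_r_max=0.3)
        assert len(ld_prune(ds, cfg)) == 10

    def test_posthoc_within_window_pairs_below_threshold(self, default_sim):
        """Brute-force verification: no retained within-window pair above r."""
        _, ds, _ = default_sim
        sub = ds.subset_loci(range(300))
        sub = linked_locus_pairs(sub, 30, seed=3)
        cfg = QcConfig(ld_window=20)
        kept_ids = set(ld_prune(sub, cfg))
        order = sorted(
            (j for j, l in enumerate(sub.loci) if l.id in kept_ids),
            key=lambda j: (sub.loci[j].scaffold, sub.loci[j].position),
        )
        for a_pos, ja in enumerate(order):
            for jb in order[max(0, a_pos - cfg.ld_window) : a_pos]:
                if sub.loci[ja].scaffold != sub.loci[jb].scaffold:
                    continue
                da, db = sub.dosage[:, ja], sub.dosage[:, jb]
                obs = (da != MISSING) & (db != MISSING)
                if obs.sum() < 3:
                    continue
                r = np.corrcoef(da[obs], db[obs])[0, 1]
                assert abs(r) <= cfg.ld_r_max + 1e-12

    def test_deterministic(self, default_sim):
        _, ds, _ = default_sim
        sub = ds.subset_loci(range(200))
        assert ld_prune(sub, QcConfig()) == ld_prune(sub, QcConfig())


class TestIbdKinship:
    def test_self_phi_half(self, default_sim):
        _, ds, _ = default_sim
        phi, _ = ibd_kinship(ds.subset_samples(range(20)))
        np.testing.assert_allclose(np.diag(phi), 0.5)

    def test_unrelated_near_zero(self):
        cfg = SimConfig(
            n_groups=1, demes_per_group=1, samples_per_deme=30, n_neutral_loci=1000,
            n_adaptive_loci=0, F_CT=0.0, F_SC=0.0, missing_rate=0.0, seed=15,
        )
        ds, _ = simulate_genotypes(cfg)
        phi, _ = ibd_kinship(ds)
        off = phi[np.triu_indices_from(phi, k=1)]
        assert np.abs(off).max() < 0.1
        assert abs(off.mean()) < 0.03

    def test_parent_offspring_quarter(self):
        cfg = SimConfig(
            F_CT=0.02, F_SC=0.01, n_adaptive_loci=0, missing_rate=0.0,
            n_related_pairs=4, seed=16,
        )
        ds, truth = simulate_genotypes(cfg)
        phi, _ = ibd_kinship(ds)
        si = {s: i for i, s in enumerate(ds.samples)}
        for a, b, _ in truth.related_pairs:
            assert phi[si[a], si[b]] == pytest.approx(0.25, abs=0.05)

    def test_low_overlap_flagged(self):
        rng = np.random.default_rng(3)
        dosage = rng.binomial(2, 0.4, size=(4, 60)).astype(np.int16)
        dosage[0, 20:] = MISSING  # only 20 loci overlap for pairs with sample 0
        ds = _dataset_from_matrix(dosage)
        _, unreliable = ibd_kinship(ds, min_overlap=50)
        assert unreliable[0, 1] and unreliable[1, 0]
        assert not unreliable[1, 2]


class TestHetDeficitAndSampleFilters:
    def test_fully_het_sample_negative_F(self):
        rng = np.random.default_rng(4)
        dosage = rng.binomial(2, 0.5, size=(30, 200)).astype(np.int16)
        dosage[0] = 1  # fully heterozygous
        ds = _dataset_from_matrix(dosage)
        F = het_deficit(ds)
        assert F[0] < -0.5

    def test_planted_inbred_removed(self):
        cfg = SimConfig(
            F_CT=0.02, F_SC=0.01, n_adaptive_loci=0, n_inbred=3, missing_rate=0.0, seed=17
        )
        ds, truth = simulate_genotypes(cfg)
        F = het_deficit(ds)
        si = {s: i for i, s in enumerate(ds.samples)}
        for s, _ in truth.inbred_samples:
            assert F[si[s]] > 0.1
        phi, _ = ibd_kinship(ds)
        out, _ = sample_filters(ds, QcConfig(), phi)
        for s, _ in truth.inbred_samples:
            assert s not in out.samples

    def test_178_to_173(self):
        """Five planted inbred among 178 -> 173 retained."""
        sizes = (10, 13, 10, 9, 11, 13, 10, 11, 10, 11, 9, 13, 15, 12, 11, 10)
        assert sum(sizes) == 178
        cfg = SimConfig(
            deme_sizes=sizes, F_CT=0.02, F_SC=0.01, n_adaptive_loci=0,
            n_inbred=5, missing_rate=0.0, seed=18,
        )
        ds, truth = simulate_genotypes(cfg)
        phi, _ = ibd_kinship(ds)
        out, report = sample_filters(ds, QcConfig(), phi)
        assert out.n_samples == 173

    def test_related_pair_lower_callrate_removed(self):
        rng = np.random.default_rng(5)
        dosage = rng.binomial(2, 0.5, size=(10, 300)).astype(np.int16)
        dosage[1] = dosage[0]  # identical pair -> phi ~ 0.5
        dosage[1, :20] = MISSING  # member 1 has the lower call rate
        ds = _dataset_from_matrix(dosage)
        phi, _ = ibd_kinship(ds)
        out, _ = sample_filters(ds, QcConfig(het_deficit_max=0.99), phi)
        assert ds.samples[0] in out.samples
        assert ds.samples[1] not in out.samples


class TestNeutralSubsetAndCascade:
    def test_subset_size_and_determinism(self, default_sim):
        _, ds, _ = default_sim
        cfg = QcConfig(neutral_subset_size=500, seed=7)
        ids1 = neutral_subset(ds, cfg)
        ids2 = neutral_subset(ds, cfg)
        assert len(ids1) == 500
        assert ids1 == ids2

    def test_subset_smaller_pool(self, default_sim):
        _, ds, _ = default_sim
        sub = ds.subset_loci(range(800))
        ids = neutral_subset(sub, QcConfig(neutral_subset_size=1500, seed=1))
        assert len(ids) == 800

    def test_cascade_telescopes(self):
        cfg = SimConfig(F_CT=0.03, F_SC=0.01, n_inbred=2, seed=19)
        ds, _ = simulate_genotypes(cfg)
        out, neutral, report, _ = run_qc(ds, QcConfig(neutral_subset_size=300, seed=2))
        report.validate_telescoping()
        names = [s.name for s in report.stages]
        assert names == ["maf_callrate", "hwe", "ld_prune", "pre_sample", "sample_filters"]
        assert out.n_loci == report.stages[2].n_out
        assert out.n_samples == report.stages[-1].n_out

    def test_qc_config_defaults(self):
        cfg = QcConfig()
        assert cfg.maf_min == 0.05
        assert cfg.hwe_alpha == 1e-6
        assert cfg.ld_r_max == 0.2
        assert cfg.kinship_max == 0.25
        assert cfg.het_deficit_max == 0.1
        assert cfg.site_callrate_min == 0.95
        assert cfg.sample_callrate_min == 0.95
        assert cfg.neutral_subset_size == 1500

    def test_report_telescoping_violation_detected(self):
        report = QcReport()
        report.add("a", "loci", 100, 10)
        report.add("b", "loci", 95, 5)  # should be 90
        with pytest.raises(ValueError, match="telescope"):
            report.validate_telescoping()
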