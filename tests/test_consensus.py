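import numpy as np
import pandas as pd
import pytest

from provscan.consensus import (
    METHODS,
    Thresholds,
    allele_freq_climate_corr,
    build_shortlists,
    consensus_sets,
    eigen_discrimination,
    eta_squared,
)
from provscan.simulate import SimConfig, simulate_genotypes


def _scan_tables(loci, axis="PC1", fst_hits=(), q_hits=(), bf_hits=(), lfmm_hits=()):
    """Construct scan output tables realizing the requested shortlists."""
    fst = pd.DataFrame(
        {
            "locus": loci,
            "neglog_quantile": [2.0 if l in fst_hits else 0.5 for l in loci],
        }
    )
    fm = pd.DataFrame(
        {
            "locus": loci,
            "axis": axis,
            "q": [0.01 if l in q_hits else 0.9 for l in loci],
        }
    )
    be = pd.DataFrame(
        {
            "locus": loci,
            "axis": axis,
            "bf": [100.0 if l in bf_hits else 1.0 for l in loci],
            "rho": [0.8 if l in bf_hits else 0.1 for l in loci],
        }
    )
    lf = pd.DataFrame(
        {
            "locus": loci,
            "axis": axis,
            "p_cal": [1e-4 if l in lfmm_hits else 0.5 for l in loci],
        }
    )
    return fst, fm, be, lf


class TestBuildShortlists:
    def test_empty_scans(self):
        loci = [f"l{i}" for i in range(10)]
        sl = build_shortlists(*_scan_tables(loci), axis="PC1")
        assert all(len(s) == 0 for s in sl.values())

    def test_threshold_defaults_echo_decision_rules(self):
        th = Thresholds()
        assert th.bf_min == 30.0
        assert th.rho_min == 0.4
        assert th.neglog_p_min == pytest.approx(1.3)
        assert th.neglog_quantile_min == pytest.approx(1.3)
        assert th.neglog_q_min == pytest.approx(1.3)

    def test_brute_force_threshold_application(self, default_sim):
        rng = np.random.default_rng(0)
        loci = [f"l{i}" for i in range(200)]
        fst = pd.DataFrame({"locus": loci, "neglog_quantile": rng.uniform(0, 3, 200)})
        fm = pd.DataFrame({"locus": loci, "axis": "PC1", "q": rng.uniform(0, 1, 200)})
        be = pd.DataFrame(
            {"locus": loci, "axis": "PC1", "bf": rng.uniform(0, 100, 200), "rho": rng.uniform(-1, 1, 200)}
        )
        lf = pd.DataFrame({"locus": loci, "axis": "PC1", "p_cal": rng.uniform(0, 1, 200)})
        sl = build_shortlists(fst, fm, be, lf, "PC1")
        th = Thresholds()
        for i, l in enumerate(loci):
            assert (l in sl["fst"]) == (fst["neglog_quantile"][i] > th.neglog_quantile_min)
            assert (l in sl["bayscenv"]) == (-np.log10(fm["q"][i]) > th.neglog_q_min)
            assert (l in sl["bayenv"]) == (be["bf"][i] > 30 and abs(be["rho"][i]) > 0.4)
            assert (l in sl["lfmm"]) == (-np.log10(lf["p_cal"][i]) > th.neglog_p_min)

    def test_locus_set_mismatch_errors(self):
        loci = [f"l{i}" for i in range(5)]
        fst, fm, be, lf = _scan_tables(loci)
        lf2 = lf.iloc[:3]
        with pytest.raises(ValueError, match="different locus sets"):
            build_shortlists(fst, fm, be, lf2, "PC1")


def consensus_oracle(shortlists, ranks, cap):
    """Brute-force set algebra: union of pairwise intersections with the
    fst&lfmm intersection truncated to its top-cap by rank."""
    from itertools import combinations

    out = set()
    for m1, m2 in combinations(METHODS, 2):
        inter = shortlists[m1] & shortlists[m2]
        if {m1, m2} == {"fst", "lfmm"}:
            inter = set(sorted(inter, key=lambda l: (-ranks.get(l, 0), l))[:cap])
        out |= inter
    return out


class TestConsensusSets:
    def test_printed_pc2_structure_gives_seven(self):
        """46-member fst&lfmm capped to 5 plus 2 lfmm&bayenv = 7."""
        arl_lfmm = {f"s{i}" for i in range(46)}
        lfmm_bay = {"#51115", "#69292"}
        shortlists = {
            "fst": arl_lfmm | {f"fst_only{i}" for i in range(1102)},
            "bayscenv": set(),
            "bayenv": lfmm_bay | {f"bay_only{i}" for i in range(16)},
            "lfmm": arl_lfmm | lfmm_bay | {f"lf_only{i}" for i in range(860)},
        }
        ranks = {l: 5.0 - i * 0.01 for i, l in enumerate(sorted(arl_lfmm))}
        ranks.update({l: 3.0 for l in lfmm_bay})
        rep = consensus_sets({"PC2": shortlists}, {"PC2": ranks}, cap=5)
        assert len(rep.per_axis["PC2"]) == 7
        assert rep.capped_pair_sizes["PC2"] == 46
        assert lfmm_bay <= rep.per_axis["PC2"]

    def test_triple_membership_deduped_and_counted(self):
        shortlists = {
            "fst": {"x", "a"},
            "bayscenv": {"x"},
            "bayenv": {"x"},
            "lfmm": {"a"},
        }
        rep = consensus_sets({"PC1": shortlists}, {"PC1": {}}, cap=5)
        assert rep.per_axis["PC1"] == {"x", "a"}
        assert rep.venn_triples["PC1"][("fst", "bayscenv", "bayenv")] == 1

    def test_capped_out_locus_survives_via_other_pair(self):
        """A locus beyond the cap stays if another pair contributes it."""
        arl_lfmm = {f"s{i}" for i in range(10)}
        ranks = {f"s{i}": 10.0 - i for i in range(10)}  # s0..s4 survive cap
        shortlists = {
            "fst": arl_lfmm,
            "bayscenv": {"s9"},  # s9 is capped out of fst&lfmm but in bayscenv&fst
            "bayenv": set(),
            "lfmm": arl_lfmm,
        }
        rep = consensus_sets({"PC1": shortlists}, {"PC1": ranks}, cap=5)
        assert "s9" in rep.per_axis["PC1"]
        assert len(rep.per_axis["PC1"]) == 6

    def test_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(1)
        loci = [f"l{i}" for i in range(300)]
        for trial in range(10):
            shortlists = {
                m: set(rng.choice(loci, size=rng.integers(0, 80), replace=False))
                for m in METHODS
            }
            ranks = {l: float(rng.random()) for l in loci}
            rep = consensus_sets({"PC1": shortlists}, {"PC1": ranks}, cap=5)
            assert rep.per_axis["PC1"] == consensus_oracle(shortlists, ranks, 5)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        loci = [f"l{i}" for i in range(100)]
        shortlists = {m: set(rng.choice(loci, size=30, replace=False)) for m in METHODS}
        ranks = {l: float(rng.random()) for l in loci}
        rep1 = consensus_sets({"PC1": shortlists}, {"PC1": ranks})
        shuffled = {m: set(sorted(s, reverse=True)) for m, s in shortlists.items()}
        rep2 = consensus_sets({"PC1": shuffled}, {"PC1": ranks})
        assert rep1.per_axis == rep2.per_axis

    def test_venn_pair_counts_consistent(self):
        rng = np.random.default_rng(3)
        loci = [f"l{i}" for i in range(200)]
        shortlists = {m: set(rng.choice(loci, size=50, replace=False)) for m in METHODS}
        rep = consensus_sets({"PC1": shortlists}, {"PC1": {}})
        for (m1, m2), count in rep.venn_pairs["PC1"].items():
            assert count == len(shortlists[m1] & shortlists[m2])


class TestAlleleFreqClimateCorr:
    def test_proportional_r_one(self, default_sim):
        _, ds, truth = default_sim
        from provscan.scan_bayesenv import deme_frequencies

        freqs, provs = deme_frequencies(ds)
        j = 0
        clim = pd.Series(freqs[:, j] * 10 + 3, index=provs)
        res = allele_freq_climate_corr(ds, [ds.loci[j].id], clim)
        assert res.iloc[0]["r"] == pytest.approx(1.0)

    def test_planted_negative_cline_sign(self):
        cfg = SimConfig(env_effect_b=-2.5, seed=71)
        ds, truth = simulate_genotypes(cfg)
        clim = pd.Series(truth.deme_env, index=[f"P{d:02d}" for d in range(16)])
        res = allele_freq_climate_corr(ds, truth.adaptive_ids(ds), clim)
        assert (res["r"] < 0).mean() > 0.9

    def test_neutral_mean_near_zero(self, neutral_sim):
        _, ds, truth = neutral_sim
        clim = pd.Series(truth.deme_env, index=[f"P{d:02d}" for d in range(16)])
        res = allele_freq_climate_corr(ds, ds.locus_ids()[:500], clim)
        assert abs(res["r"].mean()) < 0.1

    def test_monomorphic_flagged(self, tiny_ds):
        ds = tiny_ds
        # make a 5-provenance dataset with a monomorphic locus
        cfg = SimConfig(seed=72)
        ds, truth = simulate_genotypes(cfg)
        ds.dosage[:, 0] = 0
        clim = pd.Series(truth.deme_env, index=[f"P{d:02d}" for d in range(16)])
        res = allele_freq_climate_corr(ds, [ds.loci[0].id], clim)
        assert res.iloc[0]["monomorphic"]


class TestEigenDiscrimination:
    def test_perfect_separation(self):
        """Two fully diverged clusters + diagnostic loci -> eta^2 ~ 1."""
        rng = np.random.default_rng(4)
        n_per, L = 30, 20
        top = np.vstack(
            [
                rng.binomial(2, 0.02, size=(n_per, L)),
                rng.binomial(2, 0.98, size=(n_per, L)),
            ]
        )
        neutral = rng.binomial(2, 0.5, size=(2 * n_per, 200))
        from provscan.core_io import GenotypeDataset, LocusInfo

        dosage = np.hstack([top, neutral]).astype(np.int16)
        loci = [LocusInfo(f"l{j}", "s", j + 1, "A", "C") for j in range(L + 200)]
        samples = [f"g{i // n_per}_{i}" for i in range(2 * n_per)]
        ds = GenotypeDataset(samples, loci, dosage, {s: s.split("_")[0] for s in samples})
        groups = np.array([0] * n_per + [1] * n_per)
        res = eigen_discrimination(ds, [f"l{j}" for j in range(L)], groups, seed=0)
        assert res.eta2_consensus > 0.95
        assert res.eta2_random < 0.3

    def test_random_set_null_level(self):
        """Under panmixia eta^2 of a random set matches the permutation null."""
        rng = np.random.default_rng(5)
        cfg = SimConfig(
            n_groups=1, demes_per_group=4, samples_per_deme=20, n_neutral_loci=400,
            n_adaptive_loci=0, F_CT=0.0, F_SC=0.0, seed=73,
        )
        ds, _ = simulate_genotypes(cfg)
        groups = np.repeat([0, 1], 40)
        res = eigen_discrimination(ds, ds.locus_ids()[:18], groups, seed=1)
        # permutation null for eta^2 on EV1
        ev1 = res.random_scores[:, 0]
        null = [eta_squared(ev1, rng.permutation(groups)) for _ in range(500)]
        assert res.eta2_random < np.quantile(null, 0.999)

    def test_seeded_random_set_reproducible(self, default_sim):
        _, ds, truth = default_sim
        groups = truth.group_of_deme[truth.deme_of_sample]
        cons = truth.adaptive_ids(ds)
        r1 = eigen_discrimination(ds, cons, groups, seed=7)
        r2 = eigen_discrimination(ds, cons, groups, seed=7)
        assert r1.random_ids == r2.random_ids

    def test_consensus_beats_random_env_aligned_structure(self):
        """When the two ancestry clusters track the environmental gradient
        (coastal/inland style), planted adaptive loci separate the clusters
        better than random neutral loci."""
        cfg = SimConfig(env_structure_corr=0.9, seed=504)
        ds, truth = simulate_genotypes(cfg)
        groups = truth.group_of_deme[truth.deme_of_sample]
        res = eigen_discrimination(ds, truth.adaptive_ids(ds), groups, seed=2)
        assert res.eta2_consensus > res.eta2_random

    def test_needs_two_loci(self, default_sim):
        _, ds, truth = default_sim
        with pytest.raises(ValueError):
            eigen_discrimination(ds, [ds.loci[0].id], np.zeros(ds.n_samples), seed=0)
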