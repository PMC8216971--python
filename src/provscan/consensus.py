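"""Method shortlists, consensus-outlier identification and interrogation.

Consensus loci are those found by at least two of the four scan methods per
environmental axis, with the (typically large) FST-scan x LFMM intersection
capped at its top five members ranked by LFMM -log10 p. Interrogation
correlates consensus-locus allele frequencies with provenance climate and
compares eigenvector discrimination against random neutral SNP sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from provscan.core_io import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

METHODS = ("fst", "bayscenv", "bayenv", "lfmm")


@dataclass
class Thresholds:
    """Shortlist decision rules per method (defaults as in the analysis)."""

    neglog_quantile_min: float = 1.3  # FST scan: -log10(1 - FST quantile)
    neglog_q_min: float = 1.3  # F-model scan: -log10(q)
    bf_min: float = 30.0  # covariance scan: Bayes factor
    rho_min: float = 0.4  # covariance scan: |rho|
    neglog_p_min: float = 1.3  # LFMM: -log10(p)


def build_shortlists(
    fst_calls: pd.DataFrame,
    fmodel: pd.DataFrame,
    bayenv: pd.DataFrame,
    lfmm: pd.DataFrame,
    axis: str,
    thresholds: Thresholds | None = None,
) -> dict[str, set[str]]:
    """Apply the per-method decision rules; returns method -> locus-id set.

    The FST scan is environment-blind, so its shortlist is shared by every
    axis; the other three tables are filtered to ``axis``. All four scans
    must cover the same locus set (the FST scan may lack loci that are
    monomorphic/untestable).
    """
    th = thresholds or Thresholds()
    fm = fmodel[fmodel["axis"] == axis]
    be = bayenv[bayenv["axis"] == axis]
    lf = lfmm[lfmm["axis"] == axis]
    base = set(lf["locus"])
    if not (set(fm["locus"]) == base and set(be["locus"]) == base):
        raise ValueError("scan outputs cover different locus sets")
    if not set(fst_calls["locus"]) <= base:
        raise ValueError("FST scan loci not a subset of the common locus set")

    return {
        "fst": set(fst_calls.loc[fst_calls["neglog_quantile"] > th.neglog_quantile_min, "locus"]),
        "bayscenv": set(fm.loc[-np.log10(fm["q"].clip(lower=1e-300)) > th.neglog_q_min, "locus"]),
        "bayenv": set(
            be.loc[(be["bf"] > th.bf_min) & (be["rho"].abs() > th.rho_min), "locus"]
        ),
        "lfmm": set(
            lf.loc[-np.log10(lf["p_cal"].clip(lower=1e-300)) > th.neglog_p_min, "locus"]
        ),
    }


@dataclass
class ConsensusReport:
    """Per-axis consensus sets with the full pairwise/triple Venn structure."""

    per_axis: dict[str, set[str]] = field(default_factory=dict)
    venn_pairs: dict[str, dict[tuple[str, str], int]] = field(default_factory=dict)
    venn_triples: dict[str, dict[tuple[str, str, str], int]] = field(default_factory=dict)
    shortlist_sizes: dict[str, dict[str, int]] = field(default_factory=dict)
    capped_pair_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> set[str]:
        out: set[str] = set()
        for s in self.per_axis.values():
            out |= s
        return out


def consensus_sets(
    shortlists_by_axis: dict[str, dict[str, set[str]]],
    lfmm_neglog_p: dict[str, dict[str, float]],
    cap: int = 5,
    capped_pair: tuple[str, str] = ("fst", "lfmm"),
) -> ConsensusReport:
    """Union of pairwise shortlist intersections, with one capped pair.

    Per axis, every pairwise intersection contributes whole except
    ``capped_pair`` (by default FST-scan x LFMM), which is replaced by its
    top ``cap`` members under the LFMM -log10 p ranking (ties broken by locus
    id). A locus capped out of that pair still enters the consensus if it
    belongs to another contributing intersection. Duplicates count once.
    """
    report = ConsensusReport()
    for axis, shortlists in shortlists_by_axis.items():
        ranks = lfmm_neglog_p.get(axis, {})
        consensus: set[str] = set()
        pair_counts: dict[tuple[str, str], int] = {}
        for m1, m2 in combinations(METHODS, 2):
            inter = shortlists[m1] & shortlists[m2]
            pair_counts[(m1, m2)] = len(inter)
            if {m1, m2} == set(capped_pair):
                top = sorted(inter, key=lambda l: (-ranks.get(l, 0.0), l))[:cap]
                report.capped_pair_sizes[axis] = len(inter)
                consensus |= set(top)
            else:
                consensus |= inter
        triple_counts = {
            trio: len(shortlists[trio[0]] & shortlists[trio[1]] & shortlists[trio[2]])
            for trio in combinations(METHODS, 3)
        }
        report.per_axis[axis] = consensus
        report.venn_pairs[axis] = pair_counts
        report.venn_triples[axis] = triple_counts
        report.shortlist_sizes[axis] = {m: len(s) for m, s in shortlists.items()}
    return report


# ----------------------------------------------------------- interrogation


def allele_freq_climate_corr(
    ds: GenotypeDataset, locus_ids: list[str], climate_values: pd.Series
) -> pd.DataFrame:
    """Pearson r (and p) of per-provenance alt-allele frequency vs climate.

    ``climate_values`` is indexed by provenance id. Monomorphic loci get
    NaN r and a flag.
    """
    from provscan.scan_bayesenv import deme_frequencies

    provs = ds.provenances
    if len(provs) < 5:
        raise ValueError("need >= 5 provenances")
    clim = climate_values.loc[provs].to_numpy(float)
    freqs, _ = deme_frequencies(ds)
    pos = {l.id: j for j, l in enumerate(ds.loci)}
    rows = []
    for lid in locus_ids:
        f = freqs[:, pos[lid]]
        ok = ~np.isnan(f)
        if f[ok].std() == 0 or ok.sum() < 3:
            rows.append({"locus": lid, "r": np.nan, "p": np.nan, "monomorphic": True})
            continue
        res = stats.pearsonr(f[ok], clim[ok])
        rows.append(
            {"locus": lid, "r": float(res.statistic), "p": float(res.pvalue), "monomorphic": False}
        )
    return pd.DataFrame(rows)


def _genotype_pca_scores(ds: GenotypeDataset, locus_idx: np.ndarray, n_ev: int = 2) -> np.ndarray:
    """Eigenvector scores on a locus subset (center 2p, scale sqrt(2p(1-p)))."""
    X = ds.dosage[:, locus_idx].astype(float)
    X[X == MISSING] = np.nan
    p = np.nanmean(X, axis=0) / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    denom[denom == 0] = 1.0
    Z = (np.where(np.isnan(X), 2.0 * p, X) - 2.0 * p) / denom
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    k = min(n_ev, s.size)
    return U[:, :k] * s[:k]


def eta_squared(values: np.ndarray, groups: np.ndarray) -> float:
    """Between-group sum of squares / total sum of squares of ``values``."""
    total = ((values - values.mean()) ** 2).sum()
    if total == 0:
        return 0.0
    between = sum(
        (values[groups == g].size) * (values[groups == g].mean() - values.mean()) ** 2
        for g in np.unique(groups)
    )
    return float(between / total)


@dataclass
class EigenDiscrimination:
    consensus_scores: np.ndarray  # samples x 2 (EV1, EV2)
    random_scores: np.ndarray
    eta2_consensus: float
    eta2_random: float
    random_ids: list[str]


def eigen_discrimination(
    ds: GenotypeDataset,
    consensus_ids: list[str],
    group_labels: np.ndarray,
    neutral_pool: list[str] | None = None,
    seed: int = 0,
) -> EigenDiscrimination:
    """Compare EV1 group separation of consensus loci vs random neutral loci.

    The separation score is eta-squared of a two-group labeling on EV1. The
    random set (same size as the consensus set) is drawn seeded from
    ``neutral_pool`` (default: all non-consensus loci).
    """
    if len(consensus_ids) < 2:
        raise ValueError("need >= 2 consensus loci")
    pos = {l.id: j for j, l in enumerate(ds.loci)}
    cons_idx = np.array([pos[l] for l in consensus_ids])
    pool = neutral_pool if neutral_pool is not None else [
        l.id for l in ds.loci if l.id not in set(consensus_ids)
    ]
    if len(pool) < len(consensus_ids):
        raise ValueError("fewer neutral loci than consensus loci")
    rng = np.random.default_rng(seed)
    random_ids = [pool[i] for i in rng.choice(len(pool), size=len(consensus_ids), replace=False)]
    rand_idx = np.array([pos[l] for l in random_ids])

    cs = _genotype_pca_scores(ds, cons_idx)
    rs = _genotype_pca_scores(ds, rand_idx)
    groups = np.asarray(group_labels)
    return EigenDiscrimination(
        consensus_scores=cs,
        random_scores=rs,
        eta2_consensus=eta_squared(cs[:, 0], groups),
        eta2_random=eta_squared(rs[:, 0], groups),
        random_ids=random_ids,
    )
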