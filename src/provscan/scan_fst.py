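"""FST outlier scan against a simulated hierarchical-island null.

Per-locus Weir-Cockerham (1984) theta estimates are compared with the joint
(heterozygosity, FST) distribution of loci simulated under a hierarchical
Balding-Nichols island model calibrated so its median global FST matches the
observed one. A locus is an outlier when its FST exceeds the upper 5% of the
null within its heterozygosity bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from provscan.core_io import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class FstResult:
    """Per-locus Weir-Cockerham estimates plus the ratio-of-sums global FST."""

    locus_ids: list[str]
    fst: np.ndarray  # per-locus theta; NaN where undefined (monomorphic)
    het: np.ndarray  # expected heterozygosity 2p(1-p) from the pooled frequency
    a: np.ndarray  # among-population variance component
    abc: np.ndarray  # total variance component per locus
    global_fst: float  # sum(a) / sum(a+b+c)


class CalibrationError(RuntimeError):
    """Raised when the null-model differentiation cannot be bracketed."""


@dataclass
class NullModelConfig:
    """Hierarchical-island null settings (defaults echo the reference run)."""

    n_groups: int = 10
    demes_per_group: int = 100
    n_simulated_loci: int = 200_000
    het_bins: int = 50
    calibration_tolerance: float = 0.002
    calibration_loci: int = 400
    calibration_batches: int = 5
    fct_share: float = 0.5  # share of total differentiation placed between groups
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_groups, self.demes_per_group, self.n_simulated_loci, self.het_bins) < 1:
            raise ValueError("null-model counts must be positive")
        if self.calibration_tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class OutlierCall:
    """Quantile-based outlier significance for each testable locus."""

    table: pd.DataFrame  # columns: locus, het, fst, p, neglog_quantile, outlier, bonferroni

    def __post_init__(self) -> None:
        p = self.table["p"].to_numpy(float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p-values outside (0, 1]")


# ------------------------------------------------------------ WC estimation


def _pop_stats(ds: GenotypeDataset, labels: np.ndarray):
    """Per population x locus called counts, allele freqs and het fractions."""
    pops = np.unique(labels)
    P, L = pops.size, ds.n_loci
    n = np.zeros((P, L))
    p = np.zeros((P, L))
    h = np.zeros((P, L))
    d = ds.dosage
    for k, pop in enumerate(pops):
        rows = d[labels == pop]
        obs = rows != MISSING
        n[k] = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(obs, rows, 0).sum(axis=0) / (2.0 * n[k])
            h[k] = ((rows == 1).sum(axis=0)) / n[k]
    return pops, n, p, h


def wc_fst_from_counts(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham variance components from per-pop arrays (pops x loci).

    Returns (a, b, c) per locus. Populations with no called genotypes at a
    locus are excluded from that locus's estimate.
    """
    valid = n > 0
    r = valid.sum(axis=0).astype(float)
    n_eff = np.where(valid, n, 0.0)
    nbar = n_eff.sum(axis=0) / r
    sum_n2 = (n_eff**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - sum_n2 / (r * nbar)) / (r - 1.0)
        pbar = (n_eff * np.where(valid, p, 0.0)).sum(axis=0) / (r * nbar)
        s2 = (n_eff * np.where(valid, (p - pbar) ** 2, 0.0)).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_eff * np.where(valid, h, 0.0)).sum(axis=0) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
    return a, b, c


def wc_fst(ds: GenotypeDataset, labels: np.ndarray | None = None) -> FstResult:
    """Per-locus Weir-Cockerham theta and the ratio-of-sums global FST.

    ``labels`` defaults to the dataset's provenance labels. Monomorphic loci
    get FST = NaN and are excluded from the global estimator and from outlier
    testing.
    """
    if labels is None:
        labels = ds.provenance_labels()
    labels = np.asarray(labels)
    pops, counts = np.unique(labels, return_counts=True)
    if pops.size < 2:
        raise ValueError("need >= 2 populations")
    if np.any(counts < 2):
        raise ValueError("every population needs >= 2 samples")

    _, n, p, h = _pop_stats(ds, labels)
    a, b, c = wc_fst_from_counts(n, p, h)
    abc = a + b + c

    n_tot = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar_all = (n * p).sum(axis=0) / n_tot
    het = 2.0 * pbar_all * (1.0 - pbar_all)
    poly = (pbar_all > 0) & (pbar_all < 1) & (abc != 0)

    fst = np.full(ds.n_loci, np.nan)
    fst[poly] = a[poly] / abc[poly]
    with np.errstate(invalid="ignore"):
        global_fst = float(np.nansum(a[poly]) / np.nansum(abc[poly]))
    return FstResult(ds.locus_ids(), fst, het, a, abc, global_fst)


# ------------------------------------------------------- group inference


def infer_groups(
    ds: GenotypeDataset, neutral_ids: list[str], k: int, seed: int = 0
) -> dict[str, int]:
    """Assign each provenance to one of ``k`` groups for the hierarchical null.

    Samples are clustered by k-means on the first two eigenvectors of the
    neutral-subset genotype PCA; each provenance takes the majority cluster of
    its samples.
    """
    from sklearn.cluster import KMeans

    idset = set(neutral_ids)
    idx = [j for j, l in enumerate(ds.loci) if l.id in idset]
    X = ds.dosage[:, idx].astype(float)
    X[X == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu, X) - mu
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :2] * s[:2]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(scores)

    labels = ds.provenance_labels()
    groups: dict[str, int] = {}
    for prov in ds.provenances:
        members = km.labels_[labels == prov]
        groups[prov] = int(np.bincount(members).argmax())
    return groups


# ------------------------------------------------------------- null model


def _simulate_batch(
    rng: np.random.Generator,
    n_loci: int,
    deme_sizes: np.ndarray,
    deme_group: np.ndarray,
    F_CT: float,
    F_SC: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate (het, fst, a, abc) for ``n_loci`` hierarchical BN loci."""
    D = deme_sizes.size
    groups = np.unique(deme_group)
    p_anc = rng.uniform(0.01, 0.99, size=n_loci)

    def bn(p: np.ndarray, F: float) -> np.ndarray:
        if F <= 0:
            return p.copy()
        p = np.clip(p, 1e-6, 1 - 1e-6)
        return rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)

    p_group = {g: bn(p_anc, F_CT) for g in groups}
    n = np.repeat(deme_sizes[:, None], n_loci, axis=1).astype(float)
    p = np.empty((D, n_loci))
    h = np.empty((D, n_loci))
    for d in range(D):
        pd_ = np.clip(bn(p_group[deme_group[d]], F_SC), 1e-9, 1 - 1e-9)
        geno = rng.binomial(2, np.repeat(pd_[None, :], deme_sizes[d], axis=0))
        p[d] = geno.sum(axis=0) / (2.0 * deme_sizes[d])
        h[d] = (geno == 1).sum(axis=0) / deme_sizes[d]

    a, b, c = wc_fst_from_counts(n, p, h)
    abc = a + b + c
    n_tot = n.sum(axis=0)
    pbar = (n * p).sum(axis=0) / n_tot
    het = 2.0 * pbar * (1.0 - pbar)
    poly = (pbar > 0) & (pbar < 1) & (abc != 0)
    fst = np.full(n_loci, np.nan)
    fst[poly] = a[poly] / abc[poly]
    return het[poly], fst[poly], a[poly], abc[poly]


def simulate_null(
    cfg: NullModelConfig,
    deme_sizes: np.ndarray,
    deme_group: np.ndarray,
    target_fst: float,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Simulate the null (het, FST) joint distribution at the observed layout.

    Total differentiation is parameterized by one proportionality scale t with
    F_CT = fct_share * t and F_SC = (1 - fct_share) * t, calibrated by
    bisection until the median simulated global FST is within
    ``calibration_tolerance`` of ``target_fst``. Returns (het, fst, (F_CT,
    F_SC)). Only the sampled demes are simulated; unsampled demes of the
    configured hierarchy are marginal under the Balding-Nichols draw and do
    not affect sampled genotypes.
    """
    deme_sizes = np.asarray(deme_sizes, int)
    deme_group = np.asarray(deme_group)
    if deme_sizes.size != deme_group.size:
        raise ValueError("deme_sizes and deme_group length mismatch")

    def median_global(t: float) -> float:
        F_CT, F_SC = cfg.fct_share * t, (1 - cfg.fct_share) * t
        vals = []
        for b in range(cfg.calibration_batches):
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11, b]))
            _, _, a, abc = _simulate_batch(
                rng, cfg.calibration_loci, deme_sizes, deme_group, F_CT, F_SC
            )
            vals.append(a.sum() / abc.sum())
        return float(np.median(vals))

    if target_fst <= cfg.calibration_tolerance:
        t_star = 1e-6
    else:
        lo, hi = 1e-6, 0.95
        if median_global(hi) < target_fst:
            raise CalibrationError(
                f"target FST {target_fst:.4f} above reachable range (hi={median_global(hi):.4f})"
            )
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if median_global(mid) < target_fst:
                lo = mid
            else:
                hi = mid
            if abs(median_global(mid) - target_fst) <= cfg.calibration_tolerance:
                break
        t_star = 0.5 * (lo + hi)
    F_CT, F_SC = cfg.fct_share * t_star, (1 - cfg.fct_share) * t_star
    logger.info("simulate_null: calibrated F_CT=%.4f F_SC=%.4f", F_CT, F_SC)

    hets, fsts = [], []
    batch = 20_000
    done = 0
    b = 0
    while done < cfg.n_simulated_loci:
        m = min(batch, cfg.n_simulated_loci - done)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23, b]))
        het, fst, _, _ = _simulate_batch(rng, m, deme_sizes, deme_group, F_CT, F_SC)
        hets.append(het)
        fsts.append(fst)
        done += m
        b += 1
    return np.concatenate(hets), np.concatenate(fsts), (F_CT, F_SC)


def observed_layout(ds: GenotypeDataset, groups: dict[str, int] | None = None):
    """(deme sizes, deme group labels) from the dataset's provenances."""
    labels = ds.provenance_labels()
    provs = ds.provenances
    sizes = np.array([(labels == p).sum() for p in provs])
    if groups is None:
        grp = np.zeros(len(provs), dtype=int)
    else:
        grp = np.array([groups[p] for p in provs])
    return sizes, grp


# ------------------------------------------------------------ outlier calls


def outlier_pvalues(
    observed: FstResult,
    null_het: np.ndarray,
    null_fst: np.ndarray,
    cfg: NullModelConfig,
    alpha: float = 0.05,
) -> OutlierCall:
    """Heterozygosity-binned empirical upper-tail p-values per locus.

    Null pairs are split into ``het_bins`` equal-count heterozygosity bins;
    p = (1 + #{null FST >= observed}) / (1 + bin size) within the locus's
    bin. Loci with heterozygosity outside the simulated range use the nearest
    bin (flagged). The Bonferroni flag uses alpha / n_tested.
    """
    if null_fst.size < 1000:
        raise ValueError("need >= 1000 null pairs")
    order = np.argsort(null_het)
    nh, nf = null_het[order], null_fst[order]
    edges_idx = np.linspace(0, nh.size, cfg.het_bins + 1).astype(int)
    bins = [np.sort(nf[edges_idx[i] : edges_idx[i + 1]]) for i in range(cfg.het_bins)]
    # Bin boundaries on the het scale for locus lookup.
    inner = nh[np.clip(edges_idx[1:-1], 0, nh.size - 1)]

    testable = ~np.isnan(observed.fst)
    n_tested = int(testable.sum())
    bonf_alpha = alpha / max(n_tested, 1)

    rows = []
    for j in np.flatnonzero(testable):
        het, fst = observed.het[j], observed.fst[j]
        b = int(np.searchsorted(inner, het, side="right"))
        flagged = het < nh[0] or het > nh[-1]
        binned = bins[b]
        n_ge = binned.size - np.searchsorted(binned, fst, side="left")
        p = (1.0 + n_ge) / (1.0 + binned.size)
        quantile = 1.0 - p
        rows.append(
            {
                "locus": observed.locus_ids[j],
                "het": het,
                "fst": fst,
                "p": p,
                "neglog_quantile": -np.log10(p),
                "outlier": p < alpha,
                "bonferroni": p < bonf_alpha,
                "het_out_of_range": flagged,
            }
        )
    return OutlierCall(pd.DataFrame(rows))
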