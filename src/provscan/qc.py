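"""Restrictive SNP/sample filter cascade and the neutral SNP subset.

Fixed cascade order: site filters (MAF, call rate) -> Hardy-Weinberg exact
test -> LD pruning -> sample filters (kinship, heterozygosity deficit, sample
call rate). The :class:`QcReport` telescopes: retained_in - removed =
retained_out at every stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from provscan.core_io import MISSING, EmptyDatasetError, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class QcConfig:
    """Thresholds of the filter cascade (defaults as used in the analysis)."""

    maf_min: float = 0.05
    site_callrate_min: float = 0.95
    hwe_alpha: float = 1e-6
    ld_r_max: float = 0.2
    ld_window: int = 50
    kinship_max: float = 0.25
    het_deficit_max: float = 0.1
    sample_callrate_min: float = 0.95
    neutral_subset_size: int = 1500
    kinship_is_pihat: bool = False  # alternative convention: compare pi-hat itself
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "maf_min",
            "site_callrate_min",
            "hwe_alpha",
            "ld_r_max",
            "kinship_max",
            "het_deficit_max",
            "sample_callrate_min",
        ):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class QcStage:
    name: str
    kind: str  # "loci" | "samples"
    n_in: int
    n_removed: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclass
class QcReport:
    """Per-stage removal counts, in cascade order."""

    stages: list[QcStage] = field(default_factory=list)

    def add(self, name: str, kind: str, n_in: int, n_removed: int) -> None:
        self.stages.append(QcStage(name, kind, n_in, n_removed))

    def validate_telescoping(self) -> None:
        for kind in ("loci", "samples"):
            chain = [s for s in self.stages if s.kind == kind]
            for a, b in zip(chain, chain[1:]):
                if a.n_out != b.n_in:
                    raise ValueError(
                        f"QcReport does not telescope at {b.name}: {a.n_out} != {b.n_in}"
                    )

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "stage": s.name,
                    "kind": s.kind,
                    "in": s.n_in,
                    "removed": s.n_removed,
                    "retained": s.n_out,
                }
                for s in self.stages
            ],
            indent=2,
        )

    def __str__(self) -> str:
        lines = ["QC cascade:"]
        for s in self.stages:
            lines.append(
                f"  {s.name:<22} {s.kind:<8} in={s.n_in:>7} removed={s.n_removed:>6} retained={s.n_out:>7}"
            )
        return "\n".join(lines)


# ------------------------------------------------------------- site filters


def site_filters(
    ds: GenotypeDataset, cfg: QcConfig, report: QcReport | None = None
) -> tuple[GenotypeDataset, QcReport]:
    """Remove loci with MAF < maf_min or site call rate < site_callrate_min."""
    if ds.n_loci == 0:
        raise EmptyDatasetError("empty dataset")
    report = report if report is not None else QcReport()
    maf = ds.maf()
    cr = ds.site_call_rate()
    keep = (maf >= cfg.maf_min) & (cr >= cfg.site_callrate_min) & ~np.isnan(maf)
    n_removed = int((~keep).sum())
    report.add("maf_callrate", "loci", ds.n_loci, n_removed)
    if not keep.any():
        raise EmptyDatasetError("site filters removed all loci")
    return ds.subset_loci(np.flatnonzero(keep)), report


# --------------------------------------------------------------- HWE exact


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact (Levene/Haldane) two-sided Hardy-Weinberg test.

    Sums, conditional on the allele counts, the probabilities of all
    heterozygote counts whose probability does not exceed that of the observed
    count. Monomorphic loci return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("empty sample")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0

    rare = min(n_A, n_a)
    # Possible heterozygote counts share the parity of the rare allele count.
    hets = np.arange(rare % 2, rare + 1, 2)
    n_hom_rare = (rare - hets) // 2
    n_hom_common = n - hets - n_hom_rare
    # log P(h | n, n_A) up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln(n_hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(n_hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_Aa]
    if obs.size != 1:  # pragma: no cover - inconsistent counts
        raise ValueError("observed heterozygote count impossible given allele counts")
    # 1e-12 relative slack keeps ties included despite float rounding.
    return float(min(1.0, probs[probs <= obs[0] * (1 + 1e-12)].sum()))


def hwe_filter(
    ds: GenotypeDataset, cfg: QcConfig, report: QcReport | None = None
) -> tuple[GenotypeDataset, QcReport]:
    """Remove loci deviating from Hardy-Weinberg at ``hwe_alpha``."""
    report = report if report is not None else QcReport()
    pvals = np.empty(ds.n_loci)
    d = ds.dosage
    for j in range(ds.n_loci):
        col = d[:, j]
        obs = col != MISSING
        pvals[j] = hwe_exact_test(
            int((col[obs] == 0).sum()), int((col[obs] == 1).sum()), int((col[obs] == 2).sum())
        )
    keep = pvals >= cfg.hwe_alpha
    report.add("hwe", "loci", ds.n_loci, int((~keep).sum()))
    if not keep.any():
        raise EmptyDatasetError("HWE filter removed all loci")
    return ds.subset_loci(np.flatnonzero(keep)), report


# ---------------------------------------------------------------- LD pruning


def _pairwise_r(a: np.ndarray, b: np.ndarray) -> float:
    """Dosage Pearson correlation over pairwise-complete observations."""
    obs = (a != MISSING) & (b != MISSING)
    if obs.sum() < 3:
        return 0.0
    x = a[obs].astype(float)
    y = b[obs].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def ld_prune(ds: GenotypeDataset, cfg: QcConfig) -> list[str]:
    """Greedy windowed LD pruning; returns retained locus ids.

    Loci are scanned per scaffold in position order; a locus is dropped if its
    composite genotype correlation |r| with any retained locus within the
    trailing window of ``ld_window`` loci exceeds ``ld_r_max``. Deterministic
    given locus order.
    """
    order = sorted(
        range(ds.n_loci), key=lambda j: (ds.loci[j].scaffold, ds.loci[j].position)
    )
    retained: list[int] = []
    window: list[int] = []  # retained loci on the current scaffold
    current_scaffold = None
    for j in order:
        scaf = ds.loci[j].scaffold
        if scaf != current_scaffold:
            current_scaffold = scaf
            window = []
        recent = window[-cfg.ld_window :]
        if any(
            abs(_pairwise_r(ds.dosage[:, j], ds.dosage[:, k])) > cfg.ld_r_max
            for k in recent
        ):
            continue
        retained.append(j)
        window.append(j)
    retained_set = set(retained)
    return [l.id for j, l in enumerate(ds.loci) if j in retained_set]


def ld_prune_filter(
    ds: GenotypeDataset, cfg: QcConfig, report: QcReport | None = None
) -> tuple[GenotypeDataset, QcReport]:
    report = report if report is not None else QcReport()
    keep_ids = set(ld_prune(ds, cfg))
    idx = [j for j, l in enumerate(ds.loci) if l.id in keep_ids]
    report.add("ld_prune", "loci", ds.n_loci, ds.n_loci - len(idx))
    return ds.subset_loci(idx), report


# ------------------------------------------------------------------- kinship


def ibd_kinship(ds: GenotypeDataset, min_overlap: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """PLINK-style method-of-moments IBD kinship matrix.

    For each sample pair, observed identity-by-state counts are combined with
    their allele-frequency expectations under IBD states 0/1/2 to solve for
    P(IBD=0,1,2), bounded to the simplex; kinship phi = pihat/2 with
    pihat = P1/2 + P2. The diagonal is 0.5 by convention.

    Returns ``(phi, unreliable)`` where ``unreliable`` flags pairs with fewer
    than ``min_overlap`` overlapping genotypes.
    """
    d = ds.dosage
    n = ds.n_samples
    p = ds.alt_freq()
    q = 1.0 - p
    ok_locus = ~np.isnan(p)
    d = d[:, ok_locus]
    p, q = p[ok_locus], q[ok_locus]

    obs = (d != MISSING).astype(float)
    is0 = ((d == 0) & (d != MISSING)).astype(float)
    is1 = (d == 1).astype(float)
    is2 = (d == 2).astype(float)

    # Observed IBS counts per pair via one-hot products: IBS = 2 - |d1 - d2|.
    ibs0 = is0 @ is2.T + is2 @ is0.T
    ibs1 = is0 @ is1.T + is1 @ is0.T + is1 @ is2.T + is2 @ is1.T
    n_obs = obs @ obs.T
    ibs2 = n_obs - ibs0 - ibs1

    # Per-locus IBS probabilities conditional on IBD state.
    w_ibs0_ibd0 = 2 * p**2 * q**2
    w_ibs1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    w_ibs2_ibd0 = p**4 + q**4 + 4 * p**2 * q**2
    w_ibs1_ibd1 = 2 * p**2 * q + 2 * p * q**2
    w_ibs2_ibd1 = p**3 + q**3 + p**2 * q + p * q**2

    # Pair-specific expectations restricted to the pair's observed loci.
    def pair_sum(w: np.ndarray) -> np.ndarray:
        ow = obs * w  # n x L
        return ow @ obs.T

    e00 = pair_sum(w_ibs0_ibd0)
    e10 = pair_sum(w_ibs1_ibd0)
    e20 = pair_sum(w_ibs2_ibd0)
    e11 = pair_sum(w_ibs1_ibd1)
    e21 = pair_sum(w_ibs2_ibd1)

    with np.errstate(divide="ignore", invalid="ignore"):
        P0 = np.where(e00 > 0, ibs0 / e00, 0.0)
        P1 = np.where(e11 > 0, (ibs1 - P0 * e10) / e11, 0.0)
        P2 = np.where(n_obs > 0, (ibs2 - P0 * e20 - P1 * e21) / n_obs, 0.0)

    # Bound (P0, P1, P2) to the simplex.
    P0 = np.clip(P0, 0.0, 1.0)
    P1 = np.clip(P1, 0.0, 1.0)
    P2 = np.clip(P2, 0.0, 1.0)
    total = P0 + P1 + P2
    total[total == 0] = 1.0
    P0, P1, P2 = P0 / total, P1 / total, P2 / total

    pihat = P1 / 2.0 + P2
    phi = pihat / 2.0
    np.fill_diagonal(phi, 0.5)
    unreliable = n_obs < min_overlap
    np.fill_diagonal(unreliable, False)
    return phi, unreliable


# ---------------------------------------------------------- sample filtering


def het_deficit(ds: GenotypeDataset) -> np.ndarray:
    """Per-sample inbreeding-like statistic F = 1 - Het_obs / Het_exp.

    Expected heterozygosity per sample is the mean of 2p(1-p) over its
    non-missing loci, with p the dataset-wide alternative-allele frequency.
    """
    p = ds.alt_freq()
    hexp_locus = 2.0 * p * (1.0 - p)
    obs = ds.observed_mask()
    het = ds.dosage == 1
    with np.errstate(invalid="ignore", divide="ignore"):
        hobs = np.where(obs.sum(1) > 0, (het & obs).sum(1) / obs.sum(1), np.nan)
        hexp = (obs * hexp_locus).sum(1) / obs.sum(1)
        return 1.0 - hobs / hexp


def sample_filters(
    ds: GenotypeDataset,
    cfg: QcConfig,
    kinship: np.ndarray,
    report: QcReport | None = None,
) -> tuple[GenotypeDataset, QcReport]:
    """Remove samples failing call rate, heterozygote-deficit or kinship rules.

    For each pair with phi >= kinship_max the lower-call-rate member is
    removed (tie: the later sample id). Removal is iterative so that a sample
    related only to an already-removed one is kept.
    """
    report = report if report is not None else QcReport()
    n_in = ds.n_samples
    cr = ds.sample_call_rate()
    F = het_deficit(ds)

    removed = np.zeros(n_in, dtype=bool)
    removed |= cr < cfg.sample_callrate_min
    removed |= F > cfg.het_deficit_max

    score = kinship * 2.0 if cfg.kinship_is_pihat else kinship
    pairs = np.argwhere(np.triu(score >= cfg.kinship_max, k=1))
    # Worst pairs first, so the most related offender is resolved first.
    pairs = sorted(map(tuple, pairs), key=lambda ij: -score[ij[0], ij[1]])
    for i, j in pairs:
        if removed[i] or removed[j]:
            continue
        if cr[i] < cr[j]:
            victim = i
        elif cr[j] < cr[i]:
            victim = j
        else:
            victim = i if ds.samples[i] > ds.samples[j] else j
        removed[victim] = True

    keep = np.flatnonzero(~removed)
    report.add("sample_filters", "samples", n_in, int(removed.sum()))
    if keep.size == 0:
        raise EmptyDatasetError("sample filters removed all samples")
    return ds.subset_samples(keep), report


# ------------------------------------------------------------ neutral subset


def neutral_subset(ds: GenotypeDataset, cfg: QcConfig) -> list[str]:
    """Uniform random subset of loci (without replacement), seeded."""
    rng = np.random.default_rng(cfg.seed)
    ids = ds.locus_ids()
    k = min(cfg.neutral_subset_size, len(ids))
    if k < cfg.neutral_subset_size:
        logger.warning(
            "neutral_subset: only %d loci available (< %d requested)",
            len(ids),
            cfg.neutral_subset_size,
        )
    chosen = rng.choice(len(ids), size=k, replace=False)
    return [ids[i] for i in sorted(chosen)]


# ----------------------------------------------------------------- cascade


def run_qc(
    ds: GenotypeDataset, cfg: QcConfig
) -> tuple[GenotypeDataset, list[str], QcReport, np.ndarray]:
    """Run the full cascade; returns (filtered ds, neutral ids, report, phi).

    MAF/call rate and HWE are computed once on the input sample set (single
    pass, no re-filtering after sample removal).
    """
    report = QcReport()
    ds1, _ = site_filters(ds, cfg, report)
    ds2, _ = hwe_filter(ds1, cfg, report)
    ds3, _ = ld_prune_filter(ds2, cfg, report)
    report.add("pre_sample", "samples", ds3.n_samples, 0)
    phi, _ = ibd_kinship(ds3)
    ds4, _ = sample_filters(ds3, cfg, phi, report)
    report.validate_telescoping()
    neutral = neutral_subset(ds4, cfg)
    return ds4, neutral, report, phi
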