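"""Synthetic genotype, climate and ring-width generators with planted truth.

Genotypes follow a hierarchical island model: ancestral allele frequencies are
perturbed per group (Balding-Nichols with parameter ``F_CT``) and then per deme
(``F_SC``). Adaptive loci additionally receive a logit-scale shift proportional
to the deme's environmental value, producing clinal allele frequencies. The
same per-deme environmental gradient drives the first latent axis of the
simulated climate table and the provenance-level sensitivity of the simulated
ring-width series, so recovery experiments are internally consistent.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from provscan.core_io import (
    MISSING,
    ClimateTable,
    GenotypeDataset,
    LocusInfo,
    RingSeriesSet,
)


@dataclass
class SimConfig:
    """Configuration of the hierarchical-island genotype simulator."""

    n_groups: int = 2
    demes_per_group: int = 8
    samples_per_deme: int = 11
    n_neutral_loci: int = 2000
    n_adaptive_loci: int = 20
    F_CT: float = 0.08
    F_SC: float = 0.03
    env_effect_b: float = 2.5
    env_structure_corr: float = 0.5
    missing_rate: float = 0.01
    n_related_pairs: int = 0
    n_inbred: int = 0
    deme_sizes: tuple[int, ...] | None = None  # overrides samples_per_deme
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deme_sizes is not None:
            if len(self.deme_sizes) != self.n_groups * self.demes_per_group:
                raise ValueError("deme_sizes length must equal the deme count")
            if min(self.deme_sizes) < 1:
                raise ValueError("deme sizes must be positive")
        for name in ("F_CT", "F_SC", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not (-1.0 <= self.env_structure_corr <= 1.0):
            raise ValueError("env_structure_corr must be in [-1, 1]")
        if min(self.n_groups, self.demes_per_group, self.samples_per_deme) < 1:
            raise ValueError("population layout counts must be positive")
        if self.n_neutral_loci < 0 or self.n_adaptive_loci < 0:
            raise ValueError("locus counts must be non-negative")

    @property
    def n_demes(self) -> int:
        return self.n_groups * self.demes_per_group

    @property
    def n_samples(self) -> int:
        if self.deme_sizes is not None:
            return int(sum(self.deme_sizes))
        return self.n_demes * self.samples_per_deme

    @property
    def n_loci(self) -> int:
        return self.n_neutral_loci + self.n_adaptive_loci


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, sufficient for recovery scoring."""

    locus_class: np.ndarray  # "neutral" | "adaptive" per locus
    locus_effect: np.ndarray  # logit-scale env slope per locus (0 for neutral)
    deme_env: np.ndarray  # environmental value per deme (standardized)
    deme_of_sample: np.ndarray  # deme index per sample
    group_of_deme: np.ndarray  # group index per deme
    ancestry: np.ndarray  # sample x n_groups true membership proportions
    related_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    inbred_samples: list[tuple[str, float]] = field(default_factory=list)

    def adaptive_ids(self, ds: GenotypeDataset) -> list[str]:
        return [l.id for l, c in zip(ds.loci, self.locus_class) if c == "adaptive"]


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Draw frequencies Beta(p(1-F)/F, (1-p)(1-F)/F) around ancestral p."""
    if F <= 0.0:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def deme_environment(cfg: SimConfig) -> np.ndarray:
    """Standardized environmental value per deme, shared across generators.

    The environment is a mixture of the neutral structure axis (standardized
    group index) and independent noise, mixed so that its correlation with the
    structure axis is ``env_structure_corr`` in expectation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7771]))
    group = np.repeat(np.arange(cfg.n_groups), cfg.demes_per_group).astype(float)
    if cfg.n_groups > 1:
        z_group = (group - group.mean()) / group.std()
    else:
        z_group = np.zeros(cfg.n_demes)
    noise = rng.standard_normal(cfg.n_demes)
    if cfg.n_demes > 1:
        noise = (noise - noise.mean()) / noise.std()
    rho = cfg.env_structure_corr
    env = rho * z_group + np.sqrt(max(0.0, 1.0 - rho**2)) * noise
    sd = env.std()
    if sd > 0:
        env = (env - env.mean()) / sd
    return env


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Simulate a genotype dataset under the hierarchical island model.

    Returns the dataset and a :class:`SimTruth` carrying planted-locus labels,
    the deme environment, true ancestry, and any planted related/inbred
    samples.
    """
    if 2 * cfg.n_related_pairs > cfg.n_samples:
        raise ValueError("more related pairs than samples allow")
    if cfg.n_related_pairs * 2 + cfg.n_inbred > cfg.n_samples:
        raise ValueError("related pairs plus inbred samples exceed sample count")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    L = cfg.n_loci
    D = cfg.n_demes

    env = deme_environment(cfg)
    group_of_deme = np.repeat(np.arange(cfg.n_groups), cfg.demes_per_group)

    # Per-locus frequencies down the hierarchy.
    p_anc = rng.uniform(0.05, 0.95, size=L)
    p_group = np.empty((cfg.n_groups, L))
    for g in range(cfg.n_groups):
        p_group[g] = _balding_nichols(rng, p_anc, cfg.F_CT)
    p_deme = np.empty((D, L))
    for d in range(D):
        p_deme[d] = _balding_nichols(rng, p_group[group_of_deme[d]], cfg.F_SC)

    locus_class = np.array(
        ["neutral"] * cfg.n_neutral_loci + ["adaptive"] * cfg.n_adaptive_loci
    )
    locus_effect = np.zeros(L)
    if cfg.n_adaptive_loci:
        adaptive = locus_class == "adaptive"
        locus_effect[adaptive] = cfg.env_effect_b
        base = np.clip(p_deme[:, adaptive], 1e-4, 1 - 1e-4)
        p_deme[:, adaptive] = _expit(_logit(base) + cfg.env_effect_b * env[:, None])

    p_deme = np.clip(p_deme, 1e-6, 1 - 1e-6)

    # Genotypes.
    if cfg.deme_sizes is not None:
        deme_of_sample = np.repeat(np.arange(D), cfg.deme_sizes)
    else:
        deme_of_sample = np.repeat(np.arange(D), cfg.samples_per_deme)
    dosage = rng.binomial(2, p_deme[deme_of_sample, :]).astype(np.int16)

    samples = [
        f"P{deme_of_sample[i]:02d}_s{i:03d}" for i in range(cfg.n_samples)
    ]
    provenance_of = {s: f"P{deme_of_sample[i]:02d}" for i, s in enumerate(samples)}

    # Planted parent-offspring pairs: pair k rebuilds the second sample of
    # deme k as an offspring of the first (one gamete from the parent, one
    # from the deme gene pool), keeping both in the same deme.
    deme_start = np.searchsorted(deme_of_sample, np.arange(D))
    deme_count = np.bincount(deme_of_sample, minlength=D)
    if cfg.n_related_pairs > D or (cfg.n_related_pairs and deme_count.min() < 2):
        raise ValueError("not enough demes/samples for the requested related pairs")
    related_pairs: list[tuple[str, str, float]] = []
    for k in range(cfg.n_related_pairs):
        i_par, i_off = int(deme_start[k]), int(deme_start[k]) + 1
        d = k
        par = dosage[i_par]
        from_parent = np.where(
            par == 1, rng.integers(0, 2, size=L), (par // 2)
        )
        from_pool = rng.binomial(1, p_deme[d])
        dosage[i_off] = (from_parent + from_pool).astype(np.int16)
        related_pairs.append((samples[i_par], samples[i_off], 0.25))

    # Planted inbred samples (selfing-like, F = 0.5): with probability F the
    # two alleles are identical by descent. Inbred sample k takes slot
    # 2 + k // D of deme k % D, clear of the related-pair slots.
    if cfg.n_inbred and deme_count.min() < 3 + (cfg.n_inbred - 1) // D:
        raise ValueError("not enough samples per deme for the requested inbred samples")
    inbred_samples: list[tuple[str, float]] = []
    for k in range(cfg.n_inbred):
        d = k % D
        i = int(deme_start[d]) + 2 + k // D
        ibd = rng.random(L) < 0.5
        one = rng.binomial(1, p_deme[d])
        two = rng.binomial(1, p_deme[d])
        dosage[i] = np.where(ibd, 2 * one, one + two).astype(np.int16)
        inbred_samples.append((samples[i], 0.5))

    # MCAR missingness.
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = MISSING

    # Loci spread over scaffolds so LD pruning windows are exercised.
    loci = [
        LocusInfo(f"L{j:05d}", f"scaffold_{j // 100}", (j % 100) * 1000 + 1, "A", "C")
        for j in range(L)
    ]

    ds = GenotypeDataset(samples, loci, dosage, provenance_of)
    ancestry = np.zeros((cfg.n_samples, cfg.n_groups))
    ancestry[np.arange(cfg.n_samples), group_of_deme[deme_of_sample]] = 1.0
    truth = SimTruth(
        locus_class=locus_class,
        locus_effect=locus_effect,
        deme_env=env,
        deme_of_sample=deme_of_sample,
        group_of_deme=group_of_deme,
        ancestry=ancestry,
        related_pairs=related_pairs,
        inbred_samples=inbred_samples,
    )
    return ds, truth


def linked_locus_pairs(
    ds: GenotypeDataset, n_pairs: int, seed: int = 0
) -> GenotypeDataset:
    """Append near-duplicate copies of ``n_pairs`` loci (for ld_prune tests).

    Each copy equals its source locus with ~2% of calls flipped, placed at the
    next position on the same scaffold.
    """
    rng = np.random.default_rng(seed)
    idx = rng.choice(ds.n_loci, size=n_pairs, replace=False)
    new_cols = []
    new_loci = []
    for j in idx:
        col = ds.dosage[:, j].copy()
        flip = rng.random(col.size) < 0.02
        col[flip] = rng.integers(0, 3, size=flip.sum())
        src = ds.loci[j]
        new_loci.append(
            LocusInfo(f"{src.id}_dup", src.scaffold, src.position + 1, src.ref, src.alt)
        )
        new_cols.append(col)
    dosage = np.concatenate([ds.dosage, np.stack(new_cols, axis=1)], axis=1)
    return GenotypeDataset(ds.samples, ds.loci + new_loci, dosage, ds.provenance_of)


# ------------------------------------------------------------------- climate

_AXIS_SHARES = (0.48, 0.34, 0.09, 0.09)  # temperature, precipitation, radiation, snow
_AXIS_NAMES = ("tmp", "pre", "rad", "snw")


def simulate_climate(cfg: SimConfig, n_vars: int = 247, noise_sd: float = 0.30) -> ClimateTable:
    """Simulate a provenance x climate-variable table with ~2 dominant axes.

    Variables are linear combinations of 4 latent axes plus i.i.d. noise; the
    first latent axis equals the genotype simulator's deme environment, so
    climate PC1 and the planted genotype cline share a gradient. Loading
    shares are tuned so the first two PCs explain roughly 70-90% of variance
    at the default noise level.
    """
    if n_vars < 4:
        raise ValueError("need n_vars >= 4")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    D = cfg.n_demes
    axes = np.empty((D, 4))
    axes[:, 0] = deme_environment(cfg)
    for k in range(1, 4):
        z = rng.standard_normal(D)
        axes[:, k] = (z - z.mean()) / z.std()

    counts = np.floor(np.asarray(_AXIS_SHARES) * n_vars).astype(int)
    counts[0] += n_vars - counts.sum()
    primary = np.repeat(np.arange(4), counts)

    cols = {}
    for v in range(n_vars):
        k = primary[v]
        sign = -1.0 if rng.random() < 0.3 else 1.0
        weight = sign * rng.uniform(0.8, 1.2)
        cross = 0.10 * rng.standard_normal(4)
        cross[k] = 0.0
        signal = weight * axes[:, k] + axes @ cross
        values = signal + noise_sd * rng.standard_normal(D)
        cols[f"{_AXIS_NAMES[k]}_{v:03d}"] = values

    provs = [f"P{d:02d}" for d in range(D)]
    return ClimateTable(pd.DataFrame(cols, index=pd.Index(provs, name="provenance")))


# --------------------------------------------------------------------- rings


@dataclass
class RingSimConfig:
    """Parameters of the ring-width simulator (provenance-level cline)."""

    c0: float = 0.15  # baseline July-temperature sensitivity
    c1: float = 0.15  # sensitivity increase per unit source environment
    noise_sd: float = 0.12
    trees_per_provenance: int = 6
    age_scale: float = 40.0
    early_fraction: float = 0.6


def simulate_rings(
    cfg: SimConfig,
    years: Sequence[int] = range(1979, 2012),
    ring_cfg: RingSimConfig | None = None,
) -> tuple[RingSeriesSet, pd.DataFrame]:
    """Simulate ring-width series and the trial-site monthly climate.

    Ring width is a negative-exponential age trend modulated by
    ``exp(beta_prov * z(JulyT) + noise)`` with ``beta_prov = c0 + c1 * env``,
    planting a provenance-level cline of temperature sensitivity in source
    environment. Returns the series set and a long-format site climate table
    (year, month, variable, value).
    """
    years = np.asarray(list(years), dtype=int)
    if years.size < 30:
        raise ValueError("need >= 30 years")
    ring_cfg = ring_cfg or RingSimConfig()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303]))
    env = deme_environment(cfg)

    # Site monthly temperatures; July drives growth.
    month_means = np.array([-1.5, 0.2, 4.5, 9.4, 14.2, 17.5, 19.4, 18.8, 14.6, 9.2, 3.6, -0.2])
    clim_rows = []
    temps = np.empty((years.size, 12))
    for yi, y in enumerate(years):
        temps[yi] = month_means + 1.4 * rng.standard_normal(12)
        for m in range(12):
            clim_rows.append((int(y), m + 1, "tmean", float(temps[yi, m])))
    site_climate = pd.DataFrame(clim_rows, columns=["year", "month", "variable", "value"])

    july = temps[:, 6]
    z_july = (july - july.mean()) / july.std()

    rows = []
    for d in range(cfg.n_demes):
        prov = f"P{d:02d}"
        beta = ring_cfg.c0 + ring_cfg.c1 * env[d]
        for t in range(ring_cfg.trees_per_provenance):
            tree = f"{prov}_t{t}"
            age = np.arange(1, years.size + 1, dtype=float) + rng.uniform(0, 10)
            trend = 3.0 * np.exp(-age / ring_cfg.age_scale) + 0.4
            noise = ring_cfg.noise_sd * rng.standard_normal(years.size)
            total = trend * np.exp(beta * z_july + noise)
            ef = np.clip(
                ring_cfg.early_fraction + 0.03 * rng.standard_normal(years.size), 0.05, 0.95
            )
            early = total * ef
            late = total - early
            for yi, y in enumerate(years):
                rows.append((tree, prov, int(y), early[yi], late[yi], total[yi]))

    rings = RingSeriesSet(
        pd.DataFrame(
            rows, columns=["tree", "provenance", "year", "earlywood", "latewood", "total"]
        )
    )
    return rings, site_climate


# ------------------------------------------------------------------ fixtures


def tiny_fixture(seed: int = 42) -> tuple[GenotypeDataset, SimTruth]:
    """A deterministic 6-sample x 12-locus dataset for docs and unit tests."""
    cfg = SimConfig(
        n_groups=2,
        demes_per_group=1,
        samples_per_deme=3,
        n_neutral_loci=10,
        n_adaptive_loci=2,
        F_CT=0.2,
        F_SC=0.0,
        env_effect_b=3.0,
        missing_rate=0.05,
        seed=seed,
    )
    return simulate_genotypes(cfg)


def write_dataset_files(
    outdir,
    ds: GenotypeDataset,
    climate: ClimateTable | None = None,
    rings: RingSeriesSet | None = None,
    site_climate: pd.DataFrame | None = None,
    prov_coords: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write a simulated dataset in the CSV/VCF schemas core_io reads."""
    from pathlib import Path

    from provscan.core_io import write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_vcf(ds, outdir / "genotypes.vcf")
    paths["vcf"] = str(outdir / "genotypes.vcf")

    provs = ds.provenances
    counts = pd.Series(ds.provenance_labels()).value_counts()
    if prov_coords is None:
        rng = np.random.default_rng(len(provs))
        prov_df = pd.DataFrame(
            {
                "id": provs,
                "lat": 44.0 + np.arange(len(provs)) * 0.6 + rng.uniform(-0.3, 0.3, len(provs)),
                "lon": -120.0 - np.arange(len(provs)) * 0.4 + rng.uniform(-0.5, 0.5, len(provs)),
                "elev": 300 + 50 * np.arange(len(provs)),
                "n_samples": [int(counts[p]) for p in provs],
            }
        )
    else:
        prov_df = prov_coords
    prov_df.to_csv(outdir / "provenances.csv", index=False)
    paths["provenances"] = str(outdir / "provenances.csv")

    if climate is not None:
        climate.table.rename_axis("provenance").to_csv(outdir / "climate.csv")
        paths["climate"] = str(outdir / "climate.csv")
    if rings is not None:
        rings.table.to_csv(outdir / "rings.csv", index=False)
        paths["rings"] = str(outdir / "rings.csv")
    if site_climate is not None:
        site_climate.to_csv(outdir / "site_climate.csv", index=False)
        paths["site_climate"] = str(outdir / "site_climate.csv")
    return paths
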