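"""Domain types and readers/writers for genotype, metadata, climate and ring data.

Genotypes are stored as a sample x locus alt-allele dosage matrix with a
distinguished ``MISSING`` sentinel (-1) that must never enter arithmetic;
helpers that compute frequencies or call rates mask it out explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call. Kept negative so that any accidental
#: use in arithmetic is loud in tests (frequencies would leave [0, 1]).
MISSING: int = -1


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed; message names the offending line."""


class EmptyDatasetError(ValueError):
    """Raised when an operation would produce a dataset without loci or samples."""


@dataclass(frozen=True)
class LocusInfo:
    """A biallelic SNP locus with 1-based VCF coordinates."""

    id: str
    scaffold: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"locus {self.id}: ref == alt ({self.ref})")
        if self.position < 1:
            raise ValueError(f"locus {self.id}: position must be 1-based, got {self.position}")


class GenotypeDataset:
    """Sample x locus alt-allele dosage matrix with provenance labels.

    Parameters
    ----------
    samples
        Sample identifiers, one per dosage row.
    loci
        :class:`LocusInfo` per dosage column; (scaffold, position) unique.
    dosage
        Integer matrix in {0, 1, 2, MISSING}.
    provenance_of
        Mapping from sample id to provenance id; every sample must be present.
    """

    def __init__(
        self,
        samples: Sequence[str],
        loci: Sequence[LocusInfo],
        dosage: np.ndarray,
        provenance_of: Mapping[str, str],
    ) -> None:
        self.samples = list(samples)
        self.loci = list(loci)
        self.dosage = np.asarray(dosage, dtype=np.int16)
        self.provenance_of = dict(provenance_of)
        self.validate()

    # ------------------------------------------------------------------ checks
    def validate(self) -> None:
        n, m = len(self.samples), len(self.loci)
        if self.dosage.shape != (n, m):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != (n_samples={n}, n_loci={m})"
            )
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample ids")
        keys = {(l.scaffold, l.position) for l in self.loci}
        if len(keys) != m:
            raise ValueError("duplicate (scaffold, position) among loci")
        missing_prov = [s for s in self.samples if s not in self.provenance_of]
        if missing_prov:
            raise ValueError(f"samples without provenance: {missing_prov[:5]}")
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosage[~valid])
            raise ValueError(f"invalid dosage values {bad}")

    # -------------------------------------------------------------- properties
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def provenances(self) -> list[str]:
        """Distinct provenance ids in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.provenance_of[s], None)
        return list(seen)

    def provenance_labels(self) -> np.ndarray:
        return np.array([self.provenance_of[s] for s in self.samples])

    def observed_mask(self) -> np.ndarray:
        return self.dosage != MISSING

    def alt_freq(self) -> np.ndarray:
        """Per-locus alternative-allele frequency over non-missing calls."""
        obs = self.observed_mask()
        d = np.where(obs, self.dosage, 0).astype(float)
        n_called = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, d.sum(axis=0) / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def site_call_rate(self) -> np.ndarray:
        return self.observed_mask().mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return self.observed_mask().mean(axis=1)

    # ---------------------------------------------------------------- slicing
    def subset_loci(self, idx: Iterable[int]) -> "GenotypeDataset":
        idx = np.asarray(list(idx), dtype=int)
        if idx.size == 0:
            raise EmptyDatasetError("locus subset is empty")
        return GenotypeDataset(
            self.samples,
            [self.loci[i] for i in idx],
            self.dosage[:, idx],
            self.provenance_of,
        )

    def subset_samples(self, idx: Iterable[int]) -> "GenotypeDataset":
        idx = np.asarray(list(idx), dtype=int)
        if idx.size == 0:
            raise EmptyDatasetError("sample subset is empty")
        samples = [self.samples[i] for i in idx]
        return GenotypeDataset(
            samples,
            self.loci,
            self.dosage[idx, :],
            {s: self.provenance_of[s] for s in samples},
        )

    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]


@dataclass
class ProvenanceTable:
    """Provenance origins: id, coordinates, elevation and sample counts."""

    table: pd.DataFrame  # columns: id, lat, lon, elev, n_samples

    def __post_init__(self) -> None:
        required = {"id", "lat", "lon", "elev"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"provenance table missing columns: {sorted(missing)}")
        lat = self.table["lat"].to_numpy(float)
        if np.any((lat < -90) | (lat > 90)):
            raise ValueError("latitude outside [-90, 90]")
        if self.table["id"].duplicated().any():
            raise ValueError("duplicate provenance ids")

    @property
    def ids(self) -> list[str]:
        return self.table["id"].astype(str).tolist()

    @property
    def total_samples(self) -> int:
        if "n_samples" not in self.table.columns:
            raise ValueError("no n_samples column")
        return int(self.table["n_samples"].sum())


@dataclass
class ClimateTable:
    """Provenance x climate-variable matrix (no missing cells)."""

    table: pd.DataFrame  # index: provenance id; columns: variables

    def __post_init__(self) -> None:
        if self.table.shape[1] < 2:
            raise ValueError("climate table needs >= 2 variables")
        if self.table.isna().any().any():
            raise ValueError("climate table has missing cells")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate provenance rows")

    @property
    def provenances(self) -> list[str]:
        return self.table.index.astype(str).tolist()

    @property
    def variables(self) -> list[str]:
        return self.table.columns.tolist()

    def values(self) -> np.ndarray:
        return self.table.to_numpy(float)


@dataclass
class RingSeriesSet:
    """Per-tree annual ring-width series (earlywood / latewood / total, mm)."""

    table: pd.DataFrame  # columns: tree, provenance, year, earlywood, latewood, total

    def __post_init__(self) -> None:
        required = {"tree", "provenance", "year", "earlywood", "latewood", "total"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ring table missing columns: {sorted(missing)}")
        for col in ("earlywood", "latewood", "total"):
            if (self.table[col].to_numpy(float) < 0).any():
                raise ValueError(f"negative ring width in column {col}")
        for tree, sub in self.table.groupby("tree"):
            years = np.sort(sub["year"].to_numpy(int))
            if years.size > 1 and not np.all(np.diff(years) == 1):
                raise ValueError(f"tree {tree}: years not consecutive")

    @property
    def trees(self) -> list[str]:
        return self.table["tree"].astype(str).unique().tolist()

    def series(self, tree: str, component: str = "total") -> pd.Series:
        sub = self.table[self.table["tree"].astype(str) == str(tree)].sort_values("year")
        return pd.Series(
            sub[component].to_numpy(float), index=sub["year"].to_numpy(int), name=tree
        )

    def trees_of(self, provenance: str) -> list[str]:
        sub = self.table[self.table["provenance"].astype(str) == str(provenance)]
        return sub["tree"].astype(str).unique().tolist()


# ---------------------------------------------------------------------- VCF IO

_GT_TO_DOSAGE = {
    (0, 0): 0,
    (0, 1): 1,
    (1, 0): 1,
    (1, 1): 2,
}


def read_vcf(path: str | Path, provenance_of: Mapping[str, str] | None = None) -> GenotypeDataset:
    """Read a diploid VCF into a :class:`GenotypeDataset`.

    Only biallelic SNP records are kept; multi-allelic records are dropped and
    counted in the log. Half-calls ("0/.") and "./." become ``MISSING``.
    Phased and unphased separators are treated identically.

    If ``provenance_of`` is not given, the per-sample provenance is taken from
    the sample id prefix before the first underscore.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    loci: list[LocusInfo] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    try:
        for var in vcf:
            if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
                n_dropped += 1
                continue
            vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
            loci.append(LocusInfo(vid, var.CHROM, var.POS, var.REF, var.ALT[0]))
            row = np.full(len(samples), MISSING, dtype=np.int16)
            for i, gt in enumerate(var.genotypes):
                a, b = int(gt[0]), int(gt[1])
                row[i] = _GT_TO_DOSAGE.get((a, b), MISSING)
            rows.append(row)
    except Exception as exc:
        raise VcfParseError(f"malformed VCF {path} near record {len(loci) + n_dropped + 1}: {exc}") from exc
    finally:
        vcf.close()

    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    if not loci:
        raise EmptyDatasetError(f"no biallelic SNP records in {path}")

    dosage = np.stack(rows, axis=1)
    if provenance_of is None:
        provenance_of = {s: s.split("_")[0] for s in samples}
    ds = GenotypeDataset(samples, loci, dosage, provenance_of)
    ds.n_dropped_records = n_dropped  # type: ignore[attr-defined]
    return ds


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(ds: GenotypeDataset, path: str | Path) -> Path:
    """Write a GT-only VCF v4.2; inverse of :func:`read_vcf` on its subset."""
    if ds.n_loci == 0 or ds.n_samples == 0:
        raise EmptyDatasetError("refusing to write empty dataset")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen_contigs: dict[str, None] = {}
        for l in ds.loci:
            seen_contigs.setdefault(l.scaffold, None)
        for contig in seen_contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ds.samples) + "\n")
        order = sorted(range(ds.n_loci), key=lambda j: (ds.loci[j].scaffold, ds.loci[j].position))
        for j in order:
            l = ds.loci[j]
            gts = "\t".join(_DOSAGE_TO_GT[int(d)] for d in ds.dosage[:, j])
            fh.write(f"{l.scaffold}\t{l.position}\t{l.id}\t{l.ref}\t{l.alt}\t.\t.\t.\tGT\t{gts}\n")
    return path


# ------------------------------------------------------------------- table IO


def read_tables(
    provenances_csv: str | Path,
    climate_csv: str | Path | None = None,
    rings_csv: str | Path | None = None,
) -> tuple[ProvenanceTable, ClimateTable | None, RingSeriesSet | None]:
    """Read the documented CSV schemas into typed tables.

    ``provenances.csv``: id,lat,lon,elev[,n_samples];
    ``climate.csv``: provenance,var1..varK;
    ``rings.csv``: tree,provenance,year,earlywood,latewood,total.
    Provenance ids referenced by the climate and ring tables must appear in the
    provenance table.
    """
    prov_df = pd.read_csv(provenances_csv)
    prov = ProvenanceTable(prov_df)
    prov_ids = set(prov.ids)

    climate = None
    if climate_csv is not None:
        cdf = pd.read_csv(climate_csv)
        if "provenance" not in cdf.columns:
            raise ValueError("climate.csv must have a 'provenance' column")
        cdf = cdf.set_index("provenance")
        unknown = set(cdf.index.astype(str)) - prov_ids
        if unknown:
            raise ValueError(f"climate.csv provenances not in provenance table: {sorted(unknown)}")
        climate = ClimateTable(cdf)

    rings = None
    if rings_csv is not None:
        rdf = pd.read_csv(rings_csv)
        rings = RingSeriesSet(rdf)
        unknown = set(rdf["provenance"].astype(str)) - prov_ids
        if unknown:
            raise ValueError(f"rings.csv provenances not in provenance table: {sorted(unknown)}")

    return prov, climate, rings
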