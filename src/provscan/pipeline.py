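"""End-to-end workflow orchestration with caching and a machine-readable report.

Stage order: QC -> climate PCs -> trait cline -> four scans -> consensus ->
interrogation -> ancestry/RDA. Every stage writes its tabular output to the
run directory; a rerun with the same config loads cached CSVs and is
byte-identical. Percentages in the report are rounded half-up to two
decimals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from provscan import __version__
from provscan.core_io import GenotypeDataset, read_tables, read_vcf
from provscan.qc import QcConfig, QcReport, run_qc
from provscan.phenoclimate import (
    DetrendConfig,
    EnvPCs,
    climate_pca,
    cline_regression,
    monthly_series,
    provenance_responses,
)
from provscan.scan_fst import (
    NullModelConfig,
    infer_groups,
    observed_layout,
    outlier_pvalues,
    simulate_null,
    wc_fst,
)
from provscan.scan_lfmm import choose_k, impute_dosage, lfmm_fit, lfmm_test
from provscan.scan_bayesenv import (
    deme_allele_counts,
    deme_frequencies,
    env_bayes_factor,
    estimate_omega,
    fmodel_env_scan,
)
from provscan.consensus import (
    Thresholds,
    build_shortlists,
    consensus_sets,
    eigen_discrimination,
)
from provscan.ancestry_rda import rda_models, snmf_ancestry

logger = logging.getLogger(__name__)

_CSV_FMT = None  # pandas default: full round-trip precision


def percentage(count: int, total: int) -> float:
    """count/total as a percentage rounded half-up to two decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Inputs, thresholds and seeds of one pipeline run."""

    vcf: str
    provenances_csv: str
    climate_csv: str
    rings_csv: str | None = None
    site_climate_csv: str | None = None
    outdir: str = "provscan_run"
    qc: QcConfig = field(default_factory=QcConfig)
    detrend: DetrendConfig = field(default_factory=DetrendConfig)
    null_model: NullModelConfig = field(default_factory=NullModelConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    axes: tuple[str, ...] = ("PC1", "PC2")
    consensus_cap: int = 5
    k_override: int | None = None
    n_groups_override: int | None = None
    ancestry_k_max: int = 8
    rda_permutations: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, sub in (
            ("qc", QcConfig),
            ("detrend", DetrendConfig),
            ("null_model", NullModelConfig),
            ("thresholds", Thresholds),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "axes" in raw:
            raw["axes"] = tuple(raw["axes"])
        return cls(**raw)


@dataclass
class RunReport:
    """Counts, percentages and seeds of a completed (partial) run."""

    qc: list[dict] = field(default_factory=list)
    n_tested_loci: int = 0
    shortlist_sizes: dict = field(default_factory=dict)
    bonferroni_counts: dict = field(default_factory=dict)
    consensus_sizes: dict = field(default_factory=dict)
    consensus_percent: dict = field(default_factory=dict)
    venn: dict = field(default_factory=dict)
    gif: dict = field(default_factory=dict)
    chosen_k_lfmm: int | None = None
    chosen_k_ancestry: int | None = None
    cline: dict = field(default_factory=dict)
    eigen: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    version: str = __version__

    def adaptive_fraction(self, count: int) -> float:
        return percentage(count, self.n_tested_loci)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, (set, tuple)):
                return sorted(o) if isinstance(o, set) else list(o)
            raise TypeError(f"not serializable: {type(o)}")

        return json.dumps(asdict(self), indent=2, default=default, sort_keys=True)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=_CSV_FMT)


def _read_csv(path: Path) -> pd.DataFrame:
    # round_trip parsing keeps cached reruns bit-identical to fresh ones
    return pd.read_csv(path, float_precision="round_trip")


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] | None = None) -> RunReport:
    """Execute the workflow (optionally a prefix of stages) and write outputs.

    Stages: qc, phenoclimate, scan, consensus, ancestry, rda. Each stage's
    CSV outputs are cached in the run directory; a stage whose outputs exist
    is loaded, not recomputed. Any failure aborts with the stage name while
    earlier outputs remain on disk.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    all_stages = ("qc", "phenoclimate", "scan", "consensus", "ancestry", "rda")
    wanted = set(stages or all_stages)
    report = RunReport(seeds={"pipeline": cfg.seed, "qc": cfg.qc.seed, "null": cfg.null_model.seed})

    # ------------------------------------------------------------------ load
    stage = "load"
    try:
        prov, climate, rings = read_tables(
            cfg.provenances_csv, cfg.climate_csv, cfg.rings_csv
        )
        ds = read_vcf(cfg.vcf)
        site_climate = (
            pd.read_csv(cfg.site_climate_csv) if cfg.site_climate_csv else None
        )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -------------------------------------------------------------------- qc
    stage = "qc"
    try:
        ds_f, neutral_ids, qc_report, _ = run_qc(ds, cfg.qc)
        report.qc = [
            {"stage": s.name, "kind": s.kind, "in": s.n_in, "removed": s.n_removed, "retained": s.n_out}
            for s in qc_report.stages
        ]
        (out / "qc_report.json").write_text(qc_report.to_json())
        pd.DataFrame({"locus": neutral_ids}).to_csv(out / "neutral_subset.csv", index=False)
        report.n_tested_loci = ds_f.n_loci
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    if wanted <= {"qc"}:
        (out / "run_report.json").write_text(report.to_json())
        return report

    # ---------------------------------------------------------- phenoclimate
    stage = "phenoclimate"
    env_pcs: EnvPCs | None = None
    try:
        env_pcs = climate_pca(climate)
        header = ",".join(f"{v:.6f}" for v in env_pcs.explained)
        path = out / "env_pcs.csv"
        with open(path, "w") as fh:
            fh.write(f"# explained_variance,{header}\n")
            env_pcs.scores.to_csv(fh, float_format=_CSV_FMT)
        if rings is not None and site_climate is not None:
            july = monthly_series(site_climate, "tmean", 7)
            resp = provenance_responses(
                rings, july, detrend_cfg=cfg.detrend, seed=cfg.seed
            )
            _write_csv(resp.reset_index(), out / "response.csv")
            for axis in cfg.axes:
                r, p = cline_regression(resp["coef"], env_pcs.scores[axis])
                report.cline[axis] = {"r": r, "p": p}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    if wanted <= {"qc", "phenoclimate"}:
        (out / "run_report.json").write_text(report.to_json())
        return report

    # ------------------------------------------------------------------ scan
    stage = "scan"
    try:
        provs = ds_f.provenances
        labels = ds_f.provenance_labels()
        env_by_axis = {
            axis: env_pcs.scores.loc[provs, axis].to_numpy(float) for axis in cfg.axes
        }

        # Neutral matrices for K choice, omega, and group inference.
        neutral_set = set(neutral_ids)
        neutral_idx = [j for j, l in enumerate(ds_f.loci) if l.id in neutral_set]
        neutral_matrix = impute_dosage(ds_f.subset_loci(neutral_idx))

        k_lfmm = cfg.k_override if cfg.k_override is not None else choose_k(neutral_matrix)
        k_lfmm = max(k_lfmm, 1)
        report.chosen_k_lfmm = k_lfmm

        # FST scan (environment-blind, shared across axes).
        fst_path = out / "fst_scan.csv"
        if fst_path.exists():
            fst_calls = _read_csv(fst_path)
        else:
            fst_res = wc_fst(ds_f, labels)
            n_groups = cfg.n_groups_override or max(2, min(k_lfmm, len(provs) // 2))
            groups = infer_groups(ds_f, neutral_ids, n_groups, seed=cfg.seed)
            sizes, grp = observed_layout(ds_f, groups)
            het0, fst0, _ = simulate_null(cfg.null_model, sizes, grp, fst_res.global_fst)
            fst_calls = outlier_pvalues(fst_res, het0, fst0, cfg.null_model).table
            _write_csv(fst_calls, fst_path)

        # LFMM: one joint fit over the scanned axes.
        lfmm_path = out / "lfmm_scan.csv"
        X = np.column_stack([env_by_axis[a][_prov_index(labels, provs)] for a in cfg.axes])
        if lfmm_path.exists():
            lfmm_table = _read_csv(lfmm_path)
        else:
            Y = impute_dosage(ds_f)
            fit = lfmm_fit(
                Y, X, k_lfmm, locus_ids=ds_f.locus_ids(), axis_names=list(cfg.axes)
            )
            test = lfmm_test(fit)
            report.gif = test.gif
            lfmm_table = test.table
            _write_csv(lfmm_table, lfmm_path)

        # Covariance-controlled Bayes factors + F-model per axis.
        freqs, _ = deme_frequencies(ds_f)
        alt, tot, _ = deme_allele_counts(ds_f)
        neutral_freqs = freqs[:, neutral_idx]
        omega = estimate_omega(neutral_freqs, provs)
        bay_path = out / "bayenv_scan.csv"
        fm_path = out / "fmodel_scan.csv"
        if bay_path.exists():
            bayenv_table = _read_csv(bay_path)
        else:
            parts = [
                env_bayes_factor(
                    freqs,
                    env_by_axis[a],
                    omega,
                    ds_f.locus_ids(),
                    axis_name=a,
                    bf_threshold=cfg.thresholds.bf_min,
                    rho_threshold=cfg.thresholds.rho_min,
                ).table
                for a in cfg.axes
            ]
            bayenv_table = pd.concat(parts, ignore_index=True)
            _write_csv(bayenv_table, bay_path)
        if fm_path.exists():
            fmodel_table = _read_csv(fm_path)
        else:
            parts = [
                fmodel_env_scan(alt, tot, env_by_axis[a], ds_f.locus_ids(), axis_name=a).table
                for a in cfg.axes
            ]
            fmodel_table = pd.concat(parts, ignore_index=True)
            _write_csv(fmodel_table, fm_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    if wanted <= {"qc", "phenoclimate", "scan"}:
        (out / "run_report.json").write_text(report.to_json())
        return report

    # ------------------------------------------------------------- consensus
    stage = "consensus"
    try:
        shortlists_by_axis = {}
        lfmm_rank = {}
        for a in cfg.axes:
            shortlists_by_axis[a] = build_shortlists(
                fst_calls, fmodel_table, bayenv_table, lfmm_table, a, cfg.thresholds
            )
            sub = lfmm_table[lfmm_table["axis"] == a]
            lfmm_rank[a] = dict(
                zip(sub["locus"], -np.log10(sub["p_cal"].clip(lower=1e-300)))
            )
        cons = consensus_sets(shortlists_by_axis, lfmm_rank, cap=cfg.consensus_cap)
        rows = []
        for a in cfg.axes:
            for locus in sorted(cons.per_axis[a]):
                methods = [m for m, s in shortlists_by_axis[a].items() if locus in s]
                rows.append(
                    {
                        "locus": locus,
                        "axis": a,
                        "methods": "|".join(methods),
                        "lfmm_neglog_p": lfmm_rank[a].get(locus, np.nan),
                    }
                )
            report.shortlist_sizes[a] = cons.shortlist_sizes[a]
            report.consensus_sizes[a] = len(cons.per_axis[a])
            report.consensus_percent[a] = percentage(len(cons.per_axis[a]), ds_f.n_loci)
            report.venn[a] = {
                "pairs": {"&".join(k): v for k, v in cons.venn_pairs[a].items()},
                "triples": {"&".join(k): v for k, v in cons.venn_triples[a].items()},
            }
        report.bonferroni_counts = {
            "fst": int(fst_calls["bonferroni"].sum()),
            **{
                a: int(
                    lfmm_table[(lfmm_table["axis"] == a) & lfmm_table["bonferroni"]].shape[0]
                )
                for a in cfg.axes
            },
        }
        _write_csv(pd.DataFrame(rows), out / "consensus.csv")
        venn_rows = [
            {"axis": a, "cell": "&".join(k), "count": v}
            for a in cfg.axes
            for k, v in {**cons.venn_pairs[a], **cons.venn_triples[a]}.items()
        ]
        _write_csv(pd.DataFrame(venn_rows), out / "venn.csv")

        # Eigenvector interrogation on the pooled consensus set.
        total = sorted(cons.total)
        if len(total) >= 2:
            group_vec = _two_group_labels(ds_f)
            eig = eigen_discrimination(ds_f, total, group_vec, seed=cfg.seed)
            report.eigen = {
                "eta2_consensus": eig.eta2_consensus,
                "eta2_random": eig.eta2_random,
            }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    if wanted <= {"qc", "phenoclimate", "scan", "consensus"}:
        (out / "run_report.json").write_text(report.to_json())
        return report

    # -------------------------------------------------------- ancestry / rda
    stage = "ancestry"
    try:
        neutral_ds = ds_f.subset_loci(neutral_idx)
        anc = snmf_ancestry(
            neutral_ds, range(1, cfg.ancestry_k_max + 1), seed=cfg.seed
        )
        report.chosen_k_ancestry = anc.chosen_k
        q2 = anc.q_at(2) if 2 in anc.fits else anc.chosen.Q
        rows = []
        for k, f in sorted(anc.fits.items()):
            for i, s in enumerate(anc.samples):
                rows.append(
                    {"sample": s, "K": k, **{f"q{j + 1}": f.Q[i, j] for j in range(k)}}
                )
        _write_csv(pd.DataFrame(rows), out / "ancestry_Q.csv")
        _write_csv(
            pd.DataFrame(
                {
                    "K": sorted(anc.fits),
                    "cross_entropy": [anc.fits[k].cross_entropy for k in sorted(anc.fits)],
                }
            ),
            out / "crossentropy.csv",
        )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    if wanted <= {"qc", "phenoclimate", "scan", "consensus", "ancestry"}:
        (out / "run_report.json").write_text(report.to_json())
        return report

    stage = "rda"
    try:
        prov_tbl = prov.table.set_index("id")
        lat = np.array([prov_tbl.loc[p, "lat"] for p in labels], float)
        lon = np.array([prov_tbl.loc[p, "lon"] for p in labels], float)
        Y = impute_dosage(ds_f)
        pcs_per_sample = {
            a: env_by_axis[a][_prov_index(labels, provs)] for a in cfg.axes
        }
        rda = rda_models(
            Y,
            pcs_per_sample.get("PC1"),
            pcs_per_sample.get("PC2"),
            lat,
            lon,
            q2[:, 0],
            n_perm=cfg.rda_permutations,
            seed=cfg.seed,
        )
        _write_csv(rda, out / "rda.csv")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    (out / "run_report.json").write_text(report.to_json())
    return report


def _prov_index(labels: np.ndarray, provs: list[str]) -> np.ndarray:
    lookup = {p: i for i, p in enumerate(provs)}
    return np.array([lookup[l] for l in labels])


def _two_group_labels(ds: GenotypeDataset) -> np.ndarray:
    """Two-group sample labeling for eta-squared (k-means on genotype EV1)."""
    from sklearn.cluster import KMeans

    X = impute_dosage(ds)
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(U[:, :1] * s[:1])
    return km.labels_
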