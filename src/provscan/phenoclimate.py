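"""Climate PCA and dendroclimatic trait derivation.

The climate table (provenance x variables, mixed units) is reduced by
correlation-matrix PCA to standardized environmental PCs. Ring-width series
are detrended with a smoothing spline whose frequency response is 50% at a
configurable wavelength, aggregated into provenance chronologies with a Tukey
biweight robust mean, correlated with monthly site climate via bootstrapped
response functions, and the provenance-level response coefficients are
regressed on an environmental PC to quantify the genecological cline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve
from scipy import stats

from provscan.core_io import ClimateTable, RingSeriesSet

logger = logging.getLogger(__name__)


@dataclass
class EnvPCs:
    """Standardized principal-component scores of the climate table."""

    scores: pd.DataFrame  # provenance x PC1..PCk, each column mean 0 sd 1
    loadings: pd.DataFrame  # variable x component
    explained: np.ndarray  # explained-variance fraction per kept component

    def __post_init__(self) -> None:
        if np.any(np.diff(self.explained) > 1e-12):
            raise ValueError("explained variance must be non-increasing")
        if self.explained.sum() > 1.0 + 1e-9:
            raise ValueError("explained variance fractions sum above 1")

    def component(self, k: int) -> pd.Series:
        return self.scores[f"PC{k}"]


def climate_pca(climate: ClimateTable, n_components: int = 4) -> EnvPCs:
    """Correlation-matrix PCA of the climate table with standardized scores.

    Variables are z-scored (constant variables dropped with a warning), the
    SVD taken, and the first ``min(n_components, rank)`` components returned.
    Scores are column-standardized (mean 0, sd 1); each loading vector's
    largest-magnitude entry is made positive to fix signs.
    """
    X = climate.values()
    n, m = X.shape
    if n < 3:
        raise ValueError("need >= 3 provenances")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [v for v, k in zip(climate.variables, keep) if not k]
        logger.warning("climate_pca: dropping %d constant variables: %s", len(dropped), dropped[:5])
    X = X[:, keep]
    variables = [v for v, k in zip(climate.variables, keep) if k]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    tol = s.max() * max(Z.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    k = min(n_components, rank)
    ev = s**2
    explained_all = ev / ev.sum()

    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    for c in range(k):
        jmax = np.argmax(np.abs(loadings[:, c]))
        if loadings[jmax, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    # Standardize scores to unit sd per component.
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=1)

    idx = pd.Index(climate.provenances, name="provenance")
    cols = [f"PC{i + 1}" for i in range(k)]
    return EnvPCs(
        scores=pd.DataFrame(scores, index=idx, columns=cols),
        loadings=pd.DataFrame(loadings, index=variables, columns=cols),
        explained=explained_all[:k],
    )


# ----------------------------------------------------------------- detrending


@dataclass
class DetrendConfig:
    """Detrending/chronology settings."""

    spline_wavelength_years: float = 15.0  # 50% frequency-response cutoff
    biweight_c: float = 9.0

    def __post_init__(self) -> None:
        if self.spline_wavelength_years < 2:
            raise ValueError("wavelength must be >= 2 years")


def _smoothing_matrix_solve(y: np.ndarray, mu: float) -> np.ndarray:
    """Solve (I + mu DtD) f = y with D the second-difference operator."""
    n = y.size
    if n < 3:
        return y.astype(float).copy()
    D = sp.diags(
        [np.ones(n - 2), -2 * np.ones(n - 2), np.ones(n - 2)], [0, 1, 2], shape=(n - 2, n)
    )
    A = sp.eye(n) + mu * (D.T @ D)
    return spsolve(sp.csc_matrix(A), y.astype(float))


def detrend_series(series: pd.Series, cfg: DetrendConfig | None = None) -> pd.Series:
    """Detrend one ring-width series; returns index = raw / fitted.

    The fitted trend is a discrete cubic smoothing spline (second-difference
    penalized smoother) whose frequency response equals 0.5 at the configured
    wavelength: mu = (2 - 2 cos(2 pi / lambda))^-2. If the fitted curve is
    not strictly positive anywhere, the series falls back to horizontal-mean
    detrending (logged).
    """
    cfg = cfg or DetrendConfig()
    y = series.to_numpy(float)
    if y.size < cfg.spline_wavelength_years:
        raise ValueError("series shorter than the spline wavelength")
    omega = 2.0 * np.pi / cfg.spline_wavelength_years
    mu = (2.0 - 2.0 * np.cos(omega)) ** -2
    fitted = _smoothing_matrix_solve(y, mu)
    if np.any(fitted <= 0):
        logger.warning("detrend_series: non-positive fit for %s; mean detrend", series.name)
        fitted = np.full_like(y, y.mean())
        if np.any(fitted <= 0):
            raise ValueError("series mean non-positive; cannot detrend")
    return pd.Series(y / fitted, index=series.index, name=series.name)


def tukey_biweight_mean(x: np.ndarray, c: float = 9.0, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Tukey biweight robust location (c x MAD tuning), iterated to ``tol``."""
    x = np.asarray(x, float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return np.nan
    loc = np.median(x)
    for _ in range(max_iter):
        mad = np.median(np.abs(x - loc))
        if mad == 0:
            return float(loc)
        u = (x - loc) / (c * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            return float(loc)
        new = float(np.sum(w * x) / w.sum())
        if abs(new - loc) < tol:
            return new
        loc = new
    return float(loc)


def build_chronology(
    indexed: Mapping[str, pd.Series], min_trees: int = 3, cfg: DetrendConfig | None = None
) -> pd.Series:
    """Year-by-year Tukey biweight robust mean across trees of one provenance.

    Only years with at least ``min_trees`` contributing trees are included.
    """
    cfg = cfg or DetrendConfig()
    frame = pd.DataFrame({t: s for t, s in indexed.items()})
    counts = frame.notna().sum(axis=1)
    frame = frame.loc[counts >= min_trees]
    values = [
        tukey_biweight_mean(row.to_numpy(float), c=cfg.biweight_c)
        for _, row in frame.iterrows()
    ]
    return pd.Series(values, index=frame.index, name="chronology")


# -------------------------------------------------------- response functions


@dataclass
class ResponseResult:
    """Correlation of a chronology with a monthly climate variable."""

    coefficient: float  # Pearson r on the full year overlap
    boot_mean: float
    ci_low: float
    ci_high: float
    significant: bool
    n_years: int

    def __post_init__(self) -> None:
        if not (-1.0 <= self.coefficient <= 1.0):
            raise ValueError("coefficient outside [-1, 1]")
        if not (self.ci_low - 1e-12 <= self.boot_mean <= self.ci_high + 1e-12):
            raise ValueError("bootstrap mean outside its CI")


def bootstrap_response(
    chronology: pd.Series,
    climate_series: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> ResponseResult:
    """Bootstrapped correlation between a chronology and a climate series.

    Years are resampled with replacement ``n_boot`` times; the 95% CI is the
    2.5/97.5 percentile interval and the result is significant iff the CI
    excludes zero.
    """
    common = chronology.index.intersection(climate_series.index)
    if len(common) < 20:
        raise ValueError(f"only {len(common)} overlapping years (< 20)")
    x = chronology.loc[common].to_numpy(float)
    y = climate_series.loc[common].to_numpy(float)
    if y.std() == 0:
        raise ValueError("zero-variance climate series")
    r = float(stats.pearsonr(x, y).statistic)

    rng = np.random.default_rng(seed)
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    good = denom > 0
    rb = np.full(n_boot, np.nan)
    rb[good] = (xc * yc).sum(axis=1)[good] / denom[good]
    rb = rb[~np.isnan(rb)]
    lo, hi = np.percentile(rb, [2.5, 97.5])
    return ResponseResult(
        coefficient=r,
        boot_mean=float(rb.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 0 or hi < 0),
        n_years=int(n),
    )


def provenance_responses(
    rings: RingSeriesSet,
    climate_series: pd.Series,
    component: str = "earlywood",
    detrend_cfg: DetrendConfig | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Detrend, build chronologies and bootstrap responses per provenance."""
    detrend_cfg = detrend_cfg or DetrendConfig()
    rows = []
    for prov in rings.table["provenance"].astype(str).unique():
        indexed = {
            t: detrend_series(rings.series(t, component), detrend_cfg)
            for t in rings.trees_of(prov)
        }
        chron = build_chronology(indexed, cfg=detrend_cfg)
        res = bootstrap_response(chron, climate_series, n_boot=n_boot, seed=seed)
        rows.append(
            {
                "provenance": prov,
                "coef": res.coefficient,
                "boot_mean": res.boot_mean,
                "lo": res.ci_low,
                "hi": res.ci_high,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows).set_index("provenance")


def cline_regression(
    coefficients: pd.Series, env_component: pd.Series
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of response coefficients with an
    environmental PC across provenances."""
    common = coefficients.index.intersection(env_component.index)
    if len(common) < 5:
        raise ValueError("need >= 5 provenances")
    res = stats.pearsonr(
        coefficients.loc[common].to_numpy(float), env_component.loc[common].to_numpy(float)
    )
    return float(res.statistic), float(res.pvalue)


def monthly_series(site_climate: pd.DataFrame, variable: str, month: int) -> pd.Series:
    """Extract one month's values per year from the long site-climate table."""
    sub = site_climate[
        (site_climate["variable"] == variable) & (site_climate["month"] == month)
    ].sort_values("year")
    return pd.Series(sub["value"].to_numpy(float), index=sub["year"].to_numpy(int))
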