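"""Ancestry coefficients via least-squares matrix factorization, and
redundancy analysis (RDA) partitioning genotypic variance among predictors.

Ancestry replaces Bayesian MCMC clustering with the sparse nonnegative
factorization X ~ Q G (Q rows on the simplex, G allele frequencies in
[0, 1]) selected across K by a masked cross-entropy criterion. RDA models
centered dosages as per-locus multiple regressions on z-transformed
predictors; significance comes from a row-permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from provscan.core_io import GenotypeDataset
from provscan.scan_lfmm import impute_dosage

logger = logging.getLogger(__name__)


def _project_simplex(rows: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = rows.shape
    u = np.sort(rows, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(rows - theta[:, None], 0.0)


@dataclass
class AncestryFit:
    K: int
    Q: np.ndarray  # samples x K, rows on the simplex
    G: np.ndarray  # K x loci, allele frequencies in [0, 1]
    cross_entropy: float
    loss: float
    converged: bool


@dataclass
class AncestryResult:
    """Fits for each K plus the plateau-chosen K."""

    fits: dict[int, AncestryFit]
    chosen_k: int
    samples: list[str]

    @property
    def chosen(self) -> AncestryFit:
        return self.fits[self.chosen_k]

    def q_at(self, k: int) -> np.ndarray:
        return self.fits[k].Q


def _fit_single_k(
    X: np.ndarray, K: int, rng: np.random.Generator, tol: float = 1e-6, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Alternating nonnegative least squares for X ~ Q G on [0, 1] dosage/2."""
    n, L = X.shape
    if K == 1:
        Q = np.ones((n, 1))
        G = X.mean(axis=0, keepdims=True)
        loss = float(((X - Q @ G) ** 2).sum())
        return Q, G, loss, True
    Q = _project_simplex(rng.dirichlet(np.ones(K), size=n))
    G = np.clip(rng.random((K, L)), 0.05, 0.95)
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        # Q step: least squares rows projected to the simplex.
        Gt = G.T
        sol, *_ = np.linalg.lstsq(Gt, X.T, rcond=None)
        Q = _project_simplex(sol.T)
        # G step: least squares clipped to [0, 1].
        sol, *_ = np.linalg.lstsq(Q, X, rcond=None)
        G = np.clip(sol, 0.0, 1.0)
        loss = float(((X - Q @ G) ** 2).sum())
        if prev < np.inf and abs(prev - loss) <= tol * max(prev, 1e-30):
            converged = True
            prev = loss
            break
        prev = loss
    if not converged:
        logger.warning("snmf_ancestry: K=%d not converged", K)
    return Q, G, prev, converged


def _masked_cross_entropy(
    X_full: np.ndarray, Q: np.ndarray, G: np.ndarray, mask: np.ndarray
) -> float:
    """Binomial cross-entropy of held-out dosages against predicted QG."""
    if not mask.any():
        return float("nan")
    f = np.clip(Q @ G, 1e-6, 1 - 1e-6)
    x = 2.0 * X_full[mask]  # back to 0..2 allele counts
    return float(-np.mean(x * np.log(f[mask]) + (2.0 - x) * np.log(1.0 - f[mask])))


def snmf_ancestry(
    ds: GenotypeDataset,
    k_range: range = range(1, 9),
    masking_fraction: float = 0.05,
    seed: int = 0,
    plateau_rel: float = 0.01,
) -> AncestryResult:
    """Ancestry proportions across K with masked cross-entropy selection.

    The dosage matrix (mean-imputed, scaled to [0, 1]) is factorized as Q G
    for each K; a seeded fraction of entries is masked (replaced by column
    means during fitting) and their prediction cross-entropy scores each K.
    The chosen K is the smallest whose improvement over K-1 falls below
    ``plateau_rel`` (the plateau of the cross-entropy curve).
    """
    rng = np.random.default_rng(seed)
    X_full = impute_dosage(ds) / 2.0
    n, L = X_full.shape
    mask = rng.random((n, L)) < masking_fraction
    col_mean = X_full.mean(axis=0)
    X_train = np.where(mask, col_mean[None, :], X_full)

    fits: dict[int, AncestryFit] = {}
    for K in k_range:
        Q, G, loss, conv = _fit_single_k(X_train, K, np.random.default_rng(seed + 1000 + K))
        ce = _masked_cross_entropy(X_full, Q, G, mask)
        fits[K] = AncestryFit(K, Q, G, ce, loss, conv)

    ks = sorted(fits)
    chosen = ks[-1]
    for prev_k, k in zip(ks, ks[1:]):
        improvement = (fits[prev_k].cross_entropy - fits[k].cross_entropy) / abs(
            fits[prev_k].cross_entropy
        )
        if improvement < plateau_rel:
            chosen = prev_k
            break
    return AncestryResult(fits, chosen, list(ds.samples))


# ---------------------------------------------------------------------- RDA


@dataclass
class RdaResult:
    model: str
    r2: float
    adj_r2: float
    p_value: float | None
    n_permutations: int | None

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("R2 outside [0, 1]")
        if self.adj_r2 > self.r2 + 1e-12:
            raise ValueError("adjusted R2 above R2")


def _zscore(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant predictor column")
    return (X - X.mean(axis=0)) / sd


def rda_fit(Y: np.ndarray, X: np.ndarray, model: str = "rda") -> RdaResult:
    """Redundancy analysis R-squared of genotypes on predictors.

    Per-locus OLS of the centered dosage matrix on z-transformed X; R2 is the
    ratio of fitted to total sums of squares pooled over loci, adjusted by
    Ezekiel's formula with q = number of predictors.
    """
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, q = X.shape
    if n <= q + 1:
        raise ValueError("need n samples > predictors + 1")
    Xz = _zscore(X)
    if np.linalg.matrix_rank(Xz) < q:
        raise ValueError("collinear predictor matrix")
    Yc = Y - Y.mean(axis=0)
    Qx, _ = np.linalg.qr(Xz)
    fitted = Qx @ (Qx.T @ Yc)
    ss_total = float((Yc**2).sum())
    if ss_total == 0:
        raise ValueError("constant genotype matrix")
    r2 = float((fitted**2).sum() / ss_total)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)
    return RdaResult(model, r2, min(adj, r2), None, None)


def rda_permutation_test(
    Y: np.ndarray, X: np.ndarray, n_perm: int = 999, seed: int = 0, model: str = "rda"
) -> RdaResult:
    """Permutation p-value for :func:`rda_fit` by shuffling predictor rows."""
    base = rda_fit(Y, X, model)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    Y = np.asarray(Y, float)
    Yc = Y - Y.mean(axis=0)
    ss_total = float((Yc**2).sum())
    Xz = _zscore(X)
    Qx, _ = np.linalg.qr(Xz)
    rng = np.random.default_rng(seed)
    n = Y.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Qp = Qx[perm]
        # Re-center implicitly: permutation preserves column means of Xz.
        fitted = Qp @ (Qp.T @ Yc)
        r2p = (fitted**2).sum() / ss_total
        if r2p >= base.r2 - 1e-15:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return RdaResult(model, base.r2, base.adj_r2, p, n_perm)


def rda_models(
    Y: np.ndarray,
    climate_pc1: np.ndarray,
    climate_pc2: np.ndarray,
    latitude: np.ndarray,
    longitude: np.ndarray,
    ancestry_q: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """The standard battery: three combined and five individual models."""
    specs = {
        "climate": np.column_stack([climate_pc1, climate_pc2]),
        "geography": np.column_stack([latitude, longitude]),
        "ancestry": ancestry_q.reshape(-1, 1),
        "climate_pc1": climate_pc1.reshape(-1, 1),
        "climate_pc2": climate_pc2.reshape(-1, 1),
        "latitude": latitude.reshape(-1, 1),
        "longitude": longitude.reshape(-1, 1),
        "ancestry_q": ancestry_q.reshape(-1, 1),
    }
    rows = []
    for name, X in specs.items():
        res = rda_permutation_test(Y, X, n_perm=n_perm, seed=seed, model=name)
        rows.append(
            {
                "model": name,
                "r2": res.r2,
                "adj_r2": res.adj_r2,
                "p": res.p_value,
                "nperm": res.n_permutations,
            }
        )
    return pd.DataFrame(rows)
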