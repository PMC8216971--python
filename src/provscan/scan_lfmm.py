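"""Latent factor mixed model association of genotypes with environmental PCs.

The model is Y = X B^T + W + E with W a rank-K latent matrix absorbing
neutral structure. Estimation is deterministic alternating minimization
(ridge regression for B, truncated SVD for W); per-locus tests regress each
genotype column on [X, U] and are recalibrated by the genomic inflation
factor before Bonferroni / Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from provscan.core_io import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

#: Median of the chi-square(1) distribution, the GIF reference point.
CHI2_1_MEDIAN = float(stats.chi2.median(1))


def bonferroni_neglog10_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise threshold on the -log10 p scale: -log10(alpha / m)."""
    if n_tests < 1:
        raise ValueError("need >= 1 test")
    return float(-np.log10(alpha / n_tests))


def impute_dosage(ds: GenotypeDataset) -> np.ndarray:
    """Float dosage matrix with missing calls replaced by the locus mean."""
    X = ds.dosage.astype(float)
    X[X == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    return np.where(np.isnan(X), mu, X)


def choose_k(neutral_matrix: np.ndarray, k_max: int = 10) -> int:
    """Automatic scree-plot elbow on the neutral genotype matrix.

    Eigenvalues of the sample covariance are computed and K is the largest
    k <= k_max whose spacing (lambda_k - lambda_{k+1}) exceeds the mean
    spacing of the eigenvalue tail (the second half of the spectrum). Returns
    0 when no spacing stands out.
    """
    Y = np.asarray(neutral_matrix, float)
    if Y.shape[0] < 10:
        raise ValueError("need >= 10 samples")
    Yc = Y - Y.mean(axis=0)
    ev = np.linalg.svd(Yc, compute_uv=False) ** 2 / (Y.shape[0] - 1)
    if ev.size < 3:
        return 1
    spacings = -np.diff(ev)
    tail = spacings[spacings.size // 2 :]
    ref = tail.mean()
    k = 0
    for i in range(min(k_max, spacings.size)):
        # A structure eigenvalue must open a spacing well above the tail's AND
        # stand clear of its successor in relative terms; the spacing rule
        # alone fires on the smooth noise-bulk edge.
        if spacings[i] > 5.0 * ref and ev[i] > 1.3 * ev[i + 1]:
            k = i + 1
    return k


@dataclass
class LfmmFit:
    """Converged (or flagged) decomposition Y ~ X B^T + U V^T."""

    Y: np.ndarray  # centered n x L genotype matrix
    X: np.ndarray  # n x d standardized environmental design
    B: np.ndarray  # L x d effects
    U: np.ndarray  # n x K latent factors
    V: np.ndarray  # L x K latent loadings
    K: int
    ridge: float
    objective: float
    n_iter: int
    converged: bool
    locus_ids: list[str]
    axis_names: list[str]

    @property
    def residual(self) -> np.ndarray:
        return self.Y - self.X @ self.B.T - self.U @ self.V.T


def lfmm_fit(
    Y: np.ndarray,
    X: np.ndarray,
    K: int,
    ridge: float = 1e-5,
    tol: float = 1e-8,
    max_iter: int = 200,
    locus_ids: list[str] | None = None,
    axis_names: list[str] | None = None,
    projected: bool = False,
) -> LfmmFit:
    """Alternating minimization of ||Y - XB^T - UV^T||^2 + ridge ||B||^2.

    Y is centered per locus and X column-standardized internally. Starting
    from B = 0, each iteration takes (U, V) as the rank-K truncated SVD of
    Y - XB^T and then B as the ridge regression of Y - UV^T on X. The
    procedure is SVD-initialized and fully deterministic.

    By default the latent factors are free to absorb genotype variance shared
    between structure and environment (conservative under confounding). With
    ``projected=True`` the latent step instead uses the X-orthogonal part of
    the residual, which identifies (B, W) when the true latent factors are
    orthogonal to X, at the cost of attributing shared variance to B.
    """
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    n, L = Y.shape
    d = X.shape[1]
    if n <= d + K:
        raise ValueError(f"need n > d + K ({n} <= {d + K})")
    Yc = Y - Y.mean(axis=0)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)

    XtX = Xs.T @ Xs + ridge * np.eye(d)
    Qx, _ = np.linalg.qr(Xs)
    U = np.zeros((n, K))
    V = np.zeros((L, K))
    B = np.zeros((L, d))
    prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # (U, V) <- rank-K SVD of Y - XB^T (optionally X-orthogonalized)
        if K > 0:
            R = Yc - Xs @ B.T
            if projected:
                R = R - Qx @ (Qx.T @ R)
            uu, ss, vvt = np.linalg.svd(R, full_matrices=False)
            U = uu[:, :K] * ss[:K]
            V = vvt[:K].T
        # B <- ridge regression of Y - UV^T on X
        R2 = Yc - U @ V.T
        B = np.linalg.solve(XtX, Xs.T @ R2).T
        resid = Yc - Xs @ B.T - U @ V.T
        obj = float((resid**2).sum() + ridge * (B**2).sum())
        if prev < np.inf and abs(prev - obj) <= tol * max(prev, 1e-30):
            converged = True
            prev = obj
            break
        prev = obj
    if not converged:
        logger.warning("lfmm_fit: not converged after %d iterations", it)
    return LfmmFit(
        Y=Yc,
        X=Xs,
        B=B,
        U=U,
        V=V,
        K=K,
        ridge=ridge,
        objective=prev,
        n_iter=it,
        converged=converged,
        locus_ids=locus_ids or [f"L{j}" for j in range(L)],
        axis_names=axis_names or [f"PC{j + 1}" for j in range(d)],
    )


@dataclass
class LfmmTest:
    """Per-locus, per-axis association tests with GIF recalibration."""

    table: pd.DataFrame  # columns: locus, axis, z, p_raw, p_cal, bonferroni, fdr
    gif: dict[str, float]  # per-axis genomic inflation factor
    bonferroni_neglog10: float

    def __post_init__(self) -> None:
        p = self.table["p_cal"].to_numpy(float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("calibrated p outside (0, 1]")
        if any(g <= 0 for g in self.gif.values()):
            raise ValueError("GIF must be > 0")


def lfmm_test(fit: LfmmFit, alpha: float = 0.05, fdr_level: float = 0.05) -> LfmmTest:
    """Per-locus least-squares tests of each environmental axis given [X, U].

    z is the t-statistic of the axis coefficient; the genomic inflation
    factor lambda_GC = median(z^2) / median(chi2_1) recalibrates p per axis;
    flags are Bonferroni at alpha/m and Benjamini-Hochberg at ``fdr_level``.
    """
    from statsmodels.stats.multitest import multipletests

    n, L = fit.Y.shape
    d = fit.X.shape[1]
    D = [np.ones((n, 1)), fit.X]
    if fit.K > 0:
        # Guard against latent columns collinear with the design.
        q = np.linalg.matrix_rank(np.hstack([np.ones((n, 1)), fit.X, fit.U]))
        U = fit.U
        if q < 1 + d + fit.K:
            keep = []
            base = np.hstack([np.ones((n, 1)), fit.X])
            for k in range(fit.K):
                cand = np.hstack([base] + [fit.U[:, keep + [k]]])
                if np.linalg.matrix_rank(cand) == base.shape[1] + len(keep) + 1:
                    keep.append(k)
            logger.warning("lfmm_test: dropped %d collinear latent columns", fit.K - len(keep))
            U = fit.U[:, keep]
        D.append(U)
    Dm = np.hstack(D)
    q = Dm.shape[1]

    G = np.linalg.inv(Dm.T @ Dm)
    coefs = G @ Dm.T @ fit.Y  # q x L
    resid = fit.Y - Dm @ coefs
    dof = n - q
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(G), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = coefs / se

    m = L
    bonf = bonferroni_neglog10_threshold(m, alpha)
    rows = []
    gif = {}
    for a in range(d):
        z = tstat[1 + a]
        z = np.where(np.isfinite(z), z, 0.0)
        lam = float(np.median(z**2) / CHI2_1_MEDIAN)
        lam = max(lam, 1e-12)
        gif[fit.axis_names[a]] = lam
        p_raw = 2.0 * stats.t.sf(np.abs(z), dof)
        p_cal = stats.chi2.sf(z**2 / lam, 1)
        p_cal = np.clip(p_cal, np.finfo(float).tiny, 1.0)
        fdr_flags = multipletests(p_cal, alpha=fdr_level, method="fdr_bh")[0]
        for j in range(L):
            rows.append(
                {
                    "locus": fit.locus_ids[j],
                    "axis": fit.axis_names[a],
                    "z": z[j],
                    "p_raw": max(p_raw[j], np.finfo(float).tiny),
                    "p_cal": p_cal[j],
                    "bonferroni": -np.log10(p_cal[j]) > bonf,
                    "fdr": bool(fdr_flags[j]),
                }
            )
    logger.info("lfmm_test: genomic inflation factors %s", gif)
    return LfmmTest(pd.DataFrame(rows), gif, bonf)
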