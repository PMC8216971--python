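"""Environment-aware Bayesian genome scans.

Two scans operate on per-deme allele frequencies:

* a covariance-controlled association scan: standardized deme frequencies are
  whitened by the Cholesky factor of a neutral-SNP covariance matrix and a
  closed-form conjugate Bayes factor compares the linear model with and
  without the environmental regressor (plus a Spearman backup statistic);
* an F-model comparison: per locus the neutral model (alpha = 0), a
  locus-specific model (alpha free) and an environmental model
  (alpha = g * E_i) are fit by maximum likelihood under a beta-binomial
  differentiation model, ranked by BIC-approximated marginal likelihoods, and
  converted to posterior error probabilities and q-values.

Both replace MCMC machinery with deterministic estimators of the same models
and use the same decision rules (BF > 30 with |rho| > 0.4; -log10 q > 1.3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln

from provscan.core_io import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


# --------------------------------------------------------- deme frequencies


def deme_allele_counts(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(alt allele counts, called allele totals) per deme x locus."""
    labels = ds.provenance_labels()
    provs = ds.provenances
    D, L = len(provs), ds.n_loci
    alt = np.zeros((D, L))
    tot = np.zeros((D, L))
    for i, p in enumerate(provs):
        rows = ds.dosage[labels == p]
        obs = rows != MISSING
        alt[i] = np.where(obs, rows, 0).sum(axis=0)
        tot[i] = 2.0 * obs.sum(axis=0)
    return alt, tot, provs


def deme_frequencies(ds: GenotypeDataset) -> tuple[np.ndarray, list[str]]:
    alt, tot, provs = deme_allele_counts(ds)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, alt / tot, np.nan), provs


# ------------------------------------------------------------------- Omega


@dataclass
class OmegaMatrix:
    """Deme covariance of standardized allele frequencies, with Cholesky."""

    omega: np.ndarray
    chol: np.ndarray  # lower-triangular L with L L^T = omega
    demes: list[str]
    ridge: float

    @property
    def dim(self) -> int:
        return self.omega.shape[0]


def _center_scale(freqs: np.ndarray) -> np.ndarray:
    """(p_i - pbar) / sqrt(pbar (1 - pbar)) per locus, pbar the deme mean."""
    pbar = freqs.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (freqs - pbar) / np.sqrt(pbar * (1.0 - pbar))


def estimate_omega(
    neutral_freqs: np.ndarray, demes: list[str], max_cond: float = 1e8
) -> OmegaMatrix:
    """Average outer product of centered-scaled neutral frequency vectors.

    A ridge eps*I is added (doubling from a tiny start) until the condition
    number falls below ``max_cond``.
    """
    D, L = neutral_freqs.shape
    if L < 100:
        raise ValueError("need >= 100 neutral loci")
    C = _center_scale(neutral_freqs)
    ok = ~np.any(np.isnan(C), axis=0)
    C = C[:, ok]
    omega = (C @ C.T) / C.shape[1]

    eps = 0.0
    trial = omega.copy()
    base = 1e-10 * np.trace(omega) / D
    while np.linalg.cond(trial) > max_cond:
        eps = base if eps == 0.0 else eps * 2.0
        if eps > np.trace(omega):
            raise np.linalg.LinAlgError("omega singular even after maximal ridge")
        trial = omega + eps * np.eye(D)
    chol = np.linalg.cholesky(trial)
    return OmegaMatrix(trial, chol, demes, eps)


# ------------------------------------------------------------- Bayes factor


@dataclass
class EnvAssocResult:
    """Per-locus Bayes factor and Spearman backup statistic."""

    table: pd.DataFrame  # columns: locus, axis, bf, rho, shortlist

    def __post_init__(self) -> None:
        bf = self.table["bf"].to_numpy(float)
        if np.any(bf <= 0):
            raise ValueError("Bayes factors must be > 0")


def _log_marginal(z: np.ndarray, D: np.ndarray, sigma_beta: float) -> float:
    """log N(z; 0, I + sigma_beta^2 D D^T) for regressor matrix D."""
    n = z.size
    cov = np.eye(n) + sigma_beta**2 * (D @ D.T)
    sign, logdet = np.linalg.slogdet(cov)
    sol = np.linalg.solve(cov, z)
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + z @ sol))


def env_bayes_factor(
    freqs: np.ndarray,
    env: np.ndarray,
    omega: OmegaMatrix,
    locus_ids: list[str],
    axis_name: str = "PC1",
    sigma_beta: float = 1.0,
    bf_threshold: float = 30.0,
    rho_threshold: float = 0.4,
) -> EnvAssocResult:
    """Closed-form conjugate Bayes factors for env association per locus.

    The locus's centered-scaled frequency vector is whitened by the inverse
    Cholesky factor of omega; the Bayes factor compares the Gaussian linear
    model (unit residual variance, N(0, sigma_beta^2) coefficients) with
    regressors (intercept, env) against intercept alone. Monomorphic loci get
    BF = 1 and rho = 0.
    """
    env = np.asarray(env, float)
    e = (env - env.mean()) / env.std()
    Linv = np.linalg.inv(omega.chol)
    e_t = Linv @ e
    i_t = Linv @ np.ones(omega.dim)
    D1 = i_t[:, None]
    D2 = np.column_stack([i_t, e_t])

    C = _center_scale(freqs)
    rows = []
    for j, lid in enumerate(locus_ids):
        c = C[:, j]
        if np.any(np.isnan(c)):
            bf, rho = 1.0, 0.0
        else:
            z = Linv @ c
            bf = float(np.exp(_log_marginal(z, D2, sigma_beta) - _log_marginal(z, D1, sigma_beta)))
            rho = float(stats.spearmanr(z, e_t).statistic)
        rows.append(
            {
                "locus": lid,
                "axis": axis_name,
                "bf": bf,
                "rho": rho,
                "shortlist": bf > bf_threshold and abs(rho) > rho_threshold,
            }
        )
    return EnvAssocResult(pd.DataFrame(rows))


# ----------------------------------------------------------------- F-model


@dataclass
class FModelResult:
    """Per-locus model comparison (neutral / locus-specific / environmental)."""

    table: pd.DataFrame  # columns: locus, axis, pm0, pm1, pm2, pep, q, shortlist
    beta: np.ndarray  # deme effects from stage 1

    def __post_init__(self) -> None:
        pm = self.table[["pm0", "pm1", "pm2"]].to_numpy(float)
        if np.any(np.abs(pm.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("model probabilities must sum to 1")
        q = self.table.sort_values("pep")["q"].to_numpy(float)
        if np.any(np.diff(q) < -1e-12):
            raise ValueError("q-values must be monotone in PEP rank")


def _betabinom_logpmf(k: np.ndarray, n: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + gammaln(k + a)
        + gammaln(n - k + b)
        - gammaln(n + a + b)
        + gammaln(a + b)
        - gammaln(a)
        - gammaln(b)
    )


def _loglik(alt: np.ndarray, tot: np.ndarray, pbar: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Beta-binomial log likelihood per deme x locus (broadcastable theta)."""
    theta = np.clip(theta, 1e-6, 1 - 1e-6)
    p = np.clip(pbar, 1e-6, 1 - 1e-6)
    a = p * (1 - theta) / theta
    b = (1 - p) * (1 - theta) / theta
    return _betabinom_logpmf(alt, tot, a, b)


def _grid_ml(fun, lo: float = -6.0, hi: float = 6.0, coarse: int = 61, fine: int = 41):
    """Deterministic 1-D ML by coarse grid + local refinement.

    ``fun`` maps a grid array (G,) to a log-likelihood array (G, L); returns
    (best values (L,), best loglik (L,)).
    """
    grid = np.linspace(lo, hi, coarse)
    ll = fun(grid)
    best = np.argmax(ll, axis=0)
    step = grid[1] - grid[0]
    centers = grid[best]
    out_val = np.empty(centers.size)
    out_ll = np.empty(centers.size)
    fine_off = np.linspace(-step, step, fine)
    # refine all loci at once on a shared offset grid around each center
    ll2 = fun(fine_off[:, None] + centers[None, :], per_locus_grid=True)
    b2 = np.argmax(ll2, axis=0)
    out_val = centers + fine_off[b2]
    out_ll = ll2[b2, np.arange(centers.size)]
    return out_val, out_ll


def fmodel_env_scan(
    alt: np.ndarray,
    tot: np.ndarray,
    env: np.ndarray,
    locus_ids: list[str],
    axis_name: str = "PC1",
    pi: float = 0.1,
    p_env: float = 0.5,
    q_threshold: float = 0.05,
    signed_env: bool = False,
) -> FModelResult:
    """Three-model comparison per locus with BIC marginals and q-values.

    Differentiation follows logit(theta_ij) = beta_i + alpha_j; stage 1 fits
    the deme effects beta_i by ML over all loci with alpha = 0, stage 2 fits
    per locus the free-alpha model (M1) and the environmental model
    alpha = g * E_i (M2, E_i the absolute standardized environment by
    default). Priors: P(M1 or M2) = pi, P(M2 | non-neutral) = p_env. PEP =
    1 - P(M2|data); the q-value of a locus is the running mean of PEPs at or
    below its own.
    """
    alt = np.asarray(alt, float)
    tot = np.asarray(tot, float)
    env = np.asarray(env, float)
    D, L = alt.shape
    e = (env - env.mean()) / env.std()
    E = e if signed_env else np.abs(e)

    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = alt.sum(axis=0) / tot.sum(axis=0)  # per-locus pooled frequency
    pbar = np.clip(pbar, 1e-6, 1 - 1e-6)

    # Stage 1: deme effects with alpha = 0 (1-D ML per deme).
    beta = np.empty(D)
    grid = np.linspace(-8.0, 2.0, 201)
    for i in range(D):
        theta = expit(grid)[:, None]
        ll = _loglik(alt[i][None, :], tot[i][None, :], pbar[None, :], theta).sum(axis=1)
        beta[i] = grid[np.argmax(ll)]

    # Model log likelihoods.
    theta0 = expit(beta)[:, None]
    ll0 = _loglik(alt, tot, pbar[None, :], theta0).sum(axis=0)

    def ll_alpha(a_grid: np.ndarray, per_locus_grid: bool = False) -> np.ndarray:
        # theta: (G, D, L) -> sum over demes -> (G, L)
        if per_locus_grid:
            th = expit(beta[None, :, None] + a_grid[:, None, :])
        else:
            th = expit(beta[None, :, None] + a_grid[:, None, None])
        return _loglik(alt[None], tot[None], pbar[None, None, :], th).sum(axis=1)

    def ll_g(g_grid: np.ndarray, per_locus_grid: bool = False) -> np.ndarray:
        if per_locus_grid:
            th = expit(beta[None, :, None] + g_grid[:, None, :] * E[None, :, None])
        else:
            th = expit(beta[None, :, None] + g_grid[:, None, None] * E[None, :, None])
        return _loglik(alt[None], tot[None], pbar[None, None, :], th).sum(axis=1)

    _, ll1 = _grid_ml(ll_alpha)
    _, ll2 = _grid_ml(ll_g)
    # A free parameter can never fit worse than its alpha=0 special case.
    ll1 = np.maximum(ll1, ll0)
    ll2 = np.maximum(ll2, ll0)

    # BIC-approximated log marginals: penalize each free parameter by log(D)/2.
    pen = 0.5 * np.log(D)
    lm = np.stack([ll0, ll1 - pen, ll2 - pen])  # 3 x L
    lpri = np.log(np.array([1 - pi, pi * (1 - p_env), pi * p_env]))[:, None]
    post = lm + lpri
    post -= post.max(axis=0, keepdims=True)
    w = np.exp(post)
    w /= w.sum(axis=0, keepdims=True)

    pep = 1.0 - w[2]
    order = np.argsort(pep, kind="stable")
    pep_sorted = pep[order]
    q_running = np.minimum(np.cumsum(pep_sorted) / np.arange(1, L + 1), 1.0)
    # ties share the q of the last tied position (mean PEP over PEP <= own)
    last_tie = np.searchsorted(pep_sorted, pep_sorted, side="right") - 1
    q = np.empty(L)
    q[order] = q_running[last_tie]

    table = pd.DataFrame(
        {
            "locus": locus_ids,
            "axis": axis_name,
            "pm0": w[0],
            "pm1": w[1],
            "pm2": w[2],
            "pep": pep,
            "q": q,
            "shortlist": q < q_threshold,
        }
    )
    return FModelResult(table, beta)
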