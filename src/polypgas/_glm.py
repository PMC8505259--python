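"""Vectorised logistic regression for genome-wide scans.

All SNP models share the same covariate block and differ only in the final
dosage column, so Newton/IRLS can be batched across SNPs: the covariate
cross-product block is assembled for every SNP at once from a precomputed
pairwise-product matrix, per-SNP sample masks (missing genotypes) enter as
zero IRLS weights, and the (k+1)x(k+1) systems are solved with a single
batched ``numpy.linalg.solve``.  Agreement with per-SNP maximum-likelihood
fits (statsmodels) is at the 1e-6 level for well-conditioned problems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

STATUS_OK = "ok"
STATUS_MONOMORPHIC = "monomorphic"
STATUS_NOT_CONVERGED = "not_converged"
STATUS_SEPARATED = "separated"

_BETA_BOUND = 15.0  # |log-odds per allele| beyond this flags separation


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35.0, 35.0)))


def fit_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 60,
                 tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, bool]:
    """Single logistic ML fit; returns (beta, covariance, converged)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        mu = _sigmoid(X @ beta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        delta = np.linalg.solve(hess, grad)
        np.clip(delta, -5.0, 5.0, out=delta)
        beta += delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    mu = _sigmoid(X @ beta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    return beta, cov, converged


def logistic_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(X @ beta, -35.0, 35.0)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


@dataclass
class BatchGwasFit:
    beta: np.ndarray       # per-SNP log-odds per A1 allele
    se: np.ndarray
    p: np.ndarray          # Wald two-sided; NaN when status != ok
    n_used: np.ndarray
    status: np.ndarray     # object array of status strings


def gwas_logistic_batch(G: np.ndarray, y: np.ndarray, C: np.ndarray,
                        max_iter: int = 16, tol: float = 1e-8,
                        block_size: int = 2048) -> BatchGwasFit:
    """Per-SNP logistic Wald tests with shared covariates.

    Parameters
    ----------
    G : (n, m) float array of allele dosages, NaN = missing (that sample is
        dropped for that SNP only).
    y : (n,) binary outcome (0/1), no missing values.
    C : (n, k) covariate matrix including the intercept column.
    """
    y = np.asarray(y, dtype=np.float64)
    if np.all(y == y[0]):
        raise ValueError("phenotype is constant; logistic model undefined")
    C = np.asarray(C, dtype=np.float64)
    n, k = C.shape
    m = G.shape[1]

    # warm start from the covariate-only (null) fit on the full sample
    beta0, _, _ = fit_logistic(C, y)

    iu = np.triu_indices(k)
    P = C[:, iu[0]] * C[:, iu[1]]  # (n, k(k+1)/2) pairwise products

    beta = np.empty(m)
    se = np.empty(m)
    pvals = np.full(m, np.nan)
    n_used = np.empty(m, dtype=np.int64)
    status = np.empty(m, dtype=object)

    for start in range(0, m, block_size):
        sl = slice(start, min(start + block_size, m))
        Gb = np.asarray(G[:, sl], dtype=np.float64)
        B = Gb.shape[1]
        mask = np.isfinite(Gb)
        Gz = np.where(mask, Gb, 0.0)
        nb = mask.sum(axis=0)
        n_used[sl] = nb

        # monomorphic within the used samples
        gsum = Gz.sum(axis=0)
        gmean = np.divide(gsum, nb, out=np.zeros(B), where=nb > 0)
        gvar = np.divide((Gz**2).sum(axis=0), nb, out=np.zeros(B), where=nb > 0)
        gvar -= gmean**2
        mono = (gvar <= 1e-12) | (nb < k + 2)

        theta = np.tile(np.append(beta0, 0.0), (B, 1))  # (B, k+1)
        active = ~mono
        converged = np.zeros(B, dtype=bool)
        H = np.zeros((B, k + 1, k + 1))
        for _ in range(max_iter):
            if not active.any():
                break
            eta = C @ theta[:, :k].T + Gz * theta[:, k]
            mu = _sigmoid(eta)
            w = mu * (1 - mu) * mask
            r = (y[:, None] - mu) * mask

            A = P.T @ w                      # (k(k+1)/2, B) covariate block
            Hcg = C.T @ (w * Gz)             # (k, B)
            Hgg = (w * Gz * Gz).sum(axis=0)  # (B,)
            gc = C.T @ r                     # (k, B)
            gg = (Gz * r).sum(axis=0)        # (B,)

            H[:, iu[0], iu[1]] = A.T
            H[:, iu[1], iu[0]] = A.T
            H[:, :k, k] = Hcg.T
            H[:, k, :k] = Hcg.T
            H[:, k, k] = Hgg
            grad = np.concatenate([gc.T, gg[:, None]], axis=1)

            idx = np.flatnonzero(active)
            try:
                delta = np.linalg.solve(H[idx], grad[idx][..., None])[..., 0]
            except np.linalg.LinAlgError:
                delta = np.stack(
                    [_safe_solve(H[i], grad[i]) for i in idx], axis=0
                )
            np.clip(delta, -4.0, 4.0, out=delta)
            theta[idx] += delta
            done = np.max(np.abs(delta), axis=1) < tol
            converged[idx[done]] = True
            active[idx[done]] = False

        # final information matrix at the solution for SEs
        eta = C @ theta[:, :k].T + Gz * theta[:, k]
        mu = _sigmoid(eta)
        w = mu * (1 - mu) * mask
        A = P.T @ w
        Hcg = C.T @ (w * Gz)
        Hgg = (w * Gz * Gz).sum(axis=0)
        H[:, iu[0], iu[1]] = A.T
        H[:, iu[1], iu[0]] = A.T
        H[:, :k, k] = Hcg.T
        H[:, k, :k] = Hcg.T
        H[:, k, k] = Hgg

        bb = theta[:, k]
        ses = np.full(B, np.nan)
        ok_idx = np.flatnonzero(~mono)
        if ok_idx.size:
            try:
                inv = np.linalg.inv(H[ok_idx])
                ses[ok_idx] = np.sqrt(np.maximum(inv[:, k, k], 0.0))
            except np.linalg.LinAlgError:
                for i in ok_idx:
                    try:
                        ses[i] = np.sqrt(max(np.linalg.inv(H[i])[k, k], 0.0))
                    except np.linalg.LinAlgError:
                        ses[i] = np.nan

        st = np.full(B, STATUS_OK, dtype=object)
        st[mono] = STATUS_MONOMORPHIC
        separated = (~mono) & ((np.abs(bb) > _BETA_BOUND) | ~np.isfinite(ses))
        st[separated] = STATUS_SEPARATED
        unconv = (~mono) & (~separated) & (~converged)
        st[unconv] = STATUS_NOT_CONVERGED

        okay = st == STATUS_OK
        z = np.divide(bb, ses, out=np.full(B, np.nan), where=okay & (ses > 0))
        pv = np.full(B, np.nan)
        pv[okay] = 2.0 * stats.norm.sf(np.abs(z[okay]))
        # p-values live in (0, 1]; clip underflow to the smallest positive float
        pv[okay] = np.clip(pv[okay], np.finfo(float).tiny, 1.0)

        beta[sl] = bb
        se[sl] = ses
        pvals[sl] = pv
        status[sl] = st

    return BatchGwasFit(beta=beta, se=se, p=pvals, n_used=n_used, status=status)


def _safe_solve(H: np.ndarray, g: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(H, g)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(H, g, rcond=None)[0]
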