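"""REML machinery for variance components and BLUP.

Two fitting routes are provided:

* :func:`reml_single` -- one kinship plus residual, solved after a single
  eigendecomposition of K (the EMMA trick): the REML log-likelihood is
  profiled over the heritability ratio ``h = sigma2_g / (sigma2_g + sigma2_e)``
  and maximised by bounded scalar search.  Used by GBLUP and the mixed random
  forest.
* :func:`reml_multi` -- an arbitrary list of kinships plus residual, with the
  REML log-likelihood evaluated by Cholesky factorisation and maximised by
  derivative-free (Nelder-Mead) search over log-variances.  Used for the
  additive + epistatic heritability decomposition, where the two covariance
  matrices cannot be diagonalised jointly.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg, optimize

__all__ = ["reml_single", "reml_multi", "blup_solve", "standardize_genotypes"]

_JITTER = 1e-8


def standardize_genotypes(Z: np.ndarray):
    """Center and scale columns to unit variance, dropping monomorphic ones.

    Returns ``(Zs, mean, std, kept)`` where *kept* is a boolean column mask.
    """
    Z = np.asarray(Z, dtype=float)
    mean = Z.mean(axis=0)
    std = Z.std(axis=0)
    kept = std > 0
    if not kept.any():
        raise ValueError("all genotype columns are monomorphic")
    Zs = (Z[:, kept] - mean[kept]) / std[kept]
    return Zs, mean, std, kept


def _check_psd(K: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("kinship matrix is not symmetric")
    w = linalg.eigvalsh(K)
    if w.min() < -tol * max(1.0, w.max()):
        raise ValueError(f"kinship matrix is not PSD (min eigenvalue {w.min():.3g})")
    return K


def reml_single(y: np.ndarray, K: np.ndarray, check: bool = True):
    """REML fit of ``y = mu + g + e`` with one kinship.

    Returns ``(sigma2_g, sigma2_e)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if np.var(y) == 0:
        return 0.0, 0.0
    if check:
        K = _check_psd(K)
    lam, U = linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg_reml(h):
        w = h * lam + (1.0 - h)
        wi = 1.0 / w
        xwx = np.sum(xt * wi * xt)
        beta = np.sum(xt * wi * yt) / xwx
        r = yt - xt * beta
        rss = np.sum(r * wi * r)
        s2 = rss / (n - 1)
        return 0.5 * ((n - 1) * np.log(s2) + np.sum(np.log(w)) + np.log(xwx))

    res = optimize.minimize_scalar(
        neg_reml, bounds=(0.0, 1.0 - 1e-9), method="bounded",
        options={"xatol": 1e-10},
    )
    h = float(res.x)
    # compare against the boundary h=0 explicitly
    if neg_reml(0.0) <= res.fun:
        h = 0.0
    w = h * lam + (1.0 - h)
    wi = 1.0 / w
    xwx = np.sum(xt * wi * xt)
    beta = np.sum(xt * wi * yt) / xwx
    r = yt - xt * beta
    s2 = float(np.sum(r * wi * r) / (n - 1))
    return h * s2, (1.0 - h) * s2


def _neg_reml_multi(log_vars, y, Ks, X):
    n = len(y)
    V = np.zeros((n, n))
    for lv, K in zip(log_vars[:-1], Ks):
        V += np.exp(lv) * K
    V += (np.exp(log_vars[-1]) + _JITTER) * np.eye(n)
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        return 1e12
    logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_y = linalg.cho_solve((L, True), y)
    Vi_X = linalg.cho_solve((L, True), X)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ beta
    return 0.5 * (logdet_v + logdet_x + float(y @ Py))


def reml_multi(y: np.ndarray, Ks: list[np.ndarray], check: bool = True,
               max_iter: int = 2000):
    """REML fit of ``y = mu + sum_k g_k + e`` with several kinships.

    Returns ``(variances, sigma2_e, converged)`` where *variances* aligns with
    *Ks*.  Variances are constrained positive via a log parameterisation, so
    boundary solutions come out as numerically negligible values.
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.var(y) == 0:
        raise ValueError("constant response: variance components undefined")
    if check:
        Ks = [_check_psd(K) for K in Ks]
    n = len(y)
    X = np.ones((n, 1))
    vy = float(np.var(y))
    k = len(Ks) + 1

    starts = [
        np.log(np.full(k, vy / k)),
        np.log(np.r_[np.full(k - 1, 0.05 * vy), 0.95 * vy]),
        np.log(np.r_[np.full(k - 1, 0.45 * vy / max(k - 1, 1)), 0.55 * vy]),
    ]
    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            _neg_reml_multi, x0, args=(y, Ks, X), method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": 1e-6, "fatol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    if not converged:
        warnings.warn("REML did not fully converge; returning best iterate")
    v = np.exp(best.x)
    return v[:-1], float(v[-1]), converged


def blup_solve(K_tt: np.ndarray, r: np.ndarray, sigma2_g: float, sigma2_e: float,
               K_xt: np.ndarray | None = None) -> np.ndarray:
    """BLUP of the random effect from residuals ``r`` on the training block.

    ``g_hat = sigma2_g * K (sigma2_g*K + sigma2_e*I)^-1 r``; with ``K_xt``
    given, the effect is projected onto new strains via the cross-kinship.
    """
    n = len(r)
    if sigma2_g <= 0:
        m = n if K_xt is None else len(K_xt)
        return np.zeros(m)
    A = sigma2_g * K_tt + sigma2_e * np.eye(n)
    alpha = linalg.solve(A, r, assume_a="pos")
    proj = K_tt if K_xt is None else K_xt
    return sigma2_g * (proj @ alpha)
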