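"""Gaussian random-intercept linear mixed model, profiled over the variance
ratio.

The prioritization regressions model the GWAS chi-squared value of variant
*j* in LD block *i* as

    Y_ij = x_ij' beta + V_i + eps_ij,    V_i ~ N(0, s2_b),  eps ~ N(0, s2_e)

with a fixed-effect design ``x`` holding the intercept and TF-occupancy
indicators.  For a single random intercept the marginal covariance is
``s2_e (I + lam Z Z')`` with ``lam = s2_b / s2_e``, whose inverse is
block-diagonal with the closed form ``I - lam/(1 + lam n_i) J`` per block.
Both the GLS estimate and the (RE)ML log-likelihood therefore reduce to
per-block group sums, making one fit O(n) — cheap enough for the thousands
of refits the null-calibration study performs.  ``lam`` is maximized by 1-D
bounded search on the log scale (tolerance 1e-8 on the log-likelihood);
``var_ratio`` may be fixed (0 recovers OLS exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

_LOGLAM_LO, _LOGLAM_HI = -12.0, 8.0


@dataclass
class RandomInterceptFit:
    """Result of one random-intercept LMM fit."""

    coef: np.ndarray          # fixed effects, in design-column order
    se: np.ndarray            # Wald standard errors
    sigma2_e: float           # residual variance
    sigma2_b: float           # random-intercept (block) variance
    loglik: float             # maximized (restricted) log-likelihood
    reml: bool
    converged: bool
    n_obs: int
    n_groups: int

    @property
    def wald_z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def wald_p(self) -> np.ndarray:
        """Two-sided normal p-values for each fixed effect."""
        return 2.0 * stats.norm.sf(np.abs(self.wald_z))


def _profiled(y, X, codes, n_groups, lam, reml):
    """Profiled negative log-likelihood and GLS pieces at a fixed lam.

    Returns (nll, beta, cov_unscaled, sigma2_e) where ``cov_unscaled`` is
    (X' A X)^{-1} so that cov(beta) = sigma2_e * cov_unscaled.
    """
    n, p = X.shape
    group_n = np.bincount(codes, minlength=n_groups).astype(float)
    c = lam / (1.0 + lam * group_n)  # per-group shrinkage weight

    # group sums of X columns and y
    Xs = np.zeros((n_groups, p))
    for j in range(p):
        Xs[:, j] = np.bincount(codes, weights=X[:, j], minlength=n_groups)
    ys = np.bincount(codes, weights=y, minlength=n_groups)

    XtAX = X.T @ X - (Xs * c[:, None]).T @ Xs
    XtAy = X.T @ y - (Xs * c[:, None]).T @ ys
    ytAy = float(y @ y - c @ (ys ** 2))

    try:
        cov_unscaled = np.linalg.inv(XtAX)
    except np.linalg.LinAlgError:
        return np.inf, np.full(p, np.nan), np.full((p, p), np.nan), np.nan
    beta = cov_unscaled @ XtAy
    rss = ytAy - float(beta @ XtAy)
    rss = max(rss, 1e-300)
    logdet_V = float(np.log1p(lam * group_n).sum())  # log|I + lam ZZ'|
    if reml:
        dof = n - p
        sigma2 = rss / dof
        sign, logdet_XtAX = np.linalg.slogdet(XtAX)
        if sign <= 0:
            return np.inf, beta, cov_unscaled, sigma2
        nll = 0.5 * (dof * np.log(sigma2) + logdet_V + logdet_XtAX + dof)
    else:
        sigma2 = rss / n
        nll = 0.5 * (n * np.log(sigma2) + logdet_V + n)
    return nll, beta, cov_unscaled, sigma2


def fit_random_intercept(y, X, groups, reml: bool = True,
                         var_ratio: float | None = None,
                         tol: float = 1e-8) -> RandomInterceptFit:
    """Fit ``y = X beta + V_group + eps`` with a per-group random intercept.

    Parameters
    ----------
    y, X
        Response vector and fixed-effect design (include the intercept
        column explicitly).
    groups
        Group label per observation (any hashable dtype).
    reml
        Restricted ML (default) or plain ML.
    var_ratio
        If given, fixes ``lam = s2_b/s2_e`` instead of profiling it;
        ``var_ratio=0`` reproduces OLS estimates exactly.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) != len(X):
        raise ValueError("y and X length mismatch")
    codes, uniques = pd.factorize(np.asarray(groups))
    n_groups = len(uniques)
    if n_groups < 2 and var_ratio is None:
        raise ValueError("need >= 2 LD blocks to estimate a block variance")
    n, p = X.shape
    if n <= p:
        raise ValueError("more fixed effects than observations")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient "
                         "(constant or collinear columns)")

    if var_ratio is not None:
        lam = float(var_ratio)
        nll, beta, cov_u, sigma2 = _profiled(y, X, codes, n_groups, lam, reml)
        converged = np.isfinite(nll)
    else:
        def objective(loglam):
            return _profiled(y, X, codes, n_groups, np.exp(loglam), reml)[0]

        res = optimize.minimize_scalar(
            objective, bounds=(_LOGLAM_LO, _LOGLAM_HI), method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(np.exp(res.x))
        nll, beta, cov_u, sigma2 = _profiled(y, X, codes, n_groups, lam, reml)
        # boundary check: a zero block variance may beat the interior optimum
        nll0, beta0, cov_u0, sigma20 = _profiled(y, X, codes, n_groups, 0.0, reml)
        if nll0 <= nll + tol:
            lam, nll, beta, cov_u, sigma2 = 0.0, nll0, beta0, cov_u0, sigma20
        converged = bool(res.success) and np.isfinite(nll)

    se = np.sqrt(np.maximum(np.diag(cov_u) * sigma2, 0.0))
    return RandomInterceptFit(
        coef=beta, se=se, sigma2_e=float(sigma2),
        sigma2_b=float(lam * sigma2), loglik=float(-nll), reml=reml,
        converged=converged, n_obs=n, n_groups=n_groups,
    )
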