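"""Vectorized binomial-logit GLM for single-dose predictors.

The per-SNP association model is logit P(resistant) = a + b * dose with
dose in {0, 1, 2}, so the likelihood depends only on the six counts
n[dose, phenotype].  This lets thousands of SNPs be fitted simultaneously
with a two-parameter Newton iteration over (SNPs x 3) count arrays — the
per-SNP log-likelihood surface is exactly the one a generic IRLS fit
would maximize, at a fraction of the cost.

Complete separation (the MLE diverging, |b| unbounded) is detected and
the p-value falls back to the score test of b = 0 under the
intercept-only null, which is finite by construction (this is the
Cochran-Armitage-style trend statistic).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

DOSES = np.array([0.0, 1.0, 2.0])
_MAX_ABS_SLOPE = 15.0


def dose_counts(geno: np.ndarray, y: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP counts N[s, dose] and successes K[s, dose].

    ``geno``: SNPs x samples with entries {0,1,2}; ``y``: binary phenotype.
    """
    geno = np.asarray(geno)
    y = np.asarray(y).astype(bool)
    N = np.stack([(geno == d).sum(axis=1) for d in (0, 1, 2)], axis=1)
    K = np.stack([((geno == d) & y).sum(axis=1) for d in (0, 1, 2)], axis=1)
    return N.astype(float), K.astype(float)


def _loglik(N: np.ndarray, K: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # sum_x K*eta - N*log(1+exp(eta)), stable via logaddexp
    return (K * eta - N * np.logaddexp(0.0, eta)).sum(axis=1)


def fit_logistic_dose(N: np.ndarray, K: np.ndarray, max_iter: int = 50,
                      tol: float = 1e-10
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton fit of (a, b) per SNP from dose-class counts.

    Returns (a, b, converged).  SNPs whose slope runs away are reported
    unconverged (separation).
    """
    S = N.shape[0]
    a = np.zeros(S)
    b = np.zeros(S)
    tot = N.sum(axis=1)
    suc = K.sum(axis=1)
    with np.errstate(divide="ignore"):
        a = np.log((suc + 0.5) / (tot - suc + 0.5))
    active = np.ones(S, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = a[:, None] + b[:, None] * DOSES[None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = N * mu * (1 - mu)
        r = K - N * mu
        g0 = r.sum(axis=1)
        g1 = (r * DOSES).sum(axis=1)
        h00 = w.sum(axis=1)
        h01 = (w * DOSES).sum(axis=1)
        h11 = (w * DOSES ** 2).sum(axis=1)
        det = h00 * h11 - h01 ** 2
        ok = active & (det > 1e-12)
        da = np.where(ok, (h11 * g0 - h01 * g1) / np.where(det > 0, det, 1), 0)
        db = np.where(ok, (h00 * g1 - h01 * g0) / np.where(det > 0, det, 1), 0)
        # damp huge steps for stability
        step = np.maximum(np.abs(da), np.abs(db))
        scale = np.where(step > 5.0, 5.0 / np.maximum(step, 1e-300), 1.0)
        a = a + da * scale
        b = b + db * scale
        active = ok & (np.maximum(np.abs(g0), np.abs(g1)) > tol)
    converged = (~active) & (np.abs(b) < _MAX_ABS_SLOPE)
    return a, b, converged


def score_test_dose(N: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Score test of b = 0 (trend test); chi-square p with 1 df."""
    tot = N.sum(axis=1)
    ybar = K.sum(axis=1) / np.maximum(tot, 1)
    U = ((K - N * ybar[:, None]) * DOSES).sum(axis=1)
    xbar = (N * DOSES).sum(axis=1) / np.maximum(tot, 1)
    var = ybar * (1 - ybar) * (N * (DOSES - xbar[:, None]) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z2 = np.where(var > 0, U ** 2 / var, 0.0)
    return stats.chi2.sf(z2, df=1)


def logistic_lrt(geno: np.ndarray, y: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Likelihood-ratio p-values for dose association, per SNP.

    Returns (p, slope, score_fallback flags).  Constant-dose SNPs get
    p = 1.  Separated SNPs use the score test and are flagged.
    """
    N, K = dose_counts(geno, y)
    tot = N.sum(axis=1)
    suc = K.sum(axis=1)
    # null (intercept only) log-likelihood
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = suc / np.maximum(tot, 1)
        a0 = np.log(p0 / (1 - p0))
    a0 = np.clip(np.nan_to_num(a0, nan=0.0, posinf=30, neginf=-30), -30, 30)
    ll0 = _loglik(N, K, np.repeat(a0[:, None], 3, axis=1))

    a, b, converged = fit_logistic_dose(N, K)
    eta = a[:, None] + b[:, None] * DOSES[None, :]
    ll1 = _loglik(N, K, eta)
    lrt = np.maximum(2.0 * (ll1 - ll0), 0.0)
    p = stats.chi2.sf(lrt, df=1)

    constant = (N > 0).sum(axis=1) <= 1
    fallback = ~converged & ~constant
    if fallback.any():
        p_score = score_test_dose(N, K)
        p = np.where(fallback, p_score, p)
    p = np.where(constant, 1.0, p)
    b = np.where(constant, 0.0, b)
    return p, b, fallback
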