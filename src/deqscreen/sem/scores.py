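"""Regression-method factor scores and factor determinacy.

The regression (Thurstone) weights for unit-variance factors are
``W = Sigma^-1 Cov(y, eta)``; a subject's score vector is ``W' (y - mu)``.
Determinacy (Grice) is the correlation between a factor and its regression
score, ``sqrt(Cov(y, eta)' Sigma^-1 Cov(y, eta) / Var(eta))``; values of
0.80 or more are conventionally taken as acceptable for composite scoring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fit import FitError, FitResult

__all__ = ["factor_score_weights", "factor_determinacy", "compute_scores"]


def _obs_latent_cov(fit: FitResult):
    if not fit.latents:
        raise FitError("model has no latent factors")
    p = fit.n_observed
    C = fit.full_covariance
    return C[:p, :p], C[:p, p:], C[p:, p:]


def factor_score_weights(fit: FitResult) -> pd.DataFrame:
    """Regression-method factor-score weight matrix (observed x factors)."""
    Sigma, C_ol, _ = _obs_latent_cov(fit)
    try:
        W = np.linalg.solve(Sigma, C_ol)
    except np.linalg.LinAlgError:
        raise FitError("implied covariance is singular; cannot form factor scores")
    return pd.DataFrame(W, index=fit.observed, columns=fit.latents)


def factor_determinacy(fit: FitResult) -> dict:
    """Per-factor determinacy (correlation between factor and its score)."""
    Sigma, C_ol, Phi = _obs_latent_cov(fit)
    A = C_ol.T @ np.linalg.solve(Sigma, C_ol)
    rho2 = np.diag(A) / np.diag(Phi)
    return {f: float(np.sqrt(max(r, 0.0))) for f, r in zip(fit.latents, rho2)}


def compute_scores(fit: FitResult, data: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Composite factor scores for each row of ``data``.

    Rows with missing indicator values are scored with weights re-derived
    from the observed sub-covariance (the regression weights for the observed
    subset), which is the exact conditional-expectation analogue of
    renormalizing over observed entries.  Rows with no observed indicators
    get NaN scores.  Returns (scores, log) where log counts rows scored per
    missing pattern.
    """
    Sigma, C_ol, _ = _obs_latent_cov(fit)
    X = data[fit.observed].to_numpy(float)
    mu = fit.mu
    n, p = X.shape
    out = np.full((n, len(fit.latents)), np.nan)
    mask = ~np.isnan(X)
    log: dict[str, int] = {}
    codes = [tuple(row) for row in mask]
    for pattern in set(codes):
        rows = [i for i, c in enumerate(codes) if c == pattern]
        o = np.flatnonzero(np.array(pattern))
        key = "".join("1" if b else "0" for b in pattern)
        log[key] = len(rows)
        if len(o) == 0:
            continue
        W_o = np.linalg.solve(Sigma[np.ix_(o, o)], C_ol[o, :])
        out[rows, :] = (X[np.ix_(rows, o)] - mu[o]) @ W_o
    scores = pd.DataFrame(out, index=data.index, columns=fit.latents)
    return scores, log
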