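"""Maximum-likelihood and FIML estimation of covariance-structure models.

Complete data are fit by minimizing the ML discrepancy

    F_ML(theta) = ln|Sigma(theta)| - ln|S| + tr(S Sigma(theta)^-1) - p

with chi-square = (N - 1) * F_ML at the minimum.  Data with missing cells are
fit by full-information maximum likelihood: the casewise normal log-likelihood
is accumulated over missing-data patterns and the chi-square is the likelihood
ratio against the saturated (unstructured mean/covariance) model, whose
maximum is located by EM.

Both estimators share one analytic gradient built from the RAM derivative
d Sigma = dU S U' + U dS U' + U S dU' with U = F (I - A)^-1 and
dU = U E_ij (I - A)^-1 for a path entry (i, j).  Variance parameters are
optimized on the log scale; standard errors come from the numerically
differentiated observed information at the solution, evaluated in the raw
parameterization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .spec import CompiledSpec, SemSpec, SpecError

__all__ = [
    "FitResult", "fit_ml", "fit_fiml", "fit_multigroup",
    "saturated_loglik", "null_model", "FitError",
]

_GTOL = 1e-8
_FTOL = 1e-13
_MAXITER = 5000


class FitError(RuntimeError):
    pass


def _as_matrix(data, observed):
    if isinstance(data, pd.DataFrame):
        missing = [c for c in observed if c not in data.columns]
        if missing:
            raise FitError(f"data is missing columns: {missing}")
        return data[observed].to_numpy(float)
    X = np.asarray(data, float)
    if X.shape[1] != len(observed):
        raise FitError("data has wrong number of columns")
    return X


def _logdet_pd(M):
    """log-determinant via Cholesky; raises LinAlgError if not PD."""
    L = np.linalg.cholesky(M)
    return 2.0 * np.sum(np.log(np.diag(L))), L


# ---------------------------------------------------------------------------
# engines: objective + analytic gradient on the chi-square scale
# ---------------------------------------------------------------------------

class _MLEngine:
    """(N-1) * F_ML for one group of complete data."""

    def __init__(self, compiled: CompiledSpec, X: np.ndarray):
        self.c = compiled
        self.n, self.p = X.shape
        if self.n <= self.p:
            raise FitError("N must exceed the number of observed variables")
        # ML-denominator (1/N) covariance, so complete-data FIML degenerates
        # to ML exactly; the chi-square keeps the classic (N-1)*F_ML scale
        self.S = np.atleast_2d(np.cov(X, rowvar=False, ddof=0))
        try:
            self.logdet_S, _ = _logdet_pd(self.S)
        except np.linalg.LinAlgError:
            raise FitError("sample covariance matrix is not positive definite")
        self.weight = self.n - 1.0

    def value_grad(self, theta_raw):
        c = self.c
        p = c.n_observed
        A, S, M = c.assemble(theta_raw)
        v = A.shape[0]
        try:
            B = np.linalg.inv(np.eye(v) - A)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(c.n_free)
        U = B[:p, :]
        Sigma = U @ S @ U.T
        try:
            logdet, L = _logdet_pd(Sigma)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(c.n_free)
        Sinv = np.linalg.inv(Sigma)
        f = logdet - self.logdet_S + np.trace(self.S @ Sinv) - p
        G = Sinv - Sinv @ self.S @ Sinv
        H = U.T @ G @ U
        BSH = B @ S @ H
        grad = np.empty(c.n_free)
        for k, slot in enumerate(c.slots):
            g = 0.0
            for mat, i, j in slot:
                if mat == "A":
                    g += 2.0 * BSH[j, i]
                elif mat == "S":
                    g += H[i, i] if i == j else 2.0 * H[i, j]
                # mean entries do not enter F_ML
            grad[k] = g
        return self.weight * f, self.weight * grad

    def chi2_offset(self):  # objective already equals the chi-square
        return 0.0


class _PatternStats:
    __slots__ = ("idx", "n", "mean", "scatter")

    def __init__(self, idx, n, mean, scatter):
        self.idx, self.n, self.mean, self.scatter = idx, n, mean, scatter


def _patterns(X):
    """Group rows of X by missing-data pattern; per-pattern sufficient stats."""
    mask = ~np.isnan(X)
    empty = ~mask.any(axis=1)
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} rows with no observed values")
        X = X[~empty]
        mask = mask[~empty]
    out = []
    codes = np.ascontiguousarray(mask).view(
        np.dtype((np.void, mask.shape[1] * mask.dtype.itemsize))).ravel()
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_codes[1:] != sorted_codes[:-1], True])
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        rows = order[s:e]
        idx = np.flatnonzero(mask[rows[0]])
        sub = X[np.ix_(rows, idx)]
        m = sub.mean(axis=0)
        d = sub - m
        scatter = d.T @ d / len(rows)  # MLE (1/n) scatter about the pattern mean
        out.append(_PatternStats(idx, len(rows), m, scatter))
    return out


class _FIMLEngine:
    """-2 log-likelihood accumulated over missing-data patterns."""

    def __init__(self, compiled: CompiledSpec, X: np.ndarray):
        if not compiled.has_means:
            raise FitError("FIML requires a model with means/intercepts")
        self.c = compiled
        self.n, self.p = X.shape
        all_missing = np.isnan(X).all(axis=0)
        if all_missing.any():
            bad = [compiled.observed[i] for i in np.flatnonzero(all_missing)]
            raise FitError(f"variable(s) missing for all cases: {bad}")
        self.patterns = _patterns(X)
        self.n = sum(pat.n for pat in self.patterns)  # rows actually used
        self._ln2pi = np.log(2.0 * np.pi)

    def value_grad(self, theta_raw):
        c = self.c
        p = c.n_observed
        A, S, M = c.assemble(theta_raw)
        v = A.shape[0]
        try:
            B = np.linalg.inv(np.eye(v) - A)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(c.n_free)
        U = B[:p, :]
        Sigma = U @ S @ U.T
        mu = U @ M
        BM = B @ M
        f = 0.0
        H = np.zeros((v, v))
        w = np.zeros(v)
        for pat in self.patterns:
            o = pat.idx
            Sig_o = Sigma[np.ix_(o, o)]
            try:
                logdet, L = _logdet_pd(Sig_o)
            except np.linalg.LinAlgError:
                return np.inf, np.zeros(c.n_free)
            Sinv = np.linalg.inv(Sig_o)
            d = pat.mean - mu[o]
            C = pat.scatter + np.outer(d, d)
            f += pat.n * (len(o) * self._ln2pi + logdet + np.sum(Sinv * C))
            G = pat.n * (Sinv - Sinv @ C @ Sinv)
            Uo = U[o, :]
            H += Uo.T @ G @ Uo
            w += Uo.T @ (pat.n * (Sinv @ d))
        BSH = B @ S @ H
        grad = np.empty(c.n_free)
        for k, slot in enumerate(c.slots):
            g = 0.0
            for mat, i, j in slot:
                if mat == "A":
                    g += 2.0 * BSH[j, i] - 2.0 * w[i] * BM[j]
                elif mat == "S":
                    g += H[i, i] if i == j else 2.0 * H[i, j]
                else:  # mean
                    g += -2.0 * w[i]
            grad[k] = g
        return f, grad

    def chi2_offset(self):  # -2 ll of the saturated model
        return -2.0 * _saturated_loglik_patterns(self.patterns, self.p, self._ln2pi)


# ---------------------------------------------------------------------------
# saturated and independence baselines
# ---------------------------------------------------------------------------

def _saturated_loglik_patterns(patterns, p, ln2pi, tol=1e-10, max_iter=500):
    """Maximized unstructured-MVN log-likelihood with missing data, via EM."""
    # initialize from available-case means/variances, pairwise covariances
    mu = np.zeros(p)
    var = np.ones(p)
    count = np.zeros(p)
    ssum = np.zeros(p)
    ssq = np.zeros(p)
    for pat in patterns:
        o = pat.idx
        count[o] += pat.n
        ssum[o] += pat.n * pat.mean
        ssq[o] += pat.n * (np.diag(pat.scatter) + pat.mean ** 2)
    mu = ssum / count
    var = np.maximum(ssq / count - mu ** 2, 1e-8)
    Sigma = np.diag(var)
    n_total = sum(pat.n for pat in patterns)
    complete = all(len(pat.idx) == p for pat in patterns)

    def loglik(mu, Sigma):
        ll = 0.0
        for pat in patterns:
            o = pat.idx
            Sig_o = Sigma[np.ix_(o, o)]
            logdet, _ = _logdet_pd(Sig_o)
            Sinv = np.linalg.inv(Sig_o)
            d = pat.mean - mu[o]
            C = pat.scatter + np.outer(d, d)
            ll += -0.5 * pat.n * (len(o) * ln2pi + logdet + np.sum(Sinv * C))
        return ll

    if complete:
        # closed form
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        for pat in patterns:
            T1 += pat.n * pat.mean
            T2 += pat.n * (pat.scatter + np.outer(pat.mean, pat.mean))
        mu = T1 / n_total
        Sigma = T2 / n_total - np.outer(mu, mu)
        return loglik(mu, Sigma)

    prev = -np.inf
    for _ in range(max_iter):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        for pat in patterns:
            o = pat.idx
            m = np.setdiff1d(np.arange(p), o, assume_unique=True)
            n_p = pat.n
            sum_o = n_p * pat.mean
            SS_oo = n_p * (pat.scatter + np.outer(pat.mean, pat.mean))
            T1[o] += sum_o
            T2[np.ix_(o, o)] += SS_oo
            if len(m):
                Soo_inv = np.linalg.inv(Sigma[np.ix_(o, o)])
                Bmat = Sigma[np.ix_(m, o)] @ Soo_inv
                Cc = Sigma[np.ix_(m, m)] - Bmat @ Sigma[np.ix_(o, m)]
                dev_sum = sum_o - n_p * mu[o]
                sum_m = n_p * mu[m] + Bmat @ dev_sum
                T1[m] += sum_m
                Dev2 = n_p * (pat.scatter + np.outer(pat.mean - mu[o], pat.mean - mu[o]))
                cross = np.outer(sum_o, mu[m]) + (SS_oo - np.outer(sum_o, mu[o])) @ Bmat.T
                T2[np.ix_(o, m)] += cross
                T2[np.ix_(m, o)] += cross.T
                mm = (n_p * np.outer(mu[m], mu[m])
                      + np.outer(mu[m], Bmat @ dev_sum)
                      + np.outer(Bmat @ dev_sum, mu[m])
                      + Bmat @ Dev2 @ Bmat.T
                      + n_p * Cc)
                T2[np.ix_(m, m)] += mm
        mu = T1 / n_total
        Sigma = T2 / n_total - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        cur = loglik(mu, Sigma)
        if cur - prev < tol * (abs(prev) + 1.0):
            break
        prev = cur
    return cur


def saturated_loglik(data, observed=None):
    """Maximized log-likelihood of the unstructured normal model (FIML scale)."""
    X = data[observed].to_numpy(float) if isinstance(data, pd.DataFrame) else np.asarray(data, float)
    pats = _patterns(X)
    return _saturated_loglik_patterns(pats, X.shape[1], np.log(2 * np.pi))


def null_model(data, observed=None, method="ml"):
    """Chi-square and df of the independence (zero-covariance) baseline model.

    Under complete-data ML this is closed form: chi2 = -(N-1) ln|R| with R
    the sample correlation matrix and df = p(p-1)/2.  Under FIML the
    independence likelihood factorizes into per-variable univariate normal
    likelihoods on the observed cells.
    """
    if isinstance(data, pd.DataFrame):
        X = data[observed].to_numpy(float) if observed is not None else data.to_numpy(float)
    else:
        X = np.asarray(data, float)
    n, p = X.shape
    if method == "ml":
        R = np.corrcoef(X, rowvar=False)
        sign, logdet = np.linalg.slogdet(R)
        if sign <= 0:
            raise FitError("sample correlation matrix is singular")
        return -(n - 1) * logdet, p * (p - 1) // 2
    # FIML: per-variable univariate MLE on observed cells
    ll_indep = 0.0
    for j in range(p):
        x = X[:, j]
        x = x[~np.isnan(x)]
        v = max(x.var(), 1e-12)  # MLE variance
        ll_indep += -0.5 * len(x) * (np.log(2 * np.pi) + np.log(v) + 1.0)
    ll_sat = saturated_loglik(X)
    chi2 = 2.0 * (ll_sat - ll_indep)
    df = p * (p + 3) // 2 - 2 * p
    return chi2, df


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, fit statistics and implied moments of a fitted model."""

    names: list[str]
    estimates: np.ndarray
    n: int
    n_observed: int
    df: int
    chi2: float
    loglik: float | None
    fml: float | None
    Sigma: np.ndarray
    mu: np.ndarray
    A: np.ndarray
    S: np.ndarray
    M: np.ndarray
    observed: list[str]
    latents: list[str]
    converged: bool
    n_iter: int
    grad_norm: float
    method: str
    heywood: list[str] = field(default_factory=list)
    groups: list["FitResult"] | None = None
    group_ns: list[int] | None = None
    _se_fn: object = field(default=None, repr=False)
    _se: np.ndarray | None = field(default=None, repr=False)

    @property
    def params(self) -> dict:
        return dict(zip(self.names, self.estimates))

    @property
    def se(self) -> dict:
        if self._se is None:
            if self._se_fn is None:
                raise FitError("standard errors unavailable for this fit")
            self._se = self._se_fn()
        return dict(zip(self.names, self._se))

    @property
    def zvalues(self) -> dict:
        se = self.se
        return {k: (self.params[k] / se[k] if se[k] > 0 else np.nan) for k in self.names}

    @property
    def pvalues(self) -> dict:
        from scipy.stats import norm
        return {k: 2.0 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
                for k, z in self.zvalues.items()}

    @property
    def full_covariance(self) -> np.ndarray:
        """Implied covariance over all variables (observed then latents)."""
        v = self.A.shape[0]
        B = np.linalg.inv(np.eye(v) - self.A)
        return B @ self.S @ B.T

    def to_json_dict(self) -> dict:
        se = {}
        try:
            se = self.se
        except FitError:
            pass
        return {
            "estimates": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in se.items()},
            "fit": {
                "chi2": float(self.chi2), "df": int(self.df), "n": int(self.n),
                "loglik": None if self.loglik is None else float(self.loglik),
                "converged": bool(self.converged), "method": self.method,
            },
        }


# ---------------------------------------------------------------------------
# optimization driver
# ---------------------------------------------------------------------------

def _data_starts(compiled: CompiledSpec, X: np.ndarray):
    """Deterministic moment/OLS-based starting values for path models.

    Exogenous variances/covariances and means start at sample moments
    (complete rows, falling back to available-case moments); for models with
    no latents, regression slots start at per-equation OLS estimates and the
    residual variances at the OLS residual variance.
    """
    theta = compiled.starts.copy()
    p = compiled.n_observed
    complete = X[~np.isnan(X).any(axis=1)]
    if complete.shape[0] > p + 2:
        Sc = np.cov(complete, rowvar=False, ddof=1)
        mc = complete.mean(axis=0)
    else:
        Xm = np.ma.masked_invalid(X)
        Sc = np.ma.cov(Xm, rowvar=False, ddof=True).filled(0.0)
        mc = np.asarray(Xm.mean(axis=0))
        complete = None
    pure_path = not compiled.latents
    ols_cache = {}
    if pure_path and complete is not None and len(complete) > p + 2:
        # per-equation OLS for endogenous observed variables
        targets = {}
        for k, slot in enumerate(compiled.slots):
            for mat, i, j in slot:
                if mat == "A" and i < p and j < p:
                    targets.setdefault(i, []).append((k, j))
        for i, preds in targets.items():
            cols = [j for _, j in preds]
            Xd = np.column_stack([np.ones(len(complete)), complete[:, cols]])
            beta, *_ = np.linalg.lstsq(Xd, complete[:, i], rcond=None)
            resid = complete[:, i] - Xd @ beta
            ols_cache[i] = (dict(zip(cols, beta[1:])), resid.var(ddof=1))
    for k, (slot, kind) in enumerate(zip(compiled.slots, compiled.kinds)):
        mat, i, j = slot[0]
        if kind == "mean" and i < p:
            theta[k] = mc[i]
        elif kind == "variance" and mat == "S" and i < p:
            if i in ols_cache:
                theta[k] = max(ols_cache[i][1], 1e-4)
            elif not _is_endogenous(compiled, i):
                theta[k] = max(Sc[i, i], 1e-4)
        elif kind == "covariance" and mat == "S" and i < p and j < p:
            if not _is_endogenous(compiled, i) and not _is_endogenous(compiled, j):
                theta[k] = Sc[i, j]
        elif kind == "path" and mat == "A" and i in ols_cache and j in ols_cache[i][0]:
            theta[k] = ols_cache[i][0][j]
    return theta


def _is_endogenous(compiled: CompiledSpec, i: int) -> bool:
    if np.any(compiled.A0[i, :] != 0):
        return True
    return any(mat == "A" and ii == i
               for slot in compiled.slots for mat, ii, jj in slot)


def _run(engines, weights_map, compiled_list, theta0_raw_global, n_free_global,
         variance_mask_global):
    """Minimize the summed chi-square-scale objective over the global theta."""

    def to_internal(t):
        t = t.copy()
        t[variance_mask_global] = np.log(np.maximum(t[variance_mask_global], 1e-10))
        return t

    def to_raw(t):
        t = t.copy()
        t[variance_mask_global] = np.exp(t[variance_mask_global])
        return t

    def fun_raw(theta_raw):
        f = 0.0
        grad = np.zeros(n_free_global)
        for eng, idx in engines:
            fg, gg = eng.value_grad(theta_raw[idx])
            if not np.isfinite(fg):
                return np.inf, grad
            f += fg
            np.add.at(grad, idx, gg)
        return f, grad

    def fun_int(theta_int):
        theta_raw = to_raw(theta_int)
        f, g = fun_raw(theta_raw)
        if not np.isfinite(f):
            return f, np.zeros_like(theta_int)
        d = np.ones_like(theta_int)
        d[variance_mask_global] = theta_raw[variance_mask_global]
        return f, g * d

    if n_free_global == 0:  # fully fixed model: nothing to optimize
        f_min, _ = fun_raw(theta0_raw_global)
        return (theta0_raw_global, f_min, True, 0, 0.0, fun_raw)

    x0 = to_internal(theta0_raw_global.copy())
    # variances bounded below at exp(-30) so boundary (Heywood-type) cases
    # stall at the edge instead of collapsing the likelihood numerically
    bounds = [(-30.0, None) if m else (None, None) for m in variance_mask_global]
    res = optimize.minimize(
        fun_int, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": _MAXITER, "ftol": _FTOL, "gtol": _GTOL, "maxcor": 30})
    nit = int(res.nit)
    at_bound = bool(np.any(res.x[variance_mask_global] <= -29.0))
    # polish: dense-BFGS pass tightens the solution well past L-BFGS-B's
    # stopping rule (needed for optimizer-tolerance-level reproducibility)
    f_chk, g_chk = fun_int(res.x)
    if np.isfinite(f_chk) and not at_bound and np.max(np.abs(g_chk)) > 1e-9:
        res2 = optimize.minimize(fun_int, res.x, jac=True, method="BFGS",
                                 options={"gtol": 1e-9, "maxiter": 1000})
        if np.isfinite(res2.fun) and res2.fun <= f_chk + 1e-12:
            res = res2
            nit += int(res2.nit)
    theta_raw = to_raw(res.x)
    f_min, g_min = fun_raw(theta_raw)
    grad_norm = float(np.max(np.abs(g_min))) if np.all(np.isfinite(g_min)) else np.inf
    # the chi2-scale objective bottoms out near machine precision at a
    # gradient of roughly sqrt(eps)*|f|*curvature; 0.05 corresponds to
    # parameter precision far below any reported standard error
    converged = grad_norm < 0.05 or bool(res.success)
    return theta_raw, f_min, converged, nit, grad_norm, fun_raw


def _se_factory(fun_raw, theta_raw):
    """Standard errors = sqrt diag of 2 * inverse Hessian of the chi2-scale objective."""

    def compute():
        n = len(theta_raw)
        Hess = np.empty((n, n))
        h = 1e-5 * np.maximum(np.abs(theta_raw), 1.0)
        for k in range(n):
            tp = theta_raw.copy(); tp[k] += h[k]
            tm = theta_raw.copy(); tm[k] -= h[k]
            _, gp = fun_raw(tp)
            _, gm = fun_raw(tm)
            Hess[k] = (gp - gm) / (2 * h[k])
        Hess = 0.5 * (Hess + Hess.T)
        try:
            cov = 2.0 * np.linalg.inv(Hess)
        except np.linalg.LinAlgError:
            cov = 2.0 * np.linalg.pinv(Hess)
        d = np.diag(cov).copy()
        bad = d < 0
        if bad.any():
            warnings.warn("negative variance in the inverse information; "
                          "some standard errors are undefined")
            d[bad] = np.nan
        return np.sqrt(d)

    return compute


def _heywood(compiled, theta_raw, tol=1e-3):
    out = []
    for name, kind, val in zip(compiled.names, compiled.kinds, theta_raw):
        if kind == "variance" and val < tol:
            out.append(name)
    return out


def _moment_count(p, has_means):
    return p * (p + 1) // 2 + (p if has_means else 0)


def _finalize(compiled, theta_raw, f_min, chi2, n, method, converged, nit,
              grad_norm, fun_raw, df):
    A, S, M = compiled.assemble(theta_raw)
    v = A.shape[0]
    B = np.linalg.inv(np.eye(v) - A)
    U = B[:compiled.n_observed, :]
    Sigma = U @ S @ U.T
    mu = U @ M
    return FitResult(
        names=list(compiled.names), estimates=theta_raw, n=n,
        n_observed=compiled.n_observed, df=df, chi2=chi2,
        loglik=None if method == "ml" else -0.5 * f_min,
        fml=f_min / max(n - 1, 1) if method == "ml" else None,
        Sigma=Sigma, mu=mu, A=A, S=S, M=M,
        observed=list(compiled.observed), latents=list(compiled.latents),
        converged=converged, n_iter=nit, grad_norm=grad_norm, method=method,
        heywood=_heywood(compiled, theta_raw),
        _se_fn=_se_factory(fun_raw, theta_raw),
    )


def fit_ml(spec: SemSpec | CompiledSpec, data, *, start_from_data=False) -> FitResult:
    """Complete-data maximum-likelihood fit.

    Raises :class:`FitError` on missing cells, non-positive-definite sample
    covariance, or N <= p.  Non-convergence is flagged on the result, not
    raised.
    """
    compiled = spec.compile() if isinstance(spec, SemSpec) else spec
    X = _as_matrix(data, compiled.observed)
    if np.isnan(X).any():
        raise FitError("fit_ml requires complete data; use fit_fiml")
    if compiled.has_means:
        raise FitError("fit_ml models the covariance structure only; "
                       "means/intercepts require fit_fiml")
    eng = _MLEngine(compiled, X)
    theta0 = _data_starts(compiled, X) if start_from_data else compiled.starts.copy()
    idx = np.arange(compiled.n_free)
    theta, f_min, conv, nit, gnorm, fun_raw = _run(
        [(eng, idx)], None, [compiled], theta0, compiled.n_free,
        compiled._variance_mask.copy())
    df = _moment_count(compiled.n_observed, False) - compiled.n_free
    if df < 0:
        raise SpecError(f"negative degrees of freedom ({df}): model over-parameterized")
    res = _finalize(compiled, theta, f_min, f_min, X.shape[0], "ml",
                    conv, nit, gnorm, fun_raw, df)
    if not conv:
        warnings.warn(f"fit_ml did not converge (grad norm {gnorm:.2e})")
    return res


def fit_fiml(spec: SemSpec | CompiledSpec, data, *, start_from_data=False) -> FitResult:
    """Full-information ML fit of data with (or without) missing cells."""
    compiled = spec.compile() if isinstance(spec, SemSpec) else spec
    X = _as_matrix(data, compiled.observed)
    eng = _FIMLEngine(compiled, X)
    theta0 = _data_starts(compiled, X) if start_from_data else compiled.starts.copy()
    idx = np.arange(compiled.n_free)
    theta, f_min, conv, nit, gnorm, fun_raw = _run(
        [(eng, idx)], None, [compiled], theta0, compiled.n_free,
        compiled._variance_mask.copy())
    df = _moment_count(compiled.n_observed, True) - compiled.n_free
    if df < 0:
        raise SpecError(f"negative degrees of freedom ({df}): model over-parameterized")
    offset = eng.chi2_offset()  # -2 ll_sat
    # chi2 = (-2 ll_model) - (-2 ll_sat)
    res = _finalize(compiled, theta, f_min, f_min - offset, X.shape[0], "fiml",
                    conv, nit, gnorm, fun_raw, df)
    if not conv:
        warnings.warn(f"fit_fiml did not converge (grad norm {gnorm:.2e})")
    return res


def fit_multigroup(spec: SemSpec | CompiledSpec, datasets, *, constrained=(),
                   method=None, start_from_data=False) -> FitResult:
    """Simultaneous fit of one model to several groups.

    Parameters named in ``constrained`` share a single estimate across
    groups; all other free parameters are estimated per group.  With no
    constraints this is equivalent to separate single-group fits (the
    chi-squares add).  ``method`` is "ml", "fiml" or None (auto: FIML when
    any group has missing cells and the spec has means).
    """
    compiled = spec.compile() if isinstance(spec, SemSpec) else spec
    constrained = set(constrained)
    unknown = constrained - set(compiled.names)
    if unknown:
        raise SpecError(f"constrained parameters not in model: {sorted(unknown)}")
    Xs = [_as_matrix(d, compiled.observed) for d in datasets]
    any_missing = any(np.isnan(X).any() for X in Xs)
    if method is None:
        method = "fiml" if (any_missing or compiled.has_means) else "ml"
    if method == "ml" and any_missing:
        raise FitError("missing cells present; use method='fiml'")

    # global parameter vector: shared params once, others per group
    global_names: list[str] = []
    gindex: dict[str, int] = {}
    var_mask: list[bool] = []
    idx_maps = []
    theta0 = []
    for g, X in enumerate(Xs):
        local0 = _data_starts(compiled, X) if start_from_data else compiled.starts.copy()
        idx = np.empty(compiled.n_free, int)
        for k, name in enumerate(compiled.names):
            key = name if name in constrained else f"{name}@g{g}"
            if key not in gindex:
                gindex[key] = len(global_names)
                global_names.append(key)
                var_mask.append(compiled.kinds[k] == "variance")
                theta0.append(local0[k])
            idx[k] = gindex[key]
        idx_maps.append(idx)
    theta0 = np.array(theta0)
    var_mask = np.array(var_mask)

    engines = []
    offset = 0.0
    for X, idx in zip(Xs, idx_maps):
        if method == "ml":
            eng = _MLEngine(compiled, X)
        else:
            eng = _FIMLEngine(compiled, X)
            offset += eng.chi2_offset()
        engines.append((eng, idx))

    theta, f_min, conv, nit, gnorm, fun_raw = _run(
        engines, None, [compiled], theta0, len(global_names), var_mask)

    moments = sum(_moment_count(compiled.n_observed, method == "fiml") for _ in Xs)
    df = moments - len(global_names)
    chi2 = f_min if method == "ml" else f_min - offset

    # per-group implied moments from the group's slice of theta
    group_results = []
    for g, (X, idx) in enumerate(zip(Xs, idx_maps)):
        A, S, M = compiled.assemble(theta[idx])
        v = A.shape[0]
        B = np.linalg.inv(np.eye(v) - A)
        U = B[:compiled.n_observed, :]
        group_results.append((U @ S @ U.T, U @ M))

    A, S, M = compiled.assemble(theta[idx_maps[0]])
    v = A.shape[0]
    B = np.linalg.inv(np.eye(v) - A)
    U = B[:compiled.n_observed, :]
    res = FitResult(
        names=global_names, estimates=theta,
        n=sum(X.shape[0] for X in Xs), n_observed=compiled.n_observed,
        df=df, chi2=chi2,
        loglik=None if method == "ml" else -0.5 * f_min,
        fml=None, Sigma=U @ S @ U.T, mu=U @ M, A=A, S=S, M=M,
        observed=list(compiled.observed), latents=list(compiled.latents),
        converged=conv, n_iter=nit, grad_norm=gnorm, method=method,
        heywood=[], group_ns=[X.shape[0] for X in Xs],
        _se_fn=_se_factory(fun_raw, theta),
    )
    if not conv:
        warnings.warn(f"fit_multigroup did not converge (grad norm {gnorm:.2e})")
    return res
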