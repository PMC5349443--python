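"""Complete-data ML estimation: closed forms, recovery, oracles, invariances."""

import numpy as np
import pytest
from scipy import optimize

from deqscreen.sem import SemSpec, SpecError, FitError, fit_ml, fit_multigroup


def onefactor_spec(names):
    spec = SemSpec(names, ["F"])
    for v in names:
        spec.add_loading("F", v)
        spec.add_variance(v)
    spec.add_variance("F", value=1.0)
    return spec


def test_saturated_model_fits_perfectly():
    """All covariances free => Sigma(theta) = S, F_ML = 0, df = 0."""
    rng = np.random.default_rng(3)
    X = rng.multivariate_normal([0, 0, 0], [[1, .3, .2], [.3, 1, .4], [.2, .4, 1]], 500)
    spec = SemSpec(["a", "b", "c"])
    for v in ["a", "b", "c"]:
        spec.add_variance(v)
    for i, u in enumerate(["a", "b", "c"]):
        for w in ["a", "b", "c"][i + 1:]:
            spec.add_covariance(u, w)
    fit = fit_ml(spec, X)
    assert fit.df == 0
    assert abs(fit.chi2) < 1e-6
    S = np.cov(X, rowvar=False, ddof=0)
    assert np.allclose(fit.Sigma, S, atol=1e-6)


def test_onefactor_recovery_large_n(onefactor_data):
    """Loadings .8/.7/.6 recovered within +-0.01 at n = 100,000."""
    X, lam = onefactor_data
    fit = fit_ml(onefactor_spec(["x1", "x2", "x3"]), X)
    est = np.array([fit.params[f"l_F_x{i}"] for i in (1, 2, 3)])
    if est.sum() < 0:
        est = -est
    assert np.abs(est - lam).max() < 0.01
    uniq = np.array([fit.params[f"v_x{i}"] for i in (1, 2, 3)])
    assert np.abs(uniq - (1 - lam ** 2)).max() < 0.01


def test_fixed_zero_covariance_closed_form():
    """Fixing the single covariance of a correlated pair to zero gives
    chi2 = -(N-1) ln(1 - r^2) exactly."""
    rng = np.random.default_rng(1)
    n = 1000
    Z = rng.multivariate_normal([0, 0], [[1, .5], [.5, 1]], size=n)
    spec = SemSpec(["x", "y"])
    spec.add_variance("x")
    spec.add_variance("y")
    spec.add_covariance("x", "y", value=0.0)
    fit = fit_ml(spec, Z)
    r = np.corrcoef(Z.T)[0, 1]
    assert fit.df == 1
    assert fit.chi2 == pytest.approx(-(n - 1) * np.log(1 - r ** 2), rel=1e-9)


def test_oracle_statsmodels_ml_factor():
    """One-factor ML estimates match statsmodels' established ML factor
    analysis within 1e-3 on all free parameters."""
    Factor = pytest.importorskip("statsmodels.multivariate.factor").Factor
    rng = np.random.default_rng(7)
    n = 20_000
    lam = np.array([.8, .7, .6, .5])
    f = rng.standard_normal(n)
    X = f[:, None] * lam + rng.standard_normal((n, 4)) * np.sqrt(1 - lam ** 2)
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    fit = fit_ml(onefactor_spec(["x1", "x2", "x3", "x4"]), X)
    fa = Factor(X, n_factor=1, method="ml").fit()
    L = fa.loadings.ravel()
    if L.sum() < 0:
        L = -L
    ours_l = np.array([fit.params[f"l_F_x{i}"] for i in range(1, 5)])
    if ours_l.sum() < 0:
        ours_l = -ours_l
    ours_u = np.array([fit.params[f"v_x{i}"] for i in range(1, 5)])
    assert np.abs(ours_l - L).max() < 1e-3
    assert np.abs(ours_u - fa.uniqueness).max() < 1e-3


def test_oracle_bruteforce_optimizer():
    """A brute-force Nelder-Mead minimizer of the ML discrepancy, assembled
    independently of the engine, lands on the same estimates (<= 1e-3)."""
    rng = np.random.default_rng(11)
    n = 4000
    lam = np.array([.7, .6, .5])
    f = rng.standard_normal(n)
    X = f[:, None] * lam + rng.standard_normal((n, 3)) * np.sqrt(1 - lam ** 2)
    S = np.cov(X, rowvar=False, ddof=0)

    def discrepancy(theta):
        L = theta[:3].reshape(-1, 1)
        th = np.exp(theta[3:])
        Sigma = L @ L.T + np.diag(th)
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            return 1e9
        return logdet - np.linalg.slogdet(S)[1] + np.trace(S @ np.linalg.inv(Sigma)) - 3

    res = optimize.minimize(discrepancy, np.r_[[.5] * 3, np.log([.5] * 3)],
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14,
                                     "maxiter": 20000, "maxfev": 20000})
    brute_l = res.x[:3] if res.x[:3].sum() > 0 else -res.x[:3]
    fit = fit_ml(onefactor_spec(["a", "b", "c"]), X)
    est = np.array([fit.params[f"l_F_{v}"] for v in ("a", "b", "c")])
    if est.sum() < 0:
        est = -est
    assert np.abs(est - brute_l).max() < 1e-3
    assert np.abs(np.exp(res.x[3:]) -
                  [fit.params[f"v_{v}"] for v in ("a", "b", "c")]).max() < 1e-3


def test_scale_invariance():
    """Multiplying an observed variable by k rescales its loading and unique
    SD by k and leaves the chi-square unchanged."""
    rng = np.random.default_rng(5)
    n = 3000
    lam = np.array([.8, .7, .6])
    f = rng.standard_normal(n)
    X = f[:, None] * lam + rng.standard_normal((n, 3)) * np.sqrt(1 - lam ** 2)
    spec = onefactor_spec(["a", "b", "c"])
    fit1 = fit_ml(spec, X)
    k = 2.5
    X2 = X.copy()
    X2[:, 0] *= k
    fit2 = fit_ml(spec, X2)
    assert fit2.chi2 == pytest.approx(fit1.chi2, abs=1e-6)
    assert fit2.params["l_F_a"] == pytest.approx(k * fit1.params["l_F_a"], rel=1e-5)
    assert fit2.params["v_a"] == pytest.approx(k ** 2 * fit1.params["v_a"], rel=1e-4)
    assert fit2.params["l_F_b"] == pytest.approx(fit1.params["l_F_b"], rel=1e-5)


def test_multigroup_unconstrained_equals_separate_fits():
    rng = np.random.default_rng(9)
    lam = np.array([.8, .6, .7])
    def draw(n):
        f = rng.standard_normal(n)
        return f[:, None] * lam + rng.standard_normal((n, 3)) * np.sqrt(1 - lam ** 2)
    X1, X2 = draw(1500), draw(2000)
    spec = onefactor_spec(["a", "b", "c"])
    mg = fit_multigroup(spec, [X1, X2])
    f1, f2 = fit_ml(spec, X1), fit_ml(spec, X2)
    assert mg.chi2 == pytest.approx(f1.chi2 + f2.chi2, abs=1e-6)
    assert mg.df == f1.df + f2.df
    for v in ("a", "b", "c"):
        assert mg.params[f"l_F_{v}@g0"] == pytest.approx(f1.params[f"l_F_{v}"], abs=2e-6)
        assert mg.params[f"l_F_{v}@g1"] == pytest.approx(f2.params[f"l_F_{v}"], abs=2e-6)


def test_errors():
    spec = onefactor_spec(["a", "b", "c"])
    X = np.random.default_rng(0).standard_normal((100, 3))
    Xm = X.copy()
    Xm[0, 0] = np.nan
    with pytest.raises(FitError, match="complete"):
        fit_ml(spec, Xm)
    with pytest.raises(FitError):
        fit_ml(spec, X[:3])  # N <= p
    bad = SemSpec(["a", "b"], ["F"])
    bad.add_loading("F", "a")
    bad.add_variance("a")
    bad.add_variance("b")
    with pytest.raises(SpecError, match="identified"):
        bad.compile()
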