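"""Screening serum analytes as mediators of the APOE e4 effect on dEQ.

For each QC-passed analyte a simultaneous path model is fit:

    analyte_w1 ~ APOE (path c) + covariates
    dEQ_w2     ~ APOE (path a, direct) + analyte_w1 (path b) + covariates

with the exposure and covariates freely intercorrelated.  Path labels
follow the report convention of this analysis: ``a`` is the direct
APOE -> dEQ association, ``b`` the analyte's prospective effect on dEQ and
``c`` the APOE -> analyte association — note this inverts the textbook a/b
mediation notation.  The indirect (mediated) effect is the product b*c with
the Sobel/MacKinnon delta-method z, and the proportion mediated is
indirect / (indirect + direct), reported as a percentage only when the
indirect and total effects share a sign.

Analytes are classified into three panels: mediators (both b and c
significant at the gate), APOE-independent dEQ biomarkers (b significant
only) and unrelated analytes.  Findings replicate by a split-half
constrained fit: the a/b/c paths are forced equal across two random halves
and the chi-square worsening is tested against the free two-group model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .sem import (SemSpec, FitResult, fit_ml, fit_fiml, fit_multigroup,
                  fit_indices, chi2_diff_test, null_model)
from .synthetic import COVARIATES

__all__ = ["MediationResult", "BaseModelResult", "fit_base_model",
           "fit_mediation_model", "mediation_effect", "screen_panel",
           "split_half_replicate", "ScreenReport"]

GATE_DEFAULT = 1e-3
TREND_GATE = 0.05


@dataclass
class PathEstimate:
    estimate: float
    se: float
    p: float


@dataclass
class MediationResult:
    analyte: str
    path_a: PathEstimate  # APOE -> dEQ_w2 (direct, adjusted)
    path_b: PathEstimate  # analyte_w1 -> dEQ_w2
    path_c: PathEstimate  # APOE -> analyte_w1
    indirect: float
    sobel_z: float
    sobel_p: float
    proportion_mediated: float | None  # percent; None when signs disagree
    klass: str  # mediator | apoe_independent_delta_biomarker | unrelated
    survives_bonferroni: bool
    trend_mediator: bool  # both paths < 0.05 but not both < the gate
    fit: dict = field(default_factory=dict)
    replication: dict | None = None
    n: int = 0

    def to_row(self) -> dict:
        row = {"analyte": self.analyte, "n": self.n,
               "a": self.path_a.estimate, "a_se": self.path_a.se, "a_p": self.path_a.p,
               "b": self.path_b.estimate, "b_se": self.path_b.se, "b_p": self.path_b.p,
               "c": self.path_c.estimate, "c_se": self.path_c.se, "c_p": self.path_c.p,
               "indirect": self.indirect, "sobel_z": self.sobel_z,
               "sobel_p": self.sobel_p,
               "proportion_mediated_pct": self.proportion_mediated,
               "class": self.klass,
               "survives_bonferroni": self.survives_bonferroni,
               "trend_mediator": self.trend_mediator}
        if self.replication is not None:
            row.update({"repl_delta_chi2": self.replication["delta_chi2"],
                        "repl_delta_df": self.replication["delta_df"],
                        "repl_p": self.replication["p"],
                        "repl_pass": self.replication["pass"]})
        return row


@dataclass
class BaseModelResult:
    apoe_on_deq: PathEstimate
    apoe_on_gprime: PathEstimate
    gprime_dropped: bool
    n: int


def _analysis_frame(cohort: pd.DataFrame, scores: pd.DataFrame,
                    analyte: pd.Series | None = None,
                    outcome: str = "dEQ_w2") -> pd.DataFrame:
    """Assemble and standardize the per-subject analysis table.

    Wave-2 covariates and APOE are merged with composite scores (and a
    Wave-1 analyte when given); every column is z-scored so all paths are on
    the correlation scale.
    """
    w2 = cohort.loc[cohort["wave"] == 2].set_index("subject_id")
    missing_cov = [c for c in COVARIATES + ["APOE"] if c not in w2.columns]
    if missing_cov:
        raise ValueError(f"cohort lacks required columns: {missing_cov}")
    df = w2[["APOE"] + COVARIATES].astype(float)
    sc = scores.set_index("subject_id") if "subject_id" in scores.columns else scores
    df = df.join(sc[[outcome]], how="inner")
    if analyte is not None:
        df = df.join(analyte.rename("analyte"), how="left")
    out = (df - df.mean()) / df.std(ddof=1)
    return out


def _path_model_spec(*, with_analyte: bool, means: bool) -> SemSpec:
    observed = ["deq", "apoe"] + (["analyte"] if with_analyte else []) + COVARIATES
    exo = ["apoe"] + COVARIATES
    spec = SemSpec(observed)
    if with_analyte:
        spec.add_regression("analyte", "apoe", name="c")
        for cv in COVARIATES:
            spec.add_regression("analyte", cv, name=f"c_{cv}")
        spec.add_variance("analyte", name="v_analyte", start=0.9)
        spec.add_regression("deq", "analyte", name="b")
    spec.add_regression("deq", "apoe", name="a")
    for cv in COVARIATES:
        spec.add_regression("deq", cv, name=f"a_{cv}")
    spec.add_variance("deq", name="v_deq", start=0.9)
    for k, u in enumerate(exo):
        spec.add_variance(u, start=1.0)
        for v in exo[k + 1:]:
            spec.add_covariance(u, v)
    if means:
        for v in observed:
            spec.add_mean(v)
    return spec


def _fit_path_model(frame: pd.DataFrame, *, with_analyte: bool) -> FitResult:
    cols = ["deq", "apoe"] + (["analyte"] if with_analyte else []) + COVARIATES
    X = frame[cols].rename(columns={})
    has_missing = bool(X.isna().to_numpy().any())
    spec = _path_model_spec(with_analyte=with_analyte, means=has_missing)
    data = X.to_numpy(float)
    named = pd.DataFrame(data, columns=cols)
    if has_missing:
        return fit_fiml(spec, named, start_from_data=True)
    return fit_ml(spec, named, start_from_data=True)


def _path(fit: FitResult, name: str) -> PathEstimate:
    return PathEstimate(float(fit.params[name]), float(fit.se[name]),
                        float(fit.pvalues[name]))


def fit_base_model(cohort: pd.DataFrame, scores: pd.DataFrame,
                   alpha: float = 0.05) -> BaseModelResult:
    """Adjusted direct association of APOE with the dEQ and g' composites.

    Fits dEQ_w2 ~ APOE + covariates and, separately, g'_w2 ~ APOE +
    covariates (standardized coefficients).  When the APOE -> g' path is
    non-significant, g' is flagged as dropped from downstream screening.
    """
    frames = {out: _analysis_frame(cohort, scores, outcome=out)
              .rename(columns={out: "deq", "APOE": "apoe"})
              for out in ("dEQ_w2", "gprime_w2")}
    fits = {out: _fit_path_model(f, with_analyte=False)
            for out, f in frames.items()}
    a_deq = _path(fits["dEQ_w2"], "a")
    a_g = _path(fits["gprime_w2"], "a")
    return BaseModelResult(apoe_on_deq=a_deq, apoe_on_gprime=a_g,
                           gprime_dropped=bool(a_g.p >= alpha),
                           n=len(frames["dEQ_w2"]))


def mediation_effect(path_b: float, path_c: float, se_b: float, se_c: float,
                     direct_a: float):
    """Product-of-coefficients mediation effect with Sobel z.

    indirect = b*c; z = b*c / sqrt(b^2 se_c^2 + c^2 se_b^2); two-sided
    normal p.  The proportion mediated, indirect / (indirect + direct), is
    returned as a percentage and only when the indirect effect has the same
    sign as the total effect; otherwise None (flagged upstream).
    """
    for v in (path_b, path_c, se_b, se_c, direct_a):
        if not math.isfinite(v):
            raise ValueError("mediation_effect requires finite estimates and SEs")
    indirect = path_b * path_c
    denom = math.sqrt(path_b ** 2 * se_c ** 2 + path_c ** 2 * se_b ** 2)
    z = 0.0 if denom == 0.0 else indirect / denom
    p = 1.0 if z == 0.0 else 2.0 * float(norm.sf(abs(z)))
    total = indirect + direct_a
    proportion = None
    if total != 0.0 and indirect * total > 0:
        proportion = 100.0 * indirect / total
    return indirect, z, p, proportion


def fit_mediation_model(cohort: pd.DataFrame, scores: pd.DataFrame,
                        analyte: pd.Series, name: str = "analyte",
                        gate: float = GATE_DEFAULT) -> MediationResult:
    """Fit the longitudinal mediation model for one Wave-1 analyte.

    Estimation is ML on complete data and FIML when any cell is missing.
    Fit indices are reported when the model has positive df (the
    unconstrained single-group path model is saturated, so indices carry
    information only in constrained/multi-group settings).
    """
    s = pd.Series(np.asarray(analyte, float),
                  index=getattr(analyte, "index", None), name="analyte")
    if s.dropna().std(ddof=1) == 0 or s.dropna().empty:
        raise ValueError(f"analyte {name} is constant or empty")
    frame = _analysis_frame(cohort, scores, analyte=s)
    frame = frame.rename(columns={"dEQ_w2": "deq", "APOE": "apoe"})
    fit = _fit_path_model(frame, with_analyte=True)
    a, b, c = _path(fit, "a"), _path(fit, "b"), _path(fit, "c")
    indirect, z, p_sobel, prop = mediation_effect(
        b.estimate, c.estimate, b.se, c.se, a.estimate)
    klass, survives, trend = _classify(b.p, c.p, gate)
    fitblock = {"chi2": float(fit.chi2), "df": int(fit.df),
                "converged": bool(fit.converged)}
    if fit.df > 0:
        c2n, dfn = null_model(frame[["deq", "apoe", "analyte"] + COVARIATES],
                              method=fit.method)
        fi = fit_indices(fit.chi2, fit.df, c2n, dfn, fit.n)
        fitblock.update({"cmin_df": fi.cmin_df, "cfi": fi.cfi, "rmsea": fi.rmsea})
    return MediationResult(
        analyte=name, path_a=a, path_b=b, path_c=c, indirect=float(indirect),
        sobel_z=float(z), sobel_p=float(p_sobel), proportion_mediated=prop,
        klass=klass, survives_bonferroni=survives, trend_mediator=trend,
        fit=fitblock, n=int(fit.n))


def _classify(p_b: float, p_c: float, gate: float):
    if p_b < gate and p_c < gate:
        klass = "mediator"
    elif p_b < gate:
        klass = "apoe_independent_delta_biomarker"
    else:
        klass = "unrelated"
    survives = bool(p_b < GATE_DEFAULT and p_c < GATE_DEFAULT)
    trend = bool(p_b < TREND_GATE and p_c < TREND_GATE and klass != "mediator")
    return klass, survives, trend


@dataclass
class ScreenReport:
    results: list
    gate: float
    n_analytes: int
    tables: dict  # class -> list of analyte names
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.results])

    def to_json_dict(self) -> dict:
        return {"gate": self.gate, "n_analytes_tested": self.n_analytes,
                "seed": self.seed,
                "tables": self.tables,
                "results": [r.to_row() for r in self.results]}


def screen_panel(cohort: pd.DataFrame, scores: pd.DataFrame,
                 clean_panel: pd.DataFrame, gate: float = GATE_DEFAULT,
                 *, seed: int | None = None,
                 replicate: str = "mediators") -> ScreenReport:
    """Screen every QC-passed analyte and classify into the three panels.

    ``replicate`` controls split-half replication: "mediators" (default)
    replicates analytes classified as mediators or flagged as trend
    mediators, "all" replicates everything, "none" skips replication.
    Deterministic given inputs and seed; analytes are processed in sorted
    order so the output is invariant to column order.
    """
    if clean_panel.shape[1] == 0:
        raise ValueError("empty panel: no QC-passed analytes to screen")
    if replicate not in ("mediators", "all", "none"):
        raise ValueError("replicate must be 'mediators', 'all' or 'none'")
    if replicate != "none" and seed is None:
        raise ValueError("a seed is required for split-half replication")
    results = []
    for name in sorted(clean_panel.columns):
        res = fit_mediation_model(cohort, scores, clean_panel[name],
                                  name=name, gate=gate)
        if replicate == "all" or (replicate == "mediators"
                                  and (res.klass == "mediator" or res.trend_mediator)):
            d = split_half_replicate(cohort, scores, clean_panel[name], seed=seed)
            res.replication = d
        results.append(res)
    tables = {"mediator": [], "apoe_independent_delta_biomarker": [], "unrelated": []}
    for r in results:
        tables[r.klass].append(r.analyte)
    return ScreenReport(results=results, gate=gate,
                        n_analytes=len(results), tables=tables, seed=seed)


def split_half_replicate(cohort: pd.DataFrame, scores: pd.DataFrame,
                         analyte: pd.Series, seed: int,
                         groups: pd.Series | None = None) -> dict:
    """Constrained-vs-free two-group test of mediation-path homogeneity.

    Subjects are split 50/50 by a seeded random permutation (the odd subject
    goes to group 1).  The a, b and c paths are constrained equal across the
    halves and the chi-square worsening relative to the free two-group model
    is tested on 3 df; p > 0.05 (no significant worsening) counts as
    replication.  The mediation effect is recomputed from the constrained
    fit.

    ``groups`` (a two-level series indexed by subject) overrides the random
    split — useful for testing path homogeneity across a known partition
    (site, ethnicity, a planted subpopulation) rather than a random one.
    """
    s = pd.Series(np.asarray(analyte, float),
                  index=getattr(analyte, "index", None), name="analyte")
    frame = _analysis_frame(cohort, scores, analyte=s)
    frame = frame.rename(columns={"dEQ_w2": "deq", "APOE": "apoe"})
    n = len(frame)
    if n < 100:
        raise ValueError("need at least 100 subjects for a split-half fit")
    if groups is not None:
        g = groups.reindex(frame.index)
        levels = g.dropna().unique()
        if len(levels) != 2:
            raise ValueError("groups must have exactly two levels")
        g1 = frame.loc[g == levels[0]]
        g2 = frame.loc[g == levels[1]]
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        cut = (n + 1) // 2
        g1 = frame.iloc[perm[:cut]]
        g2 = frame.iloc[perm[cut:]]
    has_missing = bool(frame.isna().to_numpy().any())
    spec = _path_model_spec(with_analyte=True, means=has_missing)
    method = "fiml" if has_missing else "ml"
    fit_free = fit_multigroup(spec, [g1, g2], method=method, start_from_data=True)
    fit_con = fit_multigroup(spec, [g1, g2], constrained={"a", "b", "c"},
                             method=method, start_from_data=True)
    d = chi2_diff_test(fit_con, fit_free)
    se = fit_con.se
    est = fit_con.params
    indirect, z, p_sobel, prop = mediation_effect(
        est["b"], est["c"], se["b"], se["c"], est["a"])
    return {"delta_chi2": d.delta_chi2, "delta_df": d.delta_df, "p": d.p,
            "pass": bool(d.p > 0.05), "negative_flag": d.negative_flag,
            "constrained": {"a": est["a"], "b": est["b"], "c": est["c"],
                            "indirect": indirect, "sobel_z": z,
                            "sobel_p": p_sobel, "proportion_mediated_pct": prop},
            "group_ns": [len(g1), len(g2)], "seed": seed}
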