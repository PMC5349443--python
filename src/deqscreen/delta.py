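"""Construction and validation of the latent dementia phenotype (dEQ).

dEQ operationalizes "the cognitive correlates of functional status": a
bifactor model in which dEQ loads on all five Wave-2 indicators — four
cognitive tests (LMII, VRI, COWA, DST) and one functional scale (IADL) —
while g' (general cognitive variance unrelated to function) loads on the
four cognitive indicators only.  The factors are orthogonal and identified
by fixed unit variances, so both are on a standardized scale; no covariates
enter this construction step.

Regression-method factor weights turn the fitted model into per-subject
composite scores, validated against clinical diagnosis (ROC AUC for AD vs
NC) and dementia severity (Pearson r with CDR sum of boxes).  Scores are
oriented so that higher dEQ means better function/cognition; adverse risk
factors therefore carry negative signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr, rankdata

from .sem import (SemSpec, FitResult, fit_ml, fit_fiml, compute_scores,
                  factor_determinacy, factor_score_weights)
from .synthetic import COGNITIVE, INDICATORS

__all__ = ["DeltaModelResult", "build_deq", "validate_auc", "validate_cdr",
           "bifactor_spec"]


@dataclass
class DeltaModelResult:
    fit: FitResult
    weights: pd.DataFrame  # indicators x (dEQ, gprime)
    scores: pd.DataFrame  # subject_id, dEQ_w2, gprime_w2
    determinacy: dict
    validation: dict
    orientation_flipped: dict
    heywood: list = field(default_factory=list)
    score_pattern_log: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "fit": self.fit.to_json_dict(),
            "weights": {f: self.weights[f].to_dict() for f in self.weights.columns},
            "determinacy": self.determinacy,
            "validation": self.validation,
            "orientation_flipped": self.orientation_flipped,
            "heywood": list(self.heywood),
        }


def bifactor_spec(*, means: bool, residual_covariances=()) -> SemSpec:
    """The dEQ/g' bifactor measurement model over the five indicators."""
    spec = SemSpec(INDICATORS, ["dEQ", "gprime"])
    for ind in INDICATORS:
        spec.add_loading("dEQ", ind, start=0.6)
        spec.add_variance(ind, start=0.4)
        if means:
            spec.add_mean(ind)
    for ind in COGNITIVE:
        spec.add_loading("gprime", ind, start=0.3)
    spec.add_variance("dEQ", value=1.0)
    spec.add_variance("gprime", value=1.0)
    spec.add_covariance("dEQ", "gprime", value=0.0)  # orthogonal by construction
    for a, b in residual_covariances:
        spec.add_covariance(a, b, start=0.0)
    return spec


def build_deq(cohort: pd.DataFrame, *, residual_covariances=(),
              wave: int = 2) -> DeltaModelResult:
    """Fit the bifactor model to Wave-2 indicators and produce composite scores.

    Indicators are standardized before fitting (no covariate adjustment at
    this stage).  Complete data are fit by ML; any missing indicator cells
    switch estimation to FIML.  Factor-score weights handle missing
    indicators by re-deriving the regression weights over the observed
    subset.  ROC validation is restricted to complete cases.
    """
    w = cohort.loc[cohort["wave"] == wave].set_index("subject_id")
    missing_cols = [c for c in INDICATORS if c not in w.columns]
    if missing_cols:
        raise ValueError(f"cohort lacks indicator columns: {missing_cols}")
    X = w[INDICATORS].astype(float)
    Xz = (X - X.mean()) / X.std(ddof=1)

    has_missing = bool(Xz.isna().to_numpy().any())
    spec = bifactor_spec(means=has_missing, residual_covariances=residual_covariances)
    fit = fit_fiml(spec, Xz) if has_missing else fit_ml(spec, Xz)

    weights = factor_score_weights(fit)
    determinacy = factor_determinacy(fit)
    raw_scores, pattern_log = compute_scores(fit, Xz)

    # sign convention: a factor score should rise with its own indicators
    flipped = {}
    cog_mean = Xz[COGNITIVE].mean(axis=1)
    for f in ("dEQ", "gprime"):
        ok = np.isfinite(raw_scores[f]) & np.isfinite(cog_mean)
        r = np.corrcoef(raw_scores.loc[ok, f], cog_mean[ok])[0, 1]
        flipped[f] = bool(r < 0)
        if flipped[f]:
            raw_scores[f] = -raw_scores[f]
            weights[f] = -weights[f]

    scores = pd.DataFrame({"subject_id": raw_scores.index,
                           "dEQ_w2": raw_scores["dEQ"].to_numpy(),
                           "gprime_w2": raw_scores["gprime"].to_numpy()})

    validation: dict = {}
    complete = Xz.notna().all(axis=1)
    if "diagnosis" in w.columns:
        sub = w.loc[complete]
        sc = raw_scores.loc[complete]
        try:
            auc, ci, orient = validate_auc(sc["dEQ"], sub["diagnosis"])
            validation["auc_deq"] = {"auc": auc, "ci": ci, "flipped": orient}
            auc_g, ci_g, orient_g = validate_auc(sc["gprime"], sub["diagnosis"])
            validation["auc_gprime"] = {"auc": auc_g, "ci": ci_g, "flipped": orient_g}
        except ValueError:
            pass
    if "CDR_SB" in w.columns:
        r, p = validate_cdr(raw_scores["dEQ"], w["CDR_SB"])
        validation["cdr"] = {"r": r, "p": p}

    return DeltaModelResult(
        fit=fit, weights=weights, scores=scores, determinacy=determinacy,
        validation=validation, orientation_flipped=flipped,
        heywood=list(fit.heywood), score_pattern_log=pattern_log)


def validate_auc(scores, diagnosis, case_label="AD", control_label="NC"):
    """AUC (Mann-Whitney) for discriminating cases from controls, with 95% CI.

    Orientation: the score is applied so that lower values indicate cases;
    if the raw score discriminates in the opposite direction it is flipped
    (flag returned) so the reported AUC is >= 0.5 by convention.  The CI is
    the Hanley-McNeil normal approximation to the Mann-Whitney variance.
    Subjects with labels other than case/control (e.g. MCI) are excluded.
    """
    s = np.asarray(scores, float)
    d = np.asarray(diagnosis).astype(str)
    keep = np.isfinite(s) & np.isin(d, [case_label, control_label])
    s, d = s[keep], d[keep]
    n1 = int((d == case_label).sum())
    n2 = int((d == control_label).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(f"need at least one {case_label} and one {control_label}")
    ranks = rankdata(s)
    # AUC = P(control score > case score), ties counted half
    r_ctrl = ranks[d == control_label].sum()
    auc = (r_ctrl - n2 * (n2 + 1) / 2) / (n1 * n2)
    flipped = bool(auc < 0.5)
    if flipped:
        auc = 1.0 - auc
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
           + (n2 - 1) * (q2 - auc ** 2)) / (n1 * n2)
    half = norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    ci = (float(max(auc - half, 0.0)), float(min(auc + half, 1.0)))
    return float(auc), ci, flipped


def validate_cdr(scores, cdr):
    """Pearson correlation between composite scores and CDR sum of boxes."""
    s = np.asarray(scores, float)
    c = np.asarray(cdr, float)
    keep = np.isfinite(s) & np.isfinite(c)
    s, c = s[keep], c[keep]
    if s.size < 3 or s.std() == 0 or c.std() == 0:
        raise ValueError("zero variance or too few paired values for correlation")
    r, p = pearsonr(s, c)
    return float(r), float(p)
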