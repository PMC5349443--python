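"""Synthetic longitudinal cohorts with a known latent-mediation structure.

The generator emulates the data model this pipeline is built for: an
orthogonal bifactor cognition structure (a dementia-specific factor "delta"
loading on cognitive tests and everyday function, and a cognition-only
residual factor g'), a dichotomous APOE e4 exposure with a standardized
direct path onto delta, and a wide serum-protein panel in which a chosen
subset of analytes carries a true APOE -> analyte -> delta indirect path.
All structural paths are on the correlation (standardized) scale and every
latent is recorded, so parameter recovery can be checked against the exact
generating values.

Assay realism (duplicate reads, below-detection censoring against a least
detectable dose, batch shifts on the log-concentration scale, gross
outliers, missing cells) is added by :func:`inject_assay_artifacts` so that
the clean generative structure and the measurement artifacts can be studied
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .panel import BiomarkerPanel

__all__ = ["MediatorSpec", "GeneratorConfig", "GroundTruth", "generate",
           "inject_assay_artifacts", "ConfigError"]

INDICATORS = ["LMII", "VRI", "COWA", "DST", "IADL"]
COGNITIVE = INDICATORS[:4]
COVARIATES = ["age", "education", "ethnicity", "gender", "GDS", "HCY", "HgbA1c"]

# raw-score location/scale used when writing indicators (affine only; the
# analysis standardizes indicators before fitting)
_INDICATOR_SCALE = {"LMII": (8.0, 4.3), "VRI": (7.9, 3.7), "COWA": (8.4, 3.5),
                    "DST": (8.9, 3.0), "IADL": (10.5, 4.5)}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MediatorSpec:
    """One analyte with a true indirect path APOE -> analyte (c) -> delta (b)."""
    analyte: str
    c_path: float
    b_path: float


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of a synthetic cohort.

    Defaults mirror the cohort this pipeline targets: e4-carrier prevalence
    0.39, a standardized direct APOE -> delta path of -0.25, one true mediator
    with weak paths (c = -0.15, b = 0.15), ten delta-only analytes and a
    null balance filling a ~100-analyte panel.
    """

    n_subjects: int = 3000
    p_e4: float = 0.39
    a_direct: float = -0.25
    mediator_specs: tuple = (MediatorSpec("CRP", -0.15, 0.15),)
    n_null_analytes: int = 89
    n_delta_only_analytes: int = 10
    b_delta_only: float = 0.15
    # delta weights the memory/function end; g' (the residual of general
    # intelligence) weights fluency/attention — the profiles must not be
    # proportional or the bifactor decomposition is empirically degenerate
    loadings_delta: tuple = (0.70, 0.65, 0.55, 0.50, 0.75)  # LMII VRI COWA DST IADL
    loadings_gprime: tuple = (0.25, 0.30, 0.55, 0.60)  # cognitive indicators only
    covariate_effects: dict = field(default_factory=lambda: {
        "age": -0.10, "education": 0.10, "ethnicity": 0.0, "gender": 0.0,
        "GDS": -0.15, "HCY": -0.05, "HgbA1c": -0.05})
    delta_stability: float = 0.8  # corr(delta wave1, delta wave2)
    n_batches: int = 4
    batch_effect_sd: float = 0.3  # additive shift on the log-concentration scale
    low_censor_quantile: float = 0.05
    duplicate_cv: float = 0.04
    outlier_rate: float = 0.005
    missing_rate: float = 0.02
    missing_mechanism: str = "mcar"  # or "mar": missingness increasing as delta falls
    diagnosis_noise_sd: float = 0.5
    diagnosis_fractions: tuple = (0.418, 0.208, 0.374)  # NC, MCI, AD
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_e4", "low_censor_quantile", "outlier_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.duplicate_cv < 0 or self.batch_effect_sd < 0:
            raise ConfigError("duplicate_cv and batch_effect_sd must be nonnegative")
        for name in ("n_subjects", "n_batches"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count")
        if self.n_null_analytes < 0 or self.n_delta_only_analytes < 0:
            raise ConfigError("analyte counts must be nonnegative")
        if len(self.loadings_delta) != len(INDICATORS):
            raise ConfigError(f"loadings_delta must have {len(INDICATORS)} entries "
                              f"({', '.join(INDICATORS)})")
        if len(self.loadings_gprime) != len(COGNITIVE):
            raise ConfigError(
                f"loadings_gprime must have {len(COGNITIVE)} entries: one per "
                "cognitive indicator (IADL carries no g' loading)")
        for ld, lg in zip(self.loadings_delta[:4], self.loadings_gprime):
            if ld ** 2 + lg ** 2 >= 1.0:
                raise ConfigError("indicator communality >= 1; reduce loadings")
        if self.loadings_delta[4] ** 2 >= 1.0:
            raise ConfigError("IADL loading must be < 1 in absolute value")
        if self.missing_mechanism not in ("mcar", "mar"):
            raise ConfigError("missing_mechanism must be 'mcar' or 'mar'")
        if abs(sum(self.diagnosis_fractions) - 1.0) > 0.025:
            raise ConfigError("diagnosis_fractions must sum to ~1")

    # -- derived structure -------------------------------------------------

    def analyte_table(self) -> pd.DataFrame:
        """Per-analyte true paths and class labels."""
        rows = []
        for m in self.mediator_specs:
            rows.append((m.analyte, m.c_path, m.b_path, "mediator"))
        for k in range(self.n_delta_only_analytes):
            rows.append((f"DB{k + 1:02d}", 0.0, self.b_delta_only, "delta_only"))
        for k in range(self.n_null_analytes):
            rows.append((f"NB{k + 1:02d}", 0.0, 0.0, "null"))
        tab = pd.DataFrame(rows, columns=["analyte", "c_path", "b_path", "class"])
        if tab["analyte"].duplicated().any():
            raise ConfigError("duplicate analyte names in mediator_specs")
        tab["c_path"] = tab["c_path"].astype(float)
        tab["b_path"] = tab["b_path"].astype(float)
        return tab.set_index("analyte")

    def covariate_cov(self) -> np.ndarray:
        """Covariance of the standardized covariates (identity + two 0.1 links)."""
        C = np.eye(len(COVARIATES))
        i_age, i_gds = COVARIATES.index("age"), COVARIATES.index("GDS")
        i_hcy, i_hgb = COVARIATES.index("HCY"), COVARIATES.index("HgbA1c")
        C[i_age, i_gds] = C[i_gds, i_age] = 0.1
        C[i_hcy, i_hgb] = C[i_hgb, i_hcy] = 0.1
        return C

    def delta_residual_sd(self) -> float:
        """SD of delta's structural residual so that Var(delta) = 1 exactly."""
        tab = self.analyte_table()
        b = tab["b_path"].to_numpy()
        c = tab["c_path"].to_numpy()
        bc = float(b @ c)
        var_sys = (self.a_direct ** 2 + 2 * self.a_direct * bc
                   + float(b @ b) + bc ** 2 - float((b * c) @ (b * c)))
        g = np.array([self.covariate_effects.get(k, 0.0) for k in COVARIATES])
        var_sys += float(g @ self.covariate_cov() @ g)
        if var_sys >= 1.0:
            raise ConfigError(
                f"structural paths imply Var(delta) >= 1 (systematic share {var_sys:.3f}); "
                "reduce path magnitudes")
        return float(np.sqrt(1.0 - var_sys))


@dataclass
class GroundTruth:
    """Latent values and true parameters recorded at generation time."""

    delta_w2: np.ndarray
    delta_w1: np.ndarray
    gprime: np.ndarray
    apoe: np.ndarray
    analyte_latents: pd.DataFrame  # standardized latent per analyte (pre-assay)
    analyte_table: pd.DataFrame  # true c, b paths and class per analyte
    a_direct: float
    batch_shifts: pd.DataFrame  # batch x analyte additive log-scale shifts
    covariates_std: pd.DataFrame
    config: GeneratorConfig

    def to_json_dict(self) -> dict:
        return {
            "a_direct": self.a_direct,
            "analytes": {a: {"c_path": float(r.c_path), "b_path": float(r.b_path),
                             "class": r["class"]}
                         for a, r in self.analyte_table.iterrows()},
            "config": _config_dict(self.config),
        }


def _config_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["mediator_specs"] = [asdict(m) if not isinstance(m, dict) else m
                           for m in config.mediator_specs]
    return d


def _standardize(x):
    return (x - np.mean(x)) / np.std(x, ddof=1)


def generate(config: GeneratorConfig) -> tuple[pd.DataFrame, BiomarkerPanel, GroundTruth]:
    """Draw a cohort, a clean biomarker panel and the generating ground truth.

    The returned panel is artifact-free (identical duplicate reads, no LOW
    flags, no outliers, no missing cells); pass it through
    :func:`inject_assay_artifacts` to create the conditions the QC stage must
    handle.  Identical configs (including seed) give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    tab = config.analyte_table()
    analytes = list(tab.index)

    apoe = (rng.random(n) < config.p_e4).astype(int)
    p = config.p_e4
    apoe_std = (apoe - p) / np.sqrt(p * (1 - p))

    # covariates on a standardized latent scale, then mapped to raw units
    Cz = config.covariate_cov()
    Z = rng.multivariate_normal(np.zeros(len(COVARIATES)), Cz, size=n)
    zc = dict(zip(COVARIATES, Z.T))
    age = 70.9 + 9.5 * zc["age"]
    education = np.clip(np.round(13.2 + 4.3 * zc["education"]), 0, 22)
    ethnicity = (norm.cdf(zc["ethnicity"]) < 0.36).astype(int)
    gender = (norm.cdf(zc["gender"]) < 0.39).astype(int)
    gds = np.clip(np.round(5.6 + 5.25 * zc["GDS"]), 0, 30)
    hcy = np.maximum(10.0 + 3.0 * zc["HCY"], 0.5)
    hgba1c = np.maximum(6.0 + 1.0 * zc["HgbA1c"], 3.0)
    raw_cov = {"age": age, "education": education, "ethnicity": ethnicity,
               "gender": gender, "GDS": gds, "HCY": hcy, "HgbA1c": hgba1c}
    # effects apply to the observed (possibly discretized) covariates,
    # standardized within sample, so generating effects match what an
    # adjusted analysis of the observed columns estimates
    cov_std = {k: _standardize(v) for k, v in raw_cov.items()}

    # analyte latents: M_j = c_j * APOE_std + noise, Var = 1
    c_vec = tab["c_path"].to_numpy()
    b_vec = tab["b_path"].to_numpy()
    M = (apoe_std[:, None] * c_vec[None, :]
         + rng.standard_normal((n, len(analytes))) * np.sqrt(1 - c_vec ** 2))
    M_df = pd.DataFrame(M, columns=analytes)

    gamma = np.array([config.covariate_effects.get(k, 0.0) for k in COVARIATES])
    cov_term = sum(g * cov_std[k] for g, k in zip(gamma, COVARIATES))
    resid_sd = config.delta_residual_sd()
    delta = (config.a_direct * apoe_std + M @ b_vec + cov_term
             + resid_sd * rng.standard_normal(n))
    gprime = rng.standard_normal(n)
    rho = config.delta_stability
    delta_w1 = rho * delta + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)

    lam_d = np.asarray(config.loadings_delta, float)
    lam_g = np.r_[np.asarray(config.loadings_gprime, float), 0.0]  # IADL: no g'
    uniq_sd = np.sqrt(1 - lam_d ** 2 - lam_g ** 2)

    def indicators(dlt):
        E = rng.standard_normal((n, len(INDICATORS)))
        Y = dlt[:, None] * lam_d + gprime[:, None] * lam_g + E * uniq_sd
        out = {}
        for k, name in enumerate(INDICATORS):
            m, s = _INDICATOR_SCALE[name]
            out[name] = m + s * Y[:, k]
        return out

    y_w1 = indicators(delta_w1)
    y_w2 = indicators(delta)

    def severity(dlt):
        u = dlt + config.diagnosis_noise_sd * rng.standard_normal(n)
        sd_u = np.sqrt(1 + config.diagnosis_noise_sd ** 2)
        f_nc, f_mci, f_ad = config.diagnosis_fractions
        t_ad = norm.ppf(f_ad) * sd_u
        t_nc = norm.ppf(f_ad + f_mci) * sd_u
        diag = np.where(u < t_ad, "AD", np.where(u < t_nc, "MCI", "NC"))
        cdr_lat = 3.0 - 3.0 * dlt + 0.5 * rng.standard_normal(n)
        cdr = np.round(np.clip(cdr_lat, 0.0, 18.0) * 2) / 2  # half-point scale
        return diag, cdr

    diag_w1, cdr_w1 = severity(delta_w1)
    diag_w2, cdr_w2 = severity(delta)

    subject_id = np.array([f"S{k + 1:05d}" for k in range(n)])
    rows = []
    for wave, ys, dg, cdr in ((1, y_w1, diag_w1, cdr_w1), (2, y_w2, diag_w2, cdr_w2)):
        df = pd.DataFrame({"subject_id": subject_id, "wave": wave})
        for name in INDICATORS:
            df[name] = ys[name]
        df["age"] = age + (0.0 if wave == 1 else 2.0)
        for k in ("education", "ethnicity", "gender", "GDS", "HCY", "HgbA1c"):
            df[k] = raw_cov[k]
        df["APOE"] = apoe
        df["diagnosis"] = dg
        df["CDR_SB"] = cdr
        rows.append(df)
    cohort = pd.concat(rows, ignore_index=True)

    # cohort-side item missingness (indicators + continuous covariates)
    if config.missing_rate > 0:
        maskable = INDICATORS + ["GDS", "HCY", "HgbA1c"]
        if config.missing_mechanism == "mcar":
            prob = np.full(n, config.missing_rate)
        else:  # mar: worse delta -> more missing, mean rate preserved
            w = np.exp(-np.repeat(delta, 1))
            prob = np.clip(config.missing_rate * w / w.mean(), 0, 1)
        for wave_idx, base in ((cohort["wave"] == 1, prob), (cohort["wave"] == 2, prob)):
            sel = cohort.index[wave_idx]
            for col in maskable:
                hit = rng.random(n) < base
                cohort.loc[sel[hit], col] = np.nan

    # clean panel on the concentration scale: log-normal around the latent
    batches = pd.Series(rng.integers(0, config.n_batches, size=n),
                        index=subject_id).map(lambda b: f"B{b + 1}")
    shifts = pd.DataFrame(
        rng.normal(0.0, config.batch_effect_sd,
                   size=(config.n_batches, len(analytes))),
        index=[f"B{b + 1}" for b in range(config.n_batches)], columns=analytes)
    L = M + shifts.loc[batches.values].to_numpy()
    conc = np.exp(L)
    sd_L = np.sqrt(1 + config.batch_effect_sd ** 2)
    q = config.low_censor_quantile
    ldd = pd.Series(np.exp(norm.ppf(max(q, 1e-6)) * sd_L), index=analytes)

    reads = pd.DataFrame(conc, index=subject_id, columns=analytes)
    panel = BiomarkerPanel(
        read1=reads.copy(), read2=reads.copy(),
        low=pd.DataFrame(False, index=subject_id, columns=analytes),
        ldd=ldd, batch=batches)

    truth = GroundTruth(
        delta_w2=delta, delta_w1=delta_w1, gprime=gprime, apoe=apoe,
        analyte_latents=M_df.set_index(pd.Index(subject_id, name="subject_id")),
        analyte_table=tab, a_direct=config.a_direct, batch_shifts=shifts,
        covariates_std=pd.DataFrame(cov_std, index=subject_id),
        config=config)
    return cohort, panel, truth


def inject_assay_artifacts(panel: BiomarkerPanel, config: GeneratorConfig,
                           seed_offset: int = 1) -> BiomarkerPanel:
    """Overlay measurement artifacts on a clean panel.

    Applies, in order: duplicate-read noise at ``duplicate_cv``; LOW
    censoring of cells whose underlying concentration falls below the
    analyte's LDD (population ``low_censor_quantile``); gross outliers
    (both duplicate reads replaced by a value at least 4 pre-injection SDs
    from the analyte mean) at ``outlier_rate``; and missing cells at
    ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + seed_offset)
    out = panel.copy()
    n, m = out.read1.shape
    base = out.read1.to_numpy()  # clean concentrations (read1 == read2)

    cv = config.duplicate_cv
    r1 = base * (1.0 + cv * rng.standard_normal((n, m)))
    r2 = base * (1.0 + cv * rng.standard_normal((n, m)))
    r1 = np.maximum(r1, base * 1e-3)
    r2 = np.maximum(r2, base * 1e-3)

    low = np.zeros((n, m), bool)
    if config.low_censor_quantile > 0:
        low = base < out.ldd.to_numpy()[None, :]

    if config.outlier_rate > 0:
        mu = base.mean(axis=0)
        sd = base.std(axis=0, ddof=1)
        hit = (rng.random((n, m)) < config.outlier_rate) & ~low
        mag = mu[None, :] + (4.0 + rng.exponential(1.0, (n, m))) * sd[None, :]
        r1 = np.where(hit, mag, r1)
        r2 = np.where(hit, mag, r2)

    missing = rng.random((n, m)) < config.missing_rate
    r1[missing] = np.nan
    r2[missing] = np.nan
    low &= ~missing
    r1[low] = np.nan
    r2[low] = np.nan

    out.read1 = pd.DataFrame(r1, index=out.read1.index, columns=out.read1.columns)
    out.read2 = pd.DataFrame(r2, index=out.read2.index, columns=out.read2.columns)
    out.low = pd.DataFrame(low, index=out.low.index, columns=out.low.columns)
    return out
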