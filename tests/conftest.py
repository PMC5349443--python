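import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from deqscreen import (GeneratorConfig, generate, inject_assay_artifacts,
                       run_qc, build_deq)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

warnings.filterwarnings("ignore", message="dropping .* rows")


@pytest.fixture(scope="session")
def onefactor_data():
    """n=100k draws from a one-factor model with loadings .8/.7/.6."""
    rng = np.random.default_rng(0)
    n = 100_000
    lam = np.array([0.8, 0.7, 0.6])
    f = rng.standard_normal(n)
    X = f[:, None] * lam + rng.standard_normal((n, 3)) * np.sqrt(1 - lam ** 2)
    return X, lam


@pytest.fixture(scope="session")
def study():
    """Default-conditions cohort (n=3000, one true mediator), QC'd and scored.

    Built once per session: cohort + artifact-laden panel -> QC -> bifactor
    scores, with the generating ground truth.  The panel carries the true
    mediator (CRP), three delta-only and five null analytes to keep the
    session affordable.
    """
    cfg = dataclasses.replace(GeneratorConfig(), n_null_analytes=5,
                              n_delta_only_analytes=3, seed=2024)
    cohort, panel, truth = generate(cfg)
    panel = inject_assay_artifacts(panel, cfg)
    clean, qc_report = run_qc(panel)
    delta = build_deq(cohort)
    return {"config": cfg, "cohort": cohort, "panel": panel, "truth": truth,
            "clean": clean, "qc_report": qc_report, "delta": delta}


@pytest.fixture(scope="session")
def clean_study():
    """Artifact-free complete-data variant (for exact-identity checks)."""
    cfg = dataclasses.replace(
        GeneratorConfig(), n_null_analytes=3, n_delta_only_analytes=1,
        missing_rate=0.0, low_censor_quantile=0.0, outlier_rate=0.0,
        duplicate_cv=0.0, seed=515)
    cohort, panel, truth = generate(cfg)
    clean, _ = run_qc(panel)
    # drop cells deleted by the 3-SD screen so the table is fully complete
    complete_subjects = clean.dropna().index
    cohort = cohort[cohort.subject_id.isin(complete_subjects)].reset_index(drop=True)
    clean = clean.loc[complete_subjects]
    delta = build_deq(cohort)
    return {"config": cfg, "cohort": cohort, "truth": truth, "clean": clean,
            "delta": delta}
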