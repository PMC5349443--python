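"""Mediation paths, Sobel arithmetic, panel classification, split-half."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from deqscreen import (GeneratorConfig, MediatorSpec, generate, run_qc,
                       build_deq, fit_base_model, fit_mediation_model,
                       screen_panel, split_half_replicate)
from deqscreen.mediation import mediation_effect, _analysis_frame, _fit_path_model
from deqscreen.synthetic import COVARIATES, INDICATORS


class TestMediationEffectArithmetic:
    def test_hand_worked_example(self):
        """b = 0.15, c = -0.15, se = 0.02 each, a = -0.23: indirect -0.0225,
        z = -0.0225 / sqrt(2 * 0.15^2 * 4e-4) = -5.3033, proportion 8.9%."""
        indirect, z, p, prop = mediation_effect(0.15, -0.15, 0.02, 0.02, -0.23)
        assert indirect == pytest.approx(-0.0225)
        assert z == pytest.approx(-0.0225 / np.sqrt(2 * 0.15 ** 2 * 4e-4), rel=1e-12)
        assert z == pytest.approx(-5.3033, abs=5e-5)
        assert prop == pytest.approx(100 * 0.0225 / 0.2525, rel=1e-9)
        assert round(prop, 1) == 8.9

    def test_zero_c_gives_zero_effect(self):
        indirect, z, p, prop = mediation_effect(0.15, 0.0, 0.02, 0.02, -0.2)
        assert indirect == 0.0 and z == 0.0 and p == 1.0

    def test_noise_dominated_limit(self):
        _, z, p, _ = mediation_effect(0.01, -0.01, 0.1, 0.1, -0.2)
        assert abs(z) < 0.2 and p > 0.5

    def test_sign_disagreement_suppresses_proportion(self):
        # indirect positive, total negative: proportion undefined
        _, _, _, prop = mediation_effect(0.3, 0.3, 0.02, 0.02, -0.3)
        assert prop is None

    def test_nonfinite_errors(self):
        with pytest.raises(ValueError):
            mediation_effect(np.nan, 0.1, 0.02, 0.02, -0.2)


class TestBaseModel:
    def test_direct_path_recovery(self, study):
        """a_direct = -0.25 planted: the adjusted APOE -> dEQ path is
        negative, within 3 SE of the truth, and p < 0.001.  The APOE -> g'
        composite path is far smaller (it is nonzero only through the
        cross-contamination of regression factor scores)."""
        base = fit_base_model(study["cohort"], study["delta"].scores)
        a = base.apoe_on_deq
        assert a.estimate < 0
        assert abs(a.estimate - (-0.25)) < 3 * a.se
        assert a.p < 1e-3
        assert abs(base.apoe_on_gprime.estimate) < abs(a.estimate) / 2

    def test_null_direct_path(self):
        cfg = GeneratorConfig(n_subjects=2500, a_direct=0.0, mediator_specs=(),
                              n_null_analytes=1, n_delta_only_analytes=0,
                              missing_rate=0.0, seed=91)
        cohort, _, _ = generate(cfg)
        delta = build_deq(cohort)
        base = fit_base_model(cohort, delta.scores)
        assert abs(base.apoe_on_deq.estimate) < 3 * base.apoe_on_deq.se

    def test_adjustment_removes_confounding(self):
        """With APOE correlated with age and age affecting the outcome, the
        adjusted path recovers the direct effect while the unadjusted
        association overstates it."""
        rng = np.random.default_rng(55)
        n = 6000
        a_true = -0.20
        z_apoe = rng.standard_normal(n)
        apoe = (z_apoe > 0.3).astype(float)
        apoe_std = (apoe - apoe.mean()) / apoe.std()
        age_z = 0.6 * apoe_std + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        deq = a_true * apoe_std - 0.3 * age_z + rng.standard_normal(n) * 0.8
        cohort = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)], "wave": 2,
            "APOE": apoe, "age": 70 + 9 * age_z})
        for cv in COVARIATES:
            if cv not in cohort:
                cohort[cv] = rng.standard_normal(n)
        for ind in INDICATORS:
            cohort[ind] = 0.0  # unused here
        scores = pd.DataFrame({"subject_id": cohort["subject_id"],
                               "dEQ_w2": deq, "gprime_w2": rng.standard_normal(n)})
        base = fit_base_model(cohort, scores)
        adjusted = base.apoe_on_deq.estimate
        unadjusted = np.corrcoef(apoe_std, (deq - deq.mean()) / deq.std())[0, 1]
        a_scaled = a_true / deq.std()  # truth on the standardized-outcome scale
        assert abs(adjusted - a_scaled) < 3 * base.apoe_on_deq.se
        assert abs(unadjusted) > abs(a_scaled) + 0.1

    def test_missing_covariate_errors_by_name(self, study):
        cohort = study["cohort"].drop(columns=["GDS"])
        with pytest.raises(ValueError, match="GDS"):
            fit_base_model(cohort, study["delta"].scores)


class TestMediationModel:
    def test_true_mediator_recovered(self, study):
        res = fit_mediation_model(study["cohort"], study["delta"].scores,
                                  study["clean"]["CRP"], name="CRP")
        assert res.indirect < 0  # b > 0, c < 0 by construction
        assert abs(res.path_c.estimate - (-0.15)) < 3 * res.path_c.se
        assert abs(res.indirect - (-0.0225)) < 3 * abs(res.indirect / res.sobel_z)
        assert res.klass == "mediator"
        assert res.survives_bonferroni

    def test_total_effect_decomposition(self, clean_study):
        """Path algebra conservation: on complete data the total APOE -> dEQ
        effect from the mediator-free model equals a + b*c within 1e-6."""
        cohort, scores = clean_study["cohort"], clean_study["delta"].scores
        res = fit_mediation_model(cohort, scores, clean_study["clean"]["CRP"],
                                  name="CRP")
        frame = _analysis_frame(cohort, scores).rename(
            columns={"dEQ_w2": "deq", "APOE": "apoe"})
        total = _fit_path_model(frame, with_analyte=False).params["a"]
        assert res.path_a.estimate + res.indirect == pytest.approx(total, abs=1e-6)

    def test_constant_analyte_errors(self, study):
        const = pd.Series(1.0, index=study["clean"].index)
        with pytest.raises(ValueError, match="constant"):
            fit_mediation_model(study["cohort"], study["delta"].scores, const)

    def test_complete_mediation_limit(self):
        """A mediator carrying essentially the whole channel: the direct
        path vanishes and the proportion mediated -> 1.  (A literally
        noiseless outcome is a degenerate zero-residual boundary; a small
        residual keeps the model inside the estimable region.)"""
        rng = np.random.default_rng(66)
        n = 4000
        apoe = (rng.random(n) < 0.4).astype(float)
        apoe_std = (apoe - apoe.mean()) / apoe.std()
        m = -0.4 * apoe_std + np.sqrt(1 - 0.16) * rng.standard_normal(n)
        deq = 0.5 * m + 0.02 * rng.standard_normal(n)
        cohort = pd.DataFrame({"subject_id": [f"S{i}" for i in range(n)],
                               "wave": 2, "APOE": apoe})
        for cv in COVARIATES:
            cohort[cv] = rng.standard_normal(n)
        for ind in INDICATORS:
            cohort[ind] = 0.0
        scores = pd.DataFrame({"subject_id": cohort["subject_id"],
                               "dEQ_w2": deq, "gprime_w2": rng.standard_normal(n)})
        analyte = pd.Series(m, index=cohort["subject_id"])
        res = fit_mediation_model(cohort, scores, analyte, name="channel")
        assert abs(res.path_a.estimate) < 3 * res.path_a.se
        assert res.proportion_mediated == pytest.approx(100.0, abs=5.0)


class TestScreen:
    def test_classification_partition_and_recovery(self, study):
        rep = screen_panel(study["cohort"], study["delta"].scores,
                           study["clean"], seed=3)
        truth = study["truth"].analyte_table
        counts = sum(len(v) for v in rep.tables.values())
        assert counts == study["clean"].shape[1]  # exact partition
        got = {r.analyte: r.klass for r in rep.results}
        assert got["CRP"] == "mediator"
        for a, row in truth.iterrows():
            if row["class"] == "delta_only":
                assert got[a] == "apoe_independent_delta_biomarker"
            elif row["class"] == "null":
                assert got[a] == "unrelated"

    def test_order_invariance(self, study):
        cols = list(study["clean"].columns)
        rep1 = screen_panel(study["cohort"], study["delta"].scores,
                            study["clean"][cols], seed=3, replicate="none")
        rep2 = screen_panel(study["cohort"], study["delta"].scores,
                            study["clean"][cols[::-1]], seed=3, replicate="none")
        f1, f2 = rep1.to_frame(), rep2.to_frame()
        pd.testing.assert_frame_equal(f1, f2)

    def test_vacuous_gate_classifies_everything_mediator(self, study):
        rep = screen_panel(study["cohort"], study["delta"].scores,
                           study["clean"], gate=1.0, replicate="none")
        assert all(r.klass == "mediator" for r in rep.results)

    def test_empty_panel_errors(self, study):
        with pytest.raises(ValueError, match="empty"):
            screen_panel(study["cohort"], study["delta"].scores,
                         study["clean"].iloc[:, :0], replicate="none")


class TestSplitHalf:
    def test_deterministic_given_seed(self, study):
        r1 = split_half_replicate(study["cohort"], study["delta"].scores,
                                  study["clean"]["CRP"], seed=9)
        r2 = split_half_replicate(study["cohort"], study["delta"].scores,
                                  study["clean"]["CRP"], seed=9)
        assert r1["delta_chi2"] == r2["delta_chi2"]
        assert r1["group_ns"] == r2["group_ns"]
        assert abs(sum(r1["group_ns"]) / 2 - r1["group_ns"][0]) <= 0.5

    def test_homogeneous_paths_replicate(self, study):
        r = split_half_replicate(study["cohort"], study["delta"].scores,
                                 study["clean"]["CRP"], seed=10)
        assert r["delta_df"] == 3
        assert not r["negative_flag"]
        assert r["constrained"]["proportion_mediated_pct"] is not None

    def test_planted_heterogeneity_detected(self):
        """b present in only one known subpopulation (delta-b = 0.3): the
        constrained fit across that partition worsens significantly."""
        cfg1 = GeneratorConfig(n_subjects=1500, missing_rate=0.0,
                               mediator_specs=(MediatorSpec("CRP", -0.15, 0.3),),
                               n_null_analytes=0, n_delta_only_analytes=0, seed=201)
        cfg2 = dataclasses.replace(
            cfg1, mediator_specs=(MediatorSpec("CRP", -0.15, 0.0),), seed=202)
        c1, p1, _ = generate(cfg1)
        c2, p2, _ = generate(cfg2)
        c2 = c2.assign(subject_id="P2" + c2["subject_id"])
        p2r1 = p2.read1.copy(); p2r1.index = "P2" + p2r1.index
        cohort = pd.concat([c1, c2], ignore_index=True)
        analyte = pd.concat([np.log(p1.read1["CRP"]),
                             np.log(p2r1["CRP"])])
        delta = build_deq(cohort)
        groups = pd.Series(np.r_[np.zeros(1500), np.ones(1500)],
                           index=analyte.index)
        r = split_half_replicate(cohort, delta.scores, analyte, seed=1,
                                 groups=groups)
        assert r["p"] < 0.01  # heterogeneity detected
        r_rand = split_half_replicate(cohort, delta.scores, analyte, seed=1)
        assert r_rand["delta_df"] == 3
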