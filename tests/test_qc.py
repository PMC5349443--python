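"""Panel QC rules: duplicates, LOW handling, outliers, normalization, batch."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, skew

from deqscreen.qc import (QCError, reconcile_duplicates, resolve_low,
                          remove_outliers, normalize, adjust_batch, run_qc)
from deqscreen.panel import BiomarkerPanel


class TestReconcileDuplicates:
    @pytest.mark.parametrize("r1, r2, expected", [
        (10.0, 10.2, 10.1),   # 1.98% <= 5%: averaged
        (7.3, 7.3, 7.3),      # identical reads
    ])
    def test_kept_pairs_average(self, r1, r2, expected):
        v, n = reconcile_duplicates([r1], [r2])
        assert v[0] == pytest.approx(expected)
        assert n == 0

    def test_discordant_pair_discarded(self):
        v, n = reconcile_duplicates([10.0], [11.0])  # 9.52% > 5%
        assert np.isnan(v[0])
        assert n == 1

    def test_nonpositive_read_errors(self):
        with pytest.raises(QCError):
            reconcile_duplicates([0.0], [1.0])

    def test_missing_pair_passes_through(self):
        v, n = reconcile_duplicates([np.nan], [np.nan])
        assert np.isnan(v[0]) and n == 0


class TestResolveLow:
    def test_majority_low_drops_analyte(self):
        v = np.r_[np.full(40, np.nan), np.ones(60) * 5]
        low = np.r_[np.ones(60, bool), np.zeros(40, bool)]
        vals = np.r_[np.full(60, np.nan), np.ones(40) * 5.0]
        out, frac = resolve_low(vals, low, ldd=2.0)
        assert out is None and frac == 0.6

    def test_low_substituted_with_half_ldd(self):
        vals = np.r_[np.full(10, np.nan), np.full(90, 5.0)]
        low = np.r_[np.ones(10, bool), np.zeros(90, bool)]
        out, frac = resolve_low(vals, low, ldd=2.0)
        assert np.allclose(out[:10], 1.0)  # LDD / 2
        assert frac == pytest.approx(0.10)

    def test_exact_boundary_retained(self):
        """Exactly 50% LOW: the rule is strictly 'more than 50%'."""
        vals = np.r_[np.full(50, np.nan), np.full(50, 5.0)]
        low = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        out, frac = resolve_low(vals, low, ldd=4.0)
        assert out is not None
        assert frac == 0.5
        assert np.allclose(out[:50], 2.0)


class TestRemoveOutliers:
    def test_single_gross_outlier_deleted(self):
        v = np.r_[np.zeros(99), 100.0]
        out, n = remove_outliers(v)
        assert n == 1 and np.isnan(out[-1])

    def test_constant_column_untouched(self):
        out, n = remove_outliers(np.full(50, 3.3))
        assert n == 0 and not np.isnan(out).any()

    def test_normal_sample_deletion_rate(self):
        """Standard normal, n = 10,000: expect about 2*Phi(-3)*n ~ 27 deletions."""
        x = np.random.default_rng(123).standard_normal(10_000)
        _, n = remove_outliers(x)
        expected = 2 * norm.cdf(-3) * 10_000
        assert expected == pytest.approx(27, abs=1)
        assert 10 <= n <= 45  # +-3.5 binomial SDs around 27

    def test_short_column_warns(self):
        with pytest.warns(UserWarning):
            out, n = remove_outliers(np.array([1.0, 2.0]))
        assert n == 0


class TestNormalize:
    def test_symmetric_no_log(self):
        x = np.random.default_rng(0).normal(10, 2, 2000)
        out, logged, _ = normalize(x)
        assert not logged
        assert abs(np.nanmean(out)) < 1e-9
        assert abs(np.nanstd(out, ddof=1) - 1) < 1e-9

    def test_lognormal_gets_logged(self):
        x = np.exp(np.random.default_rng(1).standard_normal(5000))
        out, logged, _ = normalize(x)
        assert logged
        assert abs(skew(out)) < 0.1

    def test_constant_errors_with_name(self):
        with pytest.raises(QCError, match="CRP"):
            normalize(np.full(10, 2.0), name="CRP")

    def test_zero_shift_logged(self):
        x = np.r_[0.0, np.exp(np.random.default_rng(2).standard_normal(999) * 2)]
        out, logged, shift = normalize(x)
        assert logged and shift > 0


class TestAdjustBatch:
    def test_batch_means_removed(self):
        rng = np.random.default_rng(4)
        b = np.repeat(["A", "B"], 500)
        v = np.r_[rng.normal(1, 1, 500), rng.normal(-1, 1, 500)]
        out, warns = adjust_batch(v, b)
        assert not warns
        assert abs(out[:500].mean()) < 1e-8
        assert abs(out[500:].mean()) < 1e-8

    def test_single_batch_passthrough_with_warning(self):
        v = np.random.default_rng(5).normal(size=100)
        out, warns = adjust_batch(v, ["A"] * 100)
        assert any("one batch" in w for w in warns)
        z = (v - v.mean()) / (v - v.mean()).std(ddof=1)
        assert np.allclose(out, z)

    def test_between_batch_variance_eliminated(self):
        """Injected batch shifts leave a residual between-batch variance
        fraction below 1e-6 (one-way decomposition)."""
        rng = np.random.default_rng(6)
        b = rng.integers(0, 4, 2000).astype(str)
        shifts = {k: s for k, s in zip("0123", rng.normal(0, 0.5, 4))}
        v = rng.normal(size=2000) + np.array([shifts[k] for k in b])
        out, _ = adjust_batch(v, b)
        groups = pd.Series(out).groupby(b)
        ss_between = sum(len(g) * g.mean() ** 2 for _, g in groups)
        ss_total = ((out - out.mean()) ** 2).sum()
        assert ss_between / ss_total < 1e-6


class TestPipeline:
    def _panel(self, read1, read2, low=None, ldd=1.0, batch=None):
        n, m = read1.shape
        idx = [f"S{i}" for i in range(n)]
        cols = [f"A{j}" for j in range(m)]
        return BiomarkerPanel(
            read1=pd.DataFrame(read1, index=idx, columns=cols),
            read2=pd.DataFrame(read2, index=idx, columns=cols),
            low=pd.DataFrame(low if low is not None else np.zeros((n, m), bool),
                             index=idx, columns=cols),
            ldd=pd.Series(ldd, index=cols),
            batch=pd.Series(np.resize(batch if batch is not None else ["B1", "B2"], n),
                            index=idx))

    def test_conservation_and_report(self):
        rng = np.random.default_rng(9)
        base = np.exp(rng.standard_normal((300, 2)))
        r1 = base * (1 + 0.02 * rng.standard_normal((300, 2)))
        r2 = base * (1 + 0.02 * rng.standard_normal((300, 2)))
        panel = self._panel(r1, r2)
        clean, report = run_qc(panel)
        assert report.conservation_ok()
        for a, q in report.analytes.items():
            assert q.n_cells == 300
            assert q.log_applied  # lognormal input

    def test_output_standardized_and_batch_centered(self):
        rng = np.random.default_rng(10)
        base = np.exp(rng.standard_normal((400, 1)) * 0.3)
        panel = self._panel(base, base.copy(), batch=["B1", "B2", "B3", "B4"])
        clean, _ = run_qc(panel)
        col = clean["A0"].dropna()
        assert abs(col.mean()) < 1e-8
        assert abs(col.std(ddof=1) - 1) < 1e-8
        per_batch = col.groupby(panel.batch.loc[col.index]).mean()
        assert per_batch.abs().max() < 1e-8

    def test_normalize_and_batch_stages_idempotent(self):
        """Re-running the scale/location stages on their own output changes
        nothing beyond the affine re-standardization (the 3-SD deletion pass
        is single-shot by design and excluded)."""
        rng = np.random.default_rng(11)
        x = np.exp(rng.standard_normal(1000))
        b = np.resize(["B1", "B2"], 1000)
        y1, _, _ = normalize(x)
        y1, _ = adjust_batch(y1, b)
        y2, logged, _ = normalize(y1)
        assert not logged  # already symmetric
        y2, _ = adjust_batch(y2, b)
        assert np.allclose(y1, y2, atol=1e-10)

    def test_qc_does_not_touch_cohort_inputs(self):
        rng = np.random.default_rng(12)
        base = np.exp(rng.standard_normal((100, 1)))
        panel = self._panel(base, base.copy())
        before = panel.read1.copy()
        run_qc(panel)
        pd.testing.assert_frame_equal(panel.read1, before)
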