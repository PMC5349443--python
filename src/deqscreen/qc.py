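"""Quality control of raw multiplex immunoassay panels.

The fixed pipeline order is: reconcile duplicate reads (discard pairs
differing by more than 5% of their mean, average the survivors) ->
resolve below-detection flags (drop analytes that are LOW in more than half
of their non-missing cells, substitute LDD/2 elsewhere) -> delete values
beyond 3 SD of the analyte mean (single pass, raw scale) -> log-transform
highly skewed analytes and standardize to mean 0 / SD 1 -> residualize on
batch dummy variables and re-standardize.

Every deletion or drop is counted in a :class:`QCReport`; the QC stage never
touches the cohort table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import skew

from .panel import BiomarkerPanel

__all__ = ["QCError", "QCReport", "AnalyteQC", "reconcile_duplicates",
           "resolve_low", "remove_outliers", "normalize", "adjust_batch",
           "run_qc"]

DUPLICATE_TOLERANCE = 0.05
LOW_DROP_FRACTION = 0.50
OUTLIER_SD = 3.0
SKEW_THRESHOLD = 1.0


class QCError(ValueError):
    pass


@dataclass
class AnalyteQC:
    """Per-analyte audit trail of the QC pipeline."""
    n_cells: int = 0
    n_missing_in: int = 0
    n_duplicate_discarded: int = 0
    n_low: int = 0
    low_fraction: float = 0.0
    dropped: bool = False
    n_outliers_deleted: int = 0
    log_applied: bool = False
    zero_shift: float = 0.0
    n_retained: int = 0


@dataclass
class QCReport:
    analytes: dict[str, AnalyteQC] = field(default_factory=dict)
    dropped_analytes: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def conservation_ok(self) -> bool:
        """Cells in = retained + missing-in + every logged removal, per analyte."""
        for a, q in self.analytes.items():
            removed = q.n_duplicate_discarded + q.n_outliers_deleted
            if q.dropped:
                continue
            # LOW cells are substituted, not removed
            if q.n_cells != q.n_retained + q.n_missing_in + removed:
                return False
        return True

    def to_json_dict(self) -> dict:
        return {
            "analytes": {a: vars(q) for a, q in self.analytes.items()},
            "dropped_analytes": list(self.dropped_analytes),
            "warnings": list(self.warnings),
        }


def reconcile_duplicates(read1, read2, tolerance: float = DUPLICATE_TOLERANCE):
    """Average duplicate reads; discard pairs differing by > 5% of their mean.

    The relative difference is |r1 - r2| / mean(r1, r2) — symmetric and
    scale-free.  Vectorized over arrays; NaN pairs pass through as missing.
    Returns (values, n_discarded).  Non-positive numeric reads are a data
    error.
    """
    r1 = np.asarray(read1, float)
    r2 = np.asarray(read2, float)
    both = ~np.isnan(r1) & ~np.isnan(r2)
    if np.any((r1[both] <= 0) | (r2[both] <= 0)):
        raise QCError("non-positive assay read encountered")
    mean = 0.5 * (r1 + r2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.abs(r1 - r2) / mean
    discard = both & (rel > tolerance)
    out = np.where(both & ~discard, mean, np.nan)
    return out, int(discard.sum())


def resolve_low(values, low_mask, ldd: float,
                drop_fraction: float = LOW_DROP_FRACTION):
    """Substitute LDD/2 for below-detection cells, or drop a majority-LOW analyte.

    The LOW fraction is computed over non-missing cells (numeric or LOW).
    Strictly more than ``drop_fraction`` LOW drops the analyte (returns
    ``None``); at exactly the boundary the analyte is retained.
    """
    v = np.asarray(values, float).copy()
    low = np.asarray(low_mask, bool)
    non_missing = low | ~np.isnan(v)
    n_non_missing = int(non_missing.sum())
    frac = float(low.sum()) / n_non_missing if n_non_missing else 0.0
    if frac > drop_fraction:
        return None, frac
    v[low] = ldd / 2.0
    return v, frac


def remove_outliers(values, sd_limit: float = OUTLIER_SD):
    """Single-pass deletion of values beyond ``sd_limit`` SDs of the mean.

    Mean and SD come from the full pre-deletion column.  With fewer than 3
    non-missing values the column passes through with a warning; a constant
    column (SD 0) deletes nothing.
    """
    v = np.asarray(values, float).copy()
    obs = ~np.isnan(v)
    if obs.sum() < 3:
        warnings.warn("fewer than 3 values; outlier screen skipped")
        return v, 0
    m = v[obs].mean()
    s = v[obs].std(ddof=1)
    if s == 0:
        return v, 0
    out = obs & (np.abs(v - m) > sd_limit * s)
    v[out] = np.nan
    return v, int(out.sum())


def normalize(values, skew_threshold: float = SKEW_THRESHOLD, name: str = ""):
    """Log-transform highly skewed columns, then standardize to mean 0 / SD 1.

    The natural log is applied when |sample skewness| exceeds the threshold;
    zeros are shifted up by half the smallest positive value first (logged in
    the return).  A zero-variance column is an error naming the analyte.
    """
    v = np.asarray(values, float).copy()
    obs = ~np.isnan(v)
    x = v[obs]
    if x.size == 0 or np.nanstd(x, ddof=1 if x.size > 1 else 0) == 0:
        raise QCError(f"zero variance in analyte {name or '<unnamed>'}")
    log_applied = False
    shift = 0.0
    if abs(skew(x)) > skew_threshold:
        if np.any(x < 0):
            raise QCError(f"negative values preclude log transform in {name or '<unnamed>'}")
        if np.any(x == 0):
            shift = 0.5 * x[x > 0].min()
            x = x + shift
        x = np.log(x)
        log_applied = True
    sd = x.std(ddof=1)
    if sd == 0:
        raise QCError(f"zero variance in analyte {name or '<unnamed>'}")
    v[obs] = (x - x.mean()) / sd
    return v, log_applied, shift


def adjust_batch(values, batch_labels):
    """Residualize an analyte on batch dummy variables, then re-standardize.

    Reference-cell coding with an intercept; within-batch means of the output
    are zero.  A single batch passes through (re-standardized) with a
    warning, as does any singleton batch (its residual is exactly zero).
    Returns (values, warnings_list).
    """
    v = np.asarray(values, float).copy()
    b = pd.Series(batch_labels).astype(str).to_numpy()
    obs = ~np.isnan(v)
    warns = []
    levels, codes = np.unique(b[obs], return_inverse=True)
    counts = np.bincount(codes)
    for lev, cnt in zip(levels, counts):
        if cnt < 2:
            warns.append(f"batch {lev} has fewer than 2 subjects")
    if len(levels) < 2:
        warns.append("only one batch present; no adjustment applied")
        resid = v[obs] - v[obs].mean()
    else:
        X = np.zeros((obs.sum(), len(levels)))
        X[:, 0] = 1.0
        for k in range(1, len(levels)):
            X[codes == k, k] = 1.0
        beta, *_ = np.linalg.lstsq(X, v[obs], rcond=None)
        resid = v[obs] - X @ beta
    sd = resid.std(ddof=1)
    if sd == 0:
        raise QCError("zero residual variance after batch adjustment")
    v[obs] = resid / sd
    return v, warns


def run_qc(panel: BiomarkerPanel, *, duplicate_tolerance=DUPLICATE_TOLERANCE,
           low_drop_fraction=LOW_DROP_FRACTION, sd_limit=OUTLIER_SD,
           skew_threshold=SKEW_THRESHOLD) -> tuple[pd.DataFrame, QCReport]:
    """Run the full QC pipeline on a panel.

    Returns the analysis-ready wide table (subjects x surviving analytes,
    standardized, batch-residualized, NaN where cells were discarded) and the
    :class:`QCReport` audit.
    """
    report = QCReport()
    clean = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for analyte in panel.analytes:
            q = AnalyteQC()
            r1 = panel.read1[analyte].to_numpy(float)
            r2 = panel.read2[analyte].to_numpy(float)
            low = panel.low[analyte].to_numpy(bool)
            q.n_cells = len(r1)
            # a cell needs both reads (or a LOW flag) to carry information
            q.n_missing_in = int((~low & (np.isnan(r1) | np.isnan(r2))).sum())
            v, q.n_duplicate_discarded = reconcile_duplicates(
                r1, r2, tolerance=duplicate_tolerance)
            q.n_low = int(low.sum())
            v, q.low_fraction = resolve_low(v, low, float(panel.ldd[analyte]),
                                           drop_fraction=low_drop_fraction)
            if v is None:
                q.dropped = True
                report.analytes[analyte] = q
                report.dropped_analytes.append(analyte)
                continue
            v, q.n_outliers_deleted = remove_outliers(v, sd_limit=sd_limit)
            v, q.log_applied, q.zero_shift = normalize(
                v, skew_threshold=skew_threshold, name=analyte)
            v, batch_warns = adjust_batch(v, panel.batch.to_numpy())
            for w in batch_warns:
                report.warnings.append(f"{analyte}: {w}")
            q.n_retained = int((~np.isnan(v)).sum())
            report.analytes[analyte] = q
            clean[analyte] = v
        for w in caught:
            report.warnings.append(str(w.message))
    out = pd.DataFrame(clean, index=panel.subjects.copy())
    out.index.name = "subject_id"
    return out, report
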