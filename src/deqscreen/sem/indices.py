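"""Global fit indices and nested-model chi-square difference tests.

Conventions follow common SEM practice: CMIN/DF is the chi-square per degree
of freedom (< 5 read as adequate), CFI compares the target model with the
independence baseline (values near 1 good), and RMSEA is the per-df,
per-subject root of the noncentrality (<= 0.05 read as close fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist

__all__ = ["FitIndices", "fit_indices", "Chi2Diff", "chi2_diff_test"]


@dataclass
class FitIndices:
    cmin_df: float | None
    cfi: float | None
    rmsea: float | None
    defined: bool = True


def fit_indices(chi2, df, chi2_null=None, df_null=None, n=None) -> FitIndices:
    """Compute CMIN/DF, CFI and RMSEA from model and baseline chi-squares.

    CFI = 1 - max(chi2 - df, 0) / max(chi2_null - df_null, chi2 - df, 0)
    RMSEA = sqrt(max(chi2 - df, 0) / (df * (n - 1)))

    With ``df == 0`` (saturated model) the indices are undefined and a
    sentinel result with ``defined=False`` is returned.  ``chi2_null`` /
    ``df_null`` may be omitted, in which case CFI is None; ``n`` may be
    omitted, in which case RMSEA is None.
    """
    if df is None or df <= 0:
        return FitIndices(None, None, None, defined=False)
    cmin_df = chi2 / df
    cfi = None
    if chi2_null is not None and df_null is not None:
        num = max(chi2 - df, 0.0)
        den = max(chi2_null - df_null, chi2 - df, 0.0)
        cfi = 1.0 if den == 0.0 else 1.0 - num / den
        cfi = float(np.clip(cfi, 0.0, 1.0))
    rmsea = None
    if n is not None:
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    return FitIndices(float(cmin_df), cfi, rmsea)


@dataclass
class Chi2Diff:
    delta_chi2: float
    delta_df: int
    p: float
    negative_flag: bool = False


def chi2_diff_test(fit_constrained, fit_free) -> Chi2Diff:
    """Likelihood-ratio test of a constrained model against the nesting free model.

    Accepts fitted results (anything with ``chi2`` and ``df`` attributes) or
    raw (chi2, df) tuples.  A negative difference is flagged rather than
    silently clipped — it indicates an estimation problem (the constrained
    model fitting 'better' than the model it nests in).
    """
    c2c, dfc = _unpack(fit_constrained)
    c2f, dff = _unpack(fit_free)
    d_chi2 = c2c - c2f
    d_df = dfc - dff
    if d_df < 0:
        raise ValueError("constrained model must have more degrees of freedom than the free model")
    if d_chi2 < 0:
        return Chi2Diff(float(d_chi2), int(d_df), 1.0, negative_flag=True)
    p = 1.0 if d_df == 0 else float(chi2_dist.sf(d_chi2, d_df))
    return Chi2Diff(float(d_chi2), int(d_df), p)


def _unpack(obj):
    if hasattr(obj, "chi2"):
        return float(obj.chi2), int(obj.df)
    c2, df = obj
    return float(c2), int(df)
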