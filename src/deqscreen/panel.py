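"""In-memory container for a multiplex serum-biomarker panel.

A panel holds duplicate immunoassay reads per subject x analyte, a
below-detection ("LOW") flag per cell, the least detectable dose (LDD) per
analyte, and a batch label per subject.  A cell is in exactly one state:
two numeric reads, LOW, or missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BiomarkerPanel"]


@dataclass
class BiomarkerPanel:
    read1: pd.DataFrame  # subjects x analytes, NaN where LOW or missing
    read2: pd.DataFrame
    low: pd.DataFrame  # boolean, True where the cell is below detection
    ldd: pd.Series  # per analyte, > 0
    batch: pd.Series  # per subject, categorical label

    def __post_init__(self):
        if not (self.ldd > 0).all():
            bad = self.ldd.index[~(self.ldd > 0)].tolist()
            raise ValueError(f"LDD must be positive for every analyte; offending: {bad}")
        for df in (self.read2, self.low):
            if df.shape != self.read1.shape:
                raise ValueError("read1, read2 and low must share one shape")

    @property
    def analytes(self) -> list[str]:
        return list(self.read1.columns)

    @property
    def subjects(self) -> pd.Index:
        return self.read1.index

    def copy(self) -> "BiomarkerPanel":
        return BiomarkerPanel(self.read1.copy(), self.read2.copy(),
                              self.low.copy(), self.ldd.copy(), self.batch.copy())

    def cell_states(self) -> pd.DataFrame:
        """Per-cell state: 'numeric', 'low' or 'missing'."""
        numeric = self.read1.notna() & self.read2.notna() & ~self.low
        state = pd.DataFrame("missing", index=self.read1.index, columns=self.read1.columns)
        state = state.mask(self.low, "low")
        state = state.mask(numeric, "numeric")
        return state

    def to_long(self) -> pd.DataFrame:
        """Long-format table: subject_id, analyte, read1, read2 ('LOW' kept as flag)."""
        r1 = self.read1.stack(future_stack=True)
        r2 = self.read2.stack(future_stack=True)
        lw = self.low.stack(future_stack=True)
        out = pd.DataFrame({"read1": r1, "read2": r2, "low": lw})
        out.index.names = ["subject_id", "analyte"]
        return out.reset_index()

    @classmethod
    def from_long(cls, long: pd.DataFrame, ldd: pd.Series, batch: pd.Series) -> "BiomarkerPanel":
        def pivot(col):
            return long.pivot(index="subject_id", columns="analyte", values=col)
        r1, r2 = pivot("read1"), pivot("read2")
        lw = pivot("low").fillna(False).astype(bool)
        return cls(r1.astype(float), r2.astype(float), lw,
                   ldd.astype(float), batch.loc[r1.index])
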