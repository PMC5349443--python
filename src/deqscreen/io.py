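"""CSV/JSON round-trip I/O for cohorts, panels and results.

CSV dialect: comma-separated, UTF-8, header row, missing cells empty.
Panel files are long format (subject_id, analyte, read1, read2) with the
literal string ``LOW`` marking below-detection reads, plus an analyte
metadata file carrying the least detectable dose and a per-subject batch
column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import BiomarkerPanel

__all__ = ["write_cohort", "read_cohort", "write_panel", "read_panel",
           "write_clean", "read_clean", "write_json", "read_json"]

_COHORT_STR = ("subject_id", "diagnosis")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "diagnosis": str})
    if "wave" in df.columns:
        df["wave"] = df["wave"].astype(int)
    return df


def write_panel(panel: BiomarkerPanel, panel_path, meta_path) -> None:
    long = panel.to_long()
    r1 = long["read1"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    r2 = long["read2"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    r1 = r1.where(~long["low"], "LOW")
    r2 = r2.where(~long["low"], "LOW")
    out = pd.DataFrame({
        "subject_id": long["subject_id"], "analyte": long["analyte"],
        "read1": r1, "read2": r2,
        "batch": panel.batch.loc[long["subject_id"]].to_numpy()})
    out.to_csv(panel_path, index=False)
    meta = pd.DataFrame({"analyte": panel.ldd.index, "ldd": panel.ldd.to_numpy()})
    meta.to_csv(meta_path, index=False)


def read_panel(panel_path, meta_path) -> BiomarkerPanel:
    long = pd.read_csv(panel_path, dtype={"subject_id": str, "analyte": str,
                                          "read1": str, "read2": str, "batch": str},
                       keep_default_na=False)
    low = (long["read1"] == "LOW") | (long["read2"] == "LOW")
    def num(col):
        s = long[col].where(~low & (long[col] != ""), np.nan)
        return pd.to_numeric(s, errors="raise")
    long = long.assign(read1=num("read1"), read2=num("read2"), low=low)
    meta = pd.read_csv(meta_path, dtype={"analyte": str})
    ldd = meta.set_index("analyte")["ldd"].astype(float)
    batch = long.drop_duplicates("subject_id").set_index("subject_id")["batch"]
    return BiomarkerPanel.from_long(long[["subject_id", "analyte", "read1",
                                          "read2", "low"]], ldd, batch)


def write_clean(clean: pd.DataFrame, path) -> None:
    clean.to_csv(path, index=True)


def read_clean(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (pd.Series,)):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")
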