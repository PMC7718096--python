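"""CSV contracts for claims, linkage maps, alert ledgers and dispositions.

All tables are plain delimited text with documented headers; dates are
ISO-8601.  Writers are deterministic (stable row order is the caller's
responsibility; formatting is fixed) so identical runs produce byte-identical
files.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

DATE_COLUMNS = {"birth_date", "fill_date", "alert_date", "start_date", "end_date"}


def _stringify_dates(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in DATE_COLUMNS & set(out.columns):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    return out


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _stringify_dates(df).to_csv(path, index=False, lineterminator="\n")
    return path


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"postal_code": str, "pharmacy_id": str})
    for col in DATE_COLUMNS & set(df.columns):
        df[col] = pd.to_datetime(df[col])
    return df


def write_claims(claims: pd.DataFrame, path, include_truth: bool = False) -> Path:
    """Claims CSV per the documented header; the hidden true_patient_key is
    omitted unless explicitly requested."""
    cols = [c for c in claims.columns if include_truth or c != "true_patient_key"]
    return write_table(claims[cols], path)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
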