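"""Tab-separated summary-statistic tables and YAML run configuration.

The interchange format throughout the package is a TSV with header
columns ``variant_id, beta_a, se_a, beta_b, se_b`` and the optional
columns ``pval_a`` and ``block_id``.  Floats are written with 10
significant digits so that write→read round-trips are exact to 1e-12.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["read_summary_table", "write_summary_table", "read_config", "atomic_write"]

REQUIRED_COLUMNS = ("variant_id", "beta_a", "se_a", "beta_b", "se_b")
OPTIONAL_COLUMNS = ("pval_a", "block_id")
_FLOAT_FMT = "%.10g"


class SummaryTableError(ValueError):
    pass


def read_summary_table(path) -> pd.DataFrame:
    """Read and validate a two-context summary-statistic TSV.

    Raises :class:`SummaryTableError` naming the offending row (1-based,
    excluding the header) and column on bad input.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise SummaryTableError(f"{path}: cannot parse as TSV ({exc})") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryTableError(f"{path}: missing required column(s) {missing}")
    for col in ("beta_a", "se_a", "beta_b", "se_b", "pval_a"):
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() if col == "pval_a" else vals.isna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise SummaryTableError(f"{path}: non-numeric value in column {col!r}, row {row}")
        df[col] = vals
    for col in ("se_a", "se_b"):
        nonpos = df[col] <= 0
        if nonpos.any():
            row = int(nonpos.idxmax()) + 1
            raise SummaryTableError(f"{path}: non-positive {col} on row {row}")
    if "pval_a" in df.columns:
        present = df["pval_a"].notna()
        bad = present & ((df["pval_a"] <= 0) | (df["pval_a"] > 1))
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise SummaryTableError(f"{path}: pval_a outside (0, 1] on row {row}")
    if "block_id" in df.columns:
        df["block_id"] = df["block_id"].astype("int64")
    df.attrs["source"] = str(path)
    return df


def write_summary_table(df: pd.DataFrame, path) -> None:
    """Write a summary-stat table as TSV with stable float formatting."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryTableError(f"refusing to write table missing {missing}")
    cols = [c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    with atomic_write(path) as tmp:
        df[cols + extra].to_csv(tmp, sep="\t", index=False, float_format=_FLOAT_FMT)


class atomic_write:
    """Context manager writing to a sibling temp file, renamed on success."""

    def __init__(self, path):
        self.path = Path(path)
        self._tmp = None

    def __enter__(self):
        self.path.parent.mkdir(parents=True, exist_ok=True)
        fd, name = tempfile.mkstemp(dir=self.path.parent, prefix=self.path.name + ".")
        os.close(fd)
        self._tmp = Path(name)
        return self._tmp

    def __exit__(self, exc_type, exc, tb):
        if exc_type is None:
            self._tmp.replace(self.path)
        else:
            self._tmp.unlink(missing_ok=True)
        return False


def read_config(path, allowed_keys=None) -> dict:
    """Load a YAML mapping; unknown keys are rejected with a hint."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a key: value mapping")
    if allowed_keys is not None:
        unknown = sorted(set(cfg) - set(allowed_keys))
        if unknown:
            raise ValueError(
                f"{path}: unknown config key(s) {unknown}; allowed: {sorted(allowed_keys)}"
            )
    return cfg
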