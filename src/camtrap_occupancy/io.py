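"""Readers and writers for the pipeline's tabular artifacts.

Everything is delimited text by default; spreadsheet (.xlsx) input is
accepted for the covariate and detection-matrix tables so deposited
deposited data files can be consumed directly. The detection-matrix dialect
is one row per stacked site with columns ``station_id, year, o1..oK``
(missing occasions as empty/NA) and a parallel effort file with ``e1..eK``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariates import SITE_COVARIATES
from .history import DetectionHistory


def _read_table(path: str) -> pd.DataFrame:
    p = str(path)
    if p.endswith((".xlsx", ".xls")):
        return pd.read_excel(p)
    sep = "\t" if p.endswith((".tsv", ".txt")) else ","
    return pd.read_csv(p, sep=sep)


def read_records(path: str) -> pd.DataFrame:
    df = _read_table(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df[["station_id", "timestamp"]]


def write_records(records: pd.DataFrame, path: str) -> None:
    out = records.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, index=False)


def read_deployments(path: str) -> pd.DataFrame:
    df = _read_table(path)
    for col in ("start", "end"):
        df[col] = pd.to_datetime(df[col])
    return df


def write_deployments(deployments: pd.DataFrame, path: str) -> None:
    out = deployments.copy()
    for col in ("start", "end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_covariates(path: str) -> tuple[pd.DataFrame, bool]:
    """Read a site-covariate table and report whether it looks already
    z-scored (every numeric covariate with mean ~0 and SD ~1) — raw values
    are required to reproduce printed summary statistics, so callers should
    check the flag."""
    df = _read_table(path)
    numeric = [c for c in SITE_COVARIATES if c in df.columns]
    standardized = bool(numeric) and all(
        abs(df[c].mean()) < 0.05 and abs(df[c].std(ddof=1) - 1.0) < 0.05
        for c in numeric
    )
    return df, standardized


def write_covariates(cov: pd.DataFrame, path: str) -> None:
    cov.to_csv(path, index=False)


def write_history(history: DetectionHistory, y_path: str, effort_path: str) -> None:
    K = history.K
    meta = pd.DataFrame(history.site_index, columns=["station_id", "year"])
    ydf = pd.concat(
        [meta, pd.DataFrame(history.y, columns=[f"o{t + 1}" for t in range(K)])],
        axis=1,
    )
    edf = pd.concat(
        [meta, pd.DataFrame(history.effort, columns=[f"e{t + 1}" for t in range(K)])],
        axis=1,
    )
    ydf.to_csv(y_path, index=False, na_rep="NA")
    edf.to_csv(effort_path, index=False)


def read_history(
    y_path: str, effort_path: str | None = None, occasion_length: int = 15
) -> DetectionHistory:
    """Read a prebuilt detection matrix (CSV or spreadsheet), bypassing the
    builder. Without an effort file, effort defaults to the full occasion
    length wherever the matrix is non-missing."""
    ydf = _read_table(y_path)
    occ_cols = [c for c in ydf.columns if c.lower().startswith("o") and c[1:].isdigit()]
    if not occ_cols:
        occ_cols = [c for c in ydf.columns if c not in ("station_id", "year")]
    y = ydf[occ_cols].to_numpy(dtype=float)
    if "station_id" in ydf.columns:
        years = (
            ydf["year"].astype(int)
            if "year" in ydf.columns
            else pd.Series([0] * len(ydf))
        )
        site_index = list(zip(ydf["station_id"].astype(str), years))
    else:
        site_index = [(f"S{i}", 0) for i in range(len(ydf))]
    if effort_path is not None:
        edf = _read_table(effort_path)
        ecols = [c for c in edf.columns if c.lower().startswith("e") and c[1:].isdigit()]
        effort = edf[ecols].to_numpy(dtype=float)
    else:
        effort = np.where(np.isnan(y), 0.0, float(occasion_length))
    hist = DetectionHistory(
        site_index=site_index,
        y=y,
        effort=effort,
        occasion_length_days=occasion_length,
    )
    hist.validate()
    return hist
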