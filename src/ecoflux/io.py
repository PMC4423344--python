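"""Delimited-text I/O and schema validation for the five input tables.

All tables are comma-separated UTF-8 with a header row; time series are
keyed by an ISO-8601 ``timestamp`` column. Missing values are empty
fields, never sentinel numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaValidationError
from .gas_exchange import GasExchangeRecord
from .sap_flow import TreeGeometry

GAS_EXCHANGE_COLUMNS = ["Q", "Ca", "Ci", "A", "E", "gs", "T_leaf", "rh_s", "Cs"]

#: schema registry: required columns and (closed) numeric ranges per column
SCHEMAS = {
    "met": {
        "columns": ["timestamp", "T_air", "RH", "VPD", "PPFD", "theta", "throughfall"],
        "ranges": {"RH": (0, 100), "VPD": (0, 20), "PPFD": (0, 5000),
                   "theta": (0, 1), "throughfall": (0, 500), "T_air": (-50, 60)},
        "timeseries": True,
    },
    "sapflow": {
        "columns": ["timestamp", "tree_id", "depth_class", "dT"],
        "ranges": {"dT": (0, 50)},
        "timeseries": True,
    },
    "geometry": {
        "columns": ["tree_id", "species", "dbh_cm", "sapwood_area_m2", "leaf_area_m2"],
        "ranges": {"dbh_cm": (0, 500), "sapwood_area_m2": (0, 10),
                   "leaf_area_m2": (0, 10000)},
        "timeseries": False,
    },
    "traits": {
        "columns": ["leaf_id", "delta13C_leaf", "delta13C_air", "C_pct", "N_pct", "LMA"],
        "ranges": {"delta13C_leaf": (-100, 20), "N_pct": (0, 100),
                   "C_pct": (0, 100), "LMA": (0, 2000)},
        "timeseries": False,
    },
    "gas_exchange": {
        "columns": ["curve_id", "curve_type"] + GAS_EXCHANGE_COLUMNS,
        "ranges": {"Q": (0, 5000), "rh_s": (0, 1), "Ca": (0, 5000)},
        "timeseries": False,
    },
}


def write_table(df: pd.DataFrame, path) -> None:
    df = df.copy()
    if isinstance(df.index, pd.DatetimeIndex):
        df = df.reset_index(names="timestamp")
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def read_timeseries(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return df.set_index("timestamp")


def records_to_frame(records: list[GasExchangeRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in GAS_EXCHANGE_COLUMNS} for r in records])


def frame_to_records(df: pd.DataFrame) -> list[GasExchangeRecord]:
    return [
        GasExchangeRecord(**{c: float(row[c]) for c in GAS_EXCHANGE_COLUMNS})
        for _, row in df.iterrows()
    ]


def read_geometry(path) -> list[TreeGeometry]:
    df = pd.read_csv(path)
    return [
        TreeGeometry(
            tree_id=str(r.tree_id), species=str(r.species), dbh_cm=float(r.dbh_cm),
            sapwood_area_m2=float(r.sapwood_area_m2), leaf_area_m2=float(r.leaf_area_m2),
        )
        for r in df.itertuples()
    ]


def validate_table(path, schema_name: str) -> list[dict]:
    """Validate a delimited table against a named schema.

    Returns a list of violations (empty when the table is clean), each a
    dict with 'row' (1-based data row, or None for table-level problems)
    and 'message'.
    """
    if schema_name not in SCHEMAS:
        raise SchemaValidationError(f"unknown schema {schema_name!r}")
    schema = SCHEMAS[schema_name]
    try:
        df = pd.read_csv(path)
    except OSError as err:
        raise SchemaValidationError(f"cannot read {path}: {err}") from err

    violations = []
    for col in schema["columns"]:
        if col not in df.columns:
            violations.append({"row": None, "message": f"missing column {col!r}"})
    present = [c for c in schema["columns"] if c in df.columns]

    if schema["timeseries"] and "timestamp" in present:
        ts = pd.to_datetime(df["timestamp"], errors="coerce")
        bad = np.flatnonzero(ts.isna())
        for i in bad[:5]:
            violations.append({"row": int(i) + 1, "message": "unparseable timestamp"})
        if len(bad) == 0:
            key_cols = [c for c in ("tree_id", "depth_class") if c in df.columns]
            groups = df.groupby(key_cols) if key_cols else [(None, df)]
            for _, g in groups:
                gts = pd.to_datetime(g["timestamp"])
                non_mono = np.flatnonzero(np.diff(gts.astype("int64")) <= 0)
                if len(non_mono):
                    violations.append(
                        {"row": int(g.index[non_mono[0] + 1]) + 1,
                         "message": "non-monotone or duplicate timestamp"}
                    )

    for col, (lo, hi) in schema["ranges"].items():
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero((vals < lo) | (vals > hi))
        for i in bad[:10]:
            violations.append(
                {"row": int(i) + 1,
                 "message": f"{col} = {df[col].iloc[i]} outside [{lo}, {hi}]"}
            )
    return violations
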