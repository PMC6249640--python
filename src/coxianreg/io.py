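"""CSV schemas, validated readers/writers and the results bundle.

Fixed v1 schemas (header row required, lines reported 1-based including the
header):

* longitudinal: ``id,time,response[,<covariates...>]``
* survival:     ``id,time,event``  (event 1 = observed, 0 = right-censored)
* effects:      ``id,b0,b1``
* curves:       ``t,value``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import SurvivalSample

__all__ = [
    "SchemaError",
    "read_longitudinal",
    "read_survival",
    "read_effects",
    "write_survival",
    "write_effects",
    "write_curve",
    "write_results",
]


class SchemaError(ValueError):
    """Malformed input file; the message lists offending columns/lines."""


def _line_numbers(df: pd.DataFrame, mask) -> list:
    # +2: 1-based counting plus the header line.
    return (df.index[mask] + 2).tolist()[:10]


def _require_columns(df: pd.DataFrame, required, path, extra_ok=True):
    missing = [c for c in required if c not in df.columns]
    extra = [c for c in df.columns if c not in required]
    if missing or (extra and not extra_ok):
        parts = []
        if missing:
            parts.append(f"missing columns {missing}")
        if extra and not extra_ok:
            parts.append(f"unexpected columns {extra}")
        raise SchemaError(f"{path}: " + "; ".join(parts))


def read_longitudinal(path) -> pd.DataFrame:
    """Long-format biomarker table; extra columns are treated as covariates."""
    df = pd.read_csv(path)
    _require_columns(df, ["id", "time", "response"], path)
    bad = df["time"] < 0
    if bad.any():
        raise SchemaError(f"{path}: negative time at line(s) {_line_numbers(df, bad)}")
    bad = df["response"].isna()
    if bad.any():
        raise SchemaError(
            f"{path}: missing response at line(s) {_line_numbers(df, bad)}"
        )
    return df


def read_survival(path) -> SurvivalSample:
    df = pd.read_csv(path)
    _require_columns(df, ["id", "time", "event"], path, extra_ok=False)
    bad = ~df["event"].isin((0, 1))
    if bad.any():
        raise SchemaError(
            f"{path}: event must be 0 or 1 at line(s) {_line_numbers(df, bad)}"
        )
    bad = df["time"] <= 0
    if bad.any():
        raise SchemaError(
            f"{path}: non-positive time at line(s) {_line_numbers(df, bad)}"
        )
    if df["id"].duplicated().any():
        bad = df["id"].duplicated()
        raise SchemaError(
            f"{path}: duplicate subject id at line(s) {_line_numbers(df, bad)}"
        )
    return SurvivalSample.from_frame(df)


def read_effects(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["id", "b0", "b1"], path, extra_ok=False)
    bad = df[["b0", "b1"]].isna().any(axis=1) | ~np.isfinite(df[["b0", "b1"]]).all(
        axis=1
    )
    if bad.any():
        raise SchemaError(
            f"{path}: non-finite random effect at line(s) {_line_numbers(df, bad)}"
        )
    return df


def write_survival(sample: SurvivalSample, path) -> None:
    sample.to_frame().to_csv(path, index=False)


def write_effects(effects: pd.DataFrame, path) -> None:
    effects[["id", "b0", "b1"]].to_csv(path, index=False)


def write_curve(t, values, path) -> None:
    pd.DataFrame({"t": np.asarray(t), "value": np.asarray(values)}).to_csv(
        path, index=False
    )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_results(bundle: dict, directory) -> Path:
    """Write the machine-readable results bundle as ``results.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / "results.json"
    out.write_text(json.dumps(_jsonify(bundle), indent=2, sort_keys=True) + "\n")
    return out
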