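"""EMA CSV dialect, schema handling, and parameter/report serialization.

CSV dialect (version 1): columns ``subject_id``, ``timestamp``
(ISO-8601), one column per mood item, and optional ``input:<name>``
binary columns.  Missing ratings are empty cells.  Timestamps are
rounded to the nearest minute and re-expressed per subject as minutes
since that subject's first beep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ModelParameters, MoodSeries

__all__ = [
    "EmaSchema",
    "read_ema_csv",
    "write_ema_csv",
    "save_params",
    "load_params",
]

DIALECT_VERSION = 1


@dataclass
class EmaSchema:
    """Column mapping for the EMA CSV dialect."""

    mood_items: list[str]
    input_columns: list[str] = field(default_factory=list)
    subject_column: str = "subject_id"
    timestamp_column: str = "timestamp"
    valence_signs: list[int] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EmaSchema":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            mood_items=list(d["mood_items"]),
            input_columns=list(d.get("input_columns", [])),
            subject_column=d.get("subject_column", "subject_id"),
            timestamp_column=d.get("timestamp_column", "timestamp"),
            valence_signs=d.get("valence_signs"),
        )


def read_ema_csv(path: str | Path, schema: EmaSchema) -> list[MoodSeries]:
    """Parse an EMA CSV into one MoodSeries per subject (deterministic order)."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in [schema.subject_column, schema.timestamp_column, *schema.mood_items, *schema.input_columns]:
        if col not in df.columns:
            raise ValueError(f"schema column {col!r} missing from {path}")
    try:
        ts = pd.to_datetime(df[schema.timestamp_column], format="ISO8601")
    except (ValueError, TypeError) as e:
        raise ValueError(f"unparseable timestamp in {path}: {e}") from e
    for col in schema.input_columns:
        vals = df[col].dropna().unique()
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError(f"input column {col!r} is not binary")
    df = df.assign(_ts=ts.dt.round("min"))
    out = []
    for sid in sorted(df[schema.subject_column].astype(str).unique()):
        sub = df[df[schema.subject_column].astype(str) == sid].sort_values("_ts")
        minutes = ((sub["_ts"] - sub["_ts"].iloc[0]).dt.total_seconds() / 60).round().astype(np.int64)
        inputs = None
        if schema.input_columns:
            inputs = sub[schema.input_columns].fillna(0).to_numpy(dtype=float)
        out.append(
            MoodSeries(
                subject_id=sid,
                beep_times=minutes.to_numpy(),
                ratings=sub[schema.mood_items].to_numpy(dtype=float),
                inputs=inputs,
                item_names=list(schema.mood_items),
                input_names=[c.removeprefix("input:") for c in schema.input_columns],
                valence_signs=np.asarray(schema.valence_signs, dtype=float)
                if schema.valence_signs
                else None,
            )
        )
    return out


def write_ema_csv(
    path: str | Path,
    population: list[MoodSeries],
    origin: str = "2024-01-01T00:00",
) -> None:
    """Write series in the same dialect (beep minutes offset from ``origin``)."""
    t0 = pd.Timestamp(origin)
    frames = []
    for s in population:
        d = {
            "subject_id": s.subject_id,
            "timestamp": [
                (t0 + pd.Timedelta(minutes=int(m))).isoformat() for m in s.beep_times
            ],
        }
        for i, name in enumerate(s.item_names):
            d[name] = s.ratings[:, i]
        if s.inputs is not None:
            for k, name in enumerate(s.input_names):
                d[f"input:{name}"] = s.inputs[:, k].astype(int)
        frames.append(pd.DataFrame(d))
    # %.17g keeps the write->read round trip bit-exact
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def save_params(path: str | Path, params: ModelParameters, extra: dict | None = None) -> None:
    doc = params.to_dict()
    doc["dialect_version"] = DIALECT_VERSION
    if extra:
        doc["meta"] = extra
    Path(path).write_text(json.dumps(doc, indent=1))


def load_params(path: str | Path) -> ModelParameters:
    return ModelParameters.from_dict(json.loads(Path(path).read_text()))
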