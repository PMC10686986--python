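"""CSV schemas and validated readers/writers for all pipeline artifacts.

All files are comma-separated UTF-8 with '.' decimals and a mandatory
header row; times are minutes, percentages live in [0, 100]. Every
writer re-reads what it wrote and checks the schema (round-trip guard).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

SCHEMAS: dict[str, list[str]] = {
    "visits": [
        "sow_id", "group_id", "period", "day",
        "start_time", "duration_min", "feed_g", "nutritive",
    ],
    "ethogram": [
        "sow_id", "period", "active_min", "passive_min",
        "giv_pos", "giv_neg", "rec_pos", "rec_neg",
    ],
    "postures": [
        "group_id", "period", "side_lying", "ventral_lying",
        "standing", "sitting", "eating", "drinking",
    ],
    "registry": ["sow_id", "group_id", "parity", "body_weight_kg", "backfat_mm", "healthy"],
    "schedule": ["group_id", "period", "week_type", "event_type"],
    "truth": ["sow_id", "group_id", "period", "week_type", "event_type", "state"],
    "features": [
        "sow_id", "group_id", "period", "week_type",
        "index_activity", "index_giving", "index_receiving",
        "nb_nv", "nb_nnv", "time_nv", "time_nnv", "avg_nv", "avg_nnv", "rank_cat",
        "side_lying", "ventral_lying", "standing", "sitting", "eating", "drinking",
    ],
    "clusters": ["sow_id", "group_id", "period", "cluster_id", "label"],
}


class SchemaError(ValueError):
    """A CSV file does not match its declared schema."""


def check_schema(df: pd.DataFrame, name: str) -> pd.DataFrame:
    expected = SCHEMAS[name]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")
    return df[expected + [c for c in df.columns if c not in expected]]


def read_table(path: str | Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    if name in ("schedule", "truth") and "event_type" in df.columns:
        df["event_type"] = df["event_type"].fillna("")
    return check_schema(df, name)


def write_table(df: pd.DataFrame, path: str | Path, name: str, ndigits: int = 4) -> None:
    check_schema(df, name)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=f"%.{ndigits}f")
    back = read_table(path, name)  # round-trip guard
    if len(back) != len(df):
        raise SchemaError(f"{name}: round-trip row-count mismatch")
    log.info("wrote %s (%d rows) to %s", name, len(df), path)


def write_dataset(dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the six synthetic streams as CSVs; returns their paths."""
    out_dir = Path(out_dir)
    paths = {}
    for name in ("visits", "ethogram", "postures", "registry", "schedule", "truth"):
        path = out_dir / f"{name}.csv"
        write_table(getattr(dataset, name), path, name)
        paths[name] = path
    return paths


def read_dataset(in_dir: str | Path):
    from sow_welfare.simgen import SimDataset

    in_dir = Path(in_dir)
    return SimDataset(
        **{
            name: read_table(in_dir / f"{name}.csv", name)
            for name in ("visits", "ethogram", "postures", "registry", "schedule", "truth")
        }
    )
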