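"""Result serialization: mode tables as CSV, summaries and reports as JSON."""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .ritz import BucklingResult

__all__ = [
    "write_json",
    "mode_table_frame",
    "write_mode_table_csv",
    "buckling_summary",
    "sweep_frame",
]


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def mode_table_frame(result: BucklingResult, drop_non_buckling: bool = True) -> pd.DataFrame:
    """Per-mode table; non-buckling modes (no positive eigenvalue) are dropped."""
    table = result.table
    if drop_non_buckling:
        table = table.dropna(subset=["N_dimless"])
    return table.reset_index(drop=True)


def write_mode_table_csv(result: BucklingResult, path) -> None:
    mode_table_frame(result).to_csv(path, index=False)


def buckling_summary(
    result: BucklingResult, config: RunConfig, timestamp: bool = True
) -> dict:
    """JSON-ready summary: critical load, mode, parameter echo, version.

    The timestamp is isolated under its own key so that two runs of the same
    configuration are otherwise byte-identical.
    """
    out = {
        "tool": {"name": "mtshell", "version": __version__},
        "result": result.summary_dict(),
        "config": config.to_dict(),
    }
    if timestamp:
        out["timestamp"] = _dt.datetime.now(_dt.timezone.utc).isoformat()
    return out


def sweep_frame(rows: list[tuple[str, float, BucklingResult]]) -> pd.DataFrame:
    """Long-format sweep table: one row per grid point with N_cr and mode."""
    records = []
    for axis, value, res in rows:
        records.append(
            {
                "axis": axis,
                "value": value,
                "status": res.status,
                "N_cr": res.N_cr,
                "N_cr_dimless": res.N_cr_dimless,
                "m": None if res.mode is None else res.mode.m,
                "n": None if res.mode is None else res.mode.n,
                "eta": res.eta,
            }
        )
    return pd.DataFrame.from_records(records)
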