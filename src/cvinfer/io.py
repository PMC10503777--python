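"""Columnar text I/O for every pipeline stage.

All files are CSV with a single leading comment line identifying the
schema (``# cvinfer <kind> v1``); readers validate the expected columns and
name the missing ones in errors.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .params import PARAM_NAMES
from .series import ObservableSeries, WaveformRecord

_SCHEMAS = {
    "trace": ["t", "pa", "pv", "hr", "pp", "rc", "sb", "stot", "rmod",
              "iex", "s", "msvr"],
    "waveform": ["t", "abp", "cvp"],
    "observables": ["t", "pa", "pv", "hr", "pp", "rc"],
    "estimates": ["start", *PARAM_NAMES, "cost", "winner"],
    "indices": ["start", "i_bar_ex", "m_svr_mid", "k_max_rel"],
}


def write_table(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    cols = [c for c in _SCHEMAS[kind] if c in df.columns]
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table missing columns: {missing}")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# cvinfer {kind} v1\n")
        df[cols].to_csv(fh, index=False, float_format="%.10g")


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: not a {kind} table, missing columns {missing}")
    return df


def write_observables(obs: ObservableSeries, path: str | Path) -> None:
    write_table(obs.to_frame(), path, "observables")


def read_observables(path: str | Path) -> ObservableSeries:
    return ObservableSeries.from_frame(read_table(path, "observables"))


def write_waveform(rec: WaveformRecord, path: str | Path) -> None:
    write_table(rec.to_frame(), path, "waveform")


def read_waveform(path: str | Path) -> WaveformRecord:
    return WaveformRecord.from_frame(read_table(path, "waveform"))
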