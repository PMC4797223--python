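"""WAV and tabular I/O with schema validation, plus provenance records."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .audio_engine import AudioBuffer

__all__ = [
    "read_wav",
    "write_wav",
    "ColumnSpec",
    "TableSchema",
    "read_table",
    "write_table",
    "SESSION_LOG_SCHEMA",
    "OUTCOME_SCHEMA",
    "HARMS_SCHEMA",
    "ROSTER_SCHEMA",
    "write_provenance",
]

_PCM_SCALE = {np.dtype("int16"): 2 ** 15, np.dtype("int32"): 2 ** 31,
              np.dtype("uint8"): None}


def read_wav(path) -> AudioBuffer:
    """Read a WAV file into a float64 AudioBuffer (PCM scaled to ±1)."""
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - surface a uniform parse error
        raise ValueError(f"could not parse WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.dtype in (np.dtype("float32"), np.dtype("float64")):
        samples = data.astype(np.float64)
    elif data.dtype == np.dtype("uint8"):
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    else:
        raise ValueError(f"unsupported WAV encoding {data.dtype} in {path}")
    return AudioBuffer(samples=samples, rate=int(rate))


def write_wav(buf: AudioBuffer, path, encoding: str = "float32") -> None:
    """Write an AudioBuffer; ``encoding`` is 'float32' or 'pcm16'.

    Samples outside ±1 are clipped for PCM output (a clipping count could
    be logged by the caller via ``np.abs(buf.samples).max()``).
    """
    x = buf.samples
    if encoding == "float32":
        wavfile.write(path, buf.rate, x.astype(np.float32))
    elif encoding == "pcm16":
        clipped = np.clip(x, -1.0, 1.0 - 1.0 / 2 ** 15)
        wavfile.write(path, buf.rate, (clipped * 2 ** 15).astype(np.int16))
    else:
        raise ValueError(f"unsupported encoding {encoding!r}")


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    dtype: str = "float"  # "float" | "int" | "str"
    required: bool = True
    bounds: tuple[float, float] | None = None
    allowed: tuple | None = None


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple

    def validate(self, df: pd.DataFrame) -> pd.DataFrame:
        errors = []
        for col in self.columns:
            if col.name not in df.columns:
                if col.required:
                    errors.append(f"missing required column '{col.name}'")
                continue
            series = df[col.name]
            if col.dtype in ("float", "int"):
                coerced = pd.to_numeric(series, errors="coerce")
                bad = series.notna() & coerced.isna()
                for idx in df.index[bad]:
                    errors.append(f"row {idx}: '{col.name}' not numeric: "
                                  f"{series[idx]!r}")
                series = coerced
                df = df.assign(**{col.name: series})
            if col.bounds is not None:
                lo, hi = col.bounds
                bad = series.notna() & ((series < lo) | (series > hi))
                for idx in df.index[bad]:
                    errors.append(f"row {idx}: '{col.name}'={series[idx]} "
                                  f"outside [{lo}, {hi}]")
            if col.allowed is not None:
                bad = series.notna() & ~series.isin(col.allowed)
                for idx in df.index[bad]:
                    errors.append(f"row {idx}: '{col.name}'={series[idx]!r} "
                                  f"not in {col.allowed}")
        if errors:
            raise ValueError(f"schema '{self.name}' violations:\n  "
                             + "\n  ".join(errors))
        return df


SESSION_LOG_SCHEMA = TableSchema("pitch_session_log", (
    ColumnSpec("session_id", "str"),
    ColumnSpec("round", "int"),
    ColumnSpec("low_hz", "float", bounds=(0.0, np.inf)),
    ColumnSpec("high_hz", "float", bounds=(0.0, np.inf)),
    ColumnSpec("choice_low", "str", allowed=("low_end", "high_end")),
    ColumnSpec("choice_high", "str", allowed=("low_end", "high_end")),
    ColumnSpec("matched_hz", "float", bounds=(0.0, np.inf)),
    ColumnSpec("loudness", "float", required=False),
))

OUTCOME_SCHEMA = TableSchema("outcomes_long", (
    ColumnSpec("participant_id", "str"),
    ColumnSpec("arm", "str", allowed=("treatment", "placebo")),
    ColumnSpec("session", "str",
               allowed=("baseline", "pre", "post", "followup")),
    ColumnSpec("measure", "str"),
    ColumnSpec("value", "float"),
))

HARMS_SCHEMA = TableSchema("harms", (
    ColumnSpec("participant_id", "str"),
    ColumnSpec("arm", "str", allowed=("treatment", "placebo")),
    ColumnSpec("category", "str"),
))

ROSTER_SCHEMA = TableSchema("roster", (
    ColumnSpec("id", "str"),
    ColumnSpec("age", "float", bounds=(0.0, 120.0)),
    ColumnSpec("hearing_loss_db", "float", bounds=(0.0, 130.0)),
    ColumnSpec("tinnitus_hz", "float", bounds=(0.0, np.inf)),
    ColumnSpec("chronicity_months", "float", bounds=(0.0, np.inf)),
))

#: VAS bounds are enforced when the outcomes table carries VAS measures.
VAS_BOUNDS = (0.0, 100.0)


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read a CSV and validate it against ``schema``.

    Missing cells stay as NA markers (never silently zero). For the
    outcomes schema, VAS rows are additionally bounds-checked to 0–100.
    """
    df = pd.read_csv(path)
    df = schema.validate(df)
    if schema is OUTCOME_SCHEMA and len(df):
        vas = df["measure"].astype(str).str.startswith("vas")
        bad = vas & df["value"].notna() & (
            (df["value"] < VAS_BOUNDS[0]) | (df["value"] > VAS_BOUNDS[1]))
        if bad.any():
            rows = ", ".join(str(i) for i in df.index[bad])
            raise ValueError(f"VAS values outside the 0–100 bound at rows: {rows}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_provenance(path, command: str, config: dict, seed) -> None:
    """Record what produced an output: package version, config, seeds."""
    from . import __version__

    record = {"tool": "notchkit", "version": __version__,
              "command": command, "seed": seed, "config": config}
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
        fh.write("\n")
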