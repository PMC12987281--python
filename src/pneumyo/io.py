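"""CSV readers and writers for pressure traces.

Trace CSV schema: ``time_ms`` (integer), ``pressure_kpa`` (float), optional
``label`` (string).  Comma-separated, UTF-8, '.' decimal, mandatory header.
Sampling uniformity is verified on read (constant time deltas within 1 ms).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synth import PressureTrace

__all__ = ["read_trace_csv", "write_trace_csv"]


class TraceParseError(ValueError):
    """Malformed trace CSV (missing columns, bad values, irregular timing)."""


def read_trace_csv(path) -> PressureTrace:
    """Read a pressure trace, validating schema and sampling uniformity."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"time_ms", "pressure_kpa"}
    missing = required - set(df.columns)
    if missing:
        raise TraceParseError(f"{path}: missing columns {sorted(missing)}")
    pressures = pd.to_numeric(df["pressure_kpa"], errors="coerce")
    bad = pressures.isna()
    if bad.any():
        line = int(np.argmax(bad.values)) + 2  # header is line 1
        raise TraceParseError(f"{path}: non-numeric pressure at line {line}")
    t = pd.to_numeric(df["time_ms"], errors="coerce")
    if t.isna().any():
        line = int(np.argmax(t.isna().values)) + 2
        raise TraceParseError(f"{path}: non-numeric time at line {line}")
    t = t.to_numpy(dtype=float)
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            line = int(np.argmax(dt <= 0)) + 3
            raise TraceParseError(f"{path}: non-monotone time at line {line}")
        if np.any(np.abs(dt - dt[0]) > 1.0):
            line = int(np.argmax(np.abs(dt - dt[0]) > 1.0)) + 3
            raise TraceParseError(f"{path}: irregular sampling at line {line}")
        rate_hz = 1000.0 / dt[0]
    else:
        rate_hz = 100.0
    labels = None
    if "label" in df.columns:
        labels = df["label"].astype(str).to_numpy(dtype=object)
    return PressureTrace(values=pressures.to_numpy(dtype=float),
                         sampling_rate_hz=rate_hz, labels=labels,
                         meta={"source": str(path)})


def write_trace_csv(trace: PressureTrace, path) -> None:
    """Write a trace to CSV (times as integer milliseconds)."""
    dt_ms = 1000.0 / trace.sampling_rate_hz
    data = {
        "time_ms": np.round(np.arange(len(trace)) * dt_ms).astype(int),
        "pressure_kpa": trace.values,
    }
    if trace.labels is not None:
        data["label"] = trace.labels
    pd.DataFrame(data).to_csv(path, index=False)
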