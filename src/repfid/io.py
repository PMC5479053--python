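"""CSV dialects for event tables and calibration beads.

Events: ``cell_id, nanog, reporter, condition, day, replicate`` (one row per
cell).  Beads: ``intensity, mesf``.  Parsing errors name the offending
column; writing is deterministic (fixed float formatting, no timestamps).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import SchemaError
from .expression_stats import EVENT_COLUMNS, BeadSet, ExpressionSample

__all__ = ["read_events_csv", "write_events_csv", "read_beads_csv", "write_beads_csv"]


def write_events_csv(sample: ExpressionSample, path: str | Path) -> None:
    sample.data.to_csv(path, index=False, float_format="%.10g")


def read_events_csv(path: str | Path, units: str = "arbitrary") -> ExpressionSample:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"cannot parse event CSV {path}: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in ("nanog", "reporter"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(vals.to_numpy(dtype=float)))[0]
        if bad.size:
            raise SchemaError(f"{path}: column {col!r} row {bad[0] + 2} is not a finite number")
        df[col] = vals
    df["day"] = df["day"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    return ExpressionSample(data=df, units=units)


def write_beads_csv(beads: BeadSet, path: str | Path) -> None:
    pd.DataFrame({"intensity": beads.intensity, "mesf": beads.mesf}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_beads_csv(path: str | Path) -> BeadSet:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"cannot parse bead CSV {path}: {exc}") from exc
    for col in ("intensity", "mesf"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return BeadSet(intensity=df["intensity"].to_numpy(), mesf=df["mesf"].to_numpy())
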