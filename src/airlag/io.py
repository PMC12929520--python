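"""Reading and writing the canonical daily-panel CSV.

The interchange format is a single flat CSV with one row per day.  Column
names can be remapped via a schema map, so files from different providers
do not need to be renamed by hand; everything else about the schema is
validated strictly, with row numbers and dates in the error report,
because silently dropped or misparsed days are the classic time-series
pitfall.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .series import POLLUTANTS, DailySeries, ValidationError

__all__ = ["read_daily_csv", "write_daily_csv"]

_CANONICAL = ("date", *POLLUTANTS, "at", "rh", "admissions")


def read_daily_csv(path, schema_map: dict[str, str] | None = None) -> DailySeries:
    """Parse and validate a daily panel.

    ``schema_map`` maps file column names to canonical names (e.g.
    ``{"PM2.5": "pm25", "temp": "at"}``).  Dates must parse, be unique and
    gap-free; concentrations nonnegative (CO is expected in mg/m3, the
    others in ug/m3); admissions nonnegative integers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if schema_map:
        df = df.rename(columns=schema_map)
    missing = [c for c in _CANONICAL[:-1] if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path.name}: missing columns {missing}; "
            f"present: {list(df.columns)} (use schema_map to rename)"
        )
    try:
        parsed = pd.to_datetime(df["date"], format="mixed")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path.name}: malformed dates: {exc}") from exc
    df = df.assign(date=parsed).sort_values("date").reset_index(drop=True)
    try:
        return DailySeries(df)
    except ValidationError as exc:
        raise ValidationError(f"{path.name}: {exc}") from exc


def write_daily_csv(series: DailySeries, path) -> Path:
    """Write a panel back to CSV (dates as ISO strings); round-trippable."""
    path = Path(path)
    out = series.df.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return path
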