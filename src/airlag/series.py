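"""The daily city-level panel: exposures, meteorology and admission counts.

``DailySeries`` is a thin validated wrapper around a pandas DataFrame with a
fixed schema — one row per calendar day, gap-free.  It is the single input
object of the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DailySeries", "POLLUTANTS", "MET_VARS", "STRATA"]

#: canonical pollutant column names; concentrations in ug/m3 except CO (mg/m3)
POLLUTANTS = ("pm25", "pm10", "so2", "no2", "o3", "co")
MET_VARS = ("at", "rh")
STRATA = ("male", "female", "age_18_64", "age_65plus")


class ValidationError(ValueError):
    """Raised when a daily panel violates the schema invariants."""


@dataclass
class DailySeries:
    """Validated daily panel.

    Required columns: ``date`` plus the six pollutants and ``at``/``rh``.
    ``admissions`` (and optional strata counts) may be absent on
    exposure-only series produced mid-simulation.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        problems: list[str] = []
        required = ("date", *POLLUTANTS, *MET_VARS)
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")

        dates = pd.to_datetime(df["date"])
        dup = dates[dates.duplicated()]
        if len(dup):
            problems.append(f"duplicated dates: {list(dup.dt.date.astype(str))[:5]}")
        gaps = dates.diff().dropna()
        bad = gaps[gaps != pd.Timedelta(days=1)]
        if len(bad):
            problems.append(
                f"dates not consecutive at rows {list(bad.index[:5])} "
                "(gaps must be explicitly imputed before analysis)"
            )
        for col in POLLUTANTS:
            v = df[col].to_numpy(dtype=float)
            neg = np.flatnonzero(v < 0)
            if neg.size:
                problems.append(f"{col} negative at rows {neg[:5].tolist()}")
        rh = df["rh"].to_numpy(dtype=float)
        bad_rh = np.flatnonzero((rh < 0) | (rh > 100))
        if bad_rh.size:
            problems.append(f"rh outside [0, 100] at rows {bad_rh[:5].tolist()}")
        if "admissions" in df.columns:
            adm = df["admissions"].to_numpy()
            if np.any(adm < 0):
                problems.append(
                    f"admissions negative at rows {np.flatnonzero(adm < 0)[:5].tolist()}"
                )
            elif not np.allclose(adm, np.round(adm)):
                problems.append("admissions must be integer counts")
            present = [s for s in ("male", "female") if s in df.columns]
            if len(present) == 2:
                tot = df["male"].to_numpy() + df["female"].to_numpy()
                off = np.flatnonzero(tot != adm)
                if off.size:
                    problems.append(
                        f"male + female != admissions at rows {off[:5].tolist()}"
                    )
        if problems:
            raise ValidationError("; ".join(problems))

        df = df.copy()
        df["date"] = dates
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def dates(self) -> pd.Series:
        return self.df["date"]

    @property
    def has_counts(self) -> bool:
        return "admissions" in self.df.columns

    @property
    def years(self) -> pd.Series:
        return self.df["date"].dt.year

    def season(self) -> pd.Series:
        """'cold' for November-March (northern-China heating season), else 'warm'."""
        m = self.df["date"].dt.month
        return pd.Series(np.where((m >= 11) | (m <= 3), "cold", "warm"), index=self.df.index)

    def slice_dates(self, start=None, end=None) -> "DailySeries":
        d = self.df
        mask = pd.Series(True, index=d.index)
        if start is not None:
            mask &= d["date"] >= pd.Timestamp(start)
        if end is not None:
            mask &= d["date"] <= pd.Timestamp(end)
        return DailySeries(d.loc[mask].reset_index(drop=True))

    def n_years_span(self) -> float:
        """Length of the panel in years (days / 365.25)."""
        return len(self.df) / 365.25
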