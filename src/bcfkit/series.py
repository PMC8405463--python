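"""Timestamped, replicated concentration series with censoring flags.

A :class:`ConcentrationSeries` holds the measurements of one analyte in one
medium — exposure water (ug/L) or pooled organisms (ng/g wet weight) — as a
tidy :class:`pandas.DataFrame` with columns ``time_h, replicate, value,
censoring, n_pooled``.  Values below the limit of detection carry the flag
``below_lod`` (not usable quantitatively); values between LOD and LOQ carry
``below_loq`` (usable, flagged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "ConcentrationSeries",
    "CENSOR_NONE",
    "CENSOR_BELOW_LOQ",
    "CENSOR_BELOW_LOD",
    "SERIES_COLUMNS",
    "read_series_table",
    "write_series_table",
]

CENSOR_NONE = "none"
CENSOR_BELOW_LOQ = "below_loq"
CENSOR_BELOW_LOD = "below_lod"
_CENSOR_LEVELS = (CENSOR_NONE, CENSOR_BELOW_LOQ, CENSOR_BELOW_LOD)

SERIES_COLUMNS = ["analyte", "medium", "time_h", "replicate", "value", "censoring", "n_pooled"]


@dataclass
class ConcentrationSeries:
    """Measurements of one analyte in one medium.

    Attributes
    ----------
    analyte : str
    medium : {"water", "organism"}
        Fixes the unit convention: ug/L for water, ng/g wet weight for
        organism pools.
    data : pandas.DataFrame
        Columns ``time_h`` (hours, >= 0), ``replicate`` (id), ``value``
        (concentration, >= 0 when uncensored), ``censoring`` (one of
        ``none``/``below_loq``/``below_lod``), ``n_pooled`` (individuals per
        pool; 1 for water samples).
    """

    analyte: str
    medium: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.medium not in ("water", "organism"):
            raise InvalidInputError(f"medium must be 'water' or 'organism', got {self.medium!r}")
        df = pd.DataFrame(self.data).copy()
        for col, default in (("censoring", CENSOR_NONE), ("n_pooled", 1)):
            if col not in df.columns:
                df[col] = default
        missing = {"time_h", "replicate", "value"} - set(df.columns)
        if missing:
            raise InvalidInputError(f"series data missing columns {sorted(missing)}")
        df["time_h"] = df["time_h"].astype(float)
        df["value"] = df["value"].astype(float)
        df["n_pooled"] = df["n_pooled"].astype(int)
        if (df["time_h"] < 0).any():
            raise InvalidInputError("times must be >= 0")
        bad = ~df["censoring"].isin(_CENSOR_LEVELS)
        if bad.any():
            raise InvalidInputError(f"unknown censoring flags: {sorted(df.loc[bad, 'censoring'].unique())}")
        uncensored = df["censoring"] == CENSOR_NONE
        if (df.loc[uncensored, "value"] < 0).any():
            raise InvalidInputError("uncensored values must be >= 0")
        # keep rows sorted by replicate then time for stable downstream output
        df = df.sort_values(["replicate", "time_h"], kind="stable").reset_index(drop=True)
        self.data = df

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        """Sorted distinct sampling times (hours)."""
        return np.sort(self.data["time_h"].unique())

    def usable(self, include_below_loq: bool = True) -> pd.DataFrame:
        """Rows quantitatively usable for analysis.

        Below-LOD rows are always excluded; below-LOQ rows are retained by
        default (flagged but measured).
        """
        keep = [CENSOR_NONE] + ([CENSOR_BELOW_LOQ] if include_below_loq else [])
        return self.data[self.data["censoring"].isin(keep)]

    def replicate_means(self, include_below_loq: bool = True) -> pd.Series:
        """Mean usable value per sampling time, indexed by ``time_h``."""
        usable = self.usable(include_below_loq)
        return usable.groupby("time_h")["value"].mean()

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame including analyte/medium identity columns."""
        df = self.data.copy()
        df.insert(0, "medium", self.medium)
        df.insert(0, "analyte", self.analyte)
        return df[SERIES_COLUMNS]


def _from_group(analyte: str, medium: str, df: pd.DataFrame) -> ConcentrationSeries:
    return ConcentrationSeries(
        analyte=analyte,
        medium=medium,
        data=df[["time_h", "replicate", "value", "censoring", "n_pooled"]],
    )


def read_series_table(path: str | Path, sep: str | None = None) -> list[ConcentrationSeries]:
    """Read a delimited long-format table into one series per (analyte, medium).

    Expected columns: ``analyte, medium, time_h, replicate, value``
    (``censoring`` and ``n_pooled`` optional).  Raises a parse error naming
    the file on malformed input.
    """
    try:
        df = pd.read_csv(path, sep=sep, engine="python", skipinitialspace=True)
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise InvalidInputError(f"cannot read series table {path}: {exc}") from exc
    missing = {"analyte", "medium", "time_h", "replicate", "value"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (analyte, medium), grp in df.groupby(["analyte", "medium"], sort=True):
        if "censoring" not in grp.columns:
            grp = grp.assign(censoring=CENSOR_NONE)
        if "n_pooled" not in grp.columns:
            grp = grp.assign(n_pooled=1)
        grp = grp.copy()
        grp["censoring"] = grp["censoring"].fillna(CENSOR_NONE)
        out.append(_from_group(str(analyte), str(medium), grp))
    return out


def write_series_table(series: Iterable[ConcentrationSeries], path: str | Path,
                       sep: str = ",") -> None:
    """Write series as one long-format delimited table (lossless round trip)."""
    frames = [s.to_frame() for s in series]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=SERIES_COLUMNS)
    df.to_csv(path, sep=sep, index=False)
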