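"""Posture event series and sleep logs.

Events are the criterion measure in this package: ground-truth bouts of
sedentary (sitting/lying), standing, and stepping behaviour plus time-in-bed
intervals, with the integer codes used in the event CSV dialect
(``start,end,code``): 0 = sedentary, 1 = standing, 2 = stepping, 9 = in bed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEDENTARY = 0
STANDING = 1
STEPPING = 2
IN_BED = 9

VALID_CODES = frozenset({SEDENTARY, STANDING, STEPPING, IN_BED})

__all__ = [
    "SEDENTARY", "STANDING", "STEPPING", "IN_BED", "PostureEventSeries",
    "SleepLog", "write_events_csv", "read_events_csv",
]


@dataclass
class PostureEventSeries:
    """Time-ordered, non-overlapping posture bouts.

    ``frame`` has columns ``start`` and ``end`` (timestamps) and ``code``
    (integer posture code).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.reset_index(drop=True).copy()
        df["start"] = pd.to_datetime(df["start"])
        df["end"] = pd.to_datetime(df["end"])
        df["code"] = df["code"].astype(int)
        if not set(df["code"]).issubset(VALID_CODES):
            bad = sorted(set(df["code"]) - VALID_CODES)
            raise ValueError(f"unknown posture codes: {bad}")
        if (df["end"] <= df["start"]).any():
            raise ValueError("every event must have end > start")
        if not df["start"].is_monotonic_increasing:
            raise ValueError("events must be time-ordered")
        if (df["start"].iloc[1:].to_numpy() < df["end"].iloc[:-1].to_numpy()).any():
            raise ValueError("events must not overlap")
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    def of_code(self, code: int) -> pd.DataFrame:
        return self.frame[self.frame["code"] == code]

    def minutes_in_window(self, code: int, w_start, w_end) -> float:
        """Total duration (minutes) of ``code`` events clipped to [w_start, w_end)."""
        df = self.of_code(code)
        s = df["start"].clip(lower=pd.Timestamp(w_start))
        e = df["end"].clip(upper=pd.Timestamp(w_end))
        dur = (e - s).dt.total_seconds().clip(lower=0.0)
        return float(dur.sum()) / 60.0


@dataclass
class SleepLog:
    """Per-night time-in-bed intervals.

    ``frame`` has one row per night with columns ``date`` (the night label,
    a date), ``bed_start`` and ``bed_end``; intervals may cross midnight.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.reset_index(drop=True).copy()
        df["bed_start"] = pd.to_datetime(df["bed_start"])
        df["bed_end"] = pd.to_datetime(df["bed_end"])
        if (df["bed_end"] <= df["bed_start"]).any():
            raise ValueError("bed_end must be after bed_start")
        if df["date"].duplicated().any():
            raise ValueError("one time-in-bed record per night")
        self.frame = df.sort_values("bed_start").reset_index(drop=True)

    def has_night(self, date) -> bool:
        return pd.Timestamp(date).date() in set(self.frame["date"])

    def bed_intervals_in_day(self, date) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        """All in-bed intervals clipped to calendar day ``date`` (any night)."""
        d0 = pd.Timestamp(date).normalize()
        d1 = d0 + pd.Timedelta(days=1)
        out = []
        for _, row in self.frame.iterrows():
            s = max(row["bed_start"], d0)
            e = min(row["bed_end"], d1)
            if e > s:
                out.append((s, e))
        return out

    def waking_minutes(self, date) -> float:
        bed = sum((e - s).total_seconds() for s, e in self.bed_intervals_in_day(date))
        return (86400.0 - bed) / 60.0


def write_events_csv(events: PostureEventSeries, path) -> None:
    events.frame.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def read_events_csv(path) -> PostureEventSeries:
    df = pd.read_csv(path)
    expected = ["start", "end", "code"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header 'start,end,code'")
    return PostureEventSeries(df)
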