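"""Epoch-level acceleration metrics: ENMO and MAD, non-wear, imputation.

ENMO (Euclidean Norm Minus One) subtracts 1 g from the per-sample vector
magnitude, truncates negatives to zero, and averages over the epoch.  MAD
(Mean Amplitude Deviation) is the mean absolute deviation of the magnitude
around the epoch's own mean.  Both are reported in mg on a fixed 5-s epoch
grid; the trailing partial epoch is dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .recording import RawRecording

__all__ = ["WORN", "NONWEAR", "IMPUTED", "EpochSeries", "enmo_epochs",
           "mad_epochs", "epoch_series", "detect_nonwear", "impute_nonwear"]

WORN = 0
NONWEAR = 1
IMPUTED = 2


@dataclass
class EpochSeries:
    """5-s (by default) epoch ENMO and MAD values in mg, with wear flags."""

    start_time: pd.Timestamp
    epoch_s: float
    enmo_mg: np.ndarray
    mad_mg: np.ndarray
    wear: np.ndarray  # WORN / NONWEAR / IMPUTED per epoch

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.enmo_mg = np.asarray(self.enmo_mg, dtype=float)
        self.mad_mg = np.asarray(self.mad_mg, dtype=float)
        self.wear = np.asarray(self.wear, dtype=np.int8)
        n = len(self.enmo_mg)
        if len(self.mad_mg) != n or len(self.wear) != n:
            raise ValueError("all epoch sequences must have equal length")
        if np.any(self.enmo_mg < 0) or np.any(self.mad_mg < 0):
            raise ValueError("epoch metrics must be non-negative")

    def __len__(self) -> int:
        return len(self.enmo_mg)

    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self),
                             freq=pd.Timedelta(seconds=self.epoch_s))

    def values(self, metric: str) -> np.ndarray:
        if metric not in ("enmo", "mad"):
            raise ValueError("metric must be 'enmo' or 'mad'")
        return self.enmo_mg if metric == "enmo" else self.mad_mg

    def to_dataframe(self) -> pd.DataFrame:
        names = {WORN: "worn", NONWEAR: "nonwear", IMPUTED: "imputed"}
        return pd.DataFrame({
            "time": self.times(), "enmo_mg": self.enmo_mg,
            "mad_mg": self.mad_mg,
            "wear_flag": [names[int(f)] for f in self.wear],
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, epoch_s: float = 5.0):
        codes = {"worn": WORN, "nonwear": NONWEAR, "imputed": IMPUTED}
        t = pd.to_datetime(df["time"])
        if len(t) > 1:
            epoch_s = float((t.iloc[1] - t.iloc[0]).total_seconds())
        return cls(t.iloc[0], epoch_s, df["enmo_mg"].to_numpy(),
                   df["mad_mg"].to_numpy(),
                   np.array([codes[f] for f in df["wear_flag"]]))


def _epoch_magnitudes(rec: RawRecording, epoch_s: float) -> np.ndarray:
    spe = epoch_s * rec.sample_rate_hz
    if abs(spe - round(spe)) > 1e-9:
        raise ValueError("epoch_s times sample rate must be an integer")
    spe = int(round(spe))
    n_epochs = rec.n_samples // spe
    mag = np.linalg.norm(rec.samples[: n_epochs * spe], axis=1)
    return mag.reshape(n_epochs, spe)


def _enmo_from_mag(mag: np.ndarray) -> np.ndarray:
    return 1000.0 * np.maximum(mag - 1.0, 0.0).mean(axis=1, dtype=np.float64)


def _mad_from_mag(mag: np.ndarray) -> np.ndarray:
    dev = mag - mag.mean(axis=1, keepdims=True, dtype=np.float64)
    return 1000.0 * np.abs(dev).mean(axis=1, dtype=np.float64)


def enmo_epochs(rec: RawRecording, epoch_s: float = 5.0) -> np.ndarray:
    """Epoch-averaged ENMO in mg: mean of max(|a| - 1, 0) per sample."""
    return _enmo_from_mag(_epoch_magnitudes(rec, epoch_s))


def mad_epochs(rec: RawRecording, epoch_s: float = 5.0) -> np.ndarray:
    """Epoch MAD in mg: mean |r - mean(r)| of the magnitude within the epoch."""
    return _mad_from_mag(_epoch_magnitudes(rec, epoch_s))


def detect_nonwear(rec: RawRecording, epoch_s: float = 5.0,
                   block_min: float = 15.0, window_min: float = 60.0,
                   sd_threshold_mg: float = 13.0,
                   range_threshold_mg: float = 50.0,
                   min_axes: int = 2) -> np.ndarray:
    """Per-epoch non-wear flags.

    A 15-min block is non-wear when, over the surrounding 60-min window, at
    least ``min_axes`` axes show both SD below 13 mg and value range below
    50 mg (sustained, implausibly still signal).  Flags are broadcast to the
    epoch grid.  A recording shorter than one window is returned all-worn.
    """
    spe = int(round(epoch_s * rec.sample_rate_hz))
    n_epochs = rec.n_samples // spe
    flags = np.zeros(n_epochs, dtype=bool)
    if rec.duration_s < window_min * 60.0:
        return flags
    # aggregate in half-block chunks so the centred 60-min window is exact
    sph = int(round(block_min * 60.0 * rec.sample_rate_hz)) // 2
    edges = np.arange(0, rec.n_samples, sph)
    x = rec.samples
    cnt = np.diff(np.append(edges, rec.n_samples)).astype(float)[:, None]
    s1 = np.add.reduceat(x, edges, axis=0, dtype=np.float64)
    s2 = np.add.reduceat(x * x, edges, axis=0, dtype=np.float64)
    mn = np.minimum.reduceat(x, edges, axis=0)
    mx = np.maximum.reduceat(x, edges, axis=0)
    n_half = len(edges)
    n_blocks = n_half // 2
    k = int(round(window_min * 60.0 / (block_min * 60.0 / 2.0)))  # halves/window
    for b in range(n_blocks):
        h0 = max(2 * b + 1 - k // 2, 0)
        h1 = min(2 * b + 1 + k // 2, n_half)
        n = cnt[h0:h1].sum(axis=0)
        mu = s1[h0:h1].sum(axis=0) / n
        var = np.maximum(s2[h0:h1].sum(axis=0) / n - mu * mu, 0.0)
        sd = np.sqrt(var)
        rng_ = mx[h0:h1].max(axis=0) - mn[h0:h1].min(axis=0)
        still = (sd < sd_threshold_mg / 1000.0) & (rng_ < range_threshold_mg / 1000.0)
        if still.sum() >= min_axes:
            e0 = int(b * 2 * sph / spe)
            e1 = min(int(np.ceil((b + 1) * 2 * sph / spe)), n_epochs)
            flags[e0:e1] = True
    return flags


def epoch_series(rec: RawRecording, epoch_s: float = 5.0,
                 nonwear: bool = True) -> EpochSeries:
    """Compute the full epoch series (ENMO, MAD, wear flags) for a recording."""
    enmo = enmo_epochs(rec, epoch_s)
    mad = mad_epochs(rec, epoch_s)
    wear = np.full(len(enmo), WORN, dtype=np.int8)
    if nonwear:
        wear[detect_nonwear(rec, epoch_s)] = NONWEAR
    return EpochSeries(rec.start_time, epoch_s, enmo, mad, wear)


def impute_nonwear(series: EpochSeries) -> EpochSeries:
    """Impute non-wear epochs from the same clock time on other days.

    Each non-wear epoch is replaced by the mean of worn-epoch values at the
    same time-of-day slot on the other days of the recording, and flagged
    imputed.  Epochs with no worn donor in their slot are zeroed and remain
    flagged non-wear (unimputable).  Worn epochs pass through bit-exactly.
    """
    n = len(series)
    out = replace(series, enmo_mg=series.enmo_mg.copy(),
                  mad_mg=series.mad_mg.copy(), wear=series.wear.copy())
    nw = np.flatnonzero(series.wear == NONWEAR)
    if nw.size == 0:
        return out
    slots_per_day = 86400.0 / series.epoch_s
    if abs(slots_per_day - round(slots_per_day)) > 1e-9:
        raise ValueError("epoch length must divide 24 h for imputation")
    slots_per_day = int(round(slots_per_day))
    midnight = series.start_time.normalize()
    off = (series.start_time - midnight).total_seconds() / series.epoch_s
    off = int(round(off))
    slot = (off + np.arange(n)) % slots_per_day

    worn = series.wear == WORN
    n_donor = np.bincount(slot[worn], minlength=slots_per_day)
    sum_e = np.bincount(slot[worn], weights=series.enmo_mg[worn],
                        minlength=slots_per_day)
    sum_m = np.bincount(slot[worn], weights=series.mad_mg[worn],
                        minlength=slots_per_day)
    unimputable = 0
    for i in nw:
        s = slot[i]
        if n_donor[s] > 0:
            out.enmo_mg[i] = sum_e[s] / n_donor[s]
            out.mad_mg[i] = sum_m[s] / n_donor[s]
            out.wear[i] = IMPUTED
        else:
            out.enmo_mg[i] = 0.0
            out.mad_mg[i] = 0.0
            unimputable += 1
    if unimputable:
        warnings.warn(f"{unimputable} non-wear epochs had no donor day and "
                      f"remain unimputed", stacklevel=2)
    return out
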