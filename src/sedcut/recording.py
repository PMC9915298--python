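"""Raw tri-axial acceleration recordings and their CSV dialect.

A recording holds uniformly sampled acceleration in gravitational units (g).
The on-disk form is a plain text file ``time,x,y,z`` with ISO-8601 timestamps,
one row per sample, the neutral stand-in used throughout this package for a
device raw export.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SensorSpec", "RawRecording", "RawCsvError", "write_raw_csv", "read_raw_csv"]


class RawCsvError(ValueError):
    """Raised when a raw CSV file violates the expected dialect."""


@dataclass(frozen=True)
class SensorSpec:
    """Physical characteristics of the simulated tri-axial sensor.

    Parameters
    ----------
    sample_rate_hz : float
        Output data rate; the device default is 20 Hz.
    dynamic_range_g : float
        Saturation range; samples are clipped to +/- this value (default 4 g).
    noise_sd_mg : float
        Per-axis white measurement noise, standard deviation in mg.
    offset_g : tuple of 3 float
        Additive per-axis miscalibration in g (|component| < 0.25).
    gain : tuple of 3 float
        Multiplicative per-axis miscalibration (components in (0.8, 1.2)).
    """

    sample_rate_hz: float = 20.0
    dynamic_range_g: float = 4.0
    noise_sd_mg: float = 3.0
    offset_g: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.dynamic_range_g <= 0:
            raise ValueError("dynamic_range_g must be positive")
        if self.noise_sd_mg < 0:
            raise ValueError("noise_sd_mg must be non-negative")
        if len(self.offset_g) != 3 or len(self.gain) != 3:
            raise ValueError("offset_g and gain must be 3-vectors")
        if any(abs(o) >= 0.25 for o in self.offset_g):
            raise ValueError("offset components must satisfy |offset| < 0.25 g")
        if any(not 0.8 < g < 1.2 for g in self.gain):
            raise ValueError("gain components must lie in (0.8, 1.2)")

    def distort(self, ideal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Turn an ideal signal into what the sensor would record.

        Applies the per-axis gain/offset miscalibration, adds white noise and
        clips to the dynamic range.
        """
        dt = ideal.dtype if ideal.dtype in (np.float32, np.float64) else np.float64
        gain = np.asarray(self.gain, dtype=dt)
        offset = np.asarray(self.offset_g, dtype=dt)
        out = ideal * gain
        out += offset
        if self.noise_sd_mg > 0:
            noise = rng.standard_normal(ideal.shape, dtype=dt)
            noise *= dt.type(self.noise_sd_mg / 1000.0)
            out += noise
        np.clip(out, -self.dynamic_range_g, self.dynamic_range_g, out=out)
        return out

    def undistort(self, measured: np.ndarray) -> np.ndarray:
        """Inverse of the gain/offset distortion (noise and clipping excepted)."""
        gain = np.asarray(self.gain, dtype=float)
        offset = np.asarray(self.offset_g, dtype=float)
        return (measured - offset) / gain


@dataclass
class RawRecording:
    """Uniformly sampled tri-axial acceleration in g."""

    start_time: pd.Timestamp
    sample_rate_hz: float
    samples: np.ndarray  # shape (n, 3)
    dynamic_range_g: float | None = None
    calibration: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.samples = np.asarray(self.samples)
        if self.samples.dtype not in (np.float32, np.float64):
            self.samples = self.samples.astype(float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(seconds=self.duration_s)

    def times(self) -> pd.DatetimeIndex:
        step = pd.Timedelta(seconds=1.0 / self.sample_rate_hz)
        return pd.date_range(self.start_time, periods=self.n_samples, freq=step)

    def magnitude(self) -> np.ndarray:
        """Per-sample Euclidean norm of the acceleration vector, in g."""
        return np.linalg.norm(self.samples, axis=1)

    def slice_seconds(self, t0: float, t1: float) -> np.ndarray:
        """Samples in the half-open interval [t0, t1) seconds from the start."""
        i0 = int(round(t0 * self.sample_rate_hz))
        i1 = int(round(t1 * self.sample_rate_hz))
        return self.samples[max(i0, 0):max(i1, 0)]


def write_raw_csv(rec: RawRecording, path) -> None:
    """Write a recording as ``time,x,y,z`` with microsecond timestamps.

    Acceleration values are written with 6 decimal places, which round-trips
    to the micro-g.
    """
    df = pd.DataFrame(rec.samples, columns=["x", "y", "z"])
    df.insert(0, "time", rec.times())
    df.to_csv(path, index=False, float_format="%.6f",
              date_format="%Y-%m-%dT%H:%M:%S.%f")


def read_raw_csv(path) -> RawRecording:
    """Read a ``time,x,y,z`` raw file back into a :class:`RawRecording`.

    Raises
    ------
    RawCsvError
        Naming the offending line, if the header is wrong, a value fails to
        parse, or the timestamps are not strictly increasing and uniform.
    """
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != ["time", "x", "y", "z"]:
        raise RawCsvError(f"{path}: line 1: expected header 'time,x,y,z', "
                          f"got {','.join(df.columns)}")
    if len(df) == 0:
        raise RawCsvError(f"{path}: no data rows")
    times = pd.to_datetime(df["time"], format="ISO8601", errors="coerce")
    bad = np.flatnonzero(times.isna().to_numpy())
    if bad.size:
        raise RawCsvError(f"{path}: line {bad[0] + 2}: unparseable timestamp "
                          f"{df['time'].iloc[bad[0]]!r}")
    vals = np.empty((len(df), 3))
    for j, col in enumerate(("x", "y", "z")):
        v = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(v))
        if bad.size:
            raise RawCsvError(f"{path}: line {bad[0] + 2}: non-numeric value "
                              f"in column {col}")
        vals[:, j] = v
    tns = times.to_numpy().astype("datetime64[ns]").astype(np.int64)
    if len(tns) > 1:
        dt = np.diff(tns)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise RawCsvError(f"{path}: line {bad[0] + 3}: timestamps not "
                              f"strictly increasing")
        step = np.median(dt)
        if np.any(np.abs(dt - step) > max(1e-3 * step, 1000)):
            bad = int(np.argmax(np.abs(dt - step)))
            raise RawCsvError(f"{path}: line {bad + 3}: non-uniform sampling")
        rate = 1e9 / step
    else:
        rate = 20.0
    return RawRecording(start_time=pd.Timestamp(times.iloc[0]),
                        sample_rate_hz=float(rate), samples=vals)


def apply_axes_transform(rec: RawRecording, gain, offset) -> RawRecording:
    """Return a copy of ``rec`` with samples mapped to ``gain*x + offset`` per axis."""
    gain = np.asarray(gain, dtype=float)
    offset = np.asarray(offset, dtype=float)
    return replace(rec, samples=rec.samples * gain + offset)
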