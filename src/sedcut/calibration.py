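"""Auto-calibration of raw recordings against local gravity.

During stationary wear the measured acceleration vector should sit on the
unit sphere (magnitude 1 g).  Per-axis gain/offset corrections are estimated
by an iteratively re-fitted linear map that moves stationary-window means
toward the sphere; the residual mean absolute deviation from 1 g after
correction (the post-calibration error) is the file-inclusion criterion,
<0.02 g.

Stationary windows are 10-s non-overlapping blocks whose per-axis standard
deviation is below 13 mg on all three axes, the processing defaults widely
used for this step; windows containing clipped (saturated) samples are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .recording import RawRecording

__all__ = ["CalibrationModel", "find_stationary_windows", "fit_calibration",
           "apply_calibration", "AutoCalibration"]

MIN_STATIONARY_POINTS = 10
COVERAGE_G = 0.3  # sphere coverage requires points beyond +/-300 mg per axis


@dataclass(frozen=True)
class CalibrationModel:
    """Per-axis linear correction ``calibrated = gain * raw + offset``."""

    offset_g: tuple[float, float, float]
    gain: tuple[float, float, float]
    post_error_g: float
    n_stationary_windows: int
    sphere_coverage_ok: bool
    converged: bool

    def __post_init__(self) -> None:
        if self.post_error_g < 0:
            raise ValueError("post_error_g must be non-negative")
        if any(g <= 0 for g in self.gain):
            raise ValueError("gain components must be positive")

    @classmethod
    def identity(cls, post_error_g: float = 0.0, n_windows: int = 0,
                 coverage: bool = False, converged: bool = False):
        return cls((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), post_error_g,
                   n_windows, coverage, converged)

    @property
    def is_identity(self) -> bool:
        return self.offset_g == (0.0, 0.0, 0.0) and self.gain == (1.0, 1.0, 1.0)

    def transform(self, samples: np.ndarray) -> np.ndarray:
        return samples * np.asarray(self.gain) + np.asarray(self.offset_g)

    def summary(self) -> str:
        off = ", ".join(f"{o * 1000:+.1f}" for o in self.offset_g)
        gn = ", ".join(f"{g:.4f}" for g in self.gain)
        return (
            "Auto-calibration (unit-sphere fit)\n"
            f"  stationary windows : {self.n_stationary_windows}\n"
            f"  sphere coverage ok : {self.sphere_coverage_ok}\n"
            f"  converged          : {self.converged}\n"
            f"  offset (mg)        : {off}\n"
            f"  gain               : {gn}\n"
            f"  post-calibration error : {self.post_error_g:.5f} g"
        )

    def to_dict(self) -> dict:
        return {
            "offset_g": list(self.offset_g), "gain": list(self.gain),
            "post_error_g": self.post_error_g,
            "n_stationary_windows": self.n_stationary_windows,
            "sphere_coverage_ok": self.sphere_coverage_ok,
            "converged": self.converged,
        }


def find_stationary_windows(rec: RawRecording, window_s: float = 10.0,
                            sd_threshold_mg: float = 13.0) -> np.ndarray:
    """Mean acceleration of every stationary non-overlapping window.

    A window is stationary when the per-axis SD is below the threshold on all
    three axes.  Windows containing samples at the sensor's dynamic-range
    limit (clipped, abnormally high values) are discarded.  Returns an array
    of shape (n_windows, 3).
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    w = int(round(window_s * rec.sample_rate_hz))
    n_win = rec.n_samples // w
    if n_win == 0:
        raise ValueError("recording shorter than one window")
    x = rec.samples[: n_win * w].reshape(n_win, w, 3)
    sd = x.std(axis=1)
    ok = np.all(sd < sd_threshold_mg / 1000.0, axis=1)
    if rec.dynamic_range_g is not None:
        lim = rec.dynamic_range_g - 1e-9
        clipped = np.any(np.abs(x).max(axis=1) >= lim, axis=1)
        ok &= ~clipped
    return x[ok].mean(axis=1)


def _post_error(points: np.ndarray) -> float:
    return float(np.mean(np.abs(np.linalg.norm(points, axis=1) - 1.0)))


def fit_calibration(points: np.ndarray, max_iter: int = 100,
                    tol: float = 1e-9,
                    min_points: int = MIN_STATIONARY_POINTS) -> CalibrationModel:
    """Fit the gain/offset correction from stationary-window mean vectors.

    Iteratively regresses each point's closest unit-sphere position on its
    current calibrated value, per axis, accumulating the linear map.  Falls
    back to the identity model (``converged=False``) when there are too few
    points, the points do not span both signs beyond 300 mg on every axis, or
    the fit fails to improve the post-calibration error — callers may then
    substitute externally supplied back-up coefficients.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    n = pts.shape[0]
    err0 = _post_error(pts) if n else 0.0
    coverage = bool(n) and bool(
        np.all(pts.min(axis=0) < -COVERAGE_G) and np.all(pts.max(axis=0) > COVERAGE_G))
    if n < min_points or not coverage:
        return CalibrationModel.identity(err0, n, coverage, converged=False)

    gain = np.ones(3)
    offset = np.zeros(3)
    cur = pts.copy()
    res_prev = np.inf
    hit_tol = False
    for _ in range(max_iter):
        norms = np.linalg.norm(cur, axis=1)
        closest = cur / norms[:, None]
        # per-axis weighted least squares toward the sphere surface
        w = np.minimum(1.0 / np.maximum(np.abs(norms - 1.0), 1e-6), 100.0)
        for j in range(3):
            A = np.column_stack([cur[:, j], np.ones(n)]) * np.sqrt(w)[:, None]
            b = closest[:, j] * np.sqrt(w)
            (a_j, b_j), *_ = np.linalg.lstsq(A, b, rcond=None)
            gain[j] *= a_j
            offset[j] = offset[j] * a_j + b_j
            cur[:, j] = cur[:, j] * a_j + b_j
        res = float(np.mean((np.linalg.norm(cur, axis=1) - 1.0) ** 2))
        if abs(res_prev - res) < tol:
            hit_tol = True
            break
        res_prev = res

    err1 = _post_error(pts * gain + offset)
    if not np.all(np.isfinite(gain)) or np.any(gain <= 0) \
            or err1 > err0 + 1e-12:
        return CalibrationModel.identity(err0, n, coverage, converged=False)
    return CalibrationModel(tuple(offset), tuple(gain), err1, n, coverage,
                            converged=hit_tol)


def apply_calibration(rec: RawRecording, model: CalibrationModel,
                      force: bool = False) -> RawRecording:
    """Return ``rec`` with each sample mapped per axis to ``gain*x + offset``.

    Requires a converged model unless ``force`` is given (identity or back-up
    coefficients).  The recording's metadata records the model used.
    """
    if not all(np.isfinite(model.gain)) or not all(np.isfinite(model.offset_g)):
        raise ValueError("non-finite calibration model")
    if not model.converged and not force and not model.is_identity:
        raise ValueError("model did not converge; pass force=True to apply anyway")
    return replace(rec, samples=model.transform(rec.samples), calibration=model)


class AutoCalibration:
    """Sphere-fit auto-calibration of one recording.

    Parameters
    ----------
    rec : RawRecording
        The (uncalibrated) recording.
    window_s, sd_threshold_mg : float
        Stationary-window detection parameters (defaults 10 s, 13 mg).

    ``fit()`` returns the :class:`CalibrationModel`; ``fit_apply()`` also
    returns the calibrated recording (identity model applied when the fit did
    not converge, mirroring the use of back-up coefficients for short files).
    """

    def __init__(self, rec: RawRecording, window_s: float = 10.0,
                 sd_threshold_mg: float = 13.0):
        self.rec = rec
        self.window_s = window_s
        self.sd_threshold_mg = sd_threshold_mg

    def fit(self, **kwargs) -> CalibrationModel:
        pts = find_stationary_windows(self.rec, self.window_s,
                                      self.sd_threshold_mg)
        return fit_calibration(pts, **kwargs)

    def fit_apply(self, **kwargs) -> tuple[RawRecording, CalibrationModel]:
        model = self.fit(**kwargs)
        if model.converged:
            return apply_calibration(self.rec, model), model
        ident = CalibrationModel.identity(model.post_error_g,
                                          model.n_stationary_windows,
                                          model.sphere_coverage_ok, False)
        return apply_calibration(self.rec, ident, force=True), model
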