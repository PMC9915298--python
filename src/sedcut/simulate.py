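"""Synthetic thigh-worn accelerometer recordings with posture ground truth.

Two study designs are emulated:

* a scripted laboratory protocol of 12 activities (4 lying, 2 sitting and 6
  upright positions) used to derive sedentary cut-points, and
* multi-day free-living wear with alternating sedentary/upright bouts, nightly
  time-in-bed, sensor miscalibration and optional non-wear.

The signal model per bout is gravity along a posture-dependent orientation
plus a band-limited magnitude oscillation whose offset and amplitude are
solved numerically so that the 5-s epoch ENMO and MAD values match a target
distribution, then distorted by the sensor's gain/offset/noise model.
Amplitude targets vary log-normally across participants/bouts, matched to
published activity-level medians and interquartile ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import erf

from .events import IN_BED, SEDENTARY, STANDING, STEPPING, PostureEventSeries
from .recording import RawRecording, SensorSpec

__all__ = [
    "Bout", "ActivityScript", "LabelAmplitude", "ActivityAmplitudeModel",
    "BehaviourParams", "lab_protocol_script", "reference_lab_amplitudes",
    "generate_lab_recording", "generate_freeliving_recording",
    "LAB_ACTIVITY_LABELS",
]

# Activity codes 1-12 of the laboratory protocol mapped to signal labels.
LAB_ACTIVITY_LABELS = {
    1: "lying", 2: "lying", 3: "lying", 4: "lying",
    5: "sitting", 6: "sitting",
    7: "standing", 8: "walking", 9: "picking", 10: "dusting",
    11: "sweeping", 12: "stairs",
}

_SCRIPT_LABELS = frozenset({
    "lying", "sitting", "standing", "walking", "picking", "dusting",
    "sweeping", "stairs", "nonwear", "in_bed",
})

_UPRIGHT_LABELS = frozenset({
    "standing", "walking", "picking", "dusting", "sweeping", "stairs",
})

_QNORM75 = 0.6744897501960817  # 75th percentile of the standard normal


@dataclass(frozen=True)
class Bout:
    """One scripted bout: a posture/activity label over [start, end)."""

    label: str
    start: pd.Timestamp
    end: pd.Timestamp
    code: int | None = None  # lab activity number 1-12, if part of the protocol


@dataclass
class ActivityScript:
    """Ordered, non-overlapping activity bouts with optional activity codes."""

    bouts: list[Bout]

    def __post_init__(self) -> None:
        bouts = [replace(b, start=pd.Timestamp(b.start), end=pd.Timestamp(b.end))
                 for b in self.bouts]
        for b in bouts:
            if b.label not in _SCRIPT_LABELS:
                raise ValueError(f"unknown activity label {b.label!r}")
            if b.end <= b.start:
                raise ValueError(f"bout {b.label!r} must have end > start")
        for a, b in zip(bouts, bouts[1:]):
            if b.start < a.end:
                raise ValueError("bouts must be time-ordered and non-overlapping")
        self.bouts = bouts

    @property
    def start(self) -> pd.Timestamp:
        return self.bouts[0].start

    @property
    def end(self) -> pd.Timestamp:
        return self.bouts[-1].end

    def total_seconds(self) -> float:
        return (self.end - self.start).total_seconds()


def lab_protocol_script(start_time="2023-03-06 09:00:00") -> ActivityScript:
    """The 12-activity laboratory protocol.

    Activities 1-11 last 5 min and are separated by 30-s breaks; activity 12
    (stairs) lasts 2 min after a 2-min break.  Breaks are quiet standing with
    no activity code.  A 3-min quiet-standing lead-in and lead-out (device
    fitting and removal) pad the session to exactly 70 min.
    """
    t = pd.Timestamp(start_time)
    bouts: list[Bout] = []

    def add(label, minutes, code=None):
        nonlocal t
        end = t + pd.Timedelta(minutes=minutes)
        bouts.append(Bout(label, t, end, code))
        t = end

    add("standing", 3.0)  # lead-in
    for code in range(1, 12):
        add(LAB_ACTIVITY_LABELS[code], 5.0, code)
        if code < 11:
            add("standing", 0.5)  # 30-s break
    add("standing", 2.0)  # 2-min break before stairs
    add("stairs", 2.0, 12)
    add("standing", 3.0)  # lead-out
    return ActivityScript(bouts)


@dataclass(frozen=True)
class LabelAmplitude:
    """Target epoch-metric distribution for one activity label.

    Median and quartiles (mg) of the 5-s epoch ENMO and MAD values; draws
    across participants are log-normal matched to these quantiles, with a
    single latent factor per bout so both metrics scale together.
    """

    enmo: tuple[float, float, float]  # (q1, median, q3) in mg
    mad: tuple[float, float, float]

    def __post_init__(self) -> None:
        for q1, med, q3 in (self.enmo, self.mad):
            if not (0 <= q1 <= med <= q3):
                raise ValueError("quartiles must satisfy 0 <= q1 <= median <= q3")

    def _sigma(self, q: tuple[float, float, float]) -> float:
        q1, med, q3 = q
        if med <= 0 or q1 <= 0:
            return 0.0
        return (math.log(q3) - math.log(q1)) / (2 * _QNORM75)

    def draw(self, rng: np.random.Generator) -> tuple[float, float]:
        """One (enmo_mg, mad_mg) target pair."""
        z = rng.standard_normal()
        e = self.enmo[1] * math.exp(self._sigma(self.enmo) * z)
        m = self.mad[1] * math.exp(self._sigma(self.mad) * z)
        return e, m


@dataclass
class ActivityAmplitudeModel:
    """Per-label target distributions for epoch-level ENMO/MAD values."""

    labels: dict[str, LabelAmplitude]

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def draw(self, label: str, rng: np.random.Generator) -> tuple[float, float]:
        if label not in self.labels:
            raise ValueError(f"amplitude model has no entry for label {label!r}")
        return self.labels[label].draw(rng)


_STILL = LabelAmplitude(enmo=(0.0, 0.0, 0.0), mad=(0.0, 0.0, 0.0))

# Activity-level epoch metric quantiles, mg, median (Q1-Q3), for the
# laboratory activities; lying and sitting share the pooled sedentary row.
_REFERENCE_ROWS = {
    "lying":    ((3.1, 5.1, 8.6), (1.8, 4.0, 9.1)),
    "sitting":  ((3.1, 5.1, 8.6), (1.8, 4.0, 9.1)),
    "standing": ((3.6, 5.6, 31.4), (1.9, 4.5, 6.2)),
    "walking":  ((209.4, 240.5, 341.7), (268.7, 316.3, 370.2)),
    "picking":  ((174.5, 201.3, 214.3), (210.4, 245.4, 259.9)),
    "dusting":  ((47.4, 73.4, 87.7), (50.7, 60.2, 71.3)),
    "sweeping": ((65.1, 94.4, 106.9), (57.1, 77.1, 88.3)),
    "stairs":   ((217.2, 248.7, 269.2), (298.3, 349.7, 364.5)),
}


def reference_lab_amplitudes() -> ActivityAmplitudeModel:
    """Amplitude model matching the published activity-level summaries."""
    labels = {k: LabelAmplitude(enmo=e, mad=m) for k, (e, m) in _REFERENCE_ROWS.items()}
    labels["in_bed"] = _STILL
    labels["nonwear"] = _STILL
    return ActivityAmplitudeModel(labels)


def zero_amplitudes() -> ActivityAmplitudeModel:
    """All-still amplitude model (every label yields pure gravity)."""
    return ActivityAmplitudeModel({k: _STILL for k in _SCRIPT_LABELS})


# ---------------------------------------------------------------------------
# Waveform solver: magnitude r(t) = 1 + c + A sin(2 pi f t + phi), with white
# magnitude noise sigma.  Closed-form normal expectations over a phase grid
# give the predicted epoch ENMO and MAD; c and A are solved by root finding.

_PHASE = np.sin((np.arange(64) + 0.5) / 64.0 * 2.0 * np.pi)


def _phi(x):
    return np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)


def _Phi(x):
    return 0.5 * (1.0 + erf(x / math.sqrt(2.0)))


def predicted_mad(amp_mg: float, sigma_mg: float) -> float:
    """Expected epoch MAD (mg) of the oscillation-plus-noise magnitude model."""
    a = np.abs(amp_mg * _PHASE)
    if sigma_mg <= 0:
        return float(np.mean(a))
    s = sigma_mg
    val = s * math.sqrt(2.0 / math.pi) * np.exp(-0.5 * (a / s) ** 2) \
        + a * (2.0 * _Phi(a / s) - 1.0)
    return float(np.mean(val))


def predicted_enmo(c_mg: float, amp_mg: float, sigma_mg: float) -> float:
    """Expected epoch ENMO (mg): mean of max(c + A sin + noise, 0)."""
    m = c_mg + amp_mg * _PHASE
    if sigma_mg <= 0:
        return float(np.mean(np.maximum(m, 0.0)))
    s = sigma_mg
    return float(np.mean(m * _Phi(m / s) + s * _phi(m / s)))


def solve_waveform(enmo_mg: float | None, mad_mg: float,
                   sigma_mg: float) -> tuple[float, float]:
    """Solve (c, A) in g so epoch metrics hit the targets under noise ``sigma``.

    ``enmo_mg=None`` requests a zero-mean oscillation (c = 0), the signature
    of light free-living movement where the magnitude swings symmetrically
    about 1 g.
    """
    if mad_mg <= 0 and not enmo_mg:
        return 0.0, 0.0
    if mad_mg <= predicted_mad(0.0, sigma_mg) + 1e-12:
        amp = 0.0
    else:
        hi = mad_mg * math.pi / 2.0 * 4.0 + 5.0 * sigma_mg + 1.0
        amp = brentq(lambda a: predicted_mad(a, sigma_mg) - mad_mg, 0.0, hi,
                     xtol=1e-6)
    if enmo_mg is None:
        c = 0.0
    else:
        lo = -(amp + 8.0 * sigma_mg + 8.0 * enmo_mg + 1.0)
        hi = enmo_mg + 8.0 * sigma_mg + 1.0
        if predicted_enmo(lo, amp, sigma_mg) >= enmo_mg:
            c = lo  # target below the noise floor; saturate
        else:
            c = brentq(lambda x: predicted_enmo(x, amp, sigma_mg) - enmo_mg,
                       lo, hi, xtol=1e-6)
    return c / 1000.0, amp / 1000.0


# Oscillation frequencies are multiples of 0.2 Hz so every 5-s epoch holds an
# integer number of cycles and the epoch mean of the oscillation vanishes.
_FREQS = np.arange(0.8, 2.41, 0.2)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _jitter(u, max_deg: float, rng: np.random.Generator):
    """Rotate ``u`` by a random angle up to ``max_deg`` about a random axis."""
    if max_deg <= 0:
        return _unit(u)
    u = _unit(u)
    # random direction perpendicular to u
    p = rng.standard_normal(3)
    p -= p.dot(u) * u
    n = np.linalg.norm(p)
    if n < 1e-12:
        return u
    p /= n
    ang = math.radians(rng.uniform(0.0, max_deg))
    return math.cos(ang) * u + math.sin(ang) * p


_LYING_BASES = [np.array(b, dtype=float) for b in
                [(0, 0, 1), (0, 0, -1), (0, 1, 0), (0, -1, 0)]]


def _orientation(label: str, code: int | None, rng: np.random.Generator):
    """Gravity direction in the sensor frame for a posture label.

    The sensor x-axis runs along the thigh: upright postures put gravity
    within 15 degrees of +x, lying/sitting put it within 20 degrees of the
    horizontal (y-z) plane.
    """
    if label in _UPRIGHT_LABELS:
        return _jitter((1.0, 0.0, 0.0), 15.0, rng)
    if label == "lying":
        base = _LYING_BASES[(code - 1) % 4] if code else \
            _LYING_BASES[rng.integers(4)]
        return _jitter(base, 20.0, rng)
    if label == "sitting":
        psi = math.radians(rng.uniform(-30.0, 30.0))
        return _jitter((0.0, math.sin(psi), -math.cos(psi)), 20.0, rng)
    if label == "in_bed":
        v = rng.standard_normal(3)
        return _unit(v)
    if label == "nonwear":
        return np.array([0.0, 0.0, 1.0])
    raise ValueError(f"no orientation rule for label {label!r}")


def _fill_bout(ideal: np.ndarray, i0: int, i1: int, rate: float, u0,
               c: float, amp: float, rng: np.random.Generator,
               drift_deg: float = 0.0) -> None:
    n = i1 - i0
    if n <= 0:
        return
    dt = ideal.dtype
    if amp > 0:
        f = float(rng.choice(_FREQS))
        phi0 = rng.uniform(0.0, 2.0 * math.pi)
        t = np.arange(n, dtype=dt) / dt.type(rate)
        r = np.sin(dt.type(2.0 * math.pi * f) * t + dt.type(phi0))
        r *= dt.type(amp)
        r += dt.type(1.0 + c)
    else:
        r = np.full(n, 1.0 + c, dtype=dt)
    u0 = _unit(u0)
    if drift_deg > 0:
        # slow postural adjustments: piecewise rotation toward a fresh nearby
        # direction every few minutes; preserves unit magnitude exactly
        u_t = np.empty((n, 3), dtype=dt)
        u = u0
        pos = 0
        while pos < n:
            m = min(int(rng.uniform(240.0, 600.0) * rate), n - pos)
            p = rng.standard_normal(3)
            p -= p.dot(u) * u
            p /= np.linalg.norm(p)
            ang = math.radians(rng.uniform(0.5, 1.0) * drift_deg)
            a = np.linspace(0.0, ang, m, dtype=dt)
            u_t[pos:pos + m] = (np.cos(a)[:, None] * u.astype(dt)
                                + np.sin(a)[:, None] * p.astype(dt))
            u = math.cos(ang) * u + math.sin(ang) * p
            pos += m
        ideal[i0:i1] = r[:, None] * u_t
    else:
        ideal[i0:i1] = r[:, None] * np.asarray(u0, dtype=dt)


def generate_lab_recording(script: ActivityScript,
                           amp: ActivityAmplitudeModel,
                           sensor: SensorSpec,
                           seed: int) -> tuple[RawRecording, ActivityScript]:
    """Simulate one participant performing the laboratory protocol.

    Returns the sensor-distorted recording and the ground-truth script
    (unchanged).  Reproducible per seed.
    """
    for b in script.bouts:
        if b.label not in amp:
            raise ValueError(f"amplitude model missing scripted label {b.label!r}")
    rng = np.random.default_rng(seed)
    rate = sensor.sample_rate_hz
    n_total = int(round(script.total_seconds() * rate))
    ideal = np.zeros((n_total, 3), dtype=np.float32)
    ideal[:, 0] = 1.0  # unscripted gaps: quiet upright
    t0 = script.start
    for b in script.bouts:
        i0 = int(round((b.start - t0).total_seconds() * rate))
        i1 = int(round((b.end - t0).total_seconds() * rate))
        enmo_t, mad_t = amp.draw(b.label, rng)
        c, a = solve_waveform(enmo_t, mad_t, sensor.noise_sd_mg)
        u0 = _orientation(b.label, b.code, rng)
        drift = rng.uniform(4.0, 12.0) if b.label in ("lying", "sitting",
                                                      "standing", "in_bed") else 0.0
        _fill_bout(ideal, i0, i1, rate, u0, c, a, rng, drift_deg=drift)
    measured = sensor.distort(ideal, rng)
    rec = RawRecording(start_time=t0, sample_rate_hz=rate, samples=measured,
                       dynamic_range_g=sensor.dynamic_range_g)
    return rec, script


# ---------------------------------------------------------------------------
# Free-living simulation


@dataclass(frozen=True)
class BehaviourParams:
    """Daily behaviour structure of the simulated free-living cohort.

    Defaults emulate young adults wearing the device continuously: nightly
    time in bed 23:00-07:00 (+/- jitter), a sedentary fraction of waking time
    averaging 0.5717 across participants (about 549 min of a 960-min waking
    day), and upright time split between quiet standing, light household
    puttering and walking.  Light puttering is synthesised as a zero-mean
    magnitude oscillation; walking reuses the laboratory walking signature
    scaled down to self-selected free-living pace.
    """

    bed_start_hour: float = 23.0
    bed_end_hour: float = 7.0
    bed_jitter_min: float = 20.0
    sedentary_fraction_mean: float = 0.5717
    sedentary_fraction_sd: float = 0.0886
    sedentary_fraction_bounds: tuple[float, float] = (0.35, 0.80)
    day_fraction_sd: float = 0.03
    sed_bout_mean_min: float = 30.0
    sed_bout_range_min: tuple[float, float] = (5.0, 120.0)
    upright_bout_mean_min: float = 20.0
    upright_bout_range_min: tuple[float, float] = (2.0, 90.0)
    standing_weight: float = 0.04
    puttering_weight: float = 0.61
    walking_weight: float = 0.35
    segment_range_min: tuple[float, float] = (0.5, 4.0)
    puttering_mad_median_mg: float = 85.0
    puttering_mad_sigma: float = 0.45
    walking_scale_median: float = 0.55
    walking_scale_sigma: float = 0.35
    bed_segment_range_min: tuple[float, float] = (20.0, 60.0)
    nonwear_windows_h: tuple[tuple[float, float], ...] = ()  # (start_h, dur_h)
    amplitudes: ActivityAmplitudeModel = field(default_factory=reference_lab_amplitudes)


def _round5(x: float) -> float:
    return round(x / 5.0) * 5.0


def _split_durations(total_s: float, draw_s, rng) -> list[float]:
    """Partition ``total_s`` into segments drawn from ``draw_s``, rescaled to
    fit exactly and snapped to the 5-s grid (zero-length parts dropped)."""
    if total_s <= 0:
        return []
    durs = []
    acc = 0.0
    while acc < total_s:
        d = draw_s(rng)
        durs.append(d)
        acc += d
    durs = np.asarray(durs) * (total_s / acc)
    bounds = np.concatenate([[0.0], np.cumsum(durs)])
    bounds = np.round(bounds / 5.0) * 5.0
    out = np.diff(bounds)
    return [float(d) for d in out if d > 0]


def _trunc_exp(mean_s, lo_s, hi_s):
    def draw(rng):
        return float(np.clip(rng.exponential(mean_s), lo_s, hi_s))
    return draw


def generate_freeliving_recording(
    days: int,
    sensor: SensorSpec,
    behaviour: BehaviourParams | None = None,
    seed: int = 0,
    start_time="2023-03-06 00:00:00",
) -> tuple[RawRecording, PostureEventSeries]:
    """Simulate ``days`` full 24-h days of free-living wear.

    Returns the distorted raw recording and the ground-truth posture event
    series (codes: sedentary, standing, stepping, in-bed).  Realised per-day
    criterion sedentary minutes are recoverable exactly from the events.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    bp = behaviour or BehaviourParams()
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp(start_time)
    rate = sensor.sample_rate_hz
    total_s = days * 86400.0

    sed_frac = float(np.clip(
        rng.normal(bp.sedentary_fraction_mean, bp.sedentary_fraction_sd),
        *bp.sedentary_fraction_bounds))

    # Nightly bed intervals (night d runs from day d evening to day d+1
    # morning); night -1 supplies the first morning in bed.
    def jit():
        return rng.uniform(-bp.bed_jitter_min, bp.bed_jitter_min) * 60.0

    beds = []
    for d in range(-1, days):
        s = d * 86400.0 + bp.bed_start_hour * 3600.0 + jit()
        e = (d + 1) * 86400.0 + bp.bed_end_hour * 3600.0 + jit()
        s, e = _round5(max(s, 0.0)), _round5(min(e, total_s))
        if e > s:
            beds.append((s, e))

    nonwear = sorted((_round5(h * 3600.0), _round5((h + dur) * 3600.0))
                     for h, dur in bp.nonwear_windows_h)

    segments: list[tuple[float, float, str]] = []  # (t0_s, t1_s, kind)
    event_rows: list[tuple[float, float, int]] = []

    bed_draw = _trunc_exp(
        (bp.bed_segment_range_min[0] + bp.bed_segment_range_min[1]) / 2 * 60.0,
        bp.bed_segment_range_min[0] * 60.0, bp.bed_segment_range_min[1] * 60.0)
    sed_draw = _trunc_exp(bp.sed_bout_mean_min * 60.0,
                          bp.sed_bout_range_min[0] * 60.0,
                          bp.sed_bout_range_min[1] * 60.0)
    up_draw = _trunc_exp(bp.upright_bout_mean_min * 60.0,
                         bp.upright_bout_range_min[0] * 60.0,
                         bp.upright_bout_range_min[1] * 60.0)
    seg_draw = _trunc_exp(
        (bp.segment_range_min[0] + bp.segment_range_min[1]) / 2 * 60.0,
        bp.segment_range_min[0] * 60.0, bp.segment_range_min[1] * 60.0)

    for s, e in beds:
        event_rows.append((s, e, IN_BED))
        t = s
        for d in _split_durations(e - s, bed_draw, rng):
            segments.append((t, t + d, "in_bed"))
            t += d

    kinds = np.array(["standing", "puttering", "walking"])
    weights = np.array([bp.standing_weight, bp.puttering_weight,
                        bp.walking_weight])
    weights = weights / weights.sum()

    def fill_waking(w0: float, w1: float) -> None:
        # carve out requested non-wear first
        cur = w0
        pieces = []
        for ns, ne in nonwear:
            ns, ne = max(ns, cur), min(ne, w1)
            if ne > ns:
                if ns > cur:
                    pieces.append((cur, ns, True))
                pieces.append((ns, ne, False))
                cur = ne
        if w1 > cur:
            pieces.append((cur, w1, True))
        for p0, p1, worn in pieces:
            if not worn:
                segments.append((p0, p1, "nonwear"))
                continue
            _fill_behaviour(p0, p1)

    def _fill_behaviour(w0: float, w1: float) -> None:
        W = w1 - w0
        if W < 10.0:
            segments.append((w0, w1, "standing"))
            event_rows.append((w0, w1, STANDING))
            return
        frac = float(np.clip(rng.normal(sed_frac, bp.day_fraction_sd),
                             min(0.2, bp.sedentary_fraction_bounds[0]),
                             max(0.9, bp.sedentary_fraction_bounds[1])))
        # alternate sedentary / upright bouts, then rescale the two groups so
        # the day's sedentary share matches the target fraction
        durs, is_sed = [], []
        sed_turn = bool(rng.integers(2))
        while sum(durs) < W or len(durs) < 2:
            durs.append((sed_draw if sed_turn else up_draw)(rng))
            is_sed.append(sed_turn)
            sed_turn = not sed_turn
        durs = np.asarray(durs)
        sel = np.asarray(is_sed)
        if sel.sum() == 0 or (~sel).sum() == 0:  # pragma: no cover
            sel[0] = ~sel[0]
        durs[sel] *= frac * W / durs[sel].sum()
        durs[~sel] *= (1.0 - frac) * W / durs[~sel].sum()
        bounds = w0 + np.concatenate([[0.0], np.cumsum(durs)])
        bounds = np.round(bounds / 5.0) * 5.0
        for b0, b1, sed in zip(bounds[:-1], bounds[1:], sel):
            if b1 <= b0:
                continue
            if sed:
                segments.append((b0, b1, "sed"))
                event_rows.append((b0, b1, SEDENTARY))
            else:
                t = b0
                for d in _split_durations(b1 - b0, seg_draw, rng):
                    kind = str(rng.choice(kinds, p=weights))
                    segments.append((t, t + d, kind))
                    code = STEPPING if kind == "walking" else STANDING
                    event_rows.append((t, t + d, code))
                    t += d

    # waking windows between consecutive bed intervals
    cur = 0.0
    for s, e in beds:
        if s > cur:
            fill_waking(cur, s)
        cur = max(cur, e)
    if cur < total_s:
        fill_waking(cur, total_s)

    # ------------------------------------------------------------------ signal
    amp = bp.amplitudes
    n_total = int(round(total_s * rate))
    ideal = np.zeros((n_total, 3), dtype=np.float32)
    ideal[:, 0] = 1.0
    sigma = sensor.noise_sd_mg
    for s, e, kind in segments:
        i0, i1 = int(round(s * rate)), int(round(e * rate))
        if kind == "sed":
            enmo_t, mad_t = amp.draw("sitting", rng)
            u0 = _orientation("sitting", None, rng)
        elif kind == "standing":
            enmo_t, mad_t = amp.draw("standing", rng)
            u0 = _orientation("standing", None, rng)
        elif kind == "puttering":
            mad_t = bp.puttering_mad_median_mg * math.exp(
                bp.puttering_mad_sigma * rng.standard_normal())
            enmo_t = None  # zero-mean oscillation about 1 g
            u0 = _orientation("standing", None, rng)
        elif kind == "walking":
            base_e, base_m = amp.draw("walking", rng)
            scale = bp.walking_scale_median * math.exp(
                bp.walking_scale_sigma * rng.standard_normal())
            enmo_t, mad_t = base_e * scale, base_m * scale
            u0 = _orientation("walking", None, rng)
        else:  # in_bed, nonwear
            enmo_t, mad_t = amp.draw(kind, rng)
            u0 = _orientation(kind, None, rng)
        c, a = solve_waveform(enmo_t, mad_t, sigma)
        if kind == "in_bed":
            drift = rng.uniform(15.0, 40.0)  # sleepers reposition
        elif kind in ("sed", "standing"):
            drift = rng.uniform(8.0, 25.0)  # fidgeting, weight shifts
        else:
            drift = 0.0
        _fill_bout(ideal, i0, i1, rate, u0, c, a, rng, drift_deg=drift)

    measured = sensor.distort(ideal, rng)
    rec = RawRecording(start_time=t0, sample_rate_hz=rate, samples=measured,
                       dynamic_range_g=sensor.dynamic_range_g)
    rows = sorted(event_rows)
    events = PostureEventSeries(pd.DataFrame({
        "start": [t0 + pd.Timedelta(seconds=s) for s, _, _ in rows],
        "end": [t0 + pd.Timedelta(seconds=e) for _, e, _ in rows],
        "code": [c for _, _, c in rows],
    }))
    return rec, events


def sample_miscalibrated_sensor(rng: np.random.Generator,
                                max_offset_mg: float = 50.0,
                                gain_range: tuple[float, float] = (0.97, 1.03),
                                noise_sd_mg: float = 4.0,
                                sample_rate_hz: float = 20.0) -> SensorSpec:
    """A sensor with random per-axis offsets and gains, as worn devices have."""
    off = tuple(rng.uniform(-max_offset_mg, max_offset_mg, 3) / 1000.0)
    gain = tuple(rng.uniform(*gain_range, 3))
    return SensorSpec(sample_rate_hz=sample_rate_hz, noise_sd_mg=noise_sd_mg,
                      offset_g=off, gain=gain)
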