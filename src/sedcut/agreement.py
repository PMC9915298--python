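"""Agreement between criterion and cut-point sedentary estimates.

Implements the method-comparison battery used to judge a cut-point against
the criterion posture-event measure: mean percent error (MPE) and mean
absolute percent error (MAPE), Bland-Altman bias and 95% limits of agreement
on the absolute and percent scales, and the smallest symmetric equivalence
zone around the criterion mean that contains the 95% CI of the comparison
mean.

Sign convention: the per-record percent error is
``100 * (criterion - comparison) / comparison``, so a comparison method that
over-counts sedentary time yields a negative MPE.  Note that MPE and MAPE
are means of per-record ratios and need not match the ratio of cohort means;
per-record residuals are exposed for inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PairedEstimates", "mpe_mape", "bland_altman", "percent_bias",
           "equivalence_zone", "MethodAgreement", "AgreementResults"]


@dataclass
class PairedEstimates:
    """Paired criterion/comparison sedentary minutes, one row per unit."""

    frame: pd.DataFrame  # columns: id, criterion_min, comparison_min
    unit: str = "participant"

    def __post_init__(self) -> None:
        df = self.frame.reset_index(drop=True).copy()
        need = {"id", "criterion_min", "comparison_min"}
        if not need.issubset(df.columns):
            raise ValueError(f"paired frame needs columns {sorted(need)}")
        if df[["criterion_min", "comparison_min"]].isna().any().any():
            raise ValueError("missing pairs are not allowed")
        if (df[["criterion_min", "comparison_min"]] < 0).any().any():
            raise ValueError("minutes must be non-negative")
        if len(df) < 2:
            raise ValueError("need at least 2 paired records")
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def criterion(self) -> np.ndarray:
        return self.frame["criterion_min"].to_numpy(dtype=float)

    @property
    def comparison(self) -> np.ndarray:
        return self.frame["comparison_min"].to_numpy(dtype=float)

    @classmethod
    def from_arrays(cls, criterion, comparison, unit: str = "participant"):
        criterion = np.asarray(criterion, dtype=float)
        return cls(pd.DataFrame({"id": np.arange(len(criterion)),
                                 "criterion_min": criterion,
                                 "comparison_min": comparison}), unit=unit)


def _percent_errors(pairs: PairedEstimates) -> np.ndarray:
    crit, comp = pairs.criterion, pairs.comparison
    ok = comp != 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} records with zero comparison minutes "
                      f"excluded from percent-error statistics", stacklevel=3)
    return 100.0 * (crit[ok] - comp[ok]) / comp[ok]


def mpe_mape(pairs: PairedEstimates) -> tuple[float, float, float, float]:
    """Mean (signed) and mean absolute percent error with their SDs.

    Returns ``(mpe, mpe_sd, mape, mape_sd)`` in percent.
    """
    e = _percent_errors(pairs)
    if e.size < 2:
        raise ValueError("need at least 2 usable records")
    return (float(e.mean()), float(e.std(ddof=1)),
            float(np.abs(e).mean()), float(np.abs(e).std(ddof=1)))


def bland_altman(pairs: PairedEstimates,
                 scale: str = "absolute") -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement.

    ``scale='absolute'`` uses differences criterion - comparison in minutes;
    ``scale='percent'`` expresses each difference as a percentage of the
    pair mean.  Returns ``(bias, loa_lo, loa_hi)`` with
    ``loa = bias +/- 1.96 * SD(differences)``.
    """
    if len(pairs) < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs (SD unstable)")
    d = pairs.criterion - pairs.comparison
    if scale == "percent":
        d = 100.0 * d / ((pairs.criterion + pairs.comparison) / 2.0)
    elif scale != "absolute":
        raise ValueError("scale must be 'absolute' or 'percent'")
    bias = float(d.mean())
    half = 1.96 * float(d.std(ddof=1))
    return bias, bias - half, bias + half


def percent_bias(bias_min: float, criterion_mean_min: float,
                 comparison_mean_min: float) -> float:
    """Absolute bias re-expressed on the Bland-Altman percent scale,
    100 * bias / mean of the two method means."""
    return 100.0 * bias_min / ((criterion_mean_min + comparison_mean_min) / 2.0)


def equivalence_zone(pairs: PairedEstimates, max_pct: int = 100,
                     step_pct: int = 1, conf: float = 0.95
                     ) -> tuple[float, float]:
    """Smallest symmetric zone around the criterion mean achieving equivalence.

    Scans zone half-widths of 1, 2, ... percent of the criterion mean and
    returns the first for which the two-sided 95% CI of the comparison mean
    lies inside ``criterion_mean * (1 -/+ zone)``.  Also returns the zone as
    a multiple of the criterion SD, reported to 0.1 SD.
    """
    comp = pairs.comparison
    n = comp.size
    if n < 2:
        raise ValueError("CI undefined for fewer than 2 records")
    crit_mean = float(pairs.criterion.mean())
    crit_sd = float(pairs.criterion.std(ddof=1))
    m = float(comp.mean())
    half = stats.t.ppf(0.5 + conf / 2.0, n - 1) * comp.std(ddof=1) / np.sqrt(n)
    lo, hi = m - half, m + half
    for z in range(step_pct, max_pct + 1, step_pct):
        d = z / 100.0 * crit_mean
        if crit_mean - d <= lo and hi <= crit_mean + d:
            sd_mult = round((d / crit_sd) * 10.0) / 10.0 if crit_sd > 0 else np.inf
            return float(z), float(sd_mult)
    raise ValueError(f"no equivalence within {max_pct}% of the criterion mean")


@dataclass
class AgreementResults:
    """Full agreement report between a criterion and one comparison method."""

    comparison: str
    n: int
    unit: str
    criterion_mean_min: float
    criterion_sd_min: float
    comparison_mean_min: float
    comparison_sd_min: float
    mpe_pct: float
    mpe_sd_pct: float
    mape_pct: float
    mape_sd_pct: float
    bias_min: float
    loa_lo_min: float
    loa_hi_min: float
    bias_pct: float
    loa_lo_pct: float
    loa_hi_pct: float
    equiv_zone_pct: float
    equiv_zone_sd_multiple: float
    residuals: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        return (
            f"Agreement vs criterion — {self.comparison} "
            f"({self.n} {self.unit}s)\n"
            f"  criterion  : {self.criterion_mean_min:6.1f} ± "
            f"{self.criterion_sd_min:.1f} min/d\n"
            f"  comparison : {self.comparison_mean_min:6.1f} ± "
            f"{self.comparison_sd_min:.1f} min/d\n"
            f"  MPE  : {self.mpe_pct:+.1f} ± {self.mpe_sd_pct:.1f} %\n"
            f"  MAPE : {self.mape_pct:.1f} ± {self.mape_sd_pct:.1f} %\n"
            f"  Bland-Altman bias : {self.bias_min:+.0f} min "
            f"(LoA {self.loa_lo_min:.0f} to {self.loa_hi_min:.0f} min)\n"
            f"  Bland-Altman bias : {self.bias_pct:+.0f} % "
            f"(LoA {self.loa_lo_pct:.0f} to {self.loa_hi_pct:.0f} %)\n"
            f"  equivalence zone  : {self.equiv_zone_pct:.0f}% of criterion "
            f"mean ({self.equiv_zone_sd_multiple:.1f} SD)"
        )

    def plot_bland_altman(self, ax=None):
        """Difference-vs-mean plot with bias and limits of agreement."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        r = self.residuals
        mean = (r["criterion_min"] + r["comparison_min"]) / 2.0
        diff = r["criterion_min"] - r["comparison_min"]
        ax.scatter(mean, diff, s=18, alpha=0.7)
        ax.axhline(self.bias_min, color="k")
        for y in (self.loa_lo_min, self.loa_hi_min):
            ax.axhline(y, color="k", linestyle="--")
        ax.set_xlabel("mean of methods (min/d)")
        ax.set_ylabel("criterion - comparison (min/d)")
        ax.set_title(f"Bland-Altman: criterion vs {self.comparison}")
        return ax


class MethodAgreement:
    """Agreement analysis of one comparison method against the criterion.

    ``fit()`` computes MPE/MAPE, Bland-Altman on both scales, and the
    equivalence zone, returning an :class:`AgreementResults`.
    """

    def __init__(self, pairs: PairedEstimates, comparison: str = "comparison"):
        self.pairs = pairs
        self.comparison = comparison

    @classmethod
    def from_daily(cls, daily: pd.DataFrame, est_col: str,
                   unit: str = "participant",
                   comparison: str | None = None) -> "MethodAgreement":
        """Build from participant-day rows; participant-level means by default."""
        df = daily[["participant_id", "criterion_sed_min", est_col]].copy()
        if unit == "participant":
            df = df.groupby("participant_id", as_index=False).mean()
        elif unit != "day":
            raise ValueError("unit must be 'participant' or 'day'")
        pairs = PairedEstimates(df.rename(columns={
            "participant_id": "id", "criterion_sed_min": "criterion_min",
            est_col: "comparison_min"}), unit=unit)
        return cls(pairs, comparison or est_col)

    def fit(self) -> AgreementResults:
        p = self.pairs
        mpe, mpe_sd, mape, mape_sd = mpe_mape(p)
        bias, lo, hi = bland_altman(p, "absolute")
        bias_p, lo_p, hi_p = bland_altman(p, "percent")
        zone, sd_mult = equivalence_zone(p)
        res = p.frame.copy()
        res["diff_min"] = res["criterion_min"] - res["comparison_min"]
        res["pct_error"] = np.where(
            res["comparison_min"] != 0,
            100.0 * res["diff_min"] / res["comparison_min"], np.nan)
        return AgreementResults(
            comparison=self.comparison, n=len(p), unit=p.unit,
            criterion_mean_min=float(p.criterion.mean()),
            criterion_sd_min=float(p.criterion.std(ddof=1)),
            comparison_mean_min=float(p.comparison.mean()),
            comparison_sd_min=float(p.comparison.std(ddof=1)),
            mpe_pct=mpe, mpe_sd_pct=mpe_sd, mape_pct=mape, mape_sd_pct=mape_sd,
            bias_min=bias, loa_lo_min=lo, loa_hi_min=hi,
            bias_pct=bias_p, loa_lo_pct=lo_p, loa_hi_pct=hi_p,
            equiv_zone_pct=zone, equiv_zone_sd_multiple=sd_mult,
            residuals=res)
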