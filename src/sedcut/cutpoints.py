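"""Cut-point derivation from the laboratory protocol via ROC / Youden index.

Epoch values are first reduced to per-participant, per-activity means over
the trimmed interior of each scripted bout (first and last 30 s excluded).
Sedentary activities (codes 1-6: lying and sitting) form the positive class;
the classifier predicts sedentary when the metric value falls *below* the
threshold.  The optimal threshold maximises the Youden index
J = sensitivity + specificity - 1 over midpoints between consecutive
distinct values, ties broken toward the larger threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import EpochSeries
from .simulate import ActivityScript

__all__ = ["activity_means", "label_activities", "roc_youden", "classify_auc",
           "CutpointModel", "CutpointResults", "SEDENTARY_CODES"]

SEDENTARY_CODES = frozenset(range(1, 7))   # lying and sitting activities
NONSED_CODES = frozenset(range(7, 13))     # upright activities
PASSIVE_STANDING_CODE = 7


def activity_means(series: EpochSeries, script: ActivityScript,
                   trim_s: float = 30.0,
                   participant_id: str | int = 0) -> pd.DataFrame:
    """Mean epoch ENMO/MAD per scripted activity, trimmed interior only.

    Only epochs lying wholly inside ``[start + trim_s, end - trim_s)`` of a
    coded bout contribute.  Bouts shorter than twice the trim are skipped
    with a warning.  Returns columns ``participant_id, activity_code, label,
    mean_enmo_mg, mean_mad_mg, n_epochs``.
    """
    t0 = series.start_time
    ep = series.epoch_s
    rows = []
    for bout in script.bouts:
        if bout.code is None:
            continue
        if (bout.end - bout.start).total_seconds() < 2 * trim_s + ep:
            warnings.warn(f"activity {bout.code} bout shorter than twice the "
                          f"trim; skipped", stacklevel=2)
            continue
        lo = (bout.start - t0).total_seconds() + trim_s
        hi = (bout.end - t0).total_seconds() - trim_s
        k0 = int(np.ceil(lo / ep - 1e-9))
        k1 = int(np.floor(hi / ep + 1e-9))  # epochs [k0, k1)
        k0, k1 = max(k0, 0), min(k1, len(series))
        if k1 <= k0:
            warnings.warn(f"activity {bout.code} has no interior epochs; "
                          f"skipped", stacklevel=2)
            continue
        rows.append({
            "participant_id": participant_id,
            "activity_code": bout.code,
            "label": bout.label,
            "mean_enmo_mg": float(series.enmo_mg[k0:k1].mean()),
            "mean_mad_mg": float(series.mad_mg[k0:k1].mean()),
            "n_epochs": k1 - k0,
        })
    return pd.DataFrame(rows)


def label_activities(summaries: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Attach the binary sedentary label under a grouping scheme.

    ``sed_vs_nonsed``: activities 1-6 positive, 7-12 negative.
    ``sed_vs_passive_standing``: activities 1-6 positive, activity 7 (quiet
    standing) the sole negative; other activities are dropped.
    """
    codes = set(summaries["activity_code"].astype(int))
    bad = codes - (SEDENTARY_CODES | NONSED_CODES)
    if bad:
        raise ValueError(f"unknown activity codes: {sorted(bad)}")
    df = summaries.copy()
    df["is_sedentary"] = df["activity_code"].isin(SEDENTARY_CODES)
    if scheme == "sed_vs_nonsed":
        return df
    if scheme == "sed_vs_passive_standing":
        keep = df["is_sedentary"] | (df["activity_code"] == PASSIVE_STANDING_CODE)
        return df[keep].reset_index(drop=True)
    raise ValueError(f"unknown scheme {scheme!r}")


@dataclass
class CutpointResults:
    """Optimal threshold and ROC summary for one metric.

    ``threshold_mg`` maximises the Youden index for the rule
    "sedentary if value < threshold"; ``roc_points`` holds (fpr, tpr,
    threshold) along the full curve.
    """

    metric: str
    threshold_mg: float
    auc: float
    sensitivity: float
    specificity: float
    youden: float
    roc_points: pd.DataFrame = field(repr=False)
    n_positive: int = 0
    n_negative: int = 0

    @property
    def auc_band(self) -> str:
        return classify_auc(self.auc)

    def summary(self) -> str:
        return (
            f"ROC / Youden cut-point ({self.metric.upper()})\n"
            f"  positives (sedentary) : {self.n_positive}\n"
            f"  negatives             : {self.n_negative}\n"
            f"  threshold             : {self.threshold_mg:.1f} mg "
            f"(sedentary if value < threshold)\n"
            f"  sensitivity           : {self.sensitivity:.3f}\n"
            f"  specificity           : {self.specificity:.3f}\n"
            f"  Youden J              : {self.youden:.3f}\n"
            f"  AUC                   : {self.auc:.3f} ({self.auc_band})"
        )


def roc_youden(values, labels, metric: str = "value") -> CutpointResults:
    """ROC curve, AUC and Youden-optimal threshold.

    ``labels`` are truthy for the positive (sedentary) class; the decision
    rule predicts positive when ``value < threshold``.  Candidate thresholds
    are midpoints between consecutive distinct values plus the extremes;
    sensitivity = P(value < t | positive), specificity = P(value >= t |
    negative).  AUC is the trapezoidal area under (fpr, tpr); ties on J are
    broken toward the larger threshold.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be 1-d and the same length")
    pos, neg = v[y], v[~y]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    distinct = np.unique(v)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cands = np.concatenate([[-np.inf], mids, [np.inf]])
    tpr = (pos[None, :] < cands[:, None]).mean(axis=1)
    fpr = (neg[None, :] < cands[:, None]).mean(axis=1)
    j = tpr - fpr  # sens + spec - 1
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    finite = np.isfinite(cands)
    jf, cf = j[finite], cands[finite]
    best_j = jf.max()
    best = np.flatnonzero(np.isclose(jf, best_j))[-1]  # tie -> larger threshold
    thr = float(cf[best])
    sens = float((pos < thr).mean())
    spec = float((neg >= thr).mean())
    roc = pd.DataFrame({"fpr": fpr[order], "tpr": tpr[order],
                        "threshold": cands[order]})
    return CutpointResults(metric=metric, threshold_mg=thr, auc=auc,
                           sensitivity=sens, specificity=spec,
                           youden=float(sens + spec - 1.0), roc_points=roc,
                           n_positive=int(pos.size), n_negative=int(neg.size))


def classify_auc(auc: float) -> str:
    """Discrimination band: <0.7 poor, 0.70-0.79 fair, 0.80-0.89 good,
    >=0.90 excellent."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if auc < 0.70:
        return "poor"
    if auc < 0.80:
        return "fair"
    if auc < 0.90:
        return "good"
    return "excellent"


class CutpointModel:
    """Cut-point estimation from labelled per-activity means.

    Construct from value/label arrays, or with :meth:`from_summaries` from
    the ``activity_means`` table of a cohort plus a grouping scheme.
    ``fit()`` returns :class:`CutpointResults`.
    """

    def __init__(self, values, labels, metric: str = "value"):
        self.values = np.asarray(values, dtype=float)
        self.labels = np.asarray(labels, dtype=bool)
        self.metric = metric

    @classmethod
    def from_summaries(cls, summaries: pd.DataFrame, metric: str = "mad",
                       scheme: str = "sed_vs_nonsed") -> "CutpointModel":
        labelled = label_activities(summaries, scheme)
        col = {"enmo": "mean_enmo_mg", "mad": "mean_mad_mg"}[metric]
        return cls(labelled[col].to_numpy(),
                   labelled["is_sedentary"].to_numpy(), metric=metric)

    def fit(self) -> CutpointResults:
        return roc_youden(self.values, self.labels, metric=self.metric)
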