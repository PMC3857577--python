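"""Severity stratification: two-group clustering, discriminant accuracy, ROC.

Patients are split into severe vs non-severe outcome groups on a single
behavioral score by the exact least-squares two-group partition (the
1-D k=2 clustering solved by exhaustive search over the n-1 sorted
split points; for one variable this is what a two-step/k-means
clustering converges to, without any seed dependence). Lower scores are
worse, so the lower group is "severe". A one-variable linear
discriminant (pooled within-group variance, priors proportional to
group sizes) measures how cleanly the cutoff separates the scores, and
a ROC analysis of a lesion-load predictor against the severity labels
yields the decision threshold in cc.

ROC conventions: a patient is predicted severe when the predictor is at
or above the cutpoint (larger load = worse outcome); candidate
cutpoints sit midway between consecutive observed predictor values
(plus one below the minimum and one above the maximum), so the reported
threshold is a midpoint, as classical statistics packages print; the
operating point maximises Youden's J = sensitivity + specificity - 1
with ties broken toward higher specificity; AUC is the trapezoidal area,
identically the normalised Mann-Whitney U statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateInputError

__all__ = [
    "SeverityPartition",
    "ROCResult",
    "two_group_cluster",
    "severity_from_cutoff",
    "discriminant_accuracy",
    "roc_analysis",
    "stratify",
    "REPORTED_CUTOFF_BANDS",
]

#: Published cutoff bands (low, high) between the severe and non-severe
#: groups for each behavioral measure, used when reproducing the
#: published stratification table; severe = score <= low.
REPORTED_CUTOFF_BANDS = {
    "cius_per_min": (8.0, 13.0),
    "words_per_min": (31.0, 32.0),
    "bnt": (5.0, 6.0),
}


@dataclass(frozen=True)
class SeverityPartition:
    """A two-group interval split of one behavioral variable."""

    variable: str
    severe: np.ndarray = field(repr=False)  # boolean per patient
    cutoff_band: tuple[float, float]  # (max severe score, min non-severe score)

    def __post_init__(self) -> None:
        object.__setattr__(self, "severe", np.asarray(self.severe, dtype=bool))

    @property
    def n_severe(self) -> int:
        return int(self.severe.sum())

    @property
    def n_non_severe(self) -> int:
        return int((~self.severe).sum())


def two_group_cluster(scores: Sequence[float], variable: str = "") -> SeverityPartition:
    """Exact least-squares two-group split of a 1-D score.

    Scans all n-1 split points of the sorted scores and picks the one
    minimising total within-group sum of squares. The lower group is
    labelled severe (lower fluency/naming = worse outcome).
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 4:
        raise DegenerateInputError(f"need >= 4 scores, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all scores are equal; no two-group structure")
    xs = np.sort(x)
    n = x.size
    # prefix sums give O(n) within-group SS for every split
    c1, c2 = np.cumsum(xs), np.cumsum(xs**2)
    k = np.arange(1, n)  # lower-group sizes
    ss_lo = c2[k - 1] - c1[k - 1] ** 2 / k
    ss_hi = (c2[-1] - c2[k - 1]) - (c1[-1] - c1[k - 1]) ** 2 / (n - k)
    tot = ss_lo + ss_hi
    best = int(np.argmin(tot))
    low, high = float(xs[best]), float(xs[best + 1])
    if low == high:  # split fell inside a run of ties; move to the run boundary
        distinct = np.flatnonzero(xs[:-1] < xs[1:])
        j = distinct[np.argmin(tot[distinct])]
        low, high = float(xs[j]), float(xs[j + 1])
    return SeverityPartition(variable=variable, severe=x <= low, cutoff_band=(low, high))


def severity_from_cutoff(
    scores: Sequence[float], cutoff: float, variable: str = ""
) -> SeverityPartition:
    """Severity labels from an externally given cutoff: severe = score <= cutoff."""
    x = np.asarray(scores, dtype=float)
    severe = x <= cutoff
    if severe.all() or not severe.any():
        raise DegenerateInputError(f"cutoff {cutoff} puts all scores in one group")
    return SeverityPartition(
        variable=variable,
        severe=severe,
        cutoff_band=(float(x[severe].max()), float(x[~severe].min())),
    )


def discriminant_accuracy(scores: Sequence[float], partition: SeverityPartition) -> float:
    """Resubstitution accuracy of a one-variable linear discriminant.

    Gaussian classes with pooled within-group variance and priors
    proportional to group sizes; each score is assigned to the class
    with the larger discriminant value and compared with its label.
    """
    x = np.asarray(scores, dtype=float)
    sev = partition.severe
    n1, n0 = partition.n_severe, partition.n_non_severe
    if n1 == 0 or n0 == 0:
        raise DegenerateInputError("both groups must be nonempty")
    m1, m0 = x[sev].mean(), x[~sev].mean()
    s2 = (((x[sev] - m1) ** 2).sum() + ((x[~sev] - m0) ** 2).sum()) / (n1 + n0 - 2)
    if s2 == 0:  # perfectly tight groups: classify by nearest mean
        pred = np.abs(x - m1) < np.abs(x - m0)
    else:
        d1 = x * m1 / s2 - m1**2 / (2 * s2) + np.log(n1 / (n1 + n0))
        d0 = x * m0 / s2 - m0**2 / (2 * s2) + np.log(n0 / (n1 + n0))
        pred = d1 > d0
    return float((pred == sev).mean())


@dataclass(frozen=True)
class ROCResult:
    auc: float
    threshold_cc: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_points: int
    #: (threshold, sensitivity, 1-specificity) per candidate cutpoint
    curve: np.ndarray = field(repr=False)


def roc_analysis(predictor: Sequence[float], partition: SeverityPartition) -> ROCResult:
    """ROC of a lesion-load-like predictor against severity labels.

    See the module docstring for the cutpoint, Youden and tie-break
    conventions. ``accuracy`` is the raw proportion correct at the
    chosen threshold.
    """
    x = np.asarray(predictor, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("predictor contains non-finite values")
    sev = partition.severe
    n1, n0 = partition.n_severe, partition.n_non_severe
    if n1 == 0 or n0 == 0:
        raise DegenerateInputError("both groups must be nonempty")
    # AUC as the normalised Mann-Whitney U statistic (ties count 1/2),
    # identical to the trapezoidal area under the empirical curve.
    ranks = rankdata(x)
    auc = (ranks[sev].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    vals = np.unique(x)
    cuts = np.concatenate(([vals[0] - 1.0], (vals[:-1] + vals[1:]) / 2.0, [vals[-1] + 1.0]))
    best = None
    curve = np.empty((cuts.size, 3))
    for i, t in enumerate(cuts):
        pred = x >= t
        sens = (pred & sev).sum() / n1
        spec = (~pred & ~sev).sum() / n0
        curve[i] = (t, sens, 1 - spec)
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and spec > best[3]):
            best = (j, t, sens, spec)
    _, thr, sens, spec = best
    acc = float(((x >= thr) == sev).mean())
    return ROCResult(
        auc=float(auc),
        threshold_cc=float(thr),
        sensitivity=float(sens),
        specificity=float(spec),
        accuracy=acc,
        n_points=int(x.size),
        curve=curve,
    )


def stratify(load_cc: float, threshold_cc: float) -> str:
    """Classify one patient's load against a decision threshold.

    Boundary ties go to severe: for a screening rule, a load exactly at
    the threshold is treated as the worse outcome.
    """
    if not (np.isfinite(load_cc) and np.isfinite(threshold_cc)):
        raise ValueError("load and threshold must be finite")
    return "severe" if load_cc >= threshold_cc else "non_severe"
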