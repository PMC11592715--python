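"""Scan-level ROC analysis with DeLong variance and paired comparison.

Each scan is reduced to a single probability: the highest confidence among
its retained detector marks (zero when the detector produced none). Included
abnormal scans are the positive class, normal scans the negative class. The
AUC is the Mann-Whitney two-sample statistic with ties scored 1/2; its
sampling variance and the covariance between two conditions evaluated on the
same scans come from DeLong's structural components,

    V10(x_i) = mean_j psi(x_i, y_j),   V01(y_j) = mean_i psi(x_i, y_j),
    psi(x, y) = 1 if x > y, 1/2 if x = y, 0 if x < y,

    var(AUC) = S10/m + S01/n,

with ``S10``/``S01`` the sample variances (and, for the paired test, sample
cross-covariances) of the components over the m positives and n negatives.
The paired z test uses var(AUC_b - AUC_a) = var_a + var_b - 2 cov and a
two-sided normal p-value. 95% confidence intervals are the normal
approximation AUC +/- 1.96 SE, clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .cohort import NoduleSet, Scan
from .errors import UndefinedStatisticError, ValidationError
from .matching import MatchResult


@dataclass(frozen=True)
class ScanScore:
    """One scan's truth label and aggregated detection probability."""

    scan_id: str
    is_positive: bool
    probability: float


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_variance: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    operating_point: OperatingPoint | None = None


@dataclass(frozen=True)
class PairedComparison:
    """Paired DeLong comparison of two conditions on the same scans."""

    auc_a: float
    auc_b: float
    delta: float
    z: float
    p_value: float


def scan_probability(match: MatchResult, scan_id: str) -> float:
    """Highest mark confidence on the scan; 0.0 when the scan has no marks.

    Lesion, irrelevant, and non-lesion marks all contribute — on a normal
    scan only non-lesion marks can exist anyway.
    """
    return max(match.confidences_on_scan(scan_id), default=0.0)


def scan_scores(
    match: MatchResult, nodule_set: NoduleSet, scans: Iterable[Scan]
) -> list[ScanScore]:
    """Scores for one ROC: included abnormal scans vs all normal scans."""
    out = []
    for scan in sorted(scans, key=lambda s: s.scan_id):
        if scan.is_abnormal:
            if scan.scan_id not in nodule_set.abnormal_scans:
                continue
            positive = True
        else:
            positive = False
        out.append(ScanScore(scan.scan_id, positive, scan_probability(match, scan.scan_id)))
    return out


def _split(scores: Sequence[ScanScore]) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([s.probability for s in scores if s.is_positive], dtype=float)
    neg = np.array([s.probability for s in scores if not s.is_positive], dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedStatisticError(
            f"ROC needs both classes; got {len(pos)} positive and "
            f"{len(neg)} negative scans"
        )
    return pos, neg


def _components(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus DeLong structural components V10 (per positive), V01 (per negative)."""
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def auc(scores: Sequence[ScanScore]) -> float:
    """Mann-Whitney AUC with ties scored 1/2."""
    pos, neg = _split(scores)
    return _components(pos, neg)[0]


def delong_variance(scores: Sequence[ScanScore]) -> float:
    """DeLong variance of the AUC; needs >= 2 scans per class."""
    pos, neg = _split(scores)
    if len(pos) < 2 or len(neg) < 2:
        raise UndefinedStatisticError(
            "DeLong variance needs at least 2 positives and 2 negatives"
        )
    _, v10, v01 = _components(pos, neg)
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


def roc_result(
    scores: Sequence[ScanScore],
    operating_point_spec: "tuple[str, float] | None" = None,
) -> RocResult:
    """AUC with DeLong 95% CI and an optional operating point.

    ``operating_point_spec`` is ``("fixed_threshold", t)`` or
    ``("target_specificity", s)``.
    """
    pos, neg = _split(scores)
    a = _components(pos, neg)[0]
    var = delong_variance(scores)
    half = 1.96 * float(np.sqrt(var))
    op = None
    if operating_point_spec is not None:
        mode, value = operating_point_spec
        if mode == "fixed_threshold":
            op = operating_point(scores, threshold=value)
        elif mode == "target_specificity":
            op = operating_point(scores, target_specificity=value)
        else:
            raise ValidationError(f"unknown operating-point mode {mode!r}")
    return RocResult(
        auc=a,
        auc_variance=var,
        ci95=(max(0.0, a - half), min(1.0, a + half)),
        n_pos=len(pos),
        n_neg=len(neg),
        operating_point=op,
    )


def delong_paired_test(
    a: Sequence[ScanScore], b: Sequence[ScanScore]
) -> PairedComparison:
    """Two-sided paired DeLong test of AUC_b - AUC_a on the same scans.

    Both score lists must cover the same scans with the same truth labels
    (one detector condition each). When the variance of the difference is
    numerically zero the convention is p = 1 for delta = 0 and p = 0
    otherwise.
    """
    a = sorted(a, key=lambda s: s.scan_id)
    b = sorted(b, key=lambda s: s.scan_id)
    if [(s.scan_id, s.is_positive) for s in a] != [
        (s.scan_id, s.is_positive) for s in b
    ]:
        raise ValidationError(
            "paired DeLong test needs identical scans and truth labels in "
            "both conditions"
        )
    pos_a, neg_a = _split(a)
    pos_b, neg_b = _split(b)
    m, n = len(pos_a), len(neg_a)
    if m < 2 or n < 2:
        raise UndefinedStatisticError(
            "paired DeLong test needs at least 2 positives and 2 negatives"
        )
    auc_a, v10_a, v01_a = _components(pos_a, neg_a)
    auc_b, v10_b, v01_b = _components(pos_b, neg_b)
    var_a = np.var(v10_a, ddof=1) / m + np.var(v01_a, ddof=1) / n
    var_b = np.var(v10_b, ddof=1) / m + np.var(v01_b, ddof=1) / n
    cov = (
        np.cov(v10_a, v10_b, ddof=1)[0, 1] / m
        + np.cov(v01_a, v01_b, ddof=1)[0, 1] / n
    )
    delta = auc_b - auc_a
    var_delta = float(var_a + var_b - 2.0 * cov)
    if var_delta <= 0.0:
        z = 0.0 if delta == 0.0 else float(np.sign(delta)) * float("inf")
        p = 1.0 if delta == 0.0 else 0.0
    else:
        z = float(delta / np.sqrt(var_delta))
        p = float(2.0 * norm.sf(abs(z)))
    return PairedComparison(auc_a=auc_a, auc_b=auc_b, delta=delta, z=z, p_value=p)


def operating_point(
    scores: Sequence[ScanScore],
    threshold: float | None = None,
    target_specificity: float | None = None,
) -> OperatingPoint:
    """Accuracy/sensitivity/specificity at a decision threshold.

    A scan is called positive when its probability is >= the threshold. In
    ``target_specificity`` mode the threshold is the smallest candidate
    (the observed scores plus one above the maximum) achieving at least the
    requested specificity.
    """
    if (threshold is None) == (target_specificity is None):
        raise ValidationError(
            "give exactly one of threshold= or target_specificity="
        )
    pos, neg = _split(scores)
    if threshold is None:
        assert target_specificity is not None
        if target_specificity > 1.0:
            raise ValidationError(
                f"specificity target {target_specificity} is unattainable"
            )
        all_scores = np.concatenate([pos, neg])
        candidates = np.unique(all_scores).tolist() + [float(all_scores.max()) + 1.0]
        threshold = next(
            t for t in candidates if float(np.mean(neg < t)) >= target_specificity
        )
    sens = float(np.mean(pos >= threshold))
    spec = float(np.mean(neg < threshold))
    acc = (sens * len(pos) + spec * len(neg)) / (len(pos) + len(neg))
    return OperatingPoint(
        threshold=float(threshold), accuracy=acc, sensitivity=sens, specificity=spec
    )
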