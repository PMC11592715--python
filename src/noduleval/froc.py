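"""Nodule-level FROC analysis, CPM, and 6 mm size subgroups.

The FROC curve sweeps a confidence threshold over the distinct mark
confidences (plus +infinity). At each threshold t,

    sensitivity   = (# nodules with >= 1 hitting mark of confidence >= t) / n_nodules
    FP per scan   = (# non-lesion marks of confidence >= t) / n_scans

The FP denominator defaults to the included abnormal scans plus the normal
scans; an abnormal-only mode restricts both the denominator and the counted
false-positive marks to abnormal scans. Sensitivities at the target FP rates
(default 1/8, 1/4, 1/2, 1, 2, 4 per scan) are read off the sweep polyline by
linear interpolation between consecutive sweep points; a rate that coincides
with an achieved FP rate takes the maximum sensitivity there (vertical
segments collapse upward), rates beyond the largest achieved rate take the
final plateau sensitivity, and rates below the smallest achieved rate score
zero. The competition performance metric (CPM) is the arithmetic mean of the
sensitivities at the target rates.

Size subgroups follow the 6 mm Lung-RADS threshold: "< 6 mm" is a strict
inequality, so a nodule of exactly 6 mm belongs to the ">= 6 mm" subgroup.
Subgrouping demotes out-of-subgroup qualifying nodules to irrelevant (marks
on them count neither way) and keeps only scans with at least one in-subgroup
nodule as positives; one scan can belong to both subgroups.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cohort import NoduleSet, Scan
from .errors import UndefinedStatisticError, ValidationError
from .matching import NON_LESION, MatchResult, match_marks
from .perscan import ScanScore, scan_probability

DEFAULT_FP_RATES: tuple[float, ...] = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class SubgroupSpec:
    """A one-sided diameter restriction: side 'lt' (< threshold) or 'ge'."""

    threshold_mm: float = 6.0
    side: str = "lt"

    def __post_init__(self) -> None:
        if self.threshold_mm <= 0:
            raise ValidationError("subgroup threshold_mm must be positive")
        if self.side not in ("lt", "ge"):
            raise ValidationError(f"subgroup side must be 'lt' or 'ge', got {self.side!r}")

    def contains(self, diameter_mm: float) -> bool:
        if self.side == "lt":
            return diameter_mm < self.threshold_mm
        return diameter_mm >= self.threshold_mm


@dataclass(frozen=True)
class FrocResult:
    """FROC sweep points plus sensitivities at fixed FP rates and the CPM."""

    thresholds: tuple[float, ...]
    points: tuple[tuple[float, float], ...]  # (fp_per_scan, sensitivity)
    fp_rates: tuple[float, ...]
    sensitivities_at_rates: tuple[float, ...]
    cpm: float
    n_nodules: int
    n_scans: int


def cpm(sensitivities_at_rates: Sequence[float]) -> float:
    """Competition performance metric: mean sensitivity over the FP rates."""
    vals = list(sensitivities_at_rates)
    if not vals:
        raise UndefinedStatisticError("CPM of an empty sensitivity list is undefined")
    if any(not (0.0 <= v <= 1.0) for v in vals):
        raise ValidationError("sensitivities must lie in [0, 1]")
    return float(np.mean(vals))


def _interpolate(points: Sequence[tuple[float, float]], rate: float, step: bool) -> float:
    """Sensitivity at an FP rate from the ordered sweep polyline."""
    fps = [p[0] for p in points]
    if rate < fps[0]:
        return 0.0
    if rate >= fps[-1]:
        return points[-1][1]
    if step:
        # max sensitivity among points achieved at fp <= rate
        idx = bisect.bisect_right(fps, rate) - 1
        return max(p[1] for p in points[: idx + 1])
    lo = bisect.bisect_left(fps, rate)
    hi = bisect.bisect_right(fps, rate)
    if lo != hi:  # rate coincides with achieved fp values: collapse upward
        return max(p[1] for p in points[lo:hi])
    i = lo - 1  # last point strictly below, next point strictly above
    (f1, s1), (f2, s2) = points[i], points[i + 1]
    return s1 + (s2 - s1) * (rate - f1) / (f2 - f1)


def froc(
    match: MatchResult,
    nodule_set: NoduleSet,
    scans: Iterable[Scan],
    fp_rates: Sequence[float] = DEFAULT_FP_RATES,
    fp_denominator: str = "all",
    interpolation: str = "linear",
) -> FrocResult:
    """Build the FROC curve for one condition against one nodule set.

    ``fp_denominator``: 'all' counts included abnormal plus normal scans;
    'abnormal' restricts scans and counted false positives to the included
    abnormal scans. ``interpolation``: 'linear' (default) or 'step'.
    """
    rates = tuple(float(r) for r in fp_rates)
    if any(b <= a for a, b in zip(rates, rates[1:])) or any(r <= 0 for r in rates):
        raise ValidationError("fp_rates must be strictly increasing and positive")
    if fp_denominator not in ("all", "abnormal"):
        raise ValidationError(f"unknown fp_denominator {fp_denominator!r}")
    if interpolation not in ("linear", "step"):
        raise ValidationError(f"unknown interpolation {interpolation!r}")
    if not nodule_set.nodules:
        raise UndefinedStatisticError("FROC of an empty nodule set is undefined")

    counted: set[str] = set(nodule_set.abnormal_scans)
    if fp_denominator == "all":
        counted |= {s.scan_id for s in scans if not s.is_abnormal}
    n_scans = len(counted)
    if n_scans == 0:
        raise UndefinedStatisticError("FROC needs a non-empty scan list")

    best_hit = np.array(
        [
            max(match.nodule_hits.get(n.nodule_id, ()), default=-np.inf)
            for n in nodule_set.nodules
        ],
        dtype=float,
    )
    fp_confs = np.array(
        [
            a.mark.confidence
            for a in match.assignments
            if a.label == NON_LESION and a.mark.scan_id in counted
        ],
        dtype=float,
    )

    finite_hits = best_hit[np.isfinite(best_hit)]
    thresholds = np.unique(np.concatenate([finite_hits, fp_confs]))[::-1]
    sweep: list[tuple[float, float]] = [(0.0, 0.0)]  # threshold +inf
    thresh_out: list[float] = [float("inf")]
    n_nodules = len(nodule_set.nodules)
    for t in thresholds:
        sens = float(np.count_nonzero(best_hit >= t)) / n_nodules
        fp = float(np.count_nonzero(fp_confs >= t)) / n_scans
        sweep.append((fp, sens))
        thresh_out.append(float(t))

    sens_at = tuple(
        _interpolate(sweep, r, step=(interpolation == "step")) for r in rates
    )
    return FrocResult(
        thresholds=tuple(thresh_out),
        points=tuple(sweep),
        fp_rates=rates,
        sensitivities_at_rates=sens_at,
        cpm=cpm(sens_at),
        n_nodules=n_nodules,
        n_scans=n_scans,
    )


def subgroup_nodules(nodule_set: NoduleSet, spec: SubgroupSpec) -> NoduleSet:
    """Restrict a nodule set to one diameter subgroup.

    Qualifying nodules outside the subgroup become irrelevant; included
    scans without any in-subgroup nodule move to the excluded list.
    """
    in_sub = tuple(n for n in nodule_set.nodules if spec.contains(n.diameter_mm))
    out_sub = tuple(n for n in nodule_set.nodules if not spec.contains(n.diameter_mm))
    member_scans = frozenset(n.scan_id for n in in_sub)
    return NoduleSet(
        label=nodule_set.label,
        min_agreement=nodule_set.min_agreement,
        nodules=in_sub,
        abnormal_scans=member_scans,
        excluded_scans=nodule_set.excluded_scans
        | (nodule_set.abnormal_scans - member_scans),
        irrelevant_nodules=nodule_set.irrelevant_nodules + out_sub,
    )


def perscan_subgroup_scores(
    marks: Iterable,
    nodule_set: NoduleSet,
    scans: Iterable[Scan],
    spec: SubgroupSpec,
    hit_multiplier: float = 1.5,
    irrelevant_as_fp: bool = False,
) -> list[ScanScore]:
    """Scan scores for one size subgroup's ROC.

    Positives are abnormal scans holding at least one in-subgroup nodule;
    negatives are all normal scans. Marks are re-matched against the
    subgrouped ground truth. Raises when the subgroup holds no scan.
    """
    scans = list(scans)
    sub = subgroup_nodules(nodule_set, spec)
    if not sub.abnormal_scans:
        raise UndefinedStatisticError(
            f"subgroup {spec.side} {spec.threshold_mm} mm contains no abnormal scan"
        )
    sub_match = match_marks(
        marks, sub, scans, hit_multiplier=hit_multiplier,
        irrelevant_as_fp=irrelevant_as_fp,
    )
    out = []
    for scan in sorted(scans, key=lambda s: s.scan_id):
        if scan.is_abnormal:
            if scan.scan_id not in sub.abnormal_scans:
                continue
            positive = True
        else:
            positive = False
        out.append(
            ScanScore(scan.scan_id, positive, scan_probability(sub_match, scan.scan_id))
        )
    return out
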