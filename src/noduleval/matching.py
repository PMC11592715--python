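"""Classify detector marks against the consensus ground truth.

A CAD mark *hits* a nodule when its center lies strictly within
``hit_multiplier`` (default 1.5) times the nodule's radius — center-to-center
Euclidean distance on all three world-mm axes, using the consensus diameter
only. Each retained mark gets exactly one label:

``lesion``
    hits at least one qualifying nodule; assigned to the nearest hit nodule
    (ties broken by smaller nodule id). Lesion marks never count as false
    positives, and a nodule with several hitting marks still counts once
    toward sensitivity.
``irrelevant``
    hits only nodules below the agreement threshold (or outside the active
    size subgroup). Excluded from both true- and false-positive counting,
    the convention the LUNA16 evaluation applies to sub-threshold
    annotations. ``irrelevant_as_fp=True`` switches to a strict mode where
    such marks are false positives instead.
``non_lesion``
    hits nothing; the false-positive candidates.

Marks on excluded abnormal scans are dropped (counted, not errors); marks on
scans absent from the manifest are an input inconsistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .cohort import ConsensusNodule, NoduleSet, Scan, Vec3, _as_vec3, euclidean_mm
from .errors import ValidationError

LESION = "lesion"
IRRELEVANT = "irrelevant"
NON_LESION = "non_lesion"


@dataclass(frozen=True)
class CadMark:
    """One detector output: a world-mm center and a confidence in [0, 1]."""

    scan_id: str
    center: Vec3
    confidence: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", _as_vec3(self.center, "mark center"))
        if not (0.0 <= self.confidence <= 1.0) or not math.isfinite(self.confidence):
            raise ValidationError(
                f"mark on scan {self.scan_id!r}: confidence must lie in [0, 1], "
                f"got {self.confidence!r}"
            )


@dataclass(frozen=True)
class MarkAssignment:
    """One retained mark with its label and (for hits) the matched nodule."""

    mark: CadMark
    label: str
    nodule_id: str | None = None
    distance_mm: float | None = None


@dataclass
class MatchResult:
    """All mark assignments for one condition against one nodule set."""

    assignments: tuple[MarkAssignment, ...]
    n_dropped: int
    nodule_hits: Mapping[str, tuple[float, ...]]
    _conf_by_scan: dict[str, list[float]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_scan: dict[str, list[float]] = {}
        for a in self.assignments:
            by_scan.setdefault(a.mark.scan_id, []).append(a.mark.confidence)
        self._conf_by_scan = by_scan

    def confidences_on_scan(self, scan_id: str) -> list[float]:
        return self._conf_by_scan.get(scan_id, [])

    def label_counts(self) -> dict[str, int]:
        counts = {LESION: 0, IRRELEVANT: 0, NON_LESION: 0}
        for a in self.assignments:
            counts[a.label] += 1
        return counts


def is_hit(
    mark: CadMark, nodule: ConsensusNodule, multiplier: float = 1.5
) -> bool:
    """Whether a mark localizes a nodule: distance < multiplier x radius.

    Strict inequality, so a mark exactly on the threshold sphere misses.
    """
    if mark.scan_id != nodule.scan_id:
        raise ValidationError(
            f"is_hit compares a mark and nodule on one scan; got "
            f"{mark.scan_id!r} and {nodule.scan_id!r}"
        )
    return euclidean_mm(mark.center, nodule.center) < multiplier * nodule.radius_mm


def _nearest_hit(
    mark: CadMark, nodules: list[ConsensusNodule], multiplier: float
) -> tuple[ConsensusNodule, float] | None:
    best: tuple[float, str, ConsensusNodule] | None = None
    for nod in nodules:
        dist = euclidean_mm(mark.center, nod.center)
        if dist < multiplier * nod.radius_mm:
            key = (dist, nod.nodule_id, nod)
            if best is None or key[:2] < best[:2]:
                best = key
    if best is None:
        return None
    return best[2], best[0]


def match_marks(
    marks: Iterable[CadMark],
    nodule_set: NoduleSet,
    scans: Iterable[Scan],
    hit_multiplier: float = 1.5,
    irrelevant_as_fp: bool = False,
) -> MatchResult:
    """Label every mark as lesion, irrelevant, or non_lesion.

    ``scans`` is the cohort manifest; marks on the nodule set's excluded
    scans are dropped (reported via ``n_dropped``), marks on unknown scans
    raise :class:`ValidationError`. Duplicate identical marks are retained.
    """
    marks = list(marks)
    scan_by_id = {s.scan_id: s for s in scans}
    qualifying_by_scan: dict[str, list[ConsensusNodule]] = {}
    for nod in nodule_set.nodules:
        qualifying_by_scan.setdefault(nod.scan_id, []).append(nod)
    irrelevant_by_scan: dict[str, list[ConsensusNodule]] = {}
    for nod in nodule_set.irrelevant_nodules:
        irrelevant_by_scan.setdefault(nod.scan_id, []).append(nod)

    unknown = sorted({m.scan_id for m in marks if m.scan_id not in scan_by_id})
    if unknown:
        raise ValidationError(
            f"marks reference scans absent from the manifest: {unknown}"
        )

    assignments: list[MarkAssignment] = []
    hits: dict[str, list[float]] = {}
    n_dropped = 0
    for mark in marks:
        if mark.scan_id in nodule_set.excluded_scans:
            n_dropped += 1
            continue
        found = _nearest_hit(
            mark, qualifying_by_scan.get(mark.scan_id, []), hit_multiplier
        )
        if found is not None:
            nod, dist = found
            assignments.append(MarkAssignment(mark, LESION, nod.nodule_id, dist))
            hits.setdefault(nod.nodule_id, []).append(mark.confidence)
            continue
        found = _nearest_hit(
            mark, irrelevant_by_scan.get(mark.scan_id, []), hit_multiplier
        )
        if found is not None and not irrelevant_as_fp:
            nod, dist = found
            assignments.append(MarkAssignment(mark, IRRELEVANT, nod.nodule_id, dist))
            continue
        assignments.append(MarkAssignment(mark, NON_LESION))

    return MatchResult(
        assignments=tuple(assignments),
        n_dropped=n_dropped,
        nodule_hits={k: tuple(v) for k, v in hits.items()},
    )
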