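"""Scans, reader annotations, and consensus ground truth.

Multiple radiologists independently mark nodules on each CT scan by drawing
the major and minor axes on the axial slice where the nodule is largest; the
nodule diameter is the average of the two axis lengths and the center is their
intersection, expressed in world millimetres. Two annotations (on the same
scan) are taken to describe the same physical nodule when their centers are
closer than ``merge_multiplier`` (default 1.5) times the mean of their radii.
Merging that pairwise relation into ground-truth nodules is done by connected
components (union-find), which is order-independent; each component becomes a
:class:`ConsensusNodule` whose center and diameter are the unweighted means
over the member annotations.

Ground truth is then graded by reader agreement: nodule set ``A`` keeps
consensus nodules at least two readers agreed on, set ``B`` keeps those all
three agreed on. Abnormal scans left without any qualifying nodule are
excluded from the analysis for that set; lower-agreement nodules on included
scans are kept aside as *irrelevant* — detector marks on them are neither true
nor false positives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError

Vec3 = tuple[float, float, float]

#: reader-agreement threshold per nodule-set label
AGREEMENT_BY_LABEL: Mapping[str, int] = {"A": 2, "B": 3}


def _as_vec3(value: Sequence[float], what: str) -> Vec3:
    vec = tuple(float(v) for v in value)
    if len(vec) != 3 or not all(math.isfinite(v) for v in vec):
        raise ValidationError(f"{what} must be a finite 3-vector, got {value!r}")
    return vec  # type: ignore[return-value]


def euclidean_mm(a: Sequence[float], b: Sequence[float]) -> float:
    """3D Euclidean distance in world millimetres."""
    return math.dist(a, b)


@dataclass(frozen=True)
class Scan:
    """One CT scan with its abnormal/normal label from the PACS report."""

    scan_id: str
    pacs_label: str

    def __post_init__(self) -> None:
        if self.pacs_label not in ("abnormal", "normal"):
            raise ValidationError(
                f"scan {self.scan_id!r}: pacs_label must be 'abnormal' or "
                f"'normal', got {self.pacs_label!r}"
            )

    @property
    def is_abnormal(self) -> bool:
        return self.pacs_label == "abnormal"


@dataclass(frozen=True)
class ReaderAnnotation:
    """One radiologist's mark on one nodule: center plus axis lengths (mm)."""

    scan_id: str
    reader_id: str
    center: Vec3
    major_axis_mm: float
    minor_axis_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", _as_vec3(self.center, "annotation center"))
        if not (self.major_axis_mm >= self.minor_axis_mm > 0.0):
            raise ValidationError(
                f"annotation on scan {self.scan_id!r} by {self.reader_id!r}: "
                f"need major_axis_mm >= minor_axis_mm > 0, got "
                f"major={self.major_axis_mm}, minor={self.minor_axis_mm}"
            )

    @property
    def diameter_mm(self) -> float:
        """Nodule diameter: mean of major and minor axis lengths."""
        return 0.5 * (self.major_axis_mm + self.minor_axis_mm)

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.diameter_mm

    def _sort_key(self):
        return (self.reader_id, self.center, self.major_axis_mm, self.minor_axis_mm)


@dataclass(frozen=True)
class ConsensusNodule:
    """Ground-truth nodule merged from one or more reader annotations."""

    nodule_id: str
    scan_id: str
    center: Vec3
    diameter_mm: float
    n_readers: int
    members: tuple[ReaderAnnotation, ...]

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.diameter_mm


@dataclass(frozen=True)
class NoduleSet:
    """Agreement-graded ground truth for one cohort.

    ``abnormal_scans`` are the abnormal scans with at least one qualifying
    nodule; ``excluded_scans`` are abnormal scans without any and take no part
    in downstream analysis for this set; ``irrelevant_nodules`` sit on
    included scans but miss the agreement threshold.
    """

    label: str
    min_agreement: int
    nodules: tuple[ConsensusNodule, ...]
    abnormal_scans: frozenset[str]
    excluded_scans: frozenset[str]
    irrelevant_nodules: tuple[ConsensusNodule, ...] = field(default_factory=tuple)

    def nodules_on_scan(self, scan_id: str) -> list[ConsensusNodule]:
        return [n for n in self.nodules if n.scan_id == scan_id]


def same_nodule(
    a: ReaderAnnotation, b: ReaderAnnotation, multiplier: float = 1.5
) -> bool:
    """Whether two annotations on the same scan refer to the same nodule.

    True iff the center-to-center distance is strictly less than
    ``multiplier`` times the average of the two radii. Symmetric in its
    arguments; annotations from different scans are a precondition violation.
    """
    if a.scan_id != b.scan_id:
        raise ValidationError(
            f"same_nodule compares annotations on one scan; got "
            f"{a.scan_id!r} and {b.scan_id!r}"
        )
    threshold = multiplier * 0.5 * (a.radius_mm + b.radius_mm)
    return euclidean_mm(a.center, b.center) < threshold


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def consolidate(
    annotations: Iterable[ReaderAnnotation], merge_multiplier: float = 1.5
) -> list[ConsensusNodule]:
    """Merge reader annotations into consensus nodules, scan by scan.

    Clusters are the connected components of the pairwise ``same_nodule``
    graph within each scan (the pairwise rule need not be transitive).
    Each cluster yields one :class:`ConsensusNodule` with componentwise-mean
    center, mean diameter, and the count of distinct readers. Output and
    nodule ids are invariant to the input ordering: annotations are put in a
    canonical order per scan and clusters are numbered by their smallest
    member in that order. Empty input yields an empty list.
    """
    by_scan: dict[str, list[ReaderAnnotation]] = {}
    for ann in annotations:
        by_scan.setdefault(ann.scan_id, []).append(ann)

    out: list[ConsensusNodule] = []
    for scan_id in sorted(by_scan):
        anns = sorted(by_scan[scan_id], key=ReaderAnnotation._sort_key)
        uf = _UnionFind(len(anns))
        for i in range(len(anns)):
            for j in range(i + 1, len(anns)):
                if same_nodule(anns[i], anns[j], merge_multiplier):
                    uf.union(i, j)
        clusters: dict[int, list[ReaderAnnotation]] = {}
        for i, ann in enumerate(anns):
            clusters.setdefault(uf.find(i), []).append(ann)
        for k, root in enumerate(sorted(clusters)):
            members = tuple(clusters[root])
            center = tuple(
                sum(m.center[ax] for m in members) / len(members) for ax in range(3)
            )
            diameter = sum(m.diameter_mm for m in members) / len(members)
            out.append(
                ConsensusNodule(
                    nodule_id=f"{scan_id}:{k:03d}",
                    scan_id=scan_id,
                    center=center,  # type: ignore[arg-type]
                    diameter_mm=diameter,
                    n_readers=len({m.reader_id for m in members}),
                    members=members,
                )
            )
    return out


def build_nodule_set(
    consensus: Iterable[ConsensusNodule],
    scans: Iterable[Scan],
    label: str,
) -> NoduleSet:
    """Grade consensus nodules into nodule set A (>=2 readers) or B (all 3).

    Raises :class:`ValidationError` on a consensus nodule sitting on a scan
    the manifest labels normal (annotation/manifest inconsistency) or on a
    scan absent from the manifest.
    """
    if label not in AGREEMENT_BY_LABEL:
        raise ValidationError(f"nodule-set label must be 'A' or 'B', got {label!r}")
    min_agreement = AGREEMENT_BY_LABEL[label]
    scan_by_id = {s.scan_id: s for s in scans}

    consensus = list(consensus)
    for nod in consensus:
        scan = scan_by_id.get(nod.scan_id)
        if scan is None:
            raise ValidationError(
                f"consensus nodule {nod.nodule_id} on scan {nod.scan_id!r} "
                f"absent from the manifest"
            )
        if not scan.is_abnormal:
            raise ValidationError(
                f"consensus nodule {nod.nodule_id} on scan {nod.scan_id!r} "
                f"which the manifest labels normal"
            )

    qualifying = tuple(n for n in consensus if n.n_readers >= min_agreement)
    included = frozenset(n.scan_id for n in qualifying)
    excluded = frozenset(
        s.scan_id
        for s in scan_by_id.values()
        if s.is_abnormal and s.scan_id not in included
    )
    irrelevant = tuple(
        n for n in consensus if n.n_readers < min_agreement and n.scan_id in included
    )
    return NoduleSet(
        label=label,
        min_agreement=min_agreement,
        nodules=qualifying,
        abnormal_scans=included,
        excluded_scans=excluded,
        irrelevant_nodules=irrelevant,
    )
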