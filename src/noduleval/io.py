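"""CSV dialects, analysis configuration, and the end-to-end evaluation run.

File formats (period decimal separator, header row required):

* scan manifest: ``scan_id,label`` with label in {abnormal, normal};
* reader annotations: ``scan_id,reader_id,coordX,coordY,coordZ,
  major_axis_mm,minor_axis_mm`` — world mm;
* CAD marks (LUNA16 candidates dialect): ``seriesuid,coordX,coordY,coordZ,
  probability`` (``scan_id`` accepted as an alias for ``seriesuid``);
* consensus output: ``nodule_id,scan_id,coordX,coordY,coordZ,diameter_mm,
  n_readers``.

``run_evaluation`` ties the stages together: consolidate the annotations,
grade them into the requested nodule set, match each condition's marks,
compute the scan-level ROC (with the paired DeLong comparison when exactly
two conditions are given), the nodule-level FROC/CPM, and both 6 mm size
subgroups, then assemble one JSON-serializable report with an exclusion
accounting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import perscan
from .cohort import (
    ConsensusNodule,
    NoduleSet,
    ReaderAnnotation,
    Scan,
    build_nodule_set,
    consolidate,
)
from .errors import UndefinedStatisticError, ValidationError
from .froc import (
    DEFAULT_FP_RATES,
    FrocResult,
    SubgroupSpec,
    froc,
    perscan_subgroup_scores,
    subgroup_nodules,
)
from .matching import CadMark, MatchResult, match_marks

logger = logging.getLogger("noduleval")

_ANNOTATION_COLS = [
    "scan_id", "reader_id", "coordX", "coordY", "coordZ",
    "major_axis_mm", "minor_axis_mm",
]
_MANIFEST_COLS = ["scan_id", "label"]
_MARK_COLS = ["seriesuid", "coordX", "coordY", "coordZ", "probability"]


def _read_table(path: str | Path, required: Sequence[str], aliases: Mapping[str, str] = {}) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ValidationError(f"{path}: cannot parse CSV ({exc})") from exc
    df = df.rename(columns=aliases)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return df


def _row_error(path, row: int, column: str, message: str) -> ValidationError:
    return ValidationError(f"{path}: row {row}: column {column!r}: {message}")


def read_scan_manifest(path: str | Path) -> list[Scan]:
    """Read the scan manifest; duplicate scan ids are an error."""
    df = _read_table(path, _MANIFEST_COLS)
    scans = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        sid = str(row["scan_id"])
        if sid in seen:
            raise _row_error(path, i, "scan_id", f"duplicate scan id {sid!r}")
        seen.add(sid)
        label = str(row["label"])
        if label not in ("abnormal", "normal"):
            raise _row_error(path, i, "label", f"expected abnormal/normal, got {label!r}")
        scans.append(Scan(sid, label))
    logger.info("read %d scans from %s", len(scans), path)
    return scans


def read_annotations(path: str | Path) -> list[ReaderAnnotation]:
    """Read one reader-annotation table; every row parses or the row and
    column of the first offending value are reported."""
    df = _read_table(path, _ANNOTATION_COLS)
    out = []
    for i, row in df.iterrows():
        for col in _ANNOTATION_COLS[2:]:
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise _row_error(path, i, col, f"non-numeric value {row[col]!r}")
        try:
            out.append(
                ReaderAnnotation(
                    scan_id=str(row["scan_id"]),
                    reader_id=str(row["reader_id"]),
                    center=(float(row["coordX"]), float(row["coordY"]), float(row["coordZ"])),
                    major_axis_mm=float(row["major_axis_mm"]),
                    minor_axis_mm=float(row["minor_axis_mm"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    logger.info("read %d annotations from %s", len(out), path)
    return out


def read_marks(path: str | Path) -> list[CadMark]:
    """Read one CAD mark table (LUNA16 candidates dialect)."""
    df = _read_table(path, _MARK_COLS, aliases={"scan_id": "seriesuid"})
    out = []
    for i, row in df.iterrows():
        for col in _MARK_COLS[1:]:
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise _row_error(path, i, col, f"non-numeric value {row[col]!r}")
        try:
            out.append(
                CadMark(
                    scan_id=str(row["seriesuid"]),
                    center=(float(row["coordX"]), float(row["coordY"]), float(row["coordZ"])),
                    confidence=float(row["probability"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    logger.info("read %d marks from %s", len(out), path)
    return out


def write_scan_manifest(scans: Iterable[Scan], path: str | Path) -> None:
    pd.DataFrame(
        [{"scan_id": s.scan_id, "label": s.pacs_label} for s in scans]
    ).to_csv(path, index=False)


def write_annotations(annotations: Iterable[ReaderAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "scan_id": a.scan_id,
                "reader_id": a.reader_id,
                "coordX": a.center[0],
                "coordY": a.center[1],
                "coordZ": a.center[2],
                "major_axis_mm": a.major_axis_mm,
                "minor_axis_mm": a.minor_axis_mm,
            }
            for a in annotations
        ],
        columns=_ANNOTATION_COLS,
    ).to_csv(path, index=False)


def write_marks(marks: Iterable[CadMark], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "seriesuid": m.scan_id,
                "coordX": m.center[0],
                "coordY": m.center[1],
                "coordZ": m.center[2],
                "probability": m.confidence,
            }
            for m in marks
        ],
        columns=_MARK_COLS,
    ).to_csv(path, index=False)


def write_consensus(nodules: Iterable[ConsensusNodule], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "nodule_id": n.nodule_id,
                "scan_id": n.scan_id,
                "coordX": n.center[0],
                "coordY": n.center[1],
                "coordZ": n.center[2],
                "diameter_mm": n.diameter_mm,
                "n_readers": n.n_readers,
            }
            for n in nodules
        ],
        columns=["nodule_id", "scan_id", "coordX", "coordY", "coordZ", "diameter_mm", "n_readers"],
    ).to_csv(path, index=False)


def write_match_report(match: MatchResult, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "mark_index": i,
                "seriesuid": a.mark.scan_id,
                "label": a.label,
                "matched_nodule_id": a.nodule_id or "",
                "distance_mm": a.distance_mm if a.distance_mm is not None else "",
            }
            for i, a in enumerate(match.assignments)
        ]
    ).to_csv(path, index=False)


@dataclass(frozen=True)
class AnalysisConfig:
    """All knobs of one evaluation run, gathered in one place."""

    manifest_path: str
    annotations_path: str
    marks_paths: Mapping[str, str]  # condition name -> marks CSV
    nodule_set_label: str = "B"
    hit_multiplier: float = 1.5
    merge_multiplier: float = 1.5
    fp_rates: tuple[float, ...] = DEFAULT_FP_RATES
    fp_denominator: str = "all"
    interpolation: str = "linear"
    irrelevant_as_fp: bool = False
    subgroup_threshold_mm: float = 6.0
    operating_point_mode: str = "target_specificity"
    operating_point_value: float = 0.8
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.hit_multiplier <= 0 or self.merge_multiplier <= 0:
            raise ValidationError("multipliers must be positive")
        rates = tuple(self.fp_rates)
        if any(b <= a for a, b in zip(rates, rates[1:])) or any(r <= 0 for r in rates):
            raise ValidationError("fp_rates must be strictly increasing and positive")


def _roc_report(scores, op_spec) -> dict:
    r = perscan.roc_result(scores, operating_point_spec=op_spec)
    out = {
        "auc": r.auc,
        "auc_variance": r.auc_variance,
        "ci95": list(r.ci95),
        "n_pos": r.n_pos,
        "n_neg": r.n_neg,
    }
    if r.operating_point is not None:
        out["operating_point"] = dataclasses.asdict(r.operating_point)
    return out


def _froc_report(fr) -> dict:
    return {
        "fp_rates": list(fr.fp_rates),
        "sensitivities": list(fr.sensitivities_at_rates),
        "cpm": fr.cpm,
        "n_nodules": fr.n_nodules,
        "n_scans": fr.n_scans,
    }


def run_evaluation(config: AnalysisConfig) -> dict:
    """Run the full two-condition evaluation and return the report dict.

    When ``config.out_dir`` is set, also writes ``report.json``, the
    consensus table, and per-condition ROC/FROC curve CSVs there.
    """
    scans = read_scan_manifest(config.manifest_path)
    annotations = read_annotations(config.annotations_path)
    marks_by_cond = {
        cond: read_marks(path) for cond, path in config.marks_paths.items()
    }

    consensus = consolidate(annotations, merge_multiplier=config.merge_multiplier)
    nodule_set = build_nodule_set(consensus, scans, config.nodule_set_label)
    if not nodule_set.nodules:
        raise UndefinedStatisticError(
            f"nodule set {config.nodule_set_label} is empty: no consensus "
            f"nodule reaches {nodule_set.min_agreement}-reader agreement"
        )
    n_abnormal = sum(1 for s in scans if s.is_abnormal)
    n_normal = len(scans) - n_abnormal
    logger.info(
        "nodule set %s: %d nodules on %d of %d abnormal scans (%d excluded, "
        "%d irrelevant nodules)",
        nodule_set.label, len(nodule_set.nodules), len(nodule_set.abnormal_scans),
        n_abnormal, len(nodule_set.excluded_scans), len(nodule_set.irrelevant_nodules),
    )

    op_spec = (config.operating_point_mode, config.operating_point_value)
    specs = {
        "lt_6mm": SubgroupSpec(config.subgroup_threshold_mm, "lt"),
        "ge_6mm": SubgroupSpec(config.subgroup_threshold_mm, "ge"),
    }

    report: dict = {
        "nodule_set": {
            "label": nodule_set.label,
            "min_agreement": nodule_set.min_agreement,
            "n_nodules": len(nodule_set.nodules),
            "n_abnormal_included": len(nodule_set.abnormal_scans),
            "n_abnormal_excluded": len(nodule_set.excluded_scans),
            "n_irrelevant_nodules": len(nodule_set.irrelevant_nodules),
            "n_abnormal_manifest": n_abnormal,
            "n_normal": n_normal,
        },
        "parameters": {
            "hit_multiplier": config.hit_multiplier,
            "merge_multiplier": config.merge_multiplier,
            "fp_rates": list(config.fp_rates),
            "fp_denominator": config.fp_denominator,
            "interpolation": config.interpolation,
            "irrelevant_as_fp": config.irrelevant_as_fp,
            "subgroup_threshold_mm": config.subgroup_threshold_mm,
            "operating_point": [config.operating_point_mode, config.operating_point_value],
        },
        "conditions": {},
    }

    scores_by_cond: dict[str, list[perscan.ScanScore]] = {}
    froc_by_cond: dict[str, FrocResult] = {}
    curves: dict[str, FrocResult] = {}
    for cond, marks in marks_by_cond.items():
        match = match_marks(
            marks, nodule_set, scans,
            hit_multiplier=config.hit_multiplier,
            irrelevant_as_fp=config.irrelevant_as_fp,
        )
        logger.info(
            "%s: %s marks (%d dropped on excluded scans)",
            cond, match.label_counts(), match.n_dropped,
        )
        scores = perscan.scan_scores(match, nodule_set, scans)
        fr = froc(
            match, nodule_set, scans,
            fp_rates=config.fp_rates,
            fp_denominator=config.fp_denominator,
            interpolation=config.interpolation,
        )
        scores_by_cond[cond] = scores
        froc_by_cond[cond] = fr
        curves[cond] = fr

        cond_report = {
            "match_counts": match.label_counts(),
            "n_marks_dropped": match.n_dropped,
            "per_scan": _roc_report(scores, op_spec),
            "per_nodule": _froc_report(fr),
            "subgroups": {},
        }
        for name, spec in specs.items():
            sub_report: dict = {}
            sub_set = subgroup_nodules(nodule_set, spec)
            sub_report["n_nodules"] = len(sub_set.nodules)
            sub_report["n_abnormal_included"] = len(sub_set.abnormal_scans)
            try:
                sub_scores = perscan_subgroup_scores(
                    marks, nodule_set, scans, spec,
                    hit_multiplier=config.hit_multiplier,
                    irrelevant_as_fp=config.irrelevant_as_fp,
                )
                sub_report["per_scan"] = _roc_report(sub_scores, op_spec)
            except UndefinedStatisticError as exc:
                sub_report["per_scan"] = {"undefined": str(exc)}
            try:
                sub_match = match_marks(
                    marks, sub_set, scans,
                    hit_multiplier=config.hit_multiplier,
                    irrelevant_as_fp=config.irrelevant_as_fp,
                )
                sub_fr = froc(
                    sub_match, sub_set, scans,
                    fp_rates=config.fp_rates,
                    fp_denominator=config.fp_denominator,
                    interpolation=config.interpolation,
                )
                sub_report["per_nodule"] = _froc_report(sub_fr)
            except UndefinedStatisticError as exc:
                sub_report["per_nodule"] = {"undefined": str(exc)}
            cond_report["subgroups"][name] = sub_report
        report["conditions"][cond] = cond_report

    cond_names = list(marks_by_cond)
    if len(cond_names) == 2:
        a, b = cond_names
        cmp = perscan.delong_paired_test(scores_by_cond[a], scores_by_cond[b])
        report["comparison"] = {
            "condition_a": a,
            "condition_b": b,
            "per_scan_delong": dataclasses.asdict(cmp),
            "cpm_a": froc_by_cond[a].cpm,
            "cpm_b": froc_by_cond[b].cpm,
            "cpm_delta": froc_by_cond[b].cpm - froc_by_cond[a].cpm,
        }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        write_consensus(nodule_set.nodules, out / "consensus.csv")
        for cond, fr in curves.items():
            pd.DataFrame(
                {
                    "threshold": fr.thresholds,
                    "fp_per_scan": [p[0] for p in fr.points],
                    "sensitivity": [p[1] for p in fr.points],
                }
            ).to_csv(out / f"froc_{cond}.csv", index=False)
        for cond, scores in scores_by_cond.items():
            pd.DataFrame(
                [
                    {
                        "scan_id": s.scan_id,
                        "truth": int(s.is_positive),
                        "probability": s.probability,
                    }
                    for s in scores
                ]
            ).to_csv(out / f"scan_scores_{cond}.csv", index=False)
    return report
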