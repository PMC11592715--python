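import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import noduleval as nv
from noduleval.cohort import ReaderAnnotation
from noduleval.matching import CadMark
from noduleval.perscan import ScanScore
from noduleval.simulate import SyntheticConfig, generate_cohort

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_ann(scan="s1", reader="r1", center=(0.0, 0.0, 0.0), diameter=6.0, spread=0.0):
    """Annotation with major/minor axes averaging to `diameter`."""
    return ReaderAnnotation(
        scan_id=scan,
        reader_id=reader,
        center=center,
        major_axis_mm=diameter * (1 + spread),
        minor_axis_mm=diameter * (1 - spread),
    )


def make_mark(scan="s1", center=(0.0, 0.0, 0.0), confidence=0.5):
    return CadMark(scan_id=scan, center=center, confidence=confidence)


def make_scores(pos, neg):
    return [ScanScore(f"P{i:03d}", True, float(v)) for i, v in enumerate(pos)] + [
        ScanScore(f"N{i:03d}", False, float(v)) for i, v in enumerate(neg)
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A modest seeded cohort shared by pipeline-level tests."""
    return generate_cohort(SyntheticConfig(seed=11, n_abnormal=80, n_normal=70))


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    """Consensus, nodule set B, and per-condition matches for small_cohort."""
    cohort = small_cohort
    consensus = nv.consolidate(cohort.annotations)
    nodule_set = nv.build_nodule_set(consensus, cohort.scans, "B")
    matches = {
        cond: nv.match_marks(marks, nodule_set, cohort.scans)
        for cond, marks in cohort.marks.items()
    }
    return cohort, consensus, nodule_set, matches


def random_scan_annotations(rng, scan="s1", n_max=12):
    """Random annotations on one scan, sized/placed to make merges common."""
    n = int(rng.integers(1, n_max + 1))
    out = []
    for _ in range(n):
        out.append(
            make_ann(
                scan=scan,
                reader=f"r{int(rng.integers(1, 4))}",
                center=tuple(rng.uniform(0, 25, 3)),
                diameter=float(rng.uniform(3, 12)),
            )
        )
    return out
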