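"""FROC construction, CPM, and diameter subgroup analyses."""

import numpy as np
import pytest

import noduleval as nv
from noduleval.cohort import Scan
from noduleval.errors import UndefinedStatisticError
from noduleval.froc import SubgroupSpec, _interpolate
from noduleval.matching import NON_LESION

from conftest import make_ann, make_mark


def _one_scan_world(nodule_centers, diameters, marks, extra_scans=1):
    """One abnormal scan with 3-reader nodules plus `extra_scans` normals."""
    scans = [Scan("s1", "abnormal")] + [
        Scan(f"n{i}", "normal") for i in range(extra_scans)
    ]
    anns = [
        make_ann(scan="s1", reader=f"r{r}", center=c, diameter=d)
        for c, d in zip(nodule_centers, diameters)
        for r in (1, 2, 3)
    ]
    ns = nv.build_nodule_set(nv.consolidate(anns), scans, "B")
    match = nv.match_marks(marks, ns, scans)
    return scans, ns, match


class TestCpm:
    def test_mean_and_bounds(self):
        vals = [0.2, 0.4, 0.9]
        assert nv.cpm(vals) == pytest.approx(np.mean(vals))
        assert min(vals) <= nv.cpm(vals) <= max(vals)

    def test_constant_list(self):
        assert nv.cpm([0.7] * 6) == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            nv.cpm([])


class TestFrocCurve:
    def test_perfect_detector(self):
        scans, ns, match = _one_scan_world(
            [(0, 0, 0), (60, 0, 0)], [8.0, 8.0],
            [make_mark(scan="s1", center=(0, 0, 0), confidence=1.0),
             make_mark(scan="s1", center=(60, 0, 0), confidence=1.0)],
        )
        fr = nv.froc(match, ns, scans)
        assert fr.sensitivities_at_rates == (1.0,) * 6
        assert fr.cpm == 1.0

    def test_no_marks_at_all(self):
        scans, ns, match = _one_scan_world([(0, 0, 0)], [8.0], [])
        fr = nv.froc(match, ns, scans)
        assert fr.sensitivities_at_rates == (0.0,) * 6
        assert fr.cpm == 0.0

    def test_three_mark_worked_example(self):
        # 2 scans total; nodule1 hit at 0.9, one FP at 0.8, nodule2 hit at 0.6
        scans, ns, match = _one_scan_world(
            [(0, 0, 0), (60, 0, 0)], [8.0, 8.0],
            [make_mark(scan="s1", center=(0, 0, 0), confidence=0.9),
             make_mark(scan="n0", center=(0, 0, 0), confidence=0.8),
             make_mark(scan="s1", center=(60, 0, 0), confidence=0.6)],
        )
        fr = nv.froc(match, ns, scans)
        assert fr.n_scans == 2
        assert fr.points == ((0.0, 0.0), (0.0, 0.5), (0.5, 0.5), (0.5, 1.0))
        # rates within (0, 0.5) ride the horizontal segment at 0.5
        assert fr.sensitivities_at_rates == (0.5, 0.5, 1.0, 1.0, 1.0, 1.0)
        assert fr.cpm == pytest.approx(5 / 6)

    def test_step_interpolation_mode(self):
        points = [(0.0, 0.0), (0.0, 0.5), (0.5, 0.5), (0.5, 1.0)]
        assert _interpolate(points, 0.25, step=True) == 0.5
        assert _interpolate(points, 0.5, step=True) == 1.0

    def test_empty_nodule_set_rejected(self, small_analysis):
        cohort, _, nodule_set, matches = small_analysis
        empty = nv.NoduleSet("B", 3, (), frozenset(), frozenset())
        with pytest.raises(UndefinedStatisticError):
            nv.froc(matches["original_5mm"], empty, cohort.scans)

    def test_sweep_matches_bruteforce(self, small_analysis):
        """Every sweep point equals direct counting at that threshold."""
        cohort, _, nodule_set, matches = small_analysis
        match = matches["refined_1mm"]
        fr = nv.froc(match, nodule_set, cohort.scans)
        counted = set(nodule_set.abnormal_scans) | {
            s.scan_id for s in cohort.scans if not s.is_abnormal
        }
        fp_confs = [
            a.mark.confidence
            for a in match.assignments
            if a.label == NON_LESION and a.mark.scan_id in counted
        ]
        for t, (fp, sens) in zip(fr.thresholds[1:], fr.points[1:]):
            n_det = sum(
                1
                for nod in nodule_set.nodules
                if any(c >= t for c in match.nodule_hits.get(nod.nodule_id, ()))
            )
            assert sens == pytest.approx(n_det / fr.n_nodules)
            assert fp == pytest.approx(
                sum(1 for c in fp_confs if c >= t) / fr.n_scans
            )

    def test_monotone_in_fp_rate(self, small_analysis):
        cohort, _, nodule_set, matches = small_analysis
        for match in matches.values():
            fr = nv.froc(match, nodule_set, cohort.scans)
            fps = [p[0] for p in fr.points]
            sens = [p[1] for p in fr.points]
            assert fps == sorted(fps)
            assert sens == sorted(sens)
            assert min(fr.sensitivities_at_rates) <= fr.cpm <= max(
                fr.sensitivities_at_rates
            )

    def test_added_fp_never_raises_added_tp_never_lowers_sensitivity(self):
        base_marks = [
            make_mark(scan="s1", center=(0, 0, 0), confidence=0.9),
            make_mark(scan="n0", center=(0, 0, 0), confidence=0.7),
        ]
        world = lambda marks: _one_scan_world(
            [(0, 0, 0), (60, 0, 0)], [8.0, 8.0], marks
        )
        scans, ns, match = world(base_marks)
        base = nv.froc(match, ns, scans).sensitivities_at_rates
        scans, ns, match = world(
            base_marks + [make_mark(scan="n0", center=(50, 0, 0), confidence=0.95)]
        )
        more_fp = nv.froc(match, ns, scans).sensitivities_at_rates
        assert all(a <= b for a, b in zip(more_fp, base))
        scans, ns, match = world(
            base_marks + [make_mark(scan="s1", center=(60, 0, 0), confidence=0.5)]
        )
        more_tp = nv.froc(match, ns, scans).sensitivities_at_rates
        assert all(a >= b for a, b in zip(more_tp, base))

    def test_abnormal_only_denominator(self):
        scans, ns, match = _one_scan_world(
            [(0, 0, 0)], [8.0],
            [make_mark(scan="n0", center=(0, 0, 0), confidence=0.8),
             make_mark(scan="s1", center=(0, 0, 0), confidence=0.9)],
            extra_scans=3,
        )
        fr_all = nv.froc(match, ns, scans, fp_denominator="all")
        fr_abn = nv.froc(match, ns, scans, fp_denominator="abnormal")
        assert fr_all.n_scans == 4
        assert fr_abn.n_scans == 1
        # the normal-scan FP is not counted in abnormal-only mode
        assert max(p[0] for p in fr_abn.points) == 0.0


class TestSubgroups:
    def test_six_mm_boundary_goes_to_ge(self):
        nod = nv.consolidate(
            [make_ann(reader=f"r{i}", diameter=6.0) for i in (1, 2, 3)]
        )[0]
        assert SubgroupSpec(6.0, "ge").contains(nod.diameter_mm)
        assert not SubgroupSpec(6.0, "lt").contains(nod.diameter_mm)

    def test_scan_with_both_sizes_in_both_subgroups(self):
        scans, ns, _ = _one_scan_world([(0, 0, 0), (60, 0, 0)], [4.0, 8.0], [])
        lt = nv.subgroup_nodules(ns, SubgroupSpec(6.0, "lt"))
        ge = nv.subgroup_nodules(ns, SubgroupSpec(6.0, "ge"))
        assert lt.abnormal_scans == ge.abnormal_scans == {"s1"}
        assert len(lt.nodules) == len(ge.nodules) == 1
        # demoted nodules become irrelevant, not false-positive targets
        assert {n.nodule_id for n in lt.irrelevant_nodules} >= {
            n.nodule_id for n in ge.nodules
        }

    def test_trivial_threshold_keeps_everything(self, small_analysis):
        _, _, nodule_set, _ = small_analysis
        sub = nv.subgroup_nodules(nodule_set, SubgroupSpec(1e-9, "ge"))
        assert sub.nodules == nodule_set.nodules
        assert sub.abnormal_scans == nodule_set.abnormal_scans

    def test_whole_is_blend_of_parts(self, small_analysis):
        """Overall sensitivity = nodule-count-weighted mean of subgroup ones."""
        cohort, _, nodule_set, matches = small_analysis
        match = matches["refined_1mm"]
        fr_all = nv.froc(match, nodule_set, cohort.scans)
        parts = []
        for side in ("lt", "ge"):
            sub = nv.subgroup_nodules(nodule_set, SubgroupSpec(6.0, side))
            sub_match = nv.match_marks(
                cohort.marks["refined_1mm"], sub, cohort.scans
            )
            parts.append((len(sub.nodules), sub, sub_match))
        assert sum(n for n, _, _ in parts) == fr_all.n_nodules
        for t in fr_all.thresholds[1:]:
            blended = 0.0
            for n_sub, sub, sub_match in parts:
                det = sum(
                    1
                    for nod in sub.nodules
                    if any(c >= t for c in sub_match.nodule_hits.get(nod.nodule_id, ()))
                )
                blended += det
            det_all = sum(
                1
                for nod in nodule_set.nodules
                if any(c >= t for c in match.nodule_hits.get(nod.nodule_id, ()))
            )
            assert blended == det_all

    def test_perscan_subgroup_scores_positive_classes(self):
        scans = [Scan("s1", "abnormal"), Scan("s2", "abnormal"), Scan("n1", "normal")]
        anns = [
            make_ann(scan="s1", reader=f"r{i}", diameter=4.0) for i in (1, 2, 3)
        ] + [make_ann(scan="s2", reader=f"r{i}", diameter=9.0) for i in (1, 2, 3)]
        ns = nv.build_nodule_set(nv.consolidate(anns), scans, "B")
        for side, positive in (("lt", "s1"), ("ge", "s2")):
            scores = nv.perscan_subgroup_scores(
                [], ns, scans, SubgroupSpec(6.0, side)
            )
            assert [s.scan_id for s in scores if s.is_positive] == [positive]
            assert [s.scan_id for s in scores if not s.is_positive] == ["n1"]

    def test_empty_subgroup_rejected(self):
        scans = [Scan("s1", "abnormal"), Scan("n1", "normal")]
        anns = [make_ann(scan="s1", reader=f"r{i}", diameter=4.0) for i in (1, 2, 3)]
        ns = nv.build_nodule_set(nv.consolidate(anns), scans, "B")
        with pytest.raises(UndefinedStatisticError):
            nv.perscan_subgroup_scores([], ns, scans, SubgroupSpec(6.0, "ge"))
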