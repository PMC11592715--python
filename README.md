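# noduleval

Evaluation toolkit for lung-nodule computer-aided detection (CAD). It turns
multi-reader radiologist annotations into agreement-graded ground truth,
matches detector marks to nodules in 3D, and scores detectors at two levels:

* **per scan** — each scan's probability is the highest mark confidence on
  it; included abnormal scans vs normal scans give an ROC curve, its AUC
  (Mann–Whitney estimator, ties scored ½), DeLong confidence intervals, and
  a paired DeLong z-test between two imaging conditions evaluated on the
  same scans;
* **per nodule** — FROC analysis: sensitivity against mean false positives
  per scan over all confidence thresholds, sensitivities at the fixed rates
  ⅛, ¼, ½, 1, 2, 4 FP/scan, and their mean, the competition performance
  metric (CPM), with subgroup analyses at the 6 mm Lung-RADS size threshold.

It is written for detector comparisons of the paired kind — e.g. the same
CAD run on thick-slice chest CT and on thin-slice volumes synthesized from
them — where every scan is scored under both conditions.

## Ground truth and matching rules

Each radiologist marks a nodule by its axial major/minor axes; the diameter
is their mean and the radius half of that. Two annotations on one scan
describe the same nodule when their centers are closer than 1.5× the mean
of their radii (strict inequality); clusters are the connected components of
that relation, and each becomes a consensus nodule with reader-averaged
center and diameter. Nodule **set A** keeps nodules at least 2 of 3 readers
agreed on, **set B** those all 3 agreed on; abnormal scans with no
qualifying nodule are excluded from the corresponding analysis. A CAD mark
*hits* a nodule when its center lies within 1.5× the consensus radius
(3D Euclidean, world mm). Marks hitting only below-threshold nodules are
*irrelevant* — counted neither as true nor as false positives, the same
convention the LUNA16 evaluation applies to sub-threshold annotations.

Because clinical scans and commercial detector outputs cannot be shipped,
the package includes a seeded generator (`noduleval.simulate`) producing
cohorts with the same statistical structure: log-normal nodule sizes (~85%
below 6 mm), three imperfect readers, and two detector condition profiles —
a weaker "original 5 mm" and a stronger "refined 1 mm" — coupled through
common random numbers so the paired comparison behaves like a real
same-scan study.

## Worked example

```python
import noduleval as nv
from noduleval.simulate import SyntheticConfig, generate_cohort

cohort = generate_cohort(SyntheticConfig(seed=1, n_abnormal=120, n_normal=100))
consensus = nv.consolidate(cohort.annotations)
nodule_set = nv.build_nodule_set(consensus, cohort.scans, "B")
print(f"{len(nodule_set.nodules)} consensus nodules on "
      f"{len(nodule_set.abnormal_scans)} of 120 abnormal scans")

scores = {}
for cond in sorted(cohort.marks):
    match = nv.match_marks(cohort.marks[cond], nodule_set, cohort.scans)
    scores[cond] = nv.scan_scores(match, nodule_set, cohort.scans)
    roc = nv.roc_result(scores[cond])
    fr = nv.froc(match, nodule_set, cohort.scans)
    print(f"{cond}: AUC {roc.auc:.3f} (95% CI {roc.ci95[0]:.3f}-{roc.ci95[1]:.3f}), "
          f"CPM {fr.cpm:.3f}")

test = nv.delong_paired_test(scores["original_5mm"], scores["refined_1mm"])
print(f"paired DeLong: delta AUC {test.delta:+.3f}, z {test.z:.2f}, p {test.p_value:.4f}")
```

prints

```
118 consensus nodules on 84 of 120 abnormal scans
original_5mm: AUC 0.896 (95% CI 0.849-0.942), CPM 0.703
refined_1mm: AUC 0.902 (95% CI 0.857-0.948), CPM 0.757
paired DeLong: delta AUC +0.006, z 0.63, p 0.5271
```

At this cohort size the stronger condition's CPM advantage is clear while
the scan-level AUC difference is not yet significant — the paired test needs
the full-size cohort (about 500 abnormal + 332 normal scans) for that.

The same pipeline is available from the shell:

```sh
noduleval simulate --seed 1 --out-dir cohort/
noduleval evaluate --manifest cohort/manifest.csv \
    --annotations cohort/annotations.csv \
    --marks original_5mm cohort/marks_original_5mm.csv \
    --marks refined_1mm cohort/marks_refined_1mm.csv \
    --nodule-set B --out-dir results/
```

`evaluate` writes `report.json` (AUCs, CIs, the paired test, FROC
sensitivities, CPMs, 6 mm subgroups, and the scan-exclusion accounting) plus
curve CSVs. Exit codes: 0 success, 2 invalid input, 3 statistically
undefined request. Input formats are plain CSV: a scan manifest
(`scan_id,label`), reader annotations
(`scan_id,reader_id,coordX,coordY,coordZ,major_axis_mm,minor_axis_mm`, world
mm), and LUNA16-style mark tables
(`seriesuid,coordX,coordY,coordZ,probability`).

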