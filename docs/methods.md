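# Methods

This note records the statistical procedures the package implements, the
conventions chosen where the field leaves room, and what the synthetic
cohort generator does and does not emulate.

## Consensus ground truth

Readers annotate independently; an annotation's diameter is the mean of the
axial major and minor axis lengths, its radius half of that. Two
annotations on the same scan are merged when the 3D Euclidean distance
between their centers (world mm) is strictly less than
`merge_multiplier × (r₁ + r₂)/2`, default multiplier 1.5. The pairwise rule
is not transitive, so clusters are taken as connected components
(union-find) — the standard, order-independent resolution. A cluster
becomes one consensus nodule with the unweighted component-wise mean center
and mean diameter over all member annotations; its agreement count is the
number of *distinct* readers (one reader contributing two nearby marks to a
cluster is allowed and counts once toward agreement, though both marks enter
the averages).

Nodule set A requires agreement ≥ 2 of 3, set B all 3; because the
thresholds are nested, set B's nodules are always a subset of set A's.
Abnormal scans with no qualifying nodule are excluded from that set's
analysis entirely (their marks are dropped with a logged count). Qualifying
thresholds are applied per set; nodules that fail them on included scans
are kept as *irrelevant*: detector marks hitting them count neither as true
nor as false positives. A strict mode (`irrelevant_as_fp=True`) instead
treats such marks as false positives, since published evaluations are not
always explicit on this point.

Determinism: annotations are put in a canonical order per scan
(reader id, center, axes) before clustering, so the output — including
nodule ids, formed as `scan_id:index` — is invariant to input permutation.

## Matching

A mark hits a nodule when its center lies strictly within
`hit_multiplier × radius` of the consensus center (default 1.5, 3D
Euclidean, consensus diameter only — the mark's own size estimate is
ignored). A mark hitting several qualifying nodules is assigned to the
nearest, ties broken by smaller nodule id. All marks assigned to a nodule
are lesion-labelled and never count as false positives; the nodule still
counts once toward sensitivity, as "detected at threshold t" iff any of its
marks has confidence ≥ t. Duplicate identical marks are retained — they
inflate false-positive counts but not sensitivity.

## Per-scan analysis

A scan's probability is the maximum confidence over its retained marks
(lesion, irrelevant, and non-lesion alike), exactly 0.0 for scans without
marks — required so normal scans with no detections count as correctly low.
Positives are the included abnormal scans for the active nodule set,
negatives all normal scans.

AUC is the Mann–Whitney estimator with ties scored ½ (file rounding creates
ties even for continuous scores). Variance and the paired comparison follow
DeLong's structural components: with ψ(x, y) = 1, ½, 0 for x > y, x = y,
x < y,

    V10(xᵢ) = meanⱼ ψ(xᵢ, yⱼ),  V01(yⱼ) = meanᵢ ψ(xᵢ, yⱼ),
    var(AUC) = S10/m + S01/n,

S10, S01 being sample variances (ddof = 1) over the m positives and n
negatives, and the covariance between two conditions on the same scans the
analogous cross term. The paired z statistic is
(AUC_b − AUC_a)/√(var_a + var_b − 2 cov) with a two-sided normal p-value;
when the variance of the difference is numerically zero the convention is
p = 1 for a zero difference and p = 0 otherwise. Confidence intervals are
the normal approximation AUC ± 1.96 SE clipped to [0, 1] (no logit
transform). The implementation was checked against R's pROC
(`roc.test`/`ci.auc`, method "delong") on a frozen fixture, agreeing to
10⁻⁹ in AUC, variance, and p-value.

Operating points use the closed-on-the-positive-side rule
"predicted positive iff probability ≥ threshold". In target-specificity
mode the threshold is the smallest candidate score achieving at least the
requested specificity — which also maximizes sensitivity subject to that
constraint. Vendor decision thresholds behind published
accuracy/sensitivity/specificity tables are generally unstated, so
operating points here are always computed under this explicit user-chosen
rule and make no claim to reproduce any vendor's.

## Per-nodule analysis (FROC/CPM)

The FROC sweep evaluates every distinct confidence value (plus +∞):
sensitivity = detected qualifying nodules / all qualifying nodules,
FP rate = non-lesion marks ≥ t / number of scans. The FP denominator
defaults to included abnormal plus normal scans; an abnormal-only mode
(restricting both numerator and denominator) is provided because published
descriptions of "false positives per scan" do not always say which scans
they divide by.

Sensitivities at the target rates (default ⅛, ¼, ½, 1, 2, 4 per scan — six
rates, so their mean matches CPM values printed alongside six-column
sensitivity tables) are read from the sweep polyline by linear
interpolation between consecutive sweep points. A query rate that
coincides with achieved FP rates takes the maximum sensitivity there
(vertical segments collapse upward); rates beyond the largest achieved rate
take the final plateau, rates below the smallest score zero. A pure step
mode (max sensitivity at FP ≤ rate) is available. CPM is the arithmetic
mean of the six sensitivities; reports carry full precision and table
renderings round to 3 decimals.

Size subgroups split at 6 mm with "< 6 mm" strict, so a nodule of exactly
6 mm is in the "≥ 6 mm" group. Subgrouping demotes out-of-group qualifying
nodules to irrelevant and re-matches marks, positives for the subgroup ROC
being abnormal scans with at least one in-group nodule (a scan with both a
4 mm and an 8 mm nodule belongs to both subgroups). The
nodule-count-weighted blend of the two subgroups' detected counts equals
the overall count at every threshold whenever no mark hits nodules in both
groups; nearest-nodule reassignment can break this in the rare overlapping
case.

## Synthetic cohort generator

The generator emulates the structure of a paired thick-vs-thin-slice CAD
study; defaults are one fixed choice of "study conditions", not fitted
claims about any particular dataset.

* **Cohort**: 500 abnormal and 332 normal scans. Abnormal scans carry a
  zero-truncated Poisson(2.0) number of lesions placed uniformly in a
  300 × 300 × 250 mm box (no lung geometry — irrelevant to the evaluation
  math), diameters log-normal with median 4.0 mm and σ_log 0.40, putting
  84.5% of lesions below 6 mm.
* **Readers**: three, independent given diameter, detection probability
  logistic(0.6 + 0.12 d) — nearly size-neutral (≈0.75 at 4 mm) so the
  consensus sets keep the underlying size mix; annotated centers get
  per-axis Gaussian jitter with sd 0.15 r, diameters a multiplicative
  log-normal jitter (sd 0.10) split into major/minor axes. Under these
  defaults roughly 470/500 scans reach 2-of-3 agreement and 330/500 reach
  3-of-3, with ~2 consensus nodules per included scan — the same shape of
  exclusion accounting a three-reader study produces. Published per-reader
  sensitivities or jitters are not available, so these are configuration,
  not claims.
* **Detector conditions**: per-lesion sensitivity logistic(α_c + β_c d),
  true-positive confidences Beta(a, b) skewed high, center jitter sd r/3
  per axis (so essentially every emitted lesion mark satisfies the 1.5 r
  hit rule; a guaranteed-hit mode truncates the offset inside 1.4 r for
  exactness tests), plus Poisson false marks uniform in the box with
  low-skewed Beta confidences. Defaults: original 5 mm profile
  α = 0.6, β = 0.32, TP Beta(4.2, 2), 6.0 FP/scan; refined 1 mm profile
  α = 0.75, β = 0.40, TP Beta(4.7, 2), 5.5 FP/scan; both FP Beta(2, 4.5).
  These were chosen once so the default study lands near the operating
  characteristics a thick-vs-thin comparison reports (scan AUC ≈
  0.87–0.91, CPM ≈ 0.67–0.75, still-rising FROC at 4 FP/scan), with the
  refined profile uniformly stronger in sensitivity and confidence.
* **Pairing**: both conditions are readings of the same scan, so they share
  latents — one detection uniform per lesion (a uniformly higher
  sensitivity curve therefore detects a superset), one confidence uniform
  mapped through each condition's Beta quantile function, and one Poisson
  false-mark process at the larger rate thinned per condition with shared
  locations and confidence latents. Marginals are exactly as parameterized;
  the coupling only raises the cross-condition correlation to the level a
  same-scan design shows, which is what gives the paired DeLong test its
  power at realistic effect sizes.
* **Determinism**: each scan owns an RNG stream seeded by (seed, scan
  index); regeneration is byte-identical and dropping scans does not
  perturb others.

What the generator does **not** model: image content (no pixels, HU values,
or nodule texture), lung anatomy, reader correlation beyond independence
given size, and any intrinsic "conspicuity" shared between readers and
detector. The last omission is visible: in real studies the 3-of-3
agreement set tends to be easier for the detector than the 2-of-3 set,
whereas here both sets score alike. Passing tests therefore demonstrate the
correctness of the evaluation machinery and the qualitative behaviour of a
paired comparison, not detector performance on clinical data.

## Test oracles and problem sizes

Analytic expectations used by the tests: the FP rate per scan is the
Poisson rate; the asymptotic FROC plateau is E[sens(d)] under the
*agreement-weighted* diameter law — consensus nodules are a size-biased
sample, so the law's density is reweighted by w(d) = P(≥ k of 3 readers
detect), k = 2 or 3 per set — computed by numerical quadrature; the
simplified binormal score variant has AUC Φ((μ₊ − μ₋)/√(σ₊² + σ₋²)).

Stochastic checks run at sizes chosen for tight Monte-Carlo error at
desk-scale runtimes: the paired DeLong type-I error uses 5000 simulated
75 + 75 cohorts (binomial SE ≈ 0.003 at the nominal 0.05); the DeLong
variance is compared to a 10,000-replicate bootstrap at 100 + 100; the
stronger-beats-weaker directional check uses 100 seeds of 150 + 100-scan
cohorts. Brute-force oracles (pair-counting AUC, exhaustive FROC
thresholds, transitive-closure clustering) run at sizes where exhaustive
evaluation is exact and fast.

## Known limitations

* DeLong's test is mildly anticonservative at small n (empirical type-I
  ≈ 0.054 at 75 + 75); this is a property of the method, not the
  implementation.
* FROC sensitivities at rates beyond the detector's maximum achieved FP
  rate silently take the plateau value; compare detectors only over rate
  ranges both can reach.
* The irrelevant-mark convention, the FP denominator, and the
  interpolation mode are all explicit switches; published numbers can
  depend on any of them, so comparisons across toolkits should state all
  three.
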