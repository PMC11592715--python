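"""Seeded synthetic cohort generator for the evaluation pipeline.

Real inputs to this kind of study — several hundred thick-slice chest CT
scans read by three radiologists and processed by a detector under two
imaging conditions — cannot be redistributed, so this module generates a
cohort with the same statistical structure: a manifest of abnormal and
normal scans, per-reader nodule annotations with imperfect detection and
jittered geometry (so that both 2-of-3 and 3-of-3 agreement sets arise), and
per-condition CAD mark tables that share the same underlying lesions (the
paired design the scan-level comparison requires).

The generative model, per abnormal scan:

* a zero-truncated Poisson number of true lesions, centers uniform in a box,
  diameters log-normal (defaults give ~84.5% of lesions below 6 mm, matching
  the published cohorts' size mix of roughly 85-88% sub-6 mm nodules);
* each of 3 readers independently sees each lesion with probability
  ``logistic(alpha + beta * d)`` and, when they do, reports a center with
  per-axis Gaussian jitter proportional to the lesion radius and a diameter
  with multiplicative log-normal jitter split into consistent major/minor
  axes;
* each detector condition emits one mark per lesion with probability
  ``logistic(alpha_c + beta_c * d)``, center jitter proportional to the
  radius (optionally truncated inside the 1.5 r hit sphere), and a Beta
  confidence skewed high; plus a Poisson number of false marks uniform in
  the box with Beta confidences skewed low. The "refined" profile dominates
  the "original" profile in both per-lesion sensitivity and confidence
  separation, mirroring the direction of the thick-slice vs thin-slice
  comparison.

Because both conditions are two readings of the *same* scan, they are
coupled through common random numbers: each lesion carries one detection
latent (so a uniformly stronger sensitivity curve detects a superset of the
weaker condition's lesions) and one confidence latent mapped through each
condition's Beta quantile function; false marks come from one shared Poisson
process at the larger rate, thinned per condition, again with shared
location and confidence latents. This reproduces the strong cross-condition
correlation a paired clinical comparison shows, while leaving every
marginal distribution exactly as parameterized.

Determinism: every scan has its own RNG stream derived from
``(seed, scan index)``, so generation is reproducible and removing scans
does not shift the draws of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import integrate
from scipy import stats
from scipy.special import betaincinv

from .cohort import ReaderAnnotation, Scan
from .errors import ValidationError
from .matching import CadMark
from .perscan import ScanScore


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class DiameterLaw:
    """Log-normal nodule-diameter distribution, parameterized by median."""

    median_mm: float = 4.0
    sigma_log: float = 0.40

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.median_mm * np.exp(self.sigma_log * rng.standard_normal(n))

    def pdf(self, d: float) -> float:
        return stats.lognorm.pdf(d, s=self.sigma_log, scale=self.median_mm)

    def cdf(self, d: float) -> float:
        """Fraction of lesions below d mm."""
        return float(stats.lognorm.cdf(d, s=self.sigma_log, scale=self.median_mm))


@dataclass(frozen=True)
class ReaderModel:
    """Per-reader detection curve and annotation noise.

    Detection probability is logistic(alpha + beta * diameter); the defaults
    are nearly size-neutral (~75% at 4 mm, ~83% at 8 mm), so the consensus
    nodules keep the underlying ~85% sub-6 mm size mix while full 3-reader
    agreement stays roughly half as common as 2-of-3 agreement, as in the
    published nodule sets.
    """

    alpha: float = 0.6
    beta: float = 0.12
    center_jitter_frac: float = 0.15  # sd per axis, as a fraction of the radius
    diameter_jitter_sd: float = 0.10  # sd of log diameter multiplier
    axis_spread_max: float = 0.15  # major/minor asymmetry, uniform in [0, max]

    def p_detect(self, diameter_mm: float) -> float:
        return _logistic(self.alpha + self.beta * diameter_mm)


@dataclass(frozen=True)
class DetectorProfile:
    """One detector condition: sensitivity curve, confidence laws, FP process."""

    sens_alpha: float
    sens_beta: float
    tp_conf_a: float = 5.0
    tp_conf_b: float = 2.0
    loc_jitter_frac: float = 1.0 / 3.0  # sd per axis, fraction of lesion radius
    fp_rate_per_scan: float = 1.0
    fp_conf_a: float = 2.0
    fp_conf_b: float = 5.0
    guaranteed_hit: bool = False  # truncate jitter inside 1.4 r

    def __post_init__(self) -> None:
        if min(self.tp_conf_a, self.tp_conf_b, self.fp_conf_a, self.fp_conf_b) <= 0:
            raise ValidationError("Beta confidence parameters must be positive")
        if self.fp_rate_per_scan < 0:
            raise ValidationError("fp_rate_per_scan must be >= 0")

    def sensitivity(self, diameter_mm: float) -> float:
        return _logistic(self.sens_alpha + self.sens_beta * diameter_mm)


def default_profiles() -> dict[str, DetectorProfile]:
    """The two study conditions: a weaker 'original 5 mm' and a stronger
    'refined 1 mm' profile, the latter uniformly higher in per-lesion
    sensitivity and true-positive confidence."""
    return {
        "original_5mm": DetectorProfile(
            sens_alpha=0.6, sens_beta=0.32, tp_conf_a=4.2, tp_conf_b=2.0,
            fp_rate_per_scan=6.0, fp_conf_a=2.0, fp_conf_b=4.5,
        ),
        "refined_1mm": DetectorProfile(
            sens_alpha=0.75, sens_beta=0.40, tp_conf_a=4.7, tp_conf_b=2.0,
            fp_rate_per_scan=5.5, fp_conf_a=2.0, fp_conf_b=4.5,
        ),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything the generator needs; defaults are the study conditions."""

    seed: int = 0
    n_abnormal: int = 500
    n_normal: int = 332
    nodules_per_abnormal: float = 2.0  # Poisson rate, zero-truncated
    diameter_law: DiameterLaw = field(default_factory=DiameterLaw)
    volume_box_mm: tuple[float, float, float] = (300.0, 300.0, 250.0)
    n_readers: int = 3
    reader_model: ReaderModel = field(default_factory=ReaderModel)
    detector_profiles: Mapping[str, DetectorProfile] = field(
        default_factory=default_profiles
    )

    def __post_init__(self) -> None:
        if self.n_abnormal < 1 or self.n_normal < 0:
            raise ValidationError("need n_abnormal >= 1 and n_normal >= 0")
        if self.nodules_per_abnormal <= 0:
            raise ValidationError("nodules_per_abnormal must be positive")
        if not self.detector_profiles:
            raise ValidationError("need at least one detector profile")


@dataclass(frozen=True)
class Lesion:
    scan_id: str
    center: tuple[float, float, float]
    diameter_mm: float


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth kept for parameter-recovery tests only.

    ``mark_sources`` aligns with the per-condition mark lists: the index of
    the source lesion in ``lesions``, or None for a false mark.
    """

    lesions: tuple[Lesion, ...]
    mark_sources: Mapping[str, tuple[int | None, ...]]


@dataclass(frozen=True)
class SyntheticCohort:
    scans: tuple[Scan, ...]
    annotations: tuple[ReaderAnnotation, ...]
    marks: Mapping[str, tuple[CadMark, ...]]
    truth: SyntheticTruth


def _zero_truncated_poisson(rng: np.random.Generator, rate: float) -> int:
    for _ in range(10_000):
        k = int(rng.poisson(rate))
        if k >= 1:
            return k
    raise ValidationError(
        f"could not draw a positive lesion count at rate {rate} "
        f"(bounded retries exhausted)"
    )


def _jittered_center(
    rng: np.random.Generator,
    center: np.ndarray,
    radius: float,
    jitter_frac: float,
    truncate_at: float | None = None,
) -> np.ndarray:
    offset = rng.standard_normal(3) * (jitter_frac * radius)
    if truncate_at is not None:
        limit = truncate_at * radius
        for _ in range(100):
            if float(np.linalg.norm(offset)) < limit:
                break
            offset = rng.standard_normal(3) * (jitter_frac * radius)
        else:
            offset *= (0.99 * limit) / float(np.linalg.norm(offset))
    return center + offset


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate manifest, reader annotations, and per-condition CAD marks.

    Fully deterministic given ``config.seed``. Raises when the realized
    cohort contains no reader annotation at all (a configuration whose
    reader model effectively never fires).
    """
    box = np.asarray(config.volume_box_mm, dtype=float)
    conditions = sorted(config.detector_profiles)
    reader_ids = [f"R{i + 1}" for i in range(config.n_readers)]

    scans: list[Scan] = []
    annotations: list[ReaderAnnotation] = []
    lesions: list[Lesion] = []
    marks: dict[str, list[CadMark]] = {c: [] for c in conditions}
    sources: dict[str, list[int | None]] = {c: [] for c in conditions}

    n_total = config.n_abnormal + config.n_normal
    for idx in range(n_total):
        abnormal = idx < config.n_abnormal
        scan_id = f"S{idx:04d}"
        scans.append(Scan(scan_id, "abnormal" if abnormal else "normal"))
        rng = np.random.default_rng([config.seed, idx])

        scan_lesions: list[int] = []
        if abnormal:
            k = _zero_truncated_poisson(rng, config.nodules_per_abnormal)
            centers = rng.uniform(0.0, box, size=(k, 3))
            diams = config.diameter_law.sample(rng, k)
            for c, d in zip(centers, diams):
                scan_lesions.append(len(lesions))
                lesions.append(Lesion(scan_id, tuple(map(float, c)), float(d)))

            rm = config.reader_model
            for reader in reader_ids:
                for li in scan_lesions:
                    les = lesions[li]
                    if rng.random() >= rm.p_detect(les.diameter_mm):
                        continue
                    radius = 0.5 * les.diameter_mm
                    center = _jittered_center(
                        rng, np.asarray(les.center), radius, rm.center_jitter_frac
                    )
                    diam = les.diameter_mm * math.exp(
                        rm.diameter_jitter_sd * rng.standard_normal()
                    )
                    spread = rng.uniform(0.0, rm.axis_spread_max)
                    annotations.append(
                        ReaderAnnotation(
                            scan_id=scan_id,
                            reader_id=reader,
                            center=tuple(map(float, center)),
                            major_axis_mm=diam * (1.0 + spread),
                            minor_axis_mm=diam * (1.0 - spread),
                        )
                    )

        lam_max = max(
            config.detector_profiles[c].fp_rate_per_scan for c in conditions
        )
        for li in scan_lesions:
            les = lesions[li]
            radius = 0.5 * les.diameter_mm
            u_det = rng.random()
            v_conf = rng.random()
            offset_dir = rng.standard_normal(3)
            for cond in conditions:
                prof = config.detector_profiles[cond]
                if u_det >= prof.sensitivity(les.diameter_mm):
                    continue
                offset = offset_dir * (prof.loc_jitter_frac * radius)
                if prof.guaranteed_hit:
                    norm = float(np.linalg.norm(offset))
                    limit = 1.4 * radius
                    if norm >= limit:  # radial clip keeps the latent shared
                        offset = offset * (0.99 * limit / norm)
                center = np.asarray(les.center) + offset
                conf = float(betaincinv(prof.tp_conf_a, prof.tp_conf_b, v_conf))
                marks[cond].append(CadMark(scan_id, tuple(map(float, center)), conf))
                sources[cond].append(li)
        n_base = int(rng.poisson(lam_max)) if lam_max > 0 else 0
        for _ in range(n_base):
            u_keep = rng.random()
            fp_center = rng.uniform(0.0, box)
            v_conf = rng.random()
            for cond in conditions:
                prof = config.detector_profiles[cond]
                if u_keep * lam_max >= prof.fp_rate_per_scan:
                    continue
                conf = float(betaincinv(prof.fp_conf_a, prof.fp_conf_b, v_conf))
                marks[cond].append(
                    CadMark(scan_id, tuple(map(float, fp_center)), conf)
                )
                sources[cond].append(None)

    if not annotations:
        raise ValidationError(
            "generated cohort has no reader annotation; the reader model "
            "never fired — check alpha/beta and the diameter law"
        )

    return SyntheticCohort(
        scans=tuple(scans),
        annotations=tuple(annotations),
        marks={c: tuple(v) for c, v in marks.items()},
        truth=SyntheticTruth(
            lesions=tuple(lesions),
            mark_sources={c: tuple(v) for c, v in sources.items()},
        ),
    )


def agreement_weight(
    reader_model: ReaderModel, diameter_mm: float, min_agreement: int, n_readers: int = 3
) -> float:
    """P(at least min_agreement of n_readers independently see the lesion)."""
    p = reader_model.p_detect(diameter_mm)
    return float(1.0 - stats.binom.cdf(min_agreement - 1, n_readers, p))


def expected_froc_plateau(
    profile: DetectorProfile,
    law: DiameterLaw,
    reader_model: ReaderModel | None = None,
    min_agreement: int = 0,
    n_readers: int = 3,
) -> float:
    """Asymptotic FROC sensitivity: E[sens(d)] over the consensus nodules.

    Consensus nodules are a size-biased subsample of the true lesions —
    larger lesions are more likely to reach reader agreement — so the
    expectation weights the diameter law by the probability w(d) that at
    least ``min_agreement`` of the readers detect the lesion.
    ``min_agreement=0`` gives the unweighted expectation over all lesions.
    """

    def weight(d: float) -> float:
        if min_agreement <= 0 or reader_model is None:
            return 1.0
        return agreement_weight(reader_model, d, min_agreement, n_readers)

    num, _ = integrate.quad(
        lambda d: profile.sensitivity(d) * weight(d) * law.pdf(d), 0.0, np.inf
    )
    den, _ = integrate.quad(lambda d: weight(d) * law.pdf(d), 0.0, np.inf)
    return float(num / den)


def binormal_auc(
    mu_pos: float, mu_neg: float, sigma_pos: float = 1.0, sigma_neg: float = 1.0
) -> float:
    """Closed-form AUC of the binormal score model:
    Phi((mu_pos - mu_neg) / sqrt(sigma_pos^2 + sigma_neg^2))."""
    return float(
        stats.norm.cdf((mu_pos - mu_neg) / math.hypot(sigma_pos, sigma_neg))
    )


def binormal_scores(
    rng: np.random.Generator,
    n_pos: int,
    n_neg: int,
    mu_pos: float = 1.0,
    mu_neg: float = 0.0,
    sigma_pos: float = 1.0,
    sigma_neg: float = 1.0,
) -> list[ScanScore]:
    """Direct binormal scan scores — the simplified generator variant used
    to calibrate the scan-level statistics against closed forms."""
    pos = mu_pos + sigma_pos * rng.standard_normal(n_pos)
    neg = mu_neg + sigma_neg * rng.standard_normal(n_neg)
    out = [
        ScanScore(f"P{i:04d}", True, float(v)) for i, v in enumerate(pos)
    ] + [ScanScore(f"N{i:04d}", False, float(v)) for i, v in enumerate(neg)]
    return out


def closed_form_targets(config: SyntheticConfig) -> dict:
    """Analytic expectations for a configuration, used as test oracles.

    Per condition: the expected false-positive rate per scan (the Poisson
    rate) and the asymptotic FROC plateau over 2-of-3 and 3-of-3 consensus
    nodules as well as over all lesions. Plus the diameter-law fraction of
    lesions below 6 mm.
    """
    out: dict = {"fraction_lt_6mm": config.diameter_law.cdf(6.0)}
    for cond, prof in sorted(config.detector_profiles.items()):
        out[cond] = {
            "fp_per_scan": prof.fp_rate_per_scan,
            "froc_plateau_all_lesions": expected_froc_plateau(
                prof, config.diameter_law
            ),
            "froc_plateau_agree2": expected_froc_plateau(
                prof, config.diameter_law, config.reader_model, 2, config.n_readers
            ),
            "froc_plateau_agree3": expected_froc_plateau(
                prof, config.diameter_law, config.reader_model, 3, config.n_readers
            ),
        }
    return out


def perfect_config(seed: int = 0, n_abnormal: int = 20, n_normal: int = 20) -> SyntheticConfig:
    """A degenerate configuration: every reader sees every lesion with no
    jitter and both conditions detect everything inside the hit sphere with
    no false marks. Useful for exactness tests of the pipeline."""
    reader = ReaderModel(
        alpha=50.0, beta=0.0, center_jitter_frac=0.0, diameter_jitter_sd=0.0,
        axis_spread_max=0.0,
    )
    prof = DetectorProfile(
        sens_alpha=50.0, sens_beta=0.0, loc_jitter_frac=0.1,
        fp_rate_per_scan=0.0, guaranteed_hit=True,
    )
    return SyntheticConfig(
        seed=seed,
        n_abnormal=n_abnormal,
        n_normal=n_normal,
        reader_model=reader,
        detector_profiles={
            "original_5mm": prof,
            "refined_1mm": replace(prof),
        },
    )
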