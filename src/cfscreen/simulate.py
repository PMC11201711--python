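"""Synthetic screening-cohort generator.

Generates subject-level cohorts with the group structure of the screening
subset the package analyzes: 108 subjects with benign nodules, 17 with
prevalent lung cancer (diagnosed at the first round) and 12 with incident
lung cancer (rounds 2-4).  Per group, plasma cfDNA is drawn from a
log-normal distribution calibrated so that both the group mean (3.3 / 18.8
/ 4.8 ng/mL) and the fraction of subjects at or above the 3.15 ng/mL
category boundary match the published descriptive table; nodule size
classes, spiculation, emphysema and related covariates follow the same
table's per-group frequencies.

For malignant solid nodules with serial exams, volume doubling time is
coupled to ln(cfDNA) through a bivariate-Gaussian structure with a
configurable correlation (default -0.77), mean VDT 172 days, and a 20-day
lower truncation.  Second-timepoint diameters are then produced by the
exact exponential-growth inverse of the VDT estimator, plus optional
measurement noise, so the growth-kinetics module recovers the assigned VDT
at zero noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .cohort import (
    Density,
    NoduleObservation,
    OutcomeClass,
    OutcomeLabel,
    Sex,
    SmokingStatus,
    SubjectRecord,
)

__all__ = [
    "CalibrationError",
    "CohortSimParams",
    "calibrate_cfdna_lognormal",
    "generate_cohort",
    "generate_serial_diameters",
    "sample_cfdna_vdt",
]

_GROUPS = (OutcomeClass.BENIGN, OutcomeClass.PREVALENT_LC, OutcomeClass.INCIDENT_LC)

# size-class sampling ranges (mm), half-open, aligned with the reporting bins
_SIZE_RANGES = ((3.0, 6.0), (6.0, 8.0), (8.0, 15.0), (15.0, 30.0))


class CalibrationError(ValueError):
    """No log-normal distribution satisfies the requested mean and tail mass."""


def calibrate_cfdna_lognormal(
    target_mean: float, target_frac_above: float, cutoff: float = 3.15
) -> tuple[float, float]:
    """Log-normal (mu, sigma) on the natural-log scale matching a mean and a
    tail probability.

    Solves ``exp(mu + sigma^2/2) = target_mean`` and
    ``P(X >= cutoff) = target_frac_above`` exactly.  Substituting the tail
    condition ``mu = ln(cutoff) - z*sigma`` (z the upper-tail normal
    quantile) into the mean condition gives a quadratic in sigma; the
    positive root is returned.  Raises CalibrationError when no sigma > 0
    exists.
    """
    if not target_mean > 0:
        raise CalibrationError("target_mean must be positive")
    if not 0.0 < target_frac_above < 1.0:
        raise CalibrationError("target_frac_above must be in (0, 1)")
    z = float(sps.norm.ppf(1.0 - target_frac_above))
    disc = z * z + 2.0 * math.log(target_mean / cutoff)
    if disc < 0:
        raise CalibrationError(
            f"no log-normal has mean {target_mean} with P(X >= {cutoff}) = {target_frac_above}"
        )
    root = math.sqrt(disc)
    sigma = max(z + root, z - root)
    if sigma <= 0:
        raise CalibrationError(
            f"no sigma > 0 yields mean {target_mean} with P(X >= {cutoff}) = {target_frac_above}"
        )
    mu = math.log(cutoff) - z * sigma
    return mu, sigma


@dataclass(frozen=True)
class CohortSimParams:
    """Generator parameters; defaults reproduce the published group structure.

    Tuples are ordered (benign, prevalent LC, incident LC).
    """

    n_benign: int = 108
    n_prevalent: int = 17
    n_incident: int = 12
    # cfDNA (ng/mL): group means and fraction at/above the 3.15 boundary
    cfdna_target_means: tuple[float, float, float] = (3.3, 18.8, 4.8)
    cfdna_frac_above_cut: tuple[float, float, float] = (37 / 108, 14 / 17, 9 / 12)
    cfdna_cut: float = 3.15
    # explicit (mu, sigma) per group; None -> calibrated from the targets above
    cfdna_group_params: tuple[tuple[float, float], ...] | None = None
    # main-nodule size class probabilities over (<6, 6-8, 8-15, >=15) mm
    size_class_probs: tuple[tuple[float, ...], ...] = (
        (60 / 108, 22 / 108, 21 / 108, 5 / 108),
        (1 / 17, 1 / 17, 6 / 17, 9 / 17),
        (5 / 12, 2 / 12, 2 / 12, 3 / 12),
    )
    # baseline nodule-count probabilities over (0, 1, 2, 3) nodules
    nodule_count_probs: tuple[tuple[float, ...], ...] = (
        (0.0, 69 / 108, 24 / 108, 15 / 108),
        (0.0, 9 / 17, 3 / 17, 5 / 17),
        (2 / 12, 6 / 12, 2 / 12, 2 / 12),
    )
    spiculation_prob: tuple[float, float, float] = (0.028, 0.471, 0.0)
    emphysema_prob: tuple[float, float, float] = (38 / 108, 7 / 17, 4 / 12)
    female_prob: tuple[float, float, float] = (42 / 108, 4 / 17, 2 / 12)
    current_smoker_prob: tuple[float, float, float] = (78 / 108, 13 / 17, 9 / 12)
    family_history_prob: tuple[float, float, float] = (13 / 108, 3 / 17, 1 / 12)
    age_mean: tuple[float, float, float] = (61.0, 62.9, 63.0)
    age_sd: float = 3.8
    age_range: tuple[float, float] = (55.0, 69.0)
    pack_years_median: tuple[float, float, float] = (40.5, 52.5, 50.7)
    pack_years_log_sd: float = 0.35
    density_probs: tuple[float, float, float] = (0.85, 0.10, 0.05)  # solid, part-solid, non-solid
    upper_lobe_prob: float = 0.5
    adenocarcinoma_prob: float = 18 / 29
    # VDT coupling for malignant solid nodules with serial exams
    vdt_corr: float = -0.77
    vdt_mean_days: float = 172.0
    vdt_sd_days: float = 80.0
    vdt_min_days: float = 20.0
    n_prevalent_with_vdt: int = 4
    prevalent_followup_days: int = 90
    diameter_noise_sd_mm: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for n in (self.n_benign, self.n_prevalent, self.n_incident):
            if n < 0:
                raise ValueError("group sizes must be >= 0")
        if not abs(self.vdt_corr) <= 1:
            raise ValueError("|vdt_corr| must be <= 1")
        for probs in (*self.size_class_probs, *self.nodule_count_probs, self.density_probs):
            arr = np.asarray(probs, dtype=float)
            if (arr < 0).any() or (arr > 1).any() or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"probability vector {probs} must be in [0,1] and sum to 1")
        for p in (*self.spiculation_prob, *self.emphysema_prob, *self.female_prob,
                  *self.current_smoker_prob, *self.family_history_prob, self.upper_lobe_prob,
                  self.adenocarcinoma_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def group_lognormal_params(self) -> tuple[tuple[float, float], ...]:
        if self.cfdna_group_params is not None:
            return self.cfdna_group_params
        return tuple(
            calibrate_cfdna_lognormal(m, f, self.cfdna_cut)
            for m, f in zip(self.cfdna_target_means, self.cfdna_frac_above_cut)
        )


def sample_cfdna_vdt(
    n: int,
    mu: float,
    sigma: float,
    corr: float = -0.77,
    vdt_mean: float = 172.0,
    vdt_sd: float = 80.0,
    vdt_min: float = 20.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly sample (cfDNA, VDT) pairs for malignant solid nodules.

    ln(cfDNA) ~ N(mu, sigma); VDT is generated from the conditional of a
    bivariate Gaussian on (ln cfDNA, VDT) with correlation ``corr``, then
    truncated below at ``vdt_min`` days.  Returns (cfdna ng/mL, vdt days).
    """
    rng = np.random.default_rng(rng)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    log_cf = mu + sigma * z1
    v = vdt_mean + vdt_sd * (corr * z1 + math.sqrt(1.0 - corr * corr) * z2)
    v = np.maximum(v, vdt_min)
    return np.exp(log_cf), v


def generate_serial_diameters(
    true_vdt_days: float,
    d0_mm: float,
    interval_days: float,
    noise_sd_mm: float = 0.0,
    rng: np.random.Generator | int | None = None,
    nodule_id: str = "n1",
    spiculated: bool = False,
    upper_lobe: bool = False,
) -> tuple[NoduleObservation, NoduleObservation]:
    """Two solid-nodule timepoints consistent with a given doubling time.

    The noiseless second diameter is ``d0 * 2^(interval / (3 * VDT))``;
    Gaussian measurement noise (sd ``noise_sd_mm``) is added independently
    to each timepoint's diameter when requested.
    """
    if true_vdt_days == 0:
        raise ValueError("true_vdt_days must be nonzero")
    if not d0_mm > 0 or not interval_days > 0:
        raise ValueError("d0_mm and interval_days must be positive")
    rng = np.random.default_rng(rng)
    d1 = d0_mm * 2.0 ** (interval_days / (3.0 * true_vdt_days))
    if noise_sd_mm > 0:
        d0_obs = max(0.5, d0_mm + noise_sd_mm * rng.standard_normal())
        d1_obs = max(0.5, d1 + noise_sd_mm * rng.standard_normal())
    else:
        d0_obs, d1_obs = d0_mm, d1
    mk = lambda d, day: NoduleObservation(
        nodule_id=nodule_id,
        mean_diameter_mm=d,
        exam_day=int(day),
        max_diameter_mm=d,
        perp_diameter_mm=d,
        density=Density.SOLID,
        upper_lobe=upper_lobe,
        spiculated=spiculated,
    )
    return mk(d0_obs, 0), mk(d1_obs, interval_days)


def _draw_nodule(
    rng: np.random.Generator,
    nodule_id: str,
    size_range: tuple[float, float] | None,
    density_probs: tuple[float, float, float],
    spiculated: bool,
    upper_lobe_prob: float,
    force_solid: bool = False,
) -> NoduleObservation:
    if size_range is None:
        d = float(rng.uniform(3.0, 6.0))
    else:
        d = float(rng.uniform(*size_range))
    if force_solid:
        density = Density.SOLID
    else:
        density = (Density.SOLID, Density.PART_SOLID, Density.NON_SOLID)[
            int(rng.choice(3, p=density_probs))
        ]
    solid_comp = float(rng.uniform(0.3, 0.9) * d) if density is Density.PART_SOLID else 0.0
    # axial axes consistent with the mean diameter: mean = (max + perp)/2
    ecc = float(rng.uniform(0.0, 0.25))
    return NoduleObservation(
        nodule_id=nodule_id,
        mean_diameter_mm=round(d, 2),
        exam_day=0,
        max_diameter_mm=round(d * (1 + ecc), 2),
        perp_diameter_mm=round(d * (1 - ecc), 2),
        density=density,
        solid_component_mm=round(solid_comp, 2),
        upper_lobe=bool(rng.random() < upper_lobe_prob),
        spiculated=spiculated,
    )


def generate_cohort(params: CohortSimParams | None = None, seed: int | None = None) -> list[SubjectRecord]:
    """Generate a validated synthetic cohort; deterministic given the seed.

    ``seed`` overrides ``params.seed`` when given.  Group sizes are exact;
    all per-subject attributes are drawn from the configured per-group
    distributions.
    """
    params = params or CohortSimParams()
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    lognorm = params.group_lognormal_params()

    records: list[SubjectRecord] = []
    for gi, (group, n_group) in enumerate(
        zip(_GROUPS, (params.n_benign, params.n_prevalent, params.n_incident))
    ):
        mu, sigma = lognorm[gi]
        prefix = {"benign": "b", "prevalent_lc": "p", "incident_lc": "i"}[group.value]
        # prevalent subjects with serial follow-up (VDT measurable)
        vdt_subset: set[int] = set()
        if group is OutcomeClass.PREVALENT_LC and n_group > 0:
            k = min(params.n_prevalent_with_vdt, n_group)
            vdt_subset = set(rng.choice(n_group, size=k, replace=False).tolist())
        # incident subjects without a visible baseline nodule: exact count,
        # so the number of serial-exam cancers is reproducible
        zero_set: set[int] = set()
        count_probs = np.asarray(params.nodule_count_probs[gi], dtype=float)
        if group is OutcomeClass.INCIDENT_LC and n_group > 0 and count_probs[0] > 0:
            k0 = int(round(count_probs[0] * n_group))
            zero_set = set(rng.choice(n_group, size=k0, replace=False).tolist())
            nz = count_probs[1:] / count_probs[1:].sum()
        for j in range(n_group):
            sid = f"{prefix}{j + 1:03d}"
            log_cf = mu + sigma * rng.standard_normal()
            cfdna = round(float(np.exp(log_cf)), 3)

            if group is OutcomeClass.INCIDENT_LC and count_probs[0] > 0:
                n_nod = 0 if j in zero_set else 1 + int(rng.choice(3, p=nz))
            else:
                n_nod = int(rng.choice(4, p=count_probs))
            spiculated_main = bool(rng.random() < params.spiculation_prob[gi])

            histotype = (
                ("adenocarcinoma" if rng.random() < params.adenocarcinoma_prob else "other")
                if group is not OutcomeClass.BENIGN
                else None
            )

            nodules: list[NoduleObservation] = []
            wants_serial = (group is OutcomeClass.INCIDENT_LC and n_nod > 0) or (
                group is OutcomeClass.PREVALENT_LC and j in vdt_subset
            )
            v: float | None = None
            if wants_serial:
                # VDT conditional on this subject's ln(cfDNA); the pair has
                # the configured bivariate-Gaussian correlation structure
                rho = params.vdt_corr
                z1 = (log_cf - mu) / sigma
                v = params.vdt_mean_days + params.vdt_sd_days * (
                    rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal()
                )
                v = max(v, params.vdt_min_days)

            if group is OutcomeClass.INCIDENT_LC:
                if v is None:
                    dx_round = 3  # surfaced as a new nodule at the 3rd round
                else:
                    # fast growth surfaces early: the diagnosis round follows
                    # the marginal VDT quantile (expected round split 1/5/6
                    # over rounds 2/3/4 including the two new-nodule cancers)
                    u = float(sps.norm.cdf((v - params.vdt_mean_days) / params.vdt_sd_days))
                    dx_round = 2 if u < 0.1 else (3 if u < 0.4 else 4)
                outcome = OutcomeLabel(group, dx_round, histotype)
            elif group is OutcomeClass.PREVALENT_LC:
                outcome = OutcomeLabel(group, 1, histotype)
            else:
                outcome = OutcomeLabel(group)
            if n_nod > 0:
                size_ci = int(rng.choice(4, p=params.size_class_probs[gi]))
                main = _draw_nodule(
                    rng,
                    f"{sid}-n1",
                    _SIZE_RANGES[size_ci],
                    params.density_probs,
                    spiculated_main,
                    params.upper_lobe_prob,
                    force_solid=wants_serial,  # VDT is defined for solid nodules only
                )
                nodules.append(main)
                for k in range(1, n_nod):
                    nodules.append(
                        _draw_nodule(
                            rng, f"{sid}-n{k + 1}", None, params.density_probs, False, params.upper_lobe_prob
                        )
                    )
                if wants_serial:
                    if group is OutcomeClass.INCIDENT_LC:
                        interval = 365 * (outcome.diagnosis_round - 1)
                    else:
                        interval = params.prevalent_followup_days
                    t0, t1 = generate_serial_diameters(
                        v,
                        main.mean_diameter_mm,
                        interval,
                        noise_sd_mm=params.diameter_noise_sd_mm,
                        rng=rng,
                        nodule_id=main.nodule_id,
                        spiculated=main.spiculated,
                        upper_lobe=main.upper_lobe,
                    )
                    # replace the baseline draw with the measured t0 and
                    # append the follow-up timepoint (equal axes by design)
                    def _serial_obs(src: NoduleObservation) -> NoduleObservation:
                        d = round(src.mean_diameter_mm, 3)
                        return NoduleObservation(
                            nodule_id=main.nodule_id,
                            mean_diameter_mm=d,
                            exam_day=src.exam_day,
                            max_diameter_mm=d,
                            perp_diameter_mm=d,
                            density=Density.SOLID,
                            upper_lobe=main.upper_lobe,
                            spiculated=main.spiculated,
                        )

                    nodules[0] = _serial_obs(t0)
                    nodules.append(_serial_obs(t1))

            age = float(np.clip(rng.normal(params.age_mean[gi], params.age_sd), *params.age_range))
            pack = float(
                max(20.5, math.exp(math.log(params.pack_years_median[gi]) + params.pack_years_log_sd * rng.standard_normal()))
            )
            rec = SubjectRecord(
                subject_id=sid,
                age_years=round(age, 1),
                sex=Sex.FEMALE if rng.random() < params.female_prob[gi] else Sex.MALE,
                pack_years=round(pack, 1),
                smoking_status=SmokingStatus.CURRENT
                if rng.random() < params.current_smoker_prob[gi]
                else SmokingStatus.FORMER,
                family_history_lc=bool(rng.random() < params.family_history_prob[gi]),
                emphysema=bool(rng.random() < params.emphysema_prob[gi]),
                cfdna_ng_ml=cfdna,
                outcome=outcome,
                nodules=tuple(nodules),
            )
            rec.validate()
            records.append(rec)
    return records
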