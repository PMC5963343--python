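"""Synthetic qPCR cohorts with known ground truth.

The generator emulates the measurement process of a two-arm isoform
expression study: brain tissue from five diagnostic groups (pDLB, cDLB,
PDND, PDD, controls) and blood from three (DLB, PD, controls), each
sample amplified for three GBA transcript variants plus two tissue-
appropriate housekeeping genes, in duplicate wells across two
independent runs.

The Ct model is additive on the cycle scale:

    Ct[s, a, r, k] = baseline[a] - log2(fold[s, a]) + run_offset[a, r] + eps

with eps ~ Normal(0, replicate_sd) and run_offset ~ Normal(0, run_sd).
True fold changes vs the control group are configured per (group,
tissue, target); housekeeping references and controls are fixed at fold
1, so the full pipeline recovers every configured fold exactly when all
noise terms are zero.  Optional covariate links make a patient's fold a
log-linear function of age at onset or disease duration, which the
regression analyses should then recover.

Everything is driven by one ``numpy.random.Generator`` seeded from the
config, so identical configs produce byte-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .datamodel import (
    AssayPanel,
    CtMeasurement,
    SampleRecord,
    panel_for_arm,
)
from .errors import ValidationError
from .stability import DEFAULT_TIMEPOINTS_MIN, DegradationSeries

#: Plausible baseline Ct (cycles) per assay for undiluted cDNA input.
DEFAULT_BASELINE_CT = {
    "GBAtv1": 26.0,
    "GBAtv2": 25.0,
    "GBAtv5": 28.0,
    "ACTB": 20.0,
    "GUSB": 24.0,
    "PBGD": 25.0,
}

# Cohort shapes of the emulated study: group -> number of subjects.
BRAIN_GROUP_SIZES = {"CTRL": 17, "pDLB": 8, "cDLB": 12, "PDND": 12, "PDD": 13}
BLOOD_GROUP_SIZES = {"CTRL": 17, "DLB": 20, "PD": 26}

BRAIN_TISSUES = ("temporal_cortex", "caudate_nucleus")

# (onset mean, onset sd, duration mean, duration sd) in years, per group.
_COVARIATE_PARAMS = {
    "DLB": (68.0, 4.5, 5.9, 2.5),
    "PD": (65.3, 4.5, 6.5, 3.5),
    "pDLB": (68.0, 4.5, 5.9, 2.5),
    "cDLB": (68.0, 4.5, 5.9, 2.5),
    "PDND": (65.3, 4.5, 6.5, 3.5),
    "PDD": (65.3, 4.5, 10.0, 3.5),
}
_DEFAULT_COVARIATE_PARAMS = (66.0, 5.0, 6.0, 3.0)


@dataclass(frozen=True)
class CovariateLink:
    """Log-linear link from a clinical covariate to a patient's true fold.

    fold_patient = fold_group * 2^(slope * (covariate - center) + eps),
    eps ~ Normal(0, noise_sd).  ``slope`` is per year on the log2 scale.
    """

    variable: str  # "age_at_onset" | "disease_duration"
    slope: float
    center: float
    noise_sd: float = 0.0
    targets: tuple[str, ...] = ()

    def __post_init__(self):
        if self.variable not in ("age_at_onset", "disease_duration"):
            raise ValidationError(f"unknown covariate {self.variable!r}")
        if self.noise_sd < 0:
            raise ValidationError("covariate noise_sd must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one synthetic cohort."""

    seed: int = 0
    cohort_arm: str = "blood"
    groups: Mapping[str, int] = field(default_factory=lambda: dict(BLOOD_GROUP_SIZES))
    tissues: tuple[str, ...] = ("blood",)
    panel: AssayPanel | None = None
    true_fold: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    baseline_ct: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE_CT))
    replicate_sd: float = 0.25
    run_sd: float = 0.15
    n_runs: int = 2
    n_replicates: int = 2
    efficiency: Mapping[str, float] = field(default_factory=dict)
    covariate_model: CovariateLink | None = None
    rin_mean: float = 7.5
    rin_sd: float = 0.8
    control_group: str = "CTRL"

    def __post_init__(self):
        if self.panel is None:
            object.__setattr__(self, "panel", panel_for_arm(self.cohort_arm))
        object.__setattr__(self, "tissues", tuple(self.tissues))
        if self.control_group not in self.groups:
            raise ValidationError(
                f"control group {self.control_group!r} missing from groups"
            )
        if any(n < 1 for n in self.groups.values()):
            raise ValidationError("every group needs at least one subject")
        if any(f <= 0 for f in self.true_fold.values()):
            raise ValidationError("true fold changes must be positive")
        if self.replicate_sd < 0 or self.run_sd < 0:
            raise ValidationError("noise SDs must be >= 0")
        if self.n_runs < 1 or self.n_replicates < 1:
            raise ValidationError("need at least one run and one replicate")
        if not (1.0 <= self.rin_mean <= 10.0):
            raise ValidationError("rin_mean must lie in [1, 10]")
        missing = [a for a in self.panel.assays if a not in self.baseline_ct]
        if missing:
            raise ValidationError(f"baseline_ct missing for assays: {missing}")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually used; the oracle for recovery tests."""

    group_fold: Mapping[tuple[str, str, str], float]  # (group, tissue, target)
    sample_fold: Mapping[tuple[str, str], float]  # (sample_id, assay)
    patient_multiplier: Mapping[tuple[str, str], float]  # (subject_id, target)
    covariate_model: CovariateLink | None


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    """Draw from Normal(mean, sd) restricted to [lo, hi] by rejection."""
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def generate_covariates(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[dict]:
    """Clinical covariates (onset, duration, age, sex) per patient subject.

    Onset and duration are drawn from group-specific truncated normals
    parameterised to resemble a Lewy-body-disease cohort (onset around
    65-68 years, duration around 6 years); age is onset + duration.
    Returns one dict per non-control subject, in deterministic order.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = []
    for group in config.groups:
        if group == config.control_group:
            continue
        onset_m, onset_sd, dur_m, dur_sd = _COVARIATE_PARAMS.get(
            group, _DEFAULT_COVARIATE_PARAMS
        )
        if dur_m < 0 or onset_m < 0:
            raise ValidationError("covariate means must be non-negative")
        for i in range(config.groups[group]):
            onset = round(_truncated_normal(rng, onset_m, onset_sd, 40.0, 90.0), 1)
            duration = round(_truncated_normal(rng, dur_m, dur_sd, 0.5, 20.0), 1)
            out.append({
                "subject_id": f"{group}{i + 1:02d}",
                "group": group,
                "age_at_onset_years": onset,
                "disease_duration_years": duration,
                "age_years": round(onset + duration, 1),
                "sex": "M" if rng.random() < 0.5 else "F",
            })
    return out


def _patient_multiplier(
    link: CovariateLink | None,
    target: str,
    covs: dict,
    rng: np.random.Generator,
) -> float:
    if link is None:
        return 1.0
    if link.targets and target not in link.targets:
        return 1.0
    value = covs[
        "age_at_onset_years" if link.variable == "age_at_onset"
        else "disease_duration_years"
    ]
    eps = rng.normal(0.0, link.noise_sd) if link.noise_sd > 0 else 0.0
    return 2.0 ** (link.slope * (value - link.center) + eps)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[SampleRecord], list[CtMeasurement], GroundTruth]:
    """Generate sample metadata, raw Ct wells and the matching ground truth.

    Fully reproducible: the same config (including seed) yields identical
    records, and all randomness flows from one generator.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    covariates = {c["subject_id"]: c for c in generate_covariates(config, rng)}

    samples: list[SampleRecord] = []
    sample_fold: dict[tuple[str, str], float] = {}
    patient_mult: dict[tuple[str, str], float] = {}

    subjects: list[tuple[str, str]] = []  # (subject_id, group)
    for group, n in config.groups.items():
        for i in range(n):
            subjects.append((f"{group}{i + 1:02d}", group))

    for subject_id, group in subjects:
        covs = covariates.get(subject_id)
        if group != config.control_group:
            for target in panel.targets:
                patient_mult[(subject_id, target)] = _patient_multiplier(
                    config.covariate_model, target, covs, rng
                )
        if covs is None:
            age = round(_truncated_normal(rng, 74.0, 6.0, 55.0, 95.0), 1)
            sex = "M" if rng.random() < 0.5 else "F"
            onset = duration = None
        else:
            age = covs["age_years"]
            sex = covs["sex"]
            onset = covs["age_at_onset_years"]
            duration = covs["disease_duration_years"]
        rin = round(_truncated_normal(rng, config.rin_mean, config.rin_sd, 1.0, 10.0), 1)
        pm_time = (
            round(float(rng.uniform(3.0, 20.0)), 1)
            if config.cohort_arm == "brain" else None
        )
        for tissue in config.tissues:
            sample_id = f"{subject_id}-{tissue}"
            samples.append(SampleRecord(
                sample_id=sample_id,
                subject_id=subject_id,
                cohort_arm=config.cohort_arm,
                tissue=tissue,
                group=group,
                age_years=age,
                sex=sex,
                age_at_onset_years=onset,
                disease_duration_years=duration,
                post_mortem_time_hours=pm_time,
                rin=rin,
            ))
            for assay in panel.assays:
                if assay in panel.references or group == config.control_group:
                    fold = 1.0
                else:
                    fold = config.true_fold.get((group, tissue, assay), 1.0)
                    fold *= patient_mult[(subject_id, assay)]
                sample_fold[(sample_id, assay)] = fold

    run_ids = tuple(f"run{r + 1}" for r in range(config.n_runs))
    run_offsets = {
        (assay, run): (
            float(rng.normal(0.0, config.run_sd)) if config.run_sd > 0 else 0.0
        )
        for assay in panel.assays
        for run in run_ids
    }

    measurements: list[CtMeasurement] = []
    for s in samples:
        for assay in panel.assays:
            base = config.baseline_ct[assay] - math.log2(
                sample_fold[(s.sample_id, assay)]
            )
            for run in run_ids:
                for k in range(1, config.n_replicates + 1):
                    eps = (
                        float(rng.normal(0.0, config.replicate_sd))
                        if config.replicate_sd > 0 else 0.0
                    )
                    measurements.append(CtMeasurement(
                        sample_id=s.sample_id,
                        assay=assay,
                        run_id=run,
                        replicate_index=k,
                        ct=base + run_offsets[(assay, run)] + eps,
                    ))

    truth = GroundTruth(
        group_fold=dict(config.true_fold),
        sample_fold=sample_fold,
        patient_multiplier=patient_mult,
        covariate_model=config.covariate_model,
    )
    return samples, measurements, truth


def generate_dilution_series(
    assay: str,
    efficiency: float,
    baseline_ct: float,
    n_points: int = 5,
    step_log10: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[tuple[float, float]]:
    """Serial-dilution (log10_dilution, Ct) pairs for a standard curve.

    With amplification efficiency E, a 10-fold dilution costs
    1/log10(1+E) cycles, so Ct(d) = baseline - log10(d)/log10(1+E):
    at E = 1 the slope is -3.321928 cycles per log10 step.
    """
    if efficiency <= 0:
        raise ValidationError("efficiency must be positive")
    if n_points < 3:
        raise ValidationError("dilution series needs >= 3 points")
    if step_log10 <= 0 or noise_sd < 0:
        raise ValidationError("step_log10 must be > 0 and noise_sd >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_points):
        log10_d = -i * step_log10  # dilution 1, 10^-step, ...
        ct = baseline_ct - log10_d / math.log10(1.0 + efficiency)
        if noise_sd > 0:
            ct += float(rng.normal(0.0, noise_sd))
        out.append((log10_d, ct))
    return out


def generate_degradation_experiment(
    rates: Mapping[str, float],
    timepoints_min: Sequence[float] = DEFAULT_TIMEPOINTS_MIN,
    noise_sd: float = 0.0,
    seed: int | None = None,
    sample_id: str = "sim",
) -> list[DegradationSeries]:
    """Synthetic 50 C incubation time-courses, one series per assay.

    relative_amount(t) = 2^(rate * t), multiplied by log-normal noise at
    t > 0.  The RIN track declines linearly with incubation, mirroring
    how integrity scores fall as RNA fragments.
    """
    if any(r > 0 for r in rates.values()):
        raise ValidationError("decay rates must be <= 0")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = tuple(float(x) for x in timepoints_min)
    rin_track = tuple(max(1.0, 9.0 - 0.015 * x) for x in t)
    out = []
    for assay, rate in rates.items():
        amounts = []
        for x in t:
            a = 2.0 ** (rate * x)
            if noise_sd > 0 and x > 0:
                a *= 2.0 ** float(rng.normal(0.0, noise_sd))
            amounts.append(a)
        out.append(DegradationSeries(
            assay=assay,
            sample_id=sample_id,
            timepoints_min=t,
            relative_amount=tuple(amounts),
            rin_track=rin_track,
        ))
    return out


def default_blood_config(seed: int = 0) -> SimulationConfig:
    """Blood arm emulating the study: GBAtv1 suppressed in DLB and PD."""
    return SimulationConfig(
        seed=seed,
        cohort_arm="blood",
        groups=dict(BLOOD_GROUP_SIZES),
        tissues=("blood",),
        true_fold={
            ("DLB", "blood", "GBAtv1"): 0.41,
            ("PD", "blood", "GBAtv1"): 0.35,
        },
    )


def default_brain_config(seed: int = 0) -> SimulationConfig:
    """Brain arm emulating the study's temporal-cortex / caudate profile."""
    return SimulationConfig(
        seed=seed,
        cohort_arm="brain",
        groups=dict(BRAIN_GROUP_SIZES),
        tissues=BRAIN_TISSUES,
        true_fold={
            ("pDLB", "temporal_cortex", "GBAtv1"): 0.38,
            ("cDLB", "temporal_cortex", "GBAtv1"): 0.27,
            ("pDLB", "temporal_cortex", "GBAtv5"): 0.35,
            ("pDLB", "caudate_nucleus", "GBAtv1"): 0.41,
            ("cDLB", "caudate_nucleus", "GBAtv1"): 0.44,
            ("PDD", "caudate_nucleus", "GBAtv1"): 0.41,
            ("PDD", "caudate_nucleus", "GBAtv5"): 0.36,
        },
    )


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
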