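"""Shared data model: samples, raw Ct measurements, assay panels, thresholds.

The model mirrors how a real-time PCR study is organised: each *sample*
(one tissue from one subject) is measured for several *assays* (isoform-
specific targets plus housekeeping references), in one or more independent
*runs*, with technical *replicates* inside each run.  A Ct value is the PCR
cycle at which fluorescence crosses the detection threshold; wells that
never cross it are recorded as undetected (``ct is None``), never as a
numeric cap.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ValidationError

#: Diagnostic group labels accepted by the sample metadata reader.
KNOWN_GROUPS = frozenset(
    {"CTRL", "pDLB", "cDLB", "PDND", "PDD", "DLB", "PD"}
)

#: Upper bound on a plausible Ct value (cycles).
CT_MAX = 45.0


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class SampleRecord:
    """One tissue sample from one subject, with clinical covariates.

    ``age_at_onset_years`` and ``disease_duration_years`` are ``None`` for
    control subjects; ``rin`` is the electrophoretic RNA Integrity Number
    on the 1-10 scale and may be missing.
    """

    sample_id: str
    subject_id: str
    cohort_arm: str  # "brain" | "blood"
    tissue: str
    group: str
    age_years: float
    sex: str = "unknown"  # "M" | "F" | "unknown"
    age_at_onset_years: float | None = None
    disease_duration_years: float | None = None
    post_mortem_time_hours: float | None = None
    rin: float | None = None

    def __post_init__(self):
        if self.cohort_arm not in ("brain", "blood"):
            raise ValidationError(
                f"sample {self.sample_id}: unknown cohort_arm {self.cohort_arm!r}"
            )
        if self.group not in KNOWN_GROUPS:
            raise ValidationError(
                f"sample {self.sample_id}: unknown group label {self.group!r}"
            )
        if self.sex not in ("M", "F", "unknown"):
            raise ValidationError(
                f"sample {self.sample_id}: sex must be M, F or unknown"
            )
        if self.age_years is None or self.age_years < 0:
            raise ValidationError(
                f"sample {self.sample_id}: age_years must be non-negative"
            )
        onset = self.age_at_onset_years
        duration = self.disease_duration_years
        if self.group == "CTRL":
            if not _is_missing(onset) or not _is_missing(duration):
                raise ValidationError(
                    f"sample {self.sample_id}: control subject must not carry "
                    "age-at-onset or disease-duration values"
                )
        if not _is_missing(onset):
            if onset < 0:
                raise ValidationError(
                    f"sample {self.sample_id}: negative age_at_onset_years"
                )
            if onset > self.age_years:
                raise ValidationError(
                    f"sample {self.sample_id}: age_at_onset_years ({onset}) "
                    f"exceeds age_years ({self.age_years})"
                )
        if not _is_missing(duration) and duration < 0:
            raise ValidationError(
                f"sample {self.sample_id}: negative disease_duration_years"
            )
        if not (_is_missing(onset) or _is_missing(duration)):
            # onset + duration should reconstruct age to within a year
            # (covariates are typically recorded in whole years).
            if abs((onset + duration) - self.age_years) > 1.0 + 1e-9:
                raise ValidationError(
                    f"sample {self.sample_id}: onset ({onset}) + duration "
                    f"({duration}) inconsistent with age ({self.age_years})"
                )
        if not _is_missing(self.rin) and not (1.0 <= self.rin <= 10.0):
            raise ValidationError(
                f"sample {self.sample_id}: rin {self.rin} outside [1, 10]"
            )
        if not _is_missing(self.post_mortem_time_hours) and self.post_mortem_time_hours < 0:
            raise ValidationError(
                f"sample {self.sample_id}: negative post_mortem_time_hours"
            )


@dataclass(frozen=True)
class CtMeasurement:
    """One raw well reading: sample x assay x run x replicate -> Ct cycles.

    ``ct is None`` flags an undetected well (reported e.g. as
    "Undetermined" by the instrument).
    """

    sample_id: str
    assay: str
    run_id: str
    replicate_index: int
    ct: float | None

    def __post_init__(self):
        if self.replicate_index < 1:
            raise ValidationError(
                f"{self.key()}: replicate_index must be a positive integer"
            )
        if self.ct is not None:
            if math.isnan(self.ct):
                object.__setattr__(self, "ct", None)
            elif not (0.0 < self.ct <= CT_MAX):
                raise ValidationError(
                    f"{self.key()}: ct {self.ct} outside (0, {CT_MAX:g}]"
                )

    def key(self) -> tuple[str, str, str, int]:
        return (self.sample_id, self.assay, self.run_id, self.replicate_index)

    @property
    def detected(self) -> bool:
        return self.ct is not None


@dataclass(frozen=True)
class AssayPanel:
    """Targets and reference (housekeeping) assays for one tissue context."""

    targets: tuple[str, ...]
    references: tuple[str, ...]
    amplicon_size_bp: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(self, "references", tuple(self.references))
        if not self.references:
            raise ValidationError("panel needs at least one reference assay")
        if set(self.targets) & set(self.references):
            raise ValidationError("targets and references must be disjoint")
        for name, size in self.amplicon_size_bp.items():
            if size <= 0:
                raise ValidationError(f"amplicon size for {name} must be positive")

    @property
    def assays(self) -> tuple[str, ...]:
        return self.targets + self.references


@dataclass(frozen=True)
class Thresholds:
    """Fold-change significance thresholds and efficiency tolerance.

    A decrease is called only when the point estimate falls below
    ``decrease_threshold`` *and* the upper variance bound does not exceed
    it; symmetrically for increases against ``increase_threshold``.
    """

    decrease_threshold: float = 0.5
    increase_threshold: float = 1.5
    efficiency_tolerance: float = 0.1

    def __post_init__(self):
        if not (0.0 < self.decrease_threshold < 1.0 < self.increase_threshold):
            raise ValidationError(
                "thresholds must satisfy 0 < decrease < 1 < increase"
            )
        if self.efficiency_tolerance < 0:
            raise ValidationError("efficiency_tolerance must be >= 0")


# Amplicon sizes (bp) of the isoform-specific and housekeeping assays.
_AMPLICONS = {
    "GBAtv1": 214,
    "GBAtv2": 236,
    "GBAtv5": 173,
    "ACTB": 178,
    "GUSB": 176,
    "PBGD": 183,
}

#: Brain-tissue panel: GBA transcript variants vs beta-actin + beta-glucuronidase.
BRAIN_PANEL = AssayPanel(
    targets=("GBAtv1", "GBAtv2", "GBAtv5"),
    references=("ACTB", "GUSB"),
    amplicon_size_bp={k: _AMPLICONS[k] for k in
                      ("GBAtv1", "GBAtv2", "GBAtv5", "ACTB", "GUSB")},
)

#: Blood panel: same targets vs beta-actin + porphobilinogen deaminase.
BLOOD_PANEL = AssayPanel(
    targets=("GBAtv1", "GBAtv2", "GBAtv5"),
    references=("ACTB", "PBGD"),
    amplicon_size_bp={k: _AMPLICONS[k] for k in
                      ("GBAtv1", "GBAtv2", "GBAtv5", "ACTB", "PBGD")},
)


def panel_for_arm(arm: str) -> AssayPanel:
    """Default assay panel for a cohort arm ("brain" or "blood")."""
    if arm == "brain":
        return BRAIN_PANEL
    if arm == "blood":
        return BLOOD_PANEL
    raise ValidationError(f"unknown cohort arm {arm!r}")


def check_unique_measurements(measurements: Sequence[CtMeasurement]) -> None:
    """Raise :class:`ValidationError` listing duplicated well keys, if any."""
    seen: set[tuple] = set()
    dupes: list[tuple] = []
    for m in measurements:
        k = m.key()
        if k in seen:
            dupes.append(k)
        seen.add(k)
    if dupes:
        raise ValidationError(
            "duplicate (sample_id, assay, run_id, replicate) keys: "
            + ", ".join(map(str, dupes))
        )
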