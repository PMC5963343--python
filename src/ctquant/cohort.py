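"""Cohort stratification, per-patient expression and covariate analyses.

Patients are split by age at disease onset (cut 65 years: onset at 65 or
earlier is "early") or by disease duration since onset (cut 6 years:
under 6 is "short").  Per-patient relative expression is computed
against the control-group mean dCt, stratum-level estimates reuse the
group delta-delta-Ct machinery, clinical variables are compared between
strata with Welch's t-test, and expression-vs-covariate association is
assessed by ordinary least squares of log2 expression on the covariate.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AssayPanel, CtMeasurement, SampleRecord, Thresholds
from .errors import DegenerateDesignError, InsufficientDataError, ValidationError
from . import quant
from .quant import RelativeExpression

logger = logging.getLogger(__name__)

ONSET_CUT_YEARS = 65.0
DURATION_CUT_YEARS = 6.0


@dataclass(frozen=True)
class StratumDefinition:
    """A binary split of patients on one clinical variable.

    ``age_at_onset``: early iff onset <= cut (default 65), late otherwise.
    ``disease_duration``: short iff duration < cut (default 6), long
    otherwise — note the asymmetry: the onset boundary belongs to the
    early stratum, the duration boundary to the long one.
    """

    variable: str  # "age_at_onset" | "disease_duration"
    cut: float = field(default=math.nan)
    side_labels: tuple[str, str] = field(default=("", ""))

    def __post_init__(self):
        if self.variable not in ("age_at_onset", "disease_duration"):
            raise ValidationError(f"unknown stratification variable {self.variable!r}")
        if math.isnan(self.cut):
            cut = ONSET_CUT_YEARS if self.variable == "age_at_onset" else DURATION_CUT_YEARS
            object.__setattr__(self, "cut", cut)
        if self.cut <= 0:
            raise ValidationError("stratification cut must be positive")
        if self.side_labels == ("", ""):
            labels = (
                ("early_onset", "late_onset")
                if self.variable == "age_at_onset"
                else ("short_duration", "long_duration")
            )
            object.__setattr__(self, "side_labels", labels)

    def value_of(self, s: SampleRecord) -> float | None:
        v = (
            s.age_at_onset_years
            if self.variable == "age_at_onset"
            else s.disease_duration_years
        )
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    def side(self, value: float) -> str:
        if self.variable == "age_at_onset":
            return self.side_labels[0] if value <= self.cut else self.side_labels[1]
        return self.side_labels[0] if value < self.cut else self.side_labels[1]


@dataclass(frozen=True)
class PatientExpression:
    """One patient's fold change vs the control-group mean dCt."""

    subject_id: str
    target: str
    rq: float  # 2^-(dCt_patient - mean control dCt), reference-averaged
    age_years: float | None = None
    age_at_onset_years: float | None = None
    disease_duration_years: float | None = None
    sex: str = "unknown"

    def covariate(self, name: str) -> float | None:
        v = {
            "age": self.age_years,
            "age_at_onset": self.age_at_onset_years,
            "disease_duration": self.disease_duration_years,
        }[name]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)


@dataclass(frozen=True)
class RegressionResult:
    """OLS of log2 expression on a clinical covariate."""

    target: str
    covariate: str
    slope: float  # per year, on the log2 scale
    intercept: float
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class StratifiedComparison:
    """Two strata with their clinical contrast and expression estimates."""

    definition: StratumDefinition
    n: tuple[int, int]
    compared_variable: str
    means: tuple[float, float]
    ranges: tuple[tuple[float, float], tuple[float, float]]
    t_statistic: float
    p_value: float
    per_stratum: tuple[RelativeExpression, RelativeExpression]
    between: RelativeExpression  # stratum-vs-stratum contrast


# ---------------------------------------------------------------------------
# per-patient expression
# ---------------------------------------------------------------------------

def per_patient_expression(
    patient_dct: float, control_dcts: Sequence[float]
) -> float:
    """Fold change of one patient vs the mean control dCt: 2^-(dCt - mean)."""
    if len(control_dcts) == 0:
        raise InsufficientDataError("control dCt list is empty")
    return 2.0 ** -(float(patient_dct) - float(np.mean(control_dcts)))


def patient_expression_table(
    samples: Sequence[SampleRecord],
    measurements: Sequence[CtMeasurement],
    panel: AssayPanel,
    target: str,
    control_group: str = "CTRL",
    include_controls: bool = False,
) -> list[PatientExpression]:
    """Per-patient relative expression for one target.

    Each patient's rq is computed against the mean control dCt for every
    reference gene separately and the per-reference values are averaged
    arithmetically, mirroring how group estimates combine references.
    """
    means = quant.mean_ct_table(measurements)
    controls = [s for s in samples if s.group == control_group]
    if not controls:
        raise InsufficientDataError(f"no {control_group} samples in dataset")
    patients = [s for s in samples if s.group != control_group]
    if include_controls:
        patients = list(samples)
    out: list[PatientExpression] = []
    for s in patients:
        per_ref: list[float] = []
        for ref in panel.references:
            ctrl_dct = quant.sample_delta_cts(controls, means, target, ref)
            own = quant.sample_delta_cts([s], means, target, ref)
            if not own or not ctrl_dct:
                continue
            per_ref.append(
                per_patient_expression(own[s.sample_id], list(ctrl_dct.values()))
            )
        if not per_ref:
            logger.warning(
                "subject %s lacks usable %s measurements, skipped", s.subject_id, target
            )
            continue
        out.append(
            PatientExpression(
                subject_id=s.subject_id,
                target=target,
                rq=float(np.mean(per_ref)),
                age_years=s.age_years,
                age_at_onset_years=s.age_at_onset_years,
                disease_duration_years=s.disease_duration_years,
                sex=s.sex,
            )
        )
    return out


# ---------------------------------------------------------------------------
# stratification and tests
# ---------------------------------------------------------------------------

def stratify(
    patients: Sequence[SampleRecord], defn: StratumDefinition
) -> dict[str, list[SampleRecord]]:
    """Split patients into the two labelled strata of ``defn``.

    Exhaustive and mutually exclusive over patients with a non-missing
    stratification value; patients missing it are dropped with a warning.
    """
    strata: dict[str, list[SampleRecord]] = {
        defn.side_labels[0]: [],
        defn.side_labels[1]: [],
    }
    for p in patients:
        v = defn.value_of(p)
        if v is None:
            logger.warning(
                "patient %s: %s missing, excluded from stratification",
                p.subject_id, defn.variable,
            )
            continue
        strata[defn.side(v)].append(p)
    return strata


def compare_strata(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test between two strata.

    Returns (t, p).  Degenerate case: both groups constant with equal
    means gives t = 0, p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"t-test needs n >= 2 per group, got {a.size} and {b.size}"
        )
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def regress_expression(
    patients: Sequence[PatientExpression],
    covariate: str,
    log_scale: bool = True,
) -> RegressionResult:
    """OLS of log2(rq) (or rq if ``log_scale=False``) on a covariate.

    Expression changes act multiplicatively, so the log2 scale is the
    default response.  Patients missing the covariate are excluded,
    never imputed.
    """
    pts = [(p.covariate(covariate), p.rq) for p in patients]
    pts = [(x, rq) for x, rq in pts if x is not None]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"regression on {covariate} needs >= 3 patients, got {len(pts)}"
        )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if log_scale:
        y = np.log2(y)
    if np.all(x == x[0]):
        raise DegenerateDesignError(f"covariate {covariate} is constant")
    fit = stats.linregress(x, y)
    target = patients[0].target if patients else ""
    return RegressionResult(
        target=target,
        covariate=covariate,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=len(pts),
    )


# ---------------------------------------------------------------------------
# stratified expression analysis
# ---------------------------------------------------------------------------

_OTHER_VARIABLE = {
    "age_at_onset": "disease_duration_years",
    "disease_duration": "age_at_onset_years",
}


def stratified_expression(
    samples: Sequence[SampleRecord],
    measurements: Sequence[CtMeasurement],
    defn: StratumDefinition,
    panel: AssayPanel,
    target: str,
    thresholds: Thresholds = Thresholds(),
    control_group: str = "CTRL",
    baseline: str = "auto",
) -> StratifiedComparison:
    """Stratum-level expression vs controls plus a stratum-vs-stratum contrast.

    Each stratum gets the usual combined-reference estimate against the
    control group.  The between-stratum contrast applies the same
    delta-delta-Ct machinery with one stratum standing in as baseline:
    ``baseline="auto"`` (default) takes the stratum with larger mean
    expression (smaller mean dCt) so the contrast reads as a fold <= 1,
    ``baseline="second"``/``"first"`` fix the baseline explicitly.  The
    clinical contrast reported alongside is a Welch t-test on the
    complementary covariate (duration when stratifying by onset, and
    vice versa).
    """
    if baseline not in ("auto", "first", "second"):
        raise ValidationError(f"unknown baseline policy {baseline!r}")
    controls = [s for s in samples if s.group == control_group]
    patients = [s for s in samples if s.group != control_group]
    strata = stratify(patients, defn)
    labels = defn.side_labels
    for lab in labels:
        if not strata[lab]:
            raise InsufficientDataError(f"stratum {lab!r} is empty")

    means = quant.mean_ct_table(measurements)
    per_stratum = tuple(
        quant.group_estimate(
            strata[lab], controls, means, target, panel, thresholds,
            tissue=samples[0].tissue if samples else "",
            case_label=lab,
        )
        for lab in labels
    )

    # between-stratum contrast: pick the baseline stratum
    mean_dct = []
    for lab in labels:
        vals: list[float] = []
        for ref in panel.references:
            vals.extend(
                quant.sample_delta_cts(strata[lab], means, target, ref).values()
            )
        mean_dct.append(float(np.mean(vals)))
    if baseline == "auto":
        # larger expression == smaller mean dCt
        base_idx = 0 if mean_dct[0] <= mean_dct[1] else 1
    else:
        base_idx = 0 if baseline == "first" else 1
    case_idx = 1 - base_idx
    per_ref: list[RelativeExpression] = []
    for ref in panel.references:
        case_dct = quant.sample_delta_cts(strata[labels[case_idx]], means, target, ref)
        base_dct = quant.sample_delta_cts(strata[labels[base_idx]], means, target, ref)
        est = quant.compute_group_ddct(
            list(case_dct.values()), list(base_dct.values()),
            target=target, reference=ref,
            case_group=labels[case_idx], control_group=labels[base_idx],
        )
        per_ref.append(
            quant.relative_expression(est, tissue=samples[0].tissue if samples else "")
        )
    between = quant.classified(quant.combine_references(per_ref), thresholds)

    # clinical contrast on the complementary covariate
    other = _OTHER_VARIABLE[defn.variable]
    vals_by_stratum = []
    for lab in labels:
        vs = [getattr(p, other) for p in strata[lab]]
        vs = [float(v) for v in vs if v is not None and not math.isnan(float(v))]
        vals_by_stratum.append(vs)
    try:
        t, p = compare_strata(*vals_by_stratum)
    except InsufficientDataError:
        t, p = math.nan, math.nan
    means_rng = [
        (float(np.mean(v)), (min(v), max(v))) if v else (math.nan, (math.nan, math.nan))
        for v in vals_by_stratum
    ]
    return StratifiedComparison(
        definition=defn,
        n=(len(strata[labels[0]]), len(strata[labels[1]])),
        compared_variable=other,
        means=(means_rng[0][0], means_rng[1][0]),
        ranges=(means_rng[0][1], means_rng[1][1]),
        t_statistic=t,
        p_value=p,
        per_stratum=per_stratum,  # type: ignore[arg-type]
        between=between,
    )


def comparison_frame(comparisons: Sequence[StratifiedComparison]) -> pd.DataFrame:
    """Flatten stratified comparisons into a tidy table for reporting."""
    rows = []
    for c in comparisons:
        lab_a, lab_b = c.definition.side_labels
        rows.append({
            "variable": c.definition.variable,
            "cut": c.definition.cut,
            "stratum_a": lab_a,
            "stratum_b": lab_b,
            "n_a": c.n[0],
            "n_b": c.n[1],
            "compared_variable": c.compared_variable,
            "mean_a": c.means[0],
            "mean_b": c.means[1],
            "t_statistic": c.t_statistic,
            "p_value": c.p_value,
            "target": c.between.target,
            "point_a": c.per_stratum[0].point,
            "low_a": c.per_stratum[0].low,
            "high_a": c.per_stratum[0].high,
            "class_a": c.per_stratum[0].classification,
            "point_b": c.per_stratum[1].point,
            "low_b": c.per_stratum[1].low,
            "high_b": c.per_stratum[1].high,
            "class_b": c.per_stratum[1].classification,
            "between_case": c.between.case_group,
            "between_point": c.between.point,
            "between_low": c.between.low,
            "between_high": c.between.high,
            "between_class": c.between.classification,
        })
    return pd.DataFrame(rows)
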