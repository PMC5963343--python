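"""Relative quantification by the comparative-Ct (delta-delta-Ct) method.

The chain implemented here is the classic equal-efficiency workflow:

1. technical replicates are averaged per sample x assay (within run first,
   then across independent runs);
2. dCt = mean Ct(target) - mean Ct(reference) normalises out input amount;
3. ddCt = mean case dCt - mean control dCt;
4. relative expression = 2^-ddCt, with a variance interval obtained by
   evaluating 2^-(ddCt +/- SD), where SD is the sample standard deviation
   of the case dCt values;
5. with two housekeeping references, the per-reference point and bound
   estimates are averaged arithmetically;
6. a change is called *decreased* only if the point estimate is below the
   0.5 threshold and the upper bound does not exceed it, and *increased*
   only if the point is above 1.5 and the lower bound does not fall under
   it — i.e. the whole variance interval must clear the threshold.

Amplification efficiency E is estimated per assay per run from a standard
curve of Ct on log10 dilution (E = 10^(-1/slope) - 1; perfect doubling
gives slope -3.3219 and E = 1) and the equal-efficiency assumption is
checked by comparing target and reference E within a tolerance.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AssayPanel, CtMeasurement, SampleRecord, Thresholds
from .errors import (
    CurveQualityError,
    InsufficientDataError,
    MissingAssayError,
    QCError,
    ValidationError,
)

logger = logging.getLogger(__name__)

LOG2_10 = math.log2(10.0)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardCurveFit:
    """Least-squares line of Ct on log10 dilution for one assay in one run."""

    assay: str
    run_id: str
    slope: float  # cycles per log10 dilution step; negative
    intercept: float  # cycles at dilution 1
    r_squared: float
    efficiency: float  # E = 10^(-1/slope) - 1


@dataclass(frozen=True)
class EfficiencyCheck:
    """Outcome of the equal-efficiency QC between a target and a reference."""

    target_assay: str
    reference_assay: str
    run_id: str
    delta: float  # |E_target - E_reference|
    tolerance: float
    passed: bool


@dataclass(frozen=True)
class DeltaCtSummary:
    """Per-sample normalised Ct: target minus reference mean Ct."""

    sample_id: str
    target: str
    reference: str
    delta_ct: float
    n_replicates: int


@dataclass(frozen=True)
class DdctEstimate:
    """Group-level ddCt with its standard deviation (cycles)."""

    target: str
    reference: str
    case_group: str
    control_group: str
    ddct: float
    sd: float
    n_case: int
    n_control: int


@dataclass(frozen=True)
class RelativeExpression:
    """Fold-change point estimate with variance bounds and significance call.

    ``point = 2^-ddCt``, ``low = 2^-(ddCt+SD)``, ``high = 2^-(ddCt-SD)``;
    for a single-reference estimate the bounds are geometrically symmetric
    around the point (point^2 = low * high).
    """

    target: str
    case_group: str
    tissue: str
    point: float
    low: float
    high: float
    references_used: tuple[str, ...]
    classification: str = "unclassified"
    n_case: int = 0
    n_control: int = 0
    efficiency_flagged: bool = False


# ---------------------------------------------------------------------------
# replicate aggregation
# ---------------------------------------------------------------------------

def aggregate_replicates(
    measurements: Sequence[CtMeasurement],
) -> tuple[float, float, int]:
    """Aggregate the well readings of one sample x assay into (mean, sd, n).

    Replicates are averaged within each run first and the run means are
    then averaged (each independent run gets equal weight regardless of
    how many of its replicates were detected).  The reported SD is the
    sample standard deviation over *all* detected replicate values, so
    run-to-run shifts widen it alongside pipetting noise.  Undetected
    wells are excluded and do not count toward ``n``.

    Raises
    ------
    MissingAssayError
        If no replicate was detected.
    """
    if not measurements:
        raise MissingAssayError("no measurements supplied")
    keys = {(m.sample_id, m.assay) for m in measurements}
    if len(keys) > 1:
        raise ValidationError(
            f"measurements span several sample x assay combinations: {sorted(keys)}"
        )
    by_run: dict[str, list[float]] = {}
    n_undetected = 0
    for m in measurements:
        if m.detected:
            by_run.setdefault(m.run_id, []).append(m.ct)
        else:
            n_undetected += 1
    if not by_run:
        sample_id, assay = next(iter(keys))
        raise MissingAssayError(
            f"assay {assay} undetected in every replicate for sample {sample_id}"
        )
    if n_undetected:
        sample_id, assay = next(iter(keys))
        logger.warning(
            "sample %s assay %s: %d undetected replicate(s) excluded",
            sample_id, assay, n_undetected,
        )
    run_means = [float(np.mean(v)) for v in by_run.values()]
    detected = [ct for v in by_run.values() for ct in v]
    mean_ct = float(np.mean(run_means))
    sd_ct = float(np.std(detected, ddof=1)) if len(detected) > 1 else 0.0
    return mean_ct, sd_ct, len(detected)


# ---------------------------------------------------------------------------
# standard curves and efficiency
# ---------------------------------------------------------------------------

def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency E = 10^(-1/slope) - 1 for a negative slope."""
    if slope >= 0:
        raise CurveQualityError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(
    series: Iterable[tuple[float, float]],
    assay: str,
    run_id: str = "",
) -> StandardCurveFit:
    """Fit Ct = intercept + slope * log10(dilution) by ordinary least squares.

    ``series`` holds (log10_dilution, ct) pairs from a serial dilution of a
    common calibrator sample; at least three distinct dilution points are
    required.  A non-negative slope (no amplification gain with template)
    raises :class:`CurveQualityError`.
    """
    pts = [(float(x), float(y)) for x, y in series]
    if len({x for x, _ in pts}) < 3:
        raise InsufficientDataError(
            f"standard curve for {assay}/{run_id}: need >= 3 distinct "
            f"dilution points, got {len({x for x, _ in pts})}"
        )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise CurveQualityError(
            f"standard curve for {assay}/{run_id}: non-negative slope {fit.slope:g}"
        )
    return StandardCurveFit(
        assay=assay,
        run_id=run_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=efficiency_from_slope(float(fit.slope)),
    )


def check_efficiency_similarity(
    target_fit: StandardCurveFit | None,
    reference_fit: StandardCurveFit | None,
    tolerance: float = 0.1,
) -> EfficiencyCheck:
    """Check |E_target - E_reference| <= tolerance for one run.

    The comparative-Ct method assumes near-equal amplification
    efficiencies; a failed check logs a warning so downstream estimates
    can be flagged rather than silently trusted.
    """
    if target_fit is None or reference_fit is None:
        raise QCError("efficiency check needs both a target and a reference fit")
    delta = abs(target_fit.efficiency - reference_fit.efficiency)
    passed = delta <= tolerance
    if not passed:
        logger.warning(
            "efficiency mismatch %s vs %s (run %s): |dE| = %.3f > %.3f",
            target_fit.assay, reference_fit.assay, target_fit.run_id,
            delta, tolerance,
        )
    return EfficiencyCheck(
        target_assay=target_fit.assay,
        reference_assay=reference_fit.assay,
        run_id=target_fit.run_id,
        delta=delta,
        tolerance=tolerance,
        passed=passed,
    )


# ---------------------------------------------------------------------------
# dCt / ddCt / relative expression
# ---------------------------------------------------------------------------

def compute_delta_ct(
    mean_ct_target: float,
    mean_ct_reference: float,
    sample_id: str = "",
    target: str = "",
    reference: str = "",
    n_replicates: int = 1,
) -> DeltaCtSummary:
    """dCt = mean Ct(target) - mean Ct(reference) within one sample."""
    for name, v in (("target", mean_ct_target), ("reference", mean_ct_reference)):
        if v is None or not math.isfinite(v):
            raise MissingAssayError(f"mean Ct for {name} assay is missing")
    return DeltaCtSummary(
        sample_id=sample_id,
        target=target,
        reference=reference,
        delta_ct=float(mean_ct_target) - float(mean_ct_reference),
        n_replicates=n_replicates,
    )


def compute_group_ddct(
    case_dcts: Sequence[float],
    control_dcts: Sequence[float],
    target: str = "",
    reference: str = "",
    case_group: str = "",
    control_group: str = "CTRL",
) -> DdctEstimate:
    """ddCt = mean(case dCt) - mean(control dCt), with case-group SD.

    The attached SD is the sample standard deviation of the per-sample
    case dCt values; the control group enters through its mean only.
    A single case sample yields sd = 0.
    """
    if len(case_dcts) == 0 or len(control_dcts) == 0:
        raise InsufficientDataError(
            f"ddCt for {target or '?'} ({case_group or '?'} vs "
            f"{control_group}): both groups must be non-empty"
        )
    case = np.asarray(case_dcts, dtype=float)
    ctrl = np.asarray(control_dcts, dtype=float)
    sd = float(np.std(case, ddof=1)) if case.size > 1 else 0.0
    return DdctEstimate(
        target=target,
        reference=reference,
        case_group=case_group,
        control_group=control_group,
        ddct=float(case.mean() - ctrl.mean()),
        sd=sd,
        n_case=int(case.size),
        n_control=int(ctrl.size),
    )


def relative_expression(
    est: DdctEstimate, tissue: str = ""
) -> RelativeExpression:
    """Fold change 2^-ddCt with bounds 2^-(ddCt +/- SD)."""
    if est.sd < 0:
        raise ValidationError("ddCt standard deviation must be >= 0")
    return RelativeExpression(
        target=est.target,
        case_group=est.case_group,
        tissue=tissue,
        point=2.0 ** -est.ddct,
        low=2.0 ** -(est.ddct + est.sd),
        high=2.0 ** -(est.ddct - est.sd),
        references_used=(est.reference,) if est.reference else (),
        n_case=est.n_case,
        n_control=est.n_control,
    )


def combine_references(
    estimates: Sequence[RelativeExpression],
) -> RelativeExpression:
    """Average per-reference estimates into the final expression change.

    The point and both bounds are averaged arithmetically across the
    housekeeping references analysed; the inputs must describe the same
    target, case group and tissue.
    """
    if not estimates:
        raise InsufficientDataError("no per-reference estimates to combine")
    head = estimates[0]
    for e in estimates[1:]:
        if (e.target, e.case_group, e.tissue) != (
            head.target, head.case_group, head.tissue,
        ):
            raise ValidationError(
                "cannot combine estimates for different target/group/tissue: "
                f"{(e.target, e.case_group, e.tissue)} vs "
                f"{(head.target, head.case_group, head.tissue)}"
            )
    refs: tuple[str, ...] = ()
    for e in estimates:
        refs += e.references_used
    return RelativeExpression(
        target=head.target,
        case_group=head.case_group,
        tissue=head.tissue,
        point=float(np.mean([e.point for e in estimates])),
        low=float(np.mean([e.low for e in estimates])),
        high=float(np.mean([e.high for e in estimates])),
        references_used=refs,
        n_case=head.n_case,
        n_control=head.n_control,
        efficiency_flagged=any(e.efficiency_flagged for e in estimates),
    )


def classify_change(
    re: RelativeExpression, thresholds: Thresholds = Thresholds()
) -> str:
    """Significance call from the point estimate and its variance bounds.

    decreased  iff point < decrease_threshold and high <= decrease_threshold;
    increased  iff point > increase_threshold and low >= increase_threshold;
    unchanged  otherwise.  The point comparison is strict, the bound
    comparison inclusive, so a bound sitting exactly on the threshold
    still supports the call.
    """
    t = thresholds
    if re.point < t.decrease_threshold and re.high <= t.decrease_threshold:
        return "decreased"
    if re.point > t.increase_threshold and re.low >= t.increase_threshold:
        return "increased"
    return "unchanged"


def classified(
    re: RelativeExpression, thresholds: Thresholds = Thresholds()
) -> RelativeExpression:
    """Return a copy of ``re`` with its classification filled in."""
    return replace(re, classification=classify_change(re, thresholds))


def isoform_fold_difference(ct_minor: float, ct_major: float) -> float:
    """Abundance ratio between two isoforms in the same sample: 2^(Ct_minor - Ct_major).

    With equal efficiencies each extra cycle means a two-fold lower
    starting amount, so the less expressed isoform (higher Ct) yields a
    ratio >= 1.
    """
    if ct_minor is None or ct_major is None:
        raise MissingAssayError("both Ct values must be detected")
    return 2.0 ** (float(ct_minor) - float(ct_major))


# ---------------------------------------------------------------------------
# dataset-level pipeline
# ---------------------------------------------------------------------------

def mean_ct_table(
    measurements: Sequence[CtMeasurement],
) -> dict[tuple[str, str], tuple[float, float, int]]:
    """Aggregate a measurement collection into {(sample, assay): (mean, sd, n)}.

    Sample x assay combinations whose replicates are all undetected are
    dropped with a warning (the sample simply lacks that assay downstream).
    """
    grouped: dict[tuple[str, str], list[CtMeasurement]] = {}
    for m in measurements:
        grouped.setdefault((m.sample_id, m.assay), []).append(m)
    out: dict[tuple[str, str], tuple[float, float, int]] = {}
    for key, group in grouped.items():
        try:
            out[key] = aggregate_replicates(group)
        except MissingAssayError:
            logger.warning("sample %s assay %s dropped: all wells undetected", *key)
    return out


def sample_delta_cts(
    samples: Sequence[SampleRecord],
    means: Mapping[tuple[str, str], tuple[float, float, int]],
    target: str,
    reference: str,
) -> dict[str, float]:
    """Per-sample dCt for one target/reference pair; samples lacking either
    assay are skipped."""
    out: dict[str, float] = {}
    for s in samples:
        t = means.get((s.sample_id, target))
        r = means.get((s.sample_id, reference))
        if t is None or r is None:
            continue
        out[s.sample_id] = t[0] - r[0]
    return out


def group_estimate(
    case_samples: Sequence[SampleRecord],
    control_samples: Sequence[SampleRecord],
    means: Mapping[tuple[str, str], tuple[float, float, int]],
    target: str,
    panel: AssayPanel,
    thresholds: Thresholds = Thresholds(),
    tissue: str = "",
    case_label: str | None = None,
) -> RelativeExpression:
    """Combined-reference, classified estimate of one group vs its controls."""
    if not control_samples:
        raise InsufficientDataError(f"no control samples for tissue {tissue!r}")
    case_label = case_label or (case_samples[0].group if case_samples else "?")
    per_ref: list[RelativeExpression] = []
    for ref in panel.references:
        case_dct = sample_delta_cts(case_samples, means, target, ref)
        ctrl_dct = sample_delta_cts(control_samples, means, target, ref)
        if not case_dct or not ctrl_dct:
            raise InsufficientDataError(
                f"{target} vs {ref} in {tissue or 'dataset'}: no usable "
                f"dCt values ({len(case_dct)} case, {len(ctrl_dct)} control)"
            )
        est = compute_group_ddct(
            list(case_dct.values()),
            list(ctrl_dct.values()),
            target=target,
            reference=ref,
            case_group=case_label,
        )
        per_ref.append(relative_expression(est, tissue=tissue))
    return classified(combine_references(per_ref), thresholds)


def expression_profile(
    samples: Sequence[SampleRecord],
    measurements: Sequence[CtMeasurement],
    panel: AssayPanel,
    thresholds: Thresholds = Thresholds(),
    control_group: str = "CTRL",
) -> pd.DataFrame:
    """Expression-change table: one row per group x tissue x target.

    Every tissue analysed must contain samples of ``control_group``; each
    row carries the dual-reference point estimate, its variance bounds,
    the log2-scale values used for plotting, and the significance call.
    """
    means = mean_ct_table(measurements)
    tissues = sorted({s.tissue for s in samples})
    rows = []
    for tissue in tissues:
        in_tissue = [s for s in samples if s.tissue == tissue]
        controls = [s for s in in_tissue if s.group == control_group]
        if not controls:
            raise InsufficientDataError(
                f"tissue {tissue!r} has no {control_group} samples"
            )
        case_groups = sorted({s.group for s in in_tissue} - {control_group})
        for group in case_groups:
            cases = [s for s in in_tissue if s.group == group]
            for target in panel.targets:
                re = group_estimate(
                    cases, controls, means, target, panel, thresholds,
                    tissue=tissue, case_label=group,
                )
                rows.append({
                    "group": group,
                    "tissue": tissue,
                    "target": target,
                    "point": re.point,
                    "low": re.low,
                    "high": re.high,
                    "log2_point": math.log2(re.point),
                    "log2_low": math.log2(re.low),
                    "log2_high": math.log2(re.high),
                    "classification": re.classification,
                    "references_used": "+".join(re.references_used),
                    "n_case": re.n_case,
                    "n_control": re.n_control,
                })
    return pd.DataFrame(
        rows,
        columns=[
            "group", "tissue", "target", "point", "low", "high",
            "log2_point", "log2_low", "log2_high", "classification",
            "references_used", "n_case", "n_control",
        ],
    )
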