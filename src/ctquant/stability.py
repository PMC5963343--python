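"""Sample-inclusion QC and RNA degradation-rate comparability.

Post-mortem brain RNA degrades, and the comparative-Ct method is only
trustworthy if target and housekeeping transcripts decay at similar
rates near the inclusion boundary (RIN around 6).  The degradation
assay incubates total RNA at 50 degrees C, withdraws aliquots at fixed
timepoints, and tracks each transcript's remaining amount by qPCR.
Decay is modelled log-linear in time: a least-squares slope of
log2(relative amount) on minutes gives a per-minute log2 decay rate,
and two transcripts are "comparable" when neither rate exceeds the
other by more than a configurable factor (default 2x).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .datamodel import SampleRecord
from .errors import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

#: Incubation schedule of the 50 C time-course (minutes).
DEFAULT_TIMEPOINTS_MIN = (0, 15, 30, 60, 120, 240)


@dataclass(frozen=True)
class DegradationSeries:
    """Relative transcript amount over a 50 C incubation time-course.

    Amounts are fractions of the time-0 amount (so the series starts at
    1); an optional RIN track records integrity at each timepoint.
    """

    assay: str
    sample_id: str
    timepoints_min: tuple[float, ...]
    relative_amount: tuple[float, ...]
    rin_track: tuple[float, ...] | None = None

    def __post_init__(self):
        t = tuple(float(x) for x in self.timepoints_min)
        a = tuple(float(x) for x in self.relative_amount)
        object.__setattr__(self, "timepoints_min", t)
        object.__setattr__(self, "relative_amount", a)
        if len(t) != len(a):
            raise ValidationError("timepoints and amounts differ in length")
        if any(t2 <= t1 for t1, t2 in zip(t, t[1:])):
            raise ValidationError("timepoints must be strictly increasing")
        if t and t[0] != 0:
            raise ValidationError("series must start at time 0")
        if any(x <= 0 for x in a):
            raise ValidationError("relative amounts must be positive")
        if a and abs(a[0] - 1.0) > 1e-9:
            raise ValidationError("relative amount at time 0 must equal 1")
        if self.rin_track is not None:
            object.__setattr__(
                self, "rin_track", tuple(float(x) for x in self.rin_track)
            )


@dataclass(frozen=True)
class StabilityVerdict:
    """Comparability of one target's decay rate with one reference's."""

    target_assay: str
    reference_assay: str
    rate_target: float  # per-minute log2 decay, <= 0 for a decaying transcript
    rate_reference: float
    comparable: bool
    rate_ratio: float


def series_from_ct(
    assay: str,
    sample_id: str,
    timepoints_min: Sequence[float],
    ct_values: Sequence[float],
    rin_track: Sequence[float] | None = None,
) -> DegradationSeries:
    """Build a series from raw time-course Ct values.

    The relative amount at time t is 2^(Ct_0 - Ct_t): each extra cycle
    relative to the unincubated aliquot means half the template survived.
    """
    ct = [float(x) for x in ct_values]
    if not ct:
        raise ValidationError("empty Ct series")
    amounts = [2.0 ** (ct[0] - c) for c in ct]
    return DegradationSeries(
        assay=assay,
        sample_id=sample_id,
        timepoints_min=tuple(timepoints_min),
        relative_amount=tuple(amounts),
        rin_track=tuple(rin_track) if rin_track is not None else None,
    )


def filter_by_rin(
    samples: Sequence[SampleRecord], min_rin: float = 6.0
) -> tuple[list[SampleRecord], list[SampleRecord]]:
    """Partition samples into (kept, excluded) by the RIN inclusion rule.

    Kept iff RIN is strictly greater than ``min_rin``; samples with a
    missing RIN are excluded with a logged warning.  The partition is
    exhaustive: every input lands in exactly one list.
    """
    kept: list[SampleRecord] = []
    excluded: list[SampleRecord] = []
    for s in samples:
        rin = s.rin
        if rin is None or (isinstance(rin, float) and math.isnan(rin)):
            logger.warning("sample %s: RIN missing, excluded", s.sample_id)
            excluded.append(s)
        elif rin > min_rin:
            kept.append(s)
        else:
            excluded.append(s)
    return kept, excluded


def degradation_rate(series: DegradationSeries) -> float:
    """Per-minute log2 decay rate: OLS slope of log2(amount) on time.

    Exact (zero residual) on a perfectly log-linear series.  A positive
    slope — the transcript apparently gaining material over the
    incubation — is physically implausible and logged as a warning, but
    returned as-is so the caller can inspect it.
    """
    t = np.asarray(series.timepoints_min, dtype=float)
    if t.size < 3:
        raise InsufficientDataError(
            f"degradation series for {series.assay}: need >= 3 timepoints, got {t.size}"
        )
    y = np.log2(np.asarray(series.relative_amount, dtype=float))
    fit = stats.linregress(t, y)
    rate = float(fit.slope)
    if rate > 0:
        logger.warning(
            "degradation series %s/%s: positive decay rate %.4g (flagged)",
            series.assay, series.sample_id, rate,
        )
    return rate


def compare_stability(
    target_rate: float,
    reference_rate: float,
    max_ratio: float = 2.0,
    target_assay: str = "target",
    reference_assay: str = "reference",
) -> StabilityVerdict:
    """Decide whether two decay rates are similar enough for normalisation.

    Comparable iff neither absolute rate exceeds ``max_ratio`` times the
    other — a symmetric criterion, so swapping target and reference never
    changes the verdict.  Two exactly-zero rates (nothing decayed) are
    trivially comparable.
    """
    if max_ratio < 1.0:
        raise ValidationError("max_ratio must be >= 1")
    at, ar = abs(target_rate), abs(reference_rate)
    if at == 0.0 and ar == 0.0:
        comparable = True
        ratio = 1.0
    elif ar == 0.0 or at == 0.0:
        comparable = False
        ratio = math.inf if ar == 0.0 else 0.0
    else:
        comparable = (at <= max_ratio * ar) and (ar <= max_ratio * at)
        ratio = target_rate / reference_rate
    return StabilityVerdict(
        target_assay=target_assay,
        reference_assay=reference_assay,
        rate_target=target_rate,
        rate_reference=reference_rate,
        comparable=comparable,
        rate_ratio=ratio,
    )
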