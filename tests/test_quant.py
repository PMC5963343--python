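"""Unit tests for the delta-delta-Ct quantification core."""
import math

import numpy as np
import pytest

from ctquant.datamodel import Thresholds
from ctquant.errors import (
    CurveQualityError,
    InsufficientDataError,
    MissingAssayError,
    QCError,
    ValidationError,
)
from ctquant import quant
from ctquant.quant import (
    DdctEstimate,
    RelativeExpression,
    aggregate_replicates,
    check_efficiency_similarity,
    classify_change,
    combine_references,
    compute_delta_ct,
    compute_group_ddct,
    expression_profile,
    fit_standard_curve,
    isoform_fold_difference,
    relative_expression,
)

from conftest import make_ct, noiseless_dataset, make_sample


# ---------------------------------------------------------------------------
# replicate aggregation
# ---------------------------------------------------------------------------

class TestAggregateReplicates:
    def test_identical_replicates(self):
        ms = [make_ct("s1", "GBAtv1", 24.0, replicate=k) for k in (1, 2)]
        assert aggregate_replicates(ms) == (24.0, 0.0, 2)

    def test_sample_sd_of_three_replicates(self):
        ms = [make_ct("s1", "GBAtv1", ct, replicate=k)
              for k, ct in enumerate([23.8, 24.2, 24.0], start=1)]
        mean, sd, n = aggregate_replicates(ms)
        assert mean == pytest.approx(24.0)
        assert sd == pytest.approx(0.2)
        assert n == 3

    def test_all_undetected_is_missing_assay(self):
        ms = [make_ct("s1", "GBAtv1", None, replicate=k) for k in (1, 2)]
        with pytest.raises(MissingAssayError):
            aggregate_replicates(ms)

    def test_undetected_wells_excluded_from_mean_and_n(self):
        ms = [make_ct("s1", "GBAtv1", 24.0, replicate=1),
              make_ct("s1", "GBAtv1", None, replicate=2)]
        assert aggregate_replicates(ms) == (24.0, 0.0, 1)

    def test_runs_weighted_equally_despite_unequal_replicates(self):
        # run1 has mean 20 (two wells), run2 mean 26 (one well):
        # hierarchical mean is 23, not the pooled 22.
        ms = [make_ct("s1", "GBAtv1", 20.0, run_id="run1", replicate=1),
              make_ct("s1", "GBAtv1", 20.0, run_id="run1", replicate=2),
              make_ct("s1", "GBAtv1", 26.0, run_id="run2", replicate=1)]
        mean, sd, n = aggregate_replicates(ms)
        assert mean == pytest.approx(23.0)
        assert n == 3
        assert sd == pytest.approx(np.std([20.0, 20.0, 26.0], ddof=1))

    def test_mixed_sample_assay_rejected(self):
        ms = [make_ct("s1", "GBAtv1", 24.0), make_ct("s2", "GBAtv1", 24.0, replicate=2)]
        with pytest.raises(ValidationError):
            aggregate_replicates(ms)


# ---------------------------------------------------------------------------
# standard curves and efficiency
# ---------------------------------------------------------------------------

class TestStandardCurve:
    @staticmethod
    def series(slope, n=5, intercept=25.0):
        return [(-float(i), intercept - slope * i) for i in range(n)]
        # log10_dilution 0, -1, ... with ct = intercept + slope*log10_d

    def test_perfect_doubling_slope_gives_unit_efficiency(self):
        fit = fit_standard_curve(self.series(-3.321928094887362), "ACTB", "run1")
        assert fit.efficiency == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(-3.321928094887362)

    def test_slope_minus_3_6_efficiency(self):
        fit = fit_standard_curve(self.series(-3.6), "ACTB", "run1")
        assert fit.efficiency == pytest.approx(0.8957356524063758, abs=1e-9)

    def test_two_points_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_standard_curve([(0.0, 25.0), (-1.0, 28.3)], "ACTB")

    def test_non_negative_slope_rejected(self):
        with pytest.raises(CurveQualityError):
            fit_standard_curve([(0.0, 25.0), (-1.0, 24.0), (-2.0, 23.0)], "ACTB")

    @pytest.mark.parametrize("e_t, e_r, tol, passed, delta", [
        (1.00, 1.00, 0.1, True, 0.0),
        (1.00, 0.85, 0.1, False, 0.15),
        (1.00, 0.95, 0.1, True, 0.05),
    ])
    def test_efficiency_similarity(self, e_t, e_r, tol, passed, delta):
        def fit_for(e):
            slope = -1.0 / math.log10(1.0 + e)
            return fit_standard_curve(self.series(slope), "X", "run1")

        chk = check_efficiency_similarity(fit_for(e_t), fit_for(e_r), tolerance=tol)
        assert chk.passed is passed
        assert chk.delta == pytest.approx(delta, abs=1e-9)

    def test_missing_fit_is_qc_error(self):
        with pytest.raises(QCError):
            check_efficiency_similarity(None, None)


# ---------------------------------------------------------------------------
# dCt / ddCt / relative expression
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("t, r, expected", [
    (25.0, 20.0, 5.0), (20.0, 20.0, 0.0), (19.0, 22.5, -3.5),
])
def test_compute_delta_ct(t, r, expected):
    assert compute_delta_ct(t, r).delta_ct == pytest.approx(expected)


def test_compute_delta_ct_missing_mean():
    with pytest.raises(MissingAssayError):
        compute_delta_ct(float("nan"), 20.0)


class TestGroupDdct:
    def test_case_mean_minus_control_mean_with_case_sd(self):
        est = compute_group_ddct([5.0, 5.2, 5.4], [4.0, 4.0])
        assert est.ddct == pytest.approx(1.2)
        assert est.sd == pytest.approx(0.2)
        assert (est.n_case, est.n_control) == (3, 2)

    def test_identical_groups_give_zero(self):
        est = compute_group_ddct([4.0, 4.5], [4.0, 4.5])
        assert est.ddct == pytest.approx(0.0)

    def test_empty_case_list_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_group_ddct([], [4.0])

    def test_single_case_sample_has_zero_sd(self):
        assert compute_group_ddct([5.0], [4.0]).sd == 0.0


class TestRelativeExpression:
    @pytest.mark.parametrize("ddct, sd, point, low, high", [
        (0.0, 0.0, 1.0, 1.0, 1.0),
        (1.2, 0.2, 0.43527528164806206, 0.37892914162759955, 0.5),
        (-1.0, 0.0, 2.0, 2.0, 2.0),
    ])
    def test_point_and_bounds(self, ddct, sd, point, low, high):
        est = DdctEstimate("GBAtv1", "ACTB", "PD", "CTRL", ddct, sd, 3, 3)
        re = relative_expression(est)
        assert re.point == pytest.approx(point, abs=1e-12)
        assert re.low == pytest.approx(low, abs=1e-12)
        assert re.high == pytest.approx(high, abs=1e-12)

    def test_negative_sd_rejected(self):
        est = DdctEstimate("GBAtv1", "ACTB", "PD", "CTRL", 0.0, -0.1, 3, 3)
        with pytest.raises(ValidationError):
            relative_expression(est)


def _re(point, low, high, target="GBAtv1", group="PD", tissue="blood", refs=("ACTB",)):
    return RelativeExpression(
        target=target, case_group=group, tissue=tissue,
        point=point, low=low, high=high, references_used=refs,
    )


class TestCombineReferences:
    def test_single_input_identity(self):
        re = _re(0.4, 0.3, 0.5)
        out = combine_references([re])
        assert (out.point, out.low, out.high) == (0.4, 0.3, 0.5)
        assert out.references_used == ("ACTB",)

    def test_arithmetic_mean_of_components(self):
        out = combine_references([
            _re(0.4, 0.35, 0.45), _re(0.5, 0.41, 0.61, refs=("PBGD",)),
        ])
        assert out.point == pytest.approx(0.45)
        assert out.low == pytest.approx(0.38)
        assert out.high == pytest.approx(0.53)
        assert out.references_used == ("ACTB", "PBGD")

    def test_mismatched_targets_rejected(self):
        with pytest.raises(ValidationError):
            combine_references([_re(0.4, 0.3, 0.5), _re(0.4, 0.3, 0.5, target="GBAtv2")])


class TestClassifyChange:
    @pytest.mark.parametrize("triple, expected", [
        # whole variance interval below 0.5 -> significant decrease
        ((0.41, 0.38, 0.44), "decreased"),
        ((0.35, 0.32, 0.39), "decreased"),
        ((0.38, 0.29, 0.49), "decreased"),
        ((0.27, 0.14, 0.49), "decreased"),
        ((0.35, 0.23, 0.49), "decreased"),
        ((0.41, 0.38, 0.45), "decreased"),
        ((0.36, 0.34, 0.37), "decreased"),
        # point below 0.5 but upper bound above it -> not significant
        ((0.41, 0.30, 0.58), "unchanged"),
        ((0.44, 0.34, 0.61), "unchanged"),
        ((0.55, 0.43, 0.71), "unchanged"),
        ((0.64, 0.58, 0.73), "unchanged"),
        # whole interval above 1.5 -> significant increase
        ((1.90, 1.54, 2.66), "increased"),
        ((1.0, 1.0, 1.0), "unchanged"),
        # boundary: inclusive on the bound, strict on the point
        ((0.49, 0.40, 0.50), "decreased"),
        ((0.5, 0.4, 0.5), "unchanged"),
        ((1.51, 1.50, 2.0), "increased"),
        ((1.5, 1.5, 2.0), "unchanged"),
    ])
    def test_significance_rule(self, triple, expected):
        assert classify_change(_re(*triple)) == expected

    def test_custom_thresholds(self):
        t = Thresholds(decrease_threshold=0.3, increase_threshold=2.0)
        assert classify_change(_re(0.41, 0.38, 0.44), t) == "unchanged"
        assert classify_change(_re(0.2, 0.1, 0.3), t) == "decreased"


class TestIsoformFoldDifference:
    @pytest.mark.parametrize("minor, major, expected", [
        (24.0, 24.0, 1.0),
        (25.0, 24.0, 2.0),
        (27.32, 24.0, 9.986644391212895),
    ])
    def test_two_to_the_cycle_difference(self, minor, major, expected):
        assert isoform_fold_difference(minor, major) == pytest.approx(expected)

    def test_undetected_input_rejected(self):
        with pytest.raises(MissingAssayError):
            isoform_fold_difference(None, 24.0)


# ---------------------------------------------------------------------------
# dataset-level profile
# ---------------------------------------------------------------------------

class TestExpressionProfile:
    def test_null_dataset_all_unchanged(self, dual_panel):
        samples, cts = noiseless_dataset([0.0] * 5, [0.0] * 5, dual_panel)
        prof = expression_profile(samples, cts, dual_panel)
        assert set(prof["classification"]) == {"unchanged"}
        assert prof["point"].tolist() == pytest.approx([1.0])

    def test_true_fold_recovered_and_classified(self, dual_panel):
        # cases sit log2(1/0.3) cycles above controls -> fold 0.3
        offset = math.log2(1.0 / 0.3)
        samples, cts = noiseless_dataset([offset] * 5, [0.0] * 5, dual_panel)
        prof = expression_profile(samples, cts, dual_panel)
        assert prof.loc[0, "point"] == pytest.approx(0.3, abs=1e-12)
        assert prof.loc[0, "classification"] == "decreased"
        assert prof.loc[0, "log2_point"] == pytest.approx(math.log2(0.3))

    def test_tissue_without_controls_rejected(self, dual_panel):
        samples, cts = noiseless_dataset([0.0] * 3, [0.0] * 3, dual_panel)
        pons_samples = [make_sample("p1", group="PDND", tissue="pons",
                                    cohort_arm="brain")]
        pons_cts = [make_ct("p1", a, 24.0) for a in dual_panel.assays]
        with pytest.raises(InsufficientDataError):
            expression_profile(samples + pons_samples, cts + pons_cts, dual_panel)
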