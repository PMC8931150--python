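"""Standard curves, efficiency, calibrator selection, and Pfaffl CNV."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cnvsex.qpcr_quant import (
    CtRecord, DeltaCtPair, NoAmplificationError, NoCalibratorError,
    SlopeRuleError, StandardCurve, efficiency_from_slope, fit_standard_curve,
    mean_ct, pfaffl_cnv, qpcr_pipeline, select_calibrator,
    validate_slope_difference,
)

DILUTION_NG = (20.0, 10.0, 5.0, 2.5, 1.25)


def _curve(slope, intercept):
    factor, eff = efficiency_from_slope(slope)
    return StandardCurve(slope=slope, y_intercept=intercept, r_squared=1.0,
                         efficiency_percent=eff, amplification_factor=factor)


def _line_points(slope, intercept, masses=DILUTION_NG):
    return [(m, intercept + slope * math.log10(m)) for m in masses]


class TestStandardCurve:
    def test_recovers_published_target_curve_exactly(self):
        fit = fit_standard_curve(_line_points(-3.324, 38.476))
        assert fit.slope == pytest.approx(-3.324, abs=1e-9)
        assert fit.y_intercept == pytest.approx(38.476, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.efficiency_percent == pytest.approx(99.9, abs=0.05)

    def test_perfect_doubling_slope(self):
        fit = fit_standard_curve(_line_points(-1 / math.log10(2), 36.5))
        assert fit.efficiency_percent == pytest.approx(100.0, abs=1e-9)
        assert fit.amplification_factor == pytest.approx(2.0, abs=1e-12)

    def test_two_points_fit_perfectly(self):
        fit = fit_standard_curve([(20.0, 34.1), (1.25, 38.1)])
        assert fit.r_squared == pytest.approx(1.0)

    def test_rejects_single_mass(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_standard_curve([(20.0, 34.0), (20.0, 34.1)])

    def test_rejects_non_positive_mass(self):
        with pytest.raises(ValueError, match="positive"):
            fit_standard_curve([(0.0, 38.0), (10.0, 34.0)])

    @given(slope=st.floats(-4.0, -2.9), intercept=st.floats(30, 42))
    def test_efficiency_round_trip_through_fit(self, slope, intercept):
        """Fitting noise-free points generated with a known amplification
        factor recovers that factor to machine precision."""
        fit = fit_standard_curve(_line_points(slope, intercept))
        expected_factor = 10 ** (-1 / slope)
        assert fit.amplification_factor == pytest.approx(expected_factor,
                                                         rel=1e-10)


class TestEfficiency:
    @pytest.mark.parametrize(
        "slope, expected_pct",
        [(-3.324, 99.9), (-3.341, 99.2), (-1 / math.log10(2), 100.0)],
    )
    def test_percent_efficiency_from_slope(self, slope, expected_pct):
        _, eff = efficiency_from_slope(slope)
        assert round(eff, 1) == expected_pct

    def test_rejects_non_negative_slope(self):
        with pytest.raises(ValueError):
            efficiency_from_slope(0.5)


class TestSlopeRule:
    @pytest.mark.parametrize(
        "s_t, s_r, expected_diff, expected_pass",
        [(-3.324, -3.341, 0.017, True), (-3.3, -3.3, 0.0, True),
         (-3.2, -3.5, 0.3, False)],
    )
    def test_difference_and_verdict(self, s_t, s_r, expected_diff, expected_pass):
        diff, ok = validate_slope_difference(_curve(s_t, 38.0), _curve(s_r, 36.0))
        assert diff == pytest.approx(expected_diff, abs=5e-4)
        assert ok is expected_pass


class TestMeanCt:
    def test_clean_triplicate(self):
        mean, sd, flagged = mean_ct([20.9, 21.0, 21.1])
        assert (mean, flagged) == (pytest.approx(21.0), False)
        assert sd == pytest.approx(0.1, abs=1e-9)

    def test_outlier_replicate_flags(self):
        mean, sd, flagged = mean_ct([21.0, 21.0, 24.0])
        assert mean == pytest.approx(22.0)
        assert sd == pytest.approx(math.sqrt(3), rel=1e-9)  # > 0.5-cycle limit
        assert flagged

    def test_missing_replicate_flags_but_averages_rest(self):
        mean, _, flagged = mean_ct([21.0, None, 21.2])
        assert mean == pytest.approx(21.1)
        assert flagged

    def test_all_missing_is_no_amplification(self):
        with pytest.raises(NoAmplificationError, match="F3"):
            mean_ct([None, None, None], specimen="F3", gene="target")


class TestSelectCalibrator:
    def test_known_males_drawn_reproducibly(self):
        cts = {f"S{i}": (22.0, 21.0) for i in range(6)}
        sexes = {"S0": "F", "S1": "M", "S2": "M", "S3": "F", "S4": "M", "S5": "F"}
        picks = {select_calibrator(cts, known_sexes=sexes, seed=7)
                 for _ in range(5)}
        assert len(picks) == 1
        assert picks.pop() in {"S1", "S2", "S4"}

    def test_unknown_sexes_pick_largest_target_lag(self):
        cts = {"a": (21.0, 21.0), "b": (22.0, 21.0), "c": (21.0, 21.0)}
        assert select_calibrator(cts) == "b"

    def test_all_female_run_has_no_calibrator(self):
        cts = {"a": (21.0, 21.0)}
        with pytest.raises(NoCalibratorError):
            select_calibrator(cts, known_sexes={"a": "F"}, seed=0)


class TestPfaffl:
    @pytest.mark.parametrize(
        "e_t, e_r, d_t, d_r, expected",
        [
            (2.0, 2.0, 0.0, 0.0, 1.0),      # calibrator vs itself
            (2.0, 2.0, 1.0, 0.0, 2.0),      # one cycle earlier = doubled
            (1.999, 1.992, 1.0, 0.05, 1.9313),  # direct evaluation
        ],
    )
    def test_examples(self, e_t, e_r, d_t, d_r, expected):
        cnv = pfaffl_cnv(e_t, e_r, DeltaCtPair(d_t, d_r))
        assert cnv == pytest.approx(expected, abs=5e-5)

    def test_rejects_degenerate_efficiency(self):
        with pytest.raises(ValueError):
            pfaffl_cnv(1.0, 2.0, DeltaCtPair(1.0, 0.0))

    @given(e=st.floats(1.8, 2.1), d_t=st.floats(-3, 3), d_r=st.floats(-3, 3))
    def test_equal_efficiencies_reduce_to_single_power(self, e, d_t, d_r):
        cnv = pfaffl_cnv(e, e, DeltaCtPair(d_t, d_r))
        assert cnv == pytest.approx(e ** (d_t - d_r), rel=1e-9)

    @given(d=st.floats(-2, 2), bump=st.floats(0.01, 1))
    def test_monotone_in_deltas(self, d, bump):
        base = pfaffl_cnv(2.0, 2.0, DeltaCtPair(d, 0.0))
        assert pfaffl_cnv(2.0, 2.0, DeltaCtPair(d + bump, 0.0)) > base
        assert pfaffl_cnv(2.0, 2.0, DeltaCtPair(d, 0.0 + bump)) < base


def _noise_free_records(sexes: dict[str, str], run_id="run1", shift=0.0):
    """Ct table under the ideal model: E=2 exactly, 20 ng input."""
    slope_t, int_t = -1 / math.log10(2), 38.476
    slope_r, int_r = -1 / math.log10(2), 36.528
    records = []
    for spec, sex in sexes.items():
        k_t = 2 if sex == "F" else 1
        ct_t = int_t + slope_t * math.log10(20.0 * k_t / 2) + shift
        ct_r = int_r + slope_r * math.log10(20.0) + shift
        for gene, ct in (("target", ct_t), ("reference", ct_r)):
            for tech in (1, 2, 3):
                records.append(CtRecord(spec, gene, 1, tech, ct, run_id))
    return records


class TestQpcrPipeline:
    SEXES = {f"F{i}": "F" for i in range(1, 11)} | {f"M{i}": "M" for i in range(1, 11)}

    def _curves(self):
        e_slope = -1 / math.log10(2)
        return _curve(e_slope, 38.476), _curve(e_slope, 36.528)

    def test_noise_free_run_recovers_exact_copy_numbers(self):
        ct, cr = self._curves()
        results = qpcr_pipeline(_noise_free_records(self.SEXES), ct, cr,
                                calibrator="M1")
        by_spec = {r.specimen_id: r.cnv for r in results}
        for spec, sex in self.SEXES.items():
            assert by_spec[spec] == pytest.approx(2.0 if sex == "F" else 1.0,
                                                  rel=1e-9)

    def test_calibrator_cnv_is_exactly_one(self):
        ct, cr = self._curves()
        results = qpcr_pipeline(_noise_free_records(self.SEXES), ct, cr,
                                calibrator="M7")
        cal = next(r for r in results if r.specimen_id == "M7")
        assert cal.cnv == 1.0
        assert cal.calibrator_id == "M7"

    def test_run_shift_cancels(self):
        """Adding a constant to every Ct of a run (plate offset) leaves all
        CNVs unchanged: calibrator-relative differencing removes it."""
        ct, cr = self._curves()
        base = qpcr_pipeline(_noise_free_records(self.SEXES), ct, cr,
                             calibrator="M1")
        shifted = qpcr_pipeline(_noise_free_records(self.SEXES, shift=2.7),
                                ct, cr, calibrator="M1")
        for a, b in zip(base, shifted):
            assert b.cnv == pytest.approx(a.cnv, rel=1e-9)

    def test_failing_slope_rule_blocks_quantification(self):
        ct = _curve(-3.2, 38.0)
        cr = _curve(-3.6, 36.0)
        with pytest.raises(SlopeRuleError):
            qpcr_pipeline(_noise_free_records(self.SEXES), ct, cr,
                          calibrator="M1")
        # explicit override proceeds
        results = qpcr_pipeline(_noise_free_records(self.SEXES), ct, cr,
                                calibrator="M1", override_slope_rule=True)
        assert len(results) == 20

    def test_auto_calibrator_with_unknown_sexes_is_a_male(self):
        ct, cr = self._curves()
        results = qpcr_pipeline(_noise_free_records(self.SEXES), ct, cr,
                                calibrator="auto")
        cal_ids = {r.calibrator_id for r in results}
        assert len(cal_ids) == 1
        assert self.SEXES[cal_ids.pop()] == "M"
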