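"""Calibration fitting, Cq inversion, positivity calls, strand ratios and
subgenomic-excess verdicts."""

import math

import numpy as np
import pytest

from negevkit import qpcr_quant as qq
from negevkit import synthetic_data as syn
from negevkit.genome_annotation import InputError

PERFECT_SLOPE = -1 / math.log10(2)  # 100% efficiency: one doubling per cycle


def measurement(cqs, melts=None, sample="s", assay="a", strand="positive", region="g"):
    if melts is None:
        melts = [cq is not None for cq in cqs]
    return qq.QpcrMeasurement(sample, assay, strand, region, list(cqs), melts)


class TestCalibration:
    def test_noiseless_recovery_and_perfect_efficiency(self):
        series = [(10.0**k, PERFECT_SLOPE * k + 35.0) for k in range(1, 6)]
        curve = qq.fit_calibration(series)
        assert curve.slope == pytest.approx(PERFECT_SLOPE, abs=1e-9)
        assert curve.intercept == pytest.approx(35.0, abs=1e-9)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-9)
        assert curve.r2 == pytest.approx(1.0, abs=1e-12)
        assert curve.range_log10 == (1.0, 5.0)

    def test_two_points_rejected(self):
        with pytest.raises(InputError):
            qq.fit_calibration([(10.0, 30.0), (100.0, 27.0)])

    def test_zero_concentration_spread_rejected(self):
        with pytest.raises(InputError):
            qq.fit_calibration([(10.0, 30.0), (10.0, 30.1), (10.0, 29.9)])

    def test_displaced_replicate_bounds_slope(self):
        pts = [(10.0, 31.68), (100.0, 28.36), (1000.0, 25.04 + 0.5)]
        curve = qq.fit_calibration(pts)
        pair_slopes = [
            (pts[i][1] - pts[j][1]) / (math.log10(pts[i][0]) - math.log10(pts[j][0]))
            for i, j in [(0, 1), (1, 2), (0, 2)]
        ]
        assert min(pair_slopes) <= curve.slope <= max(pair_slopes)
        assert curve.r2 < 1.0

    def test_round_trip_on_noiseless_series(self):
        series = [(10.0**k, -3.4 * k + 36.0) for k in range(1, 5)]
        curve = qq.fit_calibration(series)
        for copies, cq in series:
            assert qq.cq_to_copies(curve, cq).copies == pytest.approx(copies, rel=1e-9)


class TestCqToCopies:
    def test_intercept_is_one_copy(self, calibration):
        assert qq.cq_to_copies(calibration, 37.0).copies == pytest.approx(1.0)

    def test_one_decade(self):
        curve = qq.CalibrationCurve(PERFECT_SLOPE, 35.0, 1.0, 1.0, (0, 8))
        est = qq.cq_to_copies(curve, 35.0 + PERFECT_SLOPE)
        assert est.copies == pytest.approx(10.0)

    def test_absent_cq_below_detection(self, calibration):
        est = qq.cq_to_copies(calibration, None)
        assert est.below_detection and est.copies is None

    def test_extrapolation_flagged(self, calibration):
        est = qq.cq_to_copies(calibration, 37.0 + 3.32)  # below 1 copy
        assert est.extrapolated


class TestDilutionChain:
    def test_product(self):
        chain = qq.DilutionChain({"a": 20, "b": 5, "c": 10})
        assert qq.copies_per_insect(100.0, chain) == pytest.approx(100_000.0)

    def test_empty_chain_is_identity(self):
        assert qq.copies_per_insect(42.0, qq.DilutionChain()) == 42.0

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(InputError):
            qq.DilutionChain({"a": 0.0})


class TestCallPositive:
    def test_clear_positive(self):
        call = qq.call_positive(measurement([33.8, 34.1, 34.0]))
        assert call.positive and not call.near_threshold

    def test_just_over_threshold_is_negative_with_flag(self):
        call = qq.call_positive(measurement([35.2, 35.4, 35.1]))
        assert not call.positive and call.near_threshold

    def test_exactly_at_threshold_is_negative(self):
        call = qq.call_positive(measurement([35.0, 35.0, 35.0]))
        assert not call.positive

    def test_melt_failures_gate_regardless_of_cq(self):
        call = qq.call_positive(measurement([20.0, 20.0], melts=[False, False]))
        assert not call.positive and call.mean_cq is None

    def test_minority_amplification_is_negative(self):
        call = qq.call_positive(measurement([30.0, None, None]))
        assert not call.positive

    def test_no_replicates_rejected(self):
        with pytest.raises(InputError):
            qq.call_positive(measurement([]))


def panel_from_copies(curve, pairs):
    """Noiseless panel: list of (assay, region, pos_copies, neg_copies|None)."""
    panel = []
    for assay, region, pos, neg in pairs:
        cq_pos = curve.slope * math.log10(pos) + curve.intercept
        panel.append(measurement([cq_pos] * 3, assay=assay, region=region))
        if neg is None:
            panel.append(
                measurement([None] * 3, assay=assay, region=region, strand="negative")
            )
        else:
            cq_neg = curve.slope * math.log10(neg) + curve.intercept
            panel.append(
                measurement([cq_neg] * 3, assay=assay, region=region, strand="negative")
            )
    return panel


class TestStrandRatio:
    def test_uniform_panel_mean_and_sd(self, calibration):
        pairs = [(f"a{k}", "g" if k < 2 else "g_sg", 27500.0, 100.0) for k in range(4)]
        r = qq.strand_ratio(panel_from_copies(calibration, pairs), calibration)
        assert r.mean == pytest.approx(275.0, rel=1e-6)
        assert r.sd == pytest.approx(0.0, abs=1e-6)
        assert r.n_pairs == 4 and r.excluded_pairs == 0

    def test_all_negative_below_detection(self, calibration):
        pairs = [(f"a{k}", "g", 27500.0, None) for k in range(4)]
        r = qq.strand_ratio(panel_from_copies(calibration, pairs), calibration)
        assert r.mean is None and r.excluded_pairs == 4
        assert r.lower_bound is not None and r.lower_bound > 1
        assert "below detection" in r.reason

    def test_scale_invariance(self, calibration):
        pairs1 = [(f"a{k}", "g", 2000.0, 20.0) for k in range(3)]
        pairs2 = [(a, r, p * 7, n * 7) for a, r, p, n in pairs1]
        r1 = qq.strand_ratio(panel_from_copies(calibration, pairs1), calibration)
        r2 = qq.strand_ratio(panel_from_copies(calibration, pairs2), calibration)
        assert r1.mean == pytest.approx(r2.mean, rel=1e-9)

    def test_recovery_bias_under_cq_noise(self, calibration):
        # 100-seed panels at true ratio 275, Cq noise sd 0.15: relative bias < 5%
        estimates = []
        for seed in range(100):
            spec = syn.QpcrSpec(samples={"s": syn.strand_panel(27500.0, 275.0)})
            panel, _ = syn.generate_qpcr(spec, seed=seed)
            estimates.append(qq.strand_ratio(panel, calibration).mean)
        assert abs(np.mean(estimates) / 275.0 - 1) < 0.05


class TestSubgenomicExcess:
    def test_equal_regions_no_evidence(self, calibration):
        pairs = [("a1", "g", 1000.0, 10.0), ("a2", "g", 1000.0, 10.0),
                 ("a3", "g_sg", 1000.0, 10.0), ("a4", "g_sg", 1000.0, 10.0)]
        s = qq.subgenomic_excess(panel_from_copies(calibration, pairs), calibration)
        assert s.excess == pytest.approx(1.0, rel=1e-6)
        assert s.verdict == "no sgRNA evidence"

    def test_tenfold_excess_is_evidence(self, calibration):
        pairs = [("a1", "g", 1000.0, 10.0), ("a2", "g_sg", 10000.0, 10.0)]
        s = qq.subgenomic_excess(panel_from_copies(calibration, pairs), calibration)
        assert s.excess == pytest.approx(10.0, rel=1e-6)
        assert s.verdict == "sgRNA evidence"

    def test_missing_region_undefined(self, calibration):
        pairs = [("a1", "g_sg", 1000.0, 10.0)]
        s = qq.subgenomic_excess(panel_from_copies(calibration, pairs), calibration)
        assert s.verdict == "undefined" and "g" in s.reason


class TestControls:
    def test_amplifying_control_fails_gate(self):
        gate = qq.check_controls([measurement([28.0, 28.2, 28.1], assay="no_rt")])
        assert not gate.clean and gate.failed_controls == ["no_rt"]

    def test_silent_controls_pass(self):
        gate = qq.check_controls([measurement([None, None, None], assay="ntc")])
        assert gate.clean


class TestCsvRoundTrip:
    def test_measurements_survive_csv(self, tmp_path, calibration):
        spec = syn.QpcrSpec(samples={"s": syn.strand_panel(27500.0, 275.0)})
        panel, _ = syn.generate_qpcr(spec, seed=5)
        path = tmp_path / "m.csv"
        syn.measurements_to_csv(panel, path)
        loaded = qq.read_measurements(path)
        r_orig = qq.strand_ratio(panel, calibration)
        r_load = qq.strand_ratio(loaded, calibration)
        assert r_load.mean == pytest.approx(r_orig.mean, rel=1e-9)
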