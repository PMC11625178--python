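"""Calibration fitting, registry constants, and validation statistics."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hemoquant.calibration import (
    FLAG_BELOW_RANGE,
    REGISTRY,
    apply_calibration,
    export_registry_json,
    fit_linear_calibration,
    linearity_assessment,
    lod_loq,
    mean_recovery,
    recovery,
)


class TestFit:
    def test_exact_line(self):
        curve = fit_linear_calibration([1, 2, 3], [3, 5, 7])
        assert curve.slope == pytest.approx(2.0, rel=1e-12)
        assert curve.intercept == pytest.approx(1.0, rel=1e-12)
        assert curve.valid_range == (1.0, 3.0)

    def test_refit_of_published_direct_heme_curve(self):
        # regenerate standards from the 380 nm curve and refit
        pub = REGISTRY["direct_heme_380"]
        levels = np.linspace(10, 40, 7)
        signals = pub.slope * levels + pub.intercept
        refit = fit_linear_calibration(levels, signals)
        assert refit.slope == pytest.approx(0.029, rel=1e-9)
        assert refit.intercept == pytest.approx(-0.170, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_calibration([1, 2], [1, 2])          # too few levels
        with pytest.raises(ValueError):
            fit_linear_calibration([1, 1, 1], [1, 2, 3])    # zero level variance
        with pytest.raises(ValueError):
            fit_linear_calibration([1, 2, 3], [4, 4, 4])    # slope 0 invariant


class TestApply:
    def test_inverts_published_direct_heme_curve(self):
        curve = REGISTRY["direct_heme_380"]
        assert apply_calibration(curve, 0.99).concentration == pytest.approx(40.0, rel=1e-9)
        assert apply_calibration(curve, 0.120).concentration == pytest.approx(10.0, rel=1e-9)

    def test_dilution_scaling_and_assay_side_flags(self):
        curve = REGISTRY["direct_heme_380"]
        res = apply_calibration(curve, 0.120, df=2)
        assert res.concentration == pytest.approx(20.0, rel=1e-9)
        assert res.in_range  # assay-side value is 10 uM, inside 10-40
        assert FLAG_BELOW_RANGE in apply_calibration(curve, 0.0).flags

    @given(c=st.floats(0.5, 50), df=st.sampled_from([1, 2, 4, 8]))
    def test_roundtrip_identity(self, c, df):
        curve = REGISTRY["direct_hb_405"]
        signal = curve.signal_at(c / df)
        res = apply_calibration(curve, signal, df=df)
        assert res.concentration == pytest.approx(c, rel=1e-12)


class TestRegistry:
    def test_registry_read_only(self):
        with pytest.raises(TypeError):
            REGISTRY["direct_heme_380"] = None

    def test_hplc_unit_discrepancy_flagged(self):
        for key in ("hplc_hb", "hplc_heme"):
            entry = REGISTRY[key]
            assert entry.units == "pmol"
            assert "discrepancy" in entry.note

    def test_registry_export(self, tmp_path):
        path = tmp_path / "registry.json"
        export_registry_json(path)
        payload = json.loads(path.read_text())
        assert payload["heme_assay_kit"]["slope"] == 25.64
        assert payload["harboe"] == {"factor": 0.155, "scale": 83.6,
                                     "range_uM": [1.3, 16.5]}


class TestRecovery:
    @pytest.mark.parametrize("true,est,expected", [
        (10, 10, 100.0), (10, 9, 90.0), (4, 5, 125.0),
    ])
    def test_percent_recovery(self, true, est, expected):
        assert recovery(true, est) == pytest.approx(expected)

    def test_undefined_at_zero_truth(self):
        with pytest.raises(ValueError):
            recovery(0.0, 5.0)

    def test_mean_recovery_examples(self):
        assert mean_recovery([10, 20], [10, 20]) == (100.0, 0.0)
        mrr, sd = mean_recovery([10, 10], [9, 11])
        assert mrr == pytest.approx(100.0)
        assert sd == pytest.approx(np.std([90, 110], ddof=1))  # 14.142...
        assert mean_recovery([10], [12]) == (120.0, 0.0)       # n=1: sd undefined -> 0

    def test_mean_recovery_noise_free_is_exact(self, rng):
        curve = REGISTRY["direct_hb_405"]
        levels = rng.uniform(1, 7, size=12)
        estimates = [apply_calibration(curve, curve.signal_at(c)).concentration
                     for c in levels]
        mrr, sd = mean_recovery(levels, estimates)
        assert mrr == pytest.approx(100.0, abs=1e-10)
        assert sd == pytest.approx(0.0, abs=1e-10)


class TestLinearity:
    @staticmethod
    def _make(levels, recoveries, curve):
        # signal so back-calculation returns level * recovery / 100
        return [curve.signal_at(l * r / 100.0) for l, r in zip(levels, recoveries)]

    def test_all_on_line_gives_full_range(self):
        curve = REGISTRY["direct_heme_380"]
        levels = [10, 15, 20, 25, 30, 35, 40]
        res = linearity_assessment(curve, levels, self._make(levels, [100] * 7, curve))
        assert res.linear_range == (10.0, 40.0)
        assert res.verdict

    def test_interior_outlier_splits_range_longer_side_kept(self):
        curve = REGISTRY["direct_heme_380"]
        levels = [10, 15, 20, 25, 30, 35, 40]
        recs = [100, 100, 120, 100, 100, 100, 100]  # 20 % deviation at 20 uM
        res = linearity_assessment(curve, levels, self._make(levels, recs, curve))
        assert res.linear_range == (25.0, 40.0)

    def test_exact_boundary_deviation_passes(self):
        curve = REGISTRY["direct_heme_380"]
        levels = [10, 20, 30, 40]
        recs = [100, 115, 100, 100]  # exactly 15 %
        res = linearity_assessment(curve, levels, self._make(levels, recs, curve))
        assert res.linear_range == (10.0, 40.0)
        assert all(res.passed)

    def test_no_passing_level_fails(self):
        curve = REGISTRY["direct_heme_380"]
        levels = [10, 20, 30]
        res = linearity_assessment(curve, levels, self._make(levels, [130, 70, 130], curve))
        assert res.linear_range is None
        assert not res.verdict

    @given(tol_lo=st.floats(1, 14), tol_hi=st.floats(15, 40))
    def test_monotone_in_tolerance(self, tol_lo, tol_hi):
        curve = REGISTRY["direct_heme_380"]
        levels = [10, 15, 20, 25, 30, 35, 40]
        recs = [100, 108, 88, 100, 113, 95, 100]
        lo = linearity_assessment(curve, levels, self._make(levels, recs, curve), tol_lo)
        hi = linearity_assessment(curve, levels, self._make(levels, recs, curve), tol_hi)
        n_lo = 0 if lo.linear_range is None else sum(lo.passed)
        assert sum(hi.passed) >= n_lo
        if lo.linear_range is not None:
            assert hi.linear_range is not None
            span_lo = lo.linear_range[1] - lo.linear_range[0]
            span_hi = hi.linear_range[1] - hi.linear_range[0]
            assert span_hi >= span_lo


class TestLodLoq:
    def test_closed_forms(self):
        assert lod_loq(0.01, 0.1) == (pytest.approx(0.33), pytest.approx(1.0))
        assert lod_loq(0.0, 0.5) == (0.0, 0.0)
        lod, _ = lod_loq(0.005, 0.029)
        assert lod == pytest.approx(3.3 * 0.005 / 0.029)  # ~0.569 uM

    def test_lod_below_loq_when_noisy(self):
        lod, loq = lod_loq(0.003, 0.158)
        assert 0 < lod < loq

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            lod_loq(0.01, 0.0)
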