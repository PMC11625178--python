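"""Component library, forward models, and panel generator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hemoquant.calibration import PYRIDINE_EPSILON_MM
from hemoquant.quantify import harboe_hb
from hemoquant.spectra import (
    DILUTION_GRID,
    GRID,
    PANEL_STATES,
    AssayReadoutSet,
    MeasuredSpectrum,
    SampleComposition,
    build_component_library,
    hak_signal_at_dilution,
    simulate_assay_readouts,
    simulate_plasma_panel,
    simulate_spectrum,
)


class TestComponentLibrary:
    def test_band_maxima_in_expected_windows(self, library):
        argmax = {
            k: library[k].wavelengths[np.argmax(library[k].specific_absorbance)]
            for k in library
        }
        assert argmax["labile-heme"] == pytest.approx(380, abs=2)
        assert 405 <= argmax["hemoglobin"] <= 415
        assert 450 <= argmax["bilirubin"] <= 460

    def test_all_components_nonnegative(self, library):
        for comp in library.values():
            assert np.all(comp.specific_absorbance >= 0)

    def test_chromophores_vanish_at_700_but_turbidity_does_not(self, library):
        for k in ("labile-heme", "hemoglobin", "bilirubin"):
            assert library[k].at(700.0) < 1e-6
        assert library["turbidity"].at(700.0) > 0.1

    def test_grid_must_cover_requirements(self):
        with pytest.raises(ValueError):
            build_component_library(np.arange(350.0, 701.0))

    def test_harboe_selfconsistency_on_pure_hb(self):
        # amplitude calibration: Harboe must recover pure Hb within 0.1 %
        spec = simulate_spectrum(SampleComposition(c_hb=5.0), sigma=0.0)
        res = harboe_hb(*spec.harboe_triplet())
        assert res.concentration == pytest.approx(5.0, rel=1e-3)
        assert res.concentration == pytest.approx(5.0, abs=0.005)

    def test_harboe_blind_to_heme_and_bilirubin(self):
        for comp in (SampleComposition(c_labile_heme=30.0),
                     SampleComposition(c_bilirubin=200.0)):
            spec = simulate_spectrum(comp, sigma=0.0)
            assert abs(harboe_hb(*spec.harboe_triplet()).concentration) < 1e-9


class TestSimulateSpectrum:
    def test_zero_composition_zero_noise_is_flat_zero(self):
        spec = simulate_spectrum(SampleComposition(), sigma=0.0)
        assert np.all(spec.absorbance == 0.0)

    def test_deterministic_for_fixed_seed(self):
        comp = SampleComposition(c_hb=3.0, c_labile_heme=12.0)
        a = simulate_spectrum(comp, sigma=0.01, seed=5)
        b = simulate_spectrum(comp, sigma=0.01, seed=5)
        assert np.array_equal(a.absorbance, b.absorbance)
        c = simulate_spectrum(comp, sigma=0.01, seed=6)
        assert not np.array_equal(a.absorbance, c.absorbance)

    @given(df=st.sampled_from(DILUTION_GRID))
    def test_dilution_linearity_of_every_channel(self, df):
        comp = SampleComposition(c_labile_heme=10.0, c_hb=4.0,
                                 c_bilirubin=30.0, turbidity_index=0.5)
        base = simulate_spectrum(comp, df=1, sigma=0.0)
        diluted = simulate_spectrum(comp, df=df, sigma=0.0)
        np.testing.assert_allclose(
            diluted.absorbance, base.absorbance / df, rtol=1e-12, atol=0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            simulate_spectrum(SampleComposition(), sigma=-0.1)

    def test_dilution_factor_must_be_on_grid(self):
        with pytest.raises(ValueError):
            simulate_spectrum(SampleComposition(), df=3, sigma=0.0)

    def test_hyperchromic_cross_term_raises_405(self):
        mix = SampleComposition(c_labile_heme=10.0, c_hb=5.0, interaction_coeff=1e-3)
        plain = SampleComposition(c_labile_heme=10.0, c_hb=5.0)
        a = simulate_spectrum(mix, sigma=0.0).at(405.0)
        b = simulate_spectrum(plain, sigma=0.0).at(405.0)
        assert a > b


class TestAssayReadouts:
    def test_zero_composition_signals(self):
        ro = simulate_assay_readouts(SampleComposition(), sigma=0.0)
        assert ro.hak_A400 == 0.0
        assert ro.harboe_triplet == (0.0, 0.0, 0.0)
        # apoHRP keeps the published hemoglobin cross-reactivity blank
        assert ro.apohrp_apparent_heme == pytest.approx(21.86)

    def test_all_signals_nonnegative_at_zero_noise(self, rng):
        for _ in range(25):
            comp = SampleComposition(
                c_labile_heme=float(rng.uniform(0, 50)),
                c_hb=float(rng.uniform(0, 20)),
                c_bilirubin=float(rng.uniform(0, 100)),
                turbidity_index=float(rng.uniform(0, 2)),
            )
            ro = simulate_assay_readouts(comp, sigma=0.0)
            flat = [ro.hak_A400, *ro.harboe_triplet, *ro.pyridine, *ro.sls,
                    ro.apohrp_apparent_heme, *ro.direct]
            assert min(flat) >= 0.0

    def test_pyridine_channel_conserves_heme_equivalents(self, rng):
        # 4 heme per tetramer: the reduced 556 nm channel encodes 4*c_hb + c_labile
        for _ in range(20):
            comp = SampleComposition(
                c_labile_heme=float(rng.uniform(0, 40)),
                c_hb=float(rng.uniform(0, 10)))
            ro = simulate_assay_readouts(comp, sigma=0.0)
            decoded = 1000.0 * ro.pyridine.a556_reduced / PYRIDINE_EPSILON_MM["e556_heme"]
            assert decoded == pytest.approx(comp.c_total_heme, rel=1e-12, abs=1e-12)

    def test_pure_hb_encodes_four_heme_equivalents(self):
        ro = simulate_assay_readouts(SampleComposition(c_hb=5.0), sigma=0.0)
        decoded = 1000.0 * ro.pyridine.a556_reduced / PYRIDINE_EPSILON_MM["e556_heme"]
        assert decoded == pytest.approx(20.0, rel=1e-12)

    def test_hak_channel_inverts_at_blank_offset(self):
        # a zero kit absorbance corresponds to 4.85 uM labile heme at df=1
        ro = simulate_assay_readouts(SampleComposition(c_labile_heme=4.85), sigma=0.0)
        assert ro.hak_A400 == pytest.approx(0.0, abs=1e-15)

    def test_readouts_deterministic(self):
        comp = SampleComposition(c_labile_heme=15.0, c_hb=3.0)
        a = simulate_assay_readouts(comp, sigma=0.005, seed=11)
        b = simulate_assay_readouts(comp, sigma=0.005, seed=11)
        assert a == b

    def test_hak_dilution_acts_on_concentration(self):
        # diluting twice must halve the assay-side concentration, not the signal
        a1 = simulate_assay_readouts(
            SampleComposition(c_labile_heme=30.0), sigma=0.0).hak_A400
        a2 = hak_signal_at_dilution(a1, 2)
        assert 25.64 * a2 + 4.85 == pytest.approx(15.0, rel=1e-12)


class TestPlasmaPanel:
    def test_lipemic_only_panel_has_turbidity(self):
        panel = simulate_plasma_panel(10, {"lipemic": 1.0}, seed=1, noise_sigma=0.0)
        assert all(s.composition.turbidity_index > 0 for s in panel)

    def test_severe_only_panel_exceeds_100_uM_hb(self):
        panel = simulate_plasma_panel(200, {"severe": 1.0}, seed=2, noise_sigma=0.0)
        assert all(s.composition.c_hb > 100.0 for s in panel)

    def test_panel_reproducible(self):
        a = simulate_plasma_panel(30, seed=9)
        b = simulate_plasma_panel(30, seed=9)
        for sa, sb in zip(a, b):
            assert sa.composition == sb.composition
            assert np.array_equal(sa.spectrum.absorbance, sb.spectrum.absorbance)
            assert sa.readouts == sb.readouts

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            simulate_plasma_panel(5, {"mild": 0.6, "severe": 0.6}, seed=0)
        with pytest.raises(ValueError):
            simulate_plasma_panel(5, {"unknown-state": 1.0}, seed=0)

    def test_states_cover_declared_ranges(self):
        panel = simulate_plasma_panel(300, seed=3, noise_sigma=0.0)
        for s in panel:
            rng_hb = PANEL_STATES[s.state]["hb"]
            assert rng_hb[0] <= s.composition.c_hb <= rng_hb[1]
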