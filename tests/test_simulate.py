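"""Signal-model contracts of the synthetic DPV generator."""

import numpy as np
import pytest

from voltscreen.peak_library import UnknownAnalyteError, get_profile
from voltscreen.simulate import (
    CAFFEINE_SAMPLES,
    MDMA_SAMPLES,
    MIXTURE_SAMPLES,
    R2_SUPPRESSED_SAMPLES,
    SimulationParams,
    Voltammogram,
    baseline_current,
    make_fixture_46,
    potential_grid,
    simulate_calibration,
    simulate_voltammogram,
)

NOISE_FREE = SimulationParams(noise_sd_fraction=0.0, potential_jitter_sd=0.0)


def test_grid_shapes_and_monotonicity():
    anodic = simulate_voltammogram([], "anodic", NOISE_FREE, seed=0)
    cathodic = simulate_voltammogram([], "cathodic", NOISE_FREE, seed=0)
    assert len(anodic) == 401 and len(cathodic) == 401
    assert anodic.potentials[0] == -2.0 and anodic.potentials[-1] == 2.0
    assert np.all(np.diff(anodic.potentials) > 0)
    assert np.all(np.diff(cathodic.potentials) < 0)


def test_voltammogram_rejects_wrong_monotonicity():
    grid = np.linspace(-2, 2, 11)
    with pytest.raises(ValueError):
        Voltammogram(grid, np.zeros(11), "cathodic")
    with pytest.raises(ValueError):
        Voltammogram(grid, np.zeros(10), "anodic")


def test_empty_composition_noise_free_equals_baseline_exactly():
    vg = simulate_voltammogram([], "anodic", NOISE_FREE, seed=5)
    np.testing.assert_array_equal(vg.currents, baseline_current(NOISE_FREE, vg.potentials))


def test_determinism_same_seed_identical_arrays():
    a = simulate_voltammogram([("MPHP", 100.0)], "anodic", seed=7)
    b = simulate_voltammogram([("MPHP", 100.0)], "anodic", seed=7)
    np.testing.assert_array_equal(a.currents, b.currents)
    c = simulate_voltammogram([("MPHP", 100.0)], "anodic", seed=8)
    assert not np.array_equal(a.currents, c.currents)


def test_signal_linearity_in_concentration():
    base = baseline_current(NOISE_FREE, potential_grid(NOISE_FREE, "anodic"))
    half = simulate_voltammogram([("MPHP", 50.0)], "anodic", NOISE_FREE, seed=0)
    full = simulate_voltammogram([("MPHP", 100.0)], "anodic", NOISE_FREE, seed=0)
    np.testing.assert_allclose(
        full.currents - base, 2.0 * (half.currents - base), rtol=0, atol=1e-12
    )


def test_additivity_over_composition():
    base = baseline_current(NOISE_FREE, potential_grid(NOISE_FREE, "anodic"))
    a = simulate_voltammogram([("mephedrone", 80.0)], "anodic", NOISE_FREE, seed=0)
    b = simulate_voltammogram([("caffeine", 120.0)], "anodic", NOISE_FREE, seed=0)
    ab = simulate_voltammogram(
        [("mephedrone", 80.0), ("caffeine", 120.0)], "anodic", NOISE_FREE, seed=0
    )
    np.testing.assert_allclose(
        ab.currents, a.currents + b.currents - base, rtol=0, atol=1e-12
    )


def test_bad_inputs_raise():
    with pytest.raises(UnknownAnalyteError):
        simulate_voltammogram([("nope", 10.0)], "anodic")
    with pytest.raises(ValueError):
        simulate_voltammogram([("MPHP", 0.0)], "anodic")
    with pytest.raises(ValueError):
        simulate_voltammogram([("MPHP", 10.0)], "sideways")


def test_ph_shift_moves_every_peak_more_negative():
    """At pH 10 with the default -59 mV/pH slope all peaks sit 0.118 V lower."""
    at_ph10 = SimulationParams(
        noise_sd_fraction=0.0, potential_jitter_sd=0.0, pH=10.0
    )
    assert at_ph10.ph_shift == pytest.approx(-0.118)
    base = baseline_current(NOISE_FREE, potential_grid(NOISE_FREE, "anodic"))
    for spec in get_profile("methylone").peaks_anodic:
        vg = simulate_voltammogram([("methylone", 100.0)], "anodic", at_ph10, seed=0)
        signal = (vg.currents - base) * spec.current_sign
        window = np.abs(vg.potentials - (spec.potential - 0.118)) <= 0.03
        peak_at = vg.potentials[window][np.argmax(signal[window])]
        assert peak_at == pytest.approx(spec.potential - 0.118, abs=0.011)


class TestFixture46:
    def test_counts_match_panel_composition(self, panel46):
        assert len(panel46) == 46
        assert sum(s.truth["sc_positive"] for s in panel46) == 42
        assert sum(s.truth["caffeine"] for s in panel46) == len(CAFFEINE_SAMPLES) == 14
        assert sum(s.truth["mdma"] for s in panel46) == len(MDMA_SAMPLES) == 2
        mixtures = [s for s in panel46 if len(s.truth["groups"]) > 1]
        assert {s.sample_id for s in mixtures} == set(MIXTURE_SAMPLES)

    def test_r2_suppressed_samples_are_positive_truth(self, panel46):
        flagged = {s.sample_id for s in panel46 if s.truth["r2_suppressed"]}
        assert flagged == set(R2_SUPPRESSED_SAMPLES)
        for s in panel46:
            if s.truth["r2_suppressed"]:
                assert s.truth["sc_positive"]

    def test_deterministic_given_seed(self):
        a = make_fixture_46(seed=3)
        b = make_fixture_46(seed=3)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.anodic.currents, sb.anodic.currents)
            np.testing.assert_array_equal(sa.cathodic.currents, sb.cathodic.currents)

    def test_every_group_is_represented(self, panel46):
        groups = {g for s in panel46 for g in s.truth["groups"]}
        assert groups == {"G1", "G2", "G3", "G4", "G5", "G6"}


class TestCalibrationSeries:
    def test_trace_count_and_metadata(self):
        traces = simulate_calibration("MPHP", np.linspace(15, 100, 7), 3, seed=0)
        assert len(traces) == 21
        assert {t.meta["replicate"] for t in traces} == {0, 1, 2}

    def test_noise_free_peak_current_proportional_to_concentration(self):
        base = baseline_current(NOISE_FREE, potential_grid(NOISE_FREE, "cathodic"))
        heights = []
        for conc in (20.0, 40.0, 80.0):
            (vg,) = simulate_calibration("MPHP", [conc], 1, NOISE_FREE, seed=0)
            heights.append(np.min(vg.currents - base))  # R1 is the deepest reduction
        heights = np.asarray(heights)
        np.testing.assert_allclose(heights / heights[0], [1.0, 2.0, 4.0], rtol=1e-9)

    def test_fitted_slope_matches_generator_constant(self):
        """Regression on 2%-noise data recovers amplitude_scale x rel_amplitude."""
        from voltscreen.calibration import extract_r1_currents, fit_calibration

        traces = simulate_calibration("MPHP", np.linspace(15, 100, 7), 3, seed=2)
        conc, resp = extract_r1_currents(traces)
        result = fit_calibration(conc, resp)
        expected = 0.05 * 1.0  # amplitude_scale x R1 rel_amplitude
        assert result.slope == pytest.approx(expected, rel=0.05)

    def test_empty_levels_rejected(self):
        with pytest.raises(ValueError):
            simulate_calibration("MPHP", [], 3)
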