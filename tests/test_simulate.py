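"""Synthetic PMT-trace generator: pulse shapes, arrivals, detector model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adlsfc.simulate import (
    ParticleEvent,
    TraceConfig,
    default_brightness,
    generate_trace,
    pulse_shape,
    sample_population,
    simulate_mixture,
)
from adlsfc.units import UM
from conftest import fwhm_1d

FS = 5e5


class TestPulseShape:
    def test_point_particle_limit_is_gaussian(self):
        """dp -> 0 reduces to a pure Gaussian of FWHM ds/up."""
        up, ds = 1.667e-3, 0.8 * UM
        p = pulse_shape(1e-12, up, ds, 1.0, FS)
        sigma = ds / up / 2.3548
        t = (np.arange(p.size) - p.size // 2) / FS
        np.testing.assert_allclose(p, np.exp(-(t**2) / (2 * sigma**2)), atol=1e-4)

    @pytest.mark.parametrize("dp_um", [0.4, 1.0, 5.0])
    def test_fwhm_is_transit_plus_sheet(self, dp_um):
        """Brute-force half-max search: FWHM = (dp + ds)/up within one sample."""
        up, ds = 1.667e-3, 0.8 * UM
        p = pulse_shape(dp_um * UM, up, ds, 1.0, FS)
        assert fwhm_1d(p, 1 / FS) == pytest.approx((dp_um * UM + ds) / up, abs=1 / FS)

    def test_area_linear_in_brightness(self):
        p1 = pulse_shape(1 * UM, 1.667e-3, 0.8 * UM, 1.0, FS)
        p3 = pulse_shape(1 * UM, 1.667e-3, 0.8 * UM, 3.0, FS)
        assert p3.sum() == pytest.approx(3.0 * p1.sum())

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            pulse_shape(-1.0, 1.0, 1.0, 1.0, FS)


class TestSamplePopulation:
    def test_zero_duration_gives_no_events(self, flow):
        assert sample_population(1e13, flow, 0.0, "micropillar", seed=0) == []

    def test_arrival_times_sorted_within_duration(self, flow):
        evs = sample_population(5e13, flow, 10.0, "micropillar", seed=3)
        t = np.array([e.arrival_time for e in evs])
        assert np.all(np.diff(t) >= 0) and t.min() >= 0 and t.max() <= 10.0

    def test_expected_count_micropillars(self, flow):
        """C = 1e7 / mL at Qj = 1 uL/h over 5 min injects 833 particles in
        expectation; the empirical mean over 200 seeds agrees within 3 SE."""
        conc = 1e7 * 1e6
        counts = np.array(
            [len(sample_population(conc, flow, 300.0, "micropillar", seed=s))
             for s in range(200)]
        )
        expected = conc * flow.jet_rate * 300.0
        assert expected == pytest.approx(833.3, abs=0.1)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_expected_count_microspheres_rounds_to_seven(self, flow):
        expected = 8e4 * 1e6 * flow.jet_rate * 300.0
        assert round(expected) == 7

    def test_poisson_dispersion_index(self, flow):
        """Arrival counts have variance ~ mean (index in [0.8, 1.2])."""
        conc = 3e11  # ~25 expected events in 0.3 s... scaled for speed
        counts = np.array(
            [len(sample_population(conc, flow, 300.0, "micropillar", seed=s))
             for s in range(500)]
        )
        disp = counts.var(ddof=1) / counts.mean()
        assert 0.8 < disp < 1.2

    def test_size_presets(self, flow):
        pil = sample_population(1e14, flow, 2.0, "micropillar", seed=1)
        sph = sample_population(1e14, flow, 2.0, "microsphere", seed=1)
        dpil = np.array([e.diameter for e in pil])
        dsph = np.array([e.diameter for e in sph])
        assert 0.4 * UM <= dpil.min() and dpil.max() <= 1.0 * UM
        assert abs(dsph.mean() - 5 * UM) < 0.2 * UM

    def test_unknown_preset_rejected(self, flow):
        with pytest.raises(ValueError):
            sample_population(1e12, flow, 1.0, "nanobot", seed=0)


class TestGenerateTrace:
    def test_no_events_zero_noise_is_flat_baseline(self):
        cfg = TraceConfig(duration=0.01, noise_sigma=0.0, baseline=1234.0)
        tr = generate_trace([], cfg)
        assert np.all(tr.samples == 1234)

    def test_seed_reproducibility(self, flow, geom):
        cfg = TraceConfig(duration=0.05, seed=99)
        ev = [ParticleEvent(0.02, 1 * UM, 1e4, 1.667e-3)]
        t1 = generate_trace(ev, cfg)
        t2 = generate_trace(ev, cfg)
        np.testing.assert_array_equal(t1.samples, t2.samples)

    def test_event_outside_duration_rejected(self):
        cfg = TraceConfig(duration=0.01)
        with pytest.raises(ValueError):
            generate_trace([ParticleEvent(0.5, 1 * UM, 1e4, 1.6e-3)], cfg)

    @given(
        bits=st.sampled_from([12, 16]),
        noise=st.floats(0, 2000),
        gain=st.sampled_from(["low", "medium", "high"]),
    )
    @settings(max_examples=20, deadline=None)
    def test_adc_bounds_always_hold(self, bits, noise, gain):
        cfg = TraceConfig(
            duration=0.01, adc_bits=bits, noise_sigma=noise, gain=gain, seed=1
        )
        ev = [ParticleEvent(0.005, 5 * UM, default_brightness(5 * UM), 1.667e-3)]
        tr = generate_trace(ev, cfg)
        assert tr.samples.min() >= 0 and tr.samples.max() <= 2**bits - 1

    def test_medium_gain_saturates_sphere(self):
        """A 5 um sphere clips a 16-bit converter at medium gain, widening
        its apparent FWHM relative to the unclipped low-gain pulse."""
        up = 1.667e-3
        ev = [ParticleEvent(0.05, 5 * UM, default_brightness(5 * UM), up)]
        widths = {}
        for gain in ("low", "medium", "high"):
            cfg = TraceConfig(duration=0.1, gain=gain, noise_sigma=0.0, seed=0)
            tr = generate_trace(ev, cfg)
            widths[gain] = fwhm_1d(tr.samples.astype(float) - 2000.0, 1 / FS)
            if gain == "medium":
                assert tr.samples.max() == cfg.adc_max
        assert widths["low"] < widths["medium"] <= widths["high"]

    def test_saturation_monotone_in_gain(self):
        """Raising the gain never narrows the apparent width of a clipped pulse."""
        up = 1.667e-3
        ev = [ParticleEvent(0.05, 2 * UM, default_brightness(2 * UM), up)]
        prev = 0.0
        for gain in ("low", "medium", "high"):
            cfg = TraceConfig(duration=0.1, gain=gain, noise_sigma=0.0, seed=0)
            tr = generate_trace(ev, cfg)
            w = fwhm_1d(tr.samples.astype(float) - 2000.0, 1 / FS)
            assert w >= prev - 0.1 / FS  # quantization-level jitter allowed
            prev = w


class TestSimulateMixture:
    def test_equal_ratio_gives_equal_expected_counts(self, flow):
        tr = simulate_mixture(1.0, 2e13, flow, 2.0, TraceConfig(duration=2.0), seed=5)
        labels = [e.label for e in tr.events]
        n_p = labels.count("micropillar")
        n_s = labels.count("microsphere")
        assert abs(n_p - n_s) < 4 * np.sqrt(n_p + n_s)

    def test_ratio_three_consistent_over_seeds(self, flow):
        """Pillar fraction over many seeds matches beta/(1+beta) = 0.75
        within binomial error."""
        n_p = n_tot = 0
        for seed in range(40):
            tr = simulate_mixture(
                3.0, 1e13, flow, 1.0, TraceConfig(duration=1.0), seed=seed
            )
            labels = [e.label for e in tr.events]
            n_p += labels.count("micropillar")
            n_tot += len(labels)
        frac = n_p / n_tot
        se = np.sqrt(0.75 * 0.25 / n_tot)
        assert abs(frac - 0.75) < 4 * se

    def test_invalid_beta_rejected(self, flow):
        with pytest.raises(ValueError):
            simulate_mixture(0.0, 1e12, flow, 1.0, TraceConfig(duration=1.0))
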