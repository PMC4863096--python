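"""Generator behaviour: similarity index, template banks, spike trains,
noise spectrum, SNR closure, and catalog determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from measort.core import ConvergenceError, InputError, Trace
from measort import simulate as sim


class TestBrayCurtis:
    @pytest.mark.parametrize("x, y, expected", [
        ([1.0, -2.0, 0.5], [1.0, -2.0, 0.5], 1.0),   # identical
        ([1.0, 0.0], [0.0, 1.0], 0.0),               # disjoint support
        ([2.0, 2.0], [1.0, 1.0], 1.0 - 2.0 / 6.0),   # direct evaluation
    ])
    def test_known_values(self, x, y, expected):
        assert sim.bray_curtis(np.array(x), np.array(y)) == \
            pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            sim.bray_curtis(np.zeros(3), np.zeros(4))

    def test_all_zero_rejected(self):
        with pytest.raises(InputError):
            sim.bray_curtis(np.zeros(3), np.zeros(3))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=40),
           st.data())
    def test_bounds_and_symmetry(self, xs, data):
        ys = data.draw(st.lists(st.floats(-50, 50), min_size=len(xs),
                                max_size=len(xs)))
        x, y = np.array(xs), np.array(ys)
        if np.sum(np.abs(x) + np.abs(y)) == 0:
            return
        b = sim.bray_curtis(x, y)
        assert 0.0 <= b <= 1.0 + 1e-12
        assert b == pytest.approx(sim.bray_curtis(y, x))


class TestTemplateBank:
    def test_near_orthogonal_target(self):
        bank = sim.make_template_bank(2, target_bcs=0.0, seed=1)
        b = sim.mean_pairwise_bcs([t.samples for t in bank])
        assert b < 0.1

    def test_high_similarity_target(self):
        bank = sim.make_template_bank(2, target_bcs=0.9, seed=1)
        b = sim.mean_pairwise_bcs([t.samples for t in bank])
        assert 0.85 <= b <= 0.95

    def test_deterministic(self):
        a = sim.make_template_bank(3, target_bcs=0.65, seed=9)
        b = sim.make_template_bank(3, target_bcs=0.65, seed=9)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.samples, tb.samples)

    def test_peak_strictly_inside_window(self):
        for t in sim.make_template_bank(3, target_bcs=0.3, seed=2):
            assert 0 < t.peak_index < t.n_samples - 1

    def test_unreachable_target_raises(self):
        # three units cannot all be pairwise near-orthogonal once aligned
        with pytest.raises(ConvergenceError):
            sim.make_template_bank(3, target_bcs=0.0, seed=0, max_retries=2)


class TestSpikeTimes:
    def test_zero_duration_empty(self, rng):
        t = sim.sample_spike_times(5.0, 0.0, 2.0, 25000.0, rng)
        assert len(t) == 0

    def test_count_matches_rate(self, rng):
        # 10-17 Hz total over 60 s gives the expected 600-1000 events
        t = sim.sample_spike_times(13.0, 60.0, 2.0, 25000.0, rng)
        assert 600 <= len(t) <= 1000

    def test_refractory_gap(self, rng):
        refr = round(0.002 * 25000)
        for seed in range(5):
            g = np.random.default_rng(seed)
            t = sim.sample_spike_times(8.0, 10.0, 2.0, 25000.0, g)
            assert np.all(np.diff(t) >= refr)

    def test_infeasible_rate_rejected(self, rng):
        with pytest.raises(InputError):
            sim.sample_spike_times(600.0, 1.0, 2.0, 25000.0, rng)


class TestNoise:
    def test_length_and_determinism(self):
        a = sim.make_noise(1.0, 25000.0, rng=np.random.default_rng(5))
        b = sim.make_noise(1.0, 25000.0, rng=np.random.default_rng(5))
        assert len(a) == 25000
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_band_limited_spectrum(self):
        noise = sim.make_noise(8.0, 25000.0, rng=np.random.default_rng(0))
        freqs = np.fft.rfftfreq(len(noise), d=1.0 / 25000.0)
        psd = np.abs(np.fft.rfft(noise.samples)) ** 2
        in_band = psd[(freqs > 800) & (freqs < 1200)].mean()
        out_band = psd[(freqs > 30) & (freqs < 70)].mean()
        assert out_band / in_band < 0.1

    def test_zero_mean(self):
        noise = sim.make_noise(4.0, 25000.0, rng=np.random.default_rng(1))
        assert abs(noise.samples.mean()) < 0.01 * noise.samples.std()

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(InputError):
            sim.make_noise(1.0, 25000.0, band_hz=(200.0, 20000.0),
                           rng=np.random.default_rng(0))


class TestSNR:
    def _simple_truth(self):
        tpl = sim.SpikeTemplate(np.array([0.0, 4.0, 0.0]), unit_id=0)
        return sim.GroundTruth(np.array([100]), np.array([0]), [tpl])

    def test_forced_by_definition(self):
        # spike cutout peak 4, every 1-s noise window spanning exactly 2
        fs = 1000.0
        trace = np.zeros(2000)
        trace[100] = 4.0
        noise = np.zeros(2000)
        noise[::500] = 1.0
        noise[250::500] = -1.0  # max - min = 2 per window
        truth = self._simple_truth()
        snr = sim.measure_snr(Trace(trace, fs), truth, Trace(noise, fs))
        assert snr == pytest.approx(2.0)

    def test_zero_noise_rejected(self):
        fs = 1000.0
        trace = np.zeros(2000)
        trace[100] = 4.0
        with pytest.raises(InputError):
            sim.measure_snr(Trace(trace, fs), self._simple_truth(),
                            Trace(np.zeros(2000), fs))

    def test_no_spikes_rejected(self):
        fs = 1000.0
        truth = sim.GroundTruth(np.empty(0), np.empty(0), [])
        with pytest.raises(InputError):
            sim.measure_snr(Trace(np.zeros(2000), fs), truth,
                            Trace(np.random.default_rng(0)
                                  .standard_normal(2000), fs))

    @pytest.mark.parametrize("target", [2.0, 3.0, 4.0])
    def test_closure_on_rendered_signal(self, target):
        """measure_snr of render_signal output equals the request (±5%)."""
        spec = sim.SimulationSpec(n_units=2, snr_target=target,
                                  duration_s=8.0, seed=21)
        trace, truth = sim.simulate_signal(spec)
        alpha = truth.provenance["noise_gain"]
        rng = np.random.default_rng(np.random.default_rng(21).integers(1))
        # reconstruct the scaled noise from the clean part
        clean = sim._place_templates(truth.templates, truth, len(trace))
        scaled = Trace(trace.samples - clean, trace.fs_hz)
        snr = sim.measure_snr(trace, truth, scaled)
        assert snr == pytest.approx(target, rel=0.05)


class TestRenderSignal:
    def test_single_spike_additivity(self):
        fs = 25000.0
        bank = sim.make_template_bank(2, target_bcs=0.3, seed=4)
        tpl = bank[0]
        truth = sim.GroundTruth(np.array([5000]), np.array([0]), [tpl])
        noise = sim.make_noise(1.0, fs, rng=np.random.default_rng(2))
        trace, out = sim.render_signal([tpl], truth, noise, snr_target=4.0)
        alpha = out.provenance["noise_gain"]
        residual = trace.samples - alpha * noise.samples
        start = 5000 - tpl.peak_index
        np.testing.assert_allclose(
            residual[start: start + tpl.n_samples], tpl.samples, atol=1e-9
        )
        assert np.allclose(np.delete(residual,
                                     np.arange(start, start + tpl.n_samples)),
                           0.0, atol=1e-9)

    def test_noiseless_request_rejected(self):
        bank = sim.make_template_bank(2, target_bcs=0.3, seed=4)
        truth = sim.GroundTruth(np.array([5000]), np.array([0]), bank[:1])
        noise = sim.make_noise(1.0, 25000.0, rng=np.random.default_rng(2))
        with pytest.raises(InputError):
            sim.render_signal(bank[:1], truth, noise, snr_target=0.0)

    def test_edge_spike_rejected(self):
        bank = sim.make_template_bank(2, target_bcs=0.3, seed=4)
        tpl = bank[0]
        truth = sim.GroundTruth(np.array([2]), np.array([0]), [tpl])
        noise = sim.make_noise(1.0, 25000.0, rng=np.random.default_rng(2))
        with pytest.raises(sim.PlacementError):
            sim.render_signal([tpl], truth, noise, snr_target=3.0)


class TestCatalog:
    def test_single_entry(self):
        spec = sim.CatalogSpec(groups=[(2, 0.65)], snr_levels=[3.0],
                               duration_s=4.0, master_seed=5)
        out = sim.build_catalog(spec)
        assert len(out) == 1

    def test_bitwise_deterministic(self):
        spec = sim.CatalogSpec(groups=[(2, 0.65)], snr_levels=[2.0, 4.0],
                               duration_s=4.0, master_seed=7)
        a = sim.build_catalog(spec)
        b = sim.build_catalog(spec)
        for (ta, ga), (tb, gb) in zip(a, b):
            np.testing.assert_array_equal(ta.samples, tb.samples)
            np.testing.assert_array_equal(ga.spike_times, gb.spike_times)


class TestGroundTruthInvariants:
    def test_sorted_and_refractory(self, short_signal):
        _, truth = short_signal
        assert np.all(np.diff(truth.spike_times) >= 0)
        refr = round(0.002 * 25000)
        for u in np.unique(truth.unit_labels):
            t = truth.spike_times[truth.unit_labels == u]
            assert np.all(np.diff(t) >= refr)

    def test_signal_determinism(self):
        spec = sim.SimulationSpec(n_units=2, duration_s=4.0, seed=17)
        a, _ = sim.simulate_signal(spec)
        b, _ = sim.simulate_signal(spec)
        np.testing.assert_array_equal(a.samples, b.samples)
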