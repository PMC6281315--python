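import numpy as np
import pytest

from gammakit.io import Recording, RecordingError, SpikeTrain
from gammakit.spike_phase import (circular_std, detect_spikes, firing_rate,
                                  halfwidth, instantaneous_phase,
                                  phase_distribution, preferred_phase,
                                  rayleigh_test, spike_phases)

RATE = 10_000.0


def _ap_trace(onsets_s, dur_s=2.0, amp_mv=60.0, width_ms=1.0):
    """Membrane-potential trace with triangular AP waveforms at given onsets."""
    n = int(dur_s * RATE)
    x = np.full(n, -60.0)
    w = int(width_ms / 1000 * RATE)
    ap = amp_mv * (1 - np.abs(np.linspace(-1, 1, w)))
    for t in onsets_s:
        i = int(t * RATE)
        x[i : i + w] += ap[: max(0, n - i)]
    return Recording(x, RATE, "voltage", units="mV")


class TestDetectSpikes:
    def test_recovers_injected_onsets(self):
        onsets = [0.1, 0.35, 0.6, 1.1, 1.7]
        trace = _ap_trace(onsets)
        sp = detect_spikes(trace, threshold=-20.0)
        assert sp.n_spikes == 5
        np.testing.assert_allclose(sp.times_s, onsets, atol=0.5e-3)

    def test_flat_trace_no_spikes(self):
        trace = Recording(np.full(20_000, -60.0), RATE, "voltage", units="mV")
        with pytest.warns(UserWarning):
            sp = detect_spikes(trace, threshold=-20.0)
        assert sp.n_spikes == 0

    def test_refractory_merges_close_crossings(self):
        trace = _ap_trace([0.5, 0.501])  # 1 ms apart
        sp = detect_spikes(trace, threshold=-20.0, refractory_ms=2.0)
        assert sp.n_spikes == 1

    def test_negative_polarity(self):
        x = np.zeros(20_000)
        x[5000:5010] = -50.0
        sp = detect_spikes(Recording(x, RATE, "voltage", units="mV"),
                           threshold=-20.0, polarity="negative")
        assert sp.n_spikes == 1


class TestInstantaneousPhase:
    def test_cosine_phase_is_wrapped_oscillation_phase(self):
        t = np.arange(int(10 * RATE)) / RATE
        rec = Recording(1e-5 * np.cos(2 * np.pi * 40 * t), RATE, "lfp")
        ps = instantaneous_phase(rec)
        true = np.mod(2 * np.pi * 40 * t, 2 * np.pi)
        err = np.abs(np.angle(np.exp(1j * (ps.phase - true))))
        trim = int(ps.trim_s * RATE)
        assert err[trim:-trim].max() < 0.01

    def test_peak_trough_convention(self):
        t = np.arange(int(10 * RATE)) / RATE
        rec = Recording(1e-5 * np.cos(2 * np.pi * 40 * t), RATE, "lfp")
        ps = instantaneous_phase(rec)
        i_peak = int(5.0 * RATE)          # t=5 s is a peak (200 cycles)
        i_trough = i_peak + 125           # half period of 40 Hz later
        assert min(ps.phase[i_peak], 2 * np.pi - ps.phase[i_peak]) < 0.05
        assert ps.phase[i_trough] == pytest.approx(np.pi, abs=0.05)

    def test_phase_advances_monotonically(self):
        t = np.arange(int(5 * RATE)) / RATE
        rec = Recording(np.cos(2 * np.pi * 35 * t), RATE, "lfp")
        ps = instantaneous_phase(rec)
        d = np.diff(np.unwrap(ps.phase[5000:-5000]))
        assert np.all(d > 0)

    def test_short_segment_errors(self):
        rec = Recording(np.zeros(10_000) + np.random.default_rng(0).normal(0, 1, 10_000),
                        RATE, "lfp")
        with pytest.raises(RecordingError):
            instantaneous_phase(rec.segment(0, 1.0))


class TestSpikePhases:
    def test_spikes_at_peaks_map_to_zero(self):
        t = np.arange(int(10 * RATE)) / RATE
        rec = Recording(1e-5 * np.cos(2 * np.pi * 40 * t), RATE, "lfp")
        ps = instantaneous_phase(rec)
        peaks = np.arange(1.0, 9.0, 0.1)  # multiples of the 25 ms period
        sp = SpikeTrain(times_s=peaks, epoch=(0, 10))
        phases, dropped = spike_phases(sp, ps)
        assert dropped == 0
        circ = np.minimum(phases, 2 * np.pi - phases)
        assert np.all(circ < 0.05)

    def test_spikes_at_troughs_map_to_pi(self):
        t = np.arange(int(10 * RATE)) / RATE
        rec = Recording(1e-5 * np.cos(2 * np.pi * 40 * t), RATE, "lfp")
        ps = instantaneous_phase(rec)
        troughs = np.arange(1.0125, 9.0, 0.1)
        phases, _ = spike_phases(SpikeTrain(times_s=troughs, epoch=(0, 10)), ps)
        np.testing.assert_allclose(phases, np.pi, atol=0.05)

    def test_outside_epoch_dropped_with_count(self):
        t = np.arange(int(5 * RATE)) / RATE
        rec = Recording(np.cos(2 * np.pi * 40 * t), RATE, "lfp")
        ps = instantaneous_phase(rec)
        sp = SpikeTrain(times_s=np.array([1.0, 2.0, 7.0]), epoch=(0, 10))
        with pytest.warns(UserWarning, match="dropped"):
            phases, dropped = spike_phases(sp, ps)
        assert dropped == 1
        assert phases.size == 2


class TestRayleigh:
    def test_identical_angles_maximal(self):
        R, p = rayleigh_test(np.full(100, 1.3))
        assert R == pytest.approx(1.0)
        assert p < 1e-10

    def test_symmetric_angles_cancel(self):
        ph = np.tile([0, np.pi / 2, np.pi, 3 * np.pi / 2], 2)
        R, p = rayleigh_test(ph)
        assert R == pytest.approx(0.0, abs=1e-12)
        assert p > 0.9

    def test_too_few_spikes(self):
        with pytest.raises(RecordingError, match="too few"):
            rayleigh_test(np.array([0.1, 0.2, 0.3, 0.4]))

    def test_null_calibration_small(self):
        """Type-I error ~5% at n=50 (reduced Monte-Carlo; the full 10k-run
        calibration lives in the acceptance suite)."""
        rng = np.random.default_rng(2)
        rej = sum(rayleigh_test(rng.uniform(0, 2 * np.pi, 50))[1] < 0.05
                  for _ in range(1000))
        assert rej / 1000 == pytest.approx(0.05, abs=0.02)


class TestPreferredPhase:
    def test_single_angle(self):
        assert preferred_phase(np.full(20, 4.0)) == pytest.approx(4.0)

    def test_symmetric_pair_averages_to_zero(self):
        ph = np.array([0.5, -0.5] * 10)
        assert preferred_phase(ph) == pytest.approx(0.0, abs=1e-9)

    def test_wrapped_normal_mean_recovered(self):
        rng = np.random.default_rng(42)
        ph = np.mod(rng.normal(5.2, 0.8, 2000), 2 * np.pi)
        assert preferred_phase(ph) == pytest.approx(5.2, abs=0.05)

    def test_uniform_has_no_preferred_phase(self):
        ph = np.linspace(0, 2 * np.pi, 1000, endpoint=False)
        with pytest.raises(RecordingError, match="no preferred phase"):
            preferred_phase(ph)


class TestHalfwidth:
    def test_degenerate_concentration_below_bin_width(self):
        hw, _, _ = halfwidth(np.full(300, 2.0))
        assert hw <= 2 * np.pi / 36 + 1e-9

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 1.5])
    def test_wrapped_normal_recovery(self, sigma):
        """Mean fitted FWHM ~ 2.355 sigma (20-seed version; 100-seed in
        acceptance)."""
        hws = []
        for s in range(20):
            rng = np.random.default_rng(s)
            ph = np.mod(rng.normal(3.0, sigma, 2000), 2 * np.pi)
            hws.append(halfwidth(ph)[0])
        assert np.mean(hws) == pytest.approx(2.3548 * sigma, rel=0.07)

    def test_monotone_in_sigma(self):
        means = []
        for sigma in (0.5, 1.0, 1.5):
            hws = [halfwidth(np.mod(np.random.default_rng(s).normal(3.0, sigma, 2000),
                                    2 * np.pi))[0] for s in range(10)]
            means.append(np.mean(hws))
        assert means[0] < means[1] < means[2]

    def test_distribution_summary_consistency(self):
        rng = np.random.default_rng(0)
        ph = np.mod(rng.vonmises(5.2, 3.0, 1000), 2 * np.pi)
        dist = phase_distribution(ph)
        assert dist.included
        assert dist.hist.max() == pytest.approx(1.0)
        assert dist.preferred_angle_rad == pytest.approx(5.2, abs=0.1)
        assert 0 < dist.halfwidth_rad <= 2 * np.pi
        assert circular_std(ph) == pytest.approx(
            np.sqrt(-2 * np.log(np.abs(np.mean(np.exp(1j * ph))))), rel=1e-9)


class TestFiringRate:
    def test_counts_over_minute(self):
        sp = SpikeTrain(times_s=np.linspace(0.1, 59.9, 120), epoch=(0, 60))
        rate, bins = firing_rate(sp, (0, 60))
        assert rate == pytest.approx(2.0)
        assert bins.size == 1

    def test_empty_train_zero(self):
        sp = SpikeTrain(times_s=np.array([]), epoch=(0, 60))
        rate, _ = firing_rate(sp, (0, 60))
        assert rate == 0.0

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(9)
        times = np.cumsum(rng.exponential(0.5, 1200))
        times = times[times < 300]
        times = times[np.concatenate([[True], np.diff(times) >= 0.002])]
        sp = SpikeTrain(times_s=times, epoch=(0, 300))
        rate, bins = firing_rate(sp, (0, 300))
        assert bins.size == 5
        assert rate == pytest.approx(2.0, abs=0.2)

    def test_zero_window_errors(self):
        sp = SpikeTrain(times_s=np.array([1.0]), epoch=(0, 60))
        with pytest.raises(RecordingError):
            firing_rate(sp, (10, 10))
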