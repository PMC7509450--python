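"""Trace metrics: spike detection, rates, exponential and Hill fits."""

import numpy as np
import pytest

from ca1ach import metrics


def synth_spike_train(spike_times, t_end=3000.0, dt=0.25):
    t = np.arange(0.0, t_end, dt)
    vm = np.full_like(t, -65.0)
    for ts in spike_times:
        vm[(t >= ts) & (t < ts + 1.0)] = 30.0
    return t, vm


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0, 1000.0, 1.0)
        assert metrics.detect_spikes(t, np.full_like(t, -65.0)).size == 0

    def test_three_spikes_located_at_crossings(self):
        t, vm = synth_spike_train([100.0, 600.0, 1500.0])
        st = metrics.detect_spikes(t, vm)
        assert st.size == 3
        assert np.allclose(st, [100.0, 600.0, 1500.0], atol=0.5)

    def test_refractory_deduplication(self):
        t, vm = synth_spike_train([100.0, 101.5])   # closer than 2 ms
        assert metrics.detect_spikes(t, vm).size == 1

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            metrics.detect_spikes([], [])


class TestIFR:
    def test_constant_train(self):
        st = np.arange(0.0, 1000.0, 100.0)
        t, rate = metrics.instantaneous_firing_rate(st)
        assert np.allclose(rate, 10.0)
        assert np.allclose(t, st[1:])

    def test_two_isis(self):
        t, rate = metrics.instantaneous_firing_rate([0.0, 100.0, 150.0])
        assert np.allclose(rate, [10.0, 20.0])

    def test_fewer_than_two_spikes(self):
        t, rate = metrics.instantaneous_firing_rate([5.0])
        assert t.size == 0 and rate.size == 0


class TestInhibitionDuration:
    def test_unperturbed_train(self):
        st = np.arange(0.0, 3000.0, 100.0)
        dur, censored = metrics.inhibition_duration(st, pulse_onset=1000.0)
        assert dur == pytest.approx(100.0)
        assert not censored

    def test_single_gap(self):
        st = np.concatenate([np.arange(0.0, 1001.0, 100.0),
                             np.arange(1400.0, 3000.0, 100.0)])
        dur, _ = metrics.inhibition_duration(st, pulse_onset=1000.0)
        assert dur == pytest.approx(400.0)

    def test_censored_when_no_spike_after_onset(self):
        st = np.arange(0.0, 900.0, 100.0)
        dur, censored = metrics.inhibition_duration(st, 1000.0, t_end=5000.0)
        assert censored
        assert dur == pytest.approx(5000.0 - 800.0)


class TestExpFit:
    def test_recovers_59s_time_constant(self):
        t = np.linspace(0.0, 180e3, 500)
        y = 0.175 - 0.14 * np.exp(-t / 59e3)
        tau, asym, r2 = metrics.exp_fit(t, y)
        assert tau == pytest.approx(59e3, rel=1e-3)
        assert asym == pytest.approx(0.175, rel=1e-3)
        assert r2 > 0.999

    def test_tolerates_one_percent_noise(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0.0, 180e3, 400)
        y = 0.175 - 0.14 * np.exp(-t / 59e3)
        y = y * (1.0 + 0.01 * rng.standard_normal(t.size))
        tau, _, _ = metrics.exp_fit(t, y)
        assert tau == pytest.approx(59e3, rel=0.05)

    def test_constant_series_rejected(self):
        t = np.linspace(0, 100, 50)
        with pytest.raises(ValueError, match="constant"):
            metrics.exp_fit(t, np.ones(50))


class TestHillFit:
    def test_recovers_exact_hill_parameters(self):
        dose = np.logspace(-3, 1, 15)
        resp = 0.2 + (3.0 - 0.2) * dose**1.5 / (dose**1.5 + 0.5**1.5)
        ec50, n, lo, hi = metrics.hill_fit(dose, resp)
        assert ec50 == pytest.approx(0.5, rel=1e-5)
        assert n == pytest.approx(1.5, rel=1e-4)
        assert lo == pytest.approx(0.2, abs=1e-5)
        assert hi == pytest.approx(3.0, rel=1e-5)

    def test_flat_response_rejected(self):
        dose = np.logspace(-3, 1, 8)
        with pytest.raises(ValueError, match="flat"):
            metrics.hill_fit(dose, np.ones(8))

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError, match="5 doses"):
            metrics.hill_fit([1, 2, 3], [0, 0.5, 1.0])
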