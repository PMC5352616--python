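"""Fiber network: polarity splitting, engine parity with the reference
stepper, OR-gate and dead-time semantics."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from anfsim import engine
from anfsim.axon import AxonState, detect_and_reset, resting_state, step
from anfsim.fiber import (FiberParams, SpikeTrain, simulate_trial,
                          split_stimulus, run_trials)
from anfsim.noise import NoiseSpec
from anfsim.params import default_fiber_params
from anfsim.stimulus import PulseSpec, StimulusWaveform, make_monophasic, make_paired


class TestSplitStimulus:
    def test_pure_anodic_sample(self):
        w = StimulusWaveform(samples=np.array([100.0]), t0=0.0)
        central, peripheral = split_stimulus(w, beta=0.75)
        assert central[0] == pytest.approx(100.0)
        assert peripheral[0] == pytest.approx(-75.0)

    def test_pure_cathodic_sample(self):
        w = StimulusWaveform(samples=np.array([-100.0]), t0=0.0)
        central, peripheral = split_stimulus(w, beta=0.75)
        assert central[0] == pytest.approx(-75.0)
        assert peripheral[0] == pytest.approx(100.0)

    def test_beta_one_peripheral_is_negated_waveform(self):
        w = StimulusWaveform(samples=np.array([3.0, -4.0, 0.0, 7.5]), t0=0.0)
        _, peripheral = split_stimulus(w, beta=1.0)
        np.testing.assert_allclose(peripheral, -w.samples)


def python_reference_fiber(stim_c, stim_p, noise_c, noise_p, p: FiberParams, dt):
    """Step-by-step reference using the axon-module stepper plus the fiber
    couplings, mirroring the documented semantics."""
    sp = resting_state(p.peripheral)
    sc = resting_state(p.central)
    dead_steps = int(round(p.dead_time / dt))
    last_spike = -(dead_steps + 1)
    spikes, sources = [], []
    for j in range(stim_c.size):
        gated = (j - last_spike) < dead_steps
        sp = step(sp, float(stim_p[j]), float(noise_p[j]), dt, p.peripheral,
                  stim_gated=gated)
        sc = step(sc, float(stim_c[j]), float(noise_c[j]), dt, p.central,
                  stim_gated=gated)
        spiked_p, _, _ = detect_and_reset(sp, p.peripheral)
        spiked_c, _, _ = detect_and_reset(sc, p.central)
        k = j + 1
        if spiked_p or spiked_c:
            if (k - last_spike) >= dead_steps:
                if spiked_p and spiked_c:
                    src = 0 if sp.V >= sc.V else 1
                else:
                    src = 0 if spiked_p else 1
                spikes.append(k)
                sources.append(src)
                sp = AxonState(V=sp.V, I_sub=sp.I_sub, I_supra=sp.I_supra + p.b, t=sp.t)
                sc = AxonState(V=sc.V, I_sub=sc.I_sub, I_supra=sc.I_supra + p.b, t=sc.t)
                last_spike = k
            if spiked_p:
                sp = AxonState(V=p.peripheral.v_reset, I_sub=sp.I_sub,
                               I_supra=sp.I_supra, t=sp.t)
            if spiked_c:
                sc = AxonState(V=p.central.v_reset, I_sub=sc.I_sub,
                               I_supra=sc.I_supra, t=sc.t)
    return spikes, sources


class TestEngineParity:
    @pytest.mark.parametrize("amp", [300.0, 800.0, 2000.0])
    def test_matches_reference_stepper(self, amp):
        """The fused loop and the reference axon stepper agree on spike
        indices and sources, spiking or not."""
        p = default_fiber_params(sigma_peripheral=0.0, sigma_central=0.0)
        w = make_monophasic(PulseSpec("monophasic", "cathodic", 39, amplitude=amp),
                            post_pad=2000.0)
        rng = np.random.default_rng(9)
        noise_p = rng.normal(0, 5.0, w.n_samples)
        noise_c = rng.normal(0, 5.0, w.n_samples)
        central_in, peripheral_in = split_stimulus(w, p.beta)
        ref_spikes, ref_sources = python_reference_fiber(
            central_in, peripheral_in, noise_c, noise_p, p, w.dt)

        from anfsim.fiber import _axon_tuple, _resting_cached
        rest_p = _resting_cached(p.peripheral)
        rest_c = _resting_cached(p.central)
        args_p = _axon_tuple(p.peripheral)
        args_c = _axon_tuple(p.central)
        idx, src = engine.run_fiber(
            peripheral_in, central_in, noise_p, noise_c, w.dt,
            *args_p, *(args_c[:5] + args_c[6:]),
            rest_p.V, rest_p.I_sub, rest_p.I_supra,
            rest_c.V, rest_c.I_sub, rest_c.I_supra,
            p.b, int(round(p.dead_time / w.dt)))
        assert list(idx) == ref_spikes
        assert list(src) == ref_sources


class TestFiberBehavior:
    def setup_method(self):
        self.p0 = default_fiber_params(sigma_peripheral=0.0, sigma_central=0.0)

    def test_cathodic_pulse_spikes_on_peripheral_axon(self):
        w = make_monophasic(PulseSpec("monophasic", "cathodic", 39, amplitude=800.0))
        tr = simulate_trial(w, self.p0, seed=0)
        assert tr.n_spikes == 1
        assert tr.source_names() == ["peripheral"]

    def test_anodic_pulse_spikes_on_central_axon_with_shorter_latency(self):
        wa = make_monophasic(PulseSpec("monophasic", "anodic", 39, amplitude=1100.0))
        wc = make_monophasic(PulseSpec("monophasic", "cathodic", 39, amplitude=810.0))
        ta = simulate_trial(wa, self.p0, seed=0)
        tc = simulate_trial(wc, self.p0, seed=0)
        assert ta.source_names() == ["central"]
        assert ta.spike_times[0] < tc.spike_times[0]

    def test_two_pulses_within_dead_time_yield_one_spike(self):
        pulse = make_monophasic(PulseSpec("monophasic", "cathodic", 39,
                                          amplitude=900.0), post_pad=3000.0)
        pair = make_paired(pulse, 1.0, 1.0, 300.0)
        tr = simulate_trial(pair, self.p0, seed=0)
        assert tr.n_spikes == 1

    def test_trial_reproducibility(self):
        p = default_fiber_params()
        w = make_monophasic(PulseSpec("monophasic", "cathodic", 39, amplitude=560.0))
        a = run_trials(w, p, 20, master_seed=4)
        b = run_trials(w, p, 20, master_seed=4)
        assert [t.n_spikes for t in a] == [t.n_spikes for t in b]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.spike_times, y.spike_times)

    def test_zero_noise_trials_identical(self):
        w = make_monophasic(PulseSpec("monophasic", "cathodic", 39, amplitude=800.0))
        trains = run_trials(w, self.p0, 5, master_seed=1)
        for t in trains[1:]:
            np.testing.assert_array_equal(t.spike_times, trains[0].spike_times)

    def test_spike_probability_between_0_and_1_near_threshold(self):
        p = default_fiber_params()
        w = make_monophasic(PulseSpec("monophasic", "cathodic", 39, amplitude=572.0))
        trains = run_trials(w, p, 60, master_seed=2)
        frac = np.mean([t.n_spikes > 0 for t in trains])
        assert 0.0 < frac < 1.0


@given(amp=st.floats(50.0, 5000.0), delay=st.integers(200, 1500),
       sigma=st.floats(0.0, 30.0))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_no_isi_below_dead_time(amp, delay, sigma):
    """Fuzzed paired stimuli at any level never produce inter-spike intervals
    below the dead time (SpikeTrain validates this on construction too)."""
    p = default_fiber_params(sigma_peripheral=sigma, sigma_central=sigma)
    pulse = make_monophasic(PulseSpec("monophasic", "cathodic", 100,
                                      amplitude=amp), post_pad=4000.0)
    pair = make_paired(pulse, 1.0, 1.0, float(delay))
    tr = simulate_trial(pair, p, seed=delay)
    if tr.n_spikes >= 2:
        assert np.min(np.diff(tr.spike_times)) >= p.dead_time - 1e-9


def test_spiketrain_rejects_isi_below_dead_time():
    with pytest.raises(ValueError, match="dead time"):
        SpikeTrain(spike_times=np.array([100.0, 400.0]),
                   sources=np.array([0, 1]), trial_seed=0, dead_time=500.0)
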