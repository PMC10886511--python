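"""Surrogate culture: layout, determinism, trace synthesis, crosstalk."""

import numpy as np
import pytest

from biohybrid.culture import (
    CrosstalkReport, CultureConfig, CultureNetwork, ElectrodeTrace, SpikeRaster,
    apply_bandpass, electrode_neighbors, mea_layout, simulate_culture,
    synthesize_extracellular, verify_no_crosstalk,
)
from biohybrid.encoding import IzhikevichParams, step_neuron


class TestLayout:
    def test_sixty_sites_on_cornerless_grid(self):
        layout = mea_layout()
        assert layout.shape == (60, 2)
        # 200 um pitch
        xs = np.unique(layout[:, 0])
        assert np.allclose(np.diff(xs), 200.0)
        # corners absent
        for corner in ([0, 0], [1400, 0], [0, 1400], [1400, 1400]):
            assert not np.any(np.all(layout == corner, axis=1))

    def test_interior_electrode_has_eight_neighbors(self):
        cfg = CultureConfig()
        assert electrode_neighbors(cfg.afferent_electrode).size == 8


class TestConfig:
    def test_noise_band_enforced(self):
        CultureConfig(noise_rms=10.0)
        CultureConfig(noise_rms=20.0)
        with pytest.raises(ValueError, match="10-20"):
            CultureConfig(noise_rms=25.0)

    def test_electrode_indices_checked(self):
        with pytest.raises(ValueError):
            CultureConfig(efferent_electrode=60)


class TestNetwork:
    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            CultureNetwork(CultureConfig(), None)
        with pytest.raises(ValueError, match="seed"):
            simulate_culture(CultureConfig(), 1.0, None)

    def test_identical_seed_identical_raster(self):
        cfg = CultureConfig(warmup_s=0.0)
        r1, _ = simulate_culture(cfg, 3.0, 42)
        r2, _ = simulate_culture(cfg, 3.0, 42)
        assert np.array_equal(r1.times, r2.times)
        assert np.array_equal(r1.neurons, r2.neurons)

    def test_silent_when_undriven(self):
        cfg = CultureConfig(background_drive_rate=0.0, warmup_s=0.0)
        raster, traces = simulate_culture(cfg, 2.0, 0)
        assert len(raster) == 0
        for tr in traces.values():
            assert tr.data.std() == pytest.approx(cfg.noise_rms, rel=0.05)

    def test_spontaneous_population_bursts_at_culture_rate(self):
        cfg = CultureConfig()
        raster, _ = simulate_culture(cfg, 30.0, 5)
        # population bursts: >= 40 spikes within 20 ms windows
        cnt, edges = np.histogram(raster.times, np.arange(0, 30.0, 0.02))
        hot = edges[:-1][cnt >= 40]
        bursts = hot[np.concatenate([[True], np.diff(hot) > 0.5])] if hot.size else hot
        assert bursts.size >= 4
        ibi = np.diff(bursts)
        assert 1.0 < ibi.mean() < 6.0

    def test_stimulation_evokes_activity_from_rest(self):
        """A stimulation pulse on a settled culture elicits spikes in the
        stimulated population within a short latency window; an identical
        culture without the pulse stays quiet (event-matched control)."""
        cfg = CultureConfig(background_drive_rate=0.0, warmup_s=0.0)
        stim, quiet = [], []
        for with_pulse in (True, False):
            net = CultureNetwork(cfg, 9)
            net.advance(500.0)
            spikes = net.advance(1.0, stim=with_pulse) + net.advance(14.0)
            count = sum(len(i) for _, i in spikes)
            (stim if with_pulse else quiet).append(count)
        assert stim[0] > quiet[0]
        assert stim[0] > 0

    def test_single_neuron_euler_oracle_for_stim_response(self):
        # the network's forced response of an isolated neuron matches a
        # direct single-neuron Euler integration of the same current
        cfg = CultureConfig(background_drive_rate=0.0, warmup_s=0.0,
                            connection_probability=0.0, stim_inh_factor=1.0,
                            stim_coupling_gain=200.0)
        net = CultureNetwork(cfg, 3)
        net.advance(500.0)
        target = int(net.stim_targets[0])
        v0, u0 = net.v[target], net.u[target]
        spikes = net.advance(1.0, stim=True)
        fired_net = any(target in idx for _, idx in spikes)

        p = IzhikevichParams(a=float(net.a[target]), b=float(net.b[target]),
                             c=float(net.c[target]), d=float(net.d[target]),
                             dt=cfg.dt_ms)
        from biohybrid.encoding import NeuronState
        s = NeuronState(v=float(v0), u=float(u0))
        fired_ref = False
        for _ in range(2):
            s, sp, _ = step_neuron(s, 200.0, p)
            fired_ref = fired_ref or sp
        assert fired_net == fired_ref


class TestTraces:
    def test_sixty_channels_at_twenty_khz(self):
        cfg = CultureConfig(warmup_s=0.0)
        _, traces = simulate_culture(cfg, 1.0, 2, electrodes=list(range(60)))
        assert len(traces) == 60
        for tr in traces.values():
            assert tr.fs == 20000.0
            assert len(tr) == 20000

    def test_empty_raster_noise_only(self):
        cfg = CultureConfig(warmup_s=0.0)
        net = CultureNetwork(cfg, 1)
        raster = SpikeRaster(np.empty(0), np.empty(0, np.int64), net.neuron_electrode)
        traces = synthesize_extracellular(raster, cfg, net, 1.0, seed=0)
        for tr in traces.values():
            assert tr.data.std() == pytest.approx(cfg.noise_rms, rel=0.1)

    def test_spike_amplitude_peaks_at_home_electrode(self):
        cfg = CultureConfig(warmup_s=0.0, noise_rms=10.0)
        net = CultureNetwork(cfg, 4)
        # neuron closest to its electrode: unambiguous home site
        d_home = net.electrode_dist[np.arange(cfg.n_neurons), net.neuron_electrode]
        n = int(np.argmin(d_home))
        e_home = int(net.neuron_electrode[n])
        raster = SpikeRaster(np.array([0.5]), np.array([n]), net.neuron_electrode)
        cfg_quiet = CultureConfig(warmup_s=0.0, noise_rms=10.0)
        traces = synthesize_extracellular(raster, cfg_quiet, net, 1.0, seed=1,
                                          electrodes=list(range(60)))
        window = slice(int(0.499 * 20000), int(0.503 * 20000))
        home_peak = np.abs(traces[e_home].data[window]).max()
        others = [np.abs(traces[e].data[window]).max()
                  for e in range(60) if e != e_home]
        assert home_peak >= 2.0 * np.partition(others, -1)[-1] * 0.5
        assert home_peak > 2.0 * np.median(others)

    def test_bandpass_attenuates_low_frequency(self):
        fs = 20000.0
        t = np.arange(int(fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t) + 0.1 * np.sin(2 * np.pi * 1000.0 * t)
        tr = ElectrodeTrace(x.astype(np.float32), fs, 0)
        out = apply_bandpass(tr)
        spec_in = np.abs(np.fft.rfft(tr.data))
        spec_out = np.abs(np.fft.rfft(out.data))
        freqs = np.fft.rfftfreq(len(tr), 1 / fs)
        i10 = np.argmin(np.abs(freqs - 10))
        atten_db = 20 * np.log10(spec_in[i10] / spec_out[i10])
        assert atten_db >= 20.0
        assert out.band == "100-3500"


class TestCrosstalk:
    @staticmethod
    def _stim_traces(artifact_uv, n_pulses=40, seed=0):
        cfg = CultureConfig(background_drive_rate=0.0, warmup_s=0.0,
                            stim_artifact_uv=artifact_uv)
        stim_times = 0.2 + 0.1 * np.arange(n_pulses)
        neighbors = list(electrode_neighbors(cfg.afferent_electrode))
        electrodes = [cfg.afferent_electrode, cfg.efferent_electrode] + neighbors
        _, traces = simulate_culture(cfg, float(stim_times[-1] + 0.5), seed,
                                     stim_train=stim_times, electrodes=electrodes)
        return cfg, stim_times, traces

    def test_no_stimulation_vacuous_pass(self):
        cfg = CultureConfig()
        report = verify_no_crosstalk({}, np.empty(0), 75.0, cfg)
        assert report.passed and report.checked_pulses == 0

    def test_default_attenuation_passes_half_amplitude_drop(self):
        cfg, stim_times, traces = self._stim_traces(300.0)
        report = verify_no_crosstalk(traces, stim_times, 75.0, cfg)
        assert report.passed, report.violations[:3]

    def test_doubled_artifact_gain_is_flagged(self):
        cfg, stim_times, traces = self._stim_traces(600.0)
        report = verify_no_crosstalk(traces, stim_times, 75.0, cfg)
        assert not report.passed
        assert len(report.violations) >= 1
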