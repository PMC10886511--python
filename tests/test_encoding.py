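"""Tactile encoder: input currents, Izhikevich integration, trigger trains."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biohybrid.encoding import (
    EncoderGains, IzhikevichParams, NeuronState, StimTriggerTrain,
    InstabilityError, biphasic_pulse, compute_input_current,
    encode_force_stream, render_stim_waveform, step_neuron, TRIGGER_LEVEL_V,
)
from biohybrid.plant import ForceSignal


GAINS = EncoderGains()
PARAMS = IzhikevichParams()


class TestInputCurrent:
    def test_zero_force_sa_baseline(self):
        assert compute_input_current(0.0, 0.0, GAINS, "SA") == GAINS.beta

    def test_ra_depends_solely_on_force_rate(self):
        # steady force must not enter the RA drive at all
        assert compute_input_current(10.0, 0.0, GAINS, "RA") == GAINS.alpha
        assert (compute_input_current(10.0, 0.0, GAINS, "RA")
                == compute_input_current(0.0, 0.0, GAINS, "RA"))

    def test_sa_increment_is_linear_in_both_forces(self):
        # direct arithmetic oracle on the current difference
        f1, f2 = (0.2, 1.5), (0.7, 4.0)
        dI = (compute_input_current(*f2, GAINS, "SA")
              - compute_input_current(*f1, GAINS, "SA"))
        expected = GAINS.k_sa * (f2[0] - f1[0]) + GAINS.k_ra * (f2[1] - f1[1])
        assert dI == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
    def test_nonfinite_force_rejected(self, bad):
        with pytest.raises(ValueError, match="rejected input"):
            compute_input_current(bad, 0.0, GAINS, "SA")

    def test_rectification_makes_release_excitatory(self):
        assert compute_input_current(0.0, -5.0, GAINS, "RA") == pytest.approx(
            GAINS.alpha + GAINS.k_ra * 5.0
        )
        signed = EncoderGains(rectify_f_ac=False)
        assert compute_input_current(0.0, -5.0, signed, "RA") == pytest.approx(
            signed.alpha - signed.k_ra * 5.0
        )

    @given(f_dc1=st.floats(0, 10), f_dc2=st.floats(0, 10), f_ac=st.floats(-50, 50))
    @settings(deadline=None, max_examples=50)
    def test_ra_invariance_under_steady_force(self, f_dc1, f_dc2, f_ac):
        assert (compute_input_current(f_dc1, f_ac, GAINS, "RA")
                == compute_input_current(f_dc2, f_ac, GAINS, "RA"))


class TestStepNeuron:
    def test_spike_resets_to_table_values(self):
        # drive v over the 30 mV cutoff within one step
        state = NeuronState(v=29.9, u=0.0)
        new, spiked, level = step_neuron(state, 1000.0, PARAMS)
        assert spiked and level == TRIGGER_LEVEL_V
        assert new.v == PARAMS.c == -65.0
        # the reset adds exactly d to the integrated recovery variable
        from dataclasses import replace
        no_d, _, _ = step_neuron(state, 1000.0, replace(PARAMS, d=0.0))
        assert new.u - no_d.u == pytest.approx(PARAMS.d)

    def test_zero_input_fixed_point_from_quadratic_oracle(self):
        # equilibrium solves X v^2 + (Y - b) v + Z = 0 with u = b v
        roots = np.sort(np.roots([PARAMS.X, PARAMS.Y - PARAMS.b, PARAMS.Z]).real)
        v_star = roots[0]
        assert v_star == pytest.approx(-70.0)
        state = NeuronState(v=v_star, u=PARAMS.b * v_star)
        for _ in range(2000):
            state, spiked, _ = step_neuron(state, 0.0, PARAMS)
            assert not spiked
        assert state.v == pytest.approx(v_star, abs=1e-6)
        assert state.u == pytest.approx(PARAMS.b * v_star, abs=1e-6)

    def test_resting_state_matches_oracle(self):
        s = PARAMS.resting_state()
        assert s.v == pytest.approx(-70.0)
        assert s.u == pytest.approx(-14.0)

    @staticmethod
    def _isi(params, I, t_ms=2000.0):
        state = params.resting_state()
        times = []
        n = int(round(t_ms / params.dt))
        for k in range(n):
            state, spiked, _ = step_neuron(state, I, params)
            if spiked:
                times.append((k + 1) * params.dt)
        return np.diff(times)

    def test_periodic_spiking_converges_to_fine_step_reference(self):
        # forward Euler is first order: the period error shrinks ~linearly in
        # dt and is within 5% of the dt/10 reference by dt = 0.1 ms
        errs = []
        for dt in (0.5, 0.25, 0.1):
            coarse = self._isi(IzhikevichParams(dt=dt), 8.0)
            fine = self._isi(IzhikevichParams(dt=dt / 10), 8.0)
            assert coarse.size > 10 and fine.size > 10
            errs.append(abs(np.median(coarse) / np.median(fine) - 1.0))
        assert errs[2] < 0.05
        assert errs[0] > errs[1] > errs[2]

    def test_f_i_curve_monotone_against_fine_oracle(self):
        rates = []
        for I in [4.0, 6.0, 10.0, 16.0]:
            isi = self._isi(IzhikevichParams(dt=PARAMS.dt / 10), I)
            rates.append(1000.0 / np.median(isi))
        assert np.all(np.diff(rates) > 0)

    def test_divergence_raises_and_names_dt(self):
        with pytest.raises(InstabilityError, match="dt"):
            state = NeuronState(v=0.0, u=0.0)
            for _ in range(100):
                state, _, _ = step_neuron(state, 1e7, IzhikevichParams(dt=10.0))

    def test_bounded_input_keeps_state_finite(self):
        state = PARAMS.resting_state()
        rng = np.random.default_rng(0)
        for _ in range(20000):
            state, _, _ = step_neuron(state, rng.uniform(-20, 40), PARAMS)
        assert np.isfinite(state.v) and np.isfinite(state.u)


def _force(f_dc, f_ac, rate=1000.0):
    return ForceSignal(f_dc=np.asarray(f_dc, float), f_ac=np.asarray(f_ac, float), rate=rate)


class TestEncodeStream:
    def test_empty_stream_gives_empty_train(self):
        train = encode_force_stream(_force([], []), "SA")
        assert len(train) == 0

    def test_zero_force_subthreshold_baseline_is_silent(self):
        n = 2000
        for mode in ("SA", "RA"):
            train = encode_force_stream(_force(np.zeros(n), np.zeros(n)), mode)
            assert len(train) == 0

    @staticmethod
    def _rectangular_contact(n=3000, rate=1000.0, rise=40):
        # F_DC steps up over a short ramp and back down; F_AC is its derivative
        f = np.zeros(n)
        f[1000:2000] = 1.0
        k = np.ones(rise) / rise
        f = np.convolve(f, k, mode="same")
        f_ac = np.gradient(f) * rate
        return _force(f, f_ac, rate)

    def test_ra_spikes_cluster_at_contact_edges(self):
        force = self._rectangular_contact()
        train = encode_force_stream(force, "RA")
        assert len(train) >= 2
        near_edge = [min(abs(t - 1.0), abs(t - 2.0)) < 0.15 for t in train.spike_times]
        assert np.mean(near_edge) > 0.9

    def test_sa_fires_through_hold_more_than_ra(self):
        force = self._rectangular_contact()
        sa = encode_force_stream(force, "SA").spike_times
        ra = encode_force_stream(force, "RA").spike_times
        hold = lambda t: (1.2 < t) & (t < 1.8)
        assert hold(sa).sum() > hold(ra).sum()
        # tonic hold rate in the physiologically intended band
        rate = hold(sa).sum() / 0.6
        assert 20.0 <= rate <= 80.0

    def test_ra_train_invariant_to_steady_force_offset(self):
        force = self._rectangular_contact()
        shifted = _force(force.f_dc + 0.5, force.f_ac, force.rate)
        a = encode_force_stream(force, "RA").spike_times
        b = encode_force_stream(shifted, "RA").spike_times
        assert np.array_equal(a, b)

    def test_csv_round_trip(self, tmp_path):
        train = StimTriggerTrain(np.array([0.1, 0.25, 1.0]), "SA")
        p = tmp_path / "train.csv"
        train.to_csv(p)
        back = StimTriggerTrain.from_csv(p)
        assert np.allclose(back.spike_times, train.spike_times)
        assert back.encoding == "SA"
        assert back.trigger_level == TRIGGER_LEVEL_V


class TestBiphasic:
    def test_charge_balance_and_positive_first(self):
        pulse = biphasic_pulse(20000.0, amplitude=2.0, phase_width_ms=0.2)
        assert pulse.sum() == pytest.approx(0.0)
        assert pulse[0] > 0

    def test_min_separation_matches_brute_force_scan(self):
        fs, dur = 20000.0, 1.0
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0, dur, 60))
        times = np.unique(times)
        train = StimTriggerTrain(times, "SA")
        wave = render_stim_waveform(train, fs, dur, phase_width_ms=0.2)
        # brute-force min-separation rule: later trigger loses
        min_sep = 2 * 0.2e-3
        kept, last = 0, -np.inf
        for t in times:
            if t - last >= min_sep:
                kept += 1
                last = t
        onsets = np.flatnonzero((wave > 0) & (np.roll(wave, 1) <= 0))
        assert onsets.size == kept


class TestValidation:
    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            EncoderGains(k_sa=-1.0)

    def test_dt_and_reset_validated(self):
        with pytest.raises(ValueError):
            IzhikevichParams(dt=0.0)
        with pytest.raises(ValueError):
            IzhikevichParams(c=40.0)

    def test_trigger_times_must_increase(self):
        with pytest.raises(ValueError):
            StimTriggerTrain(np.array([0.2, 0.1]), "SA")
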