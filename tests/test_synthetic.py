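"""Generator contracts: determinism, closed forms, ground-truth recovery."""

import numpy as np
import pytest

import laminet as ln
from laminet.synthetic import coupled_lfp_samples


class TestCoupledLfp:
    def test_deterministic_given_seed(self):
        spec = ln.CouplingSpec()
        a = ln.generate_coupled_lfp(spec, 10.0, 1000.0, seed=7)
        b = ln.generate_coupled_lfp(spec, 10.0, 1000.0, seed=7)
        assert np.array_equal(a.data, b.data)
        c = ln.generate_coupled_lfp(spec, 10.0, 1000.0, seed=8)
        assert not np.array_equal(a.data, c.data)

    def test_noiseless_chi1_matches_closed_form(self):
        spec = ln.CouplingSpec(
            phase_freq_hz=5.0, amp_freq_hz=65.0, coupling_strength=1.0,
            preferred_phase_deg=0.0, amp_scale=0.5, noise_sd=0.0,
        )
        fs = 1000.0
        rng = np.random.default_rng(0)
        x = coupled_lfp_samples(spec, 4.0, fs, rng)
        t = np.arange(x.size) / fs
        phi = 2 * np.pi * 5.0 * t
        env = 0.5 * (1 + np.cos(phi)) / 2.0
        expected = np.sin(phi) + env * np.sin(2 * np.pi * 65.0 * t)
        assert np.allclose(x, expected, atol=1e-12)
        # envelope maximal exactly where cos(phi)=1
        assert env[0] == np.max(env)

    def test_chi_zero_envelope_constant(self):
        spec = ln.CouplingSpec(coupling_strength=0.0, noise_sd=0.0)
        rng = np.random.default_rng(0)
        x = coupled_lfp_samples(spec, 4.0, 1000.0, rng)
        t = np.arange(x.size) / 1000.0
        # envelope reduces to the constant amp_scale: closed form holds
        expected = np.sin(2 * np.pi * spec.phase_freq_hz * t) + \
            spec.amp_scale * np.sin(2 * np.pi * spec.amp_freq_hz * t)
        assert np.allclose(x, expected, atol=1e-12)

    def test_validation_errors(self):
        spec = ln.CouplingSpec()
        with pytest.raises(ValueError):  # aliasing
            ln.generate_coupled_lfp(spec, 10.0, 100.0, seed=0)
        with pytest.raises(ValueError):  # too short
            ln.generate_coupled_lfp(spec, 1.0, 1000.0, seed=0)
        with pytest.raises(ValueError):
            ln.CouplingSpec(coupling_strength=1.5).validate()
        with pytest.raises(ValueError):
            ln.CouplingSpec(amp_freq_hz=2.0, phase_freq_hz=5.0).validate()


class TestEntrainedSpikes:
    def test_high_kappa_concentrates_at_preferred_phase(self):
        rec = ln.generate_coupled_lfp(ln.CouplingSpec(), 60.0, 1000.0, seed=1)
        spec = ln.EntrainmentSpec(kappa=50.0, preferred_phase_deg=-90.0,
                                  mean_rate_hz=10.0)
        st = ln.generate_entrained_spikes(rec, spec, seed=2)
        res = ln.phase_locking(st.times_s, rec, (4.0, 7.5))
        assert res.resultant_length > 0.95
        assert abs(ln.wrap_degrees(res.mean_angle_deg + 90.0)) < 5.0

    def test_kappa1_mean_angle_recovered_within_10_degrees(self):
        rec = ln.generate_coupled_lfp(ln.CouplingSpec(), 60.0, 1000.0, seed=3)
        spec = ln.EntrainmentSpec(kappa=1.0, preferred_phase_deg=180.0,
                                  mean_rate_hz=9.0)  # ~500 spikes in 60 s
        st = ln.generate_entrained_spikes(rec, spec, seed=4)
        assert 300 < st.n_spikes < 800
        res = ln.phase_locking(st.times_s, rec, (4.0, 7.5))
        assert abs(ln.wrap_degrees(res.mean_angle_deg - 180.0)) < 10.0

    def test_kappa_zero_yields_uniform_phases(self):
        # resultant length small and Rayleigh rarely significant
        rec = ln.generate_coupled_lfp(ln.CouplingSpec(), 60.0, 1000.0, seed=5)
        spec = ln.EntrainmentSpec(kappa=0.0, mean_rate_hz=10.0)
        n_sig = 0
        for seed in range(20):
            st = ln.generate_entrained_spikes(rec, spec, seed=100 + seed)
            res = ln.phase_locking(st.times_s, rec, (4.0, 7.5))
            n_sig += res.entrained
        assert n_sig <= 4  # ~alpha of 20 runs, generous margin

    def test_realized_rate_near_target(self):
        rec = ln.generate_coupled_lfp(ln.CouplingSpec(), 60.0, 1000.0, seed=6)
        spec = ln.EntrainmentSpec(kappa=2.0, mean_rate_hz=15.0)
        st = ln.generate_entrained_spikes(rec, spec, seed=7)
        rate = st.n_spikes / 60.0
        assert rate == pytest.approx(15.0, rel=0.15)


class TestLaminarSession:
    def test_same_seed_bitwise_identical(self):
        a = ln.generate_laminar_session(n_stimuli=12, seed=9)
        b = ln.generate_laminar_session(n_stimuli=12, seed=9)
        assert np.array_equal(a.recording.data, b.recording.data)
        assert np.array_equal(a.recording.stim_times_s, b.recording.stim_times_s)

    def test_sink_recovered_by_csd_pipeline(self, laminar_session):
        ses = laminar_session
        avg, tms, n_used, _ = ln.evoked_average(ses.recording)
        cm = ln.compute_csd(avg, tms, 100.0)
        al = ln.locate_l4(cm, layout=ses.truth["layout"])
        assert not al.failed
        assert al.l4_channel == ses.truth["sink_channel"]
        assert 0.0 <= al.sink_latency_ms <= 100.0

    def test_zero_sink_amplitude_fails_alignment(self):
        ses = ln.generate_laminar_session(n_stimuli=30, sink_amplitude=0.0,
                                          seed=13)
        avg, tms, *_ = ln.evoked_average(ses.recording)
        cm = ln.compute_csd(avg, tms, 100.0)
        al = ln.locate_l4(cm, layout=ses.truth["layout"])
        assert al.failed and al.l4_channel is None

    def test_few_stimuli_warns(self):
        with pytest.warns(UserWarning):
            ln.generate_laminar_session(n_stimuli=5, seed=1)

    def test_sink_latency_must_precede_100ms(self):
        with pytest.raises(ValueError):
            ln.generate_laminar_session(sink_latency_ms=120.0, seed=1)


class TestWaveformPopulation:
    def test_classifier_recovers_true_labels(self):
        pop = ln.generate_waveform_population(100, 300, seed=17)
        ln.classify_units(pop)
        acc = np.mean([u.putative_class == u.truth["class"] for u in pop])
        assert acc >= 0.98

    def test_all_wide_classified_excitatory(self):
        pop = ln.generate_waveform_population(0, 5, seed=18)
        ln.classify_units(pop)
        assert all(u.putative_class == "excitatory" for u in pop)

    def test_latency_distribution_is_bimodal_at_stated_modes(self):
        pop = ln.generate_waveform_population(400, 400, seed=19)
        ln.classify_units(pop)
        lats = np.array([u.trough_to_peak_ms for u in pop])
        narrow = lats[lats < 0.41]
        wide = lats[lats >= 0.41]
        assert np.median(narrow) == pytest.approx(0.25, abs=0.02)
        assert np.median(wide) == pytest.approx(0.54, abs=0.02)


class TestLongitudinalTable:
    def test_structure_and_determinism(self):
        a = ln.generate_longitudinal_table(seed=23)
        b = ln.generate_longitudinal_table(seed=23)
        assert a.equals(b)
        assert set(a.columns) == {"animal", "week", "condition", "value"}
        assert a["animal"].nunique() == 8  # study design: n = 8 animals
        assert not a.duplicated(["animal", "week", "condition"]).any()

    def test_overwhelming_effect_flags_every_week(self):
        tab = ln.generate_longitudinal_table(
            condition_effect=lambda w: 10 * 0.01, residual_sd=0.01, seed=29
        )
        fit = ln.fit_condition_time_model(tab)
        assert ln.ci_overlap_significance(fit).all()
        assert fit.lr_p < 1e-6
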