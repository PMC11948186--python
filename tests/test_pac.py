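"""KL modulation index: binning, entropy, bounds, invariances, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import laminet as ln
from laminet.pac import band_mi


def oracle_mi(p):
    """Independent brute-force binned-entropy oracle (plain Python loop)."""
    h = 0.0
    for pi in p:
        if pi > 0:
            h -= pi * np.log(pi)
    ho = np.log(len(p))
    return (ho - h) / ho


def oracle_distribution(phase_deg, amplitude, n_bins=20):
    """Two-pass histogram oracle for the phase-binned amplitude means."""
    width = 360.0 / n_bins
    means = []
    for i in range(n_bins):
        lo = -180.0 + i * width
        sel = (phase_deg >= lo) & (phase_deg < lo + width)
        means.append(amplitude[sel].mean() if sel.any() else 0.0)
    means = np.array(means)
    return means / means.sum()


class TestPhaseBinAmplitudes:
    def test_constant_amplitude_uniform_phase_gives_uniform_p(self):
        phase = np.linspace(-180, 180, 20000, endpoint=False)
        d = ln.phase_bin_amplitudes(phase, np.ones(20000))
        assert d.n_bins == 20
        assert np.allclose(d.p, 1 / 20)
        assert d.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_amplitude_confined_to_one_bin_gives_delta(self):
        phase = np.linspace(-180, 180, 36000, endpoint=False)
        amp = np.where((phase >= 0) & (phase < 18), 1.0, 0.0)
        d = ln.phase_bin_amplitudes(phase, amp)
        expect = np.zeros(20)
        expect[10] = 1.0  # [0, 18) bin
        assert np.allclose(d.p, expect)

    def test_matches_two_pass_histogram_oracle(self, coupled_recording):
        spec, rec = coupled_recording
        x = rec.data[0].astype(float)
        ph = ln.hilbert_phase(x, rec.fs_hz, (4.5, 5.5))
        amp, valid = ln.morlet_amplitude(x, rec.fs_hz, [65.0])
        d = ln.phase_bin_amplitudes(ph, amp[0], valid=valid[0])
        expected = oracle_distribution(ph[valid[0]], amp[0][valid[0]])
        assert np.allclose(d.p, expected, atol=1e-12)

    def test_rejects_mismatched_and_empty(self):
        with pytest.raises(ValueError):
            ln.phase_bin_amplitudes(np.zeros(5), np.zeros(4))
        with pytest.raises(ValueError):
            ln.phase_bin_amplitudes(np.zeros(5), np.zeros(5),
                                    valid=np.zeros(5, bool))


class TestEntropyAndMi:
    def test_analytic_entropies(self):
        assert ln.distribution_entropy(np.full(20, 1 / 20)) == pytest.approx(
            np.log(20), abs=1e-12
        )
        delta = np.zeros(20)
        delta[3] = 1.0
        assert ln.distribution_entropy(delta) == 0.0
        half = np.zeros(20)
        half[:2] = 0.5
        assert ln.distribution_entropy(half) == pytest.approx(np.log(2),
                                                              abs=1e-12)

    def test_mi_uniform_zero_delta_one_halfhalf_analytic(self):
        assert ln.modulation_index(np.full(20, 1 / 20)) == 0.0
        delta = np.zeros(20)
        delta[7] = 1.0
        assert ln.modulation_index(delta) == 1.0
        half = np.zeros(20)
        half[:2] = 0.5
        assert ln.modulation_index(half) == pytest.approx(
            1.0 - np.log(2) / np.log(20), abs=1e-12
        )

    def test_agrees_with_independent_oracle_on_random_distributions(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(20) * rng.uniform(0.1, 5.0))
            assert ln.modulation_index(p) == pytest.approx(
                oracle_mi(p), abs=1e-12
            )

    def test_logn2_reference_halves_the_index(self):
        half = np.zeros(20)
        half[:2] = 0.5
        mi_n = ln.modulation_index(half, reference="logN")
        mi_n2 = ln.modulation_index(half, reference="logN2")
        assert mi_n2 == pytest.approx((1.0 + mi_n) / 2.0, abs=1e-12)

    @given(
        st.lists(st.floats(0.01, 10.0), min_size=2, max_size=40),
        st.integers(0, 39),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_mi_bounded_and_invariant_to_bin_rotation(self, weights, shift):
        p = np.array(weights)
        p = p / p.sum()
        mi = ln.modulation_index(p)
        assert 0.0 <= mi <= 1.0
        assert ln.modulation_index(np.roll(p, shift)) == pytest.approx(
            mi, abs=1e-12
        )


class TestComodulogram:
    def test_peak_recovered_at_generator_truth(self, coupled_recording):
        spec, rec = coupled_recording
        x = rec.data[0].astype(float)
        com = ln.comodulogram(
            x, x, rec.fs_hz,
            phase_freqs_hz=np.arange(4.0, 7.6, 0.5),
            amp_freqs_hz=np.arange(55.0, 75.5, 0.5),
        )
        fp, fa = com.peak()
        assert abs(fp - spec.phase_freq_hz) <= 0.5
        assert abs(fa - spec.amp_freq_hz) <= 2.0
        assert np.all(com.mi >= 0) and np.all(com.mi <= 1)

    def test_amplitude_rescaling_invariance(self, coupled_recording):
        spec, rec = coupled_recording
        x = rec.data[0].astype(float)[:20000]
        grid = dict(phase_freqs_hz=[5.0], amp_freqs_hz=[60.0, 65.0])
        c1 = ln.comodulogram(x, x, rec.fs_hz, **grid)
        c2 = ln.comodulogram(x, 7.5 * x, rec.fs_hz, **grid)
        assert np.allclose(c1.mi, c2.mi, atol=1e-12)

    def test_directionality_channel_swap_differs(self, rng):
        fs = 1000.0
        spec = ln.CouplingSpec(coupling_strength=0.9, noise_sd=0.3)
        a = ln.generate_coupled_lfp(spec, 30.0, fs, seed=1).data[0].astype(float)
        b = rng.normal(size=a.size)
        grid = dict(phase_freqs_hz=[5.0], amp_freqs_hz=[65.0])
        ab = ln.comodulogram(a, b, fs, **grid).mi[0, 0]
        ba = ln.comodulogram(b, a, fs, **grid).mi[0, 0]
        assert ab != ba

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            ln.comodulogram(rng.normal(size=1000), rng.normal(size=1000),
                            1000.0, phase_freqs_hz=[], amp_freqs_hz=[30.0])


class TestChiMonotonicity:
    def test_mi_nondecreasing_in_coupling_strength(self):
        from scipy.stats import spearmanr

        fs = 1000.0
        rhos = []
        for seed in range(5):
            mis = []
            for chi in (0.0, 0.3, 0.6, 0.9):
                spec = ln.CouplingSpec(coupling_strength=chi)
                rec = ln.generate_coupled_lfp(spec, 40.0, fs,
                                              seed=100 * seed + int(10 * chi))
                x = rec.data[0].astype(float)
                ph = ln.hilbert_phase(x, fs, (4.5, 5.5))
                amp, valid = ln.morlet_amplitude(x, fs, [65.0])
                d = ln.phase_bin_amplitudes(ph, amp[0], valid=valid[0])
                mis.append(ln.modulation_index(d.p))
            rhos.append(spearmanr([0.0, 0.3, 0.6, 0.9], mis).statistic)
        assert np.mean(rhos) == 1.0


class TestTimecourse:
    def test_band_mi_and_assembly(self, rng):
        fs = 1000.0
        entries = []
        seed = 0
        for animal in ("a0", "a1"):
            for week, cond, chi in [(0, "evoked", 0.6), (0, "resting", 0.2)]:
                seed += 1
                rec = ln.generate_coupled_lfp(
                    ln.CouplingSpec(coupling_strength=chi), 20.0, fs, seed=seed,
                )
                com = ln.comodulogram(
                    rec.data[0].astype(float), rec.data[0].astype(float), fs,
                    phase_freqs_hz=[4.5, 5.0, 5.5], amp_freqs_hz=[60.0, 65.0, 70.0],
                )
                entries.append((animal, week, cond, com))
        df = ln.pac_timecourse(entries, phase_band=(4.5, 5.5),
                               amp_band=(60.0, 70.0))
        assert len(df) == 4
        piv = df.pivot_table(index="animal", columns="condition",
                             values="value")
        assert (piv["evoked"] > piv["resting"]).all()

    def test_duplicate_cells_rejected(self, rng):
        com = ln.Comodulogram(
            mi=np.zeros((1, 1)), phase_freqs_hz=np.array([5.0]),
            amp_freqs_hz=np.array([65.0]),
        )
        entries = [("a0", 1, "evoked", com), ("a0", 1, "evoked", com)]
        with pytest.raises(ValueError):
            ln.pac_timecourse(entries, phase_band=(4, 6), amp_band=(60, 70))
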