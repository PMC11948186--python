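"""Spike-phase distributions, entrainment MI spectra, bands, phase locking."""

import numpy as np
import pytest

import laminet as ln
from laminet.entrainment import spike_phases


def oracle_mi(p):
    h = -sum(pi * np.log(pi) for pi in p if pi > 0)
    return (np.log(len(p)) - h) / np.log(len(p))


@pytest.fixture(scope="module")
def theta_lfp():
    return ln.generate_coupled_lfp(
        ln.CouplingSpec(phase_freq_hz=6.0, amp_freq_hz=70.0,
                        coupling_strength=0.5),
        60.0, 1000.0, seed=31,
    )


class TestSpikePhaseDistribution:
    def test_all_spikes_at_one_phase_gives_delta(self):
        phase = np.full(1000, 90.0)
        d = ln.spike_phase_distribution(np.arange(0.1, 0.9, 0.01), phase,
                                        1000.0)
        assert d.p.max() == 1.0
        assert np.argmax(d.p) == 15  # [90, 108) bin

    def test_wraparound_edge_bins(self):
        phase = np.zeros(1000)
        phase[100] = -170.0
        phase[200] = 170.0
        d = ln.spike_phase_distribution([0.1, 0.2], phase, 1000.0)
        assert d.p[0] == pytest.approx(0.5)   # [-180, -162)
        assert d.p[-1] == pytest.approx(0.5)  # [162, 180)
        assert d.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_phase_independent_spiking_near_uniform(self, theta_lfp, rng):
        from scipy.stats import chisquare

        ph = ln.hilbert_phase(theta_lfp.data[0].astype(float),
                              theta_lfp.fs_hz, (5.0, 7.0))
        nonsig = 0
        for i in range(25):
            times = np.sort(rng.uniform(1.0, 59.0, 600))
            d = ln.spike_phase_distribution(times, ph, 1000.0)
            _, p = chisquare(d.n_per_bin)
            nonsig += p > 0.05
        assert nonsig >= 21  # ~93% of runs non-significant at alpha=0.05

    def test_no_spikes_errors(self):
        with pytest.raises(ValueError):
            ln.spike_phase_distribution([], np.zeros(100), 1000.0)

    def test_invalid_edges_drop_spikes(self):
        phase = np.zeros(1000)
        valid = np.ones(1000, bool)
        valid[:500] = False
        kept = spike_phases([0.1, 0.7], phase, 1000.0, valid=valid)
        assert kept.size == 1


class TestEntrainmentMi:
    def test_uniform_zero_delta_one(self):
        assert ln.entrainment_mi(np.full(20, 0.05)) == 0.0
        delta = np.zeros(20)
        delta[0] = 1.0
        assert ln.entrainment_mi(delta) == 1.0

    def test_von_mises_locking_beats_poisson_and_matches_oracle(
        self, theta_lfp, rng
    ):
        locked = ln.generate_entrained_spikes(
            theta_lfp, ln.EntrainmentSpec(band_low_hz=5.0, band_high_hz=7.0,
                                          kappa=1.0, mean_rate_hz=33.0),
            seed=41,
        )
        assert locked.n_spikes > 1500
        ph = ln.hilbert_phase(theta_lfp.data[0].astype(float), 1000.0,
                              (5.0, 7.0))
        d_locked = ln.spike_phase_distribution(locked.times_s, ph, 1000.0)
        mi_locked = ln.entrainment_mi(d_locked.p)
        assert mi_locked == pytest.approx(oracle_mi(d_locked.p), abs=1e-12)

        poisson = np.sort(rng.uniform(1.0, 59.0, 2000))
        d_pois = ln.spike_phase_distribution(poisson, ph, 1000.0)
        assert mi_locked > ln.entrainment_mi(d_pois.p)


class TestMiSpectrum:
    def test_peak_at_locking_frequency(self, theta_lfp):
        st = ln.generate_entrained_spikes(
            theta_lfp, ln.EntrainmentSpec(band_low_hz=5.0, band_high_hz=7.0,
                                          kappa=2.0, mean_rate_hz=10.0),
            seed=43,
        )
        sp = ln.mi_spectrum(st.times_s, theta_lfp,
                            freqs_hz=np.arange(4.0, 20.5, 0.5))
        peak_freq = sp.freqs_hz[np.argmax(sp.mi)]
        assert abs(peak_freq - 6.0) <= 0.5
        assert sp.mi_normalized.max() == 1.0

    def test_zero_spike_unit_rejected(self, theta_lfp):
        with pytest.raises(ValueError):
            ln.mi_spectrum([], theta_lfp)


class TestIdentifyBand:
    def _spectrum(self, freqs, hot_mask, uid):
        mi = np.where(hot_mask, 1.0, 0.1)
        return ln.EntrainmentSpectrum(
            unit_id=uid, freqs_hz=freqs, mi=mi, mi_normalized=mi,
            lfp_channel=0,
        )

    def test_two_disjoint_populations_give_two_bands(self, theta_lfp):
        freqs = np.arange(4.0, 90.5, 0.5)
        slow, fast = [], []
        for i in range(3):
            slow.append(ln.mi_spectrum(
                ln.generate_entrained_spikes(
                    theta_lfp,
                    ln.EntrainmentSpec(band_low_hz=5, band_high_hz=7,
                                       kappa=2.0, mean_rate_hz=8.0),
                    seed=50 + i,
                ).times_s, theta_lfp, freqs_hz=freqs, unit_id=f"s{i}"))
            fast.append(ln.mi_spectrum(
                ln.generate_entrained_spikes(
                    theta_lfp,
                    ln.EntrainmentSpec(band_low_hz=60, band_high_hz=80,
                                       kappa=2.0, mean_rate_hz=15.0),
                    seed=60 + i,
                ).times_s, theta_lfp, freqs_hz=freqs, unit_id=f"f{i}"))
        bands = ln.identify_band(slow + fast)
        assert len(bands) == 2
        assert bands[0][0] <= 6.0 <= bands[0][1]
        assert bands[1][0] <= 70.0 <= bands[1][1]

    def test_all_poisson_population_returns_no_band(self, theta_lfp, rng):
        freqs = np.arange(4.0, 30.5, 0.5)
        spectra = [
            ln.mi_spectrum(np.sort(rng.uniform(1, 59, 500)), theta_lfp,
                           freqs_hz=freqs, unit_id=f"p{i}")
            for i in range(4)
        ]
        bands = ln.identify_band(spectra)
        # no frequency should be "strong" for >25% of independent Poisson units
        assert bands == [] or all(hi - lo <= 1.0 for lo, hi in bands)

    def test_single_hot_unit_single_band(self):
        freqs = np.arange(4.0, 10.5, 0.5)
        hot = (freqs >= 39.5) | ((freqs >= 6.0) & (freqs <= 7.0))
        sp = self._spectrum(freqs, (freqs >= 6.0) & (freqs <= 7.0), "u")
        bands = ln.identify_band([sp])
        assert len(bands) == 1
        lo, hi = bands[0]
        assert lo == 6.0 and hi == 7.0


class TestPhaseLocking:
    def test_single_spike_not_entrained(self, theta_lfp):
        res = ln.phase_locking([10.0], theta_lfp, (5.0, 7.0))
        assert res.resultant_length == pytest.approx(1.0)
        assert not res.entrained and not res.sufficient_spikes

    def test_entrained_flag_follows_rayleigh_gate(self, theta_lfp):
        st = ln.generate_entrained_spikes(
            theta_lfp, ln.EntrainmentSpec(band_low_hz=5, band_high_hz=7,
                                          kappa=2.0, mean_rate_hz=10.0),
            seed=71,
        )
        res = ln.phase_locking(st.times_s, theta_lfp, (5.0, 7.0), week=4)
        assert res.entrained and res.rayleigh_p < 0.05
        assert res.stage == "early-chronic"

    def test_mi_invariant_to_lfp_scaling(self, theta_lfp):
        st = ln.generate_entrained_spikes(
            theta_lfp, ln.EntrainmentSpec(kappa=1.0, mean_rate_hz=10.0),
            seed=73,
        )
        freqs = np.arange(5.0, 8.0, 0.5)
        s1 = ln.mi_spectrum(st.times_s, theta_lfp.data[0].astype(float),
                            fs_hz=1000.0, freqs_hz=freqs)
        s2 = ln.mi_spectrum(st.times_s,
                            5.0 * theta_lfp.data[0].astype(float),
                            fs_hz=1000.0, freqs_hz=freqs)
        assert np.allclose(s1.mi, s2.mi, atol=1e-9)


def test_stage_binning():
    assert ln.implantation_stage(0) == "acute"
    assert ln.implantation_stage(2) == "acute"
    assert ln.implantation_stage(3) == "early-chronic"
    assert ln.implantation_stage(8) == "early-chronic"
    assert ln.implantation_stage(9) == "chronic"
    assert ln.implantation_stage(16) == "chronic"
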