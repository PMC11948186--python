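"""Phase-amplitude coupling (PAC) via the Kullback-Leibler modulation index.

The estimator bins the instantaneous phase of a slow oscillation (Channel X)
into N = 20 bins of 18 degrees, averages the instantaneous amplitude of a fast
oscillation (Channel Y) in each bin, normalizes the bin means into a
distribution P, and scores its deviation from uniformity:

    H  = -sum_i P_i log P_i          (Shannon entropy, nats)
    MI = (Ho - H) / Ho,   Ho = log N (maximum entropy)

which is the KL divergence from the uniform distribution divided by its
maximum; MI is 0 for a uniform distribution (no coupling) and 1 for a
single-bin delta (maximal coupling).  Channel X = Channel Y measures
intralaminar synchronization; Channel X != Channel Y measures directional
interlaminar coupling (phase channel upstream).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocessing import hilbert_phase, morlet_amplitude
from .types import Comodulogram, ContinuousRecording, PhaseAmplitudeDistribution

__all__ = [
    "phase_bin_amplitudes",
    "distribution_entropy",
    "modulation_index",
    "comodulogram",
    "band_mi",
    "pac_timecourse",
    "DEFAULT_PHASE_FREQS",
    "DEFAULT_AMP_FREQS",
]

# Methods-default comodulogram grids: phase 4-7.5 Hz, amplitude 30-90 Hz,
# both in 0.5 Hz steps.  A wider figure-range preset (2-20 Hz phase) is
# available for exploratory plots.
DEFAULT_PHASE_FREQS = np.arange(4.0, 7.5 + 0.25, 0.5)
DEFAULT_AMP_FREQS = np.arange(30.0, 90.0 + 0.25, 0.5)
FIGURE_PHASE_FREQS = np.arange(2.0, 20.0 + 0.25, 0.5)

MIN_SAMPLES_PER_BIN = 10  # below this in any bin -> low-confidence flag


def phase_bin_amplitudes(phase_deg, amplitude, n_bins=20, valid=None):
    """Mean amplitude per phase bin, normalized to a distribution.

    Phases (degrees in [-180, 180)) are partitioned into ``n_bins`` equal
    bins; the amplitude series is averaged within each bin and the bin means
    are normalized by their sum.  Empty bins contribute a mean of 0.
    Segments where any bin holds fewer than 10 samples are flagged
    low-confidence.
    """
    phase_deg = np.asarray(phase_deg, dtype=float).ravel()
    amplitude = np.asarray(amplitude, dtype=float).ravel()
    if phase_deg.size != amplitude.size:
        raise ValueError("phase and amplitude must have equal length")
    if n_bins < 2:
        raise ValueError("need at least 2 phase bins")
    if valid is not None:
        valid = np.asarray(valid, dtype=bool).ravel()
        phase_deg = phase_deg[valid]
        amplitude = amplitude[valid]
    if phase_deg.size == 0:
        raise ValueError("no valid samples to bin")
    if np.any(amplitude < 0):
        raise ValueError("amplitude must be non-negative")

    width = 360.0 / n_bins
    idx = np.floor((phase_deg + 180.0) / width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # guard phase == +180 after rounding
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    total = means.sum()
    if total <= 0:
        raise ValueError("total amplitude is zero; distribution undefined")
    edges = -180.0 + width * np.arange(n_bins + 1)
    return PhaseAmplitudeDistribution(
        p=means / total,
        bin_edges_deg=edges,
        n_per_bin=counts,
        low_confidence=bool(np.any(counts < MIN_SAMPLES_PER_BIN)),
    )


def distribution_entropy(p):
    """Shannon entropy in nats, with the 0 log 0 := 0 convention."""
    p = np.asarray(p, dtype=float).ravel()
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("p must be a probability distribution")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def modulation_index(p, reference="logN"):
    """KL-based modulation index of a phase-binned distribution.

    MI = (Ho - H)/Ho with Ho = log N (``reference="logN"``, default).  The
    alternative ``reference="logN2"`` uses Ho = log(N^2) = 2 log N, which
    compresses the scale by half but preserves ordering.
    """
    p = np.asarray(p, dtype=float).ravel()
    h = distribution_entropy(p)
    n = p.size
    if reference == "logN":
        ho = np.log(n)
    elif reference == "logN2":
        ho = 2.0 * np.log(n)
    else:
        raise ValueError("reference must be 'logN' or 'logN2'")
    mi = (ho - h) / ho
    # clamp away float dust so the documented [0, 1] bounds hold exactly
    return float(min(max(mi, 0.0), 1.0))


def comodulogram(
    phase_signal,
    amp_signal,
    fs_hz,
    phase_freqs_hz=None,
    amp_freqs_hz=None,
    n_bins=20,
    phase_bandwidth_hz=0.5,
    n_cycles=5.0,
    phase_channel=0,
    amp_channel=0,
    condition="",
    week=None,
    reference="logN",
):
    """MI over a (phase frequency x amplitude frequency) grid.

    The phase series is the Hilbert phase of ``phase_signal`` band-passed at
    f +/- ``phase_bandwidth_hz`` for each phase frequency; the amplitude
    series is the 5-cycle Morlet envelope of ``amp_signal`` at each amplitude
    frequency.  Edge samples invalidated by the wavelet support are excluded
    from the binning.  Swapping the two signals is a different (directional)
    computation unless they are identical.
    """
    phase_freqs_hz = (
        DEFAULT_PHASE_FREQS if phase_freqs_hz is None
        else np.atleast_1d(np.asarray(phase_freqs_hz, dtype=float))
    )
    amp_freqs_hz = (
        DEFAULT_AMP_FREQS if amp_freqs_hz is None
        else np.atleast_1d(np.asarray(amp_freqs_hz, dtype=float))
    )
    if phase_freqs_hz.size == 0 or amp_freqs_hz.size == 0:
        raise ValueError("frequency grids must be non-empty")
    phase_signal = np.asarray(phase_signal, dtype=float).ravel()
    amp_signal = np.asarray(amp_signal, dtype=float).ravel()
    if phase_signal.size != amp_signal.size:
        raise ValueError("signals must have equal length")

    amp, valid = morlet_amplitude(amp_signal, fs_hz, amp_freqs_hz,
                                  n_cycles=n_cycles)
    mi = np.empty((phase_freqs_hz.size, amp_freqs_hz.size))
    for i, fp in enumerate(phase_freqs_hz):
        band = (max(fp - phase_bandwidth_hz, 0.05), fp + phase_bandwidth_hz)
        ph = hilbert_phase(phase_signal, fs_hz, band)
        for j in range(amp_freqs_hz.size):
            dist = phase_bin_amplitudes(ph, amp[j], n_bins=n_bins,
                                        valid=valid[j])
            mi[i, j] = modulation_index(dist.p, reference=reference)
    return Comodulogram(
        mi=mi,
        phase_freqs_hz=phase_freqs_hz,
        amp_freqs_hz=amp_freqs_hz,
        phase_channel=phase_channel,
        amp_channel=amp_channel,
        condition=condition,
        week=week,
    )


def band_mi(com: Comodulogram, phase_band, amp_band):
    """Mean MI over the sub-block of a comodulogram covering the given bands."""
    pmask = (com.phase_freqs_hz >= phase_band[0]) & (
        com.phase_freqs_hz <= phase_band[1]
    )
    amask = (com.amp_freqs_hz >= amp_band[0]) & (com.amp_freqs_hz <= amp_band[1])
    if not pmask.any() or not amask.any():
        raise ValueError("band does not intersect the comodulogram grid")
    return float(com.mi[np.ix_(pmask, amask)].mean())


def pac_timecourse(comodulograms, phase_band=(4.0, 7.5), amp_band=(30.0, 90.0)):
    """Assemble per-animal, per-week, per-condition band-MI values.

    Parameters
    ----------
    comodulograms : iterable of (animal_id, week, condition, Comodulogram)
        One comodulogram per animal x week x condition cell.  Missing cells
        are simply absent from the output (never imputed).

    Returns
    -------
    DataFrame with columns animal, week, condition, value — the longitudinal
    table consumed by the spline/CI-overlap comparison.
    """
    rows = []
    for animal, week, condition, com in comodulograms:
        rows.append(
            {
                "animal": animal,
                "week": int(week),
                "condition": condition,
                "value": band_mi(com, phase_band, amp_band),
            }
        )
    df = pd.DataFrame(rows, columns=["animal", "week", "condition", "value"])
    if df.duplicated(["animal", "week", "condition"]).any():
        raise ValueError("duplicated (animal, week, condition) cells")
    return df
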