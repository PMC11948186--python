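"""Band-limited signal extraction.

LFP and spike-band Butterworth filtering, threshold spike detection,
instantaneous phase via the Hilbert transform, and instantaneous amplitude
via a 5-cycle complex Morlet wavelet.

All filters are applied forward-backward (zero phase): coupling metrics
compare phase across channels and frequencies, so any filter-induced phase
lag would bias them.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import wrap_degrees

__all__ = [
    "lfp_filter",
    "spike_band_filter",
    "bandpass_filter",
    "decimate_lfp",
    "detect_spikes",
    "hilbert_phase",
    "morlet_amplitude",
    "morlet_half_support",
]

LFP_BAND_HZ = (0.4, 300.0)
SPIKE_BAND_HZ = (300.0, 5000.0)


def _check_finite(x):
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    return x


def bandpass_filter(x, fs_hz, band, order=2):
    """Zero-phase Butterworth band-pass.

    A 2nd-order design applied with ``sosfiltfilt`` gives an effective
    4th-order magnitude response and exactly zero phase shift.
    """
    x = _check_finite(x)
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"invalid band {band}")
    nyq = fs_hz / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz at/above Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def lfp_filter(x, fs_hz, band=LFP_BAND_HZ, order=2):
    """Extract the LFP stream: 2nd-order Butterworth 0.4-300 Hz, zero phase."""
    if fs_hz <= 600.0:
        raise ValueError("lfp_filter requires fs > 600 Hz")
    return bandpass_filter(x, fs_hz, band, order=order)


def spike_band_filter(x, fs_hz, band=SPIKE_BAND_HZ, order=2):
    """Extract the spiking stream: Butterworth 0.3-5 kHz, zero phase."""
    return bandpass_filter(x, fs_hz, band, order=order)


def decimate_lfp(x, fs_hz, target_fs_hz=1000.0):
    """Anti-alias and resample a wide-band signal to an LFP-friendly rate.

    Uses polyphase resampling with the rational factor closest to
    ``target_fs_hz / fs_hz``; returns ``(y, new_fs_hz)``.
    """
    from fractions import Fraction

    x = _check_finite(x)
    if target_fs_hz >= fs_hz:
        return x, fs_hz
    frac = Fraction(target_fs_hz / fs_hz).limit_denominator(100000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    return y, fs_hz * frac.numerator / frac.denominator


def detect_spikes(x_filtered, fs_hz, n_sd=3.5, lockout_ms=1.0):
    """Threshold detection on the spike-band signal.

    The threshold is ``mean(x) - n_sd * sd(x)`` (3.5 SD below the mean by
    default); a spike is registered at each negative-going crossing, with a
    refractory lockout to avoid double-counting multiphasic waveforms.

    Returns
    -------
    times_s : ndarray
        Crossing times in seconds.
    threshold : float
        The absolute threshold applied, in input units.
    """
    x = _check_finite(x_filtered)
    if x.size < fs_hz:
        raise ValueError("need at least 1 s of data for a stable SD")
    sd = float(np.std(x))
    if sd == 0.0:
        raise ValueError("zero-variance input: threshold undefined")
    threshold = float(np.mean(x)) - n_sd * sd
    below = x < threshold
    crossings = np.flatnonzero(~below[:-1] & below[1:]) + 1
    if crossings.size == 0:
        return np.empty(0), threshold
    lockout = int(round(lockout_ms * 1e-3 * fs_hz))
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] > lockout:
            kept.append(c)
    return np.asarray(kept, dtype=float) / fs_hz, threshold


def hilbert_phase(x, fs_hz, band, order=2):
    """Instantaneous phase (degrees in [-180, 180)) of a band-limited signal.

    The input is band-passed with a zero-phase Butterworth at the band edges
    and the phase of the analytic (Hilbert) signal is returned.  0° is the
    positive peak of the oscillation, ±180° its trough.
    """
    xf = bandpass_filter(x, fs_hz, band, order=order)
    analytic = sps.hilbert(xf, axis=-1)
    return wrap_degrees(np.degrees(np.angle(analytic)))


def _morlet_wavelet(freq_hz, fs_hz, n_cycles=5.0, support_sd=3.5):
    """Complex Morlet scaled so a unit-amplitude tone yields envelope 1."""
    sigma_t = n_cycles / (2.0 * np.pi * freq_hz)
    half = int(np.ceil(support_sd * sigma_t * fs_hz))
    t = np.arange(-half, half + 1) / fs_hz
    gauss = np.exp(-(t**2) / (2.0 * sigma_t**2))
    wavelet = gauss * np.exp(2j * np.pi * freq_hz * t)
    return wavelet / (0.5 * gauss.sum())


def morlet_half_support(freq_hz, fs_hz, n_cycles=5.0, support_sd=3.5):
    """Samples at each edge contaminated by the wavelet support."""
    sigma_t = n_cycles / (2.0 * np.pi * freq_hz)
    return int(np.ceil(support_sd * sigma_t * fs_hz))


def morlet_amplitude(x, fs_hz, freqs_hz, n_cycles=5.0):
    """Instantaneous amplitude by 5-cycle complex Morlet convolution.

    Returns
    -------
    amplitude : ndarray, shape (n_freqs, n_samples)
        Envelope in input units (a unit cosine at f maps to ~1 at f).
    valid : ndarray of bool, same shape
        False within half a wavelet support of either edge; these samples
        must be excluded from downstream binned statistics.
    """
    x = _check_finite(x)
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    if np.any(freqs_hz <= 0):
        raise ValueError("frequencies must be positive")
    n = x.shape[-1]
    amp = np.empty((freqs_hz.size, n))
    valid = np.ones((freqs_hz.size, n), dtype=bool)
    for i, f in enumerate(freqs_hz):
        w = _morlet_wavelet(f, fs_hz, n_cycles=n_cycles)
        conv = sps.fftconvolve(x, w, mode="same")
        amp[i] = np.abs(conv)
        half = min(len(w) // 2, n)
        valid[i, :half] = False
        valid[i, n - half:] = False
    return amp, valid
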