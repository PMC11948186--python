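"""Ground-truth-labelled synthetic sessions.

Every statistical structure the downstream analysis assumes is emulated
here with controllable parameters and a stored ground truth:

* laminar LFP with theta-phase -> gamma-amplitude coupling of known
  strength (chi) and preferred phase,
* stimulus-locked L4 current sinks (Gaussian in depth, biphasic in time)
  within 100 ms of stimulus onset,
* spike trains phase-locked (von Mises) to a chosen LFP band, sampled as
  an inhomogeneous Poisson process by thinning,
* spike waveforms with a bimodal trough-to-peak latency distribution
  (narrow ~0.25 ms, wide ~0.54 ms),
* week-by-week longitudinal metric tables with per-animal repeated-measures
  structure.

The generators are deterministic given their seed: the same seed
reproduces a session bit-for-bit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .preprocessing import hilbert_phase
from .types import (
    ContinuousRecording,
    CouplingSpec,
    EntrainmentSpec,
    LaminarLayout,
    SpikeTrain,
    SyntheticSession,
    UnitRecord,
)

__all__ = [
    "generate_coupled_lfp",
    "generate_entrained_spikes",
    "generate_laminar_session",
    "generate_waveform_population",
    "generate_longitudinal_table",
]

# Waveform latency mixture: modes at 0.25 ms (narrow, putative inhibitory)
# and 0.54 ms (wide, putative excitatory); SD 0.04 ms puts the 0.41 ms
# class boundary 4 SD from either mode, so <2% of mass crosses it.
NARROW_LATENCY_MS = 0.25
WIDE_LATENCY_MS = 0.54
LATENCY_SD_MS = 0.04
WAVEFORM_FS_HZ = 24414.0


def coupled_lfp_samples(spec: CouplingSpec, duration_s, fs_hz, rng):
    """Raw float64 samples of one coupled channel (shared by generators).

    signal(t) = sin(phi_low) + A(t) sin(2 pi f_amp t) + noise, with the fast
    envelope A(t) = amp_scale [1 + chi cos(phi_low - phi_pref)] / (1 + chi);
    chi = 0 makes the envelope independent of the slow phase.
    """
    spec.validate()
    if not np.isfinite(duration_s) or duration_s <= 0:
        raise ValueError("duration must be positive and finite")
    if fs_hz < 2.5 * spec.amp_freq_hz:
        raise ValueError(
            f"fs {fs_hz} Hz under-samples the {spec.amp_freq_hz} Hz carrier "
            "(need fs >= 2.5 x amp frequency)"
        )
    if duration_s * spec.phase_freq_hz < 10:
        raise ValueError("need at least 10 cycles of the phase frequency")
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    phi_low = 2.0 * np.pi * spec.phase_freq_hz * t
    phi_pref = np.radians(spec.preferred_phase_deg)
    chi = spec.coupling_strength
    envelope = (
        spec.amp_scale * (1.0 + chi * np.cos(phi_low - phi_pref)) / (1.0 + chi)
    )
    x = np.sin(phi_low) + envelope * np.sin(2.0 * np.pi * spec.amp_freq_hz * t)
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, size=n)
    return x


def generate_coupled_lfp(spec: CouplingSpec, duration_s, fs_hz, seed):
    """Single-channel LFP whose gamma envelope is modulated by theta phase."""
    rng = np.random.default_rng(seed)
    x = coupled_lfp_samples(spec, duration_s, fs_hz, rng)
    return ContinuousRecording(
        data=x[None, :].astype(np.float32),
        fs_hz=float(fs_hz),
        channel_depths_um=np.array([0.0]),
    )


def generate_entrained_spikes(
    lfp: ContinuousRecording,
    spec: EntrainmentSpec,
    duration_s=None,
    seed=0,
    channel=0,
):
    """Spikes phase-locked to a band of the given LFP (von Mises locking).

    An inhomogeneous Poisson process is sampled by thinning with intensity
    lambda(t) proportional to exp(kappa cos(phi_band(t) - phi_pref)),
    normalized so the realized mean rate approaches ``spec.mean_rate_hz``;
    phi_band is the Hilbert phase of the band-filtered LFP.  kappa = 0
    yields phase-independent (uniform-phase) firing.
    """
    spec.validate()
    if duration_s is None:
        duration_s = lfp.duration_s
    if duration_s > lfp.duration_s + 1e-9:
        raise ValueError("requested duration exceeds the LFP recording")
    rng = np.random.default_rng(seed)
    fs = lfp.fs_hz
    n = int(round(duration_s * fs))
    phase_deg = hilbert_phase(
        lfp.data[channel, :n].astype(float), fs,
        (spec.band_low_hz, spec.band_high_hz),
    )
    phi = np.radians(phase_deg)
    mod = np.exp(spec.kappa * np.cos(phi - np.radians(spec.preferred_phase_deg)))
    lam = spec.mean_rate_hz * mod / mod.mean()  # Hz, per-sample intensity
    lam_max = float(lam.max())
    n_cand = rng.poisson(lam_max * duration_s)
    cand = rng.uniform(0.0, duration_s, size=n_cand)
    cand.sort()
    idx = np.minimum((cand * fs).astype(int), n - 1)
    keep = rng.uniform(0.0, 1.0, size=n_cand) < lam[idx] / lam_max
    times = cand[keep]
    if times.size == 0 and spec.mean_rate_hz * duration_s >= 1:
        warnings.warn("no spikes generated despite expected count >= 1")
    return SpikeTrain(times_s=times, channel=channel)


def _sink_waveform(time_s, latency_s, width_s, amplitude):
    """Biphasic stimulus-locked deflection: sharp negative lobe, smaller
    positive rebound."""
    neg = np.exp(-((time_s - latency_s) ** 2) / (2.0 * width_s**2))
    reb = np.exp(
        -((time_s - latency_s - 2.5 * width_s) ** 2) / (2.0 * (1.5 * width_s) ** 2)
    )
    return amplitude * (-neg + 0.35 * reb)


def generate_laminar_session(
    layout: LaminarLayout | None = None,
    coupling_by_layer: dict | None = None,
    unit_specs: list | None = None,
    n_stimuli=50,
    sink_channel=4,
    sink_latency_ms=40.0,
    sink_amplitude=1.0,
    sink_width_ms=12.0,
    sink_spatial_sd_ch=0.8,
    duration_s=None,
    fs_hz=1000.0,
    isi_s=0.5,
    seed=0,
):
    """Full 16-channel synthetic session with stimulus-locked L4 sink.

    Each channel carries the coupled background of its layer (independent
    noise per channel); stimulus-triggered averages contain a spatially
    localized negative deflection centred on ``sink_channel``, Gaussian in
    depth and biphasic in time, peaking ``sink_latency_ms`` after onset.

    ``unit_specs`` is a list of ``(channel, EntrainmentSpec, class_label)``
    tuples; class_label in {"excitatory", "inhibitory"} selects the waveform
    mode.  Ground truth (specs, sink position, labels) is stored on the
    returned session.
    """
    layout = layout or LaminarLayout()
    layout.validate()
    if coupling_by_layer is None:
        coupling_by_layer = {}
    if sink_latency_ms >= 100.0:
        raise ValueError("sink latency must be below 100 ms post-stimulus")
    if not 0 <= sink_channel < layout.n_channels:
        raise ValueError("sink_channel outside the layout")
    if n_stimuli < 10:
        warnings.warn("fewer than 10 stimuli: CSD average may be unstable")

    rng = np.random.default_rng(seed)
    depths = layout.channel_depths_um()
    if duration_s is None:
        duration_s = max(10.0, 1.0 + n_stimuli * isi_s + 1.0)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz

    stim_times = 1.0 + isi_s * np.arange(n_stimuli)
    stim_times = stim_times[stim_times + 0.3 < duration_s]

    default_spec = CouplingSpec()
    data = np.empty((layout.n_channels, n), dtype=np.float32)
    for ch in range(layout.n_channels):
        layer = layout.layer_of_depth(depths[ch])
        spec = coupling_by_layer.get(layer, default_spec)
        data[ch] = coupled_lfp_samples(spec, duration_s, fs_hz, rng).astype(
            np.float32
        )

    # add the stimulus-locked sink, Gaussian across channels
    spatial = np.exp(
        -((np.arange(layout.n_channels) - sink_channel) ** 2)
        / (2.0 * sink_spatial_sd_ch**2)
    )
    win = int(round(0.25 * fs_hz))  # 250 ms of evoked response per stimulus
    tau = np.arange(win) / fs_hz
    kernel = _sink_waveform(tau, sink_latency_ms / 1000.0, sink_width_ms / 1000.0,
                            sink_amplitude)
    for s in stim_times:
        i0 = int(round(s * fs_hz))
        i1 = min(i0 + win, n)
        data[:, i0:i1] += (spatial[:, None] * kernel[None, : i1 - i0]).astype(
            np.float32
        )

    recording = ContinuousRecording(
        data=data, fs_hz=float(fs_hz), channel_depths_um=depths,
        stim_times_s=stim_times,
    )

    units = []
    if unit_specs:
        for k, (ch, espec, label) in enumerate(unit_specs):
            train = generate_entrained_spikes(
                recording, espec, seed=int(rng.integers(2**31)), channel=ch
            )
            latency = (
                NARROW_LATENCY_MS if label == "inhibitory" else WIDE_LATENCY_MS
            )
            wf = _make_waveform(latency, WAVEFORM_FS_HZ)
            units.append(
                UnitRecord(
                    unit_id=f"u{k:03d}",
                    channel=ch,
                    depth_um=float(depths[ch]),
                    week=0,
                    spike_times_s={"evoked": train.times_s},
                    waveform=wf,
                    waveform_fs_hz=WAVEFORM_FS_HZ,
                    truth={
                        "class": label,
                        "preferred_phase_deg": espec.preferred_phase_deg,
                        "band_hz": (espec.band_low_hz, espec.band_high_hz),
                        "kappa": espec.kappa,
                    },
                )
            )

    truth = {
        "layout": layout,
        "coupling_by_layer": coupling_by_layer,
        "sink_channel": int(sink_channel),
        "sink_latency_ms": float(sink_latency_ms),
        "sink_amplitude": float(sink_amplitude),
    }
    return SyntheticSession(recording=recording, units=units, truth=truth,
                            seed=int(seed))


def _make_waveform(latency_ms, fs_hz, trough_frac=0.35, duration_ms=2.5,
                   amplitude=80.0):
    """Biphasic extracellular spike template with a set trough-to-peak lag."""
    n = int(round(duration_ms * 1e-3 * fs_hz))
    t = np.arange(n) / fs_hz * 1000.0  # ms
    t_trough = duration_ms * trough_frac
    t_peak = t_trough + latency_ms
    sd_t = max(latency_ms / 5.0, 0.04)  # keep lobes well separated
    sd_p = max(latency_ms / 3.0, 0.06)
    wf = -np.exp(-((t - t_trough) ** 2) / (2 * sd_t**2))
    wf += 0.45 * np.exp(-((t - t_peak) ** 2) / (2 * sd_p**2))
    return (amplitude * wf).astype(np.float64)


def generate_waveform_population(n_narrow, n_wide, seed=0, fs_hz=WAVEFORM_FS_HZ):
    """Units whose trough-to-peak latencies form the bimodal narrow/wide
    mixture (modes 0.25 ms and 0.54 ms, SD 0.04 ms).

    Returns UnitRecords with the true class stored in ``truth["class"]`` and
    no spike trains (waveform-only population).
    """
    if n_narrow < 0 or n_wide < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    lats = np.concatenate(
        [
            rng.normal(NARROW_LATENCY_MS, LATENCY_SD_MS, size=n_narrow),
            rng.normal(WIDE_LATENCY_MS, LATENCY_SD_MS, size=n_wide),
        ]
    )
    lats = np.clip(lats, 0.08, None)
    labels = ["inhibitory"] * n_narrow + ["excitatory"] * n_wide
    units = []
    for k, (lat, label) in enumerate(zip(lats, labels)):
        units.append(
            UnitRecord(
                unit_id=f"w{k:04d}",
                channel=0,
                depth_um=0.0,
                week=0,
                spike_times_s={},
                waveform=_make_waveform(float(lat), fs_hz),
                waveform_fs_hz=fs_hz,
                truth={"class": label, "latency_ms": float(lat)},
            )
        )
    return units


def generate_longitudinal_table(
    n_animals=8,
    weeks=tuple(range(17)),
    condition_effect=None,
    animal_sd=0.01,
    residual_sd=0.01,
    baseline=None,
    seed=0,
):
    """Per-animal, per-week, per-condition metric values with a known effect.

    value = baseline(week) + condition_effect(week) * 1[evoked]
            + animal intercept + residual noise.

    Defaults mimic an MI-scale metric (baseline 0.05) across the 8-animal,
    17-week study design; the ground-truth effect curve is stored in
    ``df.attrs["truth"]``.
    """
    if condition_effect is None:
        condition_effect = lambda w: 0.0  # noqa: E731
    if baseline is None:
        baseline = lambda w: 0.05  # noqa: E731
    rng = np.random.default_rng(seed)
    weeks = np.asarray(list(weeks), dtype=int)
    intercepts = rng.normal(0.0, animal_sd, size=n_animals)
    rows = []
    for a in range(n_animals):
        for w in weeks:
            for cond in ("resting", "evoked"):
                val = (
                    baseline(w)
                    + (condition_effect(w) if cond == "evoked" else 0.0)
                    + intercepts[a]
                    + rng.normal(0.0, residual_sd)
                )
                rows.append(
                    {"animal": f"a{a}", "week": int(w), "condition": cond,
                     "value": val}
                )
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {
        "condition_effect": {int(w): float(condition_effect(w)) for w in weeks},
        "animal_sd": animal_sd,
        "residual_sd": residual_sd,
    }
    return df
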