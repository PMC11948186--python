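"""Core in-memory containers shared across the analysis modules.

Conventions enforced at every module boundary:

* times are in seconds, frequencies in Hz, depths in micrometres;
* phases are in degrees in ``[-180, 180)``, with 0° at the positive peak of
  the band-limited oscillation and ±180° at its trough;
* channel 0 is the shallowest site and depth increases with channel index;
* continuous samples are stored as little-endian float32 so that session
  bundles round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "ContinuousRecording",
    "SpikeTrain",
    "UnitRecord",
    "CouplingSpec",
    "EntrainmentSpec",
    "LaminarLayout",
    "SyntheticSession",
    "AnalyticSeries",
    "CsdMap",
    "LaminarAlignment",
    "PhaseAmplitudeDistribution",
    "Comodulogram",
    "EntrainmentSpectrum",
    "EntrainmentResult",
    "SplineBasis",
    "wrap_degrees",
]


def wrap_degrees(deg):
    """Wrap angles (degrees) into ``[-180, 180)``."""
    return (np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class ContinuousRecording:
    """Multichannel extracellular voltage series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples), float32
        Voltage in microvolts (arbitrary for synthetic data).
    fs_hz : float
        Sampling rate.
    channel_depths_um : ndarray, shape (n_channels,)
        Depth of each site below the cortical surface, strictly increasing.
    stim_times_s : ndarray
        Stimulus onset times in seconds (empty for resting recordings).
    """

    data: np.ndarray
    fs_hz: float
    channel_depths_um: np.ndarray
    stim_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim == 1:
            self.data = self.data[None, :]
        self.channel_depths_um = np.asarray(self.channel_depths_um, dtype=float)
        self.stim_times_s = np.asarray(self.stim_times_s, dtype=float)
        if self.data.shape[0] != self.channel_depths_um.size:
            raise ValueError(
                f"{self.data.shape[0]} channels but "
                f"{self.channel_depths_um.size} depths"
            )
        if self.channel_depths_um.size > 1 and not np.all(
            np.diff(self.channel_depths_um) > 0
        ):
            raise ValueError("channel depths must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class SpikeTrain:
    """Sorted spike times for one unit, in seconds from recording start."""

    times_s: np.ndarray
    unit_id: str = "u0"
    channel: int = 0

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.size and np.any(np.diff(self.times_s) < 0):
            self.times_s = np.sort(self.times_s)

    @property
    def n_spikes(self) -> int:
        return self.times_s.size


@dataclass
class UnitRecord:
    """A sorted single unit with its mean waveform and classification."""

    unit_id: str
    channel: int
    depth_um: float
    week: int
    spike_times_s: dict  # condition -> ndarray of times (s)
    waveform: np.ndarray  # mean waveform, microvolts
    waveform_fs_hz: float
    trough_to_peak_ms: float | None = None
    putative_class: str | None = None  # "excitatory" | "inhibitory"
    truth: dict = field(default_factory=dict)  # ground-truth labels (synthetic)


# ---------------------------------------------------------------------------
# synthetic-session specifications


@dataclass(frozen=True)
class CouplingSpec:
    """Ground truth for one theta-phase -> gamma-amplitude coupled channel.

    ``coupling_strength`` (chi) is the modulation depth of the fast
    oscillation's envelope: 0 means the envelope is independent of the slow
    phase, 1 means the envelope goes to zero at the anti-preferred phase.
    """

    phase_freq_hz: float = 5.0
    amp_freq_hz: float = 65.0
    coupling_strength: float = 0.6
    preferred_phase_deg: float = 0.0
    amp_scale: float = 0.5
    noise_sd: float = 0.5

    def validate(self):
        vals = [
            self.phase_freq_hz,
            self.amp_freq_hz,
            self.coupling_strength,
            self.preferred_phase_deg,
            self.amp_scale,
            self.noise_sd,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("CouplingSpec fields must be finite")
        if self.phase_freq_hz <= 0 or self.amp_freq_hz <= 0:
            raise ValueError("frequencies must be positive")
        if self.amp_freq_hz <= self.phase_freq_hz:
            raise ValueError("amp_freq_hz must exceed phase_freq_hz")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.amp_scale <= 0:
            raise ValueError("amp_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class EntrainmentSpec:
    """Ground truth for one phase-locked (von Mises) spike train."""

    band_low_hz: float = 4.0
    band_high_hz: float = 7.5
    kappa: float = 1.0
    preferred_phase_deg: float = 0.0
    mean_rate_hz: float = 10.0

    def validate(self):
        if not self.band_low_hz < self.band_high_hz:
            raise ValueError("band_low_hz must be below band_high_hz")
        if self.band_low_hz <= 0:
            raise ValueError("band edges must be positive")
        if not np.isfinite(self.kappa) or self.kappa < 0:
            raise ValueError("kappa must be finite and non-negative")
        if self.mean_rate_hz <= 0:
            raise ValueError("mean_rate_hz must be positive")


_DEFAULT_LAYERS = {
    "L1": (0.0, 100.0),
    "L2/3": (100.0, 300.0),
    "L4": (300.0, 500.0),
    "L5/6": (500.0, 1000.0),
    "CA1": (1000.0, 1600.0),
}


@dataclass(frozen=True)
class LaminarLayout:
    """Geometry of the single-shank laminar probe.

    Defaults mirror a 16-channel, 100 µm site-spacing shank inserted to
    1600 µm, spanning all cortical layers down to hippocampal CA1.
    """

    n_channels: int = 16
    site_spacing_um: float = 100.0
    insertion_depth_um: float = 1600.0
    layer_boundaries_um: dict = field(
        default_factory=lambda: dict(_DEFAULT_LAYERS)
    )

    def validate(self):
        if self.n_channels < 3:
            raise ValueError("need at least 3 channels")
        if self.site_spacing_um <= 0 or self.insertion_depth_um <= 0:
            raise ValueError("spacing and insertion depth must be positive")
        if self.channel_depths_um()[-1] > self.insertion_depth_um:
            raise ValueError("deepest site exceeds insertion depth")

    def channel_depths_um(self) -> np.ndarray:
        """Depth of each site; channel 0 shallowest, tip at insertion depth."""
        tip = self.insertion_depth_um
        depths = tip - self.site_spacing_um * np.arange(
            self.n_channels - 1, -1, -1
        )
        return depths

    def layer_of_depth(self, depth_um: float) -> str:
        for name, (lo, hi) in self.layer_boundaries_um.items():
            if lo <= depth_um < hi:
                return name
        # anything at/below the last boundary belongs to the deepest layer
        return list(self.layer_boundaries_um)[-1]


@dataclass
class SyntheticSession:
    """A generated session with its full ground truth attached."""

    recording: ContinuousRecording
    units: list  # list[UnitRecord]
    truth: dict
    seed: int


# ---------------------------------------------------------------------------
# analysis products


@dataclass
class AnalyticSeries:
    """Per-frequency instantaneous phase and/or amplitude of one channel."""

    freqs_hz: np.ndarray
    fs_hz: float
    phase_deg: np.ndarray | None = None  # (n_freqs, n_samples)
    amplitude: np.ndarray | None = None  # (n_freqs, n_samples)
    valid: np.ndarray | None = None  # (n_freqs, n_samples) bool


@dataclass
class CsdMap:
    """Stimulus-locked current source density (sinks negative)."""

    csd: np.ndarray  # (n_channels - 2, n_times), arbitrary units / mm^2
    time_ms: np.ndarray  # relative to stimulus onset
    channel_indices: np.ndarray  # original channel index of each CSD row


@dataclass
class LaminarAlignment:
    """Layer assignment of probe channels anchored at the L4 sink."""

    l4_channel: int | None
    layer_of_channel: dict  # channel index -> layer name
    sink_latency_ms: float | None
    sink_amplitude: float | None
    failed: bool = False


@dataclass
class PhaseAmplitudeDistribution:
    """Normalized mean-amplitude (or spike-probability) per phase bin."""

    p: np.ndarray  # (n_bins,) probabilities, sums to 1
    bin_edges_deg: np.ndarray  # (n_bins + 1,)
    n_per_bin: np.ndarray  # samples (or spikes) per bin
    low_confidence: bool = False  # some bin has < 10 samples

    @property
    def n_bins(self) -> int:
        return self.p.size


@dataclass
class Comodulogram:
    """PAC modulation index over a (phase freq x amplitude freq) grid."""

    mi: np.ndarray  # (n_phase_freqs, n_amp_freqs)
    phase_freqs_hz: np.ndarray
    amp_freqs_hz: np.ndarray
    phase_channel: int = 0
    amp_channel: int = 0
    condition: str = ""
    week: int | None = None

    def peak(self) -> tuple[float, float]:
        """(phase freq, amp freq) of the maximal MI cell."""
        i, j = np.unravel_index(np.argmax(self.mi), self.mi.shape)
        return float(self.phase_freqs_hz[i]), float(self.amp_freqs_hz[j])


@dataclass
class EntrainmentSpectrum:
    """Spike-entrainment MI of one unit across LFP frequencies."""

    unit_id: str
    freqs_hz: np.ndarray
    mi: np.ndarray
    mi_normalized: np.ndarray
    lfp_channel: int


@dataclass
class EntrainmentResult:
    """Phase locking of one unit to a band-limited LFP oscillation."""

    unit_id: str
    band_hz: tuple
    phases_deg: np.ndarray
    mean_angle_deg: float
    resultant_length: float
    rayleigh_p: float
    entrained: bool
    n_spikes: int
    sufficient_spikes: bool = True
    stage: str | None = None  # acute / early-chronic / chronic


def implantation_stage(week: int) -> str:
    """Implantation stage bins: acute 0-2, early-chronic 3-8, chronic 9-16."""
    if week <= 2:
        return "acute"
    if week <= 8:
        return "early-chronic"
    return "chronic"


@dataclass
class SplineBasis:
    """Restricted cubic spline basis (linear + two restricted cubic terms)."""

    knots: np.ndarray  # 4 interior+boundary knots, ascending
    transform: Callable  # x -> (len(x), 3) design columns
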