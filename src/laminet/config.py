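"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RunConfig"]


def _grid(lo, hi, step):
    return list(np.round(np.arange(lo, hi + step / 2, step), 6))


@dataclass
class RunConfig:
    """All knobs of the pipeline, with the study defaults.

    Frequency grids follow the analysis conventions: PAC phase 4-7.5 Hz and
    amplitude 30-90 Hz in 0.5 Hz steps, entrainment 4-90 Hz; phases binned
    every 18 degrees (20 bins).
    """

    input_path: str = ""
    output_path: str = "laminet_out"
    phase_freqs_hz: list = field(default_factory=lambda: _grid(4.0, 7.5, 0.5))
    amp_freqs_hz: list = field(default_factory=lambda: _grid(30.0, 90.0, 0.5))
    entrain_freqs_hz: list = field(default_factory=lambda: _grid(4.0, 90.0, 0.5))
    bin_width_deg: float = 18.0
    phase_bandwidth_hz: float = 0.5
    lfp_band_hz: list = field(default_factory=lambda: [0.4, 300.0])
    spike_band_hz: list = field(default_factory=lambda: [300.0, 5000.0])
    filter_order: int = 2
    target_lfp_fs_hz: float = 1000.0
    conditions: list = field(default_factory=lambda: ["evoked", "resting"])
    seed: int = 0
    run_alignment: bool = True
    run_units: bool = True
    run_pac: bool = True
    run_entrainment: bool = True
    pac_channel_pairs: list = field(default_factory=lambda: [[4, 4]])
    entrain_lfp_channel: int | None = None  # default: each unit's own channel

    def __post_init__(self):
        self.validate()

    @property
    def n_bins(self) -> int:
        return int(round(360.0 / self.bin_width_deg))

    def validate(self):
        if 360.0 % self.bin_width_deg != 0:
            raise ValueError("bin width must divide 360 exactly")
        for name in ("phase_freqs_hz", "amp_freqs_hz", "entrain_freqs_hz"):
            grid = getattr(self, name)
            if len(grid) == 0:
                raise ValueError(f"{name} is empty")
            if np.any(np.diff(grid) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.lfp_band_hz[0] >= self.lfp_band_hz[1]:
            raise ValueError("invalid LFP band")
        if self.spike_band_hz[0] >= self.spike_band_hz[1]:
            raise ValueError("invalid spike band")

    def to_dict(self):
        return asdict(self)

    def hash(self) -> str:
        """Stable hash of the full configuration, stamped on every output."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d):
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path):
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))

    def to_file(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))
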