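"""Session bundles: on-disk layout for synthetic or imported sessions.

A bundle is a directory holding::

    manifest.json        layout, sampling rate, seed, ground truth
    channels.json        per-channel sidecar (file name, n_samples, fs, dtype)
    ch00.f32 ...         flat little-endian float32 voltage, one file/channel
    events.csv           stimulus onset times (seconds, 1 header row)
    spikes.csv           unit_id, time_s, condition (1 header row)
    units.csv            per-unit metadata
    waveforms.csv        unit_id + one column per waveform sample

All continuous data are stored and held in memory as float32, so a
write -> read round trip is bit-lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ContinuousRecording,
    LaminarLayout,
    SyntheticSession,
    UnitRecord,
)

__all__ = ["write_session", "read_session", "BundleError"]

DTYPE = "<f4"


class BundleError(RuntimeError):
    """A session bundle is missing, corrupt, or inconsistent."""


def _layout_to_json(layout: LaminarLayout):
    return {
        "n_channels": layout.n_channels,
        "site_spacing_um": layout.site_spacing_um,
        "insertion_depth_um": layout.insertion_depth_um,
        "layer_boundaries_um": {
            k: list(v) for k, v in layout.layer_boundaries_um.items()
        },
    }


def _layout_from_json(d):
    return LaminarLayout(
        n_channels=int(d["n_channels"]),
        site_spacing_um=float(d["site_spacing_um"]),
        insertion_depth_um=float(d["insertion_depth_um"]),
        layer_boundaries_um={
            k: tuple(v) for k, v in d["layer_boundaries_um"].items()
        },
    )


def _jsonable_truth(truth: dict):
    out = {}
    for k, v in truth.items():
        if isinstance(v, LaminarLayout):
            out[k] = {"__layout__": _layout_to_json(v)}
        elif hasattr(v, "__dataclass_fields__"):
            out[k] = {"__spec__": type(v).__name__, **vars(v)}
        elif isinstance(v, dict):
            out[k] = _jsonable_truth(v)
        elif isinstance(v, (np.integer, np.floating)):
            out[k] = v.item()
        elif isinstance(v, tuple):
            out[k] = list(v)
        else:
            out[k] = v
    return out


def write_session(session: SyntheticSession, path):
    """Serialize a session to a bundle directory; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rec = session.recording

    channels = []
    for ch in range(rec.n_channels):
        fname = f"ch{ch:02d}.f32"
        rec.data[ch].astype(DTYPE).tofile(path / fname)
        channels.append(
            {
                "channel": ch,
                "file": fname,
                "n_samples": int(rec.n_samples),
                "fs_hz": rec.fs_hz,
                "dtype": DTYPE,
                "depth_um": float(rec.channel_depths_um[ch]),
            }
        )
    (path / "channels.json").write_text(json.dumps(channels, indent=1))

    manifest = {
        "format": "laminet-session-bundle",
        "version": 1,
        "fs_hz": rec.fs_hz,
        "n_channels": rec.n_channels,
        "n_samples": int(rec.n_samples),
        "channel_depths_um": rec.channel_depths_um.tolist(),
        "seed": session.seed,
        "truth": _jsonable_truth(session.truth),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))

    pd.DataFrame({"time_s": rec.stim_times_s}).to_csv(
        path / "events.csv", index=False, float_format="%.17g"
    )

    spike_rows, unit_rows, wf_rows = [], [], []
    for u in session.units:
        for cond, times in u.spike_times_s.items():
            for tt in np.asarray(times, dtype=float):
                spike_rows.append(
                    {"unit_id": u.unit_id, "time_s": tt, "condition": cond}
                )
        unit_rows.append(
            {
                "unit_id": u.unit_id,
                "channel": u.channel,
                "depth_um": u.depth_um,
                "week": u.week,
                "waveform_fs_hz": u.waveform_fs_hz,
                "trough_to_peak_ms": u.trough_to_peak_ms,
                "putative_class": u.putative_class,
                "truth_json": json.dumps(_jsonable_truth(u.truth)),
            }
        )
        wf_rows.append(
            {"unit_id": u.unit_id,
             **{f"s{i}": v for i, v in enumerate(u.waveform)}}
        )
    pd.DataFrame(
        spike_rows, columns=["unit_id", "time_s", "condition"]
    ).to_csv(path / "spikes.csv", index=False, float_format="%.17g")
    pd.DataFrame(unit_rows).to_csv(path / "units.csv", index=False,
                                   float_format="%.17g")
    pd.DataFrame(wf_rows).to_csv(path / "waveforms.csv", index=False,
                                 float_format="%.17g")
    return path


def read_session(path) -> SyntheticSession:
    """Load a session bundle; raises BundleError on any inconsistency."""
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise BundleError(f"no manifest.json in {path}")
    manifest = json.loads(mpath.read_text())
    for key in ("fs_hz", "n_channels", "n_samples", "channel_depths_um"):
        if key not in manifest:
            raise BundleError(f"manifest missing required field {key!r}")
    fs = float(manifest["fs_hz"])
    n_channels = int(manifest["n_channels"])
    n_samples = int(manifest["n_samples"])

    channels = json.loads((path / "channels.json").read_text())
    if len(channels) != n_channels:
        raise BundleError(
            f"manifest declares {n_channels} channels, sidecar lists "
            f"{len(channels)}"
        )
    data = np.empty((n_channels, n_samples), dtype=np.float32)
    for meta in channels:
        ch = int(meta["channel"])
        if float(meta["fs_hz"]) != fs:
            raise BundleError(
                f"fs mismatch on channel {ch}: manifest {fs} Hz, "
                f"sidecar {meta['fs_hz']} Hz"
            )
        fpath = path / meta["file"]
        if not fpath.exists():
            raise BundleError(f"missing channel file {meta['file']} "
                              f"(channel {ch})")
        expected = n_samples * 4
        actual = fpath.stat().st_size
        if actual != expected:
            raise BundleError(
                f"channel file {meta['file']} truncated/corrupt: expected "
                f"{expected} bytes, found {actual} (differs at byte "
                f"{min(actual, expected)})"
            )
        data[ch] = np.fromfile(fpath, dtype=DTYPE)

    events = pd.read_csv(path / "events.csv", float_precision="round_trip")
    rec = ContinuousRecording(
        data=data,
        fs_hz=fs,
        channel_depths_um=np.asarray(manifest["channel_depths_um"], float),
        stim_times_s=events["time_s"].to_numpy(),
    )

    units = []
    upath = path / "units.csv"
    if upath.exists():
        units_df = pd.read_csv(upath)
        spikes_df = pd.read_csv(path / "spikes.csv",
                                float_precision="round_trip")
        wf_df = pd.read_csv(path / "waveforms.csv",
                            float_precision="round_trip").set_index("unit_id") \
            if (path / "waveforms.csv").exists() else None
        for _, row in units_df.iterrows():
            uid = row["unit_id"]
            mine = spikes_df[spikes_df.unit_id == uid]
            spike_times = {
                cond: grp["time_s"].to_numpy()
                for cond, grp in mine.groupby("condition")
            }
            wf = (
                wf_df.loc[uid].to_numpy(dtype=float)
                if wf_df is not None and uid in wf_df.index
                else np.empty(0)
            )
            ttp = row.get("trough_to_peak_ms")
            cls = row.get("putative_class")
            units.append(
                UnitRecord(
                    unit_id=uid,
                    channel=int(row["channel"]),
                    depth_um=float(row["depth_um"]),
                    week=int(row["week"]),
                    spike_times_s=spike_times,
                    waveform=wf,
                    waveform_fs_hz=float(row["waveform_fs_hz"]),
                    trough_to_peak_ms=None if pd.isna(ttp) else float(ttp),
                    putative_class=None if pd.isna(cls) else str(cls),
                    truth=json.loads(row["truth_json"])
                    if "truth_json" in row and isinstance(row["truth_json"], str)
                    else {},
                )
            )

    truth = manifest.get("truth", {})
    if isinstance(truth.get("layout"), dict) and "__layout__" in truth["layout"]:
        truth["layout"] = _layout_from_json(truth["layout"]["__layout__"])
    return SyntheticSession(
        recording=rec, units=units, truth=truth,
        seed=int(manifest.get("seed", 0)),
    )
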