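"""End-to-end pipeline: align depth -> classify units -> PAC -> entrainment.

Each stage writes tidy CSV/JSON artifacts stamped with the configuration
hash; a run manifest records the config, seed and package version so a rerun
with the same config reproduces the numeric outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .csd import compute_csd, evoked_average, locate_l4
from .entrainment import mi_spectrum, identify_band, phase_locking
from .io import read_session
from .pac import comodulogram
from .types import SyntheticSession
from .units import classify_units, firing_rate, yield_summary

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("laminet")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {err}") from err

        return wrapper

    return deco


@_stage("align")
def _run_alignment(session, config, out):
    rec = session.recording
    avg, time_ms, n_used, n_dropped = evoked_average(rec)
    spacing = float(np.median(np.diff(rec.channel_depths_um)))
    csd_map = compute_csd(avg, time_ms, spacing)
    layout = session.truth.get("layout")
    alignment = locate_l4(csd_map, layout=layout)
    payload = {
        "config_hash": config.hash(),
        "l4_channel": alignment.l4_channel,
        "sink_latency_ms": alignment.sink_latency_ms,
        "sink_amplitude": alignment.sink_amplitude,
        "failed": alignment.failed,
        "layer_of_channel": {str(k): v for k, v in
                             alignment.layer_of_channel.items()},
        "n_events_used": n_used,
        "n_events_dropped": n_dropped,
    }
    (out / "alignment.json").write_text(json.dumps(payload, indent=1))
    return alignment


@_stage("units")
def _run_units(session, config, alignment, out):
    units = classify_units(session.units)
    rows = []
    duration = session.recording.duration_s
    for u in units:
        for cond, times in u.spike_times_s.items():
            rows.append(
                {
                    "config_hash": config.hash(),
                    "unit_id": u.unit_id,
                    "channel": u.channel,
                    "depth_um": u.depth_um,
                    "week": u.week,
                    "condition": cond,
                    "n_spikes": len(times),
                    "firing_rate_hz": firing_rate(times, (0.0, duration)),
                    "trough_to_peak_ms": u.trough_to_peak_ms,
                    "putative_class": u.putative_class,
                }
            )
    pd.DataFrame(rows).to_csv(out / "units.csv", index=False)
    if units:
        ys = yield_summary(units, alignment=alignment)
        ys.insert(0, "config_hash", config.hash())
        ys.to_csv(out / "yield.csv", index=False)
    return units


@_stage("pac")
def _run_pac(session, config, out):
    rec = session.recording
    rows = []
    for phase_ch, amp_ch in config.pac_channel_pairs:
        com = comodulogram(
            rec.data[phase_ch].astype(float),
            rec.data[amp_ch].astype(float),
            rec.fs_hz,
            phase_freqs_hz=np.asarray(config.phase_freqs_hz),
            amp_freqs_hz=np.asarray(config.amp_freqs_hz),
            n_bins=config.n_bins,
            phase_bandwidth_hz=config.phase_bandwidth_hz,
            phase_channel=phase_ch,
            amp_channel=amp_ch,
        )
        for i, fp in enumerate(com.phase_freqs_hz):
            for j, fa in enumerate(com.amp_freqs_hz):
                rows.append(
                    {
                        "config_hash": config.hash(),
                        "phase_channel": phase_ch,
                        "amp_channel": amp_ch,
                        "phase_freq_hz": fp,
                        "amp_freq_hz": fa,
                        "mi": com.mi[i, j],
                    }
                )
    df = pd.DataFrame(rows)
    df.to_csv(out / "comodulograms.csv", index=False)
    return df


@_stage("entrain")
def _run_entrainment(session, config, out):
    rec = session.recording
    spectra = []
    for u in session.units:
        times = u.spike_times_s.get("evoked")
        if times is None or len(times) == 0:
            continue
        ch = (
            config.entrain_lfp_channel
            if config.entrain_lfp_channel is not None
            else u.channel
        )
        spectra.append(
            mi_spectrum(
                times,
                rec,
                freqs_hz=np.asarray(config.entrain_freqs_hz),
                lfp_channel=ch,
                phase_bandwidth_hz=config.phase_bandwidth_hz,
                n_bins=config.n_bins,
                unit_id=u.unit_id,
            )
        )
    if not spectra:
        return []
    heat = pd.DataFrame(
        np.stack([s.mi_normalized for s in spectra]),
        index=[s.unit_id for s in spectra],
        columns=[f"{f:g}" for f in spectra[0].freqs_hz],
    )
    heat.insert(0, "config_hash", config.hash())
    heat.to_csv(out / "entrainment_heatmap.csv")

    bands = identify_band(spectra)
    rows = []
    for u in session.units:
        times = u.spike_times_s.get("evoked")
        if times is None or len(times) == 0:
            continue
        ch = (
            config.entrain_lfp_channel
            if config.entrain_lfp_channel is not None
            else u.channel
        )
        for band in bands or []:
            res = phase_locking(times, rec, band, lfp_channel=ch,
                                unit_id=u.unit_id, week=u.week)
            rows.append(
                {
                    "config_hash": config.hash(),
                    "unit_id": u.unit_id,
                    "band_lo_hz": band[0],
                    "band_hi_hz": band[1],
                    "n_spikes": res.n_spikes,
                    "mean_angle_deg": res.mean_angle_deg,
                    "resultant_length": res.resultant_length,
                    "rayleigh_p": res.rayleigh_p,
                    "entrained": res.entrained,
                }
            )
    pd.DataFrame(rows).to_csv(out / "entrainment.csv", index=False)
    return bands


def run_pipeline(config: RunConfig, session: SyntheticSession | None = None):
    """Run every enabled stage on a session (loaded from config.input_path
    unless given) and write the report directory.

    Returns the output directory path.
    """
    config.validate()
    out = Path(config.output_path)
    out.mkdir(parents=True, exist_ok=True)
    if session is None:
        if not config.input_path:
            raise PipelineError("stage 'load' failed: no input path configured")
        session = read_session(config.input_path)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "laminet_version": __version__,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))

    alignment = None
    if config.run_alignment and session.recording.stim_times_s.size:
        alignment = _run_alignment(session, config, out)
    if config.run_units and session.units:
        _run_units(session, config, alignment, out)
    if config.run_pac:
        _run_pac(session, config, out)
    if config.run_entrainment and session.units:
        _run_entrainment(session, config, out)
    return out
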