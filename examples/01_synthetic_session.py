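"""Generate a ground-truth-labelled synthetic laminar session and save it.

Builds a 16-channel, 100 µm-spacing session with theta-gamma coupled
background LFP, a stimulus-locked L4 current sink, and a handful of
phase-locked units, then serializes it to a plain-text/binary bundle.
"""

import laminet as ln

session = ln.generate_laminar_session(
    n_stimuli=40,
    sink_channel=4,
    unit_specs=[
        (4, ln.EntrainmentSpec(kappa=2.0, mean_rate_hz=10.0), "excitatory"),
        (5, ln.EntrainmentSpec(kappa=1.0, mean_rate_hz=14.0), "inhibitory"),
    ],
    seed=0,
)

rec = session.recording
print(f"channels: {rec.n_channels}, fs: {rec.fs_hz:g} Hz, "
      f"duration: {rec.duration_s:.1f} s")
print(f"stimuli: {rec.stim_times_s.size}, units: {len(session.units)}")
print(f"ground truth sink: channel {session.truth['sink_channel']} at "
      f"{session.truth['sink_latency_ms']:g} ms post-stimulus")

path = ln.write_session(session, "scratch/demo_session")
print(f"bundle written to {path}")
# The bundle directory holds a JSON manifest (with the full ground truth),
# one float32 binary per channel, and CSV spike/event/unit tables.
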