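"""Phase-amplitude coupling: recover a known theta-gamma coupling.

Generates 60 s of LFP whose 65 Hz envelope is modulated by 5 Hz phase
(modulation depth chi = 0.8), then scans the comodulogram grid.  The
modulation index (MI) is the KL divergence of the phase-binned amplitude
distribution from uniform, normalized to [0, 1].
"""

import laminet as ln

spec = ln.CouplingSpec(phase_freq_hz=5.0, amp_freq_hz=65.0,
                       coupling_strength=0.8)
rec = ln.generate_coupled_lfp(spec, duration_s=60.0, fs_hz=1000.0, seed=1)
x = rec.data[0].astype(float)

com = ln.comodulogram(x, x, rec.fs_hz)  # phase 4-7.5 Hz, amplitude 30-90 Hz
fp, fa = com.peak()
print(f"true coupling:   phase {spec.phase_freq_hz:g} Hz -> "
      f"amplitude {spec.amp_freq_hz:g} Hz (chi = {spec.coupling_strength})")
print(f"recovered peak:  phase {fp:g} Hz -> amplitude {fa:g} Hz")
print(f"peak MI = {com.mi.max():.4f}   grid floor MI = {com.mi.min():.6f}")
# The peak cell should sit within one grid step of the generated coupling;
# away from it the MI falls to the uncoupled noise floor (near 0).
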