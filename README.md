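# laminet

Laminar functional-connectivity analysis for chronic multichannel
extracellular recordings: cross-frequency phase–amplitude coupling (PAC) of
the local field potential, spike entrainment to LFP oscillations,
current-source-density (CSD) depth alignment, waveform-based unit
classification, circular statistics, and longitudinal evoked-vs-resting
modelling — together with a synthetic-session generator that provides
ground truth for every statistical structure the analysis assumes.

The package is written for electrophysiologists who track neural circuit
function near implanted laminar probes (e.g. 16-channel, 100 µm-spacing
shanks spanning cortex and hippocampal CA1) across weeks of recording, and
for methodologists who want a tested, seed-reproducible reference
implementation of the KL-divergence modulation index and its companions.

## The core statistic

For a phase frequency $f_X$ and amplitude frequency $f_Y$, the
instantaneous phase $\Phi_X(t,f_X)$ (Hilbert transform of the band-passed
signal) is partitioned into $N = 20$ bins of 18°, and the instantaneous
amplitude $A_Y(t,f_Y)$ (5-cycle complex Morlet envelope) is averaged within
each bin.  Normalizing the bin means gives a distribution $P(i)$ whose
Shannon entropy $H = -\sum_i P_i \log P_i$ is compared with its maximum
$H_0 = \log N$:

$$\mathrm{MI} = \frac{H_0 - H}{H_0} \in [0, 1]$$

MI is 0 exactly when the amplitude is distributed uniformly over phase (no
coupling) and 1 when all amplitude mass falls in a single phase bin.  The
same index applied to spike-count distributions over phase bins yields the
spike-entrainment MI; per-unit MI spectra over 4–90 Hz, normalized to their
maximum, identify the population band(s) of strongest entrainment, and
phase locking within a band is summarized by the circular mean angle and
resultant length $R$, gated by the Rayleigh uniformity test ($p<0.05$).

Other components: evoked-average CSD ($-\Delta^2 V/\Delta z^2$, sinks
negative) anchors layer 4 at the strongest sink within 100 ms of stimulus
onset; units are classified putative inhibitory (trough-to-peak < 0.41 ms)
or excitatory (≥ 0.41 ms); longitudinal evoked-vs-resting contrasts use a
linear mixed model with a restricted cubic spline over weeks (4 knots at
the 5/35/65/95th percentiles), condition-by-time fixed effects and a
per-animal random intercept.

## Worked example

```python
import laminet as ln

spec = ln.CouplingSpec(phase_freq_hz=5.0, amp_freq_hz=65.0,
                       coupling_strength=0.8)
rec = ln.generate_coupled_lfp(spec, duration_s=60.0, fs_hz=1000.0, seed=1)
x = rec.data[0].astype(float)
com = ln.comodulogram(x, x, rec.fs_hz)   # phase 4-7.5 Hz, amp 30-90 Hz
```

Running the full script (`python examples/02_pac_comodulogram.py`) prints

```
true coupling:   phase 5 Hz -> amplitude 65 Hz (chi = 0.8)
recovered peak:  phase 5 Hz -> amplitude 64.5 Hz
peak MI = 0.0280   grid floor MI = 0.000006
```

the comodulogram peak lands on the generated coupling (5 Hz phase →
65 Hz amplitude, within one 0.5 Hz grid step), with peak MI ≈ 0.028 for
modulation depth χ = 0.8 under the default noise level, while cells away
from the coupling sit at the uncoupled noise floor (MI ≈ 10⁻⁵⁻⁶).

Each script in `examples/` demonstrates one capability end to end
(synthetic session + bundle IO, PAC, spike entrainment, CSD alignment,
longitudinal model) and prints what the numbers mean.  A thin CLI wraps the
same pipeline for shell use:

```bash
laminet simulate --out bundle --seed 0
laminet all bundle --out report
```

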