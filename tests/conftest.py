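import numpy as np
import pytest

import laminet as ln


@pytest.fixture(scope="session")
def coupled_recording():
    """60 s strongly coupled (chi=0.8) theta-gamma signal at 1 kHz."""
    spec = ln.CouplingSpec(
        phase_freq_hz=5.0, amp_freq_hz=65.0, coupling_strength=0.8
    )
    return spec, ln.generate_coupled_lfp(spec, 60.0, 1000.0, seed=11)


@pytest.fixture(scope="session")
def laminar_session():
    """Synthetic 16-channel session with a sink at channel 4 and a few units."""
    unit_specs = [
        (4, ln.EntrainmentSpec(kappa=2.0, mean_rate_hz=8.0), "excitatory"),
        (5, ln.EntrainmentSpec(kappa=1.0, mean_rate_hz=12.0), "inhibitory"),
        (6, ln.EntrainmentSpec(kappa=0.0, mean_rate_hz=6.0), "excitatory"),
    ]
    return ln.generate_laminar_session(
        n_stimuli=40, sink_channel=4, unit_specs=unit_specs, seed=21
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
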