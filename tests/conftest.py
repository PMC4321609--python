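import numpy as np
import pytest

from spindleasym.synthetic import RenderConfig, default_model, render_stack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def asym_stack():
    """Noise-free rendered spindle with a true 3D difference of 20 percent."""
    model = default_model(delta_2d=20.0)
    return render_stack(RenderConfig(model=model, seed=3, noiseless=True))


@pytest.fixture(scope="session")
def noisy_stack():
    """Same spindle at signal-to-noise ratio 10."""
    model = default_model(delta_2d=20.0)
    return render_stack(RenderConfig(model=model, seed=4, snr=10.0))
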