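import pytest

from ttubule import SceneParams, make_fluorescence_scene


@pytest.fixture(scope="session")
def noiseless_scene():
    """Two-cell scene with noise off: measurements must be exact."""
    params = SceneParams(poisson=False, gaussian_sd=0.0, perturbation_factor=0.5)
    img, truth = make_fluorescence_scene(params)
    return img, truth


@pytest.fixture(scope="session")
def default_scene():
    """Two-cell scene at default Poisson + Gaussian noise."""
    params = SceneParams(seed=42)
    img, truth = make_fluorescence_scene(params)
    return img, truth
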