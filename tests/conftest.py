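import numpy as np
import pytest

from gliamorphdyn.synthetic_data import CellSpec, TimelapseSpec, generate_cell_image


@pytest.fixture(scope="session")
def default_cell():
    """One rendered default cell with its ground truth, shared across tests."""
    spec = CellSpec(seed=11)
    image, truth = generate_cell_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def coarse_timelapse_spec():
    """Desk-scale time-lapse spec used for simulation-heavy checks: coarser
    pixels and fewer frames keep per-stack cost low without changing the
    motility model."""
    return TimelapseSpec(cell=CellSpec(pixel_size_um=0.6), n_frames=6, n_slices=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
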