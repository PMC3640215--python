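import numpy as np
import pytest

from hftica import synthetic as syn
from hftica.preprocess import VoxelTimeSeriesMatrix

TR = 0.354


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated default-scale dataset shared across tests."""
    config = syn.SimulationConfig(seed=42)
    matrices, truth, motions = syn.simulate_dataset(config)
    return config, matrices, truth, motions


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_matrix(data: np.ndarray, tr: float = TR, subject_id: str = "sub-01"):
    """Wrap a plain (T, V) array in a VoxelTimeSeriesMatrix on a flat grid."""
    n_vox = data.shape[1]
    nx = n_vox
    voxel_index = np.column_stack(
        [np.arange(n_vox), np.zeros(n_vox, dtype=int), np.zeros(n_vox, dtype=int)]
    )
    return VoxelTimeSeriesMatrix(
        data=data,
        tr_seconds=tr,
        voxel_index=voxel_index,
        subject_id=subject_id,
        grid_shape=(nx, 1, 1),
    )


def on_grid_sinusoid(freq_hz: float, n: int, tr: float = TR) -> np.ndarray:
    """Sinusoid snapped to the nearest DFT grid frequency."""
    grid = np.fft.rfftfreq(n, d=tr)
    f = grid[np.argmin(np.abs(grid - freq_hz))]
    return np.sin(2 * np.pi * f * np.arange(n) * tr), f
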