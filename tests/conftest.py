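import numpy as np
import pytest

from mdca.pipeline import RunConfig, run_pipeline
from mdca.synth import SimulationSpec

# pixel size of the nominal 420-um / 512-px field
PX = 420.0 / 512.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_sim_spec(**overrides) -> SimulationSpec:
    """A quick 64x64 recording: 4 cells, 5 microdomains each, 80 s."""
    defaults = dict(frame_size_px=64, field_of_view_um=64 * PX, n_cells=4,
                    microdomains_per_cell=5, duration_s=80.0, seed=7)
    defaults.update(overrides)
    return SimulationSpec(**defaults)


@pytest.fixture(scope="session")
def small_pipeline_result():
    """One shared end-to-end run on the small fixture recording."""
    cfg = RunConfig(seed=7, simulation=small_sim_spec(), motion_correct=False)
    return run_pipeline(cfg)
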