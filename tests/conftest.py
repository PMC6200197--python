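import numpy as np
import pytest

from microsdm.pipeline import PipelineConfig, run_pipeline
from microsdm.raster import RasterGrid
from microsdm.synthetic import TerrainSpec, generate_terrain
from microsdm.terrain import compute_slope, compute_tpi, grid_dem


@pytest.fixture(scope="session")
def gully_dem():
    """A small single-gully DEM (6 m × 6 m, 0.1 m cells) from survey points."""
    spec = TerrainSpec(extent_x=6, extent_y=6, n_gullies=1, ridge_amplitude=0.8,
                       base_slope=0.1, noise_sd=0.0, n_points=600, seed=11)
    return grid_dem(generate_terrain(spec), 0.1)


@pytest.fixture(scope="session")
def gully_tpi(gully_dem):
    return compute_tpi(gully_dem, radius=1.0)


@pytest.fixture(scope="session")
def gully_slope(gully_dem):
    return compute_slope(gully_dem)


@pytest.fixture()
def random_grid():
    rng = np.random.default_rng(7)
    return RasterGrid(0.0, 4.0, 0.1, rng.normal(0, 1, (40, 40)))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full synthetic pipeline run on a reduced fixture (12 m × 12 m,
    1,200 survey points), shared across tests that inspect its outputs."""
    out = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(
        terrain=TerrainSpec(extent_x=12.0, extent_y=12.0, n_points=1200),
        seed=1,
        write_rasters=False,
    )
    return config, run_pipeline(config, str(out / "run"))
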