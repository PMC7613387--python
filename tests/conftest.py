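import numpy as np
import pytest

import toatrait as tt


@pytest.fixture(scope="session")
def small_lut():
    """A small TOA training pool (150 simulated + 20 non-vegetated rows)."""
    return tt.build_training_set(n=150, n_nonveg=20, seed=42)


@pytest.fixture(scope="session")
def campaign():
    """Synthetic validation campaign: (truth, validation) tables."""
    return tt.synth_field_campaign(tt.CampaignConfig(seed=7))


@pytest.fixture(scope="session")
def lai_model(small_lut):
    """A GPR trained on the small pool's LAI labels."""
    return tt.train(
        small_lut.X, small_lut.traits["LAI"].to_numpy(),
        tt.TrainConfig(n_restarts=2), seed=0, trait="LAI", units="m^2/m^2",
        band_centers=tt.sentinel2_bands().centers,
    )


@pytest.fixture(scope="session")
def lai_portable(lai_model):
    return tt.export_portable(lai_model)


@pytest.fixture(scope="session")
def scene():
    """Synthetic 24x24 scene with truth rasters and validity mask."""
    spec = tt.SceneSpec.random(n_fields=8, shape=(32, 32), seed=5)
    return tt.synth_scene(spec)
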