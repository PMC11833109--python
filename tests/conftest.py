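import hypothesis
import numpy as np
import pytest

from cytofuse.config import SimConfig, TrainingConfig
from cytofuse import cae_models, synthetic_data

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50)
hypothesis.settings.load_profile("default")


SMALL_IMAGE = dict(image_height=16, image_width=16,
                   trans_height=16, trans_width=16)


@pytest.fixture(scope="session")
def stress_records():
    """Small, well-separated stress dataset shared across model tests."""
    cfg = SimConfig(n_cells=24, scenario="glucose_deprivation",
                    effect_size=2.0, seed=11, **SMALL_IMAGE)
    return synthetic_data.simulate_population(cfg)


@pytest.fixture(scope="session")
def stress_dataset(stress_records):
    return cae_models.CellImageDataset.from_records(stress_records)


@pytest.fixture()
def tiny_training_config():
    return TrainingConfig(total_epochs=3, recon_only_epochs=1, batch_size=4,
                          latent_dim=8, conv_channels=(4, 8), seed=5)


def make_light_records(n, seed=0):
    """Cheap records (blank images) for sequence-level tests."""
    img3 = np.zeros((2, 4, 4), dtype=np.float32)
    img2 = np.zeros((4, 4), dtype=np.float32)
    return [
        synthetic_data.CellRecord(
            cell_id=i, ssc_image=img3, trans_image=img2,
            fl_0h=0.0, fl_48h=0.0, true_class=i % 2,
            scenario_label="thermal_stress", dispense_index=i)
        for i in range(n)
    ]
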