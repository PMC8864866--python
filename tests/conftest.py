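import numpy as np
import pytest
from hypothesis import settings

from aplvision import synthgen
from aplvision.segmentation import DetectorConfig, train_detector

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


MIX_COMPOSITION = {"myeloblast": 0.30, "promyelocyte": 0.25,
                   "auer_promyelocyte": 0.20, "other": 0.25}


def mixed_spec(n_images=8, cells_range=(18, 32), overlap_prob=0.0,
               smudge_rate=1.5, concentration=1e9, image_size=(512, 384)):
    return synthgen.CohortSpec(
        diagnosis="MIX", n_patients=n_images, images_per_patient=1,
        cells_per_image_range=cells_range, composition=MIX_COMPOSITION,
        concentration=concentration, overlap_prob=overlap_prob,
        smudge_rate=smudge_rate, image_size=image_size)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Eight non-overlapping mixed smears with ground truth."""
    return synthgen.generate_cohort([mixed_spec(8)], seed=123)


@pytest.fixture(scope="session")
def trained_detector(tiny_dataset):
    """Detector trained on six of the tiny-dataset smears."""
    ids = tiny_dataset.image_ids()
    return train_detector(
        [tiny_dataset.images[i] for i in ids[:6]],
        [tiny_dataset.annotations[i] for i in ids[:6]],
        DetectorConfig(seed=5))


@pytest.fixture(scope="session")
def crop_pools():
    """Balanced per-type ground-truth crop pools for classifier tests."""
    from aplvision.benchmarks import harvest_crops
    pools = {}
    pools["myeloblast"] = harvest_crops(
        101, 220, lambda a: a.is_myeloblast)
    pools["promyelocyte"] = harvest_crops(
        103, 220, lambda a: a.is_promyelocyte)
    pools["auer_rod"] = harvest_crops(
        105, 220, lambda a: a.has_auer_rod, pool=lambda a: a.is_promyelocyte)
    return pools


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
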