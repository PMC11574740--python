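import warnings

import numpy as np
import pytest

from ptemark import lesion_vae as lv
from ptemark import synthetic_cohort as sc

TEST_GRID = (24, 24, 10)


@pytest.fixture(scope="session")
def parc_small():
    return sc.generate_parcellation(TEST_GRID)


@pytest.fixture(scope="session")
def small_cfg():
    return sc.CohortConfig(n_per_group=3, grid_shape=TEST_GRID, n_volumes=64, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(small_cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sc.generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def vae_fixture():
    """A small trained VAE plus matched lesioned/lesion-free test volumes.

    Grid 32x32x10 with native-size 32x32 slices; 16 lesion-free training
    subjects, 3 epochs.  Shared across tests because training dominates cost.
    """
    grid = (32, 32, 10)
    parc = sc.generate_parcellation(grid)
    cfg = sc.null_config(grid_shape=grid, n_volumes=32, seed=40)
    train_vols = [sc.generate_anatomy(cfg, (cfg.seed, i)) for i in range(16)]
    slices = lv.extract_brain_slices(train_vols, 32)
    arch = lv.VAEArchitecture(input_size=32)
    model = lv.train_vae(slices, arch, lv.TrainConfig(epochs=10, batch_size=16, seed=0))

    # clearly visible lesions (5x noise) to probe localization logic itself;
    # detection power at the study contrast is exercised at full scale
    prev = {n: (0.9, 0.9) for n in sc.ROI_NAMES}
    les_cfg = sc.CohortConfig(
        n_per_group=2, grid_shape=grid, n_volumes=32,
        lesion_prevalence=prev, lesion_intensity=5.0, seed=41,
    )
    clean, lesioned, masks = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(3):
            anat = sc.generate_anatomy(les_cfg, (les_cfg.seed, i))
            vol, mask = sc.plant_lesions(anat, parc, sc.PTE, les_cfg, (les_cfg.seed, i))
            clean.append(anat)
            lesioned.append(vol)
            masks.append(mask)
    return {
        "model": model,
        "arch": arch,
        "parc": parc,
        "train_slices": slices,
        "clean": clean,
        "lesioned": lesioned,
        "masks": masks,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
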