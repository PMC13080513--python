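import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from ienfa.image_model import CalibratedImage
from ienfa.segmentation import TrainingScribbles, train_classifier
from ienfa.synthetic_data import ImageSimParams, simulate_image


def make_toy_image(rng, shape=(60, 60), nerve_frac=0.2):
    """Separable two-population toy: nerve pixels ~0.9, background ~0.1."""
    truth = rng.uniform(size=shape) < nerve_frac
    img = np.where(
        truth,
        rng.normal(0.9, 0.02, shape),
        rng.normal(0.1, 0.02, shape),
    ).clip(0, 1)
    return CalibratedImage(nerve=img, epidermis=None, scale=1.0), truth


def scribbles_from_truth(truth_mask, image_id, rng, n_fg=300, n_bg=600):
    """Sample labels from a known mask; half the background labels come
    from the 3-px halo around the foreground so the classifier learns the
    boundary."""
    fy, fx = np.nonzero(truth_mask)
    sel = rng.choice(len(fy), min(n_fg, len(fy)), replace=False)
    dilated = ndi.binary_dilation(truth_mask, iterations=3)
    halo = dilated & ~truth_mask
    hy, hx = np.nonzero(halo)
    sh = rng.choice(len(hy), min(n_bg // 2, len(hy)), replace=False)
    by, bx = np.nonzero(~dilated)
    sb = rng.choice(len(by), n_bg - len(sh), replace=False)
    return TrainingScribbles(
        pd.DataFrame(
            {
                "image_id": image_id,
                "x": np.concatenate([fx[sel], hx[sh], bx[sb]]),
                "y": np.concatenate([fy[sel], hy[sh], by[sb]]),
                "class": ["nerve"] * len(sel) + ["background"] * (len(sh) + len(sb)),
                "round": 0,
            }
        )
    )


@pytest.fixture(scope="session")
def fibre_params():
    """Dense-fibre study conditions shared by segmentation smoke tests."""
    return ImageSimParams(fibres_per_mm=25.0)


@pytest.fixture(scope="session")
def fibre_image_train(fibre_params):
    return simulate_image(fibre_params, seed=1)


@pytest.fixture(scope="session")
def fibre_image_test(fibre_params):
    return simulate_image(fibre_params, seed=2)


@pytest.fixture(scope="session")
def fibre_classifier(fibre_image_train):
    img, truth = fibre_image_train
    rng = np.random.default_rng(0)
    scr = scribbles_from_truth(truth.fibre_mask, "train", rng)
    return train_classifier({"train": img}, scr, seed=0)
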