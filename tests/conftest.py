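import numpy as np
import pytest

from fetaldoppler import synthetic as syn

GREY_WEIGHTS = np.array([0.299, 0.587, 0.114])


def to_grey(rgb):
    return rgb @ GREY_WEIGHTS if rgb.ndim == 3 else rgb


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def ua_studies():
    """Twelve noiseless UA studies with ground truth."""
    cfg = syn.DatasetConfig(n_per_view=12, views=("UA",), noise=syn.NOISELESS)
    studies, _ = syn.generate_dataset(cfg, 101)
    return studies


@pytest.fixture(scope="session")
def ua_delineation_experiment():
    """A desk-scale UA delineation study: reduced W-Net trained for 20
    epochs on 200 synthetic UA spectrograms, with 50 held-out test studies.

    Trained once per session; shared by the delineation-quality check and
    the end-to-end pipeline tests.
    """
    from fetaldoppler import delineation as dl
    from fetaldoppler.training import TrainConfig

    cfg = syn.DatasetConfig(n_per_view=250, views=("UA",))
    studies, _ = syn.generate_dataset(cfg, 42)
    train, test = studies[:200], studies[200:250]
    pairs = [
        (st.doppler, dl.encode_truth_mask(st.truth, "UA", st.calibration).channels)
        for st in train
    ]
    model, hist = dl.train_delineator(
        pairs, "UA", TrainConfig(epochs=20, seed=0, crop_size=96)
    )
    return dict(model=model, train=train, test=test, history=hist)


@pytest.fixture(scope="session")
def mixed_studies():
    """A small noiseless dataset covering all five views."""
    cfg = syn.DatasetConfig(n_per_view=6, views=syn.ALL_VIEWS, noise=syn.NOISELESS)
    studies, index = syn.generate_dataset(cfg, 202)
    return studies, index
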