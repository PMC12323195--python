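import numpy as np
import pytest

from nsr_screen import preprocess as pp
from nsr_screen import synthetic as syn
from nsr_screen.io_consensus import BinaryMask, NsrImage


@pytest.fixture(scope="session")
def tiny_cohort_render():
    """Four participants (one per group) x 5 time points, rendered."""
    cfg = syn.CohortConfig(n_hc=1, n_per_disorder=1, seed=3)
    images, flush, labels, records, parts = syn.generate_image_dataset(
        cfg, syn.FlushKinetics(), syn.RenderConfig(seed=3))
    return {
        "config": cfg, "images": images, "flush": flush, "labels": labels,
        "records": records, "participants": parts,
    }


@pytest.fixture(scope="session")
def calibrated_sample(tiny_cohort_render):
    """One calibrated (image, label mask, flush mask) with visible flushing."""
    d = tiny_cohort_render
    img, lbm, flm = pp.preprocess_pair(d["images"][4], d["labels"][4], d["flush"][4])
    assert flm.area_px > 500
    return img, lbm, flm


@pytest.fixture
def flat_image():
    """A uniform mid-gray photograph for calibration unit tests."""
    px = np.full((40, 80, 3), 128, dtype=np.uint8)
    return NsrImage(pixels=px, participant_id="p1", time_min=5)


def random_mask(rng, shape=(16, 24), p=0.3, kind="flush"):
    return BinaryMask(pixels=rng.random(shape) < p, kind=kind)
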