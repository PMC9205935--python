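import numpy as np
import pytest
from hypothesis import settings

from radsig.features.discretise import DiscretisedRoi

settings.register_profile("deterministic", database=None, derandomize=True)
settings.load_profile("deterministic")
from radsig.phantom import OutcomeSpec, PhantomConfig, generate_phantom
from radsig.preprocess import preprocess_subject


@pytest.fixture(scope="session")
def small_phantom():
    """One rendered phantom subject (MR, CT, mask) on the default grid."""
    cfg = PhantomConfig(ct_air_fraction=0.05, ct_bone_fraction=0.05)
    return cfg, generate_phantom(cfg, seed=42)


@pytest.fixture(scope="session")
def preprocessed_subject(small_phantom):
    _, (mr, ct, mask) = small_phantom
    return preprocess_subject(mr, ct, mask, mask)


def random_disc(shape=(4, 4, 3), k=4, seed=0, roi_fraction=0.8):
    """Small random discretised ROI for oracle comparisons."""
    rng = np.random.default_rng(seed)
    roi = rng.uniform(size=shape) < roi_fraction
    if not roi.any():
        roi[0, 0, 0] = True
    levels = np.zeros(shape, dtype=np.int32)
    levels[roi] = rng.integers(1, k + 1, roi.sum())
    return DiscretisedRoi(levels=levels, roi=roi, n_bins=k)
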