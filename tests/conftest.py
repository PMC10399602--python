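import numpy as np
import pandas as pd
import pytest

from aesthstat import synthetic
from aesthstat.colorspace import (
    WhitePoint,
    lms_to_macleod_boynton,
    macleod_boynton_to_lms,
    saturation_and_hue,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """Six synthetic 64-px paintings with their planted-parameter manifest."""
    return synthetic.make_corpus(n_images=6, size=64, seed=7)


def field_from_ls(l, s, lum=None, sat_floor=0.05):
    """ChromaticField built directly from chromaticity arrays (test helper)."""
    l = np.atleast_2d(np.asarray(l, dtype=float))
    s = np.atleast_2d(np.asarray(s, dtype=float))
    lum = np.full_like(l, 0.5) if lum is None else np.atleast_2d(np.asarray(lum, float))
    cone = macleod_boynton_to_lms(l, s, lum)
    f = lms_to_macleod_boynton(cone, WhitePoint())
    saturation_and_hue(f, sat_floor=sat_floor)
    return f


@pytest.fixture
def gaussian_table(rng):
    """40 x 8 z-scorable random feature table and index, model-test sized."""
    X = rng.normal(size=(40, 8))
    cols = [f"f{i}" for i in range(8)]
    idx = [f"img{i:03d}" for i in range(40)]
    return pd.DataFrame(X, columns=cols, index=idx)
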