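import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_media(rng):
    """Random physical differential-generated media (delta_T < 0.98 pi)."""
    from mmpol import build_differential, mueller_from_differential

    media = []
    while len(media) < 60:
        LB, LBp = rng.uniform(-1.8, 1.8, 2)
        CB = rng.uniform(-1.0, 1.0)
        if np.sqrt(LB**2 + LBp**2 + CB**2) >= 0.98 * np.pi:
            continue
        LD, LDp, CD = rng.uniform(-0.6, 0.6, 3)
        a = rng.uniform(-2.0, 0.0, 3)
        L = build_differential(LB, LBp, CB, LD, LDp, CD, *a)
        media.append((L, mueller_from_differential(L)))
    return media
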