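import numpy as np
import pytest

from alignhush import FixtureSpec, encode_alignhush, generate_world, uniform_background, world_profiles


def make_random_profile(rng, n, name="p", annotated=True, zero_trans_prob=0.0):
    """Small random augmented profile for DP stress tests.

    With ``zero_trans_prob`` > 0, some transition probabilities are zeroed
    (and the group renormalised) to exercise the log-floor path that real
    plan7 sentinel scores produce.
    """
    bg = uniform_background()
    em = rng.dirichlet(np.ones(20) * 0.5, size=n)
    trans = np.zeros((n, 7))
    trans[:, :3] = rng.dirichlet([8.0, 1.0, 1.0], size=n)
    trans[:, 3:5] = rng.dirichlet([2.0, 1.0], size=n)
    trans[:, 5:] = rng.dirichlet([2.0, 1.0], size=n)
    if zero_trans_prob:
        for k in range(n):
            for group in ((0, 1, 2), (3, 4), (5, 6)):
                if rng.random() < zero_trans_prob:
                    dead = group[int(rng.integers(1, len(group)))]
                    trans[k, dead] = 0.0
                    g = list(group)
                    trans[k, g] /= trans[k, g].sum()
    hydro = rng.uniform(-4.5, 4.5, size=n)
    ss = rng.dirichlet(np.ones(3), size=n) if annotated else None
    return encode_alignhush(em, trans, bg, hydro=hydro, ss=ss, name=name)


@pytest.fixture(scope="session")
def world42():
    return generate_world(FixtureSpec(seed=42))


@pytest.fixture(scope="session")
def profiles42(world42):
    return world_profiles(world42)
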