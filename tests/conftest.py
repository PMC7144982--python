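import numpy as np
import pytest

from mvmmn import MMNParams, MixingLaw

FAMILIES = ("rsn", "exp1", "weib21")


def random_spd(rng, d, diag_boost=None):
    """A well-conditioned random symmetric positive-definite d x d matrix."""
    A = rng.standard_normal((d, d))
    return A @ A.T + (diag_boost if diag_boost is not None else d) * np.eye(d)


def random_params(rng, family, p=2, n=3, lam_scale=1.0):
    mix = getattr(MixingLaw, family)()
    return MMNParams(
        M=rng.standard_normal((p, n)),
        Lambda=lam_scale * rng.standard_normal((p, n)),
        Sigma=random_spd(rng, p),
        Psi=random_spd(rng, n),
        mixing=mix,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
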