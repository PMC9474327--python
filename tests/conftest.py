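import numpy as np
import pytest

from scbulk import GroupParams, ShiftParams


def random_group_params(rng: np.random.Generator, positive_gap: bool = False) -> GroupParams:
    """A random structurally valid GroupParams (optionally with E+ > E-)."""
    e_minus = rng.uniform(-2.0, 2.0)
    gap = rng.uniform(0.1, 3.0) if positive_gap else rng.uniform(-3.0, 3.0)
    return GroupParams(
        e_plus=e_minus + gap,
        e_minus=e_minus,
        e_r=rng.uniform(0.05, 0.95),
        v_plus=rng.uniform(0.0, 1.0),
        v_minus=rng.uniform(0.0, 1.0),
        v_r=rng.uniform(0.0, 0.02),
    )


def random_shift(rng: np.random.Generator, gp: GroupParams) -> ShiftParams:
    """A random shift whose scaled proportion stays inside [0, 1]."""
    return ShiftParams(
        d_plus=rng.uniform(-2.0, 2.0),
        d_minus=rng.uniform(-2.0, 2.0),
        alpha_r=rng.uniform(0.0, 1.0) / gp.e_r,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def sample_variance_se(x: np.ndarray) -> float:
    """Asymptotic standard error of the sample variance of ``x``.

    var(s^2) = (m4 - (N-3)/(N-1) * s^4) / N with m4 the fourth central
    sample moment; valid for any distribution with finite fourth moment.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    m4 = np.mean((x - x.mean()) ** 4)
    s2 = x.var(ddof=1)
    return float(np.sqrt(max(m4 - (n - 3) / (n - 1) * s2**2, 0.0) / n))
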