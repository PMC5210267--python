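import numpy as np
import pytest

from bonev import PValueVector


@pytest.fixture
def worked_example() -> PValueVector:
    """Ten p-values whose Bon-EV intermediates are all hand-computable."""
    p = [0.001, 0.004, 0.012, 0.2, 0.3, 0.55, 0.6, 0.7, 0.8, 0.9]
    return PValueVector([f"g{i}" for i in range(10)], p)


def make_pvector(rng: np.random.Generator, m: int) -> PValueVector:
    """Random p-value vector: a uniform/beta mixture so some vectors have
    strong signals, some none."""
    pi1 = rng.uniform(0.0, 0.6)
    k = int(round(m * pi1))
    p = np.concatenate([rng.beta(0.2, 5.0, size=k), rng.uniform(0, 1, size=m - k)])
    rng.shuffle(p)
    return PValueVector([f"h{i}" for i in range(m)], p)
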