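import numpy as np
import pytest

from dairyswap.data_model import CONSTRAINED_NUTRIENTS
from dairyswap.lp_core import LpSpec
from dairyswap.synthetic_data import dairy_fixture, generate_food_db, generate_intakes


@pytest.fixture(scope="session")
def fixture_reference():
    return dairy_fixture().reference


@pytest.fixture(scope="session")
def small_foods():
    return generate_food_db(40, seed=7)


@pytest.fixture(scope="session")
def small_intakes(small_foods):
    return generate_intakes(small_foods, n_persons=200, seed=7)


def brute_weighted_quantile(values, weights, q):
    """Independent left-continuous weighted-ECDF inverse (loop, no numpy)."""
    pairs = sorted(zip(values, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    for v, w in pairs:
        cum += w
        if cum / total >= q - 1e-12:
            return v
    return pairs[-1][0]


def random_small_spec(rng, max_foods=4, max_nutrients=3):
    """A random small LP instance for oracle-equivalence checks.

    Roughly half the instances are feasible; bounds mix finite caps and
    uncapped columns.
    """
    n = int(rng.integers(1, max_foods + 1))
    m = int(rng.integers(1, max_nutrients + 1))
    nutrients = tuple(
        rng.choice(CONSTRAINED_NUTRIENTS, size=m, replace=False)
    )
    a = rng.uniform(0.0, 2.0, size=(m, n))
    a[rng.random(size=a.shape) < 0.3] = 0.0
    b = rng.uniform(1.0, 100.0, size=m)
    upper = np.where(
        rng.random(n) < 0.5, rng.uniform(10.0, 500.0, size=n), np.inf
    )
    c = rng.uniform(0.01, 2.0, size=n)
    return LpSpec(
        codes=tuple(1000 + 2 * i for i in range(n)),
        objective="cost",
        c=c,
        A=a,
        b=b,
        upper=upper,
        nutrient_names=nutrients,
    )
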