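import numpy as np
import pytest

from paleogrowth import growth_models as gm
from paleogrowth.datasets import WholeBoneDataset
from paleogrowth.synthetic_data import gen_whole_bone, uniform_ages

LOGISTIC_PARAMS = {"a": 100.0, "b": 12.0, "c": 0.4}


@pytest.fixture(scope="session")
def logistic_full_span():
    """20 noiseless points spanning ~1%-99% of a logistic's asymptote."""
    levels = 100.0 * np.linspace(0.01, 0.99, 20)
    ages = np.asarray(gm.inverse_age("Logistic 3", LOGISTIC_PARAMS, levels))
    return WholeBoneDataset(ages=ages, dimensions=levels,
                            name="logistic-full-span")


@pytest.fixture(scope="session")
def linear_exact():
    t = np.arange(1.0, 11.0)
    return WholeBoneDataset(ages=t, dimensions=2.0 + 3.0 * t, name="line")


@pytest.fixture(scope="session")
def trex_like_analogue():
    """9-point analogue of a sparse tyrannosaur data set: one very young and
    one very old specimen, the rest mid-curve, sampled from the T. rex-shaped
    logistic with a fixed 5% heteroscedastic age-estimate perturbation (real
    LAG ages carry error; an exact sample would be unrealistically stable)."""
    from paleogrowth.synthetic_data import ErrorModel

    curve, params = "Logistic 3z", {"a": 5649.0, "c": 0.55, "d": 5.0}
    mid = np.linspace(14.0, 22.0, 7)
    ages = np.concatenate([[2.0], mid, [28.0]])
    dims = np.asarray(gm.evaluate(curve, params, ages))
    rng = np.random.default_rng(77)
    noisy = np.maximum(ErrorModel("heteroscedastic", 0.05).perturb(ages, rng),
                       0.5)
    return WholeBoneDataset(ages=noisy, dimensions=dims, name="trex-analogue",
                            dimension_type="mass", units="kg")
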