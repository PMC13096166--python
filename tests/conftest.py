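import numpy as np
import pytest

from phbo import (
    CategoricalVariable,
    ContinuousVariable,
    FittedSurrogate,
    GPHyperparameters,
    HybridSpace,
    ObservationSet,
)


@pytest.fixture
def small_space() -> HybridSpace:
    """Two categoricals (3 x 2 levels) and two continuous variables."""
    return HybridSpace(
        categoricals=(
            CategoricalVariable("salt", ("acetate", "nitrate", "chloride")),
            CategoricalVariable("ligand", ("imidazole", "triazole")),
        ),
        continuous=(
            ContinuousVariable("conc", 0.1, 2.0, units="mol/L"),
            ContinuousVariable("time", 2.0, 6.0, units="h"),
        ),
    )


@pytest.fixture
def tiny_space() -> HybridSpace:
    """One categorical (3 levels) and one continuous variable."""
    return HybridSpace(
        categoricals=(CategoricalVariable("ligand", ("a", "b", "c")),),
        continuous=(ContinuousVariable("x", 0.0, 1.0),),
    )


def random_observations(
    space: HybridSpace, n: int, seed: int, fn=None
) -> ObservationSet:
    rng = np.random.default_rng(seed)
    obs = ObservationSet()
    for _ in range(n):
        p = space.random_point(rng)
        y = float(rng.normal()) if fn is None else float(fn(p, rng))
        obs.add(p, y)
    return obs


def default_hyp(space: HybridSpace, **kw) -> GPHyperparameters:
    params = dict(
        cont_lengthscales=np.full(space.n_continuous, 0.4),
        cat_lengthscales=np.full(space.n_categorical, 0.8),
        mix_weight=0.5,
        amplitude=1.0,
        noise_variance=1e-2,
        prior_mean=0.0,
    )
    params.update(kw)
    return GPHyperparameters(**params)


def make_surrogate(
    space: HybridSpace, n: int = 10, seed: int = 0, hyp=None, fn=None
) -> FittedSurrogate:
    """A conditioned GP on random data with fixed hyperparameters."""
    obs = random_observations(space, n, seed, fn)
    return FittedSurrogate.from_observations(
        obs, space, hyp if hyp is not None else default_hyp(space)
    )
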