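import numpy as np
import pytest

from nlfba.expression_fit import FitConfig, aggregate_gene_data, fit
from nlfba.synthetic_data import (GradientSpec, ToyC4Options,
                                  make_expression_data, make_gradient_truth,
                                  make_toy_c4_model, make_toy_leaf,
                                  make_toy_two_cell)

SEED = 1


def _gradient_bundle(leaf, **spec_kwargs):
    spec = GradientSpec(seed=SEED, **spec_kwargs)
    truth = make_gradient_truth(leaf, spec)
    expr, activity, s_true = make_expression_data(truth, leaf.base, spec)
    data = aggregate_gene_data(leaf.base, expr)
    return {"spec": spec, "truth": truth, "expr": expr,
            "activity": activity, "s_true": s_true, "data": data}


@pytest.fixture(scope="session")
def noisy_bundle(toy_leaf15):
    """15-segment gradient at the study noise level (cv = 0.2)."""
    return _gradient_bundle(toy_leaf15)


@pytest.fixture(scope="session")
def noisy_fit(toy_leaf15, noisy_bundle):
    b = noisy_bundle
    return fit(toy_leaf15, b["data"], b["activity"],
               config=FitConfig(seed=SEED))


@pytest.fixture(scope="session")
def clean_bundle(toy_leaf15):
    """Noise-free gradient: both noise channels (cv and scale spread) off."""
    return _gradient_bundle(toy_leaf15, noise_cv=0.0, scale_spread=0.0)


@pytest.fixture(scope="session")
def clean_fit(toy_leaf15, clean_bundle):
    b = clean_bundle
    return fit(toy_leaf15, b["data"], b["activity"],
               config=FitConfig(seed=SEED))


@pytest.fixture(scope="session")
def toy_base():
    return make_toy_c4_model()


@pytest.fixture(scope="session")
def toy_two_cell():
    return make_toy_two_cell()


@pytest.fixture(scope="session")
def toy_leaf15():
    return make_toy_leaf(15)


@pytest.fixture(scope="session")
def toy_leaf3():
    return make_toy_leaf(3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
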