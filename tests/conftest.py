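import numpy as np
import pytest

from semgwas.model import ModelSpec
from semgwas.synthetic import make_true_model, simulate_dataset


@pytest.fixture(scope="session")
def small_true_model():
    """2 factors, 6 traits, 6 factor-SNPs, one structural edge; anchored."""
    return make_true_model(2, [3, 3], [3, 3], 0, b_edges=[(0, 1, 0.4)],
                           effect_sizes=(0.2, 0.3), seed=7, anchor=True)


@pytest.fixture(scope="session")
def small_dataset(small_true_model):
    return simulate_dataset(small_true_model, 400, seed=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def measurement_spec_from_truth(true_model):
    """Anchored measurement ModelSpec (free masks) matching a truth's
    attribution, with factors in truth order — bypasses factor analysis."""
    spec = true_model.spec
    m = ModelSpec(latent_names=list(spec.latent_names),
                  trait_names=list(spec.trait_names),
                  trait_kinds=dict(spec.trait_kinds))
    m.theta_eps_free[:] = True
    m.theta_delta_free[:] = True
    for j in range(spec.n_latent):
        rows = np.nonzero(spec.Lambda[:, j])[0]
        anchor_sign = np.sign(spec.Lambda[rows[0], j]) or 1.0
        m.Lambda[rows[0], j] = 1.0
        for r in rows[1:]:
            m.Lambda_free[r, j] = True
            m.Lambda[r, j] = (np.sign(spec.Lambda[r, j]) or 1.0) * anchor_sign
    return m
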