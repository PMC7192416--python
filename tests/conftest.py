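import numpy as np
import pytest

from gmaens import case_study_model, sample_k


@pytest.fixture(scope="session")
def case_study():
    """The built-in three-step pathway with end-product inhibition."""
    return case_study_model()


@pytest.fixture(scope="session")
def k_ensemble_small(case_study):
    model, _ = case_study
    return sample_k(model, 2000, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


def random_k(model, rng, n=1):
    """Uniform kinetic-order vectors within the model's sampling intervals."""
    cols = []
    for (rxn, sp) in model.free_entries:
        lo, hi = model.orders_free[(rxn, sp)]
        cols.append(rng.uniform(lo, hi, size=n))
    out = np.stack(cols, axis=1)
    return out[0] if n == 1 else out
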