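import numpy as np
import pytest

import normindex as ni


@pytest.fixture(scope="session")
def gait_model():
    return ni.default_gait_model()


@pytest.fixture(scope="session")
def gait_reference(gait_model):
    """A 32 x 459 synthetic able-bodied cohort."""
    return ni.generate_reference_cohort(gait_model, n=32, seed=42)


@pytest.fixture(scope="session")
def corr83_reference():
    """Two-feature reference with sample correlation exactly 0.83."""
    return ni.make_correlated_reference(n=32, r=0.83, seed=7)


def random_reference(n, p, seed, mixing=True):
    """Generic dense reference with arbitrary feature correlations."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    if mixing:
        x = x @ rng.standard_normal((p, p))
    return ni.ReferenceMatrix(
        values=x,
        subject_ids=tuple(f"s{i}" for i in range(n)),
        feature_labels=tuple(f"f{j}" for j in range(p)),
    )
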