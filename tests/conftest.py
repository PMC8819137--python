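import warnings

import numpy as np
import pytest

from emtpath.classify import get_backbone
from emtpath.synthetic import CohortSpec, SlideSpec, generate_expression_cohort


@pytest.fixture(scope="session")
def backbone():
    return get_backbone("small-cnn")


@pytest.fixture(scope="session")
def planted_cohort():
    """Well-separated two-group cohort (effect size 3, n=100)."""
    return generate_expression_cohort(CohortSpec(n_samples=100, effect_size=3.0,
                                                 seed=1))


@pytest.fixture()
def small_slide_spec():
    """Compact slide spec for unit tests; the realistic-size warning is
    irrelevant at this scale."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return SlideSpec(grid_shape=(3, 3), seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
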