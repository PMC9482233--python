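import numpy as np
import pandas as pd
import pytest

from batrasch import (
    ScaleSpec,
    ResponseMatrix,
    bat_spec,
    default_bat_config,
    generate,
)


@pytest.fixture(scope="session")
def spec():
    return bat_spec()


@pytest.fixture(scope="session")
def toy_spec():
    """Three 3-category items in one subscale."""
    return ScaleSpec(
        items=("a", "b", "c"),
        subscale_of={"a": "S", "b": "S", "c": "S"},
        n_categories={"a": 3, "b": 3, "c": 3},
        min_code=1,
        max_code=3,
    )


@pytest.fixture(scope="session")
def null_cohort():
    """One unidimensional cohort at the default study conditions (n=800)."""
    return generate(default_bat_config(seed=42))


def make_matrix(spec, responses, ages=None):
    responses = np.asarray(responses, dtype=int)
    cov = None
    if ages is not None:
        cov = pd.DataFrame({"age": ages})
    return ResponseMatrix(spec, responses, np.arange(len(responses)), cov)
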