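"""Shared fixtures: a miniature synthetic cohort, in memory and on disk."""

import numpy as np
import pytest

from netlearn.simulate import generate_cohort, make_fixture_spec, write_cohort


@pytest.fixture(scope="session")
def mini_bundles():
    """Three-subject cohort with short tasks (60 s baseline, 30 s learning)."""
    return generate_cohort(make_fixture_spec(seed=11))


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, mini_bundles):
    """The miniature cohort written in pipeline layout (CSV dialect)."""
    out = tmp_path_factory.mktemp("cohort")
    write_cohort(mini_bundles, out, fmt="csv")
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
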