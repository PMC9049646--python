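"""Shared fixtures: one synthetic study generated once per session."""

import pytest

from feasquery.fixtures import FixtureSpec, gen_artifacts, gen_patients
from feasquery.pipeline import run_generation


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=11)


@pytest.fixture(scope="session")
def artifacts(spec):
    return gen_artifacts(spec)


@pytest.fixture(scope="session")
def generated(artifacts):
    return run_generation(artifacts)


@pytest.fixture(scope="session")
def store(spec, artifacts, generated):
    return gen_patients(spec, artifacts, generated)
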