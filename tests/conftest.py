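"""Shared fixtures: the packaged annotation and one worked synthetic cohort.

The cohort bundle is generated once per session (seeded, deterministic) and
shared read-only across tests; anything mutating must copy.
"""

from importlib.resources import files

import pytest

from hoxscape import simulate
from hoxscape.annotation import parse_gtf


@pytest.fixture(scope="session")
def fixture_gtf_path(tmp_path_factory):
    return str(files("hoxscape").joinpath("data/hox_fixture.gtf"))


@pytest.fixture(scope="session")
def hox_genes(fixture_gtf_path):
    return parse_gtf(fixture_gtf_path)


@pytest.fixture(scope="session")
def bundle():
    """The worked cohort: 8/6/8 matched pairs, default planted structures."""
    return simulate.worked_fixture()


@pytest.fixture(scope="session")
def coverage(bundle):
    return bundle.coverage_frames()


@pytest.fixture(scope="session")
def pct(bundle):
    return bundle.pct_matrix()
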