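import pytest

import plastisink as ps


@pytest.fixture(scope="session")
def gyre_profile():
    """Default synthetic subtropical-gyre column, 0-5100 m."""
    return ps.synthetic_profile()


@pytest.fixture(scope="session")
def shallow_profile():
    """Short column for fast trajectory tests."""
    return ps.synthetic_profile(bottom=600.0, grid_step=5.0)


@pytest.fixture(scope="session")
def coupled_default(gyre_profile):
    """One full default coupled run (1 min settling resolution, 100 yr)."""
    return ps.run_coupled(profile=gyre_profile)
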