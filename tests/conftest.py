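"""Shared fixtures: small synthetic movies reused across test modules."""

from dataclasses import replace

import pytest

from sirs_quant.foci import segment_movie
from sirs_quant.synthetic import NoiseParams, generate_movie, get_preset


@pytest.fixture(scope="session")
def quiet_wt_preset():
    """Wild-type timing preset with the camera noise switched off."""
    return replace(get_preset("wt_timing"), noise=NoiseParams(0.0, 0.0, False))


@pytest.fixture(scope="session")
def wt_movie():
    """One noisy wild-type movie plus its planted truth."""
    return generate_movie("wt_timing", 11)


@pytest.fixture(scope="session")
def wt_centroids(wt_movie):
    movie, _ = wt_movie
    return [f.centroids for f in segment_movie(movie)]


@pytest.fixture(scope="session")
def quiet_wt_movie(quiet_wt_preset):
    return generate_movie(quiet_wt_preset, 11)
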