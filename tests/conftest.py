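"""Shared fixtures: reference subject and memoized calibrated models."""

from functools import lru_cache

import pytest

from sgltpbpk import reference_subject
from sgltpbpk.calibrate import calibrate_compound


@lru_cache(maxsize=None)
def _calibrated(name: str):
    return calibrate_compound(name)


@pytest.fixture(scope="session")
def calibrated():
    """Callable returning the (cached) lowest-dose-calibrated model."""
    return _calibrated


@pytest.fixture(scope="session")
def ref_subject():
    return reference_subject()
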