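"""Shared fixtures.

The full-geometry focal simulation is expensive, so it is computed once per
session (at half-wavelength aperture sampling, which the convergence tests
show is within 0.2% of quarter-wavelength for these metrics) and shared by
every test that needs the characterization of the therapy source.
"""
import numpy as np
import pytest

from histopam import field_model as fm


@pytest.fixture(scope="session")
def focal_characterization():
    """(FocalWidths, FootprintEllipse, BinaryMask) of the default source."""
    return fm.simulate_focal_metrics(points_per_wavelength=2, dtype=np.float32)


@pytest.fixture()
def water37():
    return fm.Medium()
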