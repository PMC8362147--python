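"""Shared fixtures: all scan data are simulated at test time.

Heavier fixtures (thorax scans) are session-scoped and reused; tests
must not mutate them in place.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from efovct.containers import CTImage
from efovct.geometry import default_geometry
from efovct.phantom import thorax_spec
from efovct.projection import forward_project, truncate

logging.getLogger("efovct").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def geo720():
    return default_geometry(720)


@pytest.fixture(scope="session")
def geo360():
    return default_geometry(360)


@pytest.fixture(scope="session")
def wide360(geo360):
    geo, _ = geo360.widened_to(geo360.bore_radius_mm)
    return geo


@pytest.fixture(scope="session")
def thorax_case(geo360, wide360):
    """Single-slice 560 mm thorax: spec, image/mask (512 grid), wide and
    truncated sinograms at 360 angles."""
    spec = thorax_spec(n_slices=1)
    image, mask = spec.rasterize(800.0 / 512, 512)
    wide_sino = forward_project(image, wide360)
    measured = truncate(wide_sino)
    return {
        "spec": spec,
        "image": image,
        "mask": mask,
        "wide_sino": wide_sino,
        "measured": measured,
    }


@pytest.fixture()
def recon_grid():
    """Empty 512-grid image centered at the isocenter (for coordinates)."""
    return CTImage(np.zeros((1, 512, 512)), 800.0 / 512)


@pytest.fixture(scope="session")
def disc_case(geo720):
    """Centered water disc (radius 100 mm) fully inside the sFoV."""
    from efovct.phantom import EllipseComponent, PhantomSpec

    spec = PhantomSpec((EllipseComponent((0.0, 0.0), (100.0, 100.0), 0.0, 0.0),))
    image, mask = spec.rasterize(800.0 / 512, 512)
    sino = forward_project(image, geo720)
    return {"spec": spec, "image": image, "mask": mask, "sino": sino}
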