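import numpy as np
import pytest

from organaxis.axis import cma_params, compute_axis_field, bin_axis
from organaxis.grid import build_hex_grid, class_distance_field, transfer_raster_to_grid
from organaxis.synthetic import LobuleSpec, make_lobule_raster


@pytest.fixture(scope="session")
def lobule():
    """Noiseless concentric lobule with one HC disc at the study's raster scale."""
    spec = LobuleSpec(hc_discs=((440.0, 480.0, 40.0),), seed=0)
    return make_lobule_raster(spec)


def grid_with_cma(lob, spacing=15.0):
    g = build_hex_grid(lob.broad.tissue_mask(), spacing, ppm=lob.spec.ppm)
    transfer_raster_to_grid(lob.broad, g, "broad")
    for cls in ("edge", "cortex", "medulla"):
        class_distance_field(g, "broad", cls, k=10)
    return g


@pytest.fixture(scope="session")
def cma_field(lobule):
    """Binned CMA field on the session lobule's annotation grid."""
    g = grid_with_cma(lobule)
    return bin_axis(compute_axis_field(g, cma_params()))
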