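import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from icscore import build_regions


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def circular_geometry():
    """Circular tumour of radius 3 mm centred in a 20×20 mm section."""
    section = Polygon([(0, 0), (20, 0), (20, 20), (0, 20)])
    tumour = Point(10, 10).buffer(3.0, quad_segs=512)
    return build_regions(section, tumour, margin_half_width_mm=0.5)


def cells_frame(xy, marker="CD3", patient_id="P000"):
    """Cell-map DataFrame from an (n, 2) coordinate array."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    return pd.DataFrame({
        "patient_id": patient_id,
        "marker": marker if isinstance(marker, str) else list(marker),
        "x_mm": xy[:, 0],
        "y_mm": xy[:, 1],
    })
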