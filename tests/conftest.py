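import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from ki67hotspot.types import TumorROI


def make_cells(xy, positive=None, cell_class="tumor", roi_id="r1",
               slide_id="T"):
    """Assemble a cell table from coordinates and a positivity mask."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    n = len(xy)
    if positive is None:
        positive = np.zeros(n, dtype=bool)
    positive = np.asarray(positive, dtype=bool)
    status = np.where(positive, "positive", "negative")
    if cell_class == "stroma":
        status = np.full(n, "not_applicable")
    return pd.DataFrame({
        "cell_id": [f"{slide_id}_c{i:05d}" for i in range(n)],
        "x_um": xy[:, 0], "y_um": xy[:, 1],
        "cell_class": cell_class, "ki67_status": status, "roi_id": roi_id,
    })


def square_roi(x0, y0, size, roi_id="r1", roi_class="invasive"):
    poly = Polygon([(x0, y0), (x0 + size, y0), (x0 + size, y0 + size),
                    (x0, y0 + size)])
    return TumorROI(roi_id, poly, roi_class)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
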