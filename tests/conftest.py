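import numpy as np
import pytest

from lumicount import (
    AcquisitionMetadata,
    EventStream,
    RegionOfInterest,
    RoiSet,
    StimulationProtocol,
)
from lumicount.synthetic_data import default_protocol


@pytest.fixture
def square_roi() -> RegionOfInterest:
    return RegionOfInterest("EB", ((100, 100), (200, 100), (200, 200), (100, 200)))


@pytest.fixture
def r2_roi_set(square_roi) -> RoiSet:
    rois = [
        square_roi,
        RegionOfInterest("BU_L", ((10, 10), (60, 10), (60, 60), (10, 60))),
        RegionOfInterest("BU_R", ((300, 10), (350, 10), (350, 60), (300, 60))),
        RegionOfInterest("cb_L", ((10, 300), (60, 300), (60, 350), (10, 350))),
        RegionOfInterest("cb_R", ((300, 300), (350, 300), (350, 350), (300, 350))),
    ]
    return RoiSet(rois, scenario="R2")


@pytest.fixture
def tiny_stream() -> EventStream:
    """Five photons inside a central square ROI, one outside."""
    x = np.array([150, 150, 150, 150, 150, 400])
    y = np.array([150, 150, 150, 150, 150, 400])
    t = np.array([3.1, 3.2, 3.9, 4.0, 4.5, 3.5])
    return EventStream(x, y, t, duration_s=10.0,
                       metadata=AcquisitionMetadata())


@pytest.fixture
def short_protocol() -> StimulationProtocol:
    """Reduced epochs for fast tests: 60 s baseline, 120 s response."""
    return default_protocol(False, baseline_s=60.0, response_s=120.0,
                            post_kcl_s=30.0)


def make_series_stream(counts, roi, t_offset=0.0):
    """Build an EventStream whose 1-s binned counts inside ``roi`` equal
    ``counts`` exactly (events placed at the ROI centroid, mid-bin)."""
    cx, cy = roi.polygon.centroid.x, roi.polygon.centroid.y
    ts, xs, ys = [], [], []
    for k, c in enumerate(counts):
        for j in range(int(c)):
            ts.append(t_offset + k + (j + 1) / (int(c) + 1))
            xs.append(int(cx))
            ys.append(int(cy))
    return EventStream(np.array(xs, dtype=int), np.array(ys, dtype=int),
                       np.array(ts), duration_s=t_offset + len(counts))
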