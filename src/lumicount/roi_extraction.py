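"""Regions of interest and 1 Hz per-ROI photon-count series.

ROIs are named simple polygons drawn in detector pixel coordinates.  The
naming vocabulary follows the imaged neuron classes: ring-neuron driver
lines (R2, R5) use five ROIs -- left/right cell-body clusters (cb_L,
cb_R), left/right bulb (BU_L, BU_R) and the ellipsoid body (EB) -- while
the columnar E-PG line uses three (GA_L, GA_R, EB).

Photon events falling inside an ROI are integrated into 1-s bins
("1 s integration time, 1 Hz") to give the photons/s series on which
response detection operates.  No pixel binning is applied: membership is
evaluated per event.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from lumicount.io_events import EventStream

__all__ = [
    "SCENARIO_ROI_NAMES",
    "RegionOfInterest",
    "RoiSet",
    "RoiTimeSeries",
    "load_roi_set",
    "save_roi_set",
    "point_in_roi",
    "points_in_roi",
    "bin_roi_counts",
    "series_frame",
]

#: ROI-name vocabulary per driver-line scenario.
SCENARIO_ROI_NAMES: dict[str, frozenset[str]] = {
    "R2": frozenset({"cb_L", "cb_R", "BU_L", "BU_R", "EB"}),
    "R5": frozenset({"cb_L", "cb_R", "BU_L", "BU_R", "EB"}),
    "EPG": frozenset({"GA_L", "GA_R", "EB"}),
}


@dataclasses.dataclass(frozen=True)
class RegionOfInterest:
    """A named simple polygon in pixel coordinates (boundary inclusive)."""

    name: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError(
                f"ROI {self.name!r}: polygon needs >= 3 vertices, "
                f"got {len(self.vertices)}"
            )
        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(
                f"ROI {self.name!r}: degenerate or self-intersecting polygon"
            )
        object.__setattr__(self, "vertices", tuple(map(tuple, self.vertices)))

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclasses.dataclass
class RoiSet:
    """The ROI collection of one recording scenario."""

    rois: list[RegionOfInterest]
    scenario: str

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_ROI_NAMES:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; "
                f"expected one of {sorted(SCENARIO_ROI_NAMES)}"
            )
        allowed = SCENARIO_ROI_NAMES[self.scenario]
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate ROI names: {names}")
        unknown = set(names) - allowed
        if unknown:
            raise ValueError(
                f"ROI names {sorted(unknown)} not in the {self.scenario} "
                f"vocabulary {sorted(allowed)}"
            )
        if set(names) != allowed:
            raise ValueError(
                f"scenario {self.scenario} requires exactly the ROIs "
                f"{sorted(allowed)}; got {sorted(names)}"
            )

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def __getitem__(self, name: str) -> RegionOfInterest:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]


@dataclasses.dataclass
class RoiTimeSeries:
    """Photon counts per fixed-width time bin within one ROI.

    ``counts[k]`` is the number of photons with arrival time in the
    half-open interval ``[t_start + k*w, t_start + (k+1)*w)``; at the
    default 1-s bin width this is photons/s.
    """

    roi_name: str
    counts: np.ndarray
    bin_width_s: float = 1.0
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.bin_width_s <= 0:
            raise ValueError("bin_width_s must be > 0")
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def times(self) -> np.ndarray:
        """Start time of each bin on the recording axis."""
        return self.t_start + np.arange(self.n_bins) * self.bin_width_s

    def bin_index(self, t: float) -> int:
        k = int(math.floor((t - self.t_start) / self.bin_width_s))
        if not 0 <= k < self.n_bins:
            raise IndexError(f"t={t} outside series")
        return k


def load_roi_set(path: str | Path) -> RoiSet:
    """Load a JSON ROI file: ``{scenario, rois: [{name, vertices}]}``."""
    path = Path(path)
    d = json.loads(path.read_text())
    rois = [
        RegionOfInterest(r["name"], tuple(map(tuple, r["vertices"])))
        for r in d["rois"]
    ]
    return RoiSet(rois, scenario=d["scenario"])


def save_roi_set(roi_set: RoiSet, path: str | Path) -> None:
    d = {
        "scenario": roi_set.scenario,
        "rois": [
            {"name": r.name, "vertices": [list(v) for v in r.vertices]}
            for r in roi_set.rois
        ],
    }
    Path(path).write_text(json.dumps(d, indent=1))


def point_in_roi(x: float, y: float, roi: RegionOfInterest) -> bool:
    """Membership test; points on the polygon boundary count as inside."""
    return bool(roi.polygon.covers(Point(x, y)))


def points_in_roi(
    x: np.ndarray, y: np.ndarray, roi: RegionOfInterest
) -> np.ndarray:
    """Vectorized membership for event arrays, boundary inclusive.

    A bounding-box prefilter keeps the polygon predicate off the bulk of
    the sensor-wide background events.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    poly = roi.polygon
    minx, miny, maxx, maxy = poly.bounds
    inside = np.zeros(x.shape, dtype=bool)
    cand = (x >= minx) & (x <= maxx) & (y >= miny) & (y <= maxy)
    if cand.any():
        pts = shapely.points(x[cand], y[cand])
        shapely.prepare(poly)
        inside[cand] = shapely.covers(poly, pts)
    return inside


def bin_roi_counts(
    stream: EventStream,
    roi: RegionOfInterest,
    bin_width_s: float = 1.0,
) -> RoiTimeSeries:
    """Integrate the photons inside ``roi`` into fixed-width time bins.

    Bin k covers the half-open interval [k*w, (k+1)*w) from the recording
    start, so no photon is ever double-counted; the series spans
    ``ceil(duration / w)`` bins.
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be > 0")
    n_bins = max(1, int(math.ceil(stream.duration_s / bin_width_s)))
    if stream.n_events == 0:
        return RoiTimeSeries(roi.name, np.zeros(n_bins, dtype=np.int64),
                             bin_width_s=bin_width_s)
    member = points_in_roi(stream.x, stream.y, roi)
    t = stream.t[member]
    edges = np.arange(n_bins + 1) * bin_width_s
    # np.histogram closes the last bin; drop events at exactly t == n_bins*w
    t = t[t < edges[-1]]
    counts, _ = np.histogram(t, bins=edges)
    return RoiTimeSeries(roi.name, counts.astype(np.int64),
                         bin_width_s=bin_width_s)


def series_frame(
    series: Sequence[RoiTimeSeries],
) -> pd.DataFrame:
    """Wide export: one ``time_s`` column plus one photons/s column per ROI."""
    if not series:
        raise ValueError("no series given")
    n = series[0].n_bins
    w = series[0].bin_width_s
    for s in series:
        if s.n_bins != n or s.bin_width_s != w:
            raise ValueError("all series must share binning")
    out = {"time_s": series[0].times}
    for s in series:
        out[s.roi_name] = s.counts
    return pd.DataFrame(out)
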