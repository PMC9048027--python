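"""Photon-event stream I/O.

The acquisition system assigns each detected photon an (x, y) pixel
coordinate on the intensified-CCD sensor and a time stamp t, and exports
the stream as CSV.  This module reads and writes that format, carries the
acquisition metadata (frame rate, sensor geometry, imaged field size) and
provides the two bits of acquisition arithmetic the rest of the package
needs: the frame period in ms and the pixel edge length in microns.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "PhotonEvent",
    "AcquisitionMetadata",
    "EventStream",
    "read_event_stream",
    "write_event_stream",
    "frame_period_ms",
    "pixel_size_um",
]


class PhotonEvent(NamedTuple):
    """A single detected photon: pixel coordinates and arrival time (s)."""

    x: int
    y: int
    t: float


@dataclasses.dataclass(frozen=True)
class AcquisitionMetadata:
    """Camera and field geometry for one recording.

    Defaults match photon-counting acquisition at 120 frames/s on a
    640 x 480 sensor imaging a 240 x 180 um field (40x objective,
    0.375 um/pixel).
    """

    frame_rate_hz: float = 120.0
    sensor_width: int = 640
    sensor_height: int = 480
    field_width_um: float = 240.0
    field_height_um: float = 180.0
    objective: str = "40x"

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def pixel_edge_um(self) -> float:
        return self.field_width_um / self.sensor_width

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMetadata":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclasses.dataclass
class EventStream:
    """An ordered photon-event stream plus its acquisition metadata.

    Events are stored as parallel numpy arrays (``x``, ``y`` integer pixel
    indices; ``t`` seconds since recording start) sorted by nondecreasing
    ``t``.  ``duration_s`` is the recording length and bounds every event
    time.
    """

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    duration_s: float
    metadata: AcquisitionMetadata = dataclasses.field(
        default_factory=AcquisitionMetadata
    )

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=np.float64)
        if not (self.x.shape == self.y.shape == self.t.shape):
            raise ValueError("x, y, t must have equal length")
        self.validate()

    def validate(self) -> None:
        m = self.metadata
        if self.t.size:
            if np.any(self.t < 0):
                raise ValueError("negative event time")
            if np.any(np.diff(self.t) < 0):
                # stable sort keeps same-frame photons in file order
                order = np.argsort(self.t, kind="stable")
                self.x, self.y, self.t = self.x[order], self.y[order], self.t[order]
            if float(self.t[-1]) > self.duration_s:
                raise ValueError(
                    f"event at t={self.t[-1]:.6f}s exceeds duration {self.duration_s}s"
                )
            if np.any((self.x < 0) | (self.x >= m.sensor_width)):
                raise ValueError("x pixel index out of sensor range")
            if np.any((self.y < 0) | (self.y >= m.sensor_height)):
                raise ValueError("y pixel index out of sensor range")
        if self.duration_s < 0:
            raise ValueError("duration_s must be >= 0")

    @property
    def n_events(self) -> int:
        return int(self.t.size)

    def __len__(self) -> int:
        return self.n_events

    def __iter__(self) -> Iterator[PhotonEvent]:
        for xi, yi, ti in zip(self.x, self.y, self.t):
            yield PhotonEvent(int(xi), int(yi), float(ti))

    def events(self) -> list[PhotonEvent]:
        return list(self)

    def shifted(self, dt: float) -> "EventStream":
        """Return a copy with every event (and the duration) delayed by dt."""
        return EventStream(
            self.x.copy(), self.y.copy(), self.t + dt, self.duration_s + dt,
            self.metadata,
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_event_stream(
    path: str | Path,
    metadata: AcquisitionMetadata | None = None,
    duration_s: float | None = None,
) -> EventStream:
    """Read a photon-event CSV (columns x, y, t) into an :class:`EventStream`.

    If ``metadata`` is omitted the JSON sidecar ``<path>.json`` is used when
    present, else acquisition defaults.  ``duration_s`` falls back to the
    sidecar value, then to the last event time.

    Raises ``ValueError`` naming the offending line for malformed rows,
    negative times, or out-of-range pixel coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    side = _sidecar_path(path)
    if metadata is None or duration_s is None:
        if side.exists():
            d = json.loads(side.read_text())
            if metadata is None:
                metadata = AcquisitionMetadata.from_dict(d)
            if duration_s is None:
                duration_s = d.get("duration_s")
    metadata = metadata or AcquisitionMetadata()

    df = pd.read_csv(path, dtype=str, comment="#")
    expected = ["x", "y", "t"]
    if list(df.columns[:3]) != expected:
        raise ValueError(
            f"{path}: expected header 'x,y,t', found {list(df.columns)!r}"
        )
    if len(df) == 0:
        return EventStream(
            np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, float),
            duration_s=float(duration_s or 0.0), metadata=metadata,
        )
    parsed = {c: pd.to_numeric(df[c], errors="coerce") for c in expected}
    for c in expected:
        bad = parsed[c].isna()
        if bad.any():
            # +2: one for the header line, one for 0- vs 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(
                f"{path}: malformed value {df[c].iloc[line - 2]!r} "
                f"in column '{c}' at line {line}"
            )
    x = parsed["x"].to_numpy(np.int64)
    y = parsed["y"].to_numpy(np.int64)
    t = parsed["t"].to_numpy(np.float64)
    if duration_s is None:
        duration_s = float(t.max()) if t.size else 0.0
    return EventStream(x, y, t, duration_s=float(duration_s), metadata=metadata)


def write_event_stream(stream: EventStream, path: str | Path) -> None:
    """Write the stream as CSV (header ``x,y,t``) plus a JSON sidecar.

    x and y are written as integers and t at full ``repr`` precision so a
    read/write round trip is lossless.
    """
    path = Path(path)
    order = np.argsort(stream.t, kind="stable")
    df = pd.DataFrame(
        {"x": stream.x[order], "y": stream.y[order], "t": stream.t[order]}
    )
    df.to_csv(path, index=False, float_format=None)
    side = stream.metadata.to_dict()
    side["duration_s"] = stream.duration_s
    _sidecar_path(path).write_text(json.dumps(side, indent=1))


def frame_period_ms(frame_rate_hz: float) -> float:
    """Frame period in milliseconds, reported to one decimal.

    At the acquisition rate of 120 frames/s this is the 8.3 ms time
    resolution of the raw stream.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame rate must be > 0")
    return round(1000.0 / frame_rate_hz, 1)


def pixel_size_um(field_extent_um: float, n_pixels: int) -> float:
    """Pixel edge length (um/pixel) from field extent and pixel count."""
    if field_extent_um <= 0 or n_pixels <= 0:
        raise ValueError("field extent and pixel count must be positive")
    return field_extent_um / n_pixels
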