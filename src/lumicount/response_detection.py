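"""Evoked-response detection on 1 Hz ROI series and feature extraction.

The detector mirrors a threshold-on-normalized-signal rule: the series is
normalized to its maximum within the evoked-response window ("the response
peak"), the response onset is a rise to >= 10% of that peak sustained for
at least 2 s (which rejects single-frame cosmic-ray bursts), and the
response end is the first fall back below the 10% threshold.  Latency,
duration, total photons and peak rate are then read from the raw counts.
Average response profiles are built by aligning each series on its own
peak within a 200-s window (100 s either side).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np

from lumicount.roi_extraction import RoiTimeSeries

__all__ = [
    "StimulationProtocol",
    "NormalizedSeries",
    "ResponseWindow",
    "ResponseFeatures",
    "AlignedProfile",
    "normalize_to_peak",
    "detect_response",
    "compute_features",
    "align_on_peak",
]

#: Fraction of the window peak the signal must reach (and hold) at onset.
DEFAULT_THRESHOLD = 0.10
#: Minimum time the signal must stay at/above threshold to count.
DEFAULT_SUSTAIN_S = 2.0


@dataclasses.dataclass(frozen=True)
class StimulationProtocol:
    """Bath-application schedule on the recording time axis (seconds).

    The standard protocol records 10 min of baseline, applies the
    stimulant (nicotine or picrotoxin) and records the evoked response
    for 10 min, then applies KCl as an integrity control.  When dopamine
    is applied it precedes the stimulant by exactly 10 min.
    """

    baseline_end_s: float
    stimulant_time_s: float
    kcl_time_s: float
    analysis_end_s: float
    stimulant: str = "nicotine"
    dopamine_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_end_s < 0:
            raise ValueError("baseline_end_s must be >= 0")
        if self.stimulant not in {"nicotine", "picrotoxin"}:
            raise ValueError(f"unknown stimulant {self.stimulant!r}")
        if self.dopamine_time_s is not None:
            if not math.isclose(self.dopamine_time_s + 600.0,
                                self.stimulant_time_s):
                raise ValueError(
                    "dopamine must precede the stimulant by 600 s "
                    f"(got dopamine at {self.dopamine_time_s}, stimulant at "
                    f"{self.stimulant_time_s})"
                )
        if not self.stimulant_time_s < self.kcl_time_s <= self.analysis_end_s:
            raise ValueError(
                "require stimulant_time_s < kcl_time_s <= analysis_end_s"
            )

    @property
    def has_dopamine(self) -> bool:
        return self.dopamine_time_s is not None

    @property
    def evoked_window(self) -> tuple[float, float]:
        """The epoch in which the drug-evoked response is sought."""
        return (self.stimulant_time_s, self.kcl_time_s)


@dataclasses.dataclass
class NormalizedSeries:
    """A series divided by its maximum within the evoked window."""

    values: np.ndarray
    bin_width_s: float
    t_start: float
    peak_rate: float
    peak_time_s: float
    window: tuple[float, float]
    roi_name: str = ""

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.values.size) * self.bin_width_s


@dataclasses.dataclass(frozen=True)
class ResponseWindow:
    """Onset/offset of one detected response on the recording axis."""

    onset_s: float
    offset_s: float
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValueError("onset must precede offset")


@dataclasses.dataclass(frozen=True)
class ResponseFeatures:
    """Summary features of one evoked response (raw photon counts)."""

    detected: bool
    latency_s: float | None = None
    duration_s: float | None = None
    total_photons: int | None = None
    peak_rate: float | None = None
    peak_time_s: float | None = None
    truncated: bool = False


@dataclasses.dataclass
class AlignedProfile:
    """Peak-aligned average profile over +/- ``half_window_s``."""

    offsets_s: np.ndarray
    mean_counts: np.ndarray
    n_contributing: np.ndarray


def _window_slice(
    t_start: float, bin_width_s: float, n: int, t_a: float, t_b: float
) -> slice:
    """Bins whose start time lies in [t_a, t_b)."""
    lo = max(0, int(math.ceil((t_a - t_start) / bin_width_s - 1e-9)))
    hi = min(n, int(math.ceil((t_b - t_start) / bin_width_s - 1e-9)))
    return slice(lo, hi)


def normalize_to_peak(
    series: RoiTimeSeries,
    window: tuple[float, float],
    subtract_baseline: bool = False,
    baseline_window: tuple[float, float] | None = None,
) -> NormalizedSeries:
    """Scale the series to its maximum photons/s within ``window``.

    The peak bin becomes exactly 1.0.  Optionally the mean rate over
    ``baseline_window`` is subtracted first (off by default: the raw
    photon-counting signal has near-zero background, so the threshold
    operates on un-subtracted rates).

    Raises ``ValueError`` on an empty window or an all-zero signal in the
    window (degenerate recording, e.g. reporter not loaded).
    """
    t_a, t_b = window
    sl = _window_slice(series.t_start, series.bin_width_s, series.n_bins,
                       t_a, t_b)
    if sl.start >= sl.stop:
        raise ValueError(f"window {window} contains no bins")
    values = series.counts.astype(float)
    if subtract_baseline:
        if baseline_window is None:
            raise ValueError("baseline_window required when subtracting")
        bsl = _window_slice(series.t_start, series.bin_width_s,
                            series.n_bins, *baseline_window)
        values = values - float(np.mean(values[bsl]))
    wvals = values[sl]
    peak_local = int(np.argmax(wvals))  # earliest bin attaining the max
    peak = float(wvals[peak_local])
    if peak <= 0:
        raise ValueError("degenerate signal: no photons in the peak window")
    peak_idx = sl.start + peak_local
    raw_peak = float(series.counts[peak_idx])
    return NormalizedSeries(
        values=values / peak,
        bin_width_s=series.bin_width_s,
        t_start=series.t_start,
        peak_rate=raw_peak,
        peak_time_s=float(series.t_start + peak_idx * series.bin_width_s),
        window=(t_a, t_b),
        roi_name=series.roi_name,
    )


def _runs_at_or_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs [i, j) where mask is True."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def detect_response(
    norm: NormalizedSeries,
    search_start_s: float,
    threshold: float = DEFAULT_THRESHOLD,
    sustain_s: float = DEFAULT_SUSTAIN_S,
    search_end_s: float | None = None,
    prefer_peak_run: bool = True,
    warn_high_baseline: bool = True,
    reject_degenerate: bool = False,
) -> ResponseWindow | None:
    """Find the evoked-response window in a normalized series.

    A candidate onset is the start of a run of consecutive bins at or
    above ``threshold`` beginning at or after ``search_start_s``; the run
    must last at least ``sustain_s`` to qualify (cosmic-ray bursts confined
    to a single frame never do).  The offset is the start of the first bin
    after onset falling back below threshold.  If the signal never
    re-crosses before ``search_end_s`` (default: the normalization-window
    end) the offset is clamped there and the window flagged truncated.

    When several runs qualify, the run containing the evoked-window peak
    is returned by default (the features are anchored on the response
    peak); ``prefer_peak_run=False`` selects the earliest run instead.
    Returns ``None`` when no run qualifies.

    When more than half of the pre-``search_start_s`` baseline bins
    already sit at/above threshold the normalized signal is degenerate
    (no evoked peak rises clearly above baseline); a warning is emitted
    and, with ``reject_degenerate=True``, the series is reported as
    having no response.
    """
    v = norm.values
    w = norm.bin_width_s
    n = v.size
    if search_end_s is None:
        search_end_s = norm.window[1]
    start_idx = int(math.ceil((search_start_s - norm.t_start) / w - 1e-9))
    end_idx = min(n, int(math.ceil((search_end_s - norm.t_start) / w - 1e-9)))
    if start_idx >= n:
        raise ValueError("search_start_s beyond series end")
    if (warn_high_baseline or reject_degenerate) and start_idx > 0:
        base = v[:start_idx]
        if np.mean(base >= threshold) > 0.5:
            if warn_high_baseline:
                warnings.warn(
                    "more than half of the baseline bins already exceed the "
                    "detection threshold; the normalized signal may be "
                    "degenerate or the peak window misplaced",
                    stacklevel=2,
                )
            if reject_degenerate:
                return None

    sustain_bins = max(1, int(math.ceil(sustain_s / w - 1e-9)))
    seg = v[start_idx:end_idx]
    runs = [
        (start_idx + a, start_idx + b)
        for a, b in _runs_at_or_above(seg >= threshold)
        if b - a >= sustain_bins
    ]
    if not runs:
        return None

    chosen = runs[0]
    if prefer_peak_run and len(runs) > 1:
        peak_idx = int(round((norm.peak_time_s - norm.t_start) / w))
        for a, b in runs:
            if a <= peak_idx < b:
                chosen = (a, b)
                break
    a, b = chosen
    onset = norm.t_start + a * w
    truncated = b >= end_idx
    offset = search_end_s if truncated else norm.t_start + b * w
    return ResponseWindow(onset_s=float(onset), offset_s=float(offset),
                          truncated=truncated)


def compute_features(
    series: RoiTimeSeries,
    window: ResponseWindow | None,
    protocol: StimulationProtocol,
) -> ResponseFeatures:
    """Latency, duration, total photons and peak of one response.

    Latency is onset minus the stimulant application time; duration is
    offset minus onset; total photons sums the raw counts over the bins in
    [onset, offset); the peak is the maximum raw photons/s in the window.
    A ``None`` window yields ``detected=False`` with absent features.
    """
    if window is None:
        return ResponseFeatures(detected=False)
    if window.onset_s < protocol.stimulant_time_s:
        raise ValueError(
            f"response onset {window.onset_s}s precedes stimulant "
            f"application at {protocol.stimulant_time_s}s"
        )
    sl = _window_slice(series.t_start, series.bin_width_s, series.n_bins,
                       window.onset_s, window.offset_s)
    counts = series.counts[sl]
    if counts.size == 0:
        raise ValueError("response window contains no bins of the series")
    peak_local = int(np.argmax(counts))
    return ResponseFeatures(
        detected=True,
        latency_s=float(window.onset_s - protocol.stimulant_time_s),
        duration_s=float(window.offset_s - window.onset_s),
        total_photons=int(np.sum(counts)),
        peak_rate=float(counts[peak_local]),
        peak_time_s=float(series.t_start
                          + (sl.start + peak_local) * series.bin_width_s),
        truncated=window.truncated,
    )


def align_on_peak(
    series_list: Sequence[RoiTimeSeries],
    peak_times_s: Sequence[float],
    half_window_s: float = 100.0,
) -> AlignedProfile:
    """Average the series after aligning each on its own response peak.

    Each series is re-indexed to integer-bin offsets within
    ``+/- half_window_s`` of its peak; the profile is the per-offset mean
    over the series that have data at that offset (``n_contributing``
    records how many).
    """
    if not series_list:
        raise ValueError("empty series list")
    if len(series_list) != len(peak_times_s):
        raise ValueError("series_list and peak_times_s length mismatch")
    w = series_list[0].bin_width_s
    for s in series_list:
        if s.bin_width_s != w:
            raise ValueError("all series must share bin width")
    half_bins = int(round(half_window_s / w))
    offsets = np.arange(-half_bins, half_bins + 1)
    total = np.zeros(offsets.size)
    n_contrib = np.zeros(offsets.size, dtype=np.int64)
    for s, pk in zip(series_list, peak_times_s):
        pk_idx = s.bin_index(pk)
        idx = pk_idx + offsets
        valid = (idx >= 0) & (idx < s.n_bins)
        total[valid] += s.counts[idx[valid]]
        n_contrib[valid] += 1
    mean = np.full(offsets.size, np.nan)
    nz = n_contrib > 0
    mean[nz] = total[nz] / n_contrib[nz]
    return AlignedProfile(
        offsets_s=offsets * w, mean_counts=mean, n_contributing=n_contrib
    )
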