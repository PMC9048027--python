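"""Synthetic photon-stream experiments with known ground truth.

No raw recordings ship with the package, so every stage of the analysis
is exercised on simulated experiments that emulate the statistical
structure of in vivo GFP-aequorin photon counting:

- per-ROI baseline photon emission plus a sensor-wide background;
- a drug-evoked response with ROI- and condition-dependent amplitude and
  latency, shaped by a double-exponential rise-and-decay kernel;
- per-fly heterogeneity as a log-normal multiplier on response amplitude
  (the generative counterpart of the random fly intercept);
- rare cosmic-ray artifacts: large photon bursts confined to a single
  8.3-ms frame, which the detector's 2-s sustain rule must reject;
- a terminal KCl-evoked surge (the preparation-integrity control).

Events are drawn from the resulting inhomogeneous Poisson rate by
per-bin thinning with exact local rate bounds and placed uniformly
inside the emitting ROI polygon, so the generator produces files in
exactly the formats the I/O and extraction modules consume.

Default rates assume a bright ellipsoid-body response of a few thousand
photons/s over a baseline of tens of photons/s; the true in vivo rates
are not tabulated anywhere, so these magnitudes are assumptions of the
generator, not measurements.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
import shapely

from lumicount.io_events import AcquisitionMetadata, EventStream
from lumicount.response_detection import StimulationProtocol
from lumicount.roi_extraction import (
    SCENARIO_ROI_NAMES,
    RegionOfInterest,
    RoiSet,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "CohortData",
    "response_kernel",
    "kernel_peak",
    "kernel_argmax",
    "default_protocol",
    "make_default_roi_set",
    "scenario_preset",
    "scale_rates",
    "simulate_fly",
    "simulate_cohort",
]

CONDITIONS = ("none", "dopamine")


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic experiment arm pair.

    ``amplitude`` and ``latency_shift_s`` are keyed by condition
    ("none" / "dopamine") then by ROI name; ``baseline_rate`` by ROI
    name.  ``amplitude`` values are evoked *peak* rates (photons/s): the
    response kernel is normalized to unit peak internally.
    """

    scenario: str = "R2"
    n_flies_per_arm: int = 13
    baseline_rate: Mapping[str, float] = dataclasses.field(default_factory=dict)
    amplitude: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=dict
    )
    latency_shift_s: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=dict
    )
    base_latency_s: float = 10.0
    tau_rise_s: float = 5.0
    tau_decay_s: float = 40.0
    fly_sd: float = 0.3
    background_rate: float = 2.0
    cosmic_rate_per_min: float = 0.5
    cosmic_magnitude: int = 200
    kcl_amplitude: float = 3000.0
    kcl_tau_rise_s: float = 2.0
    kcl_tau_decay_s: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_ROI_NAMES:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_flies_per_arm < 1:
            raise ValueError("n_flies_per_arm must be >= 1")
        for tau in (self.tau_rise_s, self.tau_decay_s,
                    self.kcl_tau_rise_s, self.kcl_tau_decay_s):
            if tau <= 0:
                raise ValueError("kernel time constants must be > 0")
        for r in self.baseline_rate.values():
            if r < 0:
                raise ValueError("baseline rates must be >= 0")
        for cond_map in self.amplitude.values():
            for a in cond_map.values():
                if a < 0:
                    raise ValueError("amplitudes must be >= 0")
        if self.background_rate < 0 or self.cosmic_rate_per_min < 0:
            raise ValueError("rates must be >= 0")

    @property
    def roi_names(self) -> list[str]:
        return sorted(SCENARIO_ROI_NAMES[self.scenario])


@dataclasses.dataclass
class GroundTruth:
    """True generative quantities, one record per simulated fly x ROI."""

    records: pd.DataFrame
    config: SyntheticConfig


@dataclasses.dataclass
class CohortData:
    """A simulated two-arm cohort ready for the analysis pipeline."""

    streams: dict[str, EventStream]
    conditions: dict[str, str]  # fly_id -> condition label
    protocols: dict[str, StimulationProtocol]  # condition -> protocol
    roi_set: RoiSet
    truth: GroundTruth

    @property
    def fly_ids(self) -> list[str]:
        return list(self.streams)


def response_kernel(
    t: np.ndarray | float, tau_rise_s: float, tau_decay_s: float
) -> np.ndarray | float:
    """Double-exponential rise-and-decay kernel, zero for t < 0.

    K(t) = (1 - exp(-t/tau_rise)) * exp(-t/tau_decay).  The peak value is
    below 1; use :func:`kernel_peak` to normalize.
    """
    if tau_rise_s <= 0 or tau_decay_s <= 0:
        raise ValueError("kernel time constants must be > 0")
    t_arr = np.asarray(t, dtype=float)
    out = np.where(
        t_arr >= 0,
        (1.0 - np.exp(-np.maximum(t_arr, 0) / tau_rise_s))
        * np.exp(-np.maximum(t_arr, 0) / tau_decay_s),
        0.0,
    )
    return float(out) if np.isscalar(t) else out


def kernel_argmax(tau_rise_s: float, tau_decay_s: float) -> float:
    """Time of the kernel maximum: tau_rise * ln(1 + tau_decay/tau_rise)."""
    return tau_rise_s * math.log(1.0 + tau_decay_s / tau_rise_s)


def kernel_peak(tau_rise_s: float, tau_decay_s: float) -> float:
    """Maximum value of the (un-normalized) response kernel."""
    return float(
        response_kernel(kernel_argmax(tau_rise_s, tau_decay_s),
                        tau_rise_s, tau_decay_s)
    )


def _kernel_max_in(
    a: np.ndarray, b: np.ndarray, onset: float,
    tau_rise_s: float, tau_decay_s: float,
) -> np.ndarray:
    """Exact max of K(t - onset) over each interval [a, b] (K unimodal)."""
    t_star = onset + kernel_argmax(tau_rise_s, tau_decay_s)
    ka = response_kernel(a - onset, tau_rise_s, tau_decay_s)
    kb = response_kernel(b - onset, tau_rise_s, tau_decay_s)
    out = np.maximum(ka, kb)
    interior = (a < t_star) & (t_star < b)
    if np.any(interior):
        out = np.where(interior, kernel_peak(tau_rise_s, tau_decay_s), out)
    return out


def default_protocol(
    has_dopamine: bool,
    stimulant: str = "nicotine",
    baseline_s: float = 600.0,
    response_s: float = 600.0,
    post_kcl_s: float = 60.0,
) -> StimulationProtocol:
    """The standard application schedule.

    10 min baseline, stimulant application, 10 min evoked-response
    recording, then KCl; when dopamine is applied it goes in at the end
    of the baseline, 10 min before the stimulant.  Shorter epochs can be
    configured for small test runs (the 600-s dopamine-to-stimulant gap
    is fixed by the protocol contract).
    """
    if has_dopamine:
        stim = baseline_s + 600.0
        dop = baseline_s
    else:
        stim = baseline_s
        dop = None
    kcl = stim + response_s
    return StimulationProtocol(
        baseline_end_s=baseline_s,
        dopamine_time_s=dop,
        stimulant_time_s=stim,
        kcl_time_s=kcl,
        analysis_end_s=kcl + post_kcl_s,
        stimulant=stimulant,
    )


def _rect(x0: float, y0: float, x1: float, y1: float) -> tuple:
    return ((x0, y0), (x1, y0), (x1, y1), (x0, y1))


def make_default_roi_set(scenario: str) -> RoiSet:
    """Plausible rectangular ROIs on the 640 x 480 sensor.

    The published experiments drew ROIs by hand on GFP images; these
    synthetic stand-ins only fix sizes and relative positions (central
    EB, flanking bulb/gall, lateral cell-body clusters).  All statistics
    downstream are geometry-agnostic.
    """
    if scenario in ("R2", "R5"):
        rois = [
            RegionOfInterest("EB", _rect(280, 190, 370, 280)),
            RegionOfInterest("BU_L", _rect(170, 190, 240, 250)),
            RegionOfInterest("BU_R", _rect(410, 190, 480, 250)),
            RegionOfInterest("cb_L", _rect(80, 60, 160, 140)),
            RegionOfInterest("cb_R", _rect(490, 60, 570, 140)),
        ]
    elif scenario == "EPG":
        rois = [
            RegionOfInterest("EB", _rect(280, 190, 370, 280)),
            RegionOfInterest("GA_L", _rect(150, 300, 230, 370)),
            RegionOfInterest("GA_R", _rect(420, 300, 500, 370)),
        ]
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return RoiSet(rois, scenario=scenario)


def scenario_preset(name: str) -> SyntheticConfig:
    """Named generative presets encoding the qualitative study findings.

    - ``R2``   (nicotine):   dopamine enhances the EB and cell-body
      response and shortens the EB latency;
    - ``R5``   (picrotoxin): dopamine reduces the response and lengthens
      the latency;
    - ``EPG``  (nicotine):   dopamine enhances the EB response only;
    - ``EPG_Dop1R1_RNAi``:   receptor knockdown neutralizes the dopamine
      effect;
    - ``EPG_Dop1R2_RNAi``:   knockdown inverts it (reduction instead of
      enhancement).

    Effect sizes are generator configuration, not measured quantities.
    """
    ring_baseline = {"EB": 50.0, "BU_L": 30.0, "BU_R": 30.0,
                     "cb_L": 30.0, "cb_R": 30.0}
    epg_baseline = {"EB": 50.0, "GA_L": 30.0, "GA_R": 30.0}
    if name == "R2":
        return SyntheticConfig(
            scenario="R2",
            baseline_rate=ring_baseline,
            amplitude={
                "none": {"EB": 2000.0, "BU_L": 400.0, "BU_R": 400.0,
                         "cb_L": 500.0, "cb_R": 500.0},
                "dopamine": {"EB": 3000.0, "BU_L": 440.0, "BU_R": 440.0,
                             "cb_L": 800.0, "cb_R": 800.0},
            },
            latency_shift_s={
                "none": {},
                "dopamine": {"EB": -5.0, "cb_L": -3.0, "cb_R": -3.0},
            },
        )
    if name == "R5":
        return SyntheticConfig(
            scenario="R5",
            baseline_rate=ring_baseline,
            amplitude={
                "none": {"EB": 2000.0, "BU_L": 500.0, "BU_R": 500.0,
                         "cb_L": 500.0, "cb_R": 500.0},
                "dopamine": {"EB": 1200.0, "BU_L": 400.0, "BU_R": 400.0,
                             "cb_L": 350.0, "cb_R": 350.0},
            },
            latency_shift_s={
                "none": {},
                "dopamine": {"EB": 10.0, "BU_L": 5.0, "BU_R": 5.0,
                             "cb_L": 5.0, "cb_R": 5.0},
            },
        )
    if name == "EPG":
        return SyntheticConfig(
            scenario="EPG",
            baseline_rate=epg_baseline,
            amplitude={
                "none": {"EB": 1500.0, "GA_L": 400.0, "GA_R": 400.0},
                "dopamine": {"EB": 2250.0, "GA_L": 400.0, "GA_R": 400.0},
            },
            latency_shift_s={"none": {}, "dopamine": {"EB": -4.0}},
        )
    if name == "EPG_Dop1R1_RNAi":
        base = scenario_preset("EPG")
        return dataclasses.replace(
            base,
            amplitude={"none": dict(base.amplitude["none"]),
                       "dopamine": dict(base.amplitude["none"])},
            latency_shift_s={"none": {}, "dopamine": {}},
        )
    if name == "EPG_Dop1R2_RNAi":
        base = scenario_preset("EPG")
        return dataclasses.replace(
            base,
            amplitude={"none": dict(base.amplitude["none"]),
                       "dopamine": {"EB": 1000.0, "GA_L": 400.0,
                                    "GA_R": 400.0}},
            latency_shift_s={"none": {}, "dopamine": {"EB": 4.0}},
        )
    raise ValueError(f"unknown preset {name!r}")


def scale_rates(config: SyntheticConfig, factor: float) -> SyntheticConfig:
    """Multiply every photon rate in the config by ``factor``.

    Useful for small test runs: relative effect sizes (and therefore all
    recovery properties) are unchanged, only the photon budget shrinks.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    return dataclasses.replace(
        config,
        baseline_rate={k: v * factor for k, v in config.baseline_rate.items()},
        amplitude={
            c: {k: v * factor for k, v in m.items()}
            for c, m in config.amplitude.items()
        },
        background_rate=config.background_rate * factor,
        kcl_amplitude=config.kcl_amplitude * factor,
    )


def _sample_in_polygon(
    rng: np.random.Generator, poly: Polygon, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform points inside a polygon by bounding-box rejection."""
    if n == 0:
        return np.empty(0), np.empty(0)
    minx, miny, maxx, maxy = poly.bounds
    shapely.prepare(poly)
    xs = np.empty(n)
    ys = np.empty(n)
    filled = 0
    frac = max(poly.area / ((maxx - minx) * (maxy - miny)), 1e-3)
    while filled < n:
        m = int((n - filled) / frac * 1.2) + 16
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        ok = shapely.covers(poly, shapely.points(cx, cy))
        k = min(int(ok.sum()), n - filled)
        xs[filled:filled + k] = cx[ok][:k]
        ys[filled:filled + k] = cy[ok][:k]
        filled += k
    return xs, ys


def _thin_events(
    rng: np.random.Generator,
    duration: float,
    rate_fn,
    bound_fn,
    grid_s: float = 1.0,
) -> np.ndarray:
    """Inhomogeneous Poisson event times by per-bin thinning.

    ``bound_fn(a, b)`` must return an upper bound of the rate on each
    interval [a, b]; candidates are drawn homogeneously at that bound and
    accepted with probability rate/bound, which is exact.
    """
    n_bins = int(math.ceil(duration / grid_s))
    edges = np.arange(n_bins + 1) * grid_s
    edges[-1] = duration
    a, b = edges[:-1], edges[1:]
    lam = bound_fn(a, b) * (b - a)
    counts = rng.poisson(lam)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    bin_idx = np.repeat(np.arange(n_bins), counts)
    t = a[bin_idx] + rng.uniform(0.0, 1.0, total) * (b - a)[bin_idx]
    bound_at = np.repeat(bound_fn(a, b), counts)
    accept = rng.uniform(0.0, 1.0, total) * bound_at <= rate_fn(t)
    return np.sort(t[accept])


def _roi_rate_fns(
    config: SyntheticConfig,
    protocol: StimulationProtocol,
    roi_name: str,
    condition: str,
    fly_multiplier: float,
):
    """(rate_fn, bound_fn, onset, peak_amplitude) for one ROI."""
    base = float(config.baseline_rate.get(roi_name, 0.0))
    amp = float(config.amplitude.get(condition, {}).get(roi_name, 0.0))
    amp *= fly_multiplier
    shift = float(config.latency_shift_s.get(condition, {}).get(roi_name, 0.0))
    onset = protocol.stimulant_time_s + config.base_latency_s + shift
    k_norm = kernel_peak(config.tau_rise_s, config.tau_decay_s)
    kcl_norm = kernel_peak(config.kcl_tau_rise_s, config.kcl_tau_decay_s)
    kcl_t = protocol.kcl_time_s
    kcl_amp = config.kcl_amplitude

    def rate(t):
        r = base + amp / k_norm * response_kernel(
            np.asarray(t) - onset, config.tau_rise_s, config.tau_decay_s
        )
        r = r + kcl_amp / kcl_norm * response_kernel(
            np.asarray(t) - kcl_t, config.kcl_tau_rise_s,
            config.kcl_tau_decay_s,
        )
        return r

    def bound(a, b):
        r = base + amp / k_norm * _kernel_max_in(
            a, b, onset, config.tau_rise_s, config.tau_decay_s
        )
        r = r + kcl_amp / kcl_norm * _kernel_max_in(
            a, b, kcl_t, config.kcl_tau_rise_s, config.kcl_tau_decay_s
        )
        return r

    return rate, bound, onset, amp


def simulate_fly(
    config: SyntheticConfig,
    protocol: StimulationProtocol,
    roi_set: RoiSet,
    fly_seed: int,
    fly_id: str | None = None,
) -> tuple[EventStream, pd.DataFrame]:
    """Simulate one fly's recording; returns the stream and truth records.

    The condition arm is inferred from the protocol (dopamine applied or
    not).  The per-fly amplitude multiplier exp(Normal(0, fly_sd)) scales
    every evoked amplitude of this fly, emulating between-fly response
    heterogeneity.  Identical ``fly_seed`` gives a byte-identical stream.
    """
    if roi_set.scenario != config.scenario:
        raise ValueError(
            f"ROI set scenario {roi_set.scenario!r} does not match config "
            f"scenario {config.scenario!r}"
        )
    condition = "dopamine" if protocol.has_dopamine else "none"
    rng = np.random.default_rng(fly_seed)
    meta = AcquisitionMetadata()
    duration = protocol.analysis_end_s
    fly_id = fly_id or f"fly{fly_seed}"
    f_mult = float(np.exp(rng.normal(0.0, config.fly_sd)))

    all_x, all_y, all_t = [], [], []
    truth_rows = []
    for roi in roi_set:
        rate_fn, bound_fn, onset, amp = _roi_rate_fns(
            config, protocol, roi.name, condition, f_mult
        )
        t = _thin_events(rng, duration, rate_fn, bound_fn)
        xs, ys = _sample_in_polygon(rng, roi.polygon, t.size)
        all_x.append(np.floor(xs))
        all_y.append(np.floor(ys))
        all_t.append(t)
        truth_rows.append(
            {
                "fly_id": fly_id,
                "condition": condition,
                "roi": roi.name,
                "fly_multiplier": f_mult,
                "amplitude": amp,
                "onset_time_s": onset,
                "latency_s": onset - protocol.stimulant_time_s,
                "fly_seed": fly_seed,
            }
        )

    # sensor-wide background ("extremely low background signal")
    n_bg = rng.poisson(config.background_rate * duration)
    if n_bg:
        all_t.append(np.sort(rng.uniform(0.0, duration, n_bg)))
        all_x.append(rng.integers(0, meta.sensor_width, n_bg).astype(float))
        all_y.append(rng.integers(0, meta.sensor_height, n_bg).astype(float))

    # cosmic rays: a large burst confined to one frame at one pixel;
    # burst times snap to the acquisition frame grid (frames tile the
    # 1-s integration bins exactly at 120 frames/s)
    n_cosmic = rng.poisson(config.cosmic_rate_per_min / 60.0 * duration)
    frame = meta.frame_period_s
    n_frames = int(duration / frame)
    for _ in range(n_cosmic):
        tc = float(rng.integers(0, n_frames)) * frame
        px = rng.integers(0, meta.sensor_width)
        py = rng.integers(0, meta.sensor_height)
        nb = int(config.cosmic_magnitude)
        all_t.append(np.sort(rng.uniform(tc, tc + frame, nb)))
        all_x.append(np.full(nb, float(px)))
        all_y.append(np.full(nb, float(py)))

    x = np.concatenate(all_x) if all_x else np.empty(0)
    y = np.concatenate(all_y) if all_y else np.empty(0)
    t = np.concatenate(all_t) if all_t else np.empty(0)
    order = np.argsort(t, kind="stable")
    x = np.clip(x[order], 0, meta.sensor_width - 1).astype(np.int64)
    y = np.clip(y[order], 0, meta.sensor_height - 1).astype(np.int64)
    stream = EventStream(x, y, t[order], duration_s=duration, metadata=meta)
    return stream, pd.DataFrame(truth_rows)


def simulate_cohort(
    config: SyntheticConfig,
    protocols: tuple[StimulationProtocol, StimulationProtocol] | None = None,
    seed: int | None = None,
    n_per_arm: tuple[int, int] | None = None,
    roi_set: RoiSet | None = None,
) -> CohortData:
    """Simulate a two-arm cohort (without / with dopamine).

    The arms share every generative parameter except the
    condition-dependent amplitude and latency maps.  Per-fly seeds are
    derived as ``seed + fly_index``, so cohorts are reproducible and
    individual flies re-simulable in isolation.
    """
    seed = config.seed if seed is None else seed
    if protocols is None:
        stim = "picrotoxin" if config.scenario == "R5" else "nicotine"
        protocols = (
            default_protocol(False, stimulant=stim),
            default_protocol(True, stimulant=stim),
        )
    proto_none, proto_dop = protocols
    if proto_none.has_dopamine or not proto_dop.has_dopamine:
        raise ValueError(
            "protocols must be (without-dopamine, with-dopamine)"
        )
    if n_per_arm is None:
        n_per_arm = (config.n_flies_per_arm, config.n_flies_per_arm)
    roi_set = roi_set or make_default_roi_set(config.scenario)

    streams: dict[str, EventStream] = {}
    conditions: dict[str, str] = {}
    truth_frames = []
    idx = 0
    for proto, n, tag in (
        (proto_none, n_per_arm[0], "none"),
        (proto_dop, n_per_arm[1], "dopamine"),
    ):
        for _ in range(n):
            fly_seed = seed + idx
            fly_id = f"fly{idx:03d}_{tag}"
            stream, truth = simulate_fly(
                config, proto, roi_set, fly_seed, fly_id=fly_id
            )
            streams[fly_id] = stream
            conditions[fly_id] = tag
            truth_frames.append(truth)
            idx += 1
    truth = GroundTruth(
        records=pd.concat(truth_frames, ignore_index=True), config=config
    )
    return CohortData(
        streams=streams,
        conditions=conditions,
        protocols={"none": proto_none, "dopamine": proto_dop},
        roi_set=roi_set,
        truth=truth,
    )
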