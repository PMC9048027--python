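"""End-to-end orchestration: simulate/load -> extract -> detect -> fit.

A pipeline run starts from either a synthetic experiment (simulate mode)
or a directory of recorded event streams (files mode), converts each
recording into 1 Hz per-ROI series, detects and characterizes the evoked
responses, fits the six-model LME suite, and writes a report with the
BIC ranking, the Bayes factor for the best model, the Bonferroni-adjusted
condition contrasts and (optionally) bootstrap confidence intervals.

Every intermediate is persisted as CSV/JSON so any stage can be audited,
re-run, or replaced; in simulate mode the whole report is reproducible
bit-for-bit from the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from lumicount._version import __version__ as _pkg_version
from lumicount.io_events import read_event_stream, write_event_stream
from lumicount.model_selection import (
    bootstrap_ci,
    build_model_data,
    fit_lme,
    model_suite,
    pairwise_contrasts,
    rank_models,
)
from lumicount.response_detection import (
    StimulationProtocol,
    compute_features,
    detect_response,
    normalize_to_peak,
)
from lumicount.roi_extraction import RoiTimeSeries, bin_roi_counts, load_roi_set, save_roi_set
from lumicount.synthetic_data import (
    CohortData,
    GroundTruth,
    default_protocol,
    make_default_roi_set,
    scale_rates,
    scenario_preset,
    simulate_cohort,
)

log = logging.getLogger("lumicount.pipeline")

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "RunReport",
    "run_pipeline",
    "extract_bins",
    "detect_features",
    "fit_models",
    "save_cohort",
    "load_cohort",
]


class PipelineStageError(RuntimeError):
    """Raised when a stage fails; names the stage and keeps the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    """Everything needed to (re)produce one analysis run."""

    scenario: str = "R2"
    mode: str = "simulate"  # "simulate" | "files"
    preset: str | None = None  # synthetic preset; defaults to scenario
    n_flies_per_arm: int | None = None
    seed: int = 0
    out_dir: str | None = None
    # files mode inputs
    data_dir: str | None = None
    # simulate-mode scaling (photon budget and epoch lengths)
    rate_scale: float = 1.0
    protocol_baseline_s: float = 600.0
    protocol_response_s: float = 600.0
    # detection parameters
    threshold: float = 0.10
    sustain_s: float = 2.0
    bin_width_s: float = 1.0
    subtract_baseline: bool = False
    reject_degenerate: bool = True
    prefer_peak_run: bool = True
    # model options
    response_mode: str = "rate"  # "rate" | "latency"
    model_window_s: float | None = None
    ci_level: float = 0.975
    n_boot: int = 0  # parametric-bootstrap replicates; 0 skips the CI stage

    def __post_init__(self) -> None:
        if self.mode not in {"simulate", "files"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.response_mode not in {"rate", "latency"}:
            raise ValueError(f"unknown response_mode {self.response_mode!r}")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.sustain_s <= 0 or self.bin_width_s <= 0:
            raise ValueError("sustain_s and bin_width_s must be > 0")
        if self.mode == "files":
            if self.data_dir is None:
                raise ValueError("files mode requires data_dir")
            d = Path(self.data_dir)
            for req in ("manifest.csv", "roi.json", "protocols.json"):
                if not (d / req).exists():
                    raise ValueError(f"files mode: missing {d / req}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunReport:
    """The full result of one pipeline run."""

    features: pd.DataFrame
    model_table: pd.DataFrame
    best_id: int
    delta_bic: float
    bf: float
    contrasts: pd.DataFrame
    ci: pd.DataFrame | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "models": self.model_table.to_dict(orient="records"),
            "best_id": self.best_id,
            "delta_bic": self.delta_bic,
            "bf": self.bf,
            "contrasts": self.contrasts.to_dict(orient="records"),
            "ci": None if self.ci is None else self.ci.to_dict(orient="records"),
            "n_flies": int(self.features["fly_id"].nunique()),
            "n_detected": int(self.features["detected"].sum()),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, default=float)

    @property
    def report_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


# ---------------------------------------------------------------- stages


def _protocol_to_dict(p: StimulationProtocol) -> dict:
    return dataclasses.asdict(p)


def _protocol_from_dict(d: dict) -> StimulationProtocol:
    return StimulationProtocol(**d)


def save_cohort(cohort: CohortData, out_dir: str | Path) -> None:
    """Persist a cohort as CSV streams + manifest + ROI/protocol JSON."""
    out = Path(out_dir)
    events = out / "events"
    events.mkdir(parents=True, exist_ok=True)
    rows = []
    for fly_id, stream in cohort.streams.items():
        path = events / f"{fly_id}.csv"
        write_event_stream(stream, path)
        rows.append({"fly_id": fly_id,
                     "condition": cohort.conditions[fly_id],
                     "path": str(path.relative_to(out))})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    save_roi_set(cohort.roi_set, out / "roi.json")
    (out / "protocols.json").write_text(json.dumps(
        {c: _protocol_to_dict(p) for c, p in cohort.protocols.items()},
        indent=1,
    ))
    if cohort.truth is not None:
        cohort.truth.records.to_csv(out / "ground_truth.csv", index=False)


def load_cohort(data_dir: str | Path) -> CohortData:
    """Load a persisted cohort (the inverse of :func:`save_cohort`)."""
    d = Path(data_dir)
    manifest = pd.read_csv(d / "manifest.csv")
    roi_set = load_roi_set(d / "roi.json")
    protocols = {
        c: _protocol_from_dict(pd_) for c, pd_ in
        json.loads((d / "protocols.json").read_text()).items()
    }
    streams = {}
    conditions = {}
    for _, row in manifest.iterrows():
        streams[row["fly_id"]] = read_event_stream(d / row["path"])
        conditions[row["fly_id"]] = row["condition"]
    truth = None
    if (d / "ground_truth.csv").exists():
        truth = GroundTruth(pd.read_csv(d / "ground_truth.csv"), config=None)
    return CohortData(streams=streams, conditions=conditions,
                      protocols=protocols, roi_set=roi_set, truth=truth)


def simulate_stage(config: PipelineConfig) -> CohortData:
    preset = scenario_preset(config.preset or config.scenario)
    if config.rate_scale != 1.0:
        preset = scale_rates(preset, config.rate_scale)
    if config.n_flies_per_arm is not None:
        preset = dataclasses.replace(
            preset, n_flies_per_arm=config.n_flies_per_arm
        )
    stim = "picrotoxin" if preset.scenario == "R5" else "nicotine"
    protocols = (
        default_protocol(False, stimulant=stim,
                         baseline_s=config.protocol_baseline_s,
                         response_s=config.protocol_response_s),
        default_protocol(True, stimulant=stim,
                         baseline_s=config.protocol_baseline_s,
                         response_s=config.protocol_response_s),
    )
    return simulate_cohort(preset, protocols=protocols, seed=config.seed)


def extract_bins(cohort: CohortData, config: PipelineConfig) -> pd.DataFrame:
    """Long table of per-ROI binned counts: one row per fly x ROI x bin."""
    frames = []
    for fly_id, stream in cohort.streams.items():
        for roi in cohort.roi_set:
            series = bin_roi_counts(stream, roi, config.bin_width_s)
            frames.append(pd.DataFrame({
                "fly_id": fly_id,
                "condition": cohort.conditions[fly_id],
                "roi": roi.name,
                "time_s": series.times,
                "count": series.counts,
            }))
    return pd.concat(frames, ignore_index=True)


def _series_from_bins(group: pd.DataFrame, bin_width_s: float) -> RoiTimeSeries:
    g = group.sort_values("time_s")
    return RoiTimeSeries(
        roi_name=str(g["roi"].iloc[0]),
        counts=g["count"].to_numpy(),
        bin_width_s=bin_width_s,
        t_start=float(g["time_s"].iloc[0]),
    )


def detect_features(
    bins: pd.DataFrame,
    protocols: dict[str, StimulationProtocol],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Run detection + feature extraction on every fly x ROI series."""
    genotype = config.preset or config.scenario
    rows = []
    for (fly_id, roi), group in bins.groupby(["fly_id", "roi"], sort=True):
        condition = str(group["condition"].iloc[0])
        protocol = protocols[condition]
        series = _series_from_bins(group, config.bin_width_s)
        base = {"fly_id": fly_id, "genotype": genotype,
                "condition": condition, "roi": roi}
        try:
            norm = normalize_to_peak(
                series, protocol.evoked_window,
                subtract_baseline=config.subtract_baseline,
                baseline_window=(0.0, protocol.baseline_end_s)
                if config.subtract_baseline else None,
            )
            window = detect_response(
                norm,
                search_start_s=protocol.stimulant_time_s,
                threshold=config.threshold,
                sustain_s=config.sustain_s,
                prefer_peak_run=config.prefer_peak_run,
                warn_high_baseline=False,
                reject_degenerate=config.reject_degenerate,
            )
        except ValueError:
            window = None
        feats = compute_features(series, window, protocol)
        rows.append({**base, **dataclasses.asdict(feats)})
    cols = ["fly_id", "genotype", "condition", "roi", "detected", "latency_s",
            "duration_s", "total_photons", "peak_rate", "peak_time_s",
            "truncated"]
    return pd.DataFrame(rows)[cols]


def fit_models(
    bins: pd.DataFrame,
    features: pd.DataFrame,
    protocols: dict[str, StimulationProtocol],
    config: PipelineConfig,
    seed: int | None = None,
) -> dict:
    """Build the model data, fit the suite, rank, contrast, bootstrap."""
    if config.response_mode == "rate":
        frames = []
        for cond, proto in protocols.items():
            stim, kcl = proto.evoked_window
            end = stim + min(
                kcl - stim,
                config.model_window_s if config.model_window_s else np.inf,
            )
            sub = bins[(bins["condition"] == cond)
                       & (bins["time_s"] >= stim)
                       & (bins["time_s"] < end)].copy()
            sub["time"] = sub["time_s"] - stim
            frames.append(sub)
        raw = pd.concat(frames, ignore_index=True)
        data = build_model_data(raw.rename(columns={"count": "rate"}),
                                response="rate")
        suite = model_suite(scenario_levels=raw["roi"].nunique(),
                            has_time=True)
    else:  # latency summaries carry no within-window time axis
        det = features[features["detected"]].copy()
        det["time"] = 0.0
        data = build_model_data(det.rename(columns={"latency_s": "latency"}),
                                response="latency")
        suite = model_suite(scenario_levels=det["roi"].nunique(),
                            has_time=False)

    fits = [fit_lme(spec, data) for spec in suite]
    comparison = rank_models(fits)
    best = comparison.best
    contrast_fit = best if best.spec.has_condition else next(
        f for f in fits if f.spec.has_interaction
    )
    contrasts = pairwise_contrasts(contrast_fit)
    ci = None
    if config.n_boot > 0:
        ci = bootstrap_ci(contrast_fit, n_sim=config.n_boot,
                          level=config.ci_level, seed=seed)
    return {
        "comparison": comparison,
        "fits": fits,
        "contrast_fit": contrast_fit,
        "contrasts": contrasts,
        "ci": ci,
    }


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute simulate/load -> extract -> detect -> fit and report.

    Intermediates (event CSVs, binned counts, feature table, report
    JSON) are written under ``config.out_dir`` when set; a stage failure
    raises :class:`PipelineStageError` naming the stage, with partial
    outputs retained on disk.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise PipelineStageError(name, exc) from exc
        log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        return result

    log.info(
        "run config: threshold=%s sustain_s=%s bin_width_s=%s mode=%s "
        "response_mode=%s seed=%s",
        config.threshold, config.sustain_s, config.bin_width_s, config.mode,
        config.response_mode, config.seed,
    )
    if config.mode == "simulate":
        cohort = _stage("simulate", simulate_stage, config)
        if out:
            _stage("persist", save_cohort, cohort, out / "dataset")
    else:
        cohort = _stage("load", load_cohort, config.data_dir)

    bins = _stage("extract", extract_bins, cohort, config)
    if out:
        bins.to_csv(out / "bins.csv", index=False)
    features = _stage("detect", detect_features, bins, cohort.protocols,
                      config)
    if out:
        features.to_csv(out / "features.csv", index=False)
    fitted = _stage("fit", fit_models, bins, features, cohort.protocols,
                    config, config.seed)

    comparison = fitted["comparison"]
    for fit in fitted["fits"]:
        log.info("model %d: %s  df=%d  BIC=%.2f", fit.spec.id,
                 fit.spec.formula, fit.df, fit.bic)
    contrasts = pd.DataFrame([dataclasses.asdict(c)
                              for c in fitted["contrasts"]])
    ci_table = None
    if fitted["ci"] is not None:
        ci_table = fitted["ci"].table().reset_index(names="coefficient")
    report = RunReport(
        features=features,
        model_table=comparison.table(),
        best_id=int(comparison.best.spec.id),
        delta_bic=comparison.delta_bic,
        bf=comparison.bf,
        contrasts=contrasts,
        ci=ci_table,
        provenance={
            "package_version": _pkg_version,
            "config": config.to_dict(),
            "config_hash": config.config_hash,
            "seed": config.seed,
        },
    )
    if out:
        (out / "report.json").write_text(report.to_json())
    return report
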