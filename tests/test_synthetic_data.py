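import dataclasses

import numpy as np
import pytest
from scipy import integrate, stats

from lumicount import (
    RegionOfInterest,
    RoiSet,
    bin_roi_counts,
    detect_response,
    normalize_to_peak,
    response_kernel,
    scenario_preset,
    simulate_cohort,
    simulate_fly,
)
from lumicount.synthetic_data import (
    SyntheticConfig,
    default_protocol,
    kernel_argmax,
    kernel_peak,
    make_default_roi_set,
    scale_rates,
)
from lumicount.synthetic_data import _roi_rate_fns


def small_config(**overrides) -> SyntheticConfig:
    """A reduced-photon-budget configuration for fast tests."""
    base = dict(
        scenario="R2",
        n_flies_per_arm=3,
        baseline_rate={"EB": 5.0, "BU_L": 3.0, "BU_R": 3.0,
                       "cb_L": 3.0, "cb_R": 3.0},
        amplitude={
            "none": {"EB": 200.0, "BU_L": 40.0, "BU_R": 40.0,
                     "cb_L": 50.0, "cb_R": 50.0},
            "dopamine": {"EB": 300.0, "BU_L": 44.0, "BU_R": 44.0,
                         "cb_L": 80.0, "cb_R": 80.0},
        },
        latency_shift_s={"none": {}, "dopamine": {"EB": -5.0}},
        background_rate=0.5,
        cosmic_rate_per_min=0.0,
        kcl_amplitude=300.0,
        tau_decay_s=30.0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


SHORT_PROTOCOLS = (
    default_protocol(False, baseline_s=60.0, response_s=120.0, post_kcl_s=30.0),
    default_protocol(True, baseline_s=60.0, response_s=120.0, post_kcl_s=30.0),
)


class TestKernel:
    def test_zero_at_onset_and_decays_to_zero(self):
        assert response_kernel(0.0, 5.0, 40.0) == 0.0
        assert response_kernel(-3.0, 5.0, 40.0) == 0.0
        assert response_kernel(1e4, 5.0, 40.0) < 1e-30

    @pytest.mark.parametrize("tr,td", [(5.0, 40.0), (2.0, 15.0), (1.0, 1.0)])
    def test_argmax_matches_numeric_maximum(self, tr, td):
        """Peak at tau_rise * ln(1 + tau_decay/tau_rise) (dK/dt = 0)."""
        t = np.linspace(0, 20 * td, 200_001)
        k = response_kernel(t, tr, td)
        t_num = t[np.argmax(k)]
        assert kernel_argmax(tr, td) == pytest.approx(t_num, abs=1e-2)
        assert kernel_peak(tr, td) == pytest.approx(k.max(), rel=1e-6)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            response_kernel(1.0, -1.0, 40.0)


class TestSimulateFly:
    def test_same_seed_identical_stream(self):
        cfg = small_config()
        roi_set = make_default_roi_set("R2")
        s1, t1 = simulate_fly(cfg, SHORT_PROTOCOLS[0], roi_set, 99)
        s2, t2 = simulate_fly(cfg, SHORT_PROTOCOLS[0], roi_set, 99)
        np.testing.assert_array_equal(s1.t, s2.t)
        np.testing.assert_array_equal(s1.x, s2.x)
        np.testing.assert_array_equal(s1.y, s2.y)
        assert t1.equals(t2)
        s3, _ = simulate_fly(cfg, SHORT_PROTOCOLS[0], roi_set, 100)
        assert s3.n_events != s1.n_events or not np.array_equal(s3.t, s1.t)

    def test_scenario_mismatch_rejected(self):
        cfg = small_config()
        with pytest.raises(ValueError, match="scenario"):
            simulate_fly(cfg, SHORT_PROTOCOLS[0],
                         make_default_roi_set("EPG"), 1)

    def test_event_count_matches_rate_integral(self):
        """Poisson concentration: per-ROI counts within 3*sqrt(lambda) of
        the numerically integrated rate, over 20 seeds."""
        cfg = small_config(background_rate=0.0)
        roi_set = make_default_roi_set("R2")
        proto = SHORT_PROTOCOLS[0]
        failures = 0
        for seed in range(20):
            stream, truth = simulate_fly(cfg, proto, roi_set, 1000 + seed)
            for roi in roi_set:
                f_mult = truth["fly_multiplier"].iloc[0]
                rate_fn, _, _, _ = _roi_rate_fns(cfg, proto, roi.name,
                                                 "none", f_mult)
                lam, _ = integrate.quad(
                    lambda t: float(rate_fn(t)), 0, proto.analysis_end_s,
                    limit=400,
                )
                got = bin_roi_counts(stream, roi).counts.sum()
                if abs(got - lam) > 3 * np.sqrt(lam):
                    failures += 1
        # 3-sigma misses are ~0.3% per check; 100 checks allow a couple
        assert failures <= 2

    def test_thinning_reproduces_constant_rate(self):
        """Chi-square goodness of fit of 10-s window counts on a
        baseline-only (constant-rate) segment, pooled over 50 seeds."""
        cfg = small_config(
            amplitude={"none": {}, "dopamine": {}}, kcl_amplitude=0.0,
            background_rate=0.0,
        )
        roi_set = make_default_roi_set("R2")
        proto = SHORT_PROTOCOLS[0]
        eb = roi_set["EB"]
        counts = []
        for seed in range(50):
            stream, _ = simulate_fly(cfg, proto, roi_set, 2000 + seed)
            series = bin_roi_counts(stream, eb, bin_width_s=10.0)
            counts.extend(series.counts[:20])
        counts = np.asarray(counts)
        lam = 5.0 * 10.0
        # bin the Poisson distribution into quantile classes
        edges = stats.poisson.ppf([0, .1, .25, .5, .75, .9, 1.0], lam)
        obs, _ = np.histogram(counts, bins=np.r_[-0.5, edges[1:-1] + 0.5,
                                                 np.inf])
        cdf = stats.poisson.cdf(np.r_[edges[1:-1], np.inf], lam)
        expected = np.diff(np.r_[0, cdf]) * counts.size
        chi2 = ((obs - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=len(obs) - 1)
        assert p > 0.01

    def test_cosmic_bursts_single_frame_and_rejected(self):
        """Artifact bursts stay within one 8.3-ms frame and are always
        discarded by the 2-s sustain rule when isolated."""
        cfg = small_config(
            amplitude={"none": {}, "dopamine": {}}, kcl_amplitude=0.0,
            cosmic_rate_per_min=4.0, cosmic_magnitude=400,
            background_rate=0.0,
        )
        sensor = RegionOfInterest("EB", ((0, 0), (639, 0), (639, 479),
                                         (0, 479)))
        roi_set = dataclasses.replace(make_default_roi_set("R2"))
        proto = SHORT_PROTOCOLS[0]
        n_detected = 0
        n_bursts = 0
        for seed in range(30):
            stream, _ = simulate_fly(cfg, proto, roi_set, 3000 + seed)
            series = bin_roi_counts(stream, sensor)
            # every burst is all-one-pixel and spans at most one frame
            pix = stream.x * 10_000 + stream.y
            vals, counts = np.unique(pix, return_counts=True)
            for p in vals[counts > 100]:
                tt = stream.t[pix == p]
                # a stray baseline photon may share the pixel; the burst
                # itself is the cluster around the median arrival time
                burst = tt[np.abs(tt - np.median(tt)) < 0.5]
                assert burst.size > 100
                assert burst.max() - burst.min() \
                    <= stream.metadata.frame_period_s
                n_bursts += 1
            # the sustain guarantee covers *isolated* bursts: two separate
            # rays in adjacent seconds legitimately form a 2-s run
            burst_bins = np.flatnonzero(series.counts > 100)
            if burst_bins.size and np.any(np.diff(burst_bins) <= 1):
                continue
            norm = normalize_to_peak(series, proto.evoked_window)
            win = detect_response(norm, proto.stimulant_time_s,
                                  warn_high_baseline=False,
                                  reject_degenerate=True)
            if win is not None:
                n_detected += 1
        assert n_bursts > 10  # the artifact generator actually fired
        assert n_detected == 0

    def test_rate_nonnegative_everywhere(self):
        cfg = small_config()
        proto = SHORT_PROTOCOLS[1]
        rate_fn, bound_fn, _, _ = _roi_rate_fns(cfg, proto, "EB",
                                                "dopamine", 1.3)
        t = np.linspace(0, proto.analysis_end_s, 5000)
        r = rate_fn(t)
        assert np.all(r >= 0)
        a = t[:-1]
        b = t[1:]
        assert np.all(bound_fn(a, b) >= np.maximum(r[:-1], r[1:]) - 1e-9)


class TestCohort:
    def test_cohort_shapes_and_arm_structure(self):
        cfg = small_config(n_flies_per_arm=3)
        cohort = simulate_cohort(cfg, protocols=SHORT_PROTOCOLS, seed=5)
        assert len(cohort.streams) == 6
        assert sorted(set(cohort.conditions.values())) == ["dopamine", "none"]
        assert len(cohort.truth.records) == 6 * 5  # per fly x ROI
        assert not cohort.protocols["none"].has_dopamine
        assert cohort.protocols["dopamine"].has_dopamine

    def test_cohort_deterministic_under_seed(self):
        cfg = small_config(n_flies_per_arm=2)
        c1 = simulate_cohort(cfg, protocols=SHORT_PROTOCOLS, seed=5)
        c2 = simulate_cohort(cfg, protocols=SHORT_PROTOCOLS, seed=5)
        for fid in c1.streams:
            np.testing.assert_array_equal(c1.streams[fid].t,
                                          c2.streams[fid].t)
        assert c1.truth.records.equals(c2.truth.records)

    def test_swapped_protocols_rejected(self):
        cfg = small_config()
        with pytest.raises(ValueError, match="without-dopamine"):
            simulate_cohort(cfg, protocols=SHORT_PROTOCOLS[::-1], seed=1)

    def test_null_amplitudes_rarely_detected(self):
        """With no evoked response anywhere, the pipeline's detector
        (degenerate-baseline guard on) reports responses in < 5% of
        fly x ROI series."""
        cfg = small_config(
            amplitude={"none": {}, "dopamine": {}}, n_flies_per_arm=5,
        )
        cohort = simulate_cohort(cfg, protocols=SHORT_PROTOCOLS, seed=11)
        n_series = 0
        n_detected = 0
        for fid, stream in cohort.streams.items():
            proto = cohort.protocols[cohort.conditions[fid]]
            for roi in cohort.roi_set:
                series = bin_roi_counts(stream, roi)
                n_series += 1
                try:
                    norm = normalize_to_peak(series, proto.evoked_window)
                except ValueError:
                    continue
                win = detect_response(norm, proto.stimulant_time_s,
                                      warn_high_baseline=False,
                                      reject_degenerate=True)
                n_detected += win is not None
        assert n_detected / n_series < 0.05


class TestPresets:
    def test_presets_encode_expected_directions(self):
        r2 = scenario_preset("R2")
        assert r2.amplitude["dopamine"]["EB"] > r2.amplitude["none"]["EB"]
        assert r2.latency_shift_s["dopamine"]["EB"] < 0
        r5 = scenario_preset("R5")
        assert r5.amplitude["dopamine"]["EB"] < r5.amplitude["none"]["EB"]
        assert r5.latency_shift_s["dopamine"]["EB"] > 0
        epg = scenario_preset("EPG")
        assert epg.amplitude["dopamine"]["EB"] > epg.amplitude["none"]["EB"]
        assert (epg.amplitude["dopamine"]["GA_L"]
                == epg.amplitude["none"]["GA_L"])
        rnai = scenario_preset("EPG_Dop1R1_RNAi")
        assert rnai.amplitude["dopamine"] == rnai.amplitude["none"]
        inverted = scenario_preset("EPG_Dop1R2_RNAi")
        assert (inverted.amplitude["dopamine"]["EB"]
                < inverted.amplitude["none"]["EB"])

    def test_scale_rates_preserves_ratios(self):
        cfg = scenario_preset("R2")
        scaled = scale_rates(cfg, 0.1)
        assert scaled.amplitude["none"]["EB"] == pytest.approx(
            0.1 * cfg.amplitude["none"]["EB"]
        )
        ratio = (scaled.amplitude["dopamine"]["EB"]
                 / scaled.amplitude["none"]["EB"])
        assert ratio == pytest.approx(
            cfg.amplitude["dopamine"]["EB"] / cfg.amplitude["none"]["EB"]
        )

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            scenario_preset("R99")

    def test_default_protocol_timing(self):
        p = default_protocol(True)
        assert p.dopamine_time_s == 600.0
        assert p.stimulant_time_s == 1200.0
        assert p.kcl_time_s == 1800.0
        q = default_protocol(False)
        assert q.stimulant_time_s == 600.0
        assert q.kcl_time_s == 1200.0
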