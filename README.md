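# lumicount

Analysis of **photon-counting bioluminescence Ca²⁺ imaging** in the
*Drosophila* central complex: GFP-aequorin recordings in which the raw
data are not images but a stream of individual detected photons, each
tagged with a sensor pixel coordinate and a time stamp (x, y, t), acquired
at 120 frames s⁻¹. The package takes such event streams through the full
analysis chain used to quantify dopaminergic modulation of ellipsoid-body
(EB) ring-neuron and E-PG-neuron responses to bath-applied stimulants
(nicotine, picrotoxin), and ships a ground-truth synthetic-experiment
generator so every stage is testable without any recordings.

## Who it is for

Researchers doing aequorin-style photon-counting imaging (no ΔF/F exists —
the signal *is* the photon rate), or anyone who wants a worked, tested
reference for the threshold/sustain evoked-response detector and the
BIC-based mixed-model selection it feeds.

## What it computes

1. **ROI time series** — photons falling inside named polygonal regions
   (cb_L/R, BU_L/R, EB for ring-neuron lines; GA_L/R, EB for E-PG) are
   integrated into 1-s bins (1 Hz, no pixel binning).
2. **Evoked-response detection** — each series is normalized to its
   maximum within the stimulant-to-KCl window (the response peak); onset
   is a rise to ≥ 10 % of that peak sustained ≥ 2 s (which rejects
   single-frame cosmic-ray bursts), offset is the fall back below 10 %.
   Features per fly × ROI: latency, duration, total photons, peak rate.
   Peak-aligned average profiles use a ±100 s window.
3. **Mixed-model selection** — six linear mixed-effects specifications
   over ROI (D₁), dopamine condition (D₂) and time (X₁), each with a
   random per-fly intercept λᵢ:

   | id | fixed effects        | df (5×2 + time) |
   |----|----------------------|-----------------|
   | 1  | D₁ × D₂              | 12              |
   | 2  | D₁ × D₂ + X₁         | 13              |
   | 3  | D₁                   | 7               |
   | 4  | D₁ + D₂              | 8               |
   | 5  | D₁ × D₂ × X₁         | 22              |
   | 6  | D₂                   | 4               |

   fitted by maximum likelihood and ranked by
   BIC = −2·logLik + df·ln(n); relative support is summarized by the
   Bayes-factor approximation **BF = e^(ΔBIC/2)**. Post hoc
   condition-within-ROI contrasts are Bonferroni-adjusted; coefficient
   uncertainty comes from a parametric bootstrap (97.5 % central
   percentile intervals, 10 000 simulations by default).
4. **Synthetic experiments** — inhomogeneous-Poisson photon streams with
   per-ROI baselines, a double-exponential evoked response with
   condition-dependent amplitude/latency, log-normal per-fly response
   multipliers, single-frame cosmic-ray artifacts and a terminal KCl
   surge; presets encode the qualitative study findings (R2: dopamine
   enhances, R5: dopamine suppresses, E-PG: EB-only enhancement, RNAi
   variants neutralize or invert it).

## Worked example

A small simulated R2 cohort (5 flies per arm, photon rates scaled to 10 %
and shortened epochs so it runs in seconds):

```python
from lumicount import PipelineConfig, run_pipeline

cfg = PipelineConfig(scenario="R2", n_flies_per_arm=5, seed=42,
                     rate_scale=0.1, protocol_baseline_s=120,
                     protocol_response_s=180, model_window_s=180)
rep = run_pipeline(cfg)
print(rep.model_table.to_string(index=False))
print(rep.contrasts.to_string(index=False))
```

prints

```
 id                    formula  df        loglik          bic
  5 y ~ roi * condition * time  22 -42375.260963 84950.831482
  2 y ~ roi * condition + time  13 -44310.666320 88739.697377
  1        y ~ roi * condition  12 -45852.124041 91813.507841
  3                    y ~ roi   7 -45907.133324 91878.001508
  4        y ~ roi + condition   8 -45905.226306 91883.292450
  6              y ~ condition   4 -47343.242173 94722.904266

                 label  roi  estimate      se        p_raw   p_adjusted
  dopamine - none | EB   EB 23.556667 3.54107 2.883238e-11 1.441619e-10
dopamine - none | BU_L BU_L  0.243333 3.54107 9.452145e-01 1.000000e+00
dopamine - none | BU_R BU_R -0.094444 3.54107 9.787220e-01 1.000000e+00
dopamine - none | cb_L cb_L  6.890000 3.54107 5.168605e-02 2.584303e-01
dopamine - none | cb_R cb_R  6.825556 3.54107 5.391234e-02 2.695617e-01
```

Reading it: the BIC ranking prefers the time-bearing interaction model
here because the synthetic response has a strong within-window time
course; the post hoc table shows the dopamine enhancement is concentrated
in the EB (+23.6 photons s⁻¹ on the window-average rate, Bonferroni-
adjusted p ≈ 1.4 × 10⁻¹⁰) and absent in the bulb, matching the generative
preset. The per-fly feature table (`rep.features`) shows the shortened
latency in the dopamine arm (≈ 5 s vs ≈ 10 s in the EB).

The same run is available stage by stage from the shell:

```sh
lumicount simulate --scenario R2 --n 5 --seed 42 --rate-scale 0.1 \
    --baseline-s 120 --response-s 180 --out cohort/
lumicount extract --data cohort/ --out bins.csv
lumicount detect  --bins bins.csv --data cohort/ --out features.csv
lumicount fit     --bins bins.csv --features features.csv --data cohort/ \
    --out report.json
```

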