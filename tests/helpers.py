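"""Shared independent oracles and model-level data generators for tests."""

import numpy as np
import pandas as pd

from lumicount import build_model_data

ROIS_5 = ["EB", "BU_L", "BU_R", "cb_L", "cb_R"]


def brute_force_detect(values, t_start, w, search_start, search_end,
                       threshold, sustain_s, peak_time):
    """Exhaustive bin-scan detection oracle.

    Enumerates every bin as a candidate onset, tests the threshold and
    sustain conditions directly, prefers the run containing the peak,
    and clamps a run reaching the search end (truncation).  Kept
    independent of the implementation it checks.
    """
    n = len(values)
    i0 = int(np.ceil((search_start - t_start) / w - 1e-9))
    i1 = min(n, int(np.ceil((search_end - t_start) / w - 1e-9)))
    need = max(1, int(np.ceil(sustain_s / w - 1e-9)))
    runs = []
    i = i0
    while i < i1:
        if values[i] >= threshold:
            j = i
            while j < i1 and values[j] >= threshold:
                j += 1
            if j - i >= need:
                runs.append((i, j))
            i = j
        else:
            i += 1
    if not runs:
        return None
    peak_idx = int(round((peak_time - t_start) / w))
    chosen = runs[0]
    for a, b in runs:
        if a <= peak_idx < b:
            chosen = (a, b)
            break
    a, b = chosen
    onset = t_start + a * w
    if b >= i1:
        return (onset, search_end, True)
    return (onset, t_start + b * w, False)


def simulate_cell_means(
    seed, n_flies_per_arm=8, n_rep=12, eb_effect=100.0, other_effect=0.0,
    fly_sd=20.0, resid_sd=30.0, rois=ROIS_5,
):
    """Data drawn from the ROI x condition cell-means model itself:
    per-cell fixed means, a Normal random fly intercept, iid Normal
    noise, plus an inert time covariate (no true time trend)."""
    rng = np.random.default_rng(seed)
    base = {r: 100.0 + 30.0 * i for i, r in enumerate(rois)}
    rows = []
    fly = 0
    for cond in ("none", "dopamine"):
        for _ in range(n_flies_per_arm):
            u = rng.normal(0, fly_sd)
            for roi in rois:
                mu = base[roi]
                if cond == "dopamine":
                    mu += eb_effect if roi == "EB" else other_effect
                y = mu + u + rng.normal(0, resid_sd, n_rep)
                for k in range(n_rep):
                    rows.append((f"fly{fly:03d}", roi, cond, float(k), y[k]))
            fly += 1
    df = pd.DataFrame(rows, columns=["fly_id", "roi", "condition", "time",
                                     "rate"])
    return build_model_data(df)
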