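"""Linear mixed-effects model suite, BIC ranking and Bayes factors.

The evoked responses are modelled with six nested-or-crossed LME
specifications over three predictors -- ROI (factor, 5 or 3 levels),
condition (factor, with/without dopamine) and time within the response
window (continuous) -- each with a random per-fly intercept:

    1. y ~ roi * condition
    2. y ~ roi * condition + time
    3. y ~ roi
    4. y ~ roi + condition
    5. y ~ roi * condition * time
    6. y ~ condition

Models are estimated by maximum likelihood (not REML: the fixed-effect
structures differ, so only ML likelihoods are comparable) and ranked by
BIC = -2 logLik + df ln(n), df counting every estimated parameter: the
fixed-effect coefficients plus the random-intercept variance and the
residual variance.  Relative support for the best model over another is
summarized by the Bayes-factor approximation BF = exp(dBIC / 2).

Post hoc condition contrasts within each ROI are Wald tests on the
fixed effects of the interaction model, Bonferroni-adjusted over the
family of ROI levels; coefficient uncertainty is quantified by a
parametric bootstrap (simulate from the fitted model, refit, take
central percentile intervals).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "FitResult",
    "ModelComparison",
    "ContrastResult",
    "BootstrapCI",
    "build_model_data",
    "model_suite",
    "count_parameters",
    "fit_lme",
    "bayes_factor",
    "log_bayes_factor",
    "rank_models",
    "pairwise_contrasts",
    "bootstrap_ci",
]

#: Variance components always estimated: random-intercept var + residual var.
N_VARIANCE_COMPONENTS = 2


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One fixed-effect specification (all carry a random fly intercept)."""

    id: int
    fixed: str  # patsy right-hand side over {roi, condition, time}
    description: str

    @property
    def formula(self) -> str:
        return f"y ~ {self.fixed}"

    @property
    def has_condition(self) -> bool:
        return "condition" in self.fixed

    @property
    def has_interaction(self) -> bool:
        return "roi * condition" in self.fixed

    @property
    def has_time(self) -> bool:
        return "time" in self.fixed


@dataclasses.dataclass
class FitResult:
    """A maximum-likelihood LME fit and everything ranking/inference needs."""

    spec: ModelSpec
    loglik: float
    n_obs: int
    df: int
    bic: float
    fe_params: pd.Series
    cov_fe: pd.DataFrame
    var_fly: float
    var_resid: float
    blups: pd.Series
    converged: bool
    _design_info: object = dataclasses.field(repr=False, default=None)
    _exog: np.ndarray = dataclasses.field(repr=False, default=None)
    _groups: np.ndarray = dataclasses.field(repr=False, default=None)
    _data: pd.DataFrame = dataclasses.field(repr=False, default=None)

    @property
    def n_flies(self) -> int:
        return int(self.blups.size)


@dataclasses.dataclass
class ModelComparison:
    """BIC ranking of a model suite fitted to the same data."""

    ranking: list[FitResult]
    delta_bic: float
    bf: float

    @property
    def best(self) -> FitResult:
        return self.ranking[0]

    def pairwise_delta(self, id_a: int, id_b: int) -> float:
        by_id = {f.spec.id: f for f in self.ranking}
        return by_id[id_b].bic - by_id[id_a].bic

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [f.spec.id for f in self.ranking],
                "formula": [f.spec.formula for f in self.ranking],
                "df": [f.df for f in self.ranking],
                "loglik": [f.loglik for f in self.ranking],
                "bic": [f.bic for f in self.ranking],
            }
        )


@dataclasses.dataclass(frozen=True)
class ContrastResult:
    """One condition-within-ROI contrast (dopamine minus control)."""

    label: str
    roi: str
    estimate: float
    se: float
    p_raw: float
    p_adjusted: float


@dataclasses.dataclass
class BootstrapCI:
    """Central percentile intervals from a parametric bootstrap."""

    level: float
    n_sim: int
    estimates: pd.Series
    lower: pd.Series
    upper: pd.Series
    n_failed: int = 0

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.estimates, "lower": self.lower,
             "upper": self.upper}
        )


def build_model_data(
    df: pd.DataFrame,
    response: str = "rate",
    reference_roi: str = "EB",
    reference_condition: str = "none",
) -> pd.DataFrame:
    """Validate and canonicalize a long response table for LME fitting.

    Expects one row per observation with columns ``fly_id``, ``roi``,
    ``condition``, ``time`` (seconds within the response window) and the
    response column.  Factors are made categorical with the stated
    reference level first so treatment coding is anchored on the
    ellipsoid body and the no-dopamine condition.
    """
    required = {"fly_id", "roi", "condition", "time", response}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"model data missing columns {sorted(missing)}")
    out = df.copy()
    out["y"] = out[response].astype(float)
    rois = list(pd.unique(out["roi"]))
    if reference_roi in rois:
        rois = [reference_roi] + sorted(r for r in rois if r != reference_roi)
    out["roi"] = pd.Categorical(out["roi"], categories=rois)
    conds = list(pd.unique(out["condition"]))
    if len(conds) > 2:
        raise ValueError(f"condition must have <= 2 levels, got {conds}")
    if reference_condition in conds:
        conds = [reference_condition] + [
            c for c in conds if c != reference_condition
        ]
    out["condition"] = pd.Categorical(out["condition"], categories=conds)
    if out["fly_id"].nunique() < 1:
        raise ValueError("no flies in model data")
    return out


def model_suite(
    scenario_levels: int = 5, has_time: bool = True
) -> list[ModelSpec]:
    """The six candidate specifications, in canonical order.

    ``scenario_levels`` is informational (the ROI factor's level count is
    read from the data at fit time); ``has_time=False`` drops the two
    time-bearing models, for response modes without a within-window time
    axis (e.g. per-fly latency summaries).
    """
    if scenario_levels < 2:
        raise ValueError("need at least 2 ROI levels")
    suite = [
        ModelSpec(1, "roi * condition", "ROI x condition interaction"),
        ModelSpec(2, "roi * condition + time",
                  "ROI x condition interaction plus time"),
        ModelSpec(3, "roi", "ROI only"),
        ModelSpec(4, "roi + condition", "additive ROI and condition"),
        ModelSpec(5, "roi * condition * time",
                  "three-way ROI x condition x time interaction"),
        ModelSpec(6, "condition", "condition only"),
    ]
    if not has_time:
        suite = [s for s in suite if not s.has_time]
    return suite


def _dummy_frame(n_d1_levels: int, n_d2_levels: int) -> pd.DataFrame:
    rois = [f"roi{i}" for i in range(n_d1_levels)]
    conds = [f"cond{i}" for i in range(n_d2_levels)]
    grid = pd.MultiIndex.from_product([rois, conds], names=["roi", "condition"])
    df = grid.to_frame(index=False)
    df["roi"] = pd.Categorical(df["roi"], categories=rois)
    df["condition"] = pd.Categorical(df["condition"], categories=conds)
    df["time"] = np.linspace(0.0, 1.0, len(df))
    return df


def count_parameters(
    spec: ModelSpec, n_d1_levels: int, n_d2_levels: int = 2
) -> int:
    """Total estimated parameters of one specification.

    The fixed-effect column count is obtained by materializing the design
    matrix on a full factor grid (treatment coding, intercept included);
    the two variance components (random-intercept and residual variance)
    are added on top.  Reproduces e.g. 12 for the 5x2 interaction model
    and 22 for the three-way interaction with time.
    """
    if n_d1_levels < 2 or n_d2_levels < 2:
        raise ValueError("factors need >= 2 levels")
    df = _dummy_frame(n_d1_levels, n_d2_levels)
    try:
        mat = patsy.dmatrix(spec.fixed, df)
    except patsy.PatsyError as exc:  # pragma: no cover
        raise ValueError(f"unknown term in {spec.fixed!r}: {exc}") from exc
    return mat.shape[1] + N_VARIANCE_COMPONENTS


def fit_lme(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit one specification by maximum likelihood.

    ``data`` must come from :func:`build_model_data`.  Raises on fewer
    than two flies (the random intercept is unidentifiable) or a
    rank-deficient fixed-effect design (naming the aliased columns).
    """
    if len(data) == 0:
        raise ValueError("empty model data")
    n_flies = data["fly_id"].nunique()
    if n_flies < 2:
        raise ValueError(
            "random fly intercept needs >= 2 flies, got "
            f"{n_flies}"
        )
    y, X = patsy.dmatrices(spec.formula, data, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name columns involved in the aliasing via QR pivoting
        _, r = np.linalg.qr(X.to_numpy())
        diag = np.abs(np.diag(r))
        aliased = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]}); "
            f"aliased terms: {aliased or 'undetermined'}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(spec.formula, data, groups=data["fly_id"])
        result = model.fit(reml=False)
    k_fe = len(result.fe_params)
    df = k_fe + N_VARIANCE_COMPONENTS
    n_obs = int(result.nobs)
    loglik = float(result.llf)
    bic = -2.0 * loglik + df * math.log(n_obs)
    blups = pd.Series(
        {g: float(np.asarray(v)[0]) for g, v in result.random_effects.items()},
        name="blup",
    )
    return FitResult(
        spec=spec,
        loglik=loglik,
        n_obs=n_obs,
        df=df,
        bic=float(bic),
        fe_params=result.fe_params.copy(),
        cov_fe=pd.DataFrame(
            np.asarray(result.cov_params())[:k_fe, :k_fe],
            index=result.fe_params.index,
            columns=result.fe_params.index,
        ),
        var_fly=float(np.asarray(result.cov_re)[0, 0]),
        var_resid=float(result.scale),
        blups=blups,
        converged=bool(result.converged),
        _design_info=X.design_info,
        _exog=X.to_numpy(),
        _groups=data["fly_id"].to_numpy(),
        _data=data,
    )


def log_bayes_factor(bic_best: float, bic_other: float) -> float:
    """Natural-log Bayes factor, (bic_other - bic_best) / 2."""
    return (bic_other - bic_best) / 2.0

def bayes_factor(bic_best: float, bic_other: float) -> float:
    """Bayes-factor approximation exp(dBIC / 2) for model support.

    dBIC is the BIC of the other model minus the best model's, so values
    above 1 favour the best model.  Overflow returns ``inf``; use
    :func:`log_bayes_factor` for the log-scale value in that regime.
    """
    try:
        return math.exp(log_bayes_factor(bic_best, bic_other))
    except OverflowError:
        return math.inf


def rank_models(fits: Sequence[FitResult]) -> ModelComparison:
    """Rank fits by ascending BIC (ties broken by smaller df)."""
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to compare")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError(f"fits are on different data (n_obs = {sorted(n_obs)})")
    ranking = sorted(fits, key=lambda f: (f.bic, f.df))
    delta = ranking[1].bic - ranking[0].bic
    return ModelComparison(
        ranking=ranking,
        delta_bic=float(delta),
        bf=bayes_factor(ranking[0].bic, ranking[1].bic),
    )


def pairwise_contrasts(fit: FitResult) -> list[ContrastResult]:
    """Condition difference within each ROI level, Bonferroni-adjusted.

    Computed on the fixed effects of an interaction fit as estimated
    marginal-mean differences (second condition level minus the
    reference, i.e. dopamine minus control), holding time at its sample
    mean when present.  The Bonferroni family is the set of ROI levels,
    so adjusted p = min(m * p, 1) with m the number of ROIs.
    """
    if not fit.spec.has_condition:
        raise ValueError("model has no condition term; contrasts undefined")
    data = fit._data
    rois = list(data["roi"].cat.categories)
    conds = list(data["condition"].cat.categories)
    if len(conds) != 2:
        raise ValueError("need exactly 2 condition levels")
    t_mean = float(data["time"].mean())
    m = len(rois)
    results = []
    from scipy import stats

    for roi in rois:
        rows = pd.DataFrame(
            {
                "roi": pd.Categorical([roi, roi],
                                      categories=data["roi"].cat.categories),
                "condition": pd.Categorical(
                    [conds[1], conds[0]],
                    categories=data["condition"].cat.categories,
                ),
                "time": [t_mean, t_mean],
            }
        )
        (design,) = patsy.build_design_matrices([fit._design_info], rows)
        L = np.asarray(design)[0] - np.asarray(design)[1]
        est = float(L @ fit.fe_params.to_numpy())
        se = float(np.sqrt(L @ fit.cov_fe.to_numpy() @ L))
        z = est / se if se > 0 else np.inf * np.sign(est)
        p = float(2.0 * stats.norm.sf(abs(z)))
        results.append(
            ContrastResult(
                label=f"{conds[1]} - {conds[0]} | {roi}",
                roi=str(roi),
                estimate=est,
                se=se,
                p_raw=p,
                p_adjusted=min(m * p, 1.0),
            )
        )
    return results


def bootstrap_ci(
    fit: FitResult,
    n_sim: int = 10_000,
    level: float = 0.975,
    seed: int | None = None,
) -> BootstrapCI:
    """Parametric-bootstrap percentile intervals for the fixed effects.

    Each replicate simulates a response vector from the fitted model --
    fixed effects plus per-fly intercepts drawn Normal(0, var_fly) and
    residuals Normal(0, var_resid) -- refits the same specification, and
    records the coefficients.  The interval keeps the central ``level``
    mass (so a 0.975 level leaves 1.25% in each tail).  Replicates whose
    refit fails to converge are dropped and counted in ``n_failed``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    X = fit._exog
    groups = fit._groups
    beta = fit.fe_params.to_numpy()
    flies = pd.unique(groups)
    fly_index = pd.Series(np.arange(len(flies)), index=flies)
    g_idx = fly_index[groups].to_numpy()
    mu = X @ beta
    sd_fly = math.sqrt(max(fit.var_fly, 0.0))
    sd_res = math.sqrt(max(fit.var_resid, 0.0))
    draws = np.empty((n_sim, len(beta)))
    n_failed = 0
    kept = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_sim):
            u = rng.normal(0.0, sd_fly, size=len(flies))
            y_sim = mu + u[g_idx] + rng.normal(0.0, sd_res, size=len(mu))
            try:
                res = sm.MixedLM(y_sim, X, groups=groups).fit(reml=False)
                draws[kept] = res.fe_params
                kept += 1
            except (np.linalg.LinAlgError, ValueError):
                n_failed += 1
    if kept == 0:
        raise RuntimeError("every bootstrap refit failed")
    draws = draws[:kept]
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(draws, alpha, axis=0)
    upper = np.quantile(draws, 1.0 - alpha, axis=0)
    idx = fit.fe_params.index
    return BootstrapCI(
        level=level,
        n_sim=n_sim,
        estimates=fit.fe_params.copy(),
        lower=pd.Series(lower, index=idx),
        upper=pd.Series(upper, index=idx),
        n_failed=n_failed,
    )
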