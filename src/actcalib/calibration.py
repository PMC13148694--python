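"""Square-root-scale calibration model and its diagnostics.

The core model regresses sqrt(MET) on sqrt(counts/min) with a full
device*placement interaction:

    sqrt(MET) = b0 + b1*sqrt(A) + sum_s [ d_s*(g0_s + g1_s*sqrt(A)) ]

where d_s are dummies for the three non-reference strata (GT3X+ hip is the
reference level).  Collapsing the dummies gives each stratum its own
working equation sqrt(MET) = b0' + b1'*sqrt(A), whose coefficient
covariance follows by the corresponding linear combination of the full
8x8 covariance.  The square-root transform linearises the concave
count-energy relationship seen on treadmill protocols.

Also provided: Pearson speed correlations, the one-way ANOVA of
sqrt(counts) over condition*stratum cells with eta-squared and Tukey HSD,
Bland-Altman agreement between predicted and measured METs, and residual
normality/heteroscedasticity diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .simulate import STRATA

__all__ = [
    "CalibrationFit",
    "StratumEquation",
    "AnovaResult",
    "BlandAltman",
    "fit_calibration",
    "stratum_equation",
    "stratum_equations",
    "predict_met",
    "pearson_speed_correlations",
    "anova_counts",
    "bland_altman",
    "residual_diagnostics",
    "z_multiplier",
]

REFERENCE_STRATUM = STRATA[0]  # GT3X_hip


def z_multiplier(level: float = 0.95, df: int | None = None, use_t: bool = False) -> float:
    """Two-sided interval multiplier: normal by default, Student t optionally."""
    q = (1 + level) / 2
    if use_t:
        if df is None:
            raise ValueError("df required for t intervals")
        return float(stats.t.ppf(q, df))
    return float(stats.norm.ppf(q))


@dataclass
class CalibrationFit:
    """Fitted calibration model: coefficients, covariance and residuals."""

    beta: pd.Series  # indexed by design-column name
    cov: pd.DataFrame  # coefficient covariance, sigma2 * (X'X)^-1
    n_obs: int
    r_squared: float
    residuals: np.ndarray  # sqrt-MET scale
    fitted: np.ndarray  # sqrt-MET scale
    sigma2: float
    strata: tuple[str, ...]  # strata present, reference first
    design: pd.DataFrame = field(repr=False)  # model matrix (for diagnostics)
    df_resid: int = 0


@dataclass
class StratumEquation:
    """Per-stratum working equation sqrt(MET) = b0 + b1*sqrt(counts/min)."""

    device: str
    placement: str
    b0: float
    b1: float
    cov2: np.ndarray | None = None  # 2x2 covariance of (b0, b1)
    b0_ci: tuple[float, float] | None = None
    b1_ci: tuple[float, float] | None = None

    @property
    def stratum(self) -> str:
        return f"{self.device}_{self.placement}"


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta_squared: float
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj


@dataclass
class BlandAltman:
    stratum: str
    bias: float  # mean(predicted - measured), METs
    loa_low: float
    loa_high: float
    proportional_slope: float  # slope of difference vs mean
    proportional_p: float
    n: int


# --------------------------------------------------------------------------
# Model fit
# --------------------------------------------------------------------------

def _design_matrix(obs: pd.DataFrame, strata: Sequence[str]) -> pd.DataFrame:
    sqrt_a = np.sqrt(obs["activity_cpm"].to_numpy(dtype=float))
    cols = {"const": np.ones(len(obs)), "sqrt_activity": sqrt_a}
    for s in strata[1:]:
        d = (obs["stratum"] == s).to_numpy(dtype=float)
        cols[f"d_{s}"] = d
    for s in strata[1:]:
        cols[f"d_{s}:sqrt_activity"] = cols[f"d_{s}"] * sqrt_a
    return pd.DataFrame(cols, index=obs.index)


def fit_calibration(obs: pd.DataFrame, reference: str = REFERENCE_STRATUM) -> CalibrationFit:
    """OLS of sqrt(MET) on sqrt(activity) with stratum dummies/interactions.

    Column order follows the canonical parameterisation: intercept, common
    slope, then one intercept offset and one slope offset per non-reference
    stratum in reporting order.  Strata absent from the data simply get no
    columns (reduced design).  Rank-deficient designs raise, naming the
    collinear columns.
    """
    if len(obs) < 10:
        raise ValueError("need at least 10 observations to fit the calibration model")
    if (obs["activity_cpm"] < 0).any():
        raise ValueError("activity_cpm must be non-negative")
    if (obs["met"] <= 0).any():
        raise ValueError("met must be positive")
    present = [s for s in STRATA if s in set(obs["stratum"])]
    if reference not in present:
        # fall back to the first present stratum as reference
        reference = present[0]
    strata = tuple([reference] + [s for s in present if s != reference])

    X = _design_matrix(obs, strata)
    y = np.sqrt(obs["met"].to_numpy(dtype=float))

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    res = sm.OLS(y, X).fit()
    return CalibrationFit(
        beta=res.params,
        cov=res.cov_params(),
        n_obs=len(obs),
        r_squared=float(res.rsquared),
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        sigma2=float(res.mse_resid),
        strata=strata,
        design=X,
        df_resid=int(res.df_resid),
    )


def _combination_vectors(fit: CalibrationFit, stratum: str) -> tuple[np.ndarray, np.ndarray]:
    names = list(fit.beta.index)
    a0 = np.zeros(len(names))
    a1 = np.zeros(len(names))
    a0[names.index("const")] = 1.0
    a1[names.index("sqrt_activity")] = 1.0
    if stratum != fit.strata[0]:
        a0[names.index(f"d_{stratum}")] = 1.0
        a1[names.index(f"d_{stratum}:sqrt_activity")] = 1.0
    return a0, a1


def stratum_equation(
    fit: CalibrationFit,
    device: str,
    placement: str,
    level: float = 0.95,
    use_t: bool = False,
) -> StratumEquation:
    """Collapse the dummy parameterisation into one stratum's equation.

    b0' = b0 (+ intercept offset), b1' = b1 (+ slope offset); the 2x2
    covariance of (b0', b1') is A Sigma A' with A the two combination
    vectors, and CIs are estimate +/- z * SE.
    """
    stratum = f"{device}_{placement}"
    if stratum not in fit.strata:
        raise ValueError(f"stratum {stratum!r} not present in fit (has {fit.strata})")
    a0, a1 = _combination_vectors(fit, stratum)
    A = np.vstack([a0, a1])
    beta = fit.beta.to_numpy()
    cov = fit.cov.to_numpy()
    est = A @ beta
    cov2 = A @ cov @ A.T
    z = z_multiplier(level, df=fit.df_resid, use_t=use_t)
    se = np.sqrt(np.diag(cov2))
    return StratumEquation(
        device,
        placement,
        b0=float(est[0]),
        b1=float(est[1]),
        cov2=cov2,
        b0_ci=(float(est[0] - z * se[0]), float(est[0] + z * se[0])),
        b1_ci=(float(est[1] - z * se[1]), float(est[1] + z * se[1])),
    )


def stratum_equations(fit: CalibrationFit, **kwargs) -> dict[str, StratumEquation]:
    """Working equations for every stratum present in the fit."""
    out = {}
    for s in fit.strata:
        device, placement = s.split("_")
        out[s] = stratum_equation(fit, device, placement, **kwargs)
    return out


def predict_met(eq: StratumEquation, activity_cpm):
    """Predicted MET at a given counts/min: (b0 + b1*sqrt(A))^2."""
    a = np.asarray(activity_cpm, dtype=float)
    if np.any(a < 0):
        raise ValueError("activity must be non-negative")
    lp = eq.b0 + eq.b1 * np.sqrt(a)
    if np.any(lp < 0):
        raise ValueError("negative linear predictor: activity out of model domain")
    out = lp**2
    return float(out) if np.isscalar(activity_cpm) else out


# --------------------------------------------------------------------------
# Descriptive and diagnostic analyses
# --------------------------------------------------------------------------

def pearson_speed_correlations(obs: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between treadmill speed and METs / per-stratum counts.

    The MET correlation deduplicates the participant*condition clusters
    (the same calorimetry value is repeated across the four strata).
    Zero-variance targets are reported with NaN r (undefined correlation).
    """
    rows = []

    def _corr(x, y, target):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            rows.append({"target": target, "r": np.nan, "p": np.nan, "n": len(x)})
            return
        r, p = stats.pearsonr(x, y)
        rows.append({"target": target, "r": float(r), "p": float(p), "n": len(x)})

    met_rows = obs.drop_duplicates(subset=["participant", "condition"])
    _corr(met_rows["speed"], met_rows["met"], "met")
    for s in STRATA:
        sub = obs[obs["stratum"] == s]
        if len(sub):
            _corr(sub["speed"], np.sqrt(sub["activity_cpm"]), f"sqrt_counts:{s}")
    return pd.DataFrame(rows)


def anova_counts(obs: pd.DataFrame, alpha: float = 0.05, tukey: bool = True) -> AnovaResult:
    """One-way ANOVA of sqrt(counts) over condition*stratum cells.

    The full design has 20 cells (5 conditions x 4 strata), hence 19
    between-group degrees of freedom.  eta^2 = SS_between / SS_total.
    Tukey HSD adjusted pairwise comparisons cover all cell pairs (skipped
    when ``tukey`` is False, e.g. in repeated null simulations).  Cells
    with fewer than 2 observations are excluded with a warning.
    """
    work = obs.copy()
    work["cell"] = work["condition"].astype(str) + "|" + work["stratum"].astype(str)
    work["sqrt_activity"] = np.sqrt(work["activity_cpm"].astype(float))
    sizes = work.groupby("cell").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding cells with <2 observations: {small}")
        work = work[~work["cell"].isin(small)]
    groups = [g["sqrt_activity"].to_numpy() for _, g in work.groupby("cell")]
    if len(groups) < 2:
        raise ValueError("need at least 2 cells with >=2 observations")

    F, p = stats.f_oneway(*groups)
    y = work["sqrt_activity"].to_numpy()
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    eta2 = ss_between / ss_total if ss_total > 0 else np.nan

    if tukey:
        tk = pairwise_tukeyhsd(work["sqrt_activity"], work["cell"], alpha=alpha)
        tukey_df = pd.DataFrame(
            tk.summary().data[1:], columns=[c.lower() for c in tk.summary().data[0]]
        )[["group1", "group2", "meandiff", "p-adj"]].rename(columns={"p-adj": "p_adj"})
    else:
        tukey_df = pd.DataFrame(columns=["group1", "group2", "meandiff", "p_adj"])
    return AnovaResult(
        F=float(F),
        df_between=len(groups) - 1,
        df_within=len(y) - len(groups),
        p=float(p),
        eta_squared=eta2,
        tukey=tukey_df,
    )


def bland_altman(
    equations: Mapping[str, StratumEquation], obs: pd.DataFrame
) -> list[BlandAltman]:
    """Agreement between model-predicted and measured METs per stratum.

    Bias is mean(predicted - measured); limits of agreement are
    bias +/- 1.96 SD of the differences; the proportional-bias check is
    the slope of difference on mean.
    """
    out = []
    for s, eq in equations.items():
        sub = obs[obs["stratum"] == s]
        if not len(sub):
            continue
        pred = predict_met(eq, sub["activity_cpm"].to_numpy())
        meas = sub["met"].to_numpy(dtype=float)
        diff = pred - meas
        mean = (pred + meas) / 2
        sd = float(diff.std(ddof=1)) if len(diff) > 1 else 0.0
        bias = float(diff.mean())
        if len(diff) > 2 and np.std(mean) > 0:
            slope, _, _, p_slope, _ = stats.linregress(mean, diff)
        else:
            slope, p_slope = np.nan, np.nan
        out.append(
            BlandAltman(
                s, bias, bias - 1.96 * sd, bias + 1.96 * sd, float(slope), float(p_slope), len(diff)
            )
        )
    return out


def residual_diagnostics(fit: CalibrationFit) -> dict:
    """Q-Q pairs, residual-vs-fitted pairs, and formal assumption tests.

    Shapiro-Wilk for normality of the sqrt-scale residuals and
    Breusch-Pagan against the model's own design for heteroscedasticity.
    """
    resid = fit.residuals
    osm, osr = stats.probplot(resid, dist="norm", fit=False)
    sub = resid if resid.size <= 4999 else np.random.default_rng(0).choice(resid, 4999, replace=False)
    sw_stat, sw_p = stats.shapiro(sub)
    bp_stat, bp_p, _, _ = het_breuschpagan(resid, fit.design.to_numpy())
    return {
        "qq_theoretical": np.asarray(osm),
        "qq_sample": np.asarray(osr),
        "fitted": fit.fitted,
        "residuals": resid,
        "shapiro_stat": float(sw_stat),
        "shapiro_p": float(sw_p),
        "breusch_pagan_stat": float(bp_stat),
        "breusch_pagan_p": float(bp_p),
        "n": int(resid.size),
    }
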