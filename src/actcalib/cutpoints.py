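"""Intensity cut-points by inverting the stratum calibration equations.

A cut-point is the counts/min value whose predicted energy expenditure
equals a MET boundary M in {3, 6, 9}:

    cutpoint(M) = ((sqrt(M) - b0) / b1)^2.

Uncertainty propagates from the 2x2 coefficient covariance by the delta
method: with g(b0, b1) the inversion above,

    dg/db0 = -2 (sqrt(M) - b0) / b1^2
    dg/db1 = -2 (sqrt(M) - b0)^2 / b1^3
    SE(g)  = sqrt(grad' Cov grad),

and the (1 - alpha) interval is g +/- z * SE, truncated below at zero
because negative counts are meaningless.  A parametric bootstrap of the
coefficient distribution is offered as a cross-check of the delta SE.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationFit, StratumEquation, stratum_equations, z_multiplier
from .simulate import STRATA

__all__ = [
    "MET_THRESHOLDS",
    "invert_cutpoint",
    "cutpoint_gradient",
    "cutpoint_ci",
    "cutpoint_se_bootstrap",
    "build_cutpoint_table",
]

#: MET boundaries separating moderate, vigorous and very vigorous activity.
MET_THRESHOLDS = (3.0, 6.0, 9.0)


def invert_cutpoint(eq: StratumEquation, met_threshold: float) -> float:
    """Counts/min at which the stratum equation predicts ``met_threshold``."""
    if met_threshold <= 0:
        raise ValueError("met_threshold must be positive")
    if eq.b1 <= 0:
        raise ValueError("slope b1 must be positive to invert")
    root = np.sqrt(met_threshold)
    if root < eq.b0:
        raise ValueError(
            f"threshold below model intercept: sqrt({met_threshold}) < b0 = {eq.b0}"
        )
    return float(((root - eq.b0) / eq.b1) ** 2)


def cutpoint_gradient(eq: StratumEquation, met_threshold: float) -> np.ndarray:
    """Gradient of the inversion w.r.t. (b0, b1)."""
    root = np.sqrt(met_threshold)
    d = root - eq.b0
    return np.array([-2 * d / eq.b1**2, -2 * d**2 / eq.b1**3])


def _check_cov2(cov2) -> np.ndarray:
    if cov2 is None:
        raise ValueError("equation has no coefficient covariance")
    cov2 = np.asarray(cov2, dtype=float)
    if cov2.shape != (2, 2) or not np.all(np.isfinite(cov2)):
        raise ValueError("cov2 must be a finite 2x2 matrix")
    if not np.allclose(cov2, cov2.T):
        raise ValueError("cov2 must be symmetric")
    if np.min(np.linalg.eigvalsh(cov2)) < -1e-10 * max(1.0, np.abs(cov2).max()):
        raise ValueError("cov2 must be positive semi-definite")
    return cov2


def cutpoint_ci(
    eq: StratumEquation, met_threshold: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Delta-method confidence interval for a cut-point.

    Returns ``(cutpoint, ci_low, ci_high)`` with the lower bound truncated
    at 0 counts/min.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    cov2 = _check_cov2(eq.cov2)
    g = invert_cutpoint(eq, met_threshold)
    grad = cutpoint_gradient(eq, met_threshold)
    se = float(np.sqrt(grad @ cov2 @ grad))
    z = z_multiplier(level)
    return g, max(0.0, g - z * se), g + z * se


def cutpoint_se_bootstrap(
    eq: StratumEquation, met_threshold: float, n_draws: int = 100_000, seed: int = 0
) -> float:
    """Parametric-bootstrap SE: empirical SD of the inversion over draws of
    (b0, b1) from their bivariate normal sampling distribution."""
    cov2 = _check_cov2(eq.cov2)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal([eq.b0, eq.b1], cov2, size=n_draws)
    root = np.sqrt(met_threshold)
    ok = (draws[:, 1] > 0) & (draws[:, 0] <= root)
    g = ((root - draws[ok, 0]) / draws[ok, 1]) ** 2
    return float(g.std(ddof=1))


def build_cutpoint_table(
    fit_or_equations, level: float = 0.95
) -> pd.DataFrame:
    """All stratum x threshold cut-points with delta-method CIs.

    Accepts a :class:`CalibrationFit` or a mapping stratum -> equation.
    Rows follow the canonical stratum order; a missing stratum yields a
    partial table with a warning.  Columns: device, placement,
    threshold_met, cutpoint, ci_low, ci_high.
    """
    if isinstance(fit_or_equations, CalibrationFit):
        equations = stratum_equations(fit_or_equations, level=level)
    else:
        equations = dict(fit_or_equations)
    missing = [s for s in STRATA if s not in equations]
    if missing:
        warnings.warn(f"strata missing from fit: {missing}; emitting partial table")
    rows = []
    for s in STRATA:
        if s not in equations:
            continue
        eq = equations[s]
        for m in MET_THRESHOLDS:
            if eq.cov2 is not None:
                cp, lo, hi = cutpoint_ci(eq, m, level=level)
            else:
                cp, lo, hi = invert_cutpoint(eq, m), np.nan, np.nan
            rows.append(
                {
                    "device": eq.device,
                    "placement": eq.placement,
                    "threshold_met": m,
                    "cutpoint": cp,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    return pd.DataFrame(rows)
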