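"""End-to-end orchestration: simulate -> preprocess -> fit -> cut-points -> evaluate.

All inter-stage artefacts are plain CSV with header rows so any ecosystem
can consume them.  A run is fully determined by its configuration (which
includes the seed): re-running with the same config reproduces
byte-identical CSVs.  The run log reconciles record counts at every stage
boundary so no data is lost silently.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import (
    DEFAULT_PROTOCOL,
    STRATA,
    TABLE_COEFFICIENTS,
    TruthParameters,
    generate_cohort,
    simulate_observation_table,
    write_cohort_dataset,
)
from .preprocess import build_observation_table, load_dataset
from .calibration import (
    anova_counts,
    bland_altman,
    fit_calibration,
    pearson_speed_correlations,
    residual_diagnostics,
    stratum_equations,
    StratumEquation,
)
from .cutpoints import MET_THRESHOLDS, build_cutpoint_table, invert_cutpoint
from .evaluation import classify_observations, stratified_reports

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "validate_table2",
    "PUBLISHED_CALIBRATION",
    "published_equations",
    "write_published_fixture",
]

#: Published calibration table: per-stratum (b0, b1) plus the printed
#: counts/min cut-points at 3/6/9 METs, used by the self-consistency check.
PUBLISHED_CALIBRATION = pd.DataFrame(
    [
        ("GT3X", "hip", 1.062, 0.0199, 1132.0, 4853.0, 9468.0),
        ("ACTT", "hip", 1.107, 0.0088, 5057.0, 23339.0, 46410.0),
        ("ACTT", "wrist", 1.233, 0.0081, 3761.0, 22368.0, 47203.0),
        ("GT3X", "wrist", 1.207, 0.0127, 1698.0, 9503.0, 19787.0),
    ],
    columns=["device", "placement", "b0", "b1", "cp3", "cp6", "cp9"],
)


def published_equations() -> dict[str, StratumEquation]:
    """Stratum equations built from the published printed coefficients."""
    return {
        f"{r.device}_{r.placement}": StratumEquation(r.device, r.placement, r.b0, r.b1)
        for r in PUBLISHED_CALIBRATION.itertuples()
    }


def write_published_fixture(path) -> Path:
    """Write the published coefficient/cut-point table in the fit-report dialect."""
    path = Path(path)
    PUBLISHED_CALIBRATION.to_csv(path, index=False)
    return path


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on; round-trips through YAML."""

    n_male: int = 34
    n_female: int = 22
    seed: int = 0
    raw_signals: bool = False  # full accel/breath simulation vs observation level
    truth_overrides: dict = field(default_factory=dict)
    sd_multiplier: float = 3.0
    time_weighted_breaths: bool = True
    ci_level: float = 0.95
    use_t_intervals: bool = False
    stratify_by: str = "stratum"  # second stratified report besides sex
    min_group_size: int = 5
    out_dir: str = "actcalib_run"
    make_plots: bool = False

    def truth(self) -> TruthParameters:
        return TruthParameters(seed=self.seed, **self.truth_overrides)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _write_fit_report(fit, equations, out: Path) -> None:
    fit.beta.rename("estimate").to_csv(out / "fit_coefficients.csv", header=True)
    fit.cov.to_csv(out / "fit_covariance.csv")
    rows = []
    for s, eq in equations.items():
        rows.append(
            {
                "device": eq.device,
                "placement": eq.placement,
                "b0": eq.b0,
                "b0_ci_low": eq.b0_ci[0],
                "b0_ci_high": eq.b0_ci[1],
                "b1": eq.b1,
                "b1_ci_low": eq.b1_ci[0],
                "b1_ci_high": eq.b1_ci[1],
            }
        )
    pd.DataFrame(rows).to_csv(out / "equations.csv", index=False)


def _write_reports(reports, out: Path, suffix: str) -> None:
    long = []
    for scope, rep in reports.items():
        rep.confusion.to_csv(out / f"confusion_{suffix}_{scope}.csv")
        m = rep.metrics.reset_index(names="class").melt(
            id_vars="class", var_name="metric", value_name="value"
        )
        m["group"] = scope
        long.append(m)
    pd.concat(long, ignore_index=True).to_csv(
        out / f"classification_metrics_{suffix}.csv", index=False
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the artefact directory.

    Stages: cohort + synthetic data (raw-signal or observation level),
    steady-state observation table, calibration fit with per-stratum
    equations, cut-point table with delta-method CIs, classification
    reports (pooled, by sex, by stratum), correlations, ANOVA,
    Bland-Altman and residual diagnostics, plus a run log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = config.truth()
    log: dict = {
        "version": __version__,
        "config_hash": config.hash(),
        "started_utc": datetime.now(timezone.utc).isoformat(),
        "stages": [],
    }

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        log["stages"].append(name)
        return result

    cohort = stage("cohort", generate_cohort, config.n_male, config.n_female, config.seed)

    if config.raw_signals:
        stage("dataset", write_cohort_dataset, cohort, truth, out / "dataset")
        breaths, epochs, _ = load_dataset(out / "dataset")
        obs, prep_log = stage(
            "preprocess",
            build_observation_table,
            breaths,
            epochs,
            DEFAULT_PROTOCOL,
            cohort,
            time_weighted=config.time_weighted_breaths,
            sd_multiplier=config.sd_multiplier,
        )
        log["preprocess"] = prep_log
    else:
        obs = stage("simulate", simulate_observation_table, cohort, truth, config.seed)
        log["preprocess"] = {"rows_out": len(obs), "rows_dropped_missing": 0}
    obs.to_csv(out / "observations.csv", index=False, float_format="%.6f")

    fit = stage("fit", fit_calibration, obs)
    equations = stratum_equations(fit, level=config.ci_level, use_t=config.use_t_intervals)
    _write_fit_report(fit, equations, out)
    log["fit"] = {"n_obs": fit.n_obs, "r_squared": fit.r_squared}

    ct = stage("cutpoints", build_cutpoint_table, fit, config.ci_level)
    ct.to_csv(out / "cutpoints.csv", index=False, float_format="%.4f")

    corr = stage("correlations", pearson_speed_correlations, obs)
    corr.to_csv(out / "correlations.csv", index=False, float_format="%.6f")
    an = stage("anova", anova_counts, obs)
    pd.DataFrame(
        [
            {
                "F": an.F,
                "df_between": an.df_between,
                "df_within": an.df_within,
                "p": an.p,
                "eta_squared": an.eta_squared,
            }
        ]
    ).to_csv(out / "anova.csv", index=False, float_format="%.6f")
    an.tukey.to_csv(out / "tukey_hsd.csv", index=False)
    ba = stage("bland_altman", bland_altman, equations, obs)
    pd.DataFrame([dataclasses.asdict(b) for b in ba]).to_csv(
        out / "bland_altman.csv", index=False, float_format="%.6f"
    )

    diag = stage("diagnostics", residual_diagnostics, fit)
    pd.DataFrame(
        {
            "fitted": diag["fitted"],
            "residual": diag["residuals"],
            "qq_theoretical": diag["qq_theoretical"],
            "qq_sample": diag["qq_sample"],
        }
    ).to_csv(out / "residual_diagnostics.csv", index=False, float_format="%.6f")
    log["diagnostics"] = {
        "shapiro_p": diag["shapiro_p"],
        "breusch_pagan_p": diag["breusch_pagan_p"],
    }

    classified = stage("classify", classify_observations, obs, ct, equations)
    _write_reports(
        stratified_reports(classified, by="none"), out, "pooled"
    )
    if classified["sex"].notna().any():
        _write_reports(
            stratified_reports(classified, by="sex", min_group_size=config.min_group_size),
            out,
            "sex",
        )
    _write_reports(
        stratified_reports(classified, by="stratum", min_group_size=config.min_group_size),
        out,
        "stratum",
    )

    if config.make_plots:
        _make_plots(diag, ba, out)

    config.to_yaml(out / "config_used.yaml")
    log["finished_utc"] = datetime.now(timezone.utc).isoformat()
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return out


def _make_plots(diag, ba_results, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].scatter(diag["qq_theoretical"], diag["qq_sample"], s=6)
    lims = [diag["qq_theoretical"].min(), diag["qq_theoretical"].max()]
    axes[0].plot(lims, np.array(lims) * diag["residuals"].std(), color="C3")
    axes[0].set_xlabel("theoretical quantiles")
    axes[0].set_ylabel("sample quantiles")
    axes[1].scatter(diag["fitted"], diag["residuals"], s=6)
    axes[1].axhline(0, color="C3")
    axes[1].set_xlabel("fitted sqrt(MET)")
    axes[1].set_ylabel("residual")
    fig.tight_layout()
    fig.savefig(out / "residual_diagnostics.png", dpi=120)
    plt.close(fig)


def validate_table2(coefficients_file=None) -> pd.DataFrame:
    """Recompute cut-points from printed (b0, b1) and report deviations.

    Reads a coefficients CSV in the fit-report dialect (device, placement,
    b0, b1, cp3, cp6, cp9); by default the shipped published table is
    used.  Returns one row per stratum x threshold with the recomputed
    cut-point and its relative deviation from the printed one.
    """
    if coefficients_file is None:
        table = PUBLISHED_CALIBRATION
    else:
        table = _parse_coefficients_csv(coefficients_file)
    rows = []
    for r in table.itertuples():
        eq = StratumEquation(r.device, r.placement, r.b0, r.b1)
        for m, printed in zip(MET_THRESHOLDS, (r.cp3, r.cp6, r.cp9)):
            recomputed = invert_cutpoint(eq, m)
            rows.append(
                {
                    "device": r.device,
                    "placement": r.placement,
                    "threshold_met": m,
                    "printed": printed,
                    "recomputed": recomputed,
                    "rel_deviation": abs(recomputed - printed) / printed,
                }
            )
    return pd.DataFrame(rows)


def _parse_coefficients_csv(path) -> pd.DataFrame:
    required = ["device", "placement", "b0", "b1", "cp3", "cp6", "cp9"]
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: line 1: empty file")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: line 1: missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            parsed = {"device": row["device"], "placement": row["placement"]}
            for c in required[2:]:
                try:
                    parsed[c] = float(row[c])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: line {lineno}: non-numeric value {row[c]!r} in column {c}"
                    ) from None
            rows.append(parsed)
    if not rows:
        raise ValueError(f"{path}: line 2: no data rows")
    return pd.DataFrame(rows)
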