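"""From raw breath and epoch streams to steady-state observations.

The calibration regression works on one row per participant, protocol
condition and device*placement stratum: the mean activity counts/min and
the mean MET over the central four minutes of each 10-min stage.  This
module applies the two cleaning rules that precede that averaging:

* errant breaths (coughs, swallows) are dropped when they deviate more
  than three standard deviations from the mean of the two preceding and
  two following breaths, in a single pass over the original series;
* each stage contributes only its central 240 s window, by which time VO2
  has plateaued.

MET is the breath-level VO2 normalised by body mass and the conventional
3.5 ml O2/kg/min resting rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import (
    VO2_PER_MET,
    BreathSeries,
    EpochSeries,
    ParticipantProfile,
    ProtocolCondition,
    DEFAULT_PROTOCOL,
    STRATA,
)

__all__ = [
    "clean_breaths",
    "central_window",
    "vo2_to_met",
    "steady_state_met",
    "steady_state_counts",
    "build_observation_table",
    "read_epoch_csv",
    "read_breath_csv",
    "OBSERVATION_COLUMNS",
]

OBSERVATION_COLUMNS = (
    "participant",
    "sex",
    "condition",
    "speed",
    "device",
    "placement",
    "stratum",
    "activity_cpm",
    "met",
)

STAGE_DURATION_S = 600.0
WINDOW_HALF_OFFSET_S = 180.0  # central 4 of 10 minutes: [180, 420)
WINDOW_LENGTH_S = 240.0


def clean_breaths(
    series: BreathSeries, sd_multiplier: float = 3.0, n_neighbours: int = 2
) -> BreathSeries:
    """Drop errant breaths by the local 3-SD rule.

    For each interior breath i the reference set is the ``n_neighbours``
    breaths before and after (the centre breath excluded); breath i is
    removed iff |v_i - m_i| > sd_multiplier * s_i where m_i, s_i are the
    mean and sample SD of the reference values.  A single pass over the
    original series: removals do not re-enter reference windows, and the
    first/last ``n_neighbours`` breaths are always retained.  With a
    perfectly constant neighbourhood (s_i = 0) any deviation is errant.

    Series with fewer than ``2 * n_neighbours + 1`` breaths are returned
    unchanged with a warning flag.
    """
    v = np.asarray(series.vo2_ml_min, dtype=float)
    n = v.size
    k = n_neighbours
    if n < 2 * k + 1:
        return replace(series, n_excluded=0, warning="too few breaths to clean")
    keep = np.ones(n, dtype=bool)
    for i in range(k, n - k):
        ref = np.concatenate([v[i - k : i], v[i + 1 : i + k + 1]])
        m = ref.mean()
        s = ref.std(ddof=1)
        if abs(v[i] - m) > sd_multiplier * s:
            keep[i] = False
    return BreathSeries(
        series.participant_id,
        series.condition,
        np.asarray(series.time_s)[keep],
        v[keep],
        series.body_mass_kg,
        n_excluded=int((~keep).sum()),
    )


def central_window(condition_start_s: float, duration_s: float = STAGE_DURATION_S):
    """Half-open central 4-minute interval of a 10-min stage.

    Raises if the stage is not the protocol's 600 s (protocol violation).
    """
    if duration_s != STAGE_DURATION_S:
        raise ValueError(
            f"central window is defined for {STAGE_DURATION_S:.0f}-s stages, got {duration_s}"
        )
    lo = condition_start_s + WINDOW_HALF_OFFSET_S
    return (lo, lo + WINDOW_LENGTH_S)


def vo2_to_met(vo2_per_kg):
    """Convert VO2 in ml O2/kg/min to METs (1 MET = 3.5 ml/kg/min)."""
    arr = np.asarray(vo2_per_kg, dtype=float)
    if np.any(arr < 0):
        raise ValueError("VO2 must be non-negative")
    out = arr / VO2_PER_MET
    return float(out) if np.isscalar(vo2_per_kg) else out


def steady_state_met(
    series: BreathSeries, window, time_weighted: bool = True
) -> float:
    """Mean MET over breaths falling in the window.

    Weights each breath by its inter-breath interval (the preceding gap,
    anchored at the window start for the first in-window breath); a simple
    unweighted mean is available for regular sampling.  Returns NaN when
    the window holds no breaths (missing-observation marker).
    """
    lo, hi = window
    t = np.asarray(series.time_s, dtype=float)
    v = np.asarray(series.vo2_ml_min, dtype=float)
    mask = (t >= lo) & (t < hi)
    if not mask.any():
        return float("nan")
    tw, vw = t[mask], v[mask]
    per_kg = vw / series.body_mass_kg
    if time_weighted:
        weights = np.diff(tw, prepend=lo)
        mean_vo2 = float(np.average(per_kg, weights=weights))
    else:
        mean_vo2 = float(per_kg.mean())
    return mean_vo2 / VO2_PER_MET


def steady_state_counts(
    series: EpochSeries, window, max_missing_frac: float = 0.05
) -> float:
    """Mean counts/min over the window's four one-minute blocks.

    Each minute's counts/min is the sum of its 60 one-second epochs; the
    window value is the mean of the four minute totals.  Minutes with
    missing epochs are rescaled to a full minute provided the whole window
    is missing at most ``max_missing_frac``; otherwise NaN is returned
    (missing-observation marker).
    """
    lo, hi = window
    t = series.time_s
    c = np.asarray(series.counts, dtype=float)
    mask = (t >= lo) & (t < hi)
    n_expected = int(round(hi - lo))
    n_present = int(mask.sum())
    if n_present < n_expected * (1 - max_missing_frac):
        return float("nan")
    minute = ((t[mask] - lo) // 60).astype(int)
    totals = []
    for m in range(int(round((hi - lo) / 60))):
        sel = minute == m
        n_m = int(sel.sum())
        if n_m == 0:
            return float("nan")
        totals.append(c[mask][sel].sum() * 60.0 / n_m)
    return float(np.mean(totals))


def _protocol_map(protocol: Sequence[ProtocolCondition]) -> dict[str, ProtocolCondition]:
    return {c.label: c for c in protocol}


def build_observation_table(
    breaths: Iterable[BreathSeries],
    epochs: Iterable[EpochSeries],
    protocol: Sequence[ProtocolCondition] = DEFAULT_PROTOCOL,
    cohort: Sequence[ParticipantProfile] | None = None,
    time_weighted: bool = True,
    sd_multiplier: float = 3.0,
):
    """Assemble one steady-state observation per participant*condition*stratum.

    Breath series are cleaned, both streams are averaged over the central
    window (times are relative to each condition's start), and rows where
    either mean is missing are dropped and counted.  Returns
    ``(DataFrame, log)`` where log records exclusion counts so that
    rows_in == rows_out + exclusions.
    """
    cond_map = _protocol_map(protocol)
    sex_map = {p.id: p.sex for p in cohort} if cohort else {}

    met_by_key: dict[tuple, float] = {}
    breaths_removed = 0
    for b in breaths:
        key = (b.participant_id, b.condition)
        if key in met_by_key:
            raise ValueError(f"duplicate breath series for {key}")
        cleaned = clean_breaths(b, sd_multiplier=sd_multiplier)
        breaths_removed += cleaned.n_excluded
        window = central_window(0.0, cond_map[b.condition].duration_s)
        met_by_key[key] = steady_state_met(cleaned, window, time_weighted=time_weighted)

    rows = []
    dropped = 0
    seen = set()
    for e in epochs:
        key = (e.participant_id, e.condition, e.stratum)
        if key in seen:
            raise ValueError(f"duplicate epoch series for {key}")
        seen.add(key)
        cond = cond_map[e.condition]
        window = central_window(0.0, cond.duration_s)
        cpm = steady_state_counts(e, window)
        met = met_by_key.get((e.participant_id, e.condition), float("nan"))
        if np.isnan(cpm) or np.isnan(met):
            dropped += 1
            continue
        rows.append(
            (
                e.participant_id,
                sex_map.get(e.participant_id),
                e.condition,
                cond.speed_kmh,
                e.device,
                e.placement,
                e.stratum,
                cpm,
                met,
            )
        )
    table = pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))
    log = {
        "errant_breaths_removed": breaths_removed,
        "rows_dropped_missing": dropped,
        "rows_out": len(table),
    }
    return table, log


# --------------------------------------------------------------------------
# CSV readers for the synthetic-data dialects
# --------------------------------------------------------------------------

def read_epoch_csv(path, participant_id: str, condition: str) -> EpochSeries:
    """Read an epoch CSV (timestamp, counts, device, placement, mode)."""
    df = pd.read_csv(path)
    return EpochSeries(
        participant_id,
        condition,
        df["device"].iloc[0],
        df["placement"].iloc[0],
        df["mode"].iloc[0],
        df["counts"].to_numpy(dtype=float),
    )


def read_breath_csv(path, participant_id: str, condition: str, body_mass_kg: float) -> BreathSeries:
    """Read a breath CSV (time_s, vo2_ml_min)."""
    df = pd.read_csv(path)
    return BreathSeries(
        participant_id,
        condition,
        df["time_s"].to_numpy(dtype=float),
        df["vo2_ml_min"].to_numpy(dtype=float),
        body_mass_kg,
    )


def load_dataset(dataset_dir, protocol: Sequence[ProtocolCondition] = DEFAULT_PROTOCOL):
    """Load a written cohort dataset into breath/epoch series lists."""
    root = Path(dataset_dir)
    meta = pd.read_csv(root / "participants.csv")
    mass = dict(zip(meta["id"], meta["mass_kg"]))
    breaths, epochs = [], []
    for bpath in sorted((root / "breaths").glob("*.csv")):
        pid, cond = bpath.stem.split("_", 1)
        breaths.append(read_breath_csv(bpath, pid, cond, mass[pid]))
    for epath in sorted((root / "epochs").glob("*.csv")):
        pid, rest = epath.stem.split("_", 1)
        cond, stratum = rest.split("_", 1)
        epochs.append(read_epoch_csv(epath, pid, cond))
    cohort_meta = [
        ParticipantProfile(r.id, r.sex, r.age, r.height_cm, r.mass_kg)
        for r in meta.itertuples()
    ]
    return breaths, epochs, cohort_meta
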