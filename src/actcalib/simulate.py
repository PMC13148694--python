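"""Synthetic treadmill-calibration data with known ground truth.

Emulates the study design behind the calibration pipeline: a cohort of
young adults walks/runs a 5-stage progressive treadmill protocol (rest, 3,
5, 7, 9 km/h; 10 min per stage) while wearing two accelerometers (a
hip/wrist ActiGraph GT3X+ recording vector-magnitude counts and a
hip/wrist ActTrust recording PIM counts, both in 1-s epochs) and breathing
into a metabolic cart that records breath-by-breath VO2.

The generator is built around a latent locomotor intensity on the sqrt-MET
scale.  For participant i in condition c,

    u_ic = sqrt(met_by_speed[speed_c]) + tau(speed_c) * z_ic,

with z_ic a standard-normal participant-by-condition deviation.  Each
device*placement stratum s has a true calibration line
sqrt(MET) = b0_s + b1_s * sqrt(counts/min), so the stratum's steady-state
counts are placed at sqrt(cpm) = (u_ic - b0_s) / b1_s (floored at zero),
while the measured MET is sqrt(MET) = u_ic + eps_ic with
eps ~ N(0, residual_sd_sqrt_met).  Every stratum's line therefore holds
exactly with y-side noise only, which is what makes downstream parameter
recovery a meaningful fitness test of the whole pipeline.

Two levels of fidelity are offered:

* :func:`simulate_observation_table` draws steady-state observations
  directly (fast; used for replicate studies), and
* the raw path :func:`simulate_raw_acceleration` -> :func:`emulate_counts`
  plus :func:`simulate_breaths`, assembled by :func:`write_cohort_dataset`,
  which synthesises gait-like tri-axial acceleration, runs it through each
  device's band-pass/epoch-integration chain, and writes breath and epoch
  CSV files for the preprocessing module to consume.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal

__all__ = [
    "ParticipantProfile",
    "ProtocolCondition",
    "DeviceSpec",
    "TruthParameters",
    "RawAccelerationSeries",
    "EpochSeries",
    "BreathSeries",
    "STRATA",
    "DEVICE_SPECS",
    "DEFAULT_PROTOCOL",
    "TABLE_COEFFICIENTS",
    "generate_cohort",
    "simulate_raw_acceleration",
    "emulate_counts",
    "simulate_breaths",
    "simulate_observation_table",
    "write_cohort_dataset",
]

# --------------------------------------------------------------------------
# Domain types and study constants
# --------------------------------------------------------------------------

#: Device*placement strata in the canonical reporting order; the first is
#: the reference level of the calibration model.
STRATA: tuple[str, ...] = ("GT3X_hip", "ACTT_hip", "ACTT_wrist", "GT3X_wrist")

#: Published per-stratum calibration coefficients on the sqrt scale
#: (intercept b0 in sqrt-MET, slope b1 in sqrt-MET per sqrt(counts/min)).
#: These double as the generator's default ground truth.
TABLE_COEFFICIENTS: dict[str, tuple[float, float]] = {
    "GT3X_hip": (1.062, 0.0199),
    "ACTT_hip": (1.107, 0.0088),
    "ACTT_wrist": (1.233, 0.0081),
    "GT3X_wrist": (1.207, 0.0127),
}

#: Sex-specific cohort statistics: mean and SD of age (y), height (cm) and
#: body mass (kg) for the emulated young-adult sample.
COHORT_STATS = {
    "male": {"age": (28.3, 4.6), "height_cm": (172.0, 6.2), "mass_kg": (78.2, 11.9)},
    "female": {"age": (26.8, 5.0), "height_cm": (160.0, 7.3), "mass_kg": (59.9, 9.4)},
}

AGE_BOUNDS = (18.0, 35.0)
MIN_MASS_KG = 35.0
MIN_HEIGHT_CM = 120.0

#: ml O2 per kg per minute corresponding to 1 MET.
VO2_PER_MET = 3.5


@dataclass(frozen=True)
class ParticipantProfile:
    """Demographic/anthropometric truth for one simulated participant."""

    id: str
    sex: str  # "male" | "female"
    age: float  # years
    height_cm: float
    body_mass_kg: float
    dominant_side: str = "right"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.body_mass_kg <= 0:
            raise ValueError("body_mass_kg must be positive")
        if self.height_cm <= 0:
            raise ValueError("height_cm must be positive")

    @property
    def bmi(self) -> float:
        """Body-mass index in kg/m^2 (derived)."""
        return self.body_mass_kg / (self.height_cm / 100.0) ** 2


@dataclass(frozen=True)
class ProtocolCondition:
    """One stage of the progressive treadmill protocol."""

    label: str
    speed_kmh: float
    duration_s: float = 600.0
    rest_after_s: float = 300.0


#: Rest plus four treadmill speeds, 10 min each, 5-min rests in between.
DEFAULT_PROTOCOL: tuple[ProtocolCondition, ...] = (
    ProtocolCondition("rest", 0.0),
    ProtocolCondition("walk3", 3.0),
    ProtocolCondition("walk5", 5.0),
    ProtocolCondition("run7", 7.0),
    ProtocolCondition("run9", 9.0),
)


@dataclass(frozen=True)
class DeviceSpec:
    """Hardware/firmware description of one worn accelerometer."""

    device: str  # "GT3X" | "ACTT"
    placement: str  # "hip" | "wrist"
    sampling_rate_hz: float
    dynamic_range_g: tuple[float, float]  # (deadband, clip); deadband 0 => none
    band_pass_hz: tuple[float, float]
    count_mode: str  # "VM" | "PIM"
    epoch_s: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.band_pass_hz
        if not lo < hi:
            raise ValueError("band_pass_hz must be (low, high) with low < high")
        if self.epoch_s != 1.0:
            raise ValueError("only 1-s epochs are supported")
        expected_mode = {"GT3X": "VM", "ACTT": "PIM"}[self.device]
        if self.count_mode != expected_mode:
            raise ValueError(f"{self.device} must use count_mode {expected_mode!r}")

    @property
    def stratum(self) -> str:
        return f"{self.device}_{self.placement}"


def _make_device_specs() -> dict[str, DeviceSpec]:
    specs = {}
    for placement in ("hip", "wrist"):
        specs[f"GT3X_{placement}"] = DeviceSpec(
            "GT3X", placement, 30.0, (0.0, 6.0), (0.25, 2.5), "VM"
        )
        specs[f"ACTT_{placement}"] = DeviceSpec(
            "ACTT", placement, 25.0, (0.03, 4.0), (0.5, 2.7), "PIM"
        )
    return specs


#: The four device*placement strata worn simultaneously by each participant.
DEVICE_SPECS: dict[str, DeviceSpec] = _make_device_specs()

#: Count scaling constants (counts per g*s of integrated filtered
#: acceleration).  Chosen once so synthetic counts land near the published
#: count magnitudes for each device; they are explicit configuration, not
#: estimates of the vendors' internal constants.
COUNT_SCALE = {"GT3X": 1000.0, "ACTT": 2500.0}


def _default_met_by_speed() -> dict[float, float]:
    # Compendium-typical treadmill values.  Rest is the *measured* standing
    # resting rate expressed through the 3.5 ml/kg/min convention, which in
    # young adults sits well above 1.0 MET.
    return {0.0: 1.6, 3.0: 2.8, 5.0: 3.8, 7.0: 7.0, 9.0: 9.5}


@dataclass
class TruthParameters:
    """Ground-truth generator parameters (the study conditions).

    b0_true/b1_true define the per-stratum calibration lines on the sqrt
    scale; residual_sd_sqrt_met is the calorimetry-side scatter of
    sqrt(MET) around the line; between_sd_base/_per_kmh set the
    between-participant spread tau(speed) = base + per_kmh * speed of the
    latent intensity.
    """

    b0_true: dict[str, float] = field(
        default_factory=lambda: {s: TABLE_COEFFICIENTS[s][0] for s in STRATA}
    )
    b1_true: dict[str, float] = field(
        default_factory=lambda: {s: TABLE_COEFFICIENTS[s][1] for s in STRATA}
    )
    residual_sd_sqrt_met: float = 0.15
    resting_vo2: float = VO2_PER_MET  # ml/kg/min at 1 MET
    met_by_speed: dict[float, float] = field(default_factory=_default_met_by_speed)
    # tau(speed) = base + per_kmh*speed on the sqrt-MET scale; at 9 km/h this
    # gives ~10% between-subject CV in MET at fixed speed (typical of
    # running-economy variability), while rest stays tightly clustered.
    between_sd_base: float = 0.02
    between_sd_per_kmh: float = 0.016
    participant_effect_corr: float = 0.6
    breath_noise_cv: float = 0.05
    errant_breath_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b1 <= 0 for b1 in self.b1_true.values()):
            raise ValueError("all b1_true must be positive")
        if self.residual_sd_sqrt_met < 0:
            raise ValueError("residual_sd_sqrt_met must be >= 0")
        if not 0 <= self.errant_breath_rate < 1:
            raise ValueError("errant_breath_rate must be in [0, 1)")

    def between_sd(self, speed_kmh: float) -> float:
        return self.between_sd_base + self.between_sd_per_kmh * speed_kmh


@dataclass
class RawAccelerationSeries:
    """Tri-axial acceleration (g) sampled at a device's native rate."""

    device_spec: DeviceSpec
    sample_times_s: np.ndarray
    xyz: np.ndarray  # shape (n, 3)
    participant_id: str | None = None
    condition: str | None = None


@dataclass
class EpochSeries:
    """1-s epoch activity counts for one participant*condition*stratum."""

    participant_id: str | None
    condition: str | None
    device: str
    placement: str
    count_mode: str
    counts: np.ndarray  # one non-negative value per second
    epoch_s: float = 1.0

    @property
    def time_s(self) -> np.ndarray:
        """Elapsed seconds at the start of each epoch."""
        return np.arange(len(self.counts), dtype=float)

    @property
    def stratum(self) -> str:
        return f"{self.device}_{self.placement}"


@dataclass
class BreathSeries:
    """Breath-by-breath VO2 record for one participant*condition."""

    participant_id: str | None
    condition: str | None
    time_s: np.ndarray  # strictly increasing, s from condition start
    vo2_ml_min: np.ndarray  # absolute VO2 per breath interval
    body_mass_kg: float
    n_excluded: int = 0
    warning: str | None = None


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

def generate_cohort(n_male: int, n_female: int, seed: int) -> list[ParticipantProfile]:
    """Draw a cohort from sex-specific normal demographics.

    Ages are clipped to the recruited 18-35 y band; mass and height are
    truncated at physiologic lower bounds.  Deterministic given ``seed``.
    """
    if n_male < 0 or n_female < 0:
        raise ValueError("n_male and n_female must be non-negative")
    if n_male + n_female < 2:
        raise ValueError(f"cohort too small: n_male + n_female = {n_male + n_female} < 2")
    rng = np.random.default_rng(seed)
    cohort: list[ParticipantProfile] = []
    idx = 1
    for sex, n in (("male", n_male), ("female", n_female)):
        stats = COHORT_STATS[sex]
        for _ in range(n):
            age = float(np.clip(rng.normal(*stats["age"]), *AGE_BOUNDS))
            height = max(float(rng.normal(*stats["height_cm"])), MIN_HEIGHT_CM)
            mass = max(float(rng.normal(*stats["mass_kg"])), MIN_MASS_KG)
            side = "right" if rng.random() < 0.9 else "left"
            cohort.append(
                ParticipantProfile(f"P{idx:03d}", sex, age, height, mass, side)
            )
            idx += 1
    return cohort


# --------------------------------------------------------------------------
# Raw gait-like acceleration and device count emulation
# --------------------------------------------------------------------------

# Per-axis harmonic weights of the gait waveform (fundamental at the step
# frequency plus two harmonics).  Hip is dominated by the vertical axis,
# the wrist by arm swing.
_HARMONICS = {
    "hip": ((1.0, 0.35, 0.12), (0.45, 0.18, 0.05), (0.30, 0.10, 0.04)),
    "wrist": ((0.80, 0.20, 0.05), (1.00, 0.30, 0.10), (0.50, 0.15, 0.05)),
}
_SENSOR_NOISE_G = 0.005
_REST_AMPLITUDE_G = 0.01


def _step_frequency_hz(speed_kmh: float) -> float:
    return 0.0 if speed_kmh <= 0 else 1.4 + 0.16 * speed_kmh


def default_amplitude_g(speed_kmh: float, placement: str) -> float:
    """Nominal gait acceleration amplitude rising with speed."""
    if speed_kmh <= 0:
        return _REST_AMPLITUDE_G
    amp = 0.05 + 0.15 * speed_kmh
    return amp * (1.4 if placement == "wrist" else 1.0)


def simulate_raw_acceleration(
    profile: ParticipantProfile,
    condition: ProtocolCondition,
    spec: DeviceSpec,
    seed,
    amplitude_g: float | None = None,
    sensor_noise_g: float = _SENSOR_NOISE_G,
) -> RawAccelerationSeries:
    """Harmonics-plus-noise gait waveform, clipped to the device range.

    At rest the waveform collapses to near-zero amplitude plus sensor
    noise.  ``amplitude_g`` overrides the speed-driven default (used by the
    dataset writer to hit a target count rate).  Deterministic given seed.
    """
    if condition.speed_kmh < 0:
        raise ValueError("condition speed must be >= 0")
    rng = np.random.default_rng(seed)
    fs = spec.sampling_rate_hz
    n = int(round(condition.duration_s * fs))
    t = np.arange(n) / fs
    if amplitude_g is None:
        amplitude_g = default_amplitude_g(condition.speed_kmh, spec.placement)

    xyz = np.zeros((n, 3))
    f0 = _step_frequency_hz(condition.speed_kmh)
    if f0 > 0 and amplitude_g > 0:
        weights = _HARMONICS[spec.placement]
        phases = rng.uniform(0, 2 * np.pi, size=(3, 3))
        for axis in range(3):
            for k, w in enumerate(weights[axis], start=1):
                xyz[:, axis] += w * np.sin(2 * np.pi * k * f0 * t + phases[axis, k - 1])
        xyz *= amplitude_g
    else:
        # near-still body: tiny postural sway/fidget inside both passbands
        sway = amplitude_g * np.sin(2 * np.pi * 0.7 * t + rng.uniform(0, 2 * np.pi))
        xyz[:, 0] = sway
    if sensor_noise_g > 0:
        xyz += rng.normal(0.0, sensor_noise_g, size=xyz.shape)

    deadband, clip = spec.dynamic_range_g
    if deadband > 0:
        xyz = np.where(np.abs(xyz) < deadband, 0.0, xyz)
    xyz = np.clip(xyz, -clip, clip)
    return RawAccelerationSeries(
        spec, t, xyz, participant_id=profile.id, condition=condition.label
    )


def _bandpass_sos(spec: DeviceSpec):
    return signal.butter(
        4, spec.band_pass_hz, btype="bandpass", fs=spec.sampling_rate_hz, output="sos"
    )


def emulate_counts(raw: RawAccelerationSeries) -> EpochSeries:
    """Band-pass, rectify and integrate acceleration into 1-s epoch counts.

    VM (GT3X): each axis is rectified and integrated per epoch, then the
    Euclidean norm of the three per-axis sums is taken.  PIM (ActTrust):
    the Euclidean norm of the filtered axes is integrated per epoch.
    """
    spec = raw.device_spec
    fs = spec.sampling_rate_hz
    samples_per_epoch = int(round(fs * spec.epoch_s))
    n_epochs = raw.xyz.shape[0] // samples_per_epoch
    if n_epochs < 1:
        raise ValueError("acceleration series shorter than one epoch")

    filt = signal.sosfiltfilt(_bandpass_sos(spec), raw.xyz, axis=0)
    filt = filt[: n_epochs * samples_per_epoch]
    dt = 1.0 / fs
    scale = COUNT_SCALE[spec.device]
    if spec.count_mode == "PIM":
        norm = np.linalg.norm(filt, axis=1)
        counts = norm.reshape(n_epochs, samples_per_epoch).sum(axis=1) * dt * scale
    else:  # VM
        per_axis = (
            np.abs(filt).reshape(n_epochs, samples_per_epoch, 3).sum(axis=1) * dt
        )
        counts = np.linalg.norm(per_axis, axis=1) * scale
    return EpochSeries(
        raw.participant_id,
        raw.condition,
        spec.device,
        spec.placement,
        spec.count_mode,
        counts,
    )


# --------------------------------------------------------------------------
# Breath-by-breath VO2 simulation
# --------------------------------------------------------------------------

_ONKINETICS_TAU_S = 30.0
_ONKINETICS_END_S = 160.0  # exact plateau from here on


def simulate_breaths(
    profile: ParticipantProfile,
    condition: ProtocolCondition,
    truth: TruthParameters,
    seed,
    target_met: float | None = None,
) -> BreathSeries:
    """Irregular breath times with VO2 rising to a steady-state plateau.

    Breath rate climbs from ~12 to ~40 breaths/min with intensity.  VO2/kg
    follows first-order on-kinetics (tau 30 s) truncated to an exact
    plateau after 160 s, so the central four minutes of a 10-min stage are
    strictly steady.  With probability ``truth.errant_breath_rate`` a
    breath is replaced by a cough/swallow-like outlier several local SDs
    from its neighbours.
    """
    rng = np.random.default_rng(seed)
    if target_met is None:
        target_met = truth.met_by_speed[condition.speed_kmh]
    v_rest = truth.resting_vo2
    v_ss = target_met * VO2_PER_MET

    rate_per_min = 12.0 + 2.8 * condition.speed_kmh
    mean_gap = 60.0 / rate_per_min
    n_max = int(condition.duration_s / mean_gap * 1.6) + 10
    if truth.breath_noise_cv > 0:
        gaps = rng.gamma(shape=16.0, scale=mean_gap / 16.0, size=n_max)
    else:
        gaps = np.full(n_max, mean_gap)
    times = np.cumsum(gaps)
    times = times[times < condition.duration_s]

    delta = v_ss - v_rest
    vo2_kg = np.where(
        times >= _ONKINETICS_END_S,
        v_ss,
        v_ss - delta * np.exp(-times / _ONKINETICS_TAU_S),
    )
    if truth.breath_noise_cv > 0:
        vo2_kg = vo2_kg * (1.0 + rng.normal(0.0, truth.breath_noise_cv, size=times.size))
    if truth.errant_breath_rate > 0:
        errant = rng.random(times.size) < truth.errant_breath_rate
        vo2_kg = np.where(errant, vo2_kg * rng.uniform(2.2, 4.0, size=times.size), vo2_kg)
    vo2_kg = np.maximum(vo2_kg, 0.0)
    return BreathSeries(
        profile.id,
        condition.label,
        times,
        vo2_kg * profile.body_mass_kg,
        profile.body_mass_kg,
    )


# --------------------------------------------------------------------------
# Latent-intensity machinery shared by both fidelity levels
# --------------------------------------------------------------------------

def _latent_intensity(
    truth: TruthParameters,
    speed_kmh: float,
    z: float,
) -> float:
    """Latent sqrt-MET intensity u for one participant*condition."""
    return float(np.sqrt(truth.met_by_speed[speed_kmh]) + truth.between_sd(speed_kmh) * z)


def _stratum_sqrt_cpm(truth: TruthParameters, stratum: str, u: float) -> float:
    """Place the stratum's steady-state sqrt(counts/min) on its true line."""
    return max(0.0, (u - truth.b0_true[stratum]) / truth.b1_true[stratum])


def _draw_cluster(truth: TruthParameters, rng, a_i: float, speed: float):
    """Draw (u, eps) for one participant*condition cluster."""
    rho = truth.participant_effect_corr
    z = rho * a_i + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal()
    u = _latent_intensity(truth, speed, z)
    eps = rng.normal(0.0, truth.residual_sd_sqrt_met) if truth.residual_sd_sqrt_met > 0 else 0.0
    return u, eps


def simulate_observation_table(
    cohort: Sequence[ParticipantProfile],
    truth: TruthParameters,
    seed: int,
    protocol: Sequence[ProtocolCondition] = DEFAULT_PROTOCOL,
    residual_mode: str = "independent",
) -> pd.DataFrame:
    """Draw the steady-state observation table directly (fast path).

    Returns one row per participant*condition*stratum with columns
    participant, sex, condition, speed, device, placement, stratum,
    activity_cpm and met — the same dialect the preprocessing module emits
    from raw streams.  All stochasticity lives in the latent intensity and
    the calorimetry residual; minute-level count noise (negligible after
    4-min averaging) is omitted at this level.

    ``residual_mode`` controls the dependence structure of the sqrt-MET
    residual: ``"independent"`` (default) draws one residual per row, so
    the calibration model's error assumptions hold exactly and nominal
    inference is calibrated; ``"shared"`` reuses one residual across the
    four strata of a participant*condition, mirroring the raw-signal path
    where a single gas-exchange measurement serves all devices.
    """
    if residual_mode not in ("independent", "shared"):
        raise ValueError("residual_mode must be 'independent' or 'shared'")
    rng = np.random.default_rng(seed)
    rows = []
    for profile in cohort:
        a_i = rng.standard_normal()
        for cond in protocol:
            u, eps = _draw_cluster(truth, rng, a_i, cond.speed_kmh)
            for stratum in STRATA:
                if residual_mode == "independent":
                    eps = (
                        rng.normal(0.0, truth.residual_sd_sqrt_met)
                        if truth.residual_sd_sqrt_met > 0
                        else 0.0
                    )
                met = (u + eps) ** 2
                x = _stratum_sqrt_cpm(truth, stratum, u)
                device, placement = stratum.split("_")
                rows.append(
                    (
                        profile.id,
                        profile.sex,
                        cond.label,
                        cond.speed_kmh,
                        device,
                        placement,
                        stratum,
                        x**2,
                        met,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "sex",
            "condition",
            "speed",
            "device",
            "placement",
            "stratum",
            "activity_cpm",
            "met",
        ],
    )


# --------------------------------------------------------------------------
# Full raw-signal cohort dataset
# --------------------------------------------------------------------------

def _calibrated_amplitude(
    profile: ParticipantProfile,
    condition: ProtocolCondition,
    spec: DeviceSpec,
    seed,
    target_cpm: float,
) -> float:
    """Amplitude (g) whose emulated counts/min approximate ``target_cpm``.

    The filter+integration chain is linear in amplitude away from the
    deadband/clip limits, so a few fixed-point refinements of a noise-free
    probe suffice.
    """
    if target_cpm <= 1e-9:
        return 0.0
    amp = max(default_amplitude_g(condition.speed_kmh, spec.placement), 0.05)
    # same seed as the actual series so harmonic phases match; noise-free
    probe_cond = ProtocolCondition(condition.label, condition.speed_kmh, 60.0)
    for _ in range(3):
        raw = simulate_raw_acceleration(
            profile, probe_cond, spec, seed, amplitude_g=amp, sensor_noise_g=0.0
        )
        cpm = float(emulate_counts(raw).counts.sum())  # 60 epochs = 1 min
        if cpm <= 1e-9:
            amp *= 2.0
            continue
        amp = float(np.clip(amp * target_cpm / cpm, 1e-4, 3.0))
    return amp


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_cohort_dataset(
    cohort: Sequence[ParticipantProfile],
    truth: TruthParameters,
    out_dir,
    protocol: Sequence[ProtocolCondition] = DEFAULT_PROTOCOL,
) -> dict:
    """Write a full raw-level cohort dataset as plain CSV files.

    Produces per participant*condition*stratum epoch CSVs, per
    participant*condition breath CSVs, a participants metadata CSV, a
    truth-parameters YAML sidecar (for parameter-recovery tests) and a
    manifest with SHA-256 checksums.  Byte-identical for identical inputs.
    """
    out = Path(out_dir)
    try:
        (out / "epochs").mkdir(parents=True, exist_ok=True)
        (out / "breaths").mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise OSError(f"cannot create dataset directory {out}: {err}") from err

    files: list[Path] = []

    meta = pd.DataFrame(
        [
            {
                "id": p.id,
                "sex": p.sex,
                "age": round(p.age, 1),
                "height_cm": round(p.height_cm, 1),
                "mass_kg": round(p.body_mass_kg, 1),
            }
            for p in cohort
        ]
    )
    meta_path = out / "participants.csv"
    meta.to_csv(meta_path, index=False)
    files.append(meta_path)

    truth_path = out / "truth.yaml"
    truth_path.write_text(yaml.safe_dump(asdict(truth), sort_keys=True))
    files.append(truth_path)

    base_time = pd.Timestamp("2022-03-21T08:00:00")
    for pi, profile in enumerate(cohort):
        rng_p = np.random.default_rng([truth.seed, pi, 900])
        a_i = rng_p.standard_normal()
        cond_offset = 0.0
        for ci, cond in enumerate(protocol):
            rng_c = np.random.default_rng([truth.seed, pi, ci, 901])
            u, eps = _draw_cluster(truth, rng_c, a_i, cond.speed_kmh)
            met_obs = (u + eps) ** 2

            breaths = simulate_breaths(
                profile, cond, truth, [truth.seed, pi, ci, 902], target_met=met_obs
            )
            bpath = out / "breaths" / f"{profile.id}_{cond.label}.csv"
            pd.DataFrame(
                {
                    "time_s": np.round(breaths.time_s, 4),
                    "vo2_ml_min": np.round(breaths.vo2_ml_min, 4),
                }
            ).to_csv(bpath, index=False)
            files.append(bpath)

            start = base_time + pd.Timedelta(seconds=cond_offset)
            for si, stratum in enumerate(STRATA):
                spec = DEVICE_SPECS[stratum]
                target_cpm = _stratum_sqrt_cpm(truth, stratum, u) ** 2
                amp = _calibrated_amplitude(
                    profile, cond, spec, [truth.seed, pi, ci, si, 904], target_cpm
                )
                raw = simulate_raw_acceleration(
                    profile, cond, spec, [truth.seed, pi, ci, si, 904], amplitude_g=amp
                )
                epochs = emulate_counts(raw)
                stamps = start + pd.to_timedelta(np.arange(epochs.counts.size), unit="s")
                epath = out / "epochs" / f"{profile.id}_{cond.label}_{stratum}.csv"
                pd.DataFrame(
                    {
                        "timestamp": stamps.strftime("%Y-%m-%dT%H:%M:%S"),
                        "counts": np.round(epochs.counts, 4),
                        "device": spec.device,
                        "placement": spec.placement,
                        "mode": spec.count_mode,
                    }
                ).to_csv(epath, index=False)
                files.append(epath)
            cond_offset += cond.duration_s + cond.rest_after_s

    manifest = {
        "n_participants": len(cohort),
        "n_conditions": len(protocol),
        "n_strata": len(STRATA),
        "files": {str(f.relative_to(out)): _sha256(f) for f in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
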