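"""Synthetic two-arm wearables cohort.

Generates a randomized cohort of older patients with permanent atrial
fibrillation, each carrying ~weeks of wrist-device heart-rate samples
(10-second cadence by default) and per-minute step counts, a clinical
covariate table, and ordinal NYHA functional-class outcomes linked to
physical activity.

The heart-rate generative model for patient *i* at minute *t* is

    hr_i(t) = mu + delta * 1[arm = digoxin] + b_i + w_{i,week(t)}
              + A * cos(2*pi*(hour(t) - 16)/24)
              + gain * steps_i(t) + e_i(t)

with patient intercepts ``b_i ~ N(0, sigma_b^2)``, week effects
``w ~ N(0, sigma_w^2)`` and AR(1) minute noise ``e``.  The week-effect
variance is derived from the configured exchangeable correlation ``rho``
of weekly means, ``sigma_w^2 = sigma_b^2 (1 - rho) / rho``, so weekly
means are compound-symmetric with correlation ``rho`` and standard
deviation ``sigma_b / sqrt(rho)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

HR_MIN_BPM = 20.0
HR_MAX_BPM = 250.0
MINUTES_PER_WEEK = 7 * 24 * 60

#: Marginal distribution targeted for end-of-trial NYHA class (I, II, III, IV).
NYHA_FINAL_MARGINAL = (0.08, 0.64, 0.26, 0.02)
#: Marginal distribution for baseline NYHA class (II, III, IV).
NYHA_BASELINE_MARGINAL = (0.72, 0.26, 0.02)


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the trial population: ~50 patients followed for 20
    weeks, weekly-mean heart rate centred on 72 bpm with s.d. 6 bpm and
    exchangeable week-to-week correlation 0.91, a null treatment effect,
    activity-coupled and circadian heart-rate structure, and ~10%
    device-off missingness.
    """

    n_patients: int = 50
    n_weeks: int = 20
    baseline_hr_bpm: float = 72.0
    treatment_effect_bpm: float = 0.0
    between_patient_sd_bpm: float = 5.72   # 6 * sqrt(0.91): weekly-mean sd 6 at rho 0.91
    within_patient_sd_bpm: float = 7.0     # stationary sd of AR(1) minute noise
    week_correlation: float = 0.91
    hr_activity_gain: float = 0.25         # bpm per step/min
    circadian_amplitude_bpm: float = 3.0
    missing_frac: float = 0.10
    mean_gap_min: int = 30
    nyha_activity_coef: float = 1.0
    seed: int = 0
    # secondary knobs
    ar_phi: float = 0.8
    hr_interval_s: int = 10
    hr_measurement_sd_bpm: float = 1.5
    active_prob: float = 0.15              # chance a daytime minute is active
    active_steps_mean: float = 18.0        # Poisson mean steps in an active minute
    activity_sd_log: float = 0.4           # patient-level spread of active_prob
    intensity_sd_log: float = 0.2          # patient-level spread of step intensity
    day_start_hour: int = 7
    day_end_hour: int = 23
    start: str = "2024-01-01T00:00:00"

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2 (cross-patient scrambling "
                             "and two-arm comparison need at least two patients)")
        if self.n_weeks < 1:
            raise ValueError("n_weeks must be >= 1")
        for name in ("between_patient_sd_bpm", "within_patient_sd_bpm",
                     "circadian_amplitude_bpm", "hr_measurement_sd_bpm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ValueError("missing_frac must lie in [0, 1)")
        if not 0.0 <= self.week_correlation < 1.0:
            raise ValueError("week_correlation must lie in [0, 1)")
        if not 0.0 <= self.ar_phi < 1.0:
            raise ValueError("ar_phi must lie in [0, 1)")

    @property
    def week_effect_sd_bpm(self) -> float:
        """Week-level random-effect sd implied by the exchangeable correlation."""
        rho = self.week_correlation
        if rho == 0.0:
            # all weekly-mean variance is week-level; pick sd equal to between-sd
            return self.between_patient_sd_bpm if self.between_patient_sd_bpm > 0 else 1.0
        return self.between_patient_sd_bpm * np.sqrt((1.0 - rho) / rho)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class PatientProfile:
    """Clinical covariates and functional-class outcomes for one patient."""

    patient_id: str
    arm: Literal["digoxin", "beta_blocker"]
    age_years: float
    gender: Literal["woman", "man"]
    heart_failure: bool
    nt_probnp_pg_ml: float
    bmi_kg_m2: float
    ecg_hr_bpm: float
    smw_distance_m: float
    smw_time_s: float
    smw_speed_m_s: float
    nyha_baseline: str = "II"
    nyha_final: str | None = None

    def __post_init__(self) -> None:
        if self.smw_time_s <= 0:
            raise ValueError("smw_time_s must be positive")
        if abs(self.smw_speed_m_s - self.smw_distance_m / self.smw_time_s) > 1e-9:
            raise ValueError("smw_speed_m_s must equal smw_distance_m / smw_time_s")


@dataclass
class RawSensorStream:
    """Timestamped pre-pooling sensor records for one patient.

    Heart rate arrives every ``hr_interval_s`` seconds; step counts are
    integer totals recorded once per minute.  Timestamps are UTC.
    """

    patient_id: str
    hr_times: np.ndarray      # datetime64[s], nondecreasing
    hr_values: np.ndarray     # float bpm in [20, 250]
    step_times: np.ndarray    # datetime64[s], nondecreasing
    step_values: np.ndarray   # nonnegative integers

    def __post_init__(self) -> None:
        if np.any(np.diff(self.hr_times.astype("int64")) < 0):
            raise ValueError("hr timestamps must be nondecreasing")
        if np.any(np.diff(self.step_times.astype("int64")) < 0):
            raise ValueError("step timestamps must be nondecreasing")
        if self.hr_values.size and (self.hr_values.min() < HR_MIN_BPM
                                    or self.hr_values.max() > HR_MAX_BPM):
            raise ValueError("heart-rate values out of [20, 250] bpm")
        if self.step_values.size and (np.any(self.step_values < 0)
                                      or np.any(self.step_values != np.round(self.step_values))):
            raise ValueError("step values must be nonnegative integers")

    @property
    def n_records(self) -> int:
        return int(self.hr_times.size + self.step_times.size)

    def to_frame(self) -> pd.DataFrame:
        """Long format: patient_id, timestamp, channel, value."""
        return pd.DataFrame({
            "patient_id": self.patient_id,
            "timestamp": np.concatenate([self.hr_times, self.step_times]),
            "channel": ["hr"] * len(self.hr_times) + ["steps"] * len(self.step_times),
            "value": np.concatenate([self.hr_values,
                                     self.step_values.astype(float)]),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RawSensorStream":
        pid = df["patient_id"].iloc[0]
        ts = pd.to_datetime(df["timestamp"]).to_numpy().astype("datetime64[s]")
        hr = df["channel"] == "hr"
        order_hr = np.argsort(ts[hr.to_numpy()], kind="stable")
        order_st = np.argsort(ts[~hr.to_numpy()], kind="stable")
        return cls(
            patient_id=str(pid),
            hr_times=ts[hr.to_numpy()][order_hr],
            hr_values=df.loc[hr, "value"].to_numpy(float)[order_hr],
            step_times=ts[(~hr).to_numpy()][order_st],
            step_values=df.loc[~hr, "value"].to_numpy(float)[order_st],
        )


def _draw_covariates(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    age = np.clip(rng.normal(75.6, 8.4, n), 50, 95)
    gender = np.where(rng.random(n) < 0.40, "woman", "man")
    heart_failure = rng.random(n) < 0.5
    nt_probnp = np.exp(rng.normal(np.log(1000.0), 0.9, n))
    bmi = np.clip(rng.normal(29.0, 5.0, n), 17, 45)
    return {"age_years": age, "gender": gender, "heart_failure": heart_failure,
            "nt_probnp_pg_ml": nt_probnp, "bmi_kg_m2": bmi}


def _minute_clock(cfg: CohortConfig, n_minutes: int) -> tuple[np.ndarray, np.ndarray]:
    """(hour-of-day per minute, datetime64[s] per minute)."""
    start = np.datetime64(cfg.start, "s")
    times = start + (np.arange(n_minutes) * 60).astype("timedelta64[s]")
    start_minute_of_day = int((start - start.astype("datetime64[D]")) / np.timedelta64(60, "s"))
    hours = (((np.arange(n_minutes) + start_minute_of_day) % 1440) / 60.0)
    return hours, times


def generate_cohort(config: CohortConfig) -> tuple[list[PatientProfile], list[RawSensorStream]]:
    """Simulate a randomized two-arm cohort with wearable streams.

    Returns patient profiles (with NYHA outcomes already assigned from the
    post-missingness streams) and one :class:`RawSensorStream` per
    patient spanning ``n_weeks``.  Deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    n_minutes = cfg.n_weeks * MINUTES_PER_WEEK
    hours, minute_times = _minute_clock(cfg, n_minutes)
    daytime = (hours >= cfg.day_start_hour) & (hours < cfg.day_end_hour)
    circadian = cfg.circadian_amplitude_bpm * np.cos(2 * np.pi * (hours - 16.0) / 24.0)
    week_of_minute = np.minimum(np.arange(n_minutes) // MINUTES_PER_WEEK, cfg.n_weeks - 1)

    # 1:1 allocation, randomized order
    arms = np.array(["digoxin", "beta_blocker"])[
        rng.permutation(np.arange(n) % 2)]
    b = rng.normal(0.0, cfg.between_patient_sd_bpm, n)
    cov = _draw_covariates(rng, n)
    # patient-level activity propensity and intensity
    act_mult = np.exp(rng.normal(0.0, cfg.activity_sd_log, n))
    p_active = np.clip(cfg.active_prob * act_mult, 0.02, 0.6)
    lam = cfg.active_steps_mean * np.exp(rng.normal(0.0, cfg.intensity_sd_log, n))

    profiles: list[PatientProfile] = []
    streams: list[RawSensorStream] = []
    samples_per_min = max(1, 60 // cfg.hr_interval_s)
    z_act = (p_active - p_active.mean()) / (p_active.std() + 1e-12)

    for i in range(n):
        # per-minute steps: daytime bursts
        active = (rng.random(n_minutes) < p_active[i]) & daytime
        steps = np.zeros(n_minutes, dtype=np.int64)
        steps[active] = rng.poisson(lam[i], int(active.sum()))

        week_eff = rng.normal(0.0, cfg.week_effect_sd_bpm, cfg.n_weeks)
        ar = _ar1(rng, n_minutes, cfg.ar_phi, cfg.within_patient_sd_bpm)
        hr_minute = (cfg.baseline_hr_bpm
                     + (cfg.treatment_effect_bpm if arms[i] == "digoxin" else 0.0)
                     + b[i] + week_eff[week_of_minute] + circadian
                     + cfg.hr_activity_gain * steps + ar)

        # emit HR at sub-minute cadence with measurement noise
        hr_samples = np.repeat(hr_minute, samples_per_min)
        hr_samples = hr_samples + rng.normal(0.0, cfg.hr_measurement_sd_bpm,
                                             hr_samples.size)
        hr_samples = np.clip(hr_samples, HR_MIN_BPM, HR_MAX_BPM)
        hr_offsets = (np.arange(n_minutes * samples_per_min)
                      * (60 // samples_per_min)).astype("timedelta64[s]")
        start = np.datetime64(cfg.start, "s")

        stream = RawSensorStream(
            patient_id=f"P{i + 1:03d}",
            hr_times=start + hr_offsets,
            hr_values=hr_samples,
            step_times=minute_times.copy(),
            step_values=steps,
        )
        if cfg.missing_frac > 0:
            stream = apply_missingness(stream, cfg.missing_frac, cfg.mean_gap_min,
                                       seed=int(rng.integers(2**31)))
        streams.append(stream)

        smw_distance = float(np.clip(rng.normal(300.0, 60.0) + 80.0 * z_act[i], 50.0, 650.0))
        smw_time = float(np.clip(rng.normal(355.0, 10.0), 300.0, 360.0))
        profiles.append(PatientProfile(
            patient_id=f"P{i + 1:03d}",
            arm=str(arms[i]),
            age_years=float(cov["age_years"][i]),
            gender=str(cov["gender"][i]),
            heart_failure=bool(cov["heart_failure"][i]),
            nt_probnp_pg_ml=float(cov["nt_probnp_pg_ml"][i]),
            bmi_kg_m2=float(cov["bmi_kg_m2"][i]),
            ecg_hr_bpm=float(cfg.baseline_hr_bpm + b[i] + rng.normal(0.0, 6.0)),
            smw_distance_m=smw_distance,
            smw_time_s=smw_time,
            smw_speed_m_s=smw_distance / smw_time,
        ))

    profiles = assign_nyha_labels(profiles, streams, cfg,
                                  seed=int(np.random.default_rng(cfg.seed + 1).integers(2**31)))
    return profiles, streams


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal sd ``sd``."""
    if sd == 0:
        return np.zeros(n)
    from scipy.signal import lfilter
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), n)
    innov[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -phi], innov)


def apply_missingness(stream: RawSensorStream, missing_frac: float,
                      mean_gap_min: int = 30, seed: int = 0) -> RawSensorStream:
    """Delete contiguous device-off gaps until ~``missing_frac`` of minutes are gone.

    Gap lengths are geometric with mean ``mean_gap_min``; both channels are
    deleted inside a gap (the device is off or not transmitting).  The
    realized deleted fraction lands within ±2 percentage points of the
    target on streams much longer than one gap.
    """
    if not 0.0 <= missing_frac < 1.0:
        raise ValueError("missing_frac must lie in [0, 1)")
    if mean_gap_min < 1:
        raise ValueError("mean_gap_min must be >= 1")
    if missing_frac == 0.0:
        return stream
    rng = np.random.default_rng(seed)

    t0 = min(stream.hr_times[0], stream.step_times[0]).astype("datetime64[s]")
    t1 = max(stream.hr_times[-1], stream.step_times[-1]).astype("datetime64[s]")
    n_minutes = int((t1 - t0) / np.timedelta64(60, "s")) + 1
    target = missing_frac * n_minutes
    deleted = np.zeros(n_minutes, dtype=bool)
    p = 1.0 / mean_gap_min
    # add gaps until the target fraction is reached; single-gap overshoot
    # is at most ~mean_gap_min minutes, well inside the 2pp band
    while deleted.sum() < target:
        start = int(rng.integers(n_minutes))
        length = int(rng.geometric(p))
        deleted[start:start + length] = True

    def keep(times: np.ndarray) -> np.ndarray:
        idx = ((times.astype("datetime64[s]") - t0) / np.timedelta64(60, "s")).astype(int)
        idx = np.clip(idx, 0, n_minutes - 1)
        return ~deleted[idx]

    khr, kst = keep(stream.hr_times), keep(stream.step_times)
    return RawSensorStream(
        patient_id=stream.patient_id,
        hr_times=stream.hr_times[khr], hr_values=stream.hr_values[khr],
        step_times=stream.step_times[kst], step_values=stream.step_values[kst],
    )


def _ordinal_from_latent(latent: np.ndarray, marginal: tuple[float, ...],
                         classes: tuple[str, ...]) -> np.ndarray:
    cuts = norm.ppf(np.cumsum(marginal[:-1]))
    return np.array([classes[int(np.searchsorted(cuts, z, side="right"))]
                     for z in latent])


def assign_nyha_labels(profiles: list[PatientProfile],
                       streams: list[RawSensorStream],
                       config: CohortConfig,
                       seed: int | None = None) -> list[PatientProfile]:
    """Draw baseline and end-of-trial NYHA classes linked to activity.

    The final class comes from an ordinal latent model
    ``latent = (-coef * z(mean weekly steps) + eps) / sqrt(coef^2 + 1)``
    thresholded so the marginal class distribution approximates the trial
    cohort (~8% I, 64% II, 26% III, 2% IV at end of trial); higher
    activity gives stochastically lower (better) class.
    """
    if not streams:
        raise ValueError("no streams supplied")
    if not np.isfinite(config.nyha_activity_coef):
        raise ValueError("nyha_activity_coef must be finite")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    weekly_steps = np.array([
        s.step_values.sum() / max(config.n_weeks, 1) for s in streams], dtype=float)
    if np.all(weekly_steps == 0):
        raise ValueError("streams carry no step data")
    z = (weekly_steps - weekly_steps.mean()) / (weekly_steps.std() + 1e-12)
    coef = config.nyha_activity_coef
    scale = np.sqrt(coef**2 + 1.0)
    latent_final = (-coef * z + rng.normal(size=len(profiles))) / scale
    latent_base = (-coef * z + rng.normal(size=len(profiles))) / scale
    finals = _ordinal_from_latent(latent_final, NYHA_FINAL_MARGINAL, ("I", "II", "III", "IV"))
    bases = _ordinal_from_latent(latent_base, NYHA_BASELINE_MARGINAL, ("II", "III", "IV"))
    out = []
    for prof, fin, bas in zip(profiles, finals, bases):
        out.append(dataclasses.replace(prof, nyha_final=str(fin), nyha_baseline=str(bas)))
    return out


def simulate_weekly_cohort(config: CohortConfig, seed: int | None = None
                           ) -> tuple[list[PatientProfile], pd.DataFrame]:
    """Draw weekly summaries directly from the marginal weekly-mean model.

    Fast path for replicate simulation studies (coverage, null calibration,
    power): weekly mean HR for patient *i* in week *w* is
    ``mu + delta*1[digoxin] + b_i + w_iw`` — exactly the distribution the
    per-minute stream generator induces on weekly means, without
    materializing minute-level data.  Returns profiles and a weekly
    summary table (columns ``patient_id, week_index, mean_hr_bpm,
    total_steps, nonmissing_minutes, activity_category``).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n, m = cfg.n_patients, cfg.n_weeks
    arms = np.array(["digoxin", "beta_blocker"])[rng.permutation(np.arange(n) % 2)]
    b = rng.normal(0.0, cfg.between_patient_sd_bpm, n)
    week_eff = rng.normal(0.0, cfg.week_effect_sd_bpm, (n, m))
    mean_hr = (cfg.baseline_hr_bpm
               + np.where(arms == "digoxin", cfg.treatment_effect_bpm, 0.0)[:, None]
               + b[:, None] + week_eff)

    act_mult = np.exp(rng.normal(0.0, cfg.activity_sd_log, n))
    p_active = np.clip(cfg.active_prob * act_mult, 0.02, 0.6)
    daytime_minutes = (cfg.day_end_hour - cfg.day_start_hour) * 60 * 7
    weekly_rate = p_active * cfg.active_steps_mean * daytime_minutes
    total_steps = rng.poisson(weekly_rate[:, None], (n, m))

    cov = _draw_covariates(rng, n)
    z_act = (p_active - p_active.mean()) / (p_active.std() + 1e-12)
    profiles = []
    for i in range(n):
        smw_distance = float(np.clip(rng.normal(300.0, 60.0) + 80.0 * z_act[i], 50.0, 650.0))
        smw_time = float(np.clip(rng.normal(355.0, 10.0), 300.0, 360.0))
        profiles.append(PatientProfile(
            patient_id=f"P{i + 1:03d}", arm=str(arms[i]),
            age_years=float(cov["age_years"][i]), gender=str(cov["gender"][i]),
            heart_failure=bool(cov["heart_failure"][i]),
            nt_probnp_pg_ml=float(cov["nt_probnp_pg_ml"][i]),
            bmi_kg_m2=float(cov["bmi_kg_m2"][i]),
            ecg_hr_bpm=float(cfg.baseline_hr_bpm + b[i] + rng.normal(0.0, 6.0)),
            smw_distance_m=smw_distance, smw_time_s=smw_time,
            smw_speed_m_s=smw_distance / smw_time,
        ))
    # NYHA from standardized mean weekly steps, same latent model as streams
    z = (total_steps.mean(axis=1) - total_steps.mean()) / (total_steps.mean(axis=1).std() + 1e-12)
    coef = cfg.nyha_activity_coef
    scale = np.sqrt(coef**2 + 1.0)
    finals = _ordinal_from_latent((-coef * z + rng.normal(size=n)) / scale,
                                  NYHA_FINAL_MARGINAL, ("I", "II", "III", "IV"))
    bases = _ordinal_from_latent((-coef * z + rng.normal(size=n)) / scale,
                                 NYHA_BASELINE_MARGINAL, ("II", "III", "IV"))
    profiles = [dataclasses.replace(p, nyha_final=str(f), nyha_baseline=str(bb))
                for p, f, bb in zip(profiles, finals, bases)]

    from .preprocessing import categorize_activity
    rows = []
    nonmiss = int(round((1.0 - cfg.missing_frac) * MINUTES_PER_WEEK))
    for i in range(n):
        for w in range(m):
            rows.append({
                "patient_id": f"P{i + 1:03d}", "week_index": w + 1,
                "mean_hr_bpm": float(mean_hr[i, w]),
                "total_steps": int(total_steps[i, w]),
                "nonmissing_minutes": nonmiss,
                "activity_category": categorize_activity(int(total_steps[i, w])),
            })
    return profiles, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O

def profiles_to_frame(profiles: list[PatientProfile]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in profiles])


def profiles_from_frame(df: pd.DataFrame) -> list[PatientProfile]:
    return [PatientProfile(**row) for row in df.to_dict("records")]


def write_streams(streams: list[RawSensorStream], path: str | Path) -> None:
    """Long-format CSV or Parquet, chosen by file suffix."""
    df = pd.concat([s.to_frame() for s in streams], ignore_index=True)
    path = Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_streams(path: str | Path) -> list[RawSensorStream]:
    path = Path(path)
    df = pd.read_parquet(path) if path.suffix == ".parquet" else pd.read_csv(path)
    return [RawSensorStream.from_frame(g) for _, g in df.groupby("patient_id", sort=True)]
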