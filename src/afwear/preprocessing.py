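"""Minute-level pooling, per-patient normalization, CNN windows, weekly summaries.

Raw streams are pooled to one-minute resolution (heart rate averaged,
steps summed within each minute); minutes with no data are kept as
explicit gaps and surfaced as a third missingness channel rather than
imputed.  Normalized 4-hour windows feed the self-supervised CNN, and
weekly summaries feed the repeated-measures treatment comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import spearmanr

from .cohort import MINUTES_PER_WEEK, RawSensorStream

#: CDC-derived weekly step thresholds: 150 min/week aerobic activity is
#: roughly 15,000 steps/week; the 300 min/week health-benefits goal
#: roughly 30,000 steps/week.
LOW_ACTIVITY_STEPS = 15_000
RECOMMENDED_ACTIVITY_STEPS = 30_000


def categorize_activity(total_steps: int) -> str:
    if total_steps < LOW_ACTIVITY_STEPS:
        return "low"
    if total_steps < RECOMMENDED_ACTIVITY_STEPS:
        return "minimum_recommended"
    return "recommended"


@dataclass
class MinuteSeries:
    """Per-minute aligned heart rate, steps, and missingness mask.

    ``mask[i] == 1`` when the minute is missing in either channel (union
    rule): one mask stays truthful for both channels.  In ``hr_bpm`` /
    ``steps``, missing minutes are NaN before normalization and 0 after
    (the per-patient mean HR and zero steps — neutral fill values).
    """

    patient_id: str
    start: np.datetime64
    hr_bpm: np.ndarray
    steps: np.ndarray
    mask: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if not (len(self.hr_bpm) == len(self.steps) == len(self.mask)):
            raise ValueError("hr, steps and mask must have equal length")

    def __len__(self) -> int:
        return len(self.mask)


@dataclass
class WindowTensor:
    """A 240-minute, 3-channel normalized segment for the CNN."""

    patient_id: str
    window_start: np.datetime64
    values: np.ndarray          # (window_min, 3): z-HR, [0,1] steps, mask
    available: bool

    @property
    def start_minute(self) -> int:
        return int(self._start_offset_min)

    _start_offset_min: int = 0


@dataclass
class WeeklySummary:
    patient_id: str
    week_index: int
    mean_hr_bpm: float
    total_steps: int
    nonmissing_minutes: int
    activity_category: str


def pool_to_minutes(stream: RawSensorStream) -> MinuteSeries:
    """Pool a raw stream to 1-minute resolution.

    Heart rate is averaged over each minute; step counts are summed over
    each minute.  One slot per calendar minute from the first to the last
    record; minutes with no record in a channel are missing there, and the
    mask flags minutes missing in either channel.
    """
    if stream.hr_times.size == 0 and stream.step_times.size == 0:
        raise ValueError("empty stream")
    if stream.hr_values.size and not np.all(np.isfinite(stream.hr_values)):
        raise ValueError("non-finite heart-rate values")
    if stream.step_values.size and not np.all(np.isfinite(stream.step_values.astype(float))):
        raise ValueError("non-finite step values")

    all_times = [t for t in (stream.hr_times, stream.step_times) if t.size]
    t0 = min(t[0] for t in all_times).astype("datetime64[m]").astype("datetime64[s]")
    t1 = max(t[-1] for t in all_times).astype("datetime64[s]")
    n = int((t1 - t0) / np.timedelta64(60, "s")) + 1

    hr = np.full(n, np.nan)
    if stream.hr_times.size:
        idx = ((stream.hr_times.astype("datetime64[s]") - t0)
               / np.timedelta64(60, "s")).astype(int)
        sums = np.bincount(idx, weights=stream.hr_values, minlength=n)
        counts = np.bincount(idx, minlength=n)
        with np.errstate(invalid="ignore"):
            hr = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    steps = np.full(n, np.nan)
    if stream.step_times.size:
        idx = ((stream.step_times.astype("datetime64[s]") - t0)
               / np.timedelta64(60, "s")).astype(int)
        ssum = np.bincount(idx, weights=stream.step_values.astype(float), minlength=n)
        scount = np.bincount(idx, minlength=n)
        steps = np.where(scount > 0, ssum, np.nan)

    mask = (np.isnan(hr) | np.isnan(steps)).astype(np.uint8)
    return MinuteSeries(patient_id=stream.patient_id, start=t0,
                        hr_bpm=hr, steps=steps, mask=mask)


def normalize_patient(series: MinuteSeries) -> MinuteSeries:
    """Per-patient normalization: HR to z-scores, steps to [0, 1].

    Statistics are the patient's own: the z-score is relative to that
    patient's mean and s.d. over nonmissing minutes; steps are divided by
    the patient's maximum per-minute count (guarded at 1 when the patient
    never moved).  Missing minutes are filled with 0 in both channels —
    the per-patient mean HR and zero steps — leaving the mask to carry
    the missingness signal.
    """
    hr_ok = ~np.isnan(series.hr_bpm)
    if hr_ok.sum() < 2:
        raise ValueError("need >= 2 nonmissing heart-rate minutes")
    mu = series.hr_bpm[hr_ok].mean()
    sd = series.hr_bpm[hr_ok].std(ddof=0)
    if sd == 0:
        raise ValueError("constant heart-rate series: zero variance")
    hr = np.where(hr_ok, (series.hr_bpm - mu) / sd, 0.0)

    st_ok = ~np.isnan(series.steps)
    max_steps = np.nanmax(series.steps) if st_ok.any() else 0.0
    denom = max(1.0, float(max_steps))
    steps = np.where(st_ok, series.steps / denom, 0.0)
    return replace(series, hr_bpm=hr, steps=steps, normalized=True)


def extract_windows(series: MinuteSeries, window_min: int = 240,
                    stride_min: int = 60,
                    availability_threshold: float = 0.5) -> list[WindowTensor]:
    """Staggered fixed-length windows over a normalized series.

    Windows start at offsets 0, stride, 2*stride, ...; a window is marked
    available when its nonmissing-minute fraction (mask channel) reaches
    the threshold.  A series shorter than one window yields no windows.
    """
    if not series.normalized:
        raise ValueError("extract_windows expects a normalized series")
    T = len(series)
    if T < window_min:
        return []
    n_windows = (T - window_min) // stride_min + 1
    out = []
    values = np.stack([series.hr_bpm, series.steps,
                       series.mask.astype(float)], axis=1)
    for k in range(n_windows):
        lo = k * stride_min
        seg = values[lo:lo + window_min]
        nonmissing = 1.0 - seg[:, 2].mean()
        out.append(WindowTensor(
            patient_id=series.patient_id,
            window_start=series.start + np.timedelta64(lo * 60, "s"),
            values=seg.copy(),
            available=bool(nonmissing >= availability_threshold),
            _start_offset_min=lo,
        ))
    return out


def weekly_summaries(series: MinuteSeries, max_weeks: int = 20,
                     min_nonmissing_frac: float = 0.1) -> list[WeeklySummary]:
    """Weekly mean HR and step totals, indexed from the first device minute.

    Weeks whose HR-nonmissing fraction falls below ``min_nonmissing_frac``
    are excluded (no imputation anywhere).  At most ``max_weeks`` weeks.
    """
    if series.normalized:
        raise ValueError("weekly summaries are computed on the raw-scale pooled series")
    T = len(series)
    out = []
    n_weeks = min(max_weeks, (T + MINUTES_PER_WEEK - 1) // MINUTES_PER_WEEK)
    for w in range(n_weeks):
        lo, hi = w * MINUTES_PER_WEEK, min((w + 1) * MINUTES_PER_WEEK, T)
        hr = series.hr_bpm[lo:hi]
        ok = ~np.isnan(hr)
        if ok.sum() / (hi - lo) < min_nonmissing_frac:
            continue
        steps = series.steps[lo:hi]
        total = int(np.nansum(steps))
        out.append(WeeklySummary(
            patient_id=series.patient_id, week_index=w + 1,
            mean_hr_bpm=float(hr[ok].mean()), total_steps=total,
            nonmissing_minutes=int((series.mask[lo:hi] == 0).sum()),
            activity_category=categorize_activity(total),
        ))
    return out


def correlation_band(rho: float) -> str:
    """Qualitative band for a correlation coefficient."""
    a = abs(rho)
    if a < 0.2:
        return "very weak"
    if a < 0.6:
        return "weak to moderate"
    return "strong"


def daytime_correlation(stream: RawSensorStream, interval_s: int = 10,
                        day_start_hour: int = 7, day_end_hour: int = 23
                        ) -> tuple[float, float, str]:
    """Spearman correlation of daytime heart rate and activity intervals.

    Records are binned at ``interval_s`` resolution by their timestamps
    (heart rate averaged, steps summed per bin); bins in the daytime span
    with both channels present are paired.  Returns ``(rho, p_value,
    band)`` with the qualitative band from :func:`correlation_band`.
    """
    if stream.hr_times.size == 0 or stream.step_times.size == 0:
        raise ValueError("both channels required")
    t0 = min(stream.hr_times[0], stream.step_times[0]).astype("datetime64[s]")

    def bin_values(times: np.ndarray, values: np.ndarray, how: str):
        idx = ((times.astype("datetime64[s]") - t0)
               / np.timedelta64(interval_s, "s")).astype(int)
        n = idx.max() + 1
        sums = np.bincount(idx, weights=values.astype(float), minlength=n)
        counts = np.bincount(idx, minlength=n)
        vals = sums / np.maximum(counts, 1) if how == "mean" else sums
        return vals, counts > 0

    hr, hr_ok = bin_values(stream.hr_times, stream.hr_values, "mean")
    st, st_ok = bin_values(stream.step_times, stream.step_values, "sum")
    n = min(len(hr), len(st))
    hr, hr_ok, st, st_ok = hr[:n], hr_ok[:n], st[:n], st_ok[:n]

    secs_of_day = ((t0 - t0.astype("datetime64[D]")) / np.timedelta64(1, "s")
                   + np.arange(n) * interval_s) % 86400
    day = (secs_of_day >= day_start_hour * 3600) & (secs_of_day < day_end_hour * 3600)
    use = hr_ok & st_ok & day
    if use.sum() < 3:
        raise ValueError("fewer than 3 paired daytime intervals")
    if np.unique(hr[use]).size < 2 or np.unique(st[use]).size < 2:
        raise ValueError("zero-variance ranks")
    rho, p = spearmanr(hr[use], st[use])
    return float(rho), float(p), correlation_band(float(rho))
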