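import numpy as np
import pandas as pd
import pytest

import afwear as aw


@pytest.fixture(scope="session")
def small_cohort():
    """8 patients, 2 weeks of streams, with moderate missingness."""
    cfg = aw.CohortConfig(n_patients=8, n_weeks=2, missing_frac=0.1, seed=42)
    profiles, streams = aw.generate_cohort(cfg)
    return cfg, profiles, streams


@pytest.fixture(scope="session")
def pooled_series(small_cohort):
    _, _, streams = small_cohort
    return [aw.pool_to_minutes(s) for s in streams]


def make_profile(pid, arm, **kw):
    base = dict(age_years=75.0, gender="woman", heart_failure=False,
                nt_probnp_pg_ml=1000.0, bmi_kg_m2=28.0, ecg_hr_bpm=72.0,
                smw_distance_m=300.0, smw_time_s=360.0, smw_speed_m_s=300.0 / 360.0,
                nyha_baseline="II", nyha_final="II")
    base.update(kw)
    return aw.PatientProfile(patient_id=pid, arm=arm, **base)


def make_weekly(pid, week, hr, steps=10_000, nonmissing=9000):
    from afwear.preprocessing import categorize_activity
    return aw.WeeklySummary(patient_id=pid, week_index=week, mean_hr_bpm=hr,
                            total_steps=steps, nonmissing_minutes=nonmissing,
                            activity_category=categorize_activity(steps))


@pytest.fixture
def toy_gee_table():
    """4 patients (2 per arm) x 2 weeks with fixed heart rates."""
    weekly = [
        make_weekly("A", 1, 74.0), make_weekly("A", 2, 76.0),
        make_weekly("B", 1, 71.0), make_weekly("B", 2, 69.0),
        make_weekly("C", 1, 68.0), make_weekly("C", 2, 70.5),
        make_weekly("D", 1, 66.0), make_weekly("D", 2, 67.0),
    ]
    profiles = [make_profile("A", "digoxin"), make_profile("B", "digoxin"),
                make_profile("C", "beta_blocker"), make_profile("D", "beta_blocker")]
    return weekly, profiles
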