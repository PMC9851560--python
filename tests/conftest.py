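"""Shared fixtures: small synthetic cohorts and hand-built series."""

from datetime import date, datetime, timedelta

import numpy as np
import pytest

from emasym.data_model import DEMANDS, SYMPTOMS, Cohort, EmaRecord, ParticipantSeries
from emasym import synthetic


def make_series(
    pid: str,
    values_by_symptom: dict,
    start: date = date(2021, 7, 5),
    n_days: int = 14,
    slots=None,
) -> ParticipantSeries:
    """Build a diary from per-symptom value lists (missing symptoms get 0).

    ``slots`` optionally gives the (day, slot) sequence; otherwise entries
    fill consecutive slots from day 0."""
    n = len(next(iter(values_by_symptom.values())))
    if slots is None:
        slots = [(i // 5, i % 5 + 1) for i in range(n)]
    hours = {1: 8, 2: 11, 3: 14, 4: 17, 5: 20}
    records = []
    for i, (day, slot) in enumerate(slots):
        d = start + timedelta(days=day)
        ts = datetime(d.year, d.month, d.day, hours[slot], 5)
        vas = {s: float(values_by_symptom.get(s, [0] * n)[i]) for s in SYMPTOMS}
        records.append(
            EmaRecord(
                participant_id=pid,
                timestamp=ts,
                prompt_slot=slot,
                vas=vas,
                demand={d_: 1 for d_ in DEMANDS},
            )
        )
    return ParticipantSeries(pid, records, start, n_days)


def make_cohort(series_list) -> Cohort:
    return Cohort(participants={s.participant_id: s for s in series_list})


@pytest.fixture(scope="session")
def default_cohort():
    """Small default-parameter synthetic cohort (shared, read-only)."""
    spec = synthetic.CohortSpec(n_participants=12, seed=42)
    cohort, truth = synthetic.generate_ema(spec)
    return cohort, truth


@pytest.fixture(scope="session")
def accel_cohort():
    """Default cohort with accelerometer epochs (shared, read-only)."""
    spec = synthetic.CohortSpec(n_participants=8, seed=7)
    cohort, truth = synthetic.generate_cohort(spec, synthetic.AccelSpec(seed=7))
    return cohort, truth
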