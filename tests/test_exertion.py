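from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from emasym import exertion, synthetic
from emasym.actigraphy import prompt_windows
from emasym.data_model import DEMANDS, SYMPTOMS, EmaRecord, ParticipantSeries, schedule_prompts
from emasym.exertion import (
    activity_symptom_correlations,
    cohort_peak_responses,
    find_peak_window,
    ma_zscore,
    peak_response,
)
from emasym.variability import UndefinedMetricError

from conftest import make_series

START = date(2021, 7, 5)


def _flat_epochs(peak_day=None, peak_slot_hour=14, peak_mg=200.0, base=5.0):
    """14 days of epochs at a low constant level, optionally one hot 3-h
    window ending at ``peak_slot_hour`` on ``peak_day``."""
    t0 = datetime(2021, 7, 5)
    times = pd.date_range(t0, periods=14 * 2880, freq="30s")
    vals = np.full(len(times), base)
    if peak_day is not None:
        end = t0 + timedelta(days=peak_day, hours=peak_slot_hour)
        start = end - timedelta(hours=3)
        mask = (times >= start) & (times < end)
        vals[mask] = peak_mg
    return pd.DataFrame({"epoch_start": times, "enmo_mg": vals})


def _full_series(bump_rel_hours=(), lag_ref=None, bump_add=10.0):
    """70 completed entries alternating 45/55; entries whose offset from
    ``lag_ref`` (a datetime) is in ``bump_rel_hours`` get ``bump_add``."""
    sched = schedule_prompts(START, 14)
    vals = []
    for i, ts in enumerate(sched):
        v = 45.0 if i % 2 == 0 else 55.0
        if lag_ref is not None:
            rel = (ts - lag_ref).total_seconds() / 3600.0
            if any(abs(rel - b) < 0.1 for b in bump_rel_hours):
                v += bump_add
        vals.append(v)
    slots = [(i // 5, i % 5 + 1) for i in range(70)]
    return make_series("P1", {"fatigue": vals, "overall": vals}, slots=slots)


class TestMaZscore:
    def test_constant_series_undefined(self):
        s = make_series("P1", {"fatigue": [50] * 20})
        with pytest.raises(UndefinedMetricError):
            ma_zscore(s, "fatigue")

    def test_matches_numpy_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(10, 90, 25)
        s = make_series("P1", {"fatigue": vals})
        ma = ma_zscore(s, "fatigue")
        z = (vals - vals.mean()) / vals.std(ddof=1)
        expected = [z[i - 3 : i + 1].mean() for i in range(3, 25)]
        assert ma["ma_z"].to_numpy() == pytest.approx(np.array(expected))

    def test_constant_z_preserved_by_moving_average(self):
        # strictly increasing by equal steps: z pattern symmetric; the MA of
        # any 4 consecutive z equals their mean, checked against numpy
        vals = np.arange(20) * 4.0 + 10
        s = make_series("P1", {"fatigue": vals})
        ma = ma_zscore(s, "fatigue")
        z = (vals - vals.mean()) / vals.std(ddof=1)
        assert ma["ma_z"].iloc[0] == pytest.approx(z[:4].mean())

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.integers(10, 60, 30).astype(float)
        s1 = make_series("P1", {"fatigue": vals})
        s2 = make_series("P1", {"fatigue": np.clip(1.5 * vals + 7, 0, 100)})
        a = ma_zscore(s1, "fatigue")["ma_z"]
        b = ma_zscore(s2, "fatigue")["ma_z"]
        assert a.to_numpy() == pytest.approx(b.to_numpy(), abs=1e-12)

    def test_stamped_at_latest_entry_time(self):
        vals = list(range(10))
        s = make_series("P1", {"fatigue": vals})
        ma = ma_zscore(s, "fatigue")
        assert list(ma["time"]) == [r.timestamp for r in s.records[3:]]


class TestFindPeak:
    def test_objective_mode_single_maximum(self):
        ep = _flat_epochs(peak_day=2, peak_slot_hour=14)
        series = _full_series()
        w = prompt_windows(ep, series.schedule)
        peak = find_peak_window(series, w, "objective_activity")
        assert peak.end == datetime(2021, 7, 7, 14, 0)
        assert peak.value == pytest.approx(200.0)

    def _series_with_demand(self, demand_by_index):
        sched = schedule_prompts(START, 14)
        records = []
        for i, ts in enumerate(sched):
            d = demand_by_index.get(i, 0)
            records.append(
                EmaRecord(
                    "P1",
                    ts + timedelta(minutes=5),
                    i % 5 + 1,
                    {s: 50.0 if i % 2 else 40.0 for s in SYMPTOMS},
                    {"physical": d, "mental": d, "emotional": d},
                )
            )
        return ParticipantSeries("P1", records, START, 14)

    def test_demand_tie_broken_by_objective_activity(self):
        # equal peak demand at day 2 slot 3 (14:00) and day 5 slot 2 (11:00);
        # only the day-2 window is hot, so it wins
        series = self._series_with_demand({12: 3, 26: 3})
        ep = _flat_epochs(peak_day=2, peak_slot_hour=14)
        w = prompt_windows(ep, series.schedule)
        peak = find_peak_window(series, w, "subjective_demand")
        assert peak.end == datetime(2021, 7, 7, 14, 0)
        assert peak.value == 9.0  # combined demand 3+3+3

    def test_demand_tie_with_equal_activity_takes_earlier(self):
        series = self._series_with_demand({12: 3, 26: 3})
        ep = _flat_epochs()  # flat everywhere: activity equal
        w = prompt_windows(ep, series.schedule)
        peak = find_peak_window(series, w, "subjective_demand")
        assert peak.end == datetime(2021, 7, 7, 14, 0)  # index 12 is earlier

    def test_no_data_raises(self):
        series = _full_series()
        empty = pd.DataFrame(
            {"anchor": [], "start": [], "end": [], "mean_enmo": [], "coverage": []}
        )
        with pytest.raises(ValueError):
            find_peak_window(series, empty, "objective_activity")


class TestPeakResponse:
    PEAK_END = datetime(2021, 7, 7, 14, 0)  # day 2, 14:00

    def _profile(self, bump_rel_hours=()):
        ep = _flat_epochs(peak_day=2, peak_slot_hour=14)
        series = _full_series(bump_rel_hours, lag_ref=self.PEAK_END)
        w = prompt_windows(ep, series.schedule)
        return peak_response(series, w)

    def test_quiet_series_not_flagged(self):
        prof = self._profile()
        assert not prof.exacerbation
        assert prof.trigger_hours == []

    def test_four_prompt_bump_at_24h_flagged_in_window(self):
        prof = self._profile(bump_rel_hours=(24, 27, 30, 42))
        assert prof.exacerbation
        assert all(12 <= t <= 60 for t in prof.trigger_hours)

    def test_short_bump_at_6h_not_flagged(self):
        # two bumped prompts at +3 and +6 h: the trailing MA carries at most
        # half the bump into [12, 60], staying under the 1.3 threshold
        prof = self._profile(bump_rel_hours=(3, 6))
        assert not prof.exacerbation

    def test_bump_beyond_60h_not_flagged(self):
        prof = self._profile(bump_rel_hours=(66, 69))
        assert not prof.exacerbation

    def test_profile_limited_to_72h_span(self):
        prof = self._profile()
        assert prof.profile["rel_hours"].between(-72, 72).all()

    def test_followup_completeness_flag(self):
        ep = _flat_epochs(peak_day=13, peak_slot_hour=14)  # peak near study end
        series = _full_series()
        w = prompt_windows(ep, series.schedule)
        prof = peak_response(series, w)
        assert not prof.complete_followup

    def test_trigger_aligns_with_injected_bump(self):
        # the first trigger must stamp a bumped entry (or the next prompt),
        # never fire before the bump arrives: alignment within one prompt
        checked = 0
        for seed in range(4):
            spec = synthetic.independence_spec(n_participants=5, seed=100 + seed)
            cohort, _ = synthetic.generate_cohort(spec, synthetic.AccelSpec(seed=seed))
            inj = synthetic.PemInjection(
                targets=list(cohort.participants),
                lag_hours=24.0,
                amplitude_sd=4.0,
                duration_prompts=4,
            )
            bumped = synthetic.inject_pem(cohort, inj)
            for pid in bumped.participants:
                series = bumped.participants[pid]
                w = prompt_windows(bumped.accel[pid], series.schedule)
                prof = peak_response(series, w)
                bump_rel = [
                    (b.timestamp - prof.peak.end).total_seconds() / 3600.0
                    for a, b in zip(
                        cohort.participants[pid].records, series.records
                    )
                    if a.vas != b.vas
                ]
                if not prof.trigger_hours or not bump_rel:
                    continue
                first = prof.trigger_hours[0]
                assert first >= bump_rel[0] - 1e-9
                assert min(abs(first - b) for b in bump_rel) <= 3.0 + 0.5
                checked += 1
        assert checked >= 10


class TestActivityCorrelations:
    def test_fatigue_copied_from_activity_gives_rho_one(self):
        ep = _flat_epochs()
        # vary daytime windows deterministically so preceding means differ
        t = pd.to_datetime(ep["epoch_start"])
        ep = ep.copy()
        ep["enmo_mg"] = (t.dt.hour + 1.0) * (t.dt.day % 7 + 1.0)
        series0 = _full_series()
        w = prompt_windows(ep, series0.schedule)
        pre = {pd.Timestamp(a): m for a, m in zip(w["anchor"], w["mean_enmo"])}
        sched = schedule_prompts(START, 14)
        vals = [pre[pd.Timestamp(ts)] / 2.0 for ts in sched]  # monotone map into 0-100
        slots = [(i // 5, i % 5 + 1) for i in range(70)]
        series = make_series("P1", {"fatigue": vals, "overall": vals}, slots=slots)
        out = activity_symptom_correlations(series, ep)
        row = out[(out.symptom == "fatigue") & (out.correlate == "pre3")].iloc[0]
        assert row["rho"] == pytest.approx(1.0)

    def test_zero_coupling_cohort_mean_near_zero(self):
        rhos = []
        for seed in (0, 1):
            spec = synthetic.independence_spec(n_participants=10, seed=seed)
            cohort, _ = synthetic.generate_cohort(spec, synthetic.AccelSpec(seed=seed))
            corrs = exertion.cohort_activity_correlations(cohort)
            m = corrs.groupby(["symptom", "correlate"])["rho"].mean()
            rhos.append(m["fatigue", "pre3"])
        assert abs(np.mean(rhos)) < 0.05

    def test_subjective_objective_coupling_moderate(self, accel_cohort):
        cohort, _ = accel_cohort
        corrs = exertion.cohort_activity_correlations(cohort)
        m = corrs.groupby(["symptom", "correlate"])["rho"].mean()
        assert 0.15 < m["demand_physical", "pre3"] < 0.5
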