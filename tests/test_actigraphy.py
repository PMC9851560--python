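from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from emasym.actigraphy import (
    CATEGORIES,
    activity_summary,
    classify_intensity,
    cohort_activity_table,
    enmo_epochs,
    load_accel,
    prompt_windows,
    window_stats,
    write_accel,
)
from emasym.data_model import schedule_prompts


def _raw(values_g, start=datetime(2021, 7, 5, 8, 0), hz=10):
    n = len(values_g)
    times = pd.date_range(start, periods=n, freq=pd.Timedelta(seconds=1 / hz))
    x, y, z = zip(*values_g) if values_g else ((), (), ())
    return pd.DataFrame({"timestamp": times, "x_g": x, "y_g": y, "z_g": z})


def _epochs(values_mg, start=datetime(2021, 7, 5, 0, 0), epoch_s=30):
    times = pd.date_range(start, periods=len(values_mg), freq=f"{epoch_s}s")
    return pd.DataFrame({"epoch_start": times, "enmo_mg": values_mg})


class TestEnmo:
    @pytest.mark.parametrize(
        "sample,expected_mg",
        [
            ((0, 0, 1.0), 0.0),  # gravity only
            ((0, 0, 1.1), 100.0),  # (1.1 - 1) * 1000
            ((0, 0, 0.0), 0.0),  # negative truncated
            ((0.6, 0, 0.8), 0.0),  # unit magnitude off-axis
        ],
    )
    def test_hand_computed_sample_values(self, sample, expected_mg):
        ep = enmo_epochs(_raw([sample] * 300))
        assert ep["enmo_mg"].iloc[0] == pytest.approx(expected_mg, abs=1e-9)

    def test_empty_input_gives_empty_series(self):
        assert len(enmo_epochs(_raw([]))) == 0

    def test_epoch_is_mean_of_samples(self):
        # half the samples at ENMO 200 mg, half at rest -> epoch mean 100
        vals = [(0, 0, 1.2)] * 150 + [(0, 0, 1.0)] * 150
        ep = enmo_epochs(_raw(vals))
        assert ep["enmo_mg"].iloc[0] == pytest.approx(100.0)


class TestClassify:
    @pytest.mark.parametrize(
        "mg,cat",
        [
            (0, "sedentary"),
            (25, "sedentary"),
            (30, "light"),
            (50, "light"),
            (100, "light"),  # boundary: light includes 100
            (100.5, "moderate"),
            (400, "moderate"),
            (450, "vigorous"),
        ],
    )
    def test_category_boundaries(self, mg, cat):
        assert classify_intensity(mg) == cat

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_intensity(-1)


class TestWindowStats:
    def test_constant_light_window(self):
        ep = _epochs([50.0] * 2880)
        w = window_stats(ep, datetime(2021, 7, 5, 14, 0), "preceding")
        assert w.mean_enmo == pytest.approx(50.0)
        assert w.proportions["light"] == 1.0
        assert w.coverage == pytest.approx(1.0)

    def test_preceding_interval_convention(self):
        ep = _epochs([10.0] * 2880)
        w = window_stats(ep, datetime(2021, 7, 5, 14, 0), "preceding")
        assert w.start == datetime(2021, 7, 5, 11, 0)
        assert w.end == datetime(2021, 7, 5, 14, 0)

    def test_mixed_window_proportions(self):
        # epochs switch from 0 to 200 mg at 12:30, the midpoint of the
        # 11:00-14:00 window -> half sedentary, half moderate, mean 100
        vals = [0.0] * 1500 + [200.0] * 1380
        ep = _epochs(vals)
        w = window_stats(ep, datetime(2021, 7, 5, 14, 0), "preceding")
        assert w.mean_enmo == pytest.approx(100.0)
        assert w.proportions["sedentary"] == pytest.approx(0.5)
        assert w.proportions["moderate"] == pytest.approx(0.5)
        assert sum(w.proportions.values()) == pytest.approx(1.0)

    def test_no_epochs_flagged_missing(self):
        ep = _epochs([10.0] * 10)
        w = window_stats(ep, datetime(2021, 8, 1, 14, 0), "preceding")
        assert w.missing

    def test_morning_window_flagged_pre_daytime(self):
        ep = _epochs([10.0] * 2880)
        w = window_stats(ep, datetime(2021, 7, 5, 8, 0), "preceding")
        assert w.pre_daytime  # the 05:00-08:00 window

    def test_preceding_windows_average_to_daytime_mean(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 80, 2880)
        ep = _epochs(vals)
        sched = schedule_prompts(datetime(2021, 7, 5).date(), 1)
        ws = prompt_windows(ep, sched)
        # daytime 08:00-20:00 is exactly the four windows 08-11..17-20
        daytime = ws[~ws["pre_daytime"]]
        t = pd.to_datetime(ep["epoch_start"])
        day_vals = ep[(t.dt.hour >= 8) & (t.dt.hour < 20)]["enmo_mg"]
        assert daytime["mean_enmo"].mean() == pytest.approx(day_vals.mean())


class TestActivitySummary:
    def _day_profile(self, block_min=0.0, block_mg=150.0, base=0.0, n_days=7):
        vals = []
        for _ in range(n_days):
            day = [base] * 2880
            nb = int(block_min * 2)  # 30-s epochs
            start = 10 * 120  # 10:00
            day[start : start + nb] = [block_mg] * nb
            vals.extend(day)
        return _epochs(vals)

    def test_constant_sedentary_day(self):
        ep = _epochs([20.0] * 2880 * 2)
        s = activity_summary(ep, "P1")
        assert s.mean_daytime_enmo == pytest.approx(20.0)
        assert s.prop_nonsedentary == 0.0
        assert s.mvpa_min_per_day == 0.0
        assert s.mvpa_bouted_min_per_week == 0.0

    def test_twelve_minute_daily_block_counts_as_bouted(self):
        ep = self._day_profile(block_min=12.0)
        s = activity_summary(ep, "P1")
        assert s.mvpa_min_per_day == pytest.approx(12.0)
        assert s.mvpa_bouted_min_per_week == pytest.approx(84.0)  # 12 x 7

    def test_eight_minute_block_below_bout_rule(self):
        ep = self._day_profile(block_min=8.0)
        s = activity_summary(ep, "P1")
        assert s.mvpa_min_per_day == pytest.approx(8.0)
        assert s.mvpa_bouted_min_per_week == 0.0

    def test_bouted_minutes_monotone_in_bout_threshold(self):
        ep = self._day_profile(block_min=12.0)
        prev = np.inf
        for thr in (5.0, 10.0, 15.0):
            s = activity_summary(ep, "P1", bout_min=thr)
            assert s.mvpa_bouted_min_per_week <= prev
            prev = s.mvpa_bouted_min_per_week

    def test_sd_variants_on_known_profile(self):
        # daytime windows 08-11/11-14/14-17/17-20 at 0/60/0/60 mg: the SD of
        # window means is sd([0,60,0,60]); within-window SDs are all zero
        day = [0.0] * 2880
        for w, level in enumerate((0.0, 60.0, 0.0, 60.0)):
            start = (8 + 3 * w) * 120
            day[start : start + 360] = [level] * 360
        ep = _epochs(day)
        s = activity_summary(ep, "P1")
        means = [0.0, 60.0, 0.0, 60.0]
        assert s.sd_of_window_means == pytest.approx(np.std(means, ddof=1))
        assert s.mean_of_window_sds == pytest.approx(0.0)


class TestAccelIO:
    def test_epoch_dialect_round_trip(self, tmp_path, accel_cohort):
        cohort, _ = accel_cohort
        path = tmp_path / "accel.csv"
        sub = {pid: cohort.accel[pid].iloc[:200] for pid in list(cohort.accel)[:2]}
        write_accel(sub, path)
        back = load_accel(path)
        assert set(back) == set(sub)
        for pid in sub:
            assert np.allclose(
                back[pid]["enmo_mg"], sub[pid]["enmo_mg"].round(3)
            )

    def test_raw_dialect_detected_and_converted(self, tmp_path):
        raw = _raw([(0, 0, 1.1)] * 600)
        raw.insert(0, "participant_id", "P1")
        p = tmp_path / "raw.csv"
        raw.to_csv(p, index=False)
        out = load_accel(p)
        assert np.allclose(out["P1"]["enmo_mg"], 100.0)

    def test_unknown_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"a": [1]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="header"):
            load_accel(p)

    def test_cohort_table_has_row_per_participant(self, accel_cohort):
        cohort, _ = accel_cohort
        tbl = cohort_activity_table(cohort.accel)
        assert len(tbl) == len(cohort.accel)
        assert (tbl["mean_daytime_enmo"] >= 0).all()
        assert (
            tbl["mvpa_bouted_min_per_week"] <= tbl["mvpa_min_per_day"] * 7 + 1e-9
        ).all()
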