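"""Wrist-accelerometer processing: ENMO, epochs, windows, summaries.

Acceleration is summarised by the Euclidean norm minus one (ENMO):
per sample, max(0, sqrt(x^2 + y^2 + z^2) - 1) in units of g, reported in
milligravitational units (mg) and averaged into 30-s epochs. Intensity
categories: sedentary < 30 mg, light 30-100 mg, moderate > 100-400 mg,
vigorous > 400 mg (light includes exactly 100; moderate excludes it).
Analysis aggregates epochs into the 3-hour windows immediately preceding
(or following) each scheduled diary prompt, and summarises each
participant's daytime (08:00-20:00) activity: mean ENMO, SD of 3-hourly
window means, proportion of time non-sedentary, daily minutes of
moderate-or-vigorous activity (MVPA) of any duration, and weekly MVPA
minutes in bouts of at least 10 consecutive minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

#: category boundaries in mg
SEDENTARY_MAX = 30.0  # sedentary: [0, 30)
LIGHT_MAX = 100.0  # light: [30, 100]; moderate: (100, 400]
MODERATE_MAX = 400.0  # vigorous: (400, inf)
CATEGORIES = ("sedentary", "light", "moderate", "vigorous")

DAY_START_H = 8
DAY_END_H = 20
DEFAULT_EPOCH_S = 30
MVPA_BOUT_MIN = 10.0  # minutes of consecutive MVPA epochs for a bout
DEFAULT_COVERAGE_THRESHOLD = 0.5


def enmo_epochs(
    samples: pd.DataFrame, epoch_s: int = DEFAULT_EPOCH_S
) -> pd.DataFrame:
    """Aggregate raw tri-axial samples (columns timestamp, x_g, y_g, z_g,
    units of g) into mean-ENMO epochs (columns epoch_start, enmo_mg).

    Per-sample ENMO = max(0, ||a|| - 1) * 1000 mg; the epoch value is the
    mean of its samples. Empty input gives an empty series."""
    if len(samples) == 0:
        return pd.DataFrame(columns=["epoch_start", "enmo_mg"])
    mag = np.sqrt(
        samples["x_g"] ** 2 + samples["y_g"] ** 2 + samples["z_g"] ** 2
    )
    enmo = np.maximum(mag - 1.0, 0.0) * 1000.0
    t = pd.to_datetime(samples["timestamp"])
    epoch = t.dt.floor(f"{epoch_s}s")
    out = (
        pd.DataFrame({"epoch_start": epoch, "enmo_mg": enmo})
        .groupby("epoch_start", as_index=False)["enmo_mg"]
        .mean()
        .sort_values("epoch_start", ignore_index=True)
    )
    return out


def classify_intensity(enmo_mg: float) -> str:
    """Intensity category of a (non-negative) mean ENMO value in mg."""
    if enmo_mg < 0 or not np.isfinite(enmo_mg):
        raise ValueError(f"ENMO must be non-negative, got {enmo_mg}")
    if enmo_mg < SEDENTARY_MAX:
        return "sedentary"
    if enmo_mg <= LIGHT_MAX:
        return "light"
    if enmo_mg <= MODERATE_MAX:
        return "moderate"
    return "vigorous"


def _category_codes(enmo: np.ndarray) -> np.ndarray:
    codes = np.zeros(len(enmo), dtype=int)
    codes[(enmo >= SEDENTARY_MAX) & (enmo <= LIGHT_MAX)] = 1
    codes[(enmo > LIGHT_MAX) & (enmo <= MODERATE_MAX)] = 2
    codes[enmo > MODERATE_MAX] = 3
    return codes


@dataclass(frozen=True)
class ActivityWindow:
    """A 3-hour (by default) epoch aggregate anchored at a prompt time."""

    anchor: datetime
    direction: str  # "preceding" | "following"
    start: datetime
    end: datetime
    mean_enmo: float
    proportions: dict  # category -> fraction of observed epoch time
    coverage: float  # observed / expected epochs
    pre_daytime: bool = False  # window begins before 08:00 (the 05-08 window)

    @property
    def missing(self) -> bool:
        return self.coverage == 0


def _sorted_arrays(epochs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t = pd.to_datetime(epochs["epoch_start"]).to_numpy(dtype="datetime64[ns]")
    v = epochs["enmo_mg"].to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    return t[order], v[order]


def _window_agg(
    t: np.ndarray,
    v: np.ndarray,
    anchor: datetime,
    direction: str,
    window_hours: float,
    epoch_s: int,
) -> ActivityWindow:
    if direction == "preceding":
        start, end = anchor - timedelta(hours=window_hours), anchor
    elif direction == "following":
        start, end = anchor, anchor + timedelta(hours=window_hours)
    else:
        raise ValueError(f"direction must be preceding/following, got {direction!r}")
    i0 = np.searchsorted(t, np.datetime64(start, "ns"), side="left")
    i1 = np.searchsorted(t, np.datetime64(end, "ns"), side="left")
    vals = v[i0:i1]
    expected = int(window_hours * 3600 / epoch_s)
    coverage = len(vals) / expected if expected else 0.0
    if len(vals) == 0:
        props = {c: float("nan") for c in CATEGORIES}
        mean = float("nan")
    else:
        codes = _category_codes(vals)
        props = {c: float(np.mean(codes == i)) for i, c in enumerate(CATEGORIES)}
        mean = float(vals.mean())
    return ActivityWindow(
        anchor=anchor,
        direction=direction,
        start=start,
        end=end,
        mean_enmo=mean,
        proportions=props,
        coverage=coverage,
        pre_daytime=start.hour < DAY_START_H and direction == "preceding",
    )


def window_stats(
    epochs: pd.DataFrame,
    anchor: datetime,
    direction: str = "preceding",
    window_hours: float = 3.0,
    epoch_s: int = DEFAULT_EPOCH_S,
) -> ActivityWindow:
    """Aggregate epochs whose start lies in the half-open window
    [anchor - w, anchor) (preceding) or [anchor, anchor + w) (following)."""
    t, v = _sorted_arrays(epochs)
    return _window_agg(t, v, anchor, direction, window_hours, epoch_s)


def prompt_windows(
    epochs: pd.DataFrame,
    schedule: list[datetime],
    direction: str = "preceding",
    window_hours: float = 3.0,
    epoch_s: int = DEFAULT_EPOCH_S,
) -> pd.DataFrame:
    """Window stats for every scheduled prompt, as a frame with columns
    anchor, start, end, mean_enmo, coverage, pre_daytime and one
    proportion column per category."""
    t, v = _sorted_arrays(epochs)
    rows = []
    for anchor in schedule:
        w = _window_agg(t, v, anchor, direction, window_hours, epoch_s)
        rows.append(
            {
                "anchor": w.anchor,
                "direction": w.direction,
                "start": w.start,
                "end": w.end,
                "mean_enmo": w.mean_enmo,
                "coverage": w.coverage,
                "pre_daytime": w.pre_daytime,
                **{f"prop_{c}": w.proportions[c] for c in CATEGORIES},
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ActivitySummary:
    participant_id: str
    mean_daytime_enmo: float  # mg over 08:00-20:00
    sd_of_window_means: float  # SD of the 3-hourly daytime window means
    mean_of_window_sds: float  # alternative reading: mean of within-window SDs
    prop_nonsedentary: float  # daytime epoch time at ENMO >= 30 mg
    mvpa_min_per_day: float  # daytime minutes > 100 mg, any duration
    mvpa_bouted_min_per_week: float  # minutes in runs >= 10 consecutive min


def _daytime_mask(t: pd.Series) -> pd.Series:
    return (t.dt.hour >= DAY_START_H) & (t.dt.hour < DAY_END_H)


def activity_summary(
    epochs: pd.DataFrame,
    participant_id: str = "",
    epoch_s: int = DEFAULT_EPOCH_S,
    bout_min: float = MVPA_BOUT_MIN,
) -> ActivitySummary:
    """Per-participant daytime activity summary (08:00-20:00 only).

    Bouted MVPA counts epoch time inside runs of >= ``bout_min``
    consecutive minutes where every epoch exceeds 100 mg, expressed as
    minutes per week (x 7 / n_days observed)."""
    t = pd.to_datetime(epochs["epoch_start"])
    day = epochs[_daytime_mask(t)].copy()
    if len(day) == 0:
        nan = float("nan")
        return ActivitySummary(participant_id, nan, nan, nan, nan, nan, nan)
    vals = day["enmo_mg"].to_numpy(dtype=float)
    tt = pd.to_datetime(day["epoch_start"])
    n_days = tt.dt.date.nunique()

    # 3-hourly daytime windows: 08-11, 11-14, 14-17, 17-20
    win = ((tt.dt.hour - DAY_START_H) // 3).to_numpy()
    key = list(zip(tt.dt.date, win))
    df = pd.DataFrame({"key": key, "v": vals})
    grouped = df.groupby("key")["v"]
    window_means = grouped.mean()
    window_sds = grouped.std(ddof=1)

    mvpa_mask = vals > LIGHT_MAX
    mvpa_min_day = float(mvpa_mask.sum() * epoch_s / 60.0 / n_days)

    # bouted MVPA: consecutive-epoch runs (within the same day) >= bout_min
    bouted_epochs = 0
    need = int(round(bout_min * 60 / epoch_s))
    dates = tt.dt.date.to_numpy()
    run = 0
    for i in range(len(vals)):
        contiguous = (
            i > 0
            and dates[i] == dates[i - 1]
            and (tt.iloc[i] - tt.iloc[i - 1]) == pd.Timedelta(seconds=epoch_s)
        )
        if mvpa_mask[i] and (run == 0 or contiguous):
            run += 1
        else:
            if run >= need:
                bouted_epochs += run
            run = 1 if mvpa_mask[i] else 0
    if run >= need:
        bouted_epochs += run
    bouted_week = float(bouted_epochs * epoch_s / 60.0 * 7.0 / n_days)

    return ActivitySummary(
        participant_id=participant_id,
        mean_daytime_enmo=float(vals.mean()),
        sd_of_window_means=float(window_means.std(ddof=1)),
        mean_of_window_sds=float(window_sds.mean()),
        prop_nonsedentary=float(np.mean(vals >= SEDENTARY_MAX)),
        mvpa_min_per_day=mvpa_min_day,
        mvpa_bouted_min_per_week=bouted_week,
    )


def cohort_activity_table(
    accel: dict[str, pd.DataFrame], epoch_s: int = DEFAULT_EPOCH_S
) -> pd.DataFrame:
    """Per-participant activity summaries plus cohort median/IQR rows."""
    rows = []
    for pid, epochs in accel.items():
        s = activity_summary(epochs, pid, epoch_s=epoch_s)
        rows.append(vars(s))
    return pd.DataFrame(rows)


def load_accel(path, epoch_s: int = DEFAULT_EPOCH_S) -> dict[str, pd.DataFrame]:
    """Read accelerometer CSV in either dialect (auto-detected by header):
    raw `participant_id,timestamp,x_g,y_g,z_g` or epoch
    `participant_id,epoch_start,enmo_mg`. Returns epoch frames per
    participant."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    out = {}
    if {"participant_id", "epoch_start", "enmo_mg"} <= cols:
        for pid, grp in df.groupby("participant_id", sort=True):
            g = grp[["epoch_start", "enmo_mg"]].copy()
            g["epoch_start"] = pd.to_datetime(g["epoch_start"])
            out[str(pid)] = g.sort_values("epoch_start", ignore_index=True)
    elif {"participant_id", "timestamp", "x_g", "y_g", "z_g"} <= cols:
        for pid, grp in df.groupby("participant_id", sort=True):
            out[str(pid)] = enmo_epochs(grp, epoch_s=epoch_s)
    else:
        raise ValueError(
            "unrecognised accelerometer CSV header; expected epoch dialect "
            "(participant_id, epoch_start, enmo_mg) or raw dialect "
            "(participant_id, timestamp, x_g, y_g, z_g)"
        )
    return out


def write_accel(accel: dict[str, pd.DataFrame], path) -> None:
    """Write epoch-dialect accelerometer CSV."""
    frames = []
    for pid, g in accel.items():
        f = g.copy()
        f.insert(0, "participant_id", pid)
        frames.append(f)
    df = pd.concat(frames, ignore_index=True)
    df["epoch_start"] = pd.to_datetime(df["epoch_start"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    df["enmo_mg"] = df["enmo_mg"].round(3)
    df.to_csv(path, index=False)
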