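"""Symptom-activity coupling and post-exertional exacerbation detection.

Two complementary analyses:

1. Within-person Spearman correlations of fatigue (and overall
   unwellness) with objective activity (mean ENMO in the 3-h window
   preceding the entry, the preceding 1-h window, and the 3-h window
   following it) and with subjective demand (physical item and combined
   0-9 score).

2. A delayed-exacerbation detector: fatigue and overall ratings are
   z-scored within person, smoothed by an unweighted trailing moving
   average over the 4 most recent completed entries, and aligned to the
   participant's single most active 3-h window (or, in subjective mode,
   the entry with the highest combined demand — ties broken by the
   higher objective activity, then by the earlier time). A participant
   is flagged when one or more moving-average z-scores reach >= 1.3
   (about the 90th centile of a normal distribution) for either symptom
   between 12 and 60 hours after the end of the peak window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .actigraphy import DEFAULT_COVERAGE_THRESHOLD, prompt_windows, window_stats
from .correlations import spearman
from .data_model import Cohort, ParticipantSeries
from .variability import UndefinedMetricError

MA_WINDOW = 4
Z_THRESHOLD = 1.3
DETECTION_WINDOW_H = (12.0, 60.0)
PROFILE_SPAN_H = 72.0


def ma_zscore(
    series: ParticipantSeries,
    symptom: str,
    window: int = MA_WINDOW,
    consecutive_slots_only: bool = False,
) -> pd.DataFrame:
    """Within-person z-scores smoothed by a trailing unweighted moving
    average over the ``window`` most recent completed entries, stamped at
    the latest entry's time.

    By default the window spans gaps (missing prompts, overnight);
    ``consecutive_slots_only`` restricts it to runs of consecutive
    same-day slots. Needs >= window + 1 entries and nonzero SD."""
    v = series.values(symptom)
    if len(v) < window + 1:
        raise UndefinedMetricError(f"need at least {window + 1} entries")
    sd = float(np.std(v, ddof=1))
    if sd == 0:
        raise UndefinedMetricError(f"zero within-person SD for {symptom}")
    z = (v - float(np.mean(v))) / sd
    times = [r.timestamp for r in series.records]
    rows = []
    for i in range(window - 1, len(z)):
        if consecutive_slots_only:
            ok = all(
                times[j].date() == times[j - 1].date()
                and series.records[j].prompt_slot
                == series.records[j - 1].prompt_slot + 1
                for j in range(i - window + 2, i + 1)
            )
            if not ok:
                continue
        rows.append({"time": times[i], "ma_z": float(np.mean(z[i - window + 1 : i + 1]))})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PeakWindow:
    start: datetime
    end: datetime
    kind: str  # objective_activity | subjective_demand
    value: float  # peak mean ENMO (objective) or combined demand (subjective)


def find_peak_window(
    series: ParticipantSeries,
    windows: pd.DataFrame,
    mode: str = "objective_activity",
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> PeakWindow:
    """The participant's peak 3-h window over the study.

    Objective mode: the prompt-preceding window with the highest mean
    ENMO (among windows with adequate coverage). Subjective mode: the
    entry with the highest combined demand; equal-demand ties are broken
    by the higher objective activity in the corresponding window, then
    by the earlier time."""
    w = windows[windows["coverage"] >= coverage_threshold]
    if mode == "objective_activity":
        if len(w) == 0 or w["mean_enmo"].isna().all():
            raise ValueError("no usable activity windows")
        row = w.loc[w["mean_enmo"].idxmax()]
        return PeakWindow(
            start=row["start"].to_pydatetime(),
            end=row["end"].to_pydatetime(),
            kind="objective_activity",
            value=float(row["mean_enmo"]),
        )
    if mode == "subjective_demand":
        if not series.records:
            raise ValueError("no diary entries")
        enmo_by_anchor = {
            pd.Timestamp(a): m for a, m in zip(w["anchor"], w["mean_enmo"])
        }
        sched_hours = {1: 8, 2: 11, 3: 14, 4: 17, 5: 20}
        best = None
        for r in series.records:
            anchor = pd.Timestamp(
                r.timestamp.replace(
                    hour=sched_hours[r.prompt_slot], minute=0, second=0, microsecond=0
                )
            )
            act = float(enmo_by_anchor.get(anchor, np.nan))
            key = (
                r.combined_demand,
                act if np.isfinite(act) else -np.inf,
                -anchor.timestamp(),  # later time sorts lower -> earliest wins
            )
            if best is None or key > best[0]:
                best = (key, anchor, r.combined_demand)
        _, anchor, demand = best
        return PeakWindow(
            start=(anchor - timedelta(hours=3)).to_pydatetime(),
            end=anchor.to_pydatetime(),
            kind="subjective_demand",
            value=float(demand),
        )
    raise ValueError(f"unknown peak mode {mode!r}")


@dataclass
class PeakResponseProfile:
    """Moving-average z trajectories of fatigue and overall unwellness
    aligned to the end of the peak window."""

    participant_id: str
    peak: PeakWindow
    profile: pd.DataFrame  # rel_hours, ma_z_fatigue, ma_z_overall
    exacerbation: bool
    trigger_hours: list[float] = field(default_factory=list)
    complete_followup: bool = True  # False when the study ends < 60 h post peak
    boundary_trigger: bool = False  # a trigger lies exactly on 12 or 60 h


def peak_response(
    series: ParticipantSeries,
    windows: pd.DataFrame,
    mode: str = "objective_activity",
    z_threshold: float = Z_THRESHOLD,
    detection_window_h: tuple[float, float] = DETECTION_WINDOW_H,
) -> PeakResponseProfile:
    """Align MA z-scores to the peak window and apply the exacerbation
    criterion: any MA z >= threshold for fatigue or overall at a relative
    time (hours from the peak window's end) inside [12, 60]."""
    peak = find_peak_window(series, windows, mode=mode)
    mas = {}
    for sym in ("fatigue", "overall"):
        mas[sym] = ma_zscore(series, sym).set_index("time")["ma_z"]
    times = sorted(set(mas["fatigue"].index) | set(mas["overall"].index))
    rows = []
    for t in times:
        rel = (t - peak.end).total_seconds() / 3600.0
        if -PROFILE_SPAN_H <= rel <= PROFILE_SPAN_H:
            rows.append(
                {
                    "rel_hours": rel,
                    "ma_z_fatigue": float(mas["fatigue"].get(t, np.nan)),
                    "ma_z_overall": float(mas["overall"].get(t, np.nan)),
                }
            )
    profile = pd.DataFrame(rows, columns=["rel_hours", "ma_z_fatigue", "ma_z_overall"])
    lo, hi = detection_window_h
    triggers = []
    for _, row in profile.iterrows():
        if lo <= row["rel_hours"] <= hi and (
            row["ma_z_fatigue"] >= z_threshold or row["ma_z_overall"] >= z_threshold
        ):
            triggers.append(float(row["rel_hours"]))
    last = max((r.timestamp for r in series.records), default=peak.end)
    complete = (last - peak.end).total_seconds() / 3600.0 >= hi
    return PeakResponseProfile(
        participant_id=series.participant_id,
        peak=peak,
        profile=profile,
        exacerbation=bool(triggers),
        trigger_hours=triggers,
        complete_followup=complete,
        boundary_trigger=any(t in (lo, hi) for t in triggers),
    )


def cohort_peak_responses(
    cohort: Cohort, mode: str = "objective_activity"
) -> pd.DataFrame:
    """Exacerbation flags for every participant with accelerometer data."""
    rows = []
    for pid, epochs in cohort.accel.items():
        series = cohort.participants[pid]
        windows = prompt_windows(epochs, series.schedule)
        try:
            prof = peak_response(series, windows, mode=mode)
        except (UndefinedMetricError, ValueError) as exc:
            rows.append(
                {"participant_id": pid, "exacerbation": None, "note": str(exc)}
            )
            continue
        rows.append(
            {
                "participant_id": pid,
                "exacerbation": prof.exacerbation,
                "n_triggers": len(prof.trigger_hours),
                "first_trigger_h": prof.trigger_hours[0] if prof.trigger_hours else np.nan,
                "peak_value": prof.peak.value,
                "peak_end": prof.peak.end,
                "complete_followup": prof.complete_followup,
                "note": "",
            }
        )
    return pd.DataFrame(rows)


def activity_symptom_correlations(
    series: ParticipantSeries,
    epochs: pd.DataFrame,
    symptoms: tuple[str, ...] = ("fatigue", "overall"),
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Within-person Spearman correlations of each symptom with objective
    activity (preceding 3-h / preceding 1-h / following 3-h mean ENMO)
    and subjective demand (physical item, combined score).

    Low-coverage windows are excluded; requires >= ``min_pairs`` matched
    entry-window pairs per correlate."""
    from .actigraphy import DEFAULT_EPOCH_S, _sorted_arrays, _window_agg

    t_arr, v_arr = _sorted_arrays(epochs)
    sched_hours = {1: 8, 2: 11, 3: 14, 4: 17, 5: 20}
    rows = []
    for r in series.records:
        anchor = r.timestamp.replace(
            hour=sched_hours[r.prompt_slot], minute=0, second=0, microsecond=0
        )
        w_pre3 = _window_agg(t_arr, v_arr, anchor, "preceding", 3.0, DEFAULT_EPOCH_S)
        w_pre1 = _window_agg(t_arr, v_arr, anchor, "preceding", 1.0, DEFAULT_EPOCH_S)
        w_post3 = _window_agg(t_arr, v_arr, anchor, "following", 3.0, DEFAULT_EPOCH_S)
        rows.append(
            {
                **{f"vas_{s}": r.vas[s] for s in symptoms},
                "pre3": w_pre3.mean_enmo if w_pre3.coverage >= coverage_threshold else np.nan,
                "pre1": w_pre1.mean_enmo if w_pre1.coverage >= coverage_threshold else np.nan,
                "post3": w_post3.mean_enmo if w_post3.coverage >= coverage_threshold else np.nan,
                "demand_physical": r.demand["physical"],
                "combined_demand": r.combined_demand,
            }
        )
    df = pd.DataFrame(rows)
    correlates = ("pre3", "pre1", "post3", "demand_physical", "combined_demand")
    out = []
    for s in symptoms:
        for c in correlates:
            sub = df[[f"vas_{s}", c]].dropna()
            if len(sub) < min_pairs:
                rho, p, n = np.nan, np.nan, len(sub)
            else:
                rho, p = spearman(sub[f"vas_{s}"].to_numpy(), sub[c].to_numpy())
                n = len(sub)
            out.append(
                {
                    "participant_id": series.participant_id,
                    "symptom": s,
                    "correlate": c,
                    "rho": rho,
                    "p_value": p,
                    "n": n,
                }
            )
    # the objective-vs-subjective check: physical demand against activity
    sub = df[["demand_physical", "pre3"]].dropna()
    if len(sub) >= min_pairs:
        rho, p = spearman(sub["demand_physical"].to_numpy(), sub["pre3"].to_numpy())
        out.append(
            {
                "participant_id": series.participant_id,
                "symptom": "demand_physical",
                "correlate": "pre3",
                "rho": rho,
                "p_value": p,
                "n": len(sub),
            }
        )
    return pd.DataFrame(out)


def cohort_activity_correlations(cohort: Cohort) -> pd.DataFrame:
    """Pooled per-participant activity-symptom correlations with cohort
    means per (symptom, correlate)."""
    frames = []
    for pid, epochs in cohort.accel.items():
        frames.append(activity_symptom_correlations(cohort.participants[pid], epochs))
    if not frames:
        return pd.DataFrame(
            columns=["participant_id", "symptom", "correlate", "rho", "p_value", "n"]
        )
    return pd.concat(frames, ignore_index=True)
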