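"""Within-person symptom variability: magnitude, dispersion, instability.

Per participant and symptom the diary series is summarised by its mean
(magnitude), range, sample SD (dispersion) and the root mean square of
successive differences, RMSSD (instability). RMSSD relates to the serial
structure of the series: for white noise RMSSD -> SD * sqrt(2), while
positive lag-1 autocorrelation pulls it below that; RMSSD exceeding SD
therefore indicates weak moment-to-moment coupling. A symptom counts as
present for a participant when its median rating is >= 15 on the 0-100
VAS (one point on a 7-item Likert scale). Diurnal trends are tested by
OLS of the rating on the prompt slot (1-5) pooled over days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SYMPTOMS, Cohort, ParticipantSeries

#: median VAS at or above which a symptom counts as present (one point on
#: a 7-item Likert scale)
PRESENCE_THRESHOLD = 15.0


class UndefinedMetricError(ValueError):
    """Metric undefined for this series (too few entries / zero variance)."""


def rmssd(values) -> float:
    """Root mean square of successive differences between consecutive
    completed entries, in chronological order. Requires >= 2 values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise UndefinedMetricError("RMSSD needs at least 2 entries")
    d = np.diff(v)
    return float(np.sqrt(np.mean(d**2)))


@dataclass(frozen=True)
class VariabilitySummary:
    participant_id: str
    symptom: str
    n: int
    mean: float
    vmin: float
    vmax: float
    median: float
    sd: float
    rmssd: float
    above_threshold: bool


def summarize(
    series: ParticipantSeries, symptom: str, *, same_day_rmssd: bool = False
) -> VariabilitySummary:
    """Variability summary over a participant's completed entries.

    SD uses the sample (n-1) denominator. RMSSD by default pairs
    consecutive completed entries even across a missing prompt or the
    overnight gap; ``same_day_rmssd`` restricts pairs to entries on the
    same calendar day."""
    v = series.values(symptom)
    if v.size == 0:
        raise UndefinedMetricError(f"no entries for {symptom}")
    if same_day_rmssd:
        days = np.array([r.timestamp.date() for r in series.records])
        sq, n_pairs = 0.0, 0
        for i in range(1, len(v)):
            if days[i] == days[i - 1]:
                sq += (v[i] - v[i - 1]) ** 2
                n_pairs += 1
        if n_pairs == 0:
            raise UndefinedMetricError("no same-day successive pairs")
        rm = float(np.sqrt(sq / n_pairs))
    else:
        rm = rmssd(v) if v.size >= 2 else float("nan")
    med = float(np.median(v))
    return VariabilitySummary(
        participant_id=series.participant_id,
        symptom=symptom,
        n=int(v.size),
        mean=float(np.mean(v)),
        vmin=float(np.min(v)),
        vmax=float(np.max(v)),
        median=med,
        sd=float(np.std(v, ddof=1)) if v.size >= 2 else float("nan"),
        rmssd=rm,
        above_threshold=med >= PRESENCE_THRESHOLD,
    )


@dataclass(frozen=True)
class DiurnalTrend:
    participant_id: str
    symptom: str
    slope: float  # VAS units per slot
    p_value: float
    classification: str  # increase / decrease / none


def diurnal_trend(
    series: ParticipantSeries, symptom: str, alpha: float = 0.05
) -> DiurnalTrend:
    """OLS regression of the rating on the prompt slot (1-5), pooled over
    days; two-sided slope test. Slots are treated as numeric, being
    evenly spaced 3 h apart."""
    slots = np.array([r.prompt_slot for r in series.records], dtype=float)
    v = series.values(symptom)
    if len(np.unique(slots)) < 2:
        raise UndefinedMetricError("diurnal trend needs >= 2 distinct slots")
    res = stats.linregress(slots, v)
    slope, p = float(res.slope), float(res.pvalue)
    if np.isnan(p):  # zero-variance response: flat, no trend
        slope, p = 0.0, 1.0
    if p < alpha and slope > 0:
        cls = "increase"
    elif p < alpha and slope < 0:
        cls = "decrease"
    else:
        cls = "none"
    return DiurnalTrend(series.participant_id, symptom, slope, p, cls)


def participant_metrics(cohort: Cohort) -> pd.DataFrame:
    """Long frame of per-participant, per-symptom variability summaries."""
    rows = []
    for p in cohort:
        for s in SYMPTOMS:
            sm = summarize(p, s)
            rows.append(
                {
                    "participant_id": sm.participant_id,
                    "symptom": s,
                    "n": sm.n,
                    "mean": sm.mean,
                    "min": sm.vmin,
                    "max": sm.vmax,
                    "median": sm.median,
                    "sd": sm.sd,
                    "rmssd": sm.rmssd,
                    "above_threshold": sm.above_threshold,
                }
            )
    return pd.DataFrame(rows)


def cohort_table(cohort: Cohort) -> pd.DataFrame:
    """Cohort symptom descriptives, one row per symptom: count and % of
    participants above the presence threshold, and the between-person
    median and IQR of the within-person mean, SD and RMSSD."""
    pm = participant_metrics(cohort)
    n_part = pm["participant_id"].nunique()
    rows = []
    for s in SYMPTOMS:
        g = pm[pm["symptom"] == s]
        q = lambda col, p: float(np.percentile(g[col].dropna(), p))
        rows.append(
            {
                "symptom": s,
                "n_above_threshold": int(g["above_threshold"].sum()),
                "pct_above_threshold": 100.0 * g["above_threshold"].mean(),
                "mean_median": float(g["mean"].median()),
                "mean_iqr_lo": q("mean", 25),
                "mean_iqr_hi": q("mean", 75),
                "mean_min": float(g["mean"].min()),
                "mean_max": float(g["mean"].max()),
                "sd_median": float(g["sd"].median()),
                "sd_iqr_lo": q("sd", 25),
                "sd_iqr_hi": q("sd", 75),
                "rmssd_median": float(g["rmssd"].median()),
                "rmssd_iqr_lo": q("rmssd", 25),
                "rmssd_iqr_hi": q("rmssd", 75),
                "n_participants": n_part,
            }
        )
    return pd.DataFrame(rows)


def diurnal_classification_counts(cohort: Cohort, symptom: str) -> dict[str, int]:
    """How many participants show a significant diurnal increase/decrease."""
    counts = {"increase": 0, "decrease": 0, "none": 0}
    for p in cohort:
        try:
            counts[diurnal_trend(p, symptom).classification] += 1
        except UndefinedMetricError:
            counts["none"] += 1
    return counts
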