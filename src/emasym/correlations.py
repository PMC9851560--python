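"""Within-person Spearman correlations between symptom pairs.

A pair is computed for a participant only when the median rating of each
symptom over their completed entries is greater than zero (so rarely
present symptoms do not generate spurious coefficients). Significance is
reported at two thresholds: uncorrected p < .05 and Bonferroni-corrected
for the 28 pairs of the 8-symptom family (p < .05/28 ~ .0018).
Coefficients are binned by absolute value: none [0, .1), weak [.1, .3),
moderate [.3, .5), strong [.5, 1].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SYMPTOMS, Cohort, ParticipantSeries
from .variability import UndefinedMetricError

N_PAIR_FAMILY = len(SYMPTOMS) * (len(SYMPTOMS) - 1) // 2  # 28
BONFERRONI_ALPHA = 0.05 / N_PAIR_FAMILY

STRENGTH_BINS = (("none", 0.0, 0.1), ("weak", 0.1, 0.3), ("moderate", 0.3, 0.5), ("strong", 0.5, 1.0 + 1e-12))


@dataclass(frozen=True)
class CorrelationResult:
    participant_id: str
    symptom_a: str
    symptom_b: str
    included: bool
    n_pairs: int
    rho: float | None
    p_value: float | None
    significant_uncorrected: bool
    significant_bonferroni: bool
    strength: str | None
    sign: str | None
    low_n: bool = False  # included but < 3 joint observations


def classify_strength(rho: float) -> tuple[str, str]:
    """(strength, sign) bin of a correlation coefficient.

    Bins partition |rho| half-open at 0.1/0.3/0.5; sign is "zero" when
    |rho| < 0.1."""
    if not np.isfinite(rho) or abs(rho) > 1 + 1e-12:
        raise ValueError(f"|rho| must be <= 1, got {rho}")
    a = abs(rho)
    for name, lo, hi in STRENGTH_BINS:
        if lo <= a < hi:
            strength = name
            break
    sign = "zero" if a < 0.1 else ("positive" if rho > 0 else "negative")
    return strength, sign


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with mid-rank ties; p by the t approximation on the
    rank correlation, exact permutation for n < 10."""
    n = len(x)
    if n < 10:
        res = stats.spearmanr(x, y)
        rho = float(res.statistic)
        if np.isnan(rho):
            return rho, float("nan")
        perm = stats.permutation_test(
            (x,),
            lambda xs: stats.spearmanr(xs, y).statistic,
            permutation_type="pairings",
            n_resamples=10000 if n > 7 else np.inf,
            alternative="two-sided",
            random_state=0,
        )
        return rho, float(perm.pvalue)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def within_person_rho(
    series: ParticipantSeries, symptom_a: str, symptom_b: str
) -> CorrelationResult:
    """Spearman correlation of one symptom pair within one participant,
    with the median-greater-than-zero inclusion rule."""
    va, vb = series.values(symptom_a), series.values(symptom_b)
    included = bool(np.median(va) > 0 and np.median(vb) > 0)
    base = dict(
        participant_id=series.participant_id,
        symptom_a=symptom_a,
        symptom_b=symptom_b,
        included=included,
        n_pairs=int(min(len(va), len(vb))),
    )
    if not included:
        return CorrelationResult(
            **base, rho=None, p_value=None, significant_uncorrected=False,
            significant_bonferroni=False, strength=None, sign=None,
        )
    if len(va) < 3:
        return CorrelationResult(
            **base, rho=None, p_value=None, significant_uncorrected=False,
            significant_bonferroni=False, strength=None, sign=None, low_n=True,
        )
    rho, p = spearman(va, vb)
    if np.isnan(rho):  # a constant (but nonzero) series: coefficient undefined
        return CorrelationResult(
            **base, rho=None, p_value=None, significant_uncorrected=False,
            significant_bonferroni=False, strength=None, sign=None, low_n=True,
        )
    strength, sign = classify_strength(rho)
    return CorrelationResult(
        **base,
        rho=rho,
        p_value=p,
        significant_uncorrected=bool(p < 0.05),
        significant_bonferroni=bool(p < BONFERRONI_ALPHA),
        strength=strength,
        sign=sign,
    )


def all_pairs(cohort: Cohort) -> pd.DataFrame:
    """Long frame of CorrelationResults for every participant and pair."""
    rows = []
    for p in cohort:
        for a, b in itertools.combinations(SYMPTOMS, 2):
            r = within_person_rho(p, a, b)
            rows.append(vars(r))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairSummary:
    symptom_a: str
    symptom_b: str
    n_reported: int
    mean_rho: float
    bin_counts: dict


def cohort_pair_summary(cohort: Cohort, symptom_a: str, symptom_b: str) -> PairSummary:
    """Distribution of one pair's coefficients over included participants:
    count reported, arithmetic mean rho, and counts per strength bin."""
    rhos = []
    bins = {name: 0 for name, *_ in STRENGTH_BINS}
    for p in cohort:
        r = within_person_rho(p, symptom_a, symptom_b)
        if r.included and r.rho is not None:
            rhos.append(r.rho)
            bins[r.strength] += 1
    return PairSummary(
        symptom_a=symptom_a,
        symptom_b=symptom_b,
        n_reported=len(rhos),
        mean_rho=float(np.mean(rhos)) if rhos else float("nan"),
        bin_counts=bins,
    )


def rho_vs_level(
    cohort: Cohort, symptom_a: str, symptom_b: str
) -> dict[str, tuple[float, float]]:
    """Does a pair's correlation strengthen with symptom level? OLS of
    each included participant's rho on their mean VAS, per symptom of the
    pair; returns {symptom: (slope, p)}."""
    rows = []
    for p in cohort:
        r = within_person_rho(p, symptom_a, symptom_b)
        if r.included and r.rho is not None:
            rows.append(
                (r.rho, float(np.mean(p.values(symptom_a))), float(np.mean(p.values(symptom_b))))
            )
    if len(rows) < 3:
        raise UndefinedMetricError("need >= 3 included participants")
    arr = np.array(rows)
    out = {}
    for j, sym in ((1, symptom_a), (2, symptom_b)):
        if np.ptp(arr[:, j]) == 0 or np.ptp(arr[:, 0]) == 0:
            out[sym] = (0.0, 1.0)
            continue
        res = stats.linregress(arr[:, j], arr[:, 0])
        out[sym] = (float(res.slope), float(res.pvalue))
    return out


def heatmap_matrix(series: ParticipantSeries) -> pd.DataFrame:
    """Symmetric matrix of unadjusted rho over included pairs for one
    participant; excluded pairs are NaN, the diagonal is 1 for symptoms
    with median > 0."""
    mat = pd.DataFrame(np.nan, index=list(SYMPTOMS), columns=list(SYMPTOMS))
    medians = {s: float(np.median(series.values(s))) for s in SYMPTOMS}
    for s in SYMPTOMS:
        if medians[s] > 0:
            mat.loc[s, s] = 1.0
    for a, b in itertools.combinations(SYMPTOMS, 2):
        r = within_person_rho(series, a, b)
        if r.rho is not None:
            mat.loc[a, b] = mat.loc[b, a] = r.rho
    return mat


def strength_distribution(pairs: pd.DataFrame) -> dict:
    """Cohort-wide strength/sign tallies over all reported coefficients
    (input: frame from :func:`all_pairs`)."""
    rep = pairs[pairs["rho"].notna()]
    n = len(rep)
    out = {
        "n_reported": n,
        "strong": int((rep["strength"] == "strong").sum()),
        "moderate": int((rep["strength"] == "moderate").sum()),
        "weak": int((rep["strength"] == "weak").sum()),
        "none": int((rep["strength"] == "none").sum()),
        "negative": int((rep["sign"] == "negative").sum()),
    }
    for k in ("strong", "moderate", "weak", "none", "negative"):
        out[f"pct_{k}"] = 100.0 * out[k] / n if n else float("nan")
    return out
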