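# Methods

This note records the models implemented in `emasym`, their assumptions,
the defaults that matter, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Study design assumptions

The package targets a 14-day EMA protocol with five prompts per day at
fixed clock times (08:00, 11:00, 14:00, 17:00, 20:00), eight 0–100 VAS
symptom items and three 0–3 demand Likerts per entry, plus continuous
wrist accelerometry. Timestamps are time-zone-naive local clock time (a
single-time-zone study). An entry belongs to a prompt slot if it falls in
[scheduled, scheduled + 3 h); later entries are rejected as
slot-inconsistent, and when several raw entries map to one slot the
earliest is kept and the rest reported. Participants with fewer than 35
completed entries (half of the 70 possible) are discarded before any
analysis, as are explicitly listed protocol violators; missing prompts
are never imputed anywhere in the pipeline.

## Variability metrics

Per person and symptom: mean, range, sample SD (n − 1 denominator — the
population/sample choice is not dictated by the design; sample was
chosen and is stated here), and RMSSD over consecutive completed entries.
By default RMSSD pairs span missing prompts and the overnight gap; a
strict same-day mode (`same_day_rmssd=True`) is provided because the
day-boundary rule is only essential for the network analysis, where lags
have a causal reading. A symptom is "present" for a participant when its
median rating is ≥ 15 (one point on a 7-item Likert scale); the
equivalent phrasing "≥ 15 on at least 50% of entries" is the same rule.
Diurnal trend is OLS of the rating on the numeric slot index 1–5 pooled
over days (slots are evenly spaced 3 h apart), two-sided test at α = .05.

## Pairwise correlations

Spearman with mid-rank ties. P-values use the t approximation on the
rank correlation for n ≥ 10 and an exact/pairings permutation test below
that. A pair is included for a participant only when both symptoms have
median > 0 over that participant's entries. The Bonferroni family is
fixed at 28 (8 choose 2) regardless of per-participant inclusion, giving
the single threshold 0.05/28 ≈ .0018. Strength bins partition |ρ|
half-open at 0.1/0.3/0.5 (the printed ranges "0.1 to 0.29" / "0.3–0.49" /
"≥ 0.5" leave boundary values ambiguous; half-open bins make them
well-defined), and negative coefficients are binned by absolute value.

## Graphical VAR

Model: within-person standardized x(t) = B·x(t−1) + e(t),
e(t) ~ N(0, K⁻¹). Standardization uses each participant's own mean and
SD over all completed entries. Lagged pairs are consecutive same-day
completed prompts only. Zero-variance symptoms are dropped from that
participant's individual model with a diagnostic; in the pooled design
the participant's rows are kept with that symptom's deviations set to
zero (a constant series deviates from its own mean by exactly zero), so
a rarely-present symptom does not eject whole participants from the
pooled fit.

Estimation alternates until the joint penalized objective moves by less
than 1e−4 (max 50 iterations):

1. **B step** — coordinate descent on
   tr(S(B)·K) + λ_B·Σ|B_ij|, the precision-weighted L1 regression
   (gradient G = 2(K·B·S_xx − K·S_xy'), curvature 2·K_ii·(S_xx)_jj,
   exact soft-threshold coordinate updates). The precision weighting is
   what makes the alternation meaningful: an unweighted B step would
   never change after its first pass.
2. **K step** — graphical lasso (scikit-learn) on the residual
   covariance with off-diagonal penalty λ_K; a ridge bump with a
   diagnostic if the residual covariance is numerically singular.

Edges are coefficients that are nonzero at the selected penalties — the
package's reading of "statistically significant" edges for this class of
estimator; no separate p-values are computed. Penalty selection minimizes
EBIC = −2·loglik + df·log(n) + 4·γ·df·log(k) with γ = 0.5 (df = nonzero
B entries + upper-triangle nonzero K off-diagonals), over 20 log-spaced
values per penalty from λ_max down to 0.01·λ_max (10 per penalty for
individual fits), ties broken toward larger penalties. Fits are
warm-started along the grid. At λ = 0 and k = 2 the estimator reproduces
closed-form least squares to 1e−6 (tested).

The between-person network is the partial-correlation matrix of
per-participant mean VAS, regularized by EBIC-selected graphical lasso —
the estimator behind a "between-subject network" is not uniquely
determined by the design, and this choice is recorded here. Pooled
temporal edges are reported as the lag-1 coefficients on standardized
data without any further rescaling to directed partial correlations,
which is likewise stated as a choice. When accelerometry is present the
preceding-window mean ENMO can enter as a ninth node, standardized like
a symptom.

## Actigraphy

ENMO = max(0, √(x² + y² + z²) − 1 g)·1000 mg per sample, averaged into
30-s epochs (an intermediate 5-s epoch stage would be an identity for
means over aligned spans and is skipped). Intensity categories:
sedentary [0, 30), light [30, 100], moderate (100, 400], vigorous
(400, ∞) — the boundary values 30/100/400 are resolved so that printed
integer ranges ("30–100", "101–400") remain correct while the partition
is well-defined on continuous ENMO. Windows are half-open 3-h intervals
anchored at scheduled prompts; the 08:00 prompt's preceding window
(05:00–08:00) is computed but flagged pre-daytime, and daytime summaries
use 08:00–20:00 only. "SD of activity" is implemented as the SD of the
3-hourly daytime window means (the alternative, mean of within-window
SDs, is also computed and reported alongside). Bouted MVPA counts epoch
time inside runs of ≥ 10 consecutive minutes all above 100 mg. Raw-signal
gravity calibration and non-wear detection are out of scope: synthetic
signals are calibrated by construction, real input may be supplied as
precomputed ENMO epochs, and a per-window coverage fraction (threshold
0.5, configurable) lets downstream stages exclude sparse windows.

## Post-exertional exacerbation detector

Fatigue and overall unwellness are z-scored within person (whole-series
mean/SD), smoothed by a *trailing* unweighted moving average over the 4
most recent completed entries (the centered/trailing choice is open; the
trailing form is causally interpretable and is the default), stamped at
the latest entry's time, and aligned to the end of the peak 3-h window
("after the peak period" is read from the period's end; configurable).
The MA window spans gaps by default; a strict consecutive-slot mode
exists. A participant is flagged when ≥ 1 MA z ≥ 1.3 (taken as printed,
not 1.2816) for either symptom at a relative time in the closed interval
[12, 60] h; boundary triggers are flagged in the output. The objective
peak is the prompt-preceding window with maximal mean ENMO; the
subjective peak is the entry with maximal combined demand (0–9), ties
broken by the higher objective activity, then by the earlier time.
Participants whose peak falls within 60 h of study end keep their profile
but carry a lowered completeness flag. Multiple or overlapping activity
peaks are out of scope.

## Synthetic cohort generator

The generator is the package's stand-in for the undeposited study data;
its defaults are the study conditions. 74 participants × 14 days × 5
prompts. Person means μ_p ~ N(m, Σ_between) with m = (59, 60, 25, 25,
10, 38, 38, 25) on the VAS scale and between-person SDs of roughly
11–26 mg VAS points with moderate positive correlations (strongest for
overall–fatigue and fatigue–pain). Within a day the latent series is
x(t) = μ_p + B(x(t−1) − μ_p) + e(t): B is diagonal with autocorrelations
0.20–0.36 (anxiety highest) and no cross-lags; K encodes weak
contemporaneous partial correlations (fatigue–cognition 0.21,
fatigue–pain 0.19, … ; overall–fatigue 0.52 so that the *unadjusted*
fatigue–overall correlation lands near 0.57–0.58) with innovation SDs of
4–13.5 VAS points. Each day's opening state is drawn exactly from the
VAR's stationary distribution via the discrete Lyapunov equation —
equivalent in distribution to a long burn-in, and consistent with the
analysis rule that lags never span days. Latent values are clipped to
[0, 100] then rounded half-up; the clipped fraction is reported
(specs with means in [20, 80] and SDs ≤ 15 clip under 5%; the default
cohort clips more because several symptoms genuinely sit near zero for
many people). Missingness is slot-dependent — (0.35, 0.20, 0.20, 0.18,
0.19), first prompt most often skipped — averaging 22.4%, i.e. 77.6%
completion. Entry delays are whole minutes, exponential with mean 15,
capped inside the slot window.

Activity: each 3-h window gets a latent lognormal level around a
per-participant median of ~28 mg (pre-daytime window scaled to a
quarter). Epoch traces put lognormal noise around ¾ of the level plus,
with probability increasing in the level, one continuous 6–22-min bout
at 110–280 mg; nights are ~1.5 mg noise. Demand Likerts are quantile-bins
of noisy copies of their latent drivers (physical ← window activity,
mental ← cognition, emotional ← anxiety); the physical-demand noise ratio
(2.2) was fixed once so that the subjective–objective Spearman lands
near 0.31, and the activity→fatigue/overall coupling (−0.12 innovation-SD
units per SD of log activity) so the fatigue–activity correlation lands
near −0.09 — both are free parameters of the design whose scale the
emulated study only reports as those correlations. The injectable
post-exertional flare bumps fatigue and overall by a configured multiple
of the within-person SD on the first `duration_prompts` completed entries
at or after peak + lag (a flare persists across skipped prompts and the
overnight gap; a pure time-window bump would often hit only one entry and
be invisible to a 4-point moving average).

What the generator does **not** emulate: measurement reactivity,
weekday/weekend structure, non-wear and device artifacts, zero-inflation
beyond clipping, person-level heterogeneity of B and K, and any
activity→symptom dynamics richer than the single contemporaneous
coupling plus injected flares. Passing tests therefore demonstrate that
the estimators recover the structure this class of model generates at
study scale — not that real Long Covid data contain that structure.

## Problem sizes and numerical choices

Recovery and calibration checks run at the scale the design implies
(74 participants, ~78% completion ⇒ ~2,500 pooled lagged pairs); seed
counts per check (10 for edge recovery, 20 for type-I and detector-null
rates) were chosen as the package's own test conditions. The strong-edge
recovery cohort (`recovery_spec`: temporal coefficients ≥ 0.3 on the
diagonal plus two cross-lags, three contemporaneous partial correlations
≥ 0.3) exists because support recovery is only a meaningful criterion
when true edges are comfortably above the EBIC detection floor; the
default cohort's study-magnitude edges (0.1–0.2) sit near that floor by
design. GVAR convergence tolerance is 1e−4 on the joint objective,
coordinate-descent tolerance 1e−7; near-zero precision entries below
1e−6 (relative) are truncated so edge sets are well defined. Degenerate
inputs (constant series, empty windows, singular residual covariance)
signal explicit undefined-metric errors, missing-window flags, or
ridge-stabilized fits with diagnostics rather than propagating NaNs.

## Known limitations

* The pooled GVAR treats all participants as sharing one B and K; the
  per-participant fits are independent, not shrunk toward the pooled
  model (no random-effects multilevel GVAR).
* EBIC with γ = 0.5 at n ≈ 35 pairs is conservative: individual networks
  are sparse and autocorrelation counts at the individual level sit well
  below the pooled values.
* The exacerbation detector analyses a single peak per participant and
  inherits the moving average's 9-hour memory: flares that begin just
  before hour 12 can legitimately trigger inside the window.
* VAS ratings are treated as continuous; integer rounding and clipping
  at the scale ends slightly bias correlations for symptoms near 0.
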