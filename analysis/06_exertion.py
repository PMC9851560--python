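#!/usr/bin/env python
"""Symptom-activity coupling and post-exertional exacerbation detection.

Findings on the default cohort: subjective physical demand tracks
objective activity moderately (mean rho ~ 0.3) while fatigue is only
weakly (negatively) coupled to recent activity — and a small fraction of
participants show a delayed moving-average z >= 1.3 for fatigue or
overall unwellness 12-60 h after their single most active 3-h window.
A positive-control cohort with injected 2-SD delayed bumps verifies the
detector fires when a true flare is present.
"""

import sys
from pathlib import Path

from emasym import exertion, synthetic

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
RESULTS = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    spec = synthetic.CohortSpec(seed=SEED)
    cohort, _ = synthetic.generate_cohort(spec, synthetic.AccelSpec(seed=SEED))

    corrs = exertion.cohort_activity_correlations(cohort)
    corrs.to_csv(RESULTS / "activity_correlations.csv", index=False)
    means = corrs.groupby(["symptom", "correlate"])["rho"].mean()
    print("mean within-person correlations with objective/subjective activity:")
    print(means.round(3).to_string())

    flags = exertion.cohort_peak_responses(cohort)
    flags.to_csv(RESULTS / "exacerbation_flags.csv", index=False)
    n_flag = int(flags["exacerbation"].sum())
    print(
        f"\npost-exertional exacerbation: {n_flag}/{len(flags)} participants "
        f"({100 * n_flag / len(flags):.1f}%) flagged without any injection"
    )

    inj = synthetic.PemInjection(
        targets=list(cohort.participants)[:10], lag_hours=24.0, amplitude_sd=2.0
    )
    bumped = synthetic.inject_pem(cohort, inj)
    bflags = exertion.cohort_peak_responses(bumped).set_index("participant_id")
    hit = sum(bool(bflags.loc[pid, "exacerbation"]) for pid in inj.targets)
    print(
        f"positive control: {hit}/{len(inj.targets)} injected participants "
        f"flagged (2-SD bump at +24 h)"
    )


if __name__ == "__main__":
    main()
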