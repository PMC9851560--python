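"""End-to-end pipeline orchestration with a validated config and a
deterministic artifact bundle.

Stages: data load or synthetic generation -> completion filter ->
variability descriptives -> pairwise correlations -> GVAR networks ->
actigraphy summaries -> exertion-response analysis. Every artifact is a
CSV/JSON file under the output directory; a manifest records the config
hash, seed, package versions and artifact checksums, so identical
config + seed reproduces identical artifacts byte for byte (wall-clock
stage timings go to a separate run log, not the manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .data_model import (
    SYMPTOMS,
    Cohort,
    completion_stats,
    load_ema,
    validate_and_filter,
    write_ema,
)
from . import actigraphy, correlations, exertion, gvar, synthetic, variability

log = logging.getLogger("emasym.pipeline")


class SyntheticConfig(BaseModel):
    enabled: bool = True
    n_participants: int = 74
    n_days: int = 14
    seed: int = Field(default=1, description="mandatory for synthetic runs")
    preset: str = "default"  # default | independence | recovery
    generate_accel: bool = True
    inject_pem_targets: list[str] = []
    inject_lag_hours: float = 24.0
    inject_amplitude_sd: float = 2.0
    inject_duration_prompts: int = 4


class StageToggles(BaseModel):
    variability: bool = True
    correlations: bool = True
    networks: bool = True
    actigraphy: bool = True
    exertion: bool = True


class PipelineConfig(BaseModel):
    """All tunables with their study defaults."""

    ema_csv: str | None = None
    accel_csv: str | None = None
    synthetic: SyntheticConfig = SyntheticConfig()
    stages: StageToggles = StageToggles()
    min_entries: int = 35
    manual_exclusions: list[str] = []
    presence_threshold: float = 15.0
    ebic_gamma: float = 0.5
    pooled_n_lambda: int = 20
    individual_n_lambda: int = 10
    min_lagged_pairs: int = 10
    fit_individual_networks: bool = True
    include_activity_node: bool = False
    z_threshold: float = 1.3
    detection_window_h: tuple[float, float] = (12.0, 60.0)
    coverage_threshold: float = 0.5
    outdir: str = "results/run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Hash over every parameter that affects numbers (the output
        directory is excluded: it only relocates artifacts)."""
        d = self.model_dump()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _spec_for(cfg: SyntheticConfig) -> synthetic.CohortSpec:
    kw = dict(n_participants=cfg.n_participants, n_days=cfg.n_days, seed=cfg.seed)
    if cfg.preset == "independence":
        return synthetic.independence_spec(**kw)
    if cfg.preset == "recovery":
        return synthetic.recovery_spec(**kw)
    return synthetic.CohortSpec(**kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _acquire_data(config: PipelineConfig, outdir: Path) -> tuple[Cohort, dict | None]:
    truth_json = None
    if config.synthetic.enabled:
        spec = _spec_for(config.synthetic)
        accel_spec = (
            synthetic.AccelSpec(seed=config.synthetic.seed)
            if config.synthetic.generate_accel
            else None
        )
        injection = None
        if config.synthetic.inject_pem_targets:
            injection = synthetic.PemInjection(
                targets=config.synthetic.inject_pem_targets,
                lag_hours=config.synthetic.inject_lag_hours,
                amplitude_sd=config.synthetic.inject_amplitude_sd,
                duration_prompts=config.synthetic.inject_duration_prompts,
            )
        cohort, truth = synthetic.generate_cohort(spec, accel_spec, injection)
        truth_json = truth.to_json_dict()
        write_ema(cohort, outdir / "ema.csv")
    else:
        if not config.ema_csv:
            raise ValueError("either synthetic.enabled or ema_csv must be set")
        cohort = load_ema(config.ema_csv)
        if config.accel_csv:
            cohort.accel = actigraphy.load_accel(config.accel_csv)
    return cohort, truth_json


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    artifacts: list[Path] = []

    def stage(name):
        log.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    s = stage("acquire")
    cohort, truth_json = _acquire_data(config, outdir)
    if truth_json is not None:
        (outdir / "ground_truth.json").write_text(json.dumps(truth_json, indent=1))
        artifacts.append(outdir / "ground_truth.json")
    if (outdir / "ema.csv").exists():
        artifacts.append(outdir / "ema.csv")
    done(s)

    s = stage("filter")
    cohort, report = validate_and_filter(
        cohort, config.min_entries, config.manual_exclusions
    )
    report.excluded.to_csv(outdir / "exclusions.csv", index=False)
    artifacts.append(outdir / "exclusions.csv")
    stats = completion_stats(cohort)
    (outdir / "completion.json").write_text(
        json.dumps(
            {
                "total_entries": stats.total_entries,
                "n_participants": stats.n_participants,
                "pct_of_possible": round(stats.pct_of_possible, 2),
                "per_slot_counts": stats.per_slot_counts,
                "median_per_participant": stats.median_per_participant,
                "person_days": stats.person_days,
            },
            indent=1,
        )
    )
    artifacts.append(outdir / "completion.json")
    done(s)

    bundle: dict = {"completion": stats, "skipped": []}

    if config.stages.variability:
        s = stage("variability")
        pm = variability.participant_metrics(cohort)
        pm.to_csv(outdir / "participant_metrics.csv", index=False)
        tbl = variability.cohort_table(cohort)
        tbl.to_csv(outdir / "symptom_table.csv", index=False)
        diurnal = pd.DataFrame(
            [
                {"symptom": sym, **variability.diurnal_classification_counts(cohort, sym)}
                for sym in SYMPTOMS
            ]
        )
        diurnal.to_csv(outdir / "diurnal_trends.csv", index=False)
        artifacts += [
            outdir / "participant_metrics.csv",
            outdir / "symptom_table.csv",
            outdir / "diurnal_trends.csv",
        ]
        bundle["symptom_table"] = tbl
        done(s)
    else:
        bundle["skipped"].append("variability")

    if config.stages.correlations:
        s = stage("correlations")
        pairs = correlations.all_pairs(cohort)
        pairs.to_csv(outdir / "pairwise_correlations.csv", index=False)
        dist = correlations.strength_distribution(pairs)
        (outdir / "correlation_distribution.json").write_text(
            json.dumps(dist, indent=1)
        )
        artifacts += [
            outdir / "pairwise_correlations.csv",
            outdir / "correlation_distribution.json",
        ]
        bundle["pairs"] = pairs
        bundle["correlation_distribution"] = dist
        done(s)
    else:
        bundle["skipped"].append("correlations")

    if config.stages.networks:
        s = stage("networks")
        activity_map = None
        variables: tuple[str, ...] = SYMPTOMS
        if config.include_activity_node and cohort.accel:
            activity_map = {}
            for pid, epochs in cohort.accel.items():
                w = actigraphy.prompt_windows(
                    epochs, cohort.participants[pid].schedule
                )
                activity_map[pid] = pd.Series(
                    w["mean_enmo"].to_numpy(), index=pd.to_datetime(w["anchor"])
                )
            variables = SYMPTOMS + ("activity",)
        nets = gvar.pooled_networks(
            cohort,
            variables,
            activity_by_participant=activity_map,
            gamma=config.ebic_gamma,
            pooled_n_lambda=config.pooled_n_lambda,
            individual_n_lambda=config.individual_n_lambda,
            min_pairs=config.min_lagged_pairs,
            fit_individuals=config.fit_individual_networks,
        )
        nets.edge_list().to_csv(outdir / "network_edges.csv", index=False)
        (outdir / "networks.json").write_text(
            json.dumps(
                {
                    "variables": list(nets.variables),
                    "between": nets.between.tolist(),
                    "contemporaneous": nets.contemporaneous.tolist(),
                    "temporal": nets.temporal.tolist(),
                },
                indent=1,
            )
        )
        ap = gvar.autocorrelation_profile(nets)
        ap.to_csv(outdir / "autocorrelations.csv", index=False)
        artifacts += [
            outdir / "network_edges.csv",
            outdir / "networks.json",
            outdir / "autocorrelations.csv",
        ]
        bundle["networks"] = nets
        done(s)
    else:
        bundle["skipped"].append("networks")

    if config.stages.actigraphy and cohort.accel:
        s = stage("actigraphy")
        tbl3 = actigraphy.cohort_activity_table(cohort.accel)
        tbl3.to_csv(outdir / "activity_summary.csv", index=False)
        artifacts.append(outdir / "activity_summary.csv")
        bundle["activity_summary"] = tbl3
        done(s)
    else:
        bundle["skipped"].append("actigraphy")

    if config.stages.exertion and cohort.accel:
        s = stage("exertion")
        flags = exertion.cohort_peak_responses(cohort)
        flags.to_csv(outdir / "exacerbation_flags.csv", index=False)
        corrs = exertion.cohort_activity_correlations(cohort)
        corrs.to_csv(outdir / "activity_correlations.csv", index=False)
        summ = (
            corrs.groupby(["symptom", "correlate"])["rho"].mean().reset_index()
            if len(corrs)
            else pd.DataFrame(columns=["symptom", "correlate", "rho"])
        )
        summ.to_csv(outdir / "activity_correlation_means.csv", index=False)
        artifacts += [
            outdir / "exacerbation_flags.csv",
            outdir / "activity_correlations.csv",
            outdir / "activity_correlation_means.csv",
        ]
        bundle["exacerbation_flags"] = flags
        bundle["activity_correlation_means"] = summ
        done(s)
    else:
        bundle["skipped"].append("exertion")

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.model_dump(mode="json"),
        "config_hash": config.config_hash(),
        "seed": config.synthetic.seed if config.synthetic.enabled else None,
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
        "stages_skipped": bundle["skipped"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (outdir / "run_log.json").write_text(
        json.dumps({"timings_s": {k: round(v, 3) for k, v in timings.items()}}, indent=1)
    )
    bundle["manifest"] = manifest
    return bundle


def write_report(bundle: dict, path) -> str:
    """Human-readable markdown summary of a pipeline bundle. Pure: no
    recomputation, only formatting of what the bundle already holds."""
    lines = ["# EMA symptom-dynamics pipeline report", ""]
    stats = bundle["completion"]
    lines += [
        "## Completion",
        f"- participants analysed: {stats.n_participants}",
        f"- diary entries: {stats.total_entries} "
        f"({stats.pct_of_possible:.1f}% of possible)",
        f"- median entries per participant: {stats.median_per_participant:.1f}",
        "",
    ]
    skipped = set(bundle.get("skipped", []))

    lines.append("## Symptom variability")
    if "symptom_table" in bundle:
        t = bundle["symptom_table"]
        for _, r in t.iterrows():
            lines.append(
                f"- {r['symptom']}: {r['n_above_threshold']} above threshold "
                f"({r['pct_above_threshold']:.1f}%), median mean VAS "
                f"{r['mean_median']:.0f}, median SD {r['sd_median']:.1f}, "
                f"median RMSSD {r['rmssd_median']:.1f}"
            )
    else:
        lines.append("- skipped")
    lines.append("")

    lines.append("## Pairwise correlations")
    if "correlation_distribution" in bundle:
        d = bundle["correlation_distribution"]
        lines.append(
            f"- {d['n_reported']} coefficients reported: "
            f"{d['pct_strong']:.1f}% strong, {d['pct_moderate']:.1f}% moderate, "
            f"{d['pct_weak']:.1f}% weak, {d['pct_none']:.1f}% none; "
            f"{d['pct_negative']:.1f}% negative"
        )
    else:
        lines.append("- skipped")
    lines.append("")

    lines.append("## Networks")
    if "networks" in bundle:
        nets = bundle["networks"]
        el = nets.edge_list()
        for net in ("between", "contemporaneous", "temporal"):
            n = len(el[(el["network_type"] == net) & (el["participant_id"].isin(["pooled", "between"]))])
            lines.append(f"- {net} network edges (pooled): {n}")
        lines.append(f"- individual models fitted: {len(nets.individual)}")
    else:
        lines.append("- skipped")
    lines.append("")

    lines.append("## Actigraphy")
    if "activity_summary" in bundle:
        t = bundle["activity_summary"]
        lines.append(
            f"- {len(t)} participants; median daytime ENMO "
            f"{t['mean_daytime_enmo'].median():.1f} mg; median bouted MVPA "
            f"{t['mvpa_bouted_min_per_week'].median():.0f} min/week"
        )
    else:
        lines.append("- skipped")
    lines.append("")

    lines.append("## Post-exertional exacerbation")
    if "exacerbation_flags" in bundle:
        f = bundle["exacerbation_flags"]
        flagged = f["exacerbation"].fillna(False).astype(bool)
        lines.append(
            f"- {int(flagged.sum())} of {len(f)} participants flagged "
            f"({100 * flagged.mean():.1f}%)"
        )
    else:
        lines.append("- skipped")
    lines.append("")
    lines.append(f"Config hash: {bundle['manifest']['config_hash']}")
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text
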