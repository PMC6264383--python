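"""End-to-end orchestration: simulate -> feedback -> GLM -> group stats.

`run_full_study` reproduces the whole analysis chain on a simulated
cohort and emits the group-level report: localizer calibration per
subject, online feedback traces, per-run offline PSC estimates, median
aggregation, the 2x2 repeated-measures ANOVAs, the directed t-tests and
informed Bayes factors, and the physiological-confound table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .feedback import Calibration, run_feedback_engine
from .glm import (
    build_localizer_design_matrix,
    build_nf_design_matrix,
    extract_psc,
    fit_glm_prewhitened,
    localizer_psc,
)
from .protocol import LEVELS, REGIONS
from .simulate import Cohort, SubjectSimParams, simulate_cohort
from .stats import (
    aggregate_median_psc,
    derive_prior_scale,
    informed_bayes_t,
    one_sample_t,
    paired_t,
    physio_task_analysis,
    rm_anova_2x2,
    run_difference_trend,
)

#: prior-scale fractions used for the informed Bayesian t-tests
M1_PRIOR_FRACTION = 0.75  # of the group M1 localizer PSC
SMA_PRIOR_FRACTION = 0.50  # of the group SMA localizer PSC (the low/high spacing)


@dataclass
class PipelineConfig:
    """Configuration of a full simulated study run."""

    n_subjects: int = 17
    seed: int = 0
    n_runs_per_region: int = 5
    noise_sd: float = 6.0
    ar1_rho: float = 0.3
    between_subject_sd: float = 0.25
    level_sd: float = 0.08
    rounding: str = "nearest"
    window: str = "causal"
    corrector: str = "fdr"
    write_traces: bool = False
    outdir: str | None = None

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def calibrate_subject(subject, cohort: Cohort) -> dict[str, float]:
    """Per-region localizer PSC for one subject (offline localizer GLM)."""
    X = build_localizer_design_matrix(subject.plan.localizer, cohort.hrf)
    return {
        region: localizer_psc(fit_glm_prewhitened(subject.localizer.roi[region], X))
        for region in REGIONS
    }


def analyze_cohort(cohort: Cohort, window: str = "causal", rounding: str = "nearest"):
    """Run calibration, online feedback and offline GLM over a whole cohort.

    Returns ``(psc_table, loc_table, traces)``: per-run PSC estimates for
    both regions, per-subject localizer PSCs, and the online feedback
    traces keyed by (subject, run_id).
    """
    psc_rows = []
    loc_rows = []
    traces = {}
    for subject in cohort.subjects:
        sid = subject.plan.subject_id
        psc_loc = calibrate_subject(subject, cohort)
        for region in REGIONS:
            loc_rows.append({"subject": sid, "region": region, "psc_loc": psc_loc[region]})
        for run in subject.nf_runs:
            calib = Calibration(psc_loc, run.target_region)
            traces[(sid, run.run_id)] = run_feedback_engine(
                run.roi[run.target_region], run.design, calib,
                cohort.protocol, rounding=rounding, window=window,
            )
            X = build_nf_design_matrix(run.design, cohort.hrf)
            for region in REGIONS:
                fit = fit_glm_prewhitened(run.roi[region], X)
                condition = "active" if region == run.target_region else "passive"
                for level in LEVELS:
                    est = extract_psc(
                        fit, X, level,
                        region=region, condition=condition,
                        run_id=run.run_id, subject=sid,
                    )
                    psc_rows.append(vars(est))
    return pd.DataFrame(psc_rows), pd.DataFrame(loc_rows), traces


def _physio_records(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for subject in cohort.subjects:
        for run in subject.nf_runs:
            for kind, trace in run.physio.items():
                rows.append(
                    {
                        "subject": subject.plan.subject_id,
                        "region": run.target_region,
                        "kind": kind,
                        "values": trace.values,
                    }
                )
    return pd.DataFrame(rows)


def group_report(cohort: Cohort, psc_table: pd.DataFrame, loc_table: pd.DataFrame,
                 corrector: str = "fdr") -> dict:
    """Group-level statistics mirroring the study's results layout."""
    group = aggregate_median_psc(psc_table)
    loc_means = loc_table.groupby("region")["psc_loc"].mean()

    report: dict[str, Any] = {
        "localizer_psc_group_mean": loc_means.to_dict(),
        "anova": {},
        "t_tests": {},
        "bayes": {},
        "run_trend": {},
    }

    wide = group.pivot_table(
        index="subject", columns=["region", "condition", "level"], values="median_psc"
    )
    for region in REGIONS:
        report["anova"][region] = [
            vars(e) for e in rm_anova_2x2(group, region)
        ]
        report["run_trend"][region] = vars(run_difference_trend(psc_table, region))

    # SMA level effect, pooled across feedback conditions (directed high > low)
    sma_high = wide[[("SMA", c, "high") for c in ("active", "passive")]].mean(axis=1)
    sma_low = wide[[("SMA", c, "low") for c in ("active", "passive")]].mean(axis=1)
    t_level = paired_t(sma_high.to_numpy(), sma_low.to_numpy(), side="greater")
    report["t_tests"]["SMA_level_high_gt_low"] = vars(t_level)

    # M1 deactivation per condition (directed less than zero), levels averaged
    m1_tests = {}
    for condition in ("active", "passive"):
        m1 = wide[[("M1", condition, lev) for lev in LEVELS]].mean(axis=1)
        m1_tests[condition] = one_sample_t(m1.to_numpy(), side="less")
        report["t_tests"][f"M1_{condition}_deactivation"] = vars(m1_tests[condition])

    # informed Bayesian t-tests with localizer-derived prior scales
    scale_m1 = derive_prior_scale(float(loc_means["M1"]), M1_PRIOR_FRACTION)
    scale_sma = derive_prior_scale(float(loc_means["SMA"]), SMA_PRIOR_FRACTION)
    n = len(cohort.subjects)
    report["bayes"]["prior_scales"] = {"M1": scale_m1, "SMA": scale_sma}
    report["bayes"]["SMA_level_high_gt_low"] = vars(
        informed_bayes_t(t_level.t, n, scale_sma, side="greater")
    )
    for condition, res in m1_tests.items():
        report["bayes"][f"M1_{condition}_deactivation"] = vars(
            informed_bayes_t(res.t, n, scale_m1, side="less")
        )

    # physiological confound table
    design = cohort.subjects[0].nf_runs[0].design
    physio = physio_task_analysis(
        _physio_records(cohort), design, cohort.hrf, corrector=corrector
    )
    report["physio"] = [vars(r) for r in physio]
    report["corrector"] = corrector
    return report


def run_full_study(config: PipelineConfig) -> dict:
    """Simulate a cohort and run the full analysis chain.

    Returns a report bundle (dict); when ``config.outdir`` is set, writes
    the PSC table, group table, report JSON and a provenance manifest.
    """
    template = SubjectSimParams(noise_sd=config.noise_sd, ar1_rho=config.ar1_rho)
    cohort = simulate_cohort(
        n_subjects=config.n_subjects,
        template=template,
        between_subject_sd=config.between_subject_sd,
        seed=config.seed,
        level_sd=config.level_sd,
        n_runs_per_region=config.n_runs_per_region,
    )
    psc_table, loc_table, traces = analyze_cohort(
        cohort, window=config.window, rounding=config.rounding
    )
    report = group_report(cohort, psc_table, loc_table, corrector=config.corrector)
    bundle = {
        "config": config.to_dict(),
        "report": report,
        "psc_table": psc_table,
        "loc_table": loc_table,
    }
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        psc_table.to_csv(outdir / "psc_table.csv", index=False)
        loc_table.to_csv(outdir / "localizer_psc.csv", index=False)
        aggregate_median_psc(psc_table).to_csv(outdir / "group_table.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=_jsonify))
        if config.write_traces:
            tdir = outdir / "traces"
            tdir.mkdir(exist_ok=True)
            for (sid, run_id), trace in traces.items():
                trace.to_frame().to_csv(tdir / f"{sid}_{run_id}_feedback.csv", index=False)
        manifest = {
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "package_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def make_fixtures(seed: int = 0) -> Cohort:
    """Miniature cohort for tests and docs: 3 subjects, 2 NF runs per region."""
    return simulate_cohort(
        n_subjects=3, seed=seed, n_runs_per_region=2
    )
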