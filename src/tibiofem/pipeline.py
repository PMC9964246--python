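"""End-to-end study pipeline: cohort -> contact solve -> failure curves ->
group statistics, with deterministic seeding and CSV/JSON export.

A single study seed fans out through ``numpy.random.SeedSequence`` into one
child seed per group, so each stage can be re-run in isolation and two runs
with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as tstats
from .cohort import G, cohort_frame, generate_cohort, waveform_frame
from .config import StudyConfig
from .contact import build_element_grid, solve_contact
from .failure import participant_failure

log = logging.getLogger("tibiofem")

#: outcomes contrasted between groups, mirroring the study's result tables
CONTRAST_OUTCOMES = [
    "peak_force_bw",
    "peak_force_n",
    "cumulative_load_bw_m",
    "cumulative_load_n_m",
    "vastus_intermedius_bw",
    "vastus_lateralis_bw",
    "vastus_medialis_bw",
    "vastus_intermedius_n",
    "vastus_lateralis_n",
    "vastus_medialis_n",
    "peak_stress_mpa",
    "peak_strain",
    "p_fail_pct",
    "p_fail_repair_pct",
]

REGRESSION_OUTCOMES = ["peak_force_n", "peak_stress_mpa", "peak_strain"]


@dataclass
class StudyReport:
    participants: pd.DataFrame  # one row per participant, all outcomes
    summaries: pd.DataFrame  # group x outcome: mean, sd, ci
    comparisons: dict[str, tstats.GroupComparison]
    regressions: dict[str, dict[str, tstats.RegressionResult]]
    curves: dict[str, pd.DataFrame]  # group -> averaged failure curves
    config: StudyConfig
    seed_children: dict[str, int]


def run_full_study(config: StudyConfig) -> StudyReport:
    config.validate()
    root = np.random.SeedSequence(config.seed)
    child_h, child_o = root.spawn(2)
    grid = build_element_grid(config.geometry)

    frames, curve_means = [], {}
    for spec, child in ((config.healthy, child_h), (config.obese, child_o)):
        profiles = generate_cohort(spec, child)
        rows, curves = [], []
        for p in profiles:
            try:
                sol = solve_contact(
                    grid, config.geometry, p.peak_force_n, p.flexion_at_peak
                )
                curve = participant_failure(p, sol, config.failure)
            except (RuntimeError, ValueError) as exc:
                raise RuntimeError(
                    f"participant {p.id}: contact/failure stage failed: {exc}"
                ) from exc
            rows.append(
                {
                    "peak_stress_mpa": sol.peak_stress,
                    "peak_strain": sol.peak_strain,
                    "contact_area_mm2": sol.contact_area,
                    "stressed_volume_mm3": sol.stressed_volume,
                    "penetration_mm": sol.penetration,
                    "t_fail_years": curve.t_fail,
                    "p_fail_pct": 100.0 * curve.p_fail[-1],
                    "p_fail_repair_pct": 100.0 * curve.p_fail_repair[-1],
                    "cumulative_load_n_m": tstats.cumulative_load(
                        p.stance_waveform, p.stride_length
                    ),
                }
            )
            curves.append(curve)
        mech = pd.DataFrame(rows)
        frame = pd.concat([cohort_frame(profiles), mech], axis=1)
        frame["cumulative_load_bw_m"] = frame["cumulative_load_n_m"] / (
            frame["mass_kg"] * G
        )
        frames.append(frame)
        curve_means[spec.label] = pd.DataFrame(
            {
                "time_years": curves[0].times,
                "p_fail": np.mean([c.p_fail for c in curves], axis=0),
                "p_fail_repair": np.mean([c.p_fail_repair for c in curves], axis=0),
            }
        )
        curve_means[spec.label + "_waveforms"] = profiles  # kept for export

    participants = pd.concat(frames, ignore_index=True)

    # group statistics need at least two members per group; single-member
    # groups still get per-participant outputs and averaged curves
    group_sizes = participants.groupby("group").size()
    stats_possible = bool((group_sizes >= 2).all())
    summaries = []
    if stats_possible:
        for outcome in CONTRAST_OUTCOMES:
            for label, sub in participants.groupby("group"):
                s = tstats.summarize(sub[outcome])
                summaries.append(
                    {
                        "outcome": outcome, "group": label, "n": s["n"],
                        "mean": s["mean"], "sd": s["sd"],
                        "ci95_lower": s["ci95"][0], "ci95_upper": s["ci95"][1],
                    }
                )
    summaries = pd.DataFrame(summaries)

    comparisons = (
        {
            outcome: tstats.group_compare(
                participants[outcome], participants["group"],
                reference="healthy_weight",
            )
            for outcome in CONTRAST_OUTCOMES
        }
        if stats_possible
        else {}
    )
    regressions = {
        label: {
            outcome: tstats.regress(sub["bmi"], sub[outcome])
            for outcome in REGRESSION_OUTCOMES
        }
        for label, sub in participants.groupby("group")
        if len(sub) >= 3 and np.ptp(sub["bmi"]) > 0
    }

    profiles_by_group = {
        k.removesuffix("_waveforms"): v
        for k, v in curve_means.items()
        if k.endswith("_waveforms")
    }
    curves = {k: v for k, v in curve_means.items() if not k.endswith("_waveforms")}
    report = StudyReport(
        participants=participants,
        summaries=summaries,
        comparisons=comparisons,
        regressions=regressions,
        curves=curves,
        config=config,
        seed_children={
            "healthy_weight": int(child_h.generate_state(1)[0]),
            "obese": int(child_o.generate_state(1)[0]),
        },
    )
    report._profiles = profiles_by_group  # used by write_report for waveforms
    return report


# -- export ----------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # round-trip fidelity


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def export_failure_curves(report: StudyReport, out_dir: str | Path) -> list[Path]:
    """Group-averaged with/without-repair curves, one CSV per group."""
    if not report.curves:
        raise ValueError("report contains no failure curves")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, frame in report.curves.items():
        path = out / f"failure_curve_{label}.csv"
        _write_csv(frame, path)
        paths.append(path)
    return paths


def _comparison_record(c: tstats.GroupComparison) -> dict:
    return {
        "b": c.b, "se": c.se, "t": c.t, "df": c.df,
        "ci95": list(c.ci95), "p": c.p, "groups": list(c.groups),
    }


def write_report(report: StudyReport, out_dir: str | Path | None = None) -> Path:
    """Write all study outputs; returns the output directory."""
    out = Path(out_dir if out_dir is not None else report.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    _write_csv(report.participants, out / "participants.csv")
    _write_csv(report.summaries, out / "group_summaries.csv")
    export_failure_curves(report, out)
    if report.config.write_waveforms:
        for label, profiles in getattr(report, "_profiles", {}).items():
            _write_csv(waveform_frame(profiles), out / f"waveforms_{label}.csv")

    results = {
        "comparisons": {
            k: _comparison_record(v) for k, v in report.comparisons.items()
        },
        "regressions": {
            g: {k: dataclasses.asdict(v) for k, v in d.items()}
            for g, d in report.regressions.items()
        },
    }
    (out / "statistics.json").write_text(json.dumps(results, indent=2))

    config_dict = report.config.to_dict()
    config_blob = json.dumps(config_dict, sort_keys=True).encode()
    provenance = {
        "seed": report.config.seed,
        "seed_children": report.seed_children,
        "config_sha256": hashlib.sha256(config_blob).hexdigest(),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    (out / "run_log.json").write_text(
        json.dumps({"provenance": provenance, "config": config_dict}, indent=2)
    )
    log.info("study report written to %s", out)
    return out
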