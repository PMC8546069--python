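"""Pipeline orchestration: simulate -> process -> link -> fit -> report.

Each stage reads and writes plain CSV/JSON in the run directory, so any
stage can be rerun or audited in isolation; a manifest records the
config snapshot, seed, stage timings and output digests.  Every record
is accounted for: a directed pair either yields an included estimate or
an exclusion reason, and the report reconciles those counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ConfigurationError, StudyConfig
from .ibi import baseline_reference, compute_reactivity, flag_artifacts, segment_minutes
from .linkage import estimate_linkage_table, screen_outliers
from .mixedmodel import (
    build_model_frame,
    fit_crossclassified,
    linear_trend_by_condition,
    simple_effects_by_session,
    test_effect,
)
from .synthetic import default_truth, generate_roster, simulate_study

MAIN_EFFECT_TERMS = [
    "drug", "receiver_role", "sender_role", "session",
    "drug:session", "receiver_role:session", "sender_role:session",
    "receiver_role:sender_role",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(
    config: StudyConfig | dict | None = None,
    mode: str = "synthetic",
    outdir: str | Path = "run",
    seed: int | None = None,
    minutes_csv: str | Path | None = None,
    beats_csv: str | Path | None = None,
    roster_csv: str | Path | None = None,
    strict_baseline: bool = False,
    outlier_mode: str = "exclude",
    df_method: str = "satterthwaite",
    truth_overrides: dict | None = None,
) -> Path:
    """Run the full analysis; returns the output directory.

    Synthetic mode generates the study from ``config``; real mode reads
    a minute-level CSV (or a beat CSV, which is artifact-flagged and
    segmented first) plus a roster CSV with the same schemas the
    synthetic writer emits.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    if config is None:
        config = StudyConfig()
    elif isinstance(config, dict):
        config = StudyConfig.from_dict(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))

    if mode == "synthetic":
        roster = generate_roster(config)
        truth = default_truth(config, roster, **(truth_overrides or {}))
        study = simulate_study(config, truth=truth, roster=roster)
        minutes = study.minutes
        _write_csv(roster, out / "roster.csv")
        _write_csv(minutes, out / "minutes.csv")
        (out / "truth.json").write_text(truth.to_json())
    elif mode == "real":
        if roster_csv is None:
            raise ConfigurationError("real mode requires a roster CSV")
        roster = pd.read_csv(roster_csv)
        need = {"person_id", "cohort_id", "role", "drug_condition"}
        if not need.issubset(roster.columns):
            raise ConfigurationError(
                f"roster CSV must have columns {sorted(need)}"
            )
        if minutes_csv is not None:
            minutes = pd.read_csv(minutes_csv)
        elif beats_csv is not None:
            from .ibi import read_beat_csv

            beats = read_beat_csv(beats_csv)
            flagged = flag_artifacts(beats)
            parts = []
            for (sess, win), grp in flagged.groupby(["session", "window"]):
                length = (
                    config.baseline_length_min
                    if win == "baseline"
                    else config.session_lengths_min[int(sess) - 1]
                )
                seg = segment_minutes(grp, length)
                seg["session"], seg["window"] = sess, win
                parts.append(seg)
            minutes = pd.concat(parts, ignore_index=True)
        else:
            raise ConfigurationError("real mode requires minutes or beats CSV")
        if "window" not in minutes.columns:
            raise ConfigurationError("minute CSV must mark baseline vs session rows")
        _write_csv(minutes, out / "minutes.csv")
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    timings["simulate" if mode == "synthetic" else "ingest"] = (
        time.perf_counter() - t0
    )

    # --- process: baseline reference and reactivity -----------------------
    t0 = time.perf_counter()
    base = minutes[minutes["window"] == "baseline"]
    sess = minutes[minutes["window"] == "session"]
    refs, excl = baseline_reference(base, strict=strict_baseline)
    reactivity = compute_reactivity(sess, refs)
    _write_csv(reactivity, out / "reactivity.csv")
    _write_csv(excl, out / "baseline_exclusions.csv")
    timings["process"] = time.perf_counter() - t0

    # --- link: directed pairwise estimates --------------------------------
    t0 = time.perf_counter()
    session_lengths = {
        s + 1: config.session_lengths_min[s] for s in range(config.n_sessions)
    }
    table = estimate_linkage_table(reactivity, roster, session_lengths)
    table = screen_outliers(table, mode=outlier_mode)
    _write_csv(table, out / "linkage.csv")
    timings["link"] = time.perf_counter() - t0

    # --- fit: cross-classified mixed model --------------------------------
    t0 = time.perf_counter()
    frame = build_model_frame(table)
    fit = fit_crossclassified(frame)
    report = {
        "n_estimates": int(frame.n),
        "converged": fit.converged,
        "variance_components": fit.variance_components,
        "boundary": fit.boundary,
        "fixed_effects": fit.fixed_effects.to_dict(orient="records"),
        "tests": {},
        "simple_effects": {},
        "linear_trends": {},
    }
    for term in MAIN_EFFECT_TERMS:
        t = test_effect(fit, term, df_method=df_method)
        report["tests"][term] = dataclasses.asdict(t)
    for s in range(1, config.n_sessions + 1):
        report["simple_effects"][str(s)] = [
            dataclasses.asdict(t)
            for t in simple_effects_by_session(fit, s, df_method=df_method)
        ]
    report["linear_trends"] = [
        dataclasses.asdict(t)
        for t in linear_trend_by_condition(fit, df_method=df_method)
    ]
    (out / "model_report.json").write_text(json.dumps(report, indent=1))
    _write_csv(fit.fixed_effects, out / "fixed_effects.csv")
    vc = pd.DataFrame(
        sorted(fit.variance_components.items()), columns=["component", "variance"]
    )
    _write_csv(vc, out / "variance_components.csv")
    timings["fit"] = time.perf_counter() - t0

    # --- manifest ----------------------------------------------------------
    outputs = sorted(p.name for p in out.glob("*.csv")) + [
        "model_report.json"
    ] + (["truth.json"] if mode == "synthetic" else [])
    manifest = {
        "version": __version__,
        "mode": mode,
        "seed": config.seed,
        "config": config.to_dict(),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "digests": {name: _sha256(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def summarize(run_dir: str | Path) -> dict:
    """Human-auditable summary of one completed run.

    Returns (and writes as summary.json) the condition × session mean
    linkage with SEs, the exclusion accounting per rule, and the
    missing-data accounting overall and by condition (session windows;
    minutes lost to missed sessions count as missing).
    """
    run = Path(run_dir)
    table = pd.read_csv(run / "linkage.csv")
    minutes = pd.read_csv(run / "minutes.csv")

    sess = minutes[minutes["window"] == "session"]
    missing = sess["mean_ibi_ms"].isna()
    miss = {"overall_pct": round(100.0 * missing.mean(), 1)}
    if "drug_condition" in sess.columns:
        for cond, grp in sess.groupby("drug_condition"):
            miss[f"{cond}_pct"] = round(
                100.0 * grp["mean_ibi_ms"].isna().mean(), 1
            )

    reasons = (
        table.loc[~table["included"], "exclusion_reason"]
        .value_counts()
        .to_dict()
    )
    accounting = {
        "total_estimates": int(len(table)),
        "included": int(table["included"].sum()),
        "excluded": int((~table["included"]).sum()),
        "excluded_by_reason": {str(k): int(v) for k, v in reasons.items()},
        "excluded_pct": round(100.0 * (~table["included"]).mean(), 1),
    }

    inc = table[table["included"]]
    cells = (
        inc.groupby(["drug_condition", "session"])["b1"]
        .agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="size")
        .reset_index()
    )
    summary = {
        "mean_linkage_by_condition_session": cells.round(4).to_dict(
            orient="records"
        ),
        "exclusions": accounting,
        "missing_ibi": miss,
    }
    (run / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def format_summary(summary: dict) -> str:
    lines = ["Mean linkage (b1) by condition and session:"]
    for row in summary["mean_linkage_by_condition_session"]:
        lines.append(
            f"  {row['drug_condition']:>9} session {row['session']}: "
            f"{row['mean']:+.4f} +/- {row['se']:.4f} (n={row['n']})"
        )
    acc = summary["exclusions"]
    lines.append(
        f"Estimates: {acc['total_estimates']} total, {acc['included']} included, "
        f"{acc['excluded']} excluded ({acc['excluded_pct']}%)"
    )
    for reason, n in acc["excluded_by_reason"].items():
        lines.append(f"  excluded [{reason}]: {n}")
    miss = summary["missing_ibi"]
    lines.append(f"Missing IBI minutes: {miss['overall_pct']}% overall")
    for k, v in miss.items():
        if k != "overall_pct":
            lines.append(f"  {k.replace('_pct', '')}: {v}%")
    return "\n".join(lines)
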