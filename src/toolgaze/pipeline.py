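"""End-to-end pipeline: simulate/read -> detect -> classify -> summarize -> report.

A run is reproducible from (config, inputs, seed): one explicit seed
drives every stochastic stage, and the manifest records config hash,
input/output checksums and per-stage record counts, with exclusion
reasons tallied so every removal is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    SessionSummary,
    fit_log_curve,
    gaze_cell_means,
    summaries_to_frame,
    summarize_behavior,
)
from .config import RunConfig
from .errors import InsufficientDataError, ToolgazeError
from .fixation import DispersionParams, detect_fixations
from .io import (
    read_annotations,
    read_events,
    read_gaze_stream,
    write_dataset,
    write_report,
)
from .report import build_report
from .strategy import classify_session, fixations_per_drop, strategy_percentages
from .synthetic import LearningParams, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    seed: Optional[int]
    versions: dict = field(default_factory=dict)
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "versions": self.versions,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "counts": self.counts,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


@contextmanager
def _stage(name: str):
    """Re-raise any stage failure with the stage named."""
    try:
        yield
    except ToolgazeError as exc:
        raise ToolgazeError(f"[stage {name}] {exc}") from exc
    except FileNotFoundError as exc:
        raise ToolgazeError(f"[stage {name}] missing input file: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _checksums(root: Path, paths: Sequence[Path]) -> list:
    return [
        {"path": str(Path(p).relative_to(root)), "sha256": _sha256(Path(p))}
        for p in sorted(paths, key=str)
    ]


def _classified_frame(classified) -> pd.DataFrame:
    rows = []
    for c in classified:
        f = c.fixation
        rows.append({
            "trial_id": c.trial_id,
            "start_ms": f.start_ms,
            "end_ms": f.end_ms,
            "duration_ms": f.duration_ms,
            "centroid_x": round(f.centroid[0], 3),
            "centroid_y": round(f.centroid[1], 3),
            "dispersion_px": round(f.dispersion_px, 3),
            "n_samples": f.n_samples,
            "lead_mm": None if c.lead_mm is None else round(c.lead_mm, 4),
            "strategy": c.strategy,
            "difficulty": c.difficulty,
            "exclusion_reason": c.exclusion_reason,
        })
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    out_dir,
    sim_params: Optional[LearningParams] = None,
    input_index: Optional[pd.DataFrame] = None,
    seed: Optional[int] = None,
) -> RunManifest:
    """Execute the full pipeline into ``out_dir``; returns the manifest.

    Exactly one of ``sim_params`` (simulate the study, write the raw
    delimited files, then analyze them through the same readers real data
    would use) or ``input_index`` (a table with columns subject_id,
    session_idx, trial_idx, events and optional gaze/annot paths) must be
    given.
    """
    if (sim_params is None) == (input_index is None):
        raise ToolgazeError("provide exactly one of sim_params or input_index")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if sim_params is not None:
        if seed is not None:
            sim_params = replace(sim_params, seed=seed)
        with _stage("synthetic_data"):
            datasets = simulate_dataset(sim_params)
            raw_dir = out / "raw"
            index_rows = write_dataset(datasets, raw_dir, config.dialect)
        input_index = pd.DataFrame(index_rows)
        used_seed = sim_params.seed
    else:
        used_seed = seed

    counts: dict = {
        "trials": 0, "drops": 0, "samples_in": 0,
        "fixations_detected": 0, "fixations_kept": 0,
        "excluded_by_reason": {},
    }
    det_params = DispersionParams(
        max_dispersion_px=config.dispersion_px,
        min_duration_ms=config.min_fix_duration_ms,
        max_gap_samples=config.max_gap_samples,
    )

    summaries: list[SessionSummary] = []
    all_classified = []
    input_paths: list[Path] = []
    for subject_id, subj_df in input_index.groupby("subject_id", sort=True):
        for session_idx, sess_df in subj_df.groupby("session_idx", sort=True):
            sess_df = sess_df.sort_values("trial_idx")
            with _stage("gaze_io"):
                events = [
                    read_events(p, config.dialect) for p in sess_df["events"]
                ]
                input_paths.extend(Path(p) for p in sess_df["events"])
            summary = summarize_behavior(subject_id, int(session_idx), events)
            counts["trials"] += len(events)
            counts["drops"] += sum(ev.n_drops for ev in events)

            has_gaze = (
                "gaze" in sess_df.columns
                and sess_df["gaze"].notna().all()
                and "annot" in sess_df.columns
                and sess_df["annot"].notna().all()
            )
            if has_gaze:
                trials = []
                with _stage("gaze_io"):
                    for (_, rec), ev in zip(sess_df.iterrows(), events):
                        gaze = read_gaze_stream(rec["gaze"], config.dialect)
                        annot = read_annotations(rec["annot"], config.dialect)
                        input_paths.extend([Path(rec["gaze"]), Path(rec["annot"])])
                        trials.append((gaze, annot, ev))
                with _stage("fixation_detection"):
                    detected = [
                        (detect_fixations(g, det_params), a, ev)
                        for g, a, ev in trials
                    ]
                counts["samples_in"] += sum(len(g) for g, _, _ in trials)
                with _stage("strategy_classification"):
                    classified = classify_session(detected, config)
                counts["fixations_detected"] += len(classified)
                counts["fixations_kept"] += sum(c.kept for c in classified)
                for c in classified:
                    if not c.kept:
                        tally = counts["excluded_by_reason"]
                        tally[c.exclusion_reason] = tally.get(c.exclusion_reason, 0) + 1
                summary.percentages = strategy_percentages(classified)
                summary.fixations_per_drop = fixations_per_drop(classified, events)
                dur, lead = gaze_cell_means(classified)
                summary.mean_duration_ms = dur
                summary.mean_lead_mm = lead
                all_classified.extend(classified)
            summaries.append(summary)

    assert counts["fixations_kept"] + sum(
        counts["excluded_by_reason"].values()
    ) == counts["fixations_detected"], "fixation counts not conserved"

    with _stage("behavior_metrics"):
        frame = summaries_to_frame(summaries)
        write_report(frame, out / "summaries.csv", config.dialect)
        session_means = frame.groupby("session_idx")["mdpm_mean"].mean()
        curve = None
        if len(session_means) >= 3:
            curve = fit_log_curve(
                session_means.to_numpy(), session_means.index.to_numpy()
            )
            (out / "learning_curve.json").write_text(json.dumps({
                "a": curve.a, "b": curve.b, "r_squared": curve.r_squared,
            }, indent=2, sort_keys=True) + "\n")

    if all_classified:
        _classified_frame(all_classified).to_csv(
            out / "classified_fixations.csv", sep=config.delimiter, index=False
        )

    report_dir = out / "report"
    try:
        report = build_report(frame)
    except InsufficientDataError as exc:
        logger.warning("statistical report skipped: %s", exc)
        counts["report"] = f"skipped: {exc}"
    except ToolgazeError as exc:
        raise ToolgazeError(f"[stage stats_report] {exc}") from exc
    else:
        report_dir.mkdir(exist_ok=True)
        for name, tab in sorted(report.tables.items()):
            tab.to_csv(report_dir / f"{name}.csv", sep=config.delimiter, index=False)
        (report_dir / "narrative.txt").write_text(report.narrative + "\n")

    config_payload = config.model_dump_json().encode()
    outputs = [p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"]
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_payload).hexdigest(),
        seed=used_seed,
        versions={
            "toolgaze": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        inputs=_checksums(out if sim_params is not None else Path("."),
                          input_paths) if sim_params is not None else [
            {"path": str(p), "sha256": _sha256(Path(p))} for p in sorted(set(map(str, input_paths)))
        ],
        outputs=_checksums(out, outputs),
        counts=counts,
    )
    manifest.to_json(out / "manifest.json")
    return manifest
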