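"""Delimited-text readers and writers for gaze, annotation and event logs.

Formats (documented bit-exactly in ``docs/formats.md``):

* gaze:        ``t_ms,x_px,y_px,valid``
* annotations: ``t_ms,cyl_base_x,cyl_base_y,cyl_apex_x,cyl_apex_y,tip_x,tip_y,phase,in_setup``
  (``tip_x``/``tip_y`` empty when the chopstick tip is occluded)
* events:      ``event,cycle,t_ms`` with event in {trial_start, trial_end,
  grasp_onset, grasp_success, drop, return_complete}; trial-level rows
  leave ``cycle`` empty.

The default dialect is comma-separated UTF-8 with one header line; the
``smi-like`` dialect accepts/produces tab-separated files with the same
columns.  Readers never silently drop rows: every exclusion or repair is
logged with a reason code.  Writing then reading any record kind is the
identity.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DialectError, FormatError
from .types import (
    PHASES,
    SCENE_HEIGHT_PX,
    SCENE_WIDTH_PX,
    Cycle,
    FrameAnnotation,
    GazeStream,
    Point,
    TrialEvents,
)

logger = logging.getLogger(__name__)

_GAZE_COLUMNS = ["t_ms", "x_px", "y_px", "valid"]
_ANNOT_COLUMNS = [
    "t_ms", "cyl_base_x", "cyl_base_y", "cyl_apex_x", "cyl_apex_y",
    "tip_x", "tip_y", "phase", "in_setup",
]
_EVENT_COLUMNS = ["event", "cycle", "t_ms"]
_CYCLE_EVENTS = ["grasp_onset", "grasp_success", "drop", "return_complete"]
_DELIMS = {"csv": ",", "smi-like": "\t"}


def _delim(dialect: str) -> str:
    try:
        return _DELIMS[dialect]
    except KeyError:
        raise DialectError(f"unknown dialect {dialect!r}; expected one of {list(_DELIMS)}")


def _read_table(path, dialect: str, expected: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=_delim(dialect))
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: unparseable ({exc})") from exc
    unknown = [c for c in df.columns if c not in expected]
    missing = [c for c in expected if c not in df.columns]
    if unknown or missing:
        raise DialectError(
            f"{path}: column mismatch (unknown {unknown}, missing {missing}); "
            f"expected {expected}"
        )
    return df[expected]


# -- gaze -------------------------------------------------------------------


def read_gaze_stream(path, dialect: str = "csv", trial_id: str | None = None) -> GazeStream:
    """Read and validate one gaze stream.

    Samples with coordinates outside the scene frame (or non-finite) are
    retained but re-flagged invalid (reason ``out_of_range``).  Non-monotone
    timestamps raise :class:`FormatError` naming the first offending row.
    """
    df = _read_table(path, dialect, _GAZE_COLUMNS)
    t = df["t_ms"].to_numpy()
    if not np.all(np.isfinite(t)):
        raise FormatError(f"{path}: non-numeric timestamp")
    x = df["x_px"].to_numpy(dtype=float)
    y = df["y_px"].to_numpy(dtype=float)
    valid = df["valid"].to_numpy().astype(bool)
    in_range = (
        np.isfinite(x) & np.isfinite(y)
        & (x >= 0) & (x <= SCENE_WIDTH_PX) & (y >= 0) & (y <= SCENE_HEIGHT_PX)
    )
    flagged = valid & ~in_range
    if np.any(flagged):
        for row in np.nonzero(flagged)[0]:
            logger.warning(
                "%s row %d: reason=out_of_range x=%r y=%r; flagged invalid",
                path, int(row) + 1, x[row], y[row],
            )
        valid = valid & in_range
    try:
        return GazeStream(
            t=t.astype(np.int64), x=x, y=y, valid=valid,
            trial_id=trial_id or Path(path).stem,
        )
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_gaze_stream(stream: GazeStream, path, dialect: str = "csv") -> None:
    df = pd.DataFrame({
        "t_ms": stream.t,
        "x_px": stream.x,
        "y_px": stream.y,
        "valid": stream.valid.astype(int),
    })
    df.to_csv(path, sep=_delim(dialect), index=False)


# -- annotations ------------------------------------------------------------


def read_annotations(path, dialect: str = "csv") -> list[FrameAnnotation]:
    """Read per-frame scene annotations (schema-validated)."""
    df = _read_table(path, dialect, _ANNOT_COLUMNS)
    bad = ~df["phase"].isin(PHASES)
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise FormatError(
            f"{path} row {row + 1}: unknown phase label {df['phase'].iloc[row]!r}"
        )
    out = []
    for i, rec in enumerate(df.itertuples(index=False)):
        tip = None
        if np.isfinite(rec.tip_x) and np.isfinite(rec.tip_y):
            tip = Point(float(rec.tip_x), float(rec.tip_y))
        try:
            out.append(
                FrameAnnotation(
                    t=int(rec.t_ms),
                    cyl_base=Point(float(rec.cyl_base_x), float(rec.cyl_base_y)),
                    cyl_apex=Point(float(rec.cyl_apex_x), float(rec.cyl_apex_y)),
                    tip=tip,
                    phase=str(rec.phase),
                    in_setup=bool(rec.in_setup),
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path} row {i + 1}: {exc}") from exc
    return out


def write_annotations(annotations: Sequence[FrameAnnotation], path, dialect: str = "csv") -> None:
    rows = []
    for a in annotations:
        rows.append({
            "t_ms": a.t,
            "cyl_base_x": a.cyl_base.x, "cyl_base_y": a.cyl_base.y,
            "cyl_apex_x": a.cyl_apex.x, "cyl_apex_y": a.cyl_apex.y,
            "tip_x": a.tip.x if a.tip else np.nan,
            "tip_y": a.tip.y if a.tip else np.nan,
            "phase": a.phase,
            "in_setup": int(a.in_setup),
        })
    pd.DataFrame(rows, columns=_ANNOT_COLUMNS).to_csv(path, sep=_delim(dialect), index=False)


# -- events -----------------------------------------------------------------


def read_events(path, dialect: str = "csv", trial_id: str | None = None) -> TrialEvents:
    """Read one trial's event log.

    Cycles missing any of the four cycle events are dropped with a logged
    ``incomplete_cycle`` reason; an empty cycle list is a valid trial with
    zero successful drops.
    """
    df = _read_table(path, dialect, _EVENT_COLUMNS)
    known = set(_CYCLE_EVENTS) | {"trial_start", "trial_end"}
    bad = ~df["event"].isin(sorted(known))
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise FormatError(f"{path} row {row + 1}: unknown event {df['event'].iloc[row]!r}")

    def _trial_level(name: str) -> int:
        sel = df[df["event"] == name]
        if len(sel) != 1:
            raise FormatError(f"{path}: expected exactly one {name} row, got {len(sel)}")
        return int(sel["t_ms"].iloc[0])

    start, end = _trial_level("trial_start"), _trial_level("trial_end")
    cycles = []
    cyc_df = df[df["event"].isin(_CYCLE_EVENTS)]
    for cyc_idx, grp in cyc_df.groupby("cycle", sort=True):
        stamps = dict(zip(grp["event"], grp["t_ms"]))
        if set(stamps) != set(_CYCLE_EVENTS):
            logger.warning(
                "%s cycle %s: reason=incomplete_cycle (has %s); dropped",
                path, cyc_idx, sorted(stamps),
            )
            continue
        cycles.append(Cycle(*(int(stamps[e]) for e in _CYCLE_EVENTS)))
    cycles.sort(key=lambda c: c.grasp_onset)
    try:
        return TrialEvents(
            trial_start=start, trial_end=end, cycles=cycles,
            trial_id=trial_id or Path(path).stem,
        )
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_events(events: TrialEvents, path, dialect: str = "csv") -> None:
    rows = [{"event": "trial_start", "cycle": np.nan, "t_ms": events.trial_start}]
    for i, c in enumerate(events.cycles):
        for name, t in zip(_CYCLE_EVENTS, c):
            rows.append({"event": name, "cycle": i, "t_ms": t})
    rows.append({"event": "trial_end", "cycle": np.nan, "t_ms": events.trial_end})
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    df["cycle"] = df["cycle"].astype("Int64")
    df.to_csv(path, sep=_delim(dialect), index=False)


# -- reports ----------------------------------------------------------------


def write_report(summaries, path, dialect: str = "csv") -> None:
    """Write the per subject x session summary table."""
    from .behavior import summaries_to_frame

    if isinstance(summaries, pd.DataFrame):
        df = summaries
    else:
        df = summaries_to_frame(summaries)
    df.to_csv(path, sep=_delim(dialect), index=False)


def read_report(path, dialect: str = "csv") -> pd.DataFrame:
    return pd.read_csv(path, sep=_delim(dialect))


# -- whole-dataset convenience ---------------------------------------------


def write_trial(trial, out_dir, dialect: str = "csv") -> dict:
    """Write a simulated trial's files; returns {kind: path}."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["events"] = out_dir / f"{trial.trial_id}_events.csv"
    write_events(trial.events, paths["events"], dialect)
    if trial.gaze is not None:
        paths["gaze"] = out_dir / f"{trial.trial_id}_gaze.csv"
        write_gaze_stream(trial.gaze, paths["gaze"], dialect)
    if trial.annotations is not None:
        paths["annot"] = out_dir / f"{trial.trial_id}_annot.csv"
        write_annotations(trial.annotations, paths["annot"], dialect)
    return paths


def write_dataset(datasets, out_dir, dialect: str = "csv") -> list[dict]:
    """Write a list of SubjectDataset objects under ``out_dir/<subject>/``.

    ``out_dir/index.csv`` lists every trial with paths relative to
    ``out_dir`` (reproducible across working directories); the returned
    rows carry absolute paths for immediate consumption.
    """
    out_dir = Path(out_dir)
    index, index_rel = [], []
    for ds in datasets:
        for session, trials in sorted(ds.sessions.items()):
            for trial in trials:
                paths = write_trial(trial, out_dir / ds.subject_id, dialect)
                meta = {
                    "subject_id": ds.subject_id,
                    "session_idx": session,
                    "trial_idx": trial.trial_idx,
                }
                index.append({**meta, **{k: str(v) for k, v in paths.items()}})
                index_rel.append(
                    {**meta, **{k: str(v.relative_to(out_dir)) for k, v in paths.items()}}
                )
    pd.DataFrame(index_rel).to_csv(out_dir / "index.csv", index=False)
    return index
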