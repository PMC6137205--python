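"""Dispersion-threshold (I-DT) fixation detection.

A fixation is a maximal run of gaze samples whose spatial dispersion stays
at or below a pixel threshold for at least a minimum duration.  Dispersion
of a sample window is the classic I-DT metric

    (max x - min x) + (max y - min y)

The detector is the standard greedy left-to-right scheme: seed a window
spanning the minimum duration; if its dispersion is within the threshold,
extend it rightward until the next sample would violate the threshold,
emit the window as a fixation and resume after it; otherwise slide the
window start by one sample.

Defaults mirror a head-mounted tracker's event detector at 30 Hz:
maximum dispersion 100 px, minimum duration 80 ms.  At 30 Hz the minimum
duration forces every fixation to contain at least three samples (in fact
four, since duration is measured first-to-last sample timestamp).

Invalid samples (blinks, tracking loss): gaps of at most ``max_gap_samples``
(default 2) flanked by valid samples are bridged by linear interpolation;
longer gaps are hard breaks that terminate any open window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ToolgazeError
from .types import GazeStream

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DispersionParams:
    max_dispersion_px: float = 100.0
    min_duration_ms: float = 80.0
    max_gap_samples: int = 2

    def __post_init__(self) -> None:
        if self.max_dispersion_px <= 0 or self.min_duration_ms <= 0:
            raise ToolgazeError("dispersion and duration thresholds must be positive")


@dataclass(frozen=True)
class Fixation:
    """A detected stationary gaze epoch."""

    start_ms: int
    end_ms: int
    centroid: tuple[float, float]
    dispersion_px: float
    n_samples: int

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms

    @property
    def midpoint_ms(self) -> float:
        return 0.5 * (self.start_ms + self.end_ms)


def dispersion(points: Iterable[tuple[float, float]]) -> float:
    """Sum of coordinate ranges of a point cloud (px)."""
    pts = np.asarray(list(points), dtype=float)
    if pts.size == 0:
        raise ValueError("dispersion of an empty point set is undefined")
    pts = pts.reshape(-1, 2)
    return float(np.ptp(pts[:, 0]) + np.ptp(pts[:, 1]))


def _bridge_gaps(stream: GazeStream, max_gap: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate short invalid runs; return (x, y, usable mask).

    Runs of <= max_gap invalid samples with valid neighbours on both sides
    are filled by linear interpolation in time and marked usable; anything
    longer (or touching the stream boundary) stays unusable.
    """
    x = stream.x.copy()
    y = stream.y.copy()
    usable = stream.valid.copy()
    n = len(stream)
    i = 0
    n_bridged = 0
    while i < n:
        if usable[i]:
            i += 1
            continue
        j = i
        while j < n and not usable[j]:
            j += 1
        run = j - i
        if 0 < run <= max_gap and i > 0 and j < n:
            t0, t1 = stream.t[i - 1], stream.t[j]
            for k in range(i, j):
                w = (stream.t[k] - t0) / (t1 - t0)
                x[k] = (1 - w) * x[i - 1] + w * x[j]
                y[k] = (1 - w) * y[i - 1] + w * y[j]
            usable[i:j] = True
            n_bridged += run
        i = j
    if n_bridged:
        logger.debug("bridged %d invalid samples by interpolation", n_bridged)
    return x, y, usable


def _segments(usable: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of consecutive usable samples."""
    segs = []
    n = len(usable)
    i = 0
    while i < n:
        if not usable[i]:
            i += 1
            continue
        j = i
        while j < n and usable[j]:
            j += 1
        segs.append((i, j))
        i = j
    return segs


def _emit(t, x, y, i, j) -> Fixation:
    xs, ys = x[i : j + 1], y[i : j + 1]
    return Fixation(
        start_ms=int(t[i]),
        end_ms=int(t[j]),
        centroid=(float(xs.mean()), float(ys.mean())),
        dispersion_px=float(np.ptp(xs) + np.ptp(ys)),
        n_samples=j - i + 1,
    )


def detect_fixations(
    stream: GazeStream, params: DispersionParams | None = None
) -> list[Fixation]:
    """Greedy I-DT fixation detection over one gaze stream.

    Returns time-ordered, non-overlapping fixations, each satisfying both
    the dispersion and the minimum-duration threshold.  A stream shorter
    than the minimum duration yields an empty list.
    """
    params = params or DispersionParams()
    x, y, usable = _bridge_gaps(stream, params.max_gap_samples)
    t = stream.t
    out: list[Fixation] = []
    for s0, s1 in _segments(usable):
        i = s0
        while i < s1:
            # seed: smallest window [i, j] spanning the minimum duration
            j = i + 1
            while j < s1 and t[j] - t[i] < params.min_duration_ms:
                j += 1
            if j >= s1:
                break
            xs_min, xs_max = x[i : j + 1].min(), x[i : j + 1].max()
            ys_min, ys_max = y[i : j + 1].min(), y[i : j + 1].max()
            if (xs_max - xs_min) + (ys_max - ys_min) <= params.max_dispersion_px:
                while j + 1 < s1:
                    nx_min = min(xs_min, x[j + 1])
                    nx_max = max(xs_max, x[j + 1])
                    ny_min = min(ys_min, y[j + 1])
                    ny_max = max(ys_max, y[j + 1])
                    if (nx_max - nx_min) + (ny_max - ny_min) > params.max_dispersion_px:
                        break
                    xs_min, xs_max, ys_min, ys_max = nx_min, nx_max, ny_min, ny_max
                    j += 1
                fix = _emit(t, x, y, i, j)
                assert fix.duration_ms >= params.min_duration_ms
                assert fix.dispersion_px <= params.max_dispersion_px + 1e-9
                out.append(fix)
                i = j + 1
            else:
                i += 1
    return out


def total_fixation_time_ms(fixations: Sequence[Fixation]) -> float:
    return float(sum(f.duration_ms for f in fixations))
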