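"""Reference implementations and stream generators for validation.

:func:`detect_fixations_reference` re-derives the dispersion-threshold
detector directly from its written definition with naive full-window
re-scans (pure Python, O(n^3)); it shares no code with the production
detector and serves as its equivalence oracle on small streams.

:func:`random_gaze_stream` draws adversarial little streams — stationary
holds of varying spread and length, drifting walks, large jumps,
invalid-sample runs — for property and equivalence testing.
"""

from __future__ import annotations

import numpy as np

from .types import GazeStream


def _naive_dispersion(xs, ys) -> float:
    return (max(xs) - min(xs)) + (max(ys) - min(ys))


def detect_fixations_reference(
    stream: GazeStream,
    max_dispersion_px: float = 100.0,
    min_duration_ms: float = 80.0,
    max_gap_samples: int = 2,
) -> list[tuple[int, int]]:
    """Naive I-DT over one stream; returns (start_idx, end_idx) pairs.

    Definition followed literally: bridge invalid runs of at most
    ``max_gap_samples`` interior samples by linear interpolation; within
    each maximal run of usable samples, seed the smallest window spanning
    the minimum duration, extend while the (fully recomputed) dispersion
    stays within threshold, emit, and resume after the window; otherwise
    advance the window start by one.
    """
    t = [int(v) for v in stream.t]
    x = [float(v) for v in stream.x]
    y = [float(v) for v in stream.y]
    usable = [bool(v) for v in stream.valid]
    n = len(t)

    # gap bridging, re-derived
    i = 0
    while i < n:
        if usable[i]:
            i += 1
            continue
        j = i
        while j < n and not usable[j]:
            j += 1
        if (j - i) <= max_gap_samples and i > 0 and j < n:
            for k in range(i, j):
                w = (t[k] - t[i - 1]) / (t[j] - t[i - 1])
                x[k] = (1 - w) * x[i - 1] + w * x[j]
                y[k] = (1 - w) * y[i - 1] + w * y[j]
                usable[k] = True
        i = j

    # usable segments
    fixations = []
    seg_start = None
    bounds = []
    for i in range(n + 1):
        if i < n and usable[i]:
            if seg_start is None:
                seg_start = i
        elif seg_start is not None:
            bounds.append((seg_start, i))
            seg_start = None

    for s0, s1 in bounds:
        i = s0
        while i < s1:
            j = i + 1
            while j < s1 and t[j] - t[i] < min_duration_ms:
                j += 1
            if j >= s1:
                break
            if _naive_dispersion(x[i : j + 1], y[i : j + 1]) <= max_dispersion_px:
                while (
                    j + 1 < s1
                    and _naive_dispersion(x[i : j + 2], y[i : j + 2]) <= max_dispersion_px
                ):
                    j += 1
                fixations.append((i, j))
                i = j + 1
            else:
                i += 1
    return fixations


def random_gaze_stream(rng: np.random.Generator, n_max: int = 200) -> GazeStream:
    """A random stream of holds, walks, jumps and dropouts (<= n_max samples)."""
    n = int(rng.integers(10, n_max + 1))
    xs, ys, valid = [], [], []
    px, py = rng.uniform(100, 1180), rng.uniform(100, 860)
    while len(xs) < n:
        kind = rng.choice(["hold", "walk", "jump", "invalid"], p=[0.4, 0.3, 0.2, 0.1])
        length = int(rng.integers(1, 16))
        if kind == "hold":
            spread = rng.uniform(0, 80)
            for _ in range(length):
                xs.append(px + rng.uniform(-spread / 2, spread / 2))
                ys.append(py + rng.uniform(-spread / 2, spread / 2))
                valid.append(True)
        elif kind == "walk":
            for _ in range(length):
                px += rng.uniform(-60, 60)
                py += rng.uniform(-60, 60)
                xs.append(px)
                ys.append(py)
                valid.append(True)
        elif kind == "jump":
            px, py = rng.uniform(0, 1280), rng.uniform(0, 960)
            xs.append(px)
            ys.append(py)
            valid.append(True)
        else:
            for _ in range(min(length, 4)):
                xs.append(px)
                ys.append(py)
                valid.append(False)
    xs, ys, valid = xs[:n], ys[:n], valid[:n]
    t = np.array([(i * 1000) // 30 for i in range(n)], dtype=np.int64)
    return GazeStream(
        t=t,
        x=np.clip(xs, 0, 1280),
        y=np.clip(ys, 0, 960),
        valid=np.array(valid, dtype=bool),
        trial_id="random",
    )
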