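"""Run-pause parsing of particle tracks.

Organelle tracks alternate *runs* (directed motion at roughly constant
velocity along the motility axis) and *pauses* (sub-threshold displacement).
The parser classifies each frame by windowed velocity along a supplied 1-D
projection axis (toward-nucleus = minus by convention), merges the frames
into segments that tile the track, and enforces a minimum pause duration and
minimum run length. Direction-resolved summaries (run distance, pause
duration, fraction of time paused, directional switching probability) are
computed per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "Track",
    "MotilitySegment",
    "ParsingParams",
    "MotilitySummary",
    "parse_track",
    "summarize_motility",
]


@dataclass
class Track:
    """A 2-D particle track plus its 1-D motility-axis projection."""

    track_id: str
    time: np.ndarray  # s, strictly increasing
    xy: np.ndarray  # nm, shape (n, 2)
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise InputError("xy must have shape (n, 2)")
        if self.time.shape[0] != self.xy.shape[0]:
            raise InputError("time and xy must have equal length")
        if not np.all(np.isfinite(self.xy)) or not np.all(np.isfinite(self.time)):
            raise InputError("coordinates must be finite")
        norm = np.linalg.norm(self.axis)
        if norm == 0:
            raise InputError("projection axis must be non-zero")
        self.axis = self.axis / norm

    @property
    def projection(self) -> np.ndarray:
        """Position along the motility axis, nm."""
        return self.xy @ self.axis


@dataclass
class MotilitySegment:
    """A run or pause parsed from one track.

    ``distance`` is the magnitude of the net displacement along the
    projection axis (nm); for pauses it is the (small) residual
    displacement. ``direction`` is ``plus``/``minus`` for runs and ``none``
    for pauses.
    """

    kind: str  # "run" | "pause"
    direction: str  # "plus" | "minus" | "none"
    distance: float  # nm, magnitude
    duration: float  # s
    start_time: float  # s
    track_id: str = ""
    condition: str = ""


@dataclass
class ParsingParams:
    """Thresholds for run-pause classification.

    A frame is a pause candidate when the smaller of its forward- and
    backward-windowed speeds falls below ``pause_speed_threshold`` (the
    two-sided minimum keeps direction reversals from masquerading as
    pauses). Pauses shorter than ``min_pause_duration`` do not break a run;
    runs with net displacement below ``min_run_length`` are reclassified as
    pauses.
    """

    smoothing_frames: int = 3
    pause_speed_threshold: float = 50.0  # nm/s
    min_pause_duration: float = 0.5  # s
    min_run_length: float = 50.0  # nm
    velocity_window: float | None = None  # s; defaults to min_pause_duration


def _rolling_mean(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.astype(float)
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(x.astype(float), size=w, mode="nearest")


def parse_track(track: Track, params: ParsingParams | None = None) -> list[MotilitySegment]:
    """Parse one track into an ordered list of segments that tile it."""
    if params is None:
        params = ParsingParams()
    t = track.time
    if t.size < 3:
        raise InputError("track must contain at least 3 samples")
    if np.any(np.diff(t) <= 0):
        raise InputError(f"non-monotone time in track {track.track_id!r}")

    raw = track.projection
    p = _rolling_mean(raw, params.smoothing_frames)
    n = p.size
    dt = float(np.median(np.diff(t)))
    win_s = params.velocity_window if params.velocity_window is not None else params.min_pause_duration
    h = max(1, int(round(win_s / dt)))

    # a frame is a pause iff some full window of ~min_pause length covering
    # it has a net displacement rate below threshold; any window touching a
    # run picks up its displacement, so pause extents are recovered sharply
    if n > h:
        rate = np.abs(p[h:] - p[:-h]) / (t[h:] - t[:-h])
        slow_start = rate < params.pause_speed_threshold  # window j covers frames j..j+h
        edges = np.zeros(n + 1, dtype=int)
        idx_slow = np.flatnonzero(slow_start)
        np.add.at(edges, idx_slow, 1)
        np.add.at(edges, np.minimum(idx_slow + h + 1, n), -1)
        pause_frame = np.cumsum(edges[:-1]) > 0
    else:
        overall = abs(p[-1] - p[0]) / (t[-1] - t[0])
        pause_frame = np.full(n, overall < params.pause_speed_threshold)

    # run direction from a centered difference of the smoothed projection
    hc = max(1, h // 2)
    idx = np.arange(n)
    lo = np.maximum(idx - hc, 0)
    hi = np.minimum(idx + hc, n - 1)
    centered = (p[hi] - p[lo]) / (t[hi] - t[lo])

    # per-frame state: 0 = pause, +1 / -1 = run direction
    state = np.where(pause_frame, 0, np.where(centered >= 0, 1, -1))

    # contiguous-state boundaries; segment j spans samples [b[j], b[j+1]]
    change = np.flatnonzero(np.diff(state)) + 1
    bounds = np.concatenate(([0], change, [n - 1]))
    states = [int(state[b]) for b in bounds[:-1]]
    bounds = bounds.tolist()
    # degenerate duplicate boundary when the last frame starts a new state
    if len(bounds) >= 2 and bounds[-1] == bounds[-2]:
        bounds.pop(-2)
        states.pop(-1)

    def seg_duration(j: int) -> float:
        return float(t[bounds[j + 1]] - t[bounds[j]])

    def seg_disp(j: int) -> float:
        # distances come from the raw projection: smoothing is for
        # classification only and would clip displacement at track edges
        return float(raw[bounds[j + 1]] - raw[bounds[j]])

    def merge_equal_adjacent() -> None:
        j = 0
        while j < len(states) - 1:
            if states[j] == states[j + 1]:
                del states[j + 1]
                del bounds[j + 1]
            else:
                j += 1

    def run_direction(j: int) -> int:
        d = seg_disp(j)
        return 1 if d >= 0 else -1

    for _ in range(20):  # repair until stable (bounded)
        changed = False
        merge_equal_adjacent()

        # pauses shorter than the minimum do not break a run
        j = 0
        while j < len(states):
            if states[j] == 0 and seg_duration(j) < params.min_pause_duration and len(states) > 1:
                left_run = j > 0 and states[j - 1] != 0
                right_run = j < len(states) - 1 and states[j + 1] != 0
                if left_run and right_run:
                    # absorbed: neighbors merge if co-directional, else the
                    # boundary moves to the midpoint of the interruption
                    if states[j - 1] == states[j + 1]:
                        del states[j]
                        del bounds[j]
                        merge_equal_adjacent()
                    else:
                        mid = (bounds[j] + bounds[j + 1]) // 2
                        del states[j]
                        del bounds[j + 1]
                        bounds[j] = mid
                    changed = True
                    continue
                if left_run or right_run:
                    del states[j]
                    del bounds[j + 1 if right_run and not left_run else j]
                    changed = True
                    continue
            j += 1

        # runs below the minimum net displacement become pauses
        for j in range(len(states)):
            if states[j] != 0 and abs(seg_disp(j)) < params.min_run_length:
                states[j] = 0
                changed = True
        merge_equal_adjacent()

        # re-anchor run directions to their net displacement
        for j in range(len(states)):
            if states[j] != 0:
                d = run_direction(j)
                if d != states[j]:
                    states[j] = d
                    changed = True
        merge_equal_adjacent()

        if not changed:
            break

    segments: list[MotilitySegment] = []
    for j, s in enumerate(states):
        disp = seg_disp(j)
        segments.append(
            MotilitySegment(
                kind="pause" if s == 0 else "run",
                direction="none" if s == 0 else ("plus" if s > 0 else "minus"),
                distance=abs(disp),
                duration=seg_duration(j),
                start_time=float(t[bounds[j]]),
                track_id=track.track_id,
                condition=track.condition,
            )
        )
    return segments


@dataclass
class MotilitySummary:
    """Per-condition, direction-resolved motility statistics."""

    runs: pd.DataFrame  # rows: (condition, direction)
    pauses: pd.DataFrame  # rows: condition
    switching: pd.DataFrame  # rows: condition


def _sem(x: np.ndarray) -> float:
    return float(sps.sem(x)) if x.size >= 2 else float("nan")


def summarize_motility(
    segments_by_condition: Mapping[str, Sequence[Sequence[MotilitySegment]]],
) -> MotilitySummary:
    """Summarize parsed segments.

    ``segments_by_condition`` maps each condition to a list of per-track
    segment lists (track identity is needed to count directional
    transitions). Switching probability counts, over consecutive runs within
    a track (ignoring intervening pauses), the fraction of transitions that
    reverse direction: reversals / (reversals + same-direction resumptions).
    """
    if not segments_by_condition:
        raise InputError("no segments supplied")
    run_rows, pause_rows, switch_rows = [], [], []
    for condition, tracks in segments_by_condition.items():
        all_segs = [s for track in tracks for s in track]
        if not all_segs:
            raise InputError(f"condition {condition!r} has no segments")
        for direction in ("plus", "minus"):
            dist = np.array(
                [s.distance for s in all_segs if s.kind == "run" and s.direction == direction]
            )
            if dist.size:
                run_rows.append(
                    {
                        "condition": condition,
                        "direction": direction,
                        "n_runs": dist.size,
                        "mean_run_nm": float(dist.mean()),
                        "sem_run_nm": _sem(dist),
                    }
                )
        pauses = np.array([s.duration for s in all_segs if s.kind == "pause"])
        total_time = sum(s.duration for s in all_segs)
        pause_rows.append(
            {
                "condition": condition,
                "n_pauses": pauses.size,
                "mean_pause_s": float(pauses.mean()) if pauses.size else float("nan"),
                "sem_pause_s": _sem(pauses),
                "fraction_time_paused": float(pauses.sum() / total_time) if total_time else float("nan"),
            }
        )
        reversals = resumptions = 0
        for track in tracks:
            dirs = [s.direction for s in track if s.kind == "run"]
            for prev, cur in zip(dirs, dirs[1:]):
                if prev == cur:
                    resumptions += 1
                else:
                    reversals += 1
        n_trans = reversals + resumptions
        switch_rows.append(
            {
                "condition": condition,
                "n_transitions": n_trans,
                "switching_probability": reversals / n_trans if n_trans else float("nan"),
            }
        )
    return MotilitySummary(
        runs=pd.DataFrame(run_rows),
        pauses=pd.DataFrame(pause_rows),
        switching=pd.DataFrame(switch_rows),
    )


def segments_to_frame(segments: Sequence[MotilitySegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "track_id": [s.track_id for s in segments],
            "condition": [s.condition for s in segments],
            "kind": [s.kind for s in segments],
            "direction": [s.direction for s in segments],
            "distance_nm": [s.distance for s in segments],
            "duration_s": [s.duration for s in segments],
            "start_time_s": [s.start_time for s in segments],
        }
    )
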