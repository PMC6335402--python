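"""Optical-trap escape-attempt analysis.

A trapped cargo driven by a team of motors makes successive *escape
attempts*: excursions away from the trap center that end either in escape
(the cargo crosses the escape radius, nominally 200 nm, and leaves the
harmonic region of the trap) or in failure (the motors detach and the cargo
snaps back to the trap center at high velocity). Position is recorded by a
position-sensitive detector at high bandwidth (nominally 2 kHz) and force is
the trap restoring force ``F = k * x`` with trap stiffness ``k`` in pN/nm.

This module parses a position trace into :class:`AttemptRecord` objects and
aggregates cohorts of cargos into per-attempt-index *adaptation profiles*:
mean peak force, mean persistence time (the time over which force is
maintained, operationally the time above a configurable fraction of that
attempt's peak), and the escaped fraction with its binomial standard error
sqrt(f * (1 - f) / n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import uniform_filter1d

from .errors import InputError, UndefinedValueError
from .stats import hypothesis_test

__all__ = [
    "ForceTrace",
    "AttemptRecord",
    "AdaptationProfile",
    "DetectionParams",
    "TrendFit",
    "detect_attempts",
    "escaped_fraction",
    "escaped_fraction_counts",
    "adaptation_profile",
    "fit_adaptation_trend",
]


@dataclass
class ForceTrace:
    """One cargo's trap-relative position series.

    ``position`` is signed along the microtubule axis; by convention
    minus-end (inward) excursions are positive. Attempt detection uses the
    magnitude, so the convention only matters for bookkeeping.
    """

    time: np.ndarray  # s, uniform grid
    position: np.ndarray  # nm relative to trap center
    trap_stiffness: float  # pN/nm
    sampling_rate: float  # Hz
    cargo_id: str = ""
    experiment_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.time.shape != self.position.shape:
            raise InputError("time and position must have equal length")
        if self.trap_stiffness <= 0:
            raise InputError("trap_stiffness must be positive")
        if not np.all(np.isfinite(self.position)):
            raise InputError("positions must be finite")

    def validate_uniform(self, rtol: float = 1e-3) -> float:
        """Return the sample interval, or raise if the grid is non-uniform."""
        if self.time.size < 2:
            raise InputError("trace must contain at least 2 samples")
        dts = np.diff(self.time)
        dt = float(np.median(dts))
        if dt <= 0 or np.any(np.abs(dts - dt) > rtol * dt):
            raise InputError(
                f"non-uniform sampling in trace {self.cargo_id!r}: "
                f"max deviation {np.max(np.abs(dts - dt)):.3g} s"
            )
        return dt


@dataclass
class AttemptRecord:
    """One escape attempt of one cargo."""

    cargo_id: str
    attempt_index: int  # 1-based ordinal within the cargo
    peak_force: float  # pN
    persistence_time: float  # s
    outcome: str  # "escaped" | "failed"
    start_time: float  # s
    end_time: float  # s
    experiment_id: str = ""
    condition: str = ""


@dataclass
class DetectionParams:
    """Tunable thresholds for attempt parsing.

    Defaults: an attempt starts when force exceeds 0.5 pN above baseline,
    persistence is the time above half of the attempt's peak force, a
    snapback is an inward return faster than 5 um/s sustained for >= 5 ms,
    and the escape radius is 200 nm.
    """

    excursion_start_force: float = 0.5  # pN above baseline
    peak_fraction: float = 0.5  # persistence threshold as fraction of peak
    snapback_speed_threshold: float = 5000.0  # nm/s
    snapback_min_duration: float = 0.005  # s
    escape_radius: float = 200.0  # nm
    smoothing_window: float = 0.025  # s, moving-average for peak/threshold work
    velocity_window: float = 0.0025  # s, light smoothing for snapback velocity
    min_attempt_duration: float = 0.02  # s, reject shorter excursions as blips
    merge_gap: float = 0.05  # s, sub-threshold gaps shorter than this do not split


def _odd_window(duration_s: float, fs: float) -> int:
    n = max(1, int(round(duration_s * fs)))
    return n if n % 2 == 1 else n + 1


def _bool_regions(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def detect_attempts(
    trace: ForceTrace, params: DetectionParams | None = None
) -> list[AttemptRecord]:
    """Parse a position trace into ordered, disjoint escape attempts.

    Returns an empty list (not an error) when no sample exceeds the
    excursion-start force. Raises :class:`InputError` on non-uniform
    sampling.
    """
    if params is None:
        params = DetectionParams()
    dt = trace.validate_uniform()
    fs = 1.0 / dt
    k = trace.trap_stiffness
    n = trace.position.size

    smooth = uniform_filter1d(
        trace.position, size=_odd_window(params.smoothing_window, fs), mode="nearest"
    )
    force = k * np.abs(smooth)

    above = force >= params.excursion_start_force
    regions = _bool_regions(above)
    if not regions:
        return []

    # sub-threshold gaps shorter than merge_gap do not split an attempt
    max_gap = int(round(params.merge_gap * fs))
    merged: list[list[int]] = []
    for start, stop in regions:
        if merged and start - merged[-1][1] < max_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    min_len = int(round(params.min_attempt_duration * fs))
    merged = [r for r in merged if r[1] - r[0] >= min_len]
    if not merged:
        return []

    # inward velocity from a lightly smoothed trace (snapback detection)
    fast = uniform_filter1d(
        trace.position, size=_odd_window(params.velocity_window, fs), mode="nearest"
    )
    velocity = np.gradient(fast, dt)
    inward = -velocity * np.sign(np.where(fast == 0, 1.0, fast))
    snap_len = max(1, int(round(params.snapback_min_duration * fs)))

    records: list[AttemptRecord] = []
    for idx, (start, stop) in enumerate(merged, start=1):
        seg_force = force[start:stop]
        peak = float(seg_force.max())
        persistence = float(np.count_nonzero(seg_force >= params.peak_fraction * peak) * dt)
        crossed = bool(np.max(np.abs(smooth[start:stop])) >= params.escape_radius)
        returned = stop < n  # excursion terminated by a return below threshold

        snapback = False
        if returned:
            fast_inward = inward[start:stop] >= params.snapback_speed_threshold
            snapback = any(
                (r_stop - r_start) >= snap_len for r_start, r_stop in _bool_regions(fast_inward)
            )

        outcome = "escaped" if (crossed and not returned) else "failed"
        # snapback flag is diagnostic: a returned excursion is failed whether
        # or not the return was fast enough to register as a snapback
        _ = snapback
        records.append(
            AttemptRecord(
                cargo_id=trace.cargo_id,
                attempt_index=idx,
                peak_force=peak,
                persistence_time=persistence,
                outcome=outcome,
                start_time=float(trace.time[start]),
                end_time=float(trace.time[min(stop, n - 1)]),
                experiment_id=trace.experiment_id,
                condition=trace.condition,
            )
        )
    return records


def escaped_fraction_counts(n_escaped: int, n: int) -> tuple[float, float]:
    """Escaped fraction and its binomial standard error sqrt(f(1-f)/n)."""
    if n <= 0:
        raise UndefinedValueError("escaped fraction undefined for n = 0")
    if not 0 <= n_escaped <= n:
        raise InputError(f"need 0 <= escaped <= n, got {n_escaped}/{n}")
    f = n_escaped / n
    return f, math.sqrt(f * (1.0 - f) / n)


def escaped_fraction(
    attempts: Sequence[AttemptRecord], attempt_index: int
) -> tuple[float, float]:
    """Escaped fraction among cargos that reached ``attempt_index``.

    The error is the binomial standard error sqrt(f(1-f)/n) over the n
    cargos that made the attempt.
    """
    at_index = [a for a in attempts if a.attempt_index == attempt_index]
    if not at_index:
        raise UndefinedValueError(f"no attempts at index {attempt_index}")
    n_escaped = sum(a.outcome == "escaped" for a in at_index)
    return escaped_fraction_counts(n_escaped, len(at_index))


@dataclass
class AdaptationProfile:
    """Per-attempt-index aggregate for one condition.

    ``table`` has one row per attempt index with columns
    ``mean_peak_force, sem_peak_force, mean_persistence, sem_persistence,
    escaped_fraction, escaped_se, n_cargos, p_force_vs_first,
    p_persistence_vs_first``. Means and SEMs are computed across
    *experiments* (each experiment contributes its cargo-level mean), not
    across pooled cargos; the escaped fraction pools cargos with the
    binomial error formula.
    """

    condition: str
    table: pd.DataFrame
    n_experiments: int
    experiment_means: pd.DataFrame = field(repr=False, default=None)
    sem_available: bool = True


def attempts_to_frame(attempts: Sequence[AttemptRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cargo_id": [a.cargo_id for a in attempts],
            "experiment_id": [a.experiment_id for a in attempts],
            "condition": [a.condition for a in attempts],
            "attempt_index": [a.attempt_index for a in attempts],
            "peak_force": [a.peak_force for a in attempts],
            "persistence_time": [a.persistence_time for a in attempts],
            "outcome": [a.outcome for a in attempts],
            "start_time": [a.start_time for a in attempts],
            "end_time": [a.end_time for a in attempts],
        }
    )


def adaptation_profile(
    attempts_by_experiment: Mapping[str, Sequence[AttemptRecord]],
    condition: str = "",
    max_attempt_index: int = 5,
    equal_var: bool = True,
) -> AdaptationProfile:
    """Two-level aggregation of attempts into a per-attempt profile.

    Within each experiment, cargo-level peak forces and persistence times
    are averaged at each attempt index; the profile then reports the mean
    and SEM of those per-experiment means. Attempt indices above
    ``max_attempt_index`` are ignored. Two-sided t-test p-values compare
    each attempt index against attempt 1 on the per-experiment means
    (Student's by default, Welch with ``equal_var=False``).

    With a single experiment the profile is still emitted, with SEMs set to
    NaN and ``sem_available=False``.
    """
    if not attempts_by_experiment:
        raise InputError("no experiments supplied")
    rows = []
    for exp_id, attempts in attempts_by_experiment.items():
        for a in attempts:
            if 1 <= a.attempt_index <= max_attempt_index:
                rows.append(
                    (
                        exp_id,
                        a.attempt_index,
                        a.peak_force,
                        a.persistence_time,
                        a.outcome == "escaped",
                    )
                )
    if not rows:
        raise InputError("no attempts within the aggregated index range")
    df = pd.DataFrame(
        rows, columns=["experiment_id", "attempt_index", "peak_force", "persistence_time", "escaped"]
    )
    exp_means = (
        df.groupby(["experiment_id", "attempt_index"])
        .agg(
            mean_peak_force=("peak_force", "mean"),
            mean_persistence=("persistence_time", "mean"),
            n_cargos=("peak_force", "size"),
        )
        .reset_index()
    )
    n_experiments = df["experiment_id"].nunique()
    sem_available = n_experiments >= 2

    out_rows = []
    for index in sorted(df["attempt_index"].unique()):
        sub = exp_means[exp_means["attempt_index"] == index]
        pooled = df[df["attempt_index"] == index]
        f, se = escaped_fraction_counts(int(pooled["escaped"].sum()), len(pooled))
        n_exp_here = len(sub)
        out_rows.append(
            {
                "attempt_index": int(index),
                "mean_peak_force": float(sub["mean_peak_force"].mean()),
                "sem_peak_force": float(sps.sem(sub["mean_peak_force"]))
                if n_exp_here >= 2
                else np.nan,
                "mean_persistence": float(sub["mean_persistence"].mean()),
                "sem_persistence": float(sps.sem(sub["mean_persistence"]))
                if n_exp_here >= 2
                else np.nan,
                "escaped_fraction": f,
                "escaped_se": se,
                "n_cargos": int(pooled["cargo_id"].size) if "cargo_id" in pooled else len(pooled),
                "n_experiments": n_exp_here,
            }
        )
    table = pd.DataFrame(out_rows).set_index("attempt_index", drop=False)

    # attempt-k vs attempt-1 comparisons on per-experiment means
    p_force = {1: np.nan}
    p_pers = {1: np.nan}
    first = exp_means[exp_means["attempt_index"] == 1]
    for index in table.index:
        if index == 1:
            continue
        sub = exp_means[exp_means["attempt_index"] == index]
        if len(sub) >= 2 and len(first) >= 2:
            p_force[index] = hypothesis_test(
                "t", sub["mean_peak_force"], first["mean_peak_force"], equal_var=equal_var
            ).p_value
            p_pers[index] = hypothesis_test(
                "t", sub["mean_persistence"], first["mean_persistence"], equal_var=equal_var
            ).p_value
        else:
            p_force[index] = np.nan
            p_pers[index] = np.nan
    table["p_force_vs_first"] = pd.Series(p_force)
    table["p_persistence_vs_first"] = pd.Series(p_pers)

    return AdaptationProfile(
        condition=condition,
        table=table,
        n_experiments=n_experiments,
        experiment_means=exp_means,
        sem_available=sem_available,
    )


@dataclass
class TrendFit:
    force_slope: float  # pN per attempt
    force_stderr: float
    persistence_slope: float  # s per attempt
    persistence_stderr: float


def fit_adaptation_trend(profile: AdaptationProfile) -> TrendFit:
    """OLS slopes of per-attempt mean force and persistence vs attempt index."""
    table = profile.table
    x = table["attempt_index"].to_numpy(dtype=float)
    if x.size < 2:
        raise UndefinedValueError("trend fit requires at least 2 attempt indices")
    fit_f = sps.linregress(x, table["mean_peak_force"].to_numpy(dtype=float))
    fit_p = sps.linregress(x, table["mean_persistence"].to_numpy(dtype=float))
    return TrendFit(
        force_slope=float(fit_f.slope),
        force_stderr=float(fit_f.stderr) if x.size > 2 else float("nan"),
        persistence_slope=float(fit_p.slope),
        persistence_stderr=float(fit_p.stderr) if x.size > 2 else float("nan"),
    )
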