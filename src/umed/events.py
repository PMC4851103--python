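"""Turn an interval classification into a temporal event sequence.

After the optimal classification, each maximal run of consecutive intervals
``[W_i .. W_j]`` sharing a group label delimits one state ``(E, t_E, d_E)``.
The run is mapped to a sample span by

    [ (i-1)*d + M*L_w - d/2 ,  (j-1)*d + M*L_w + d/2 ]

with localization constant ``M = 6/7`` (empirically more accurate than the
window midpoint ``M = 1/2``). The span uses exactly d samples per interval,
so spans of adjacent runs abut without overlap and every duration is
``(j - i + 1) * d / fs`` seconds.

The most populous group is, by default, treated as the event-free baseline
(in EEG terms: the cognitive background); its runs are kept separately as
the portions without events (PWA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

M_DEFAULT = 6.0 / 7.0


@dataclass(frozen=True)
class State:
    """One detected event: label, onset (s), duration (s), plus provenance."""

    label: int
    t_onset: float
    duration: float
    run: tuple[int, int]            # 1-based interval run (i, j)
    start_sample: float             # possibly fractional
    end_sample: float


@dataclass
class EventSequence:
    """Temporal sequence P = <(E, t_E, d_E), ...> plus baseline spans."""

    states: list[State]
    baseline_runs: list[tuple[int, int, float, float]]  # (i, j, start_s, end_s)
    baseline_label: int
    fs: float
    d: int
    L_w: int
    M: float = M_DEFAULT

    def __len__(self) -> int:
        return len(self.states)

    def labels(self) -> list[int]:
        return [s.label for s in self.states]


def group_consecutive(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal consecutive labels, as (label, i, j) 1-based.

    Every interval belongs to exactly one run; runs are in temporal order.
    """
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.shape[0] < 1:
        raise ValueError("need a non-empty 1-D label vector")
    change = np.flatnonzero(labels[1:] != labels[:-1])
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(labels) - 1]])
    return [(int(labels[s]), int(s + 1), int(e + 1))
            for s, e in zip(starts, ends)]


def localize(i: int, j: int, d: int, L_w: int,
             M: float = M_DEFAULT) -> tuple[float, float]:
    """Sample span of the run of intervals W_i..W_j (1-based, inclusive).

    Returns fractional sample positions; ``end - start == (j - i + 1) * d``
    identically.
    """
    if i < 1 or j < i:
        raise ValueError(f"need 1 <= i <= j, got i={i}, j={j}")
    if d <= 0 or L_w <= 0:
        raise ValueError("d and L_w must be positive")
    start = (i - 1) * d + M * L_w - d / 2.0
    end = (j - 1) * d + M * L_w + d / 2.0
    return start, end


def build_sequence(runs, d: int, L_w: int, fs: float, baseline_label: int,
                   M: float = M_DEFAULT, t_start: float = 0.0,
                   prefix_samples: int = 0) -> EventSequence:
    """Assemble the event sequence from labeled interval runs.

    Non-baseline runs become states localized on the sample axis and
    expressed in seconds; baseline runs are retained as event-free spans.
    ``prefix_samples`` shifts spans left by that amount (a synthetic
    event-free prefix prepended before analysis): runs entirely inside the
    prefix are dropped, runs straddling it are clipped at real sample 0.
    """
    states: list[State] = []
    baseline: list[tuple[int, int, float, float]] = []
    for label, i, j in runs:
        s0, s1 = localize(i, j, d, L_w, M)
        s0 -= prefix_samples
        s1 -= prefix_samples
        if s1 <= 0:
            continue
        s0 = max(s0, 0.0)
        if label == baseline_label:
            baseline.append((i, j, t_start + s0 / fs, t_start + s1 / fs))
        else:
            states.append(State(
                label=label,
                t_onset=t_start + s0 / fs,
                duration=(s1 - s0) / fs,
                run=(i, j),
                start_sample=s0,
                end_sample=s1,
            ))
    return EventSequence(states=states, baseline_runs=baseline,
                         baseline_label=baseline_label, fs=fs, d=d, L_w=L_w,
                         M=M)


def truncate2(x: float) -> float:
    """Truncate (not round) to 2 decimals, the display convention for
    durations (0.375 s prints as 0.37 s); machine-readable output keeps
    full precision."""
    return math.floor(x * 100.0) / 100.0


def event_stats(seq: EventSequence) -> tuple[pd.DataFrame, int]:
    """Per-label occurrence counts and durations, plus the NIC.

    Returns ``(table, nic)``: one row per event label with occurrence count,
    total and mean duration in seconds; NIC (number of independent
    components for downstream ICA) = number of distinct labels present,
    baseline included.
    """
    rows = {}
    for s in seq.states:
        r = rows.setdefault(s.label, {"label": s.label, "count": 0,
                                      "total_duration_s": 0.0})
        r["count"] += 1
        r["total_duration_s"] += s.duration
    table = pd.DataFrame(
        sorted(rows.values(), key=lambda r: r["label"]),
        columns=["label", "count", "total_duration_s"],
    )
    if len(table):
        table["mean_duration_s"] = table["total_duration_s"] / table["count"]
    else:
        table["mean_duration_s"] = pd.Series(dtype=float)
    return table, nic(seq)


def nic(seq: EventSequence, t0: float | None = None,
        t1: float | None = None) -> int:
    """Number of distinct cluster labels present in a time span.

    Baseline counts as one component; with no events anywhere in the span
    the NIC is 1 (baseline only). ``t0``/``t1`` default to the whole
    sequence.
    """
    def overlaps(a0: float, a1: float) -> bool:
        lo = -np.inf if t0 is None else t0
        hi = np.inf if t1 is None else t1
        return a1 > lo and a0 < hi

    labels = {s.label for s in seq.states
              if overlaps(s.t_onset, s.t_onset + s.duration)}
    if t0 is None and t1 is None:
        base = 1  # baseline always present across the whole recording
    else:
        base = int(any(overlaps(b0, b1) for _, _, b0, b1 in seq.baseline_runs))
        base = max(base, 0 if labels else 1)
    return len(labels) + base
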