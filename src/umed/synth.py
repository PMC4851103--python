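"""Synthetic multichannel signals with planted, labeled event regimes.

Every channel follows a stationary baseline AR(2) process; events are short
segments where the samples are generated by a different AR(2) regime
instead (``mode="replace"``, the default — features are then cleanly
regime-determined) or where an independent realization of the event process
is added on top of the running baseline (``mode="additive"``, closer to how
real EEG artifacts superimpose on the cognitive signal, and a harder test).
Event timing is shared across channels, emulating the cross-channel
correlation of real multichannel events; the sample paths are independently
seeded per channel.

The generator always places an event-free prefix of at least ``min_gap``
samples first, so the initial event-free period the detector needs is
guaranteed, and returns per-sample ground-truth labels from which
majority-vote interval labels can be derived for any (L_w, d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .signal import MultichannelSignal
from .windows import make_windows

_BURN_IN = 512


@dataclass(frozen=True)
class RegimeSpec:
    """One AR(2) regime: label, coefficients, gain and occurrence plan.

    ``ar_coeffs = (a_1, a_2)`` in the convention
    ``x[t] = a_1 x[t-1] + a_2 x[t-2] + e[t]`` and must lie inside the
    stationarity triangle ``|a_2| < 1``, ``a_1 + a_2 < 1``,
    ``a_2 - a_1 < 1``.
    """

    label: str
    ar_coeffs: tuple[float, float]
    gain: float = 1.0
    duration: int = 0          # samples per occurrence (events only)
    occurrences: int = 1

    def __post_init__(self) -> None:
        a1, a2 = self.ar_coeffs
        if not (abs(a2) < 1 and a1 + a2 < 1 and a2 - a1 < 1):
            raise ValueError(
                f"regime {self.label!r}: ({a1}, {a2}) is outside the AR(2) "
                "stationarity triangle"
            )


@dataclass
class GroundTruth:
    """Per-sample regime labels plus the planted event list."""

    sample_labels: np.ndarray               # T strings
    events: list[tuple[str, int, int]]      # (label, start, end) samples, end exclusive
    baseline_label: str

    def interval_labels(self, L_w: int, d: int) -> np.ndarray:
        """Majority regime per sliding window, for any (L_w, d)."""
        ws = make_windows(len(self.sample_labels), L_w, d)
        out = np.empty(ws.IN, dtype=object)
        for idx, s in enumerate(ws.starts):
            seg = self.sample_labels[s:s + L_w]
            vals, counts = np.unique(seg, return_counts=True)
            out[idx] = vals[np.argmax(counts)]
        return out


def _simulate_ar2(a1: float, a2: float, n: int, sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    e = rng.standard_normal(n + _BURN_IN) * sd
    x = lfilter([1.0], [1.0, -a1, -a2], e)
    return x[_BURN_IN:]


def generate(baseline: RegimeSpec, events: list[RegimeSpec], Q: int, T: int,
             fs: float, noise_sd: float = 1.0, min_gap: int = 256,
             seed: int = 0, mode: str = "replace",
             ) -> tuple[MultichannelSignal, GroundTruth]:
    """Generate a Q x T multichannel signal with planted AR(2) events.

    Occurrences of all event regimes are placed in seeded-random order with
    gaps of at least ``min_gap`` baseline samples before each (so the first
    ``min_gap`` samples are always event-free); slack is spread randomly
    over the gaps. Same seed, same output, bit for bit.
    """
    if mode not in {"replace", "additive"}:
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    occ = [spec for spec in events for _ in range(spec.occurrences)]
    for spec in occ:
        if spec.duration < 1:
            raise ValueError(f"event regime {spec.label!r} needs duration >= 1")
    order = rng.permutation(len(occ))
    occ = [occ[i] for i in order]
    total_ev = sum(s.duration for s in occ)
    slack = T - total_ev - min_gap * len(occ)
    if slack < 0:
        raise ValueError(
            f"overcrowded timeline: {total_ev} event samples + "
            f"{min_gap * len(occ)} gap samples exceed T={T}"
        )
    extra = rng.multinomial(slack, np.full(len(occ) + 1, 1.0 / (len(occ) + 1)))
    placements: list[tuple[RegimeSpec, int]] = []
    cursor = 0
    for g, spec in enumerate(occ):
        cursor += min_gap + int(extra[g])
        placements.append((spec, cursor))
        cursor += spec.duration

    labels = np.full(T, baseline.label, dtype=object)
    ev_list: list[tuple[str, int, int]] = []
    for spec, start in placements:
        labels[start:start + spec.duration] = spec.label
        ev_list.append((spec.label, start, start + spec.duration))

    # Segment timeline: alternating baseline and event stretches.
    segments: list[tuple[RegimeSpec, int, int]] = []
    cursor = 0
    for spec, start in placements:
        if start > cursor:
            segments.append((baseline, cursor, start))
        segments.append((spec, start, start + spec.duration))
        cursor = start + spec.duration
    if cursor < T:
        segments.append((baseline, cursor, T))

    a1, a2 = baseline.ar_coeffs
    samples = np.empty((Q, T))
    for q in range(Q):
        samples[q] = baseline.gain * _simulate_ar2(a1, a2, T, noise_sd, rng)
        for spec, s0, s1 in segments:
            if spec is baseline:
                continue
            b1, b2 = spec.ar_coeffs
            seg = spec.gain * _simulate_ar2(b1, b2, s1 - s0, noise_sd, rng)
            if mode == "replace":
                samples[q, s0:s1] = seg
            else:
                samples[q, s0:s1] += seg

    signal = MultichannelSignal(samples=samples, fs=fs)
    truth = GroundTruth(sample_labels=labels, events=ev_list,
                        baseline_label=baseline.label)
    return signal, truth


def study_conditions() -> dict:
    """The package's reference synthetic-study conditions.

    A 60 s, 4-channel recording at 256 Hz: baseline AR(0.3, 0.2) with three
    event regimes at well-separated corners of the stationarity triangle,
    two 3 s occurrences each, and at least 2 s of baseline before every
    event. Used by the recovery tests and the worked example.
    """
    return dict(
        baseline=RegimeSpec("baseline", (0.3, 0.2)),
        events=[
            RegimeSpec("resonant", (1.6, -0.9), duration=768, occurrences=2),
            RegimeSpec("alternating", (-1.2, -0.5), duration=768, occurrences=2),
            RegimeSpec("oscillatory", (0.0, -0.8), duration=768, occurrences=2),
        ],
        Q=4,
        T=60 * 256,
        fs=256.0,
        noise_sd=1.0,
        min_gap=512,
    )
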