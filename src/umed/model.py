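"""The UMED model: joint optimization of window size and cluster count.

The detector never sees labels. For a grid of window sizes it extracts the
AR(2) feature matrix, builds one average-linkage dendrogram per size, cuts
it at every candidate group count g, and scores each cut with the S_Dbw
validity index. The per-size minimum ``MIn^m`` (at group count ``No^m``)
is minimized again across sizes; the overall minimum ``MIn^H`` fixes the
optimal window ``L_w^H`` and group count ``No^H``, and the final
classification is the cut of the ``L_w^H`` dendrogram into ``No^H`` groups.

Before the grid runs, a cheap gate discards window sizes whose dendrogram
does not represent the feature distances faithfully: the smallest candidate
size whose cophenetic correlation reaches the threshold U (default 0.85)
starts the grid.

The recording must open with an event-free stretch longer than the largest
window tested; when the caller cannot guarantee one, a synthetic event-free
prefix (white noise, amplitude matched to the start of the recording) is
prepended and later clipped out of the reported events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import events as ev
from . import metrics
from .signal import MultichannelSignal, read_signal, write_events
from .windows import (DegenerateWindowError, FeatureMatrix, WindowSet,
                      feature_matrix, make_windows)


def default_candidates(fs: float, T: int) -> list[int]:
    """Default window-size schedule for the CCC gate.

    Doubling then linear: 32, 64, then +32 steps up to one second of
    samples (and never beyond the signal length).
    """
    top = int(min(round(fs), T))
    sizes = [s for s in (32, 64) if s <= top]
    s = 96
    while s <= top:
        sizes.append(s)
        s += 32
    if not sizes:
        raise ValueError(f"signal too short for any candidate window (T={T})")
    return sizes


@dataclass
class SearchConfig:
    """Run configuration for the window/cluster-count search.

    Parameters
    ----------
    d : int
        Slide width in samples (never optimized; 32 by default).
    U : float
        CCC gate threshold in (0, 1); "reaches approximately U" is
        implemented as CCC >= U - ccc_tolerance.
    candidate_sizes : sequence of int, optional
        Increasing window sizes for the gate; defaults to
        :func:`default_candidates`.
    D_L, N_L : int
        Grid step (samples) and number of increments: sizes tested are
        ``L_w^0 + m * D_L`` for m = 0..N_L.
    N_G : int
        Partition counts tested are 2..N_G+1.
    ipt : int or None
        Length in samples of the known initial event-free period; None
        means unknown, in which case a synthetic event-free prefix is
        prepended.
    seed : int
        Seeds the synthetic prefix (the search itself is deterministic).
    """

    d: int = 32
    U: float = 0.85
    ccc_tolerance: float = 0.001
    candidate_sizes: tuple[int, ...] | None = None
    D_L: int = 5
    N_L: int = 6
    N_G: int = 9
    ipt: int | None = None
    seed: int = 0
    sdbw_stdev_variant: str = "printed"
    M: float = ev.M_DEFAULT
    baseline_label: int | None = None
    order: int = 2
    max_extension_rounds: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.U < 1:
            raise ValueError(f"U must be in (0, 1), got {self.U}")
        if self.D_L < 1 or self.N_L < 0 or self.N_G < 2 or self.d < 1:
            raise ValueError("need D_L >= 1, N_L >= 0, N_G >= 2, d >= 1")


@dataclass
class _SizeEntry:
    """Everything computed for one window size L_w^m."""

    L_w: int
    window_set: WindowSet
    FV: FeatureMatrix
    tree: np.ndarray
    ccc: float
    sdbw: dict[int, float] = field(default_factory=dict)

    def score(self, g_values, variant: str) -> None:
        for g in g_values:
            if g in self.sdbw or g > self.FV.values.shape[0]:
                continue
            labels = metrics.cut_tree(self.tree, g)
            self.sdbw[g] = metrics.s_dbw(self.FV, labels,
                                         stdev_variant=variant)

    def _first_minimum(self) -> tuple[int, float] | None:
        """First well-surrounded minimum of S_Dbw over the scanned g.

        Scanning group counts upward, the optimum is the first g whose
        index does not improve at g+1 — the sequential stopping rule the
        online mode uses, and identical to the global minimum whenever the
        index is U-shaped in g. Returns None when the index is still
        decreasing at the largest scanned g (minimum at the partition
        boundary; the caller extends the scan).
        """
        gs = sorted(self.sdbw)
        for a, b in zip(gs, gs[1:]):
            if self.sdbw[a] <= self.sdbw[b]:
                return a, self.sdbw[a]
        return None

    @property
    def No(self) -> int:
        found = self._first_minimum()
        return sorted(self.sdbw)[-1] if found is None else found[0]

    @property
    def MIn(self) -> float:
        found = self._first_minimum()
        return min(self.sdbw.values()) if found is None else found[1]


@dataclass
class ScanResult:
    """Grid-search record: per-size (L_w, CCC, No, MIn) and the optimum."""

    entries: list[_SizeEntry]
    opt_index: int
    L_w0: int
    config: SearchConfig
    N_G_final: int

    @property
    def L_w_opt(self) -> int:
        return self.entries[self.opt_index].L_w

    @property
    def No_opt(self) -> int:
        return self.entries[self.opt_index].No

    @property
    def MIn_opt(self) -> float:
        return self.entries[self.opt_index].MIn

    @property
    def CCC_opt(self) -> float:
        return self.entries[self.opt_index].ccc

    @property
    def FV_opt(self) -> FeatureMatrix:
        return self.entries[self.opt_index].FV

    @property
    def tree_opt(self) -> np.ndarray:
        return self.entries[self.opt_index].tree

    def to_frame(self) -> pd.DataFrame:
        """Scan table: one row per window size, like the run report."""
        return pd.DataFrame(
            {
                "L_w": [e.L_w for e in self.entries],
                "CCC": [e.ccc for e in self.entries],
                "No": [e.No for e in self.entries],
                "MIn": [e.MIn for e in self.entries],
            }
        )


def _eval_size(signal: MultichannelSignal, L_w: int,
               cfg: SearchConfig) -> _SizeEntry:
    ws = make_windows(signal, L_w, cfg.d)
    try:
        FV = feature_matrix(signal, ws, order=cfg.order)
    except DegenerateWindowError as err:
        raise DegenerateWindowError(
            f"L_w={L_w}: {err}", window=err.window, channel=err.channel
        ) from err
    tree = metrics.linkage_average(FV)
    ccc = metrics.cophenetic_correlation(FV, tree)
    return _SizeEntry(L_w=L_w, window_set=ws, FV=FV, tree=tree, ccc=ccc)


def select_min_window(signal: MultichannelSignal,
                      cfg: SearchConfig) -> int:
    """Smallest candidate window size whose CCC reaches the gate U.

    Scans the candidate sizes in increasing order and stops at the first
    one with CCC >= U - ccc_tolerance. Raises with the full (size, CCC)
    list when no candidate passes, so the caller can extend the schedule.
    """
    sizes = cfg.candidate_sizes
    if sizes is None:
        sizes = default_candidates(signal.fs, signal.n_samples)
    sizes = [int(s) for s in sizes]
    if not sizes or any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("candidate_sizes must be non-empty and increasing")
    if sizes[-1] > signal.n_samples:
        raise ValueError("largest candidate window exceeds the signal")
    tried = []
    for L_w in sizes:
        entry = _eval_size(signal, L_w, cfg)
        tried.append((L_w, entry.ccc))
        if entry.ccc >= cfg.U - cfg.ccc_tolerance:
            return L_w
    raise ValueError(
        "no candidate window reaches the CCC gate "
        f"U={cfg.U}: " + ", ".join(f"(L_w={s}, CCC={c:.4f})" for s, c in tried)
        + "; extend candidate_sizes"
    )


def grid_search(signal: MultichannelSignal, L_w0: int,
                cfg: SearchConfig) -> ScanResult:
    """Score the window-size grid and locate the S_Dbw optimum.

    Sizes ``L_w^m = L_w^0 + m * D_L`` (m = 0..N_L) are each clustered once;
    the dendrogram is cut at every g in 2..N_G+1 and scored with S_Dbw.
    ``No^m`` is the first well-surrounded minimum of the index in g (the
    global minimum for a U-shaped index; see ``_first_minimum`` for the
    degenerate-tail rationale) and ``MIn^m`` its value. If some size's
    index is still decreasing at the partition boundary g = N_G+1, N_G is
    enlarged and all sizes re-scored at the new counts; if the overall
    optimum lands at the largest size, the grid is extended upward. Both
    extensions are capped; hitting the cap raises with diagnostics.
    """
    if L_w0 + cfg.N_L * cfg.D_L > signal.n_samples:
        raise ValueError("grid exceeds signal length; reduce N_L or D_L")
    sizes = [L_w0 + m * cfg.D_L for m in range(cfg.N_L + 1)]
    entries = [_eval_size(signal, L, cfg) for L in sizes]
    n_g = cfg.N_G
    ng_rounds = nl_rounds = 0
    while True:
        for e in entries:
            e.score(range(2, n_g + 2), cfg.sdbw_stdev_variant)
        pending = [e for e in entries if e._first_minimum() is None]
        if pending and ng_rounds < cfg.max_extension_rounds:
            ng_rounds += 1
            n_g += max(2, cfg.N_G // 2)
            continue
        valid = [e for e in entries if e._first_minimum() is not None]
        if not valid:
            raise RuntimeError(
                f"no window size has a well-surrounded S_Dbw minimum up to "
                f"g={n_g + 1} after {ng_rounds} extensions; scan table:\n"
                f"{ScanResult(entries, 0, L_w0, cfg, n_g).to_frame()}"
            )
        if pending:
            warnings.warn(
                "S_Dbw still decreasing at g="
                f"{n_g + 1} for L_w in {[e.L_w for e in pending]}; these "
                "sizes have no well-surrounded optimum and are excluded",
                stacklevel=2,
            )
        mins = [e.MIn if e._first_minimum() is not None else np.inf
                for e in entries]
        opt = int(np.argmin(mins))        # tie -> smaller L_w
        if opt == len(entries) - 1 and cfg.N_L > 0:
            if nl_rounds >= cfg.max_extension_rounds:
                raise RuntimeError(
                    f"window-size optimum still at the grid edge after "
                    f"{nl_rounds} extensions (largest L_w="
                    f"{entries[-1].L_w}); scan table:\n"
                    f"{ScanResult(entries, opt, L_w0, cfg, n_g).to_frame()}"
                )
            new_sizes = [entries[-1].L_w + (i + 1) * cfg.D_L
                         for i in range(2)]
            if new_sizes[-1] > signal.n_samples:
                raise RuntimeError(
                    "grid extension exceeds the signal length"
                )
            if cfg.ipt is not None and new_sizes[-1] >= cfg.ipt:
                warnings.warn(
                    "grid extension exceeds the declared event-free period; "
                    "consider a synthetic prefix (ipt=None)",
                    stacklevel=2,
                )
            nl_rounds += 1
            entries.extend(_eval_size(signal, L, cfg) for L in new_sizes)
            continue
        return ScanResult(entries=entries, opt_index=opt, L_w0=L_w0,
                          config=cfg, N_G_final=n_g)


def classify_optimal(scan: ScanResult) -> np.ndarray:
    """Final classification: cut the optimal dendrogram into No^H groups.

    Group numbers 1..No^H are assigned in order of first appearance along
    the time axis.
    """
    return metrics.cut_tree(scan.tree_opt, scan.No_opt)


@dataclass
class IncrementalResult:
    """Outcome of classifying a batch of new intervals against a reference.

    ``labels`` gives each new interval the inherited reference group label,
    or a fresh label (> reference group count) where ``is_new`` is True —
    a new event type not present in the reference. ``updated_reference``
    and ``updated_labels`` are the reference dataset after the batch:
    recognized intervals removed, novel ones retained.
    """

    labels: np.ndarray
    is_new: np.ndarray
    n_groups: int
    ind_values: dict[int, float]
    updated_reference: np.ndarray
    updated_labels: np.ndarray


def incremental_classify(scan: ScanResult | None, new_rows: np.ndarray,
                         n_int: int | None = None,
                         reference: np.ndarray | None = None,
                         reference_labels: np.ndarray | None = None,
                         max_extra_groups: int = 10,
                         stdev_variant: str | None = None) -> IncrementalResult:
    """Classify new intervals against a fitted reference (online mode).

    The batch of feature rows (computed with the reference's L_w^H and d)
    is appended to the reference dataset; S_Dbw is evaluated at successive
    group counts g = No^H, No^H+1, ... (``IndN`` values), stopping at the
    first g whose index is smaller than the next one. Hierarchical
    clustering at that g assigns the batch: rows landing in clusters that
    contain reference intervals inherit the majority reference label and
    are dropped from the dataset; rows forming reference-free clusters are
    flagged as a new event type and retained.

    Either ``scan`` (a fitted grid search) or explicit ``reference`` +
    ``reference_labels`` arrays must be given.
    """
    if scan is None and (reference is None or reference_labels is None):
        raise ValueError("need a ScanResult or reference + reference_labels")
    ref = scan.FV_opt.values if reference is None else np.asarray(reference)
    ref_labels = (classify_optimal(scan) if reference_labels is None
                  else np.asarray(reference_labels))
    if stdev_variant is None:
        stdev_variant = (scan.config.sdbw_stdev_variant if scan is not None
                         else "printed")
    new_rows = np.atleast_2d(np.asarray(new_rows, dtype=float))
    if new_rows.shape[1] != ref.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: reference has {ref.shape[1]}, "
            f"new rows have {new_rows.shape[1]}"
        )
    if n_int is not None and new_rows.shape[0] != n_int:
        raise ValueError(f"expected {n_int} new rows, got {new_rows.shape[0]}")

    X = np.vstack([ref, new_rows])
    tree = metrics.linkage_average(X)
    no_h = int(ref_labels.max())
    ind: dict[int, float] = {}

    def ind_at(g: int) -> float:
        if g not in ind:
            ind[g] = metrics.s_dbw(X, metrics.cut_tree(tree, g),
                                   stdev_variant=stdev_variant)
        return ind[g]

    g_star = None
    for g in range(no_h, no_h + max_extra_groups):
        if ind_at(g) < ind_at(g + 1):
            g_star = g
            break
    if g_star is None:
        raise RuntimeError(
            f"S_Dbw kept decreasing up to g={no_h + max_extra_groups}; "
            "the batch does not resemble the reference"
        )

    combined = metrics.cut_tree(tree, g_star)
    n_ref = ref.shape[0]
    out = np.zeros(new_rows.shape[0], dtype=np.int64)
    is_new = np.zeros(new_rows.shape[0], dtype=bool)
    next_new = no_h + 1
    for c in np.unique(combined):
        in_ref = combined[:n_ref] == c
        in_new = combined[n_ref:] == c
        if not np.any(in_new):
            continue
        if np.any(in_ref):
            vals, counts = np.unique(ref_labels[in_ref], return_counts=True)
            out[in_new] = vals[np.argmax(counts)]
        else:
            out[in_new] = next_new
            is_new[in_new] = True
            next_new += 1
    updated_ref = np.vstack([ref, new_rows[is_new]])
    updated_labels = np.concatenate([ref_labels, out[is_new]])
    return IncrementalResult(labels=out, is_new=is_new, n_groups=g_star,
                             ind_values=dict(ind),
                             updated_reference=updated_ref,
                             updated_labels=updated_labels)


class UMED:
    """Unsupervised multichannel event detector.

    Parameters
    ----------
    signal : MultichannelSignal
        The recording to analyze.
    config : SearchConfig, optional
        Full run configuration; keyword overrides (``d=...``, ``U=...``,
        ``N_G=...`` etc.) are applied on top.

    Examples
    --------
    >>> from umed import UMED, synth
    >>> sig, truth = synth.generate(**synth.study_conditions(), seed=7)
    >>> res = UMED(sig, ipt=512, candidate_sizes=(64, 96, 128),
    ...            D_L=8, N_L=6, N_G=5).fit()
    >>> res.No_opt                                        # doctest: +SKIP
    4
    """

    def __init__(self, signal: MultichannelSignal,
                 config: SearchConfig | None = None, **overrides):
        self.signal = signal
        cfg = config if config is not None else SearchConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        self.config = cfg

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fs: float,
                       **kwargs) -> "UMED":
        """Build from a samples-by-channels DataFrame."""
        sig = MultichannelSignal(samples=df.to_numpy(dtype=float).T, fs=fs,
                                 channel_labels=[str(c) for c in df.columns])
        return cls(sig, **kwargs)

    @classmethod
    def from_file(cls, path, format: str | None = None,
                  fs: float | None = None, **kwargs) -> "UMED":
        """Build from an EDF or CSV recording on disk."""
        return cls(read_signal(path, format=format, fs=fs), **kwargs)

    def _padded(self) -> tuple[MultichannelSignal, int]:
        """Prepend a synthetic event-free prefix when the IPT requires it."""
        cfg = self.config
        sig = self.signal
        # Worst-case largest window after capped grid extensions.
        budget = ((max(cfg.candidate_sizes) if cfg.candidate_sizes
                   else int(min(round(sig.fs), sig.n_samples)))
                  + (cfg.N_L + 2 * cfg.max_extension_rounds) * cfg.D_L)
        if cfg.ipt is not None and budget < cfg.ipt:
            return sig, 0
        prefix_len = budget + cfg.d
        rng = np.random.default_rng(cfg.seed)
        head = sig.samples[:, :min(budget, sig.n_samples)]
        sd = head.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        prefix = rng.standard_normal((sig.n_channels, prefix_len)) * sd
        padded = MultichannelSignal(
            samples=np.hstack([prefix, sig.samples]),
            fs=sig.fs,
            channel_labels=sig.channel_labels,
            t_start=sig.t_start,
        )
        return padded, prefix_len

    def fit(self) -> "UMEDResults":
        """Run the full pipeline and return the results object.

        Gate the window size by CCC, grid-search (window size x group
        count) under S_Dbw, classify at the optimum, and build the event
        sequence. Fully deterministic for a given signal and config.
        """
        cfg = self.config
        work, prefix = self._padded()
        L_w0 = select_min_window(work, cfg)
        scan = grid_search(work, L_w0, cfg)
        if scan.CCC_opt < cfg.U - cfg.ccc_tolerance:
            warnings.warn(
                f"CCC at the optimal window ({scan.CCC_opt:.4f}) is below "
                f"the gate U={cfg.U}", stacklevel=2,
            )
        labels = classify_optimal(scan)
        if cfg.baseline_label is not None:
            baseline = cfg.baseline_label
        else:
            counts = np.bincount(labels)
            baseline = int(np.argmax(counts))
        runs = ev.group_consecutive(labels)
        seq = ev.build_sequence(runs, cfg.d, scan.L_w_opt, work.fs,
                                baseline, M=cfg.M,
                                t_start=self.signal.t_start,
                                prefix_samples=prefix)
        return UMEDResults(model=self, scan=scan, labels=labels, events=seq,
                           baseline_label=baseline, prefix_samples=prefix)


class UMEDResults:
    """Fit results: scan table, optimal classification, event sequence."""

    def __init__(self, model: UMED, scan: ScanResult, labels: np.ndarray,
                 events: ev.EventSequence, baseline_label: int,
                 prefix_samples: int):
        self.model = model
        self.scan = scan
        self.labels = labels
        self.events = events
        self.baseline_label = baseline_label
        self.prefix_samples = prefix_samples

    # -- convenience accessors -------------------------------------------
    @property
    def L_w_opt(self) -> int:
        return self.scan.L_w_opt

    @property
    def No_opt(self) -> int:
        return self.scan.No_opt

    @property
    def MIn_opt(self) -> float:
        return self.scan.MIn_opt

    @property
    def CCC_opt(self) -> float:
        return self.scan.CCC_opt

    @property
    def feature_matrix(self) -> FeatureMatrix:
        return self.scan.FV_opt

    def scan_table(self) -> pd.DataFrame:
        return self.scan.to_frame()

    def group_sizes(self) -> pd.Series:
        """Intervals per group, indexed G1..Gk."""
        counts = np.bincount(self.labels)[1:]
        return pd.Series(counts, index=[f"G{i + 1}" for i in
                                        range(len(counts))], name="intervals")

    def event_stats(self) -> pd.DataFrame:
        table, _ = ev.event_stats(self.events)
        return table

    def nic(self, t0: float | None = None, t1: float | None = None) -> int:
        """Number of independent components in a time span (for ICA)."""
        return ev.nic(self.events, t0, t1)

    def classify_increment(self, new_rows, n_int: int | None = None,
                           ) -> IncrementalResult:
        """Online mode: classify a batch of new intervals (see
        :func:`incremental_classify`)."""
        return incremental_classify(self.scan, new_rows, n_int=n_int)

    def save_events(self, path) -> None:
        """Write the events CSV plus the JSON run report."""
        write_events(self.events, path, params=self.report())

    def report(self) -> dict:
        cfg = self.model.config
        return {
            "L_w_opt": int(self.L_w_opt),
            "No_opt": int(self.No_opt),
            "MIn_opt": float(self.MIn_opt),
            "CCC_opt": float(self.CCC_opt),
            "L_w0": int(self.scan.L_w0),
            "d": int(cfg.d),
            "U": float(cfg.U),
            "baseline_label": int(self.baseline_label),
            "n_intervals": int(len(self.labels)),
            "n_events": len(self.events),
            "nic": self.nic(),
            "prefix_samples": int(self.prefix_samples),
            "scan": self.scan_table().to_dict(orient="records"),
        }

    def plot_clusters(self, ax=None):
        from .viz import plot_clusters
        return plot_clusters(self.feature_matrix, self.labels, ax=ax)

    def summary(self) -> str:
        """Human-readable run summary (scan table and optimum)."""
        sig = self.model.signal
        cfg = self.model.config
        lines = [
            "UMED fit summary".center(64),
            "=" * 64,
            f"Channels: {sig.n_channels:<6d} Samples: {sig.n_samples:<10d} "
            f"fs: {sig.fs:g} Hz",
            f"Slide d: {cfg.d:<7d} CCC gate U: {cfg.U:<8g} "
            f"Gate window L_w^0: {self.scan.L_w0}",
            "-" * 64,
            f"{'L_w':>6} {'CCC':>10} {'No':>5} {'MIn':>10}",
        ]
        for _, row in self.scan_table().iterrows():
            lines.append(f"{int(row.L_w):>6} {row.CCC:>10.4f} "
                         f"{int(row.No):>5} {row.MIn:>10.4f}")
        lines += [
            "-" * 64,
            f"Optimum: L_w^H={self.L_w_opt}, No^H={self.No_opt}, "
            f"MIn^H={self.MIn_opt:.4f}, CCC^H={self.CCC_opt:.4f}",
            f"Baseline group: G{self.baseline_label} "
            f"({int(np.sum(self.labels == self.baseline_label))} of "
            f"{len(self.labels)} intervals)",
            f"Events: {len(self.events)} states, "
            f"{len(set(self.events.labels()))} distinct types, "
            f"NIC={self.nic()}",
            "=" * 64,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<UMEDResults L_w^H={self.L_w_opt} No^H={self.No_opt} "
                f"MIn^H={self.MIn_opt:.4f} events={len(self.events)}>")
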