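"""Multichannel signal container and I/O.

A multichannel (MC) signal is a set of simultaneously recorded,
cross-correlated channels ``X(t) = [CH_1(t) ... CH_Q(t)]`` sampled at a
common rate. Supported on-disk formats are EDF/EDF+ (read, via :mod:`mne`)
and a plain CSV layout (read/write): one row per sample, one column per
channel, a header row of channel labels, and the sampling rate in a leading
``# fs=<Hz>`` comment line.

All sample indexing in this package is 0-based; window (interval) numbering
exposed to users is 1-based (W_1 .. W_IN).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class MultichannelSignal:
    """A Q-channel recording of T samples at a common sampling rate.

    Parameters
    ----------
    samples : ndarray, shape (Q, T)
        Channel-major sample matrix, arbitrary units; must be finite.
    fs : float
        Sampling rate in Hz, > 0.
    channel_labels : list of str, optional
        Q unique labels; defaults to ``CH1 .. CHQ``.
    t_start : float
        Time of sample 0 in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str] = field(default=None)  # type: ignore[assignment]
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D (Q, T) matrix")
        q, t = self.samples.shape
        if q < 1 or t < 2:
            raise ValidationError(f"need Q >= 1 and T >= 2, got Q={q}, T={t}")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValidationError(f"sampling rate must be > 0, got {self.fs}")
        bad = np.argwhere(~np.isfinite(self.samples))
        if bad.size:
            ch, idx = bad[0]
            label = (
                self.channel_labels[ch]
                if self.channel_labels is not None
                else f"CH{ch + 1}"
            )
            raise ValidationError(
                f"non-finite sample in channel {label!r} at index {idx}"
            )
        if self.channel_labels is None:
            self.channel_labels = [f"CH{i + 1}" for i in range(q)]
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != q:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {q} channels"
            )
        if len(set(self.channel_labels)) != q:
            raise ValidationError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples.T, columns=self.channel_labels)


def read_signal(path: str | Path, format: str | None = None,
                fs: float | None = None) -> MultichannelSignal:
    """Read a multichannel recording from EDF or CSV.

    Parameters
    ----------
    path : path
        Input file.
    format : {"edf", "csv"}, optional
        Inferred from the file suffix when omitted.
    fs : float, optional
        Sampling rate for CSV files lacking a ``# fs=`` header line.

    Returns
    -------
    MultichannelSignal
        Channel order is preserved from the file.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read signal file: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() in {".edf", ".bdf"} else "csv"
    if format == "edf":
        return _read_edf(path)
    if format == "csv":
        return _read_csv(path, fs=fs)
    raise ValueError(f"unknown format {format!r} (expected 'edf' or 'csv')")


def _read_edf(path: Path) -> MultichannelSignal:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return MultichannelSignal(
        samples=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def _read_csv(path: Path, fs: float | None = None) -> MultichannelSignal:
    header_fs = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first.lstrip("#").replace(",", " ").split():
            if token.startswith("fs="):
                header_fs = float(token[3:])
    if header_fs is not None:
        fs = header_fs
    if fs is None:
        raise ValidationError(
            f"{path}: CSV has no '# fs=<Hz>' header line and no fs was given"
        )
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    samples = df.to_numpy(dtype=float).T
    # Locate the first missing cell for a precise error message.
    if not np.all(np.isfinite(samples)):
        ch, idx = np.argwhere(~np.isfinite(samples))[0]
        raise ValidationError(
            f"{path}: non-finite sample in channel {df.columns[ch]!r} "
            f"at row {idx}"
        )
    return MultichannelSignal(samples=samples, fs=fs,
                              channel_labels=[str(c) for c in df.columns])


def write_signal(signal: MultichannelSignal, path: str | Path) -> None:
    """Write a signal as CSV (rows = samples, columns = channels).

    The sampling rate goes into a leading ``# fs=<Hz>`` comment so that
    :func:`read_signal` round-trips losslessly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={signal.fs!r}\n")
        fh.write(",".join(signal.channel_labels) + "\n")
        np.savetxt(fh, signal.samples.T, delimiter=",", fmt="%.17g")


EVENT_COLUMNS = ["label", "start_sample", "end_sample",
                 "start_s", "end_s", "duration_s"]


def write_events(events, path: str | Path, params: dict | None = None) -> None:
    """Write an event sequence as CSV plus a JSON run-report sidecar.

    One row per detected state: label, start/end in (possibly fractional)
    samples, start/end/duration in seconds at full precision. ``params``
    (e.g. the optimal window size, slide width, group count, CCC and S_Dbw
    minimum of the run) lands in ``<path>.json``.
    """
    path = Path(path)
    rows = [
        {
            "label": s.label,
            "start_sample": s.start_sample,
            "end_sample": s.end_sample,
            "start_s": s.t_onset,
            "end_s": s.t_onset + s.duration,
            "duration_s": s.duration,
        }
        for s in events.states
    ]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(params or {}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_events(path: str | Path) -> pd.DataFrame:
    """Read back an events CSV written by :func:`write_events`."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read events file: {path}")
    return pd.read_csv(path)
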