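"""Interictal functional connectivity from multichannel electrophysiology.

The coupling matrix of the network model is estimated from seizure-free
(interictal) recordings: the signal is band-pass filtered, cut into short
overlapping windows, Pearson-correlated within each window, averaged over
windows, and finally rectified (negative correlations, interpreted as long
range inhibition, are set to zero).  The result is a symmetric nonnegative
matrix ``C`` with zero diagonal whose entry ``C[i, j]`` couples nodes *i*
and *j* in the dynamical model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "FunctionalConnectivity",
    "preprocess",
    "segment_windows",
    "functional_connectivity",
    "rectify",
]


@dataclass
class Recording:
    """Multichannel recording, ``samples`` laid out channels x time.

    Parameters
    ----------
    samples:
        Real matrix of shape ``(n_channels, n_samples)``, arbitrary units.
    fs:
        Sampling rate in Hz.
    labels:
        Per-channel identifiers; generated as ``ch00, ch01, ...`` if omitted.
    bad_mask:
        Boolean per channel; ``True`` marks a dysfunctional channel that is
        excluded from every downstream computation.
    """

    samples: np.ndarray
    fs: float
    labels: list[str] | None = None
    bad_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n = self.samples.shape[0]
        if self.labels is None:
            self.labels = [f"ch{i:02d}" for i in range(n)]
        if len(self.labels) != n:
            raise ValueError("labels length does not match channel count")
        if self.bad_mask is None:
            self.bad_mask = np.zeros(n, dtype=bool)
        self.bad_mask = np.asarray(self.bad_mask, dtype=bool)
        if self.bad_mask.shape != (n,):
            raise ValueError("bad_mask length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def good_channels(self) -> np.ndarray:
        return np.flatnonzero(~self.bad_mask)


@dataclass
class FunctionalConnectivity:
    """Symmetric nonnegative coupling matrix with zero diagonal."""

    C: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("C must be square")
        if not self.labels:
            self.labels = [f"n{i:02d}" for i in range(self.C.shape[0])]
        if len(self.labels) != self.C.shape[0]:
            raise ValueError("labels length does not match matrix size")
        if not np.allclose(self.C, self.C.T, atol=1e-10):
            raise ValueError("C must be symmetric")
        if np.any(self.C < -1e-12):
            raise ValueError("C must be nonnegative (rectified)")
        if np.any(np.abs(np.diag(self.C)) > 1e-12):
            raise ValueError("diagonal of C must be zero (no self-coupling)")

    @property
    def n_nodes(self) -> int:
        return self.C.shape[0]

    def index_of(self, nodes) -> np.ndarray:
        """Resolve labels or integer indices to integer indices."""
        out, unknown = [], []
        for n in nodes:
            if isinstance(n, (int, np.integer)):
                if not 0 <= int(n) < self.n_nodes:
                    unknown.append(n)
                else:
                    out.append(int(n))
            elif n in self.labels:
                out.append(self.labels.index(n))
            else:
                unknown.append(n)
        if unknown:
            raise KeyError(f"unknown node labels/indices: {unknown}")
        return np.asarray(sorted(set(out)), dtype=int)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.C, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FunctionalConnectivity":
        df = pd.read_csv(path, index_col=0)
        return cls(C=df.to_numpy(dtype=float), labels=[str(c) for c in df.columns])


def _design_bandpass(fs: float, band_low: float, band_high: float, order: int = 4):
    nyq = fs / 2.0
    if not (0 < band_low < band_high < nyq):
        raise ValueError(
            f"band edges ({band_low}, {band_high}) Hz must satisfy "
            f"0 < low < high < Nyquist ({nyq} Hz)"
        )
    return signal.butter(order, [band_low, band_high], btype="bandpass",
                         fs=fs, output="sos")


def preprocess(
    rec: Recording,
    band_low: float = 1.0,
    band_high: float = 70.0,
    notch: float | None = 60.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase band-pass plus optional notch filter.

    A forward-backward (zero-phase) Butterworth band-pass of the given
    ``order`` in second-order sections, followed by an IIR notch of quality
    ``notch_q``, both run with ``filtfilt``-style odd edge padding so channel
    count and length are preserved.  ``notch=None`` disables line-noise
    removal.
    """
    sos = _design_bandpass(rec.fs, band_low, band_high, order)
    if notch is not None and not (band_low < notch < band_high):
        raise ValueError(f"notch {notch} Hz must lie inside the passband or be None")
    out = signal.sosfiltfilt(sos, rec.samples, axis=1)
    if notch is not None:
        b, a = signal.iirnotch(notch, notch_q, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=1)
    logger.debug(
        "preprocess: butterworth order=%d band=(%g, %g) Hz, notch=%s Hz (Q=%g)",
        order, band_low, band_high, notch, notch_q,
    )
    return replace(rec, samples=out)


def segment_windows(rec: Recording, win: float = 1.0, step: float = 0.5) -> np.ndarray:
    """Cut a recording into overlapping windows.

    Returns an array of shape ``(n_windows, n_channels, win_samples)``.
    Window and step lengths are converted to samples by rounding; a trailing
    partial window is dropped.
    """
    w = int(round(win * rec.fs))
    s = int(round(step * rec.fs))
    if w <= 0 or s <= 0:
        raise ValueError("win and step must be positive")
    if rec.n_samples < w:
        raise ValueError(
            f"recording duration {rec.duration:.3f}s is shorter than the "
            f"window {win}s"
        )
    n_win = (rec.n_samples - w) // s + 1
    starts = np.arange(n_win) * s
    idx = starts[:, None] + np.arange(w)[None, :]
    return rec.samples[:, idx].transpose(1, 0, 2)


def _windowed_mean_correlation(x: np.ndarray) -> np.ndarray:
    """Mean over windows of within-window Pearson correlation.

    ``x`` has shape (n_windows, n_channels, win_samples).  Within each window
    only the mean is removed (no detrending).  Channel pairs involving a
    zero-variance channel contribute correlation 0 for that window.
    """
    n_win, n_ch, w = x.shape
    xc = x - x.mean(axis=2, keepdims=True)
    sd = xc.std(axis=2)
    acc = np.zeros((n_ch, n_ch))
    n_degenerate = 0
    for k in range(n_win):
        cov = (xc[k] @ xc[k].T) / w
        s = sd[k]
        ok = s > 0
        denom = np.outer(s, s)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / denom
        bad = ~(np.outer(ok, ok))
        if bad.any():
            r[bad] = 0.0
            n_degenerate += 1
        # numerical safety: round-off can push |r| marginally past 1
        np.clip(r, -1.0, 1.0, out=r)
        acc += r
    if n_degenerate:
        logger.warning(
            "%d/%d windows contained a zero-variance channel; affected pairs "
            "contributed correlation 0", n_degenerate, n_win,
        )
    return acc / n_win


def rectify(C_raw: np.ndarray) -> np.ndarray:
    """Set negative correlations to zero, keeping symmetry.

    Entries must lie in [-1, 1] up to a 1e-9 tolerance.
    """
    C_raw = np.asarray(C_raw, dtype=float)
    if np.any(np.abs(C_raw) > 1.0 + 1e-9):
        raise ValueError("correlation entries outside [-1, 1]")
    return np.maximum(np.clip(C_raw, -1.0, 1.0), 0.0)


def functional_connectivity(
    rec: Recording,
    win: float = 1.0,
    step: float = 0.5,
    grouping: dict[str, str] | None = None,
) -> FunctionalConnectivity:
    """Windowed-correlation functional connectivity.

    Per-window Pearson correlations between every pair of good channels are
    averaged over all windows and then rectified; the diagonal is zeroed
    (self-coupling is absorbed into the node's own dynamics).

    ``grouping`` optionally maps channel labels to region names; the region
    level connectivity is the average of the channel-level (signed, pre
    rectification) correlations between the two regions' channels, matching
    the convention of averaging electrode contacts into regions.
    """
    good = rec.good_channels()
    if good.size < 2:
        raise ValueError("need at least two good channels")
    segs = segment_windows(rec, win=win, step=step)[:, good, :]
    R = _windowed_mean_correlation(segs)
    labels = [rec.labels[i] for i in good]

    if grouping is not None:
        regions = sorted({grouping.get(l, l) for l in labels})
        members = {g: [i for i, l in enumerate(labels) if grouping.get(l, l) == g]
                   for g in regions}
        G = np.zeros((len(regions), len(regions)))
        for a, ga in enumerate(regions):
            for b, gb in enumerate(regions):
                ia, ib = members[ga], members[gb]
                block = R[np.ix_(ia, ib)]
                if a == b:
                    n = len(ia)
                    G[a, b] = 1.0 if n == 1 else block[np.triu_indices(n, 1)].mean()
                else:
                    G[a, b] = block.mean()
        R, labels = (G + G.T) / 2.0, regions

    C = rectify(R)
    np.fill_diagonal(C, 0.0)
    return FunctionalConnectivity(C=C, labels=labels)
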