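"""Readers for recordings and connectivity matrices.

Two recording formats are supported: EDF (through :mod:`mne`, an optional
dependency) and a delimited text matrix whose header row holds the channel
labels and whose data rows are samples (time down the rows); the latter is
transposed into the package's channels x samples convention.  Connectivity
matrices travel as CSV with a label header row and column
(:meth:`ictonet.connectivity.FunctionalConnectivity.to_csv`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import Recording

__all__ = ["read_edf", "read_recording_csv", "write_recording_csv"]


def read_edf(path, bad_channels: list[str] | None = None) -> Recording:
    """Load an EDF recording; requires the optional ``mne`` dependency."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("EDF reading requires the 'mne' package "
                          "(install ictonet[edf])") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    bad = set(bad_channels or [])
    mask = np.array([l in bad for l in labels])
    return Recording(samples=raw.get_data(), fs=float(raw.info["sfreq"]),
                     labels=labels, bad_mask=mask)


def read_recording_csv(path, fs: float,
                       bad_channels: list[str] | None = None,
                       sep: str = ",") -> Recording:
    """Delimited matrix: header row of channel labels, rows of samples."""
    df = pd.read_csv(path, sep=sep)
    labels = [str(c) for c in df.columns]
    bad = set(bad_channels or [])
    mask = np.array([l in bad for l in labels])
    return Recording(samples=df.to_numpy(dtype=float).T, fs=fs,
                     labels=labels, bad_mask=mask)


def write_recording_csv(rec: Recording, path, sep: str = ",") -> None:
    pd.DataFrame(rec.samples.T, columns=rec.labels).to_csv(
        path, sep=sep, index=False)
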