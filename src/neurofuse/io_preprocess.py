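"""Recording I/O and the standard preprocessing chain.

Reads EDF and delimited-text recordings, applies zero-phase notch and FIR
band-pass filtering, average re-referencing, and fixed-length epoching.
Artifact-component removal and bad-channel interpolation are intentionally
not provided.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from . import edfio

#: Canonical frequency bands (Hz) used whenever individualized boundaries
#: are not requested.
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: Standard 8-channel montage.
DEFAULT_CHANNELS: tuple[str, ...] = ("F3", "F4", "T3", "C3", "C4", "T4", "O1", "O2")


class PreprocessError(ValueError):
    """Raised for invalid preprocessing parameters or malformed inputs."""


@dataclass
class Recording:
    """A multichannel signal: channels x samples matrix in microvolts."""

    data: np.ndarray
    fs: float
    labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise PreprocessError("data must be a 2-D channels x samples matrix")
        if self.data.shape[0] != len(self.labels):
            raise PreprocessError(
                f"{self.data.shape[0]} rows but {len(self.labels)} labels"
            )
        if not self.fs > 0:
            raise PreprocessError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise PreprocessError("NaN values in signal matrix")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "Recording":
        return replace(self, data=np.asarray(data, dtype=np.float64))


@dataclass
class EpochSet:
    """Epoched view of a recording: epochs x channels x samples."""

    data: np.ndarray
    fs: float
    labels: list[str]
    epoch_len: float
    overlap: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# I/O


def write_tsv(rec: Recording, path: str | os.PathLike) -> None:
    """Write a recording as tab-separated text: ``# fs=`` comment, label
    header, one row per channel."""
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        fh.write("\t".join(rec.labels) + "\n")
        for row in rec.data:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def read_tsv(path: str | os.PathLike, fs: float | None = None) -> Recording:
    labels: list[str] | None = None
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if stripped.startswith("fs="):
                    fs = float(stripped[3:])
                continue
            if labels is None:
                labels = line.split("\t")
                continue
            try:
                rows.append(np.array([float(v) for v in line.split("\t")]))
            except ValueError as exc:
                raise PreprocessError(f"{path}: line {lineno}: {exc}") from exc
    if labels is None or not rows:
        raise PreprocessError(f"{path}: no header or no data rows")
    if fs is None:
        raise PreprocessError(
            f"{path}: sampling rate missing (no '# fs=' line and no fs argument)"
        )
    if len(rows) != len(labels):
        raise PreprocessError(
            f"{path}: header has {len(labels)} labels but file has {len(rows)} channel rows"
        )
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise PreprocessError(f"{path}: ragged channel rows, lengths {sorted(lengths)}")
    return Recording(np.vstack(rows), fs=fs, labels=labels)


def read_recording(
    path: str | os.PathLike, format: str | None = None, fs: float | None = None
) -> Recording:
    """Load a recording from an EDF file or a TSV matrix.

    ``format`` is inferred from the extension when omitted. TSV files need a
    ``# fs=<Hz>`` comment line or an explicit ``fs`` argument.
    """
    if format is None:
        ext = os.path.splitext(str(path))[1].lower()
        format = "edf" if ext == ".edf" else "tsv"
    if format == "edf":
        data, fs_read, labels = edfio.read_edf(path)
        return Recording(data, fs=fs_read, labels=labels)
    if format == "tsv":
        return read_tsv(path, fs=fs)
    raise PreprocessError(f"unknown format {format!r}")


def write_recording(rec: Recording, path: str | os.PathLike, format: str | None = None) -> None:
    if format is None:
        ext = os.path.splitext(str(path))[1].lower()
        format = "edf" if ext == ".edf" else "tsv"
    if format == "edf":
        edfio.write_edf(path, rec.data, rec.fs, rec.labels)
    elif format == "tsv":
        write_tsv(rec, path)
    else:
        raise PreprocessError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Filters (all zero-phase)


def notch_filter(rec: Recording, freq: float = 50.0, q: float = 30.0) -> Recording:
    """Zero-phase narrowband rejection at ``freq`` Hz (IIR notch, forward-backward)."""
    if freq >= rec.fs / 2:
        raise PreprocessError(f"notch frequency {freq} Hz >= Nyquist {rec.fs / 2} Hz")
    b, a = signal.iirnotch(freq, Q=q, fs=rec.fs)
    return rec.copy_with(signal.filtfilt(b, a, rec.data, axis=1))


def _fir_taps(lo: float, hi: float, fs: float) -> np.ndarray:
    # Transition width: 25% of the lower edge, floored at 0.5 Hz.
    trans = max(0.25 * lo, 0.5)
    numtaps = int(np.ceil(3.3 * fs / trans))
    numtaps += 1 - numtaps % 2  # odd length -> type-I linear phase
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=fs)


def bandpass_fir(rec: Recording, lo: float = 0.5, hi: float = 45.0) -> Recording:
    """Zero-phase windowed-sinc FIR band-pass (applied forward-backward)."""
    if not (0 < lo < hi < rec.fs / 2):
        raise PreprocessError(
            f"band ({lo}, {hi}) Hz invalid for fs={rec.fs} Hz (need 0 < lo < hi < fs/2)"
        )
    taps = _fir_taps(lo, hi, rec.fs)
    padlen = min(3 * len(taps), rec.n_samples - 1)
    out = signal.filtfilt(taps, [1.0], rec.data, axis=1, padlen=padlen)
    return rec.copy_with(out)


def bandpass_bank(
    rec: Recording, bands: list[tuple[float, float]]
) -> list[Recording]:
    """One band-pass filtered copy of ``rec`` per (lo, hi) pair."""
    return [bandpass_fir(rec, lo, hi) for lo, hi in bands]


def rereference_average(rec: Recording) -> Recording:
    """Subtract the instantaneous cross-channel mean from every channel."""
    if rec.n_channels < 2:
        raise PreprocessError("average reference needs at least 2 channels")
    return rec.copy_with(rec.data - rec.data.mean(axis=0, keepdims=True))


# ---------------------------------------------------------------------------
# Epoching


def epoch(rec: Recording, epoch_len: float, overlap: float = 0.0) -> EpochSet:
    """Segment into fixed-length epochs; a trailing partial epoch is discarded.

    Epoch count is ``1 + floor((T - L) / (L * (1 - overlap)))`` with L the
    epoch length in samples; windows are half-open ``[start, start + L)``.
    """
    if not 0 <= overlap < 1:
        raise PreprocessError("overlap must be in [0, 1)")
    L = int(round(epoch_len * rec.fs))
    if L < 2:
        raise PreprocessError("epoch length must span at least 2 samples")
    T = rec.n_samples
    if T < L:
        raise PreprocessError(
            f"recording of {T} samples shorter than one epoch ({L} samples)"
        )
    hop = max(1, int(round(L * (1 - overlap))))
    n_ep = 1 + (T - L) // hop
    starts = np.arange(n_ep) * hop
    data = np.stack([rec.data[:, s : s + L] for s in starts])
    return EpochSet(
        data=data,
        fs=rec.fs,
        labels=list(rec.labels),
        epoch_len=epoch_len,
        overlap=overlap,
        meta=dict(rec.meta),
    )


def preprocess(
    rec: Recording,
    notch: float | None = 50.0,
    band: tuple[float, float] | None = (0.5, 45.0),
    rereference: bool = True,
) -> Recording:
    """Standard chain: notch -> band-pass -> average reference."""
    out = rec
    if notch is not None:
        out = notch_filter(out, notch)
    if band is not None:
        out = bandpass_fir(out, *band)
    if rereference:
        out = rereference_average(out)
    return out
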