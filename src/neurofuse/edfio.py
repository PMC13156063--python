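"""Minimal EDF (European Data Format) reader/writer.

Supports continuous multichannel recordings where every signal shares one
sampling rate — sufficient for 8-channel scalp EEG. Samples are stored as
16-bit little-endian integers with per-signal linear scaling, per the EDF
specification header layout (256-byte fixed header + 256 bytes per signal).
"""

from __future__ import annotations

import os

import numpy as np


class EDFError(ValueError):
    pass


def _field(text: str, width: int) -> bytes:
    raw = text.encode("ascii")[:width]
    return raw + b" " * (width - len(raw))


def write_edf(
    path: str | os.PathLike,
    data: np.ndarray,
    fs: float,
    labels: list[str],
    physical_range: tuple[float, float] | None = None,
) -> None:
    """Write a channels x samples float matrix as a 16-bit EDF file.

    Samples that do not fill a whole number of 1-second data records are
    zero-padded (EDF has no partial-record concept); the reader trims by the
    stored record count, so pad samples survive a round trip — callers who
    need exact lengths should use whole-second durations.
    """
    data = np.asarray(data, dtype=np.float64)
    ns, n_samp = data.shape
    if len(labels) != ns:
        raise EDFError("label count does not match channel count")
    spr = int(round(fs))  # samples per 1-second record
    if abs(spr - fs) > 1e-9:
        raise EDFError("writer supports integer sampling rates only")
    n_rec = int(np.ceil(n_samp / spr))

    if physical_range is None:
        span = np.abs(data).max() if data.size else 1.0
        span = max(span, 1e-12)
        physical_range = (-span, span)
    pmin, pmax = physical_range
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)

    header = b"".join(
        [
            _field("0", 8),  # version
            _field("X X X X", 80),  # patient id (anonymous)
            _field("Startdate X X X X", 80),  # recording id
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (1 + ns)), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field("1", 8),  # record duration (s)
            _field(str(ns), 4),
        ]
    )
    sig_headers = b"".join(
        [
            b"".join(_field(lab, 16) for lab in labels),
            b"".join(_field("AgAgCl electrode", 80) for _ in labels),
            b"".join(_field("uV", 8) for _ in labels),
            b"".join(_field(f"{pmin:.6g}", 8) for _ in labels),
            b"".join(_field(f"{pmax:.6g}", 8) for _ in labels),
            b"".join(_field(str(dmin), 8) for _ in labels),
            b"".join(_field(str(dmax), 8) for _ in labels),
            b"".join(_field("", 80) for _ in labels),
            b"".join(_field(str(spr), 8) for _ in labels),
            b"".join(_field("", 32) for _ in labels),
        ]
    )

    padded = np.zeros((ns, n_rec * spr))
    padded[:, :n_samp] = data
    digital = np.clip(np.round((padded - pmin) / scale) + dmin, dmin, dmax).astype(
        "<i2"
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_headers)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path: str | os.PathLike) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (channels x samples, fs, labels)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise EDFError(f"{path}: truncated EDF header")

    def ascii_at(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    try:
        n_rec = int(ascii_at(236, 8))
        rec_dur = float(ascii_at(244, 8))
        ns = int(ascii_at(252, 4))
    except ValueError as exc:
        raise EDFError(f"{path}: malformed fixed header: {exc}") from exc

    base = 256
    # Signal header blocks in spec order: label, transducer, dim, pmin, pmax,
    # dmin, dmax, prefilter, samples-per-record, reserved.
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    offsets = np.concatenate([[0], np.cumsum([w * ns for w in widths])])
    blocks = []
    for w, off in zip(widths, offsets[:-1]):
        start = base + int(off)
        blocks.append(
            [raw[start + i * w : start + (i + 1) * w].decode("ascii", errors="replace").strip() for i in range(ns)]
        )
    labels, _, _, pmins, pmaxs, dmins, dmaxs, _, sprs, _ = blocks
    try:
        pmin = np.array([float(v) for v in pmins])
        pmax = np.array([float(v) for v in pmaxs])
        dmin = np.array([float(v) for v in dmins])
        dmax = np.array([float(v) for v in dmaxs])
        spr = np.array([int(v) for v in sprs])
    except ValueError as exc:
        raise EDFError(f"{path}: malformed signal headers: {exc}") from exc
    if len(set(spr)) != 1:
        raise EDFError(f"{path}: mixed per-signal sampling rates unsupported")
    spr0 = int(spr[0])
    fs = spr0 / rec_dur

    data_off = 256 * (1 + ns)
    expected = data_off + n_rec * ns * spr0 * 2
    if len(raw) < expected:
        raise EDFError(
            f"{path}: file holds {len(raw)} bytes, header promises {expected}"
        )
    digital = np.frombuffer(raw[data_off:expected], dtype="<i2")
    digital = digital.reshape(n_rec, ns, spr0)
    data = np.concatenate([digital[r] for r in range(n_rec)], axis=1).astype(np.float64)
    scale = (pmax - pmin) / (dmax - dmin)
    data = (data - dmin[:, None]) * scale[:, None] + pmin[:, None]
    return data, fs, labels
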