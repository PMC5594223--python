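"""Minimal European Data Format (EDF) I/O for continuous EEG segments.

Implements the plain EDF layout: a 256-byte fixed header, 256 bytes of
signal headers per channel, and 16-bit little-endian sample records.
One data record per second (sampling-rate samples per channel).  Writing
is exposed because no EDF writer is available as a dependency; reading is
provided for symmetry and is cross-checked against mne's independent EDF
reader in the test suite.

Physical scaling uses per-channel physical min/max mapped onto the full
digital range -32768..32767, so round-trip error is bounded by half a
quantization step.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
from numpy.typing import NDArray

__all__ = ["write_edf", "read_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} > {width}")
    return b.ljust(width)


def write_edf(
    path,
    data: NDArray[np.float64],
    sfreq: float,
    channel_labels: list[str],
    physical_dim: str = "uV",
    patient_id: str = "X",
    recording_id: str = "synthetic",
) -> None:
    """Write a channels x samples array as 16-bit EDF.

    The sampling rate must be a positive integer (one data record per
    second).  Trailing samples that do not fill a whole record are
    dropped.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be channels x samples")
    if not float(sfreq).is_integer() or sfreq <= 0:
        raise ValueError("sfreq must be a positive integer for EDF records")
    fs = int(sfreq)
    m, n = data.shape
    if len(channel_labels) != m:
        raise ValueError("channel label count mismatch")
    n_records = n // fs
    if n_records < 1:
        raise ValueError("need at least one second of data")
    data = data[:, : n_records * fs]

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    # avoid zero physical range
    flat = pmax - pmin <= 0
    pmax = np.where(flat, pmin + 1.0, pmax)

    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((data - pmin[:, None]) / scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field(recording_id, 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 * (1 + m)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(m), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_field(lab, 16) for lab in channel_labels),
            b"".join(_field("", 80) for _ in range(m)),
            b"".join(_field(physical_dim, 8) for _ in range(m)),
            b"".join(_field(f"{v:.8g}"[:8], 8) for v in pmin),
            b"".join(_field(f"{v:.8g}"[:8], 8) for v in pmax),
            b"".join(_field(str(_DIG_MIN), 8) for _ in range(m)),
            b"".join(_field(str(_DIG_MAX), 8) for _ in range(m)),
            b"".join(_field("", 80) for _ in range(m)),
            b"".join(_field(str(fs), 8) for _ in range(m)),
            b"".join(_field("", 32) for _ in range(m)),
        ]
    )
    records = digital.reshape(m, n_records, fs).transpose(1, 0, 2)
    Path(path).write_bytes(header + sig + records.tobytes())


def read_edf(path):
    """Read a 16-bit EDF file; returns (data, labels, sfreq).

    ``data`` is channels x samples in physical units.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError("truncated EDF header")
    n_records = int(raw[236:244].decode("ascii"))
    record_dur = float(raw[244:252].decode("ascii"))
    m = int(raw[252:256].decode("ascii"))
    off = 256

    def _sig_fields(width):
        nonlocal off
        out = [
            raw[off + i * width: off + (i + 1) * width].decode("ascii").strip()
            for i in range(m)
        ]
        off += m * width
        return out

    labels = _sig_fields(16)
    _sig_fields(80)  # transducer
    _sig_fields(8)   # physical dim
    pmin = np.array([float(v) for v in _sig_fields(8)])
    pmax = np.array([float(v) for v in _sig_fields(8)])
    dmin = np.array([float(v) for v in _sig_fields(8)])
    dmax = np.array([float(v) for v in _sig_fields(8)])
    _sig_fields(80)  # prefiltering
    spr = np.array([int(v) for v in _sig_fields(8)])
    _sig_fields(32)  # reserved
    if len(set(spr)) != 1:
        raise ValueError("mixed per-channel sampling rates not supported")
    fs = spr[0] / record_dur

    payload = np.frombuffer(raw[off:], dtype="<i2")
    expected = n_records * m * spr[0]
    if payload.size < expected:
        raise ValueError("truncated EDF data section")
    records = payload[:expected].reshape(n_records, m, spr[0])
    digital = records.transpose(1, 0, 2).reshape(m, n_records * spr[0])
    scale = (pmax - pmin) / (dmax - dmin)
    data = (digital - dmin[:, None]) * scale[:, None] + pmin[:, None]
    return data, labels, float(fs)
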