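"""Minimal EDF (European Data Format) reader/writer.

Supports the plain 16-bit continuous variant: one data record per second,
identical sampling rate on every signal, physical units in microvolts.
Trailing samples that do not fill a whole record are dropped on write.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

from .recording import Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, rec: Recording, patient_id: str = "X",
              recording_id: str = "eegbeta") -> None:
    if rec.fs != int(rec.fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(rec.fs)  # samples per 1 s record
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one EDF record (1 s)")
    data = rec.data[:, : n_records * spr]
    n_sig = rec.n_channels
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    # avoid a zero physical range on constant channels
    flat = pmax - pmin < 1e-9
    pmax = np.where(flat, pmin + 1.0, pmax)

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(str(256 * (1 + n_sig)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(n_sig), 4),
    ])
    sig_header = b"".join([
        b"".join(_field(lab, 16) for lab in rec.labels),
        b"".join(_field("AgAgCl electrode", 80) for _ in range(n_sig)),
        b"".join(_field("uV", 8) for _ in range(n_sig)),
        b"".join(_field(f"{pmin[i]:.8g}"[:8], 8) for i in range(n_sig)),
        b"".join(_field(f"{pmax[i]:.8g}"[:8], 8) for i in range(n_sig)),
        b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_sig)),
        b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_sig)),
        b"".join(_field("", 80) for _ in range(n_sig)),
        b"".join(_field(str(spr), 8) for _ in range(n_sig)),
        b"".join(_field("", 32) for _ in range(n_sig)),
    ])
    # header fields are 8-char ASCII: re-read our own physical extrema so the
    # digital scaling is consistent with what a reader will parse
    pmin_r = np.array([float(f"{pmin[i]:.8g}"[:8]) for i in range(n_sig)])
    pmax_r = np.array([float(f"{pmax[i]:.8g}"[:8]) for i in range(n_sig)])
    pmax_r = np.where(pmax_r - pmin_r < 1e-9, pmin_r + 1.0, pmax_r)
    gain = (_DIG_MAX - _DIG_MIN) / (pmax_r - pmin_r)
    dig = np.rint((np.clip(data.T, pmin_r, pmax_r) - pmin_r) * gain + _DIG_MIN).T
    dig = dig.astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            fh.write(dig[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path: str | Path) -> Recording:
    with open(path, "rb") as fh:
        raw = fh.read()

    def s(a: int, b: int) -> str:
        return raw[a:b].decode("ascii").strip()

    n_records = int(s(236, 244))
    record_dur = float(s(244, 252))
    n_sig = int(s(252, 256))
    off = 256

    def sig_fields(width: int):
        nonlocal off
        vals = [s(off + i * width, off + (i + 1) * width) for i in range(n_sig)]
        off += n_sig * width
        return vals

    labels = sig_fields(16)
    sig_fields(80)  # transducer
    sig_fields(8)  # physical dimension
    pmin = np.array([float(v) for v in sig_fields(8)])
    pmax = np.array([float(v) for v in sig_fields(8)])
    dmin = np.array([float(v) for v in sig_fields(8)])
    dmax = np.array([float(v) for v in sig_fields(8)])
    sig_fields(80)  # prefiltering
    spr = [int(v) for v in sig_fields(8)]
    sig_fields(32)  # reserved
    if len(set(spr)) != 1:
        raise ValueError("mixed per-signal rates are not supported")
    spr = spr[0]
    fs = spr / record_dur
    payload = np.frombuffer(raw, dtype="<i2", offset=256 * (1 + n_sig))
    payload = payload[: n_records * n_sig * spr].reshape(n_records, n_sig, spr)
    dig = payload.transpose(1, 0, 2).reshape(n_sig, n_records * spr).astype(float)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (dig - dmin[:, None]) * gain[:, None] + pmin[:, None]
    return Recording(data=data, fs=fs, labels=tuple(labels))
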