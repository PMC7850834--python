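"""Minimal EDF+C writer.

EDF stores each signal as 16-bit integers with a per-signal linear mapping
between digital and physical (microvolt) ranges, in fixed-duration data
records.  This writer emits one-second records, an EDF+ annotation signal
carrying the interval annotations as TALs, and zero-pads the final record
when the recording length is not a whole number of seconds.  Reading is
delegated to :mod:`mne` (see :func:`emdwave.io_signals.read_edf`), which
doubles as an independent check on this writer in the round-trip tests.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .io_signals import EEGRecording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: object, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _fit_float(value: float, width: int = 8) -> str:
    """Shortest decimal representation of ``value`` fitting ``width`` chars."""
    for prec in range(7, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width and "e" not in s and "E" not in s:
            return s
    return f"{value:.0f}"[:width]


def _annotation_records(
    rec: "EEGRecording", n_records: int
) -> list[bytes]:
    """One TAL byte block per record: timestamp TAL + annotations starting there."""
    per_record: list[bytes] = []
    for r in range(n_records):
        block = f"+{r}\x14\x14\x00".encode("ascii")
        for label, start, end in rec.annotations:
            if r <= start < r + 1:
                tal = f"+{start:g}\x15{end - start:g}\x14{label}\x14\x00"
                block += tal.encode("utf-8")
        per_record.append(block)
    return per_record


def write_edf(path: Path, rec: "EEGRecording") -> None:
    if abs(rec.fs - round(rec.fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(rec.fs))
    n_ch, n_samp = rec.data.shape
    n_records = max(1, math.ceil(n_samp / fs))

    # physical range per channel; header stores the (8-char) rounded string
    # and the scaling reuses the parsed-back value so they agree exactly
    pmaxs, pmins = [], []
    for ch in range(n_ch):
        amp = float(np.max(np.abs(rec.data[ch]))) or 1.0
        pstr = _fit_float(amp * 1.000001)
        pmaxs.append(pstr)
        pmins.append(_fit_float(-float(pstr)))

    ann_blocks = _annotation_records(rec, n_records)
    ann_bytes = max(max(len(b) for b in ann_blocks), 24)
    ann_bytes += ann_bytes % 2  # whole number of 2-byte samples
    ann_spr = ann_bytes // 2

    ns = n_ch + 1
    header_bytes = 256 * (ns + 1)

    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field("X X X X", 80))
        fh.write(_field("Startdate 01-JAN-2000 X X X", 80))
        fh.write(_field("01.01.00", 8))
        fh.write(_field("00.00.00", 8))
        fh.write(_field(header_bytes, 8))
        fh.write(_field("EDF+C", 44))
        fh.write(_field(n_records, 8))
        fh.write(_field("1", 8))
        fh.write(_field(ns, 4))

        labels = list(rec.channel_names) + ["EDF Annotations"]
        fh.write(b"".join(_field(l, 16) for l in labels))
        fh.write(b"".join(_field("", 80) for _ in labels))
        fh.write(b"".join(_field(d, 8) for d in ["uV"] * n_ch + [""]))
        fh.write(b"".join(_field(p, 8) for p in pmins + ["-1"]))
        fh.write(b"".join(_field(p, 8) for p in pmaxs + ["1"]))
        fh.write(b"".join(_field(d, 8) for d in [_DIG_MIN] * n_ch + [_DIG_MIN]))
        fh.write(b"".join(_field(d, 8) for d in [_DIG_MAX] * n_ch + [_DIG_MAX]))
        fh.write(b"".join(_field("", 80) for _ in labels))
        fh.write(b"".join(_field(s, 8) for s in [fs] * n_ch + [ann_spr]))
        fh.write(b"".join(_field("", 32) for _ in labels))

        padded = np.zeros((n_ch, n_records * fs))
        padded[:, :n_samp] = rec.data
        scale = np.array(
            [(_DIG_MAX - _DIG_MIN) / (float(pmaxs[c]) - float(pmins[c]))
             for c in range(n_ch)]
        )
        offset = np.array([float(pmins[c]) for c in range(n_ch)])
        digital = np.rint(
            (padded - offset[:, None]) * scale[:, None] + _DIG_MIN
        ).astype("<i2")

        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
            fh.write(ann_blocks[r].ljust(ann_bytes, b"\x00"))
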