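"""Minimal WFDB (PhysioNet waveform database) record and annotation I/O.

Covers exactly what rhythm-interval extraction from long ambulatory ECG
records needs: text ``.hea`` headers, signal format 16 (interleaved
little-endian int16) ``.dat`` files, and MIT-format ``.atr`` annotation
files whose AUX strings carry rhythm-change labels (``(AFIB``, ``(N``, …).
A writer for the same subset exists so test fixtures can be produced
programmatically and round-tripped.

Not a general WFDB implementation: multi-segment records, non-16 signal
formats and non-rhythm annotation semantics are out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

# MIT annotation type codes used here
_RHYTHM = 28
_NORMAL_BEAT = 1
_SKIP = 59
_NUM = 60
_SUB = 61
_CHN = 62
_AUX = 63


class WfdbError(IOError):
    """Base class for WFDB I/O failures."""


class RecordMissingError(WfdbError):
    """Header or signal file for the record does not exist."""


class AnnotationMissingError(WfdbError):
    """The record exists but has no rhythm annotation file."""


@dataclass(frozen=True)
class RhythmInterval:
    """Half-open, 0-based sample interval labeled with one rhythm."""

    start: int
    end: int
    rhythm: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def write_record(
    prefix: str | os.PathLike,
    signal: np.ndarray,
    fs: float,
    rhythm_onsets: list[tuple[int, str]] | None = None,
    gain: float = 200.0,
    units: str = "mV",
) -> None:
    """Write ``<prefix>.hea`` + ``<prefix>.dat`` (format 16) and optionally
    ``<prefix>.atr`` with rhythm-change annotations.

    ``signal`` is (n_samples,) or (n_samples, n_leads) in physical units;
    ``rhythm_onsets`` is a list of (sample, rhythm) pairs, e.g.
    ``[(0, "N"), (150000, "AFIB")]``.
    """
    prefix = os.fspath(prefix)
    sig = np.atleast_2d(np.asarray(signal, dtype=float).T).T  # (n, nsig)
    n, nsig = sig.shape
    record = os.path.basename(prefix)
    digital = np.clip(np.round(sig * gain), -32768, 32767).astype("<i2")
    with open(prefix + ".hea", "w") as fh:
        fh.write(f"{record} {nsig} {fs:g} {n}\n")
        for j in range(nsig):
            fh.write(f"{record}.dat 16 {gain:g}/{units} 16 0 "
                     f"{int(digital[0, j])} 0 0 lead{j}\n")
    digital.reshape(-1, order="C").tofile(prefix + ".dat")
    if rhythm_onsets is not None:
        write_annotations(prefix + ".atr",
                          [(t, _RHYTHM, "(" + r.lstrip("(")) for t, r in rhythm_onsets])


def write_annotations(path: str | os.PathLike, anns: list[tuple[int, int, str | None]]) -> None:
    """Write MIT-format annotations: (sample, type_code, aux_string_or_None)."""
    out = bytearray()

    def word(code: int, time: int) -> None:
        w = ((code & 0x3F) << 10) | (time & 0x3FF)
        out.extend(w.to_bytes(2, "little"))

    prev = 0
    for t, code, aux in sorted(anns, key=lambda a: a[0]):
        delta = t - prev
        if delta > 1023 or delta < 0:
            word(_SKIP, 0)
            out.extend(((delta >> 16) & 0xFFFF).to_bytes(2, "little"))
            out.extend((delta & 0xFFFF).to_bytes(2, "little"))
            delta = 0
        word(code, delta)
        if aux:
            raw = aux.encode()
            word(_AUX, len(raw))
            out.extend(raw)
            if len(raw) % 2:
                out.extend(b"\x00")
        prev = t
    out.extend(b"\x00\x00")
    with open(path, "wb") as fh:
        fh.write(bytes(out))


def read_annotations(path: str | os.PathLike) -> list[tuple[int, int, str | None]]:
    """Parse MIT-format annotations into (sample, type_code, aux) triples."""
    with open(path, "rb") as fh:
        buf = fh.read()
    anns: list[list] = []
    t = 0
    pending = 0
    i = 0
    while i + 1 < len(buf):
        w = int.from_bytes(buf[i : i + 2], "little")
        i += 2
        code = w >> 10
        field = w & 0x3FF
        if code == 0 and field == 0:
            break
        if code == _SKIP:
            hi = int.from_bytes(buf[i : i + 2], "little")
            lo = int.from_bytes(buf[i + 2 : i + 4], "little")
            i += 4
            pending += (hi << 16) | lo
        elif code == _AUX:
            raw = buf[i : i + field]
            i += field + (field % 2)
            if anns:
                anns[-1][2] = raw.rstrip(b"\x00").decode(errors="replace")
        elif code in (_NUM, _SUB, _CHN):
            continue
        else:
            t += pending + field
            pending = 0
            anns.append([t, code, None])
    return [tuple(a) for a in anns]


def _parse_header(path: str) -> tuple[str, int, float, int, list[float]]:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    record, nsig = head[0], int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n = int(head[3]) if len(head) > 3 else 0
    gains = []
    for ln in lines[1 : 1 + nsig]:
        parts = ln.split()
        fmt = parts[1].split("x")[0]
        if fmt != "16":
            raise WfdbError(f"unsupported signal format {parts[1]!r} (only format 16)")
        gain_field = parts[2].split("/")[0] if len(parts) > 2 else "200"
        g = float(gain_field.split("(")[0])
        gains.append(g if g != 0 else 200.0)
    return record, nsig, fs, n, gains


def read_record(prefix: str | os.PathLike) -> tuple[np.ndarray, float, list[RhythmInterval]]:
    """Read a rhythm-annotated record: (signal (n, nsig) in physical units, fs, intervals).

    Each rhythm annotation opens an interval that the next rhythm annotation
    (or the end of the record) closes.  Distinguishes a missing record from
    a record without rhythm labels.
    """
    prefix = os.fspath(prefix)
    hea, dat, atr = prefix + ".hea", prefix + ".dat", prefix + ".atr"
    if not os.path.exists(hea) or not os.path.exists(dat):
        raise RecordMissingError(f"no WFDB record at {prefix!r} (need .hea and .dat)")
    _, nsig, fs, n, gains = _parse_header(hea)
    raw = np.fromfile(dat, dtype="<i2")
    if n:
        raw = raw[: n * nsig]
    sig = raw.reshape(-1, nsig).astype(float) / np.asarray(gains)
    if not os.path.exists(atr):
        raise AnnotationMissingError(
            f"record {prefix!r} exists but has no rhythm annotation file (.atr)"
        )
    anns = read_annotations(atr)
    onsets = [(t, aux.lstrip("(")) for t, code, aux in anns
              if aux and aux.startswith("(")]
    intervals: list[RhythmInterval] = []
    for i, (t, rhythm) in enumerate(onsets):
        end = onsets[i + 1][0] if i + 1 < len(onsets) else sig.shape[0]
        if end > t:
            intervals.append(RhythmInterval(t, end, rhythm))
    return sig, fs, intervals
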