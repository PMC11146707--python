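"""Dataset I/O: segment containers, record windowing, and 8:1:1 splits.

Long rhythm-annotated recordings are cut into non-overlapping fixed-length
windows that must lie entirely inside a single rhythm interval (window
purity); windows restart at every interval boundary, so an interval of
``L`` samples yields exactly ``floor(L / window_samples)`` windows.

Segment datasets travel in two dialects, both written by the simulator and
read back here: a directory of per-segment CSV files (one sample per row,
``# key: value`` header lines for fs/label/duration) and a single HDF5
container with ``/signals`` (variable-length), ``/labels`` and ``/fs``.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .ecgsim import EcgSegment
from .wfdbio import (  # noqa: F401  (re-exported record API)
    AnnotationMissingError,
    RecordMissingError,
    RhythmInterval,
    WfdbError,
    read_record as read_wfdb_record,
    write_record as write_wfdb_record,
)

AF_LABELS = frozenset({"AFIB"})


# ---------------------------------------------------------------------------
# windowing

def window_record(
    signal: np.ndarray,
    fs: float,
    intervals: list[RhythmInterval],
    window_s: float = 10.0,
    af_labels: frozenset | set = AF_LABELS,
) -> list[EcgSegment]:
    """Pure, non-overlapping windows from one rhythm-annotated lead.

    A window is emitted only if it lies entirely inside a single rhythm
    interval; its binary label is ``"af"`` iff that interval's rhythm is in
    ``af_labels`` (default: atrial fibrillation only — flutter, junctional
    and normal rhythms all count as non-AF).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("window_record expects a single lead (1-D signal)")
    w = int(round(window_s * fs))
    out: list[EcgSegment] = []
    for iv in intervals:
        label = "af" if iv.rhythm in af_labels else "non_af"
        n_win = iv.length // w
        for i in range(n_win):
            s = iv.start + i * w
            out.append(
                EcgSegment(samples=x[s : s + w].copy(), fs=fs, label=label,
                           duration=w / fs)
            )
    return out


# ---------------------------------------------------------------------------
# splitting

@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint train/val/test index lists forming an 8:1:1 partition."""

    train: tuple[int, ...]
    val: tuple[int, ...]
    test: tuple[int, ...]
    seed: int

    def __post_init__(self):
        all_idx = set(self.train) | set(self.val) | set(self.test)
        n = len(self.train) + len(self.val) + len(self.test)
        if len(all_idx) != n:
            raise ValueError("split parts overlap")
        if all_idx != set(range(n)):
            raise ValueError("split parts do not cover 0..n-1")


def _largest_remainder(n: int, ratios=(0.8, 0.1, 0.1)) -> tuple[int, int, int]:
    exact = [n * r for r in ratios]
    base = [int(e) for e in exact]
    short = n - sum(base)
    order = sorted(range(3), key=lambda i: exact[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return tuple(base)


def split_811(
    n: int, seed: int, stratify_labels: list | None = None
) -> SplitAssignment:
    """Random 8:1:1 partition of ``range(n)`` (largest-remainder rounding).

    With ``stratify_labels`` the 8:1:1 proportions hold within each label
    class (to within one element).
    """
    if n < 10:
        raise ValueError(f"need at least 10 items for an 8:1:1 split, got {n}")
    rng = np.random.default_rng(seed)
    if stratify_labels is None:
        groups = [np.arange(n)]
    else:
        labels = np.asarray(stratify_labels)
        if len(labels) != n:
            raise ValueError("stratify_labels length must equal n")
        groups = [np.nonzero(labels == c)[0] for c in sorted(set(labels.tolist()))]
    parts: list[list[int]] = [[], [], []]
    for g in groups:
        perm = rng.permutation(g)
        n_tr, n_va, n_te = _largest_remainder(len(g))
        parts[0] += perm[:n_tr].tolist()
        parts[1] += perm[n_tr : n_tr + n_va].tolist()
        parts[2] += perm[n_tr + n_va :].tolist()
    return SplitAssignment(tuple(parts[0]), tuple(parts[1]), tuple(parts[2]), seed)


# ---------------------------------------------------------------------------
# segment dataset containers

def write_csv_dir(segments: list[EcgSegment], path: str | os.PathLike) -> None:
    """One CSV per segment: ``# key: value`` header lines then one sample per row."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(len(segments))))
    for i, seg in enumerate(segments):
        fname = path / f"seg{i:0{width}d}.csv"
        with open(fname, "w") as fh:
            fh.write(f"# fs: {seg.fs:g}\n# label: {seg.label}\n"
                     f"# duration: {seg.duration:.6g}\n")
            np.savetxt(fh, seg.samples, fmt="%.6f")


def read_csv_dir(path: str | os.PathLike) -> list[EcgSegment]:
    path = Path(path)
    files = sorted(path.glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no segment CSV files under {path}")
    segments = []
    for f in files:
        meta = {}
        with open(f) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
        samples = np.loadtxt(f, comments="#")
        segments.append(
            EcgSegment(samples=np.atleast_1d(samples), fs=float(meta["fs"]),
                       label=meta["label"], duration=float(meta["duration"]))
        )
    return segments


def write_h5(segments: list[EcgSegment], path: str | os.PathLike) -> None:
    """Single-file container: variable-length /signals plus /labels and /fs."""
    with h5py.File(path, "w") as fh:
        vlen = h5py.special_dtype(vlen=np.float64)
        ds = fh.create_dataset("signals", (len(segments),), dtype=vlen)
        for i, seg in enumerate(segments):
            ds[i] = seg.samples
        fh.create_dataset("labels",
                          data=np.array([s.label for s in segments], dtype="S16"))
        fh.create_dataset("fs", data=np.array([s.fs for s in segments]))


def read_h5(path: str | os.PathLike) -> list[EcgSegment]:
    with h5py.File(path, "r") as fh:
        signals = [np.asarray(v) for v in fh["signals"][...]]
        labels = [b.decode() for b in fh["labels"][...]]
        fs = fh["fs"][...]
    return [
        EcgSegment(samples=x, fs=float(f), label=lab, duration=len(x) / float(f))
        for x, lab, f in zip(signals, labels, fs)
    ]


def load_segments(path: str | os.PathLike) -> list[EcgSegment]:
    """Load a segment dataset from either dialect (CSV directory or HDF5 file)."""
    p = Path(path)
    if p.is_dir():
        return read_csv_dir(p)
    return read_h5(p)


# ---------------------------------------------------------------------------
# CinC-2017-style loader

CINC_LABELS = ("normal", "af", "other", "noise")


def load_cinc_style(path: str | os.PathLike) -> tuple[list[EcgSegment], list[str]]:
    """Load variable-length four-class records with a REFERENCE.csv label table.

    ``path`` holds one CSV signal file per record (``<id>.csv`` in the
    segment-CSV dialect) plus ``REFERENCE.csv`` mapping record id to one of
    Normal/AF/Other/Noise.  Returns ``(segments, errors)``: unmatched ids on
    either side are reported in ``errors``, never dropped silently.
    Durations outside the 9–30 s regime trigger a warning but are kept.
    """
    path = Path(path)
    ref = path / "REFERENCE.csv"
    if not ref.exists():
        raise FileNotFoundError(f"no label table at {ref}")
    table: dict[str, str] = {}
    with open(ref) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rec_id, _, label = line.partition(",")
            table[rec_id.strip()] = label.strip().lower()
    errors: list[str] = []
    segments: list[EcgSegment] = []
    seen = set()
    for f in sorted(path.glob("*.csv")):
        if f.name == "REFERENCE.csv":
            continue
        rec_id = f.stem
        seen.add(rec_id)
        if rec_id not in table:
            errors.append(f"record {rec_id!r} has no label row")
            continue
        label = table[rec_id]
        if label not in CINC_LABELS:
            errors.append(f"record {rec_id!r} has unknown label {label!r}")
            continue
        seg = _read_single_csv(f, label)
        if not (9.0 <= seg.duration <= 30.0):
            warnings.warn(
                f"record {rec_id!r} duration {seg.duration:.1f} s outside [9, 30] s; kept"
            )
        segments.append(seg)
    for rec_id in table:
        if rec_id not in seen:
            errors.append(f"label row {rec_id!r} has no record file")
    return segments, errors


def _read_single_csv(f: Path, label: str | None = None) -> EcgSegment:
    meta = {}
    with open(f) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
    samples = np.atleast_1d(np.loadtxt(f, comments="#"))
    fs = float(meta.get("fs", 300.0))
    return EcgSegment(samples=samples, fs=fs,
                      label=label or meta.get("label", "unknown"),
                      duration=len(samples) / fs)
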