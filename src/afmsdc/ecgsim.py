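"""Synthetic single-lead ECG rhythm simulator.

Generates labeled ECG segments carrying the statistical signatures that
separate the four rhythm classes used in AF screening:

* ``normal`` — regular RR intervals (low coefficient of variation), a P wave
  before every QRS complex, no fibrillatory activity.
* ``af`` — irregular RR intervals with no serial correlation, absent P
  waves, and a low-amplitude 4–10 Hz fibrillatory (f-wave) oscillation.
* ``other`` — sinus rhythm with injected premature beats (a shortened RR
  interval followed by a compensatory pause), one concrete mechanism for
  the heterogeneous "other rhythm" class.
* ``noise`` — band-limited noise with no beat structure at all.

Two recording regimes are emulated: fixed 10-s segments at 250 Hz
(ambulatory Holter windows) and variable 9–30 s records at 300 Hz
(handheld single-lead devices).  Morphology is a sum of Gaussian bumps
(P, Q, R, S, T); it is a test-bench surrogate, not a biophysical model.

All randomness flows through explicit integer seeds; identical inputs give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

MAX_AMPLITUDE_MV = 5.0
_BAND = (0.1, 40.0)  # ambulatory Holter analog bandwidth, Hz


@dataclass(frozen=True)
class RhythmParams:
    """Generative parameters of one rhythm class.

    ``mean_rr`` and ``rr_cv`` set the beat-interval law; ``p_wave_amplitude``
    (mV) scales the atrial P bump; ``f_wave_amplitude``/``f_wave_freq`` set
    the fibrillatory oscillation; ``noise_sd`` (mV) is additive band-limited
    sensor noise.  ``pvc_prob`` only matters for the ``other`` class.
    """

    rhythm_label: str
    mean_rr: float = 0.8
    rr_cv: float = 0.05
    p_wave_amplitude: float = 0.15
    f_wave_amplitude: float = 0.0
    f_wave_freq: float = 6.0
    noise_sd: float = 0.03
    pvc_prob: float = 0.0

    def __post_init__(self):
        if self.rhythm_label not in ("normal", "af", "other", "noise"):
            raise ValueError(f"unknown rhythm label {self.rhythm_label!r}")
        if not (4.0 <= self.f_wave_freq <= 10.0):
            raise ValueError("f_wave_freq must lie in the fibrillatory band [4, 10] Hz")


DEFAULT_PARAMS: dict[str, RhythmParams] = {
    "normal": RhythmParams("normal", mean_rr=0.8, rr_cv=0.05,
                           p_wave_amplitude=0.15, f_wave_amplitude=0.0),
    "af": RhythmParams("af", mean_rr=0.7, rr_cv=0.30,
                       p_wave_amplitude=0.0, f_wave_amplitude=0.10, f_wave_freq=6.5),
    "other": RhythmParams("other", mean_rr=0.8, rr_cv=0.06,
                          p_wave_amplitude=0.15, pvc_prob=0.18),
    "noise": RhythmParams("noise", noise_sd=0.35),
}


@dataclass
class EcgSegment:
    """A labeled single-lead ECG window."""

    samples: np.ndarray  # mV
    fs: float            # Hz
    label: str
    duration: float      # seconds

    def __post_init__(self):
        expected = int(round(self.fs * self.duration))
        if len(self.samples) != expected:
            raise ValueError(
                f"sample count {len(self.samples)} != round(fs * duration) = {expected}"
            )


def simulate_rr(params: RhythmParams, duration: float, seed: int) -> np.ndarray:
    """Draw a beat-interval sequence whose cumulative sum covers ``duration``.

    Sinus rhythm uses a truncated normal around ``mean_rr``; AF an i.i.d.
    lognormal with coefficient of variation ``rr_cv`` (irregular, no serial
    correlation); ``other`` injects premature-beat pairs (0.6 RR then a 1.4 RR
    compensatory pause) into a sinus stream.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if params.mean_rr <= 0.2:
        raise ValueError(
            f"mean_rr={params.mean_rr} s is nonphysiological (must exceed 0.2 s)"
        )
    rng = np.random.default_rng(seed)
    n_max = int(np.ceil(duration / params.mean_rr * 3)) + 4
    if params.rhythm_label == "af":
        sigma = np.sqrt(np.log1p(params.rr_cv**2))
        mu = np.log(params.mean_rr) - sigma**2 / 2
        rr = rng.lognormal(mu, sigma, size=n_max)
    else:
        rr = rng.normal(params.mean_rr, params.rr_cv * params.mean_rr, size=n_max)
        if params.pvc_prob > 0:
            hit = rng.random(n_max) < params.pvc_prob
            for i in np.nonzero(hit)[0]:
                if i + 1 < n_max:
                    rr[i] *= 0.6
                    rr[i + 1] *= 1.4
    rr = np.clip(rr, 0.25, 3.0)
    n = int(np.searchsorted(np.cumsum(rr), duration)) + 1
    return rr[: min(n, n_max)]


def beat_template(fs: float, include_p: bool = True,
                  p_amplitude: float = 0.15) -> tuple[np.ndarray, int]:
    """One P-QRS-T complex as a sum of Gaussian bumps.

    Returns ``(waveform, r_index)`` where ``r_index`` is the sample of the R
    peak inside the waveform.  Bump latencies are relative to the R peak;
    amplitudes are in mV with the R peak as global maximum.
    """
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz to resolve the QRS complex")
    # (latency s, width s, amplitude mV)
    bumps = [
        (-0.035, 0.012, -0.10),   # Q
        (0.0, 0.014, 1.00),       # R
        (0.040, 0.013, -0.18),    # S
        (0.230, 0.050, 0.32),     # T
    ]
    if include_p:
        bumps.insert(0, (-0.170, 0.025, p_amplitude))  # P
    t0, t1 = -0.28, 0.42
    t = np.arange(int(round(t0 * fs)), int(round(t1 * fs)) + 1) / fs
    wave = np.zeros_like(t)
    for lat, width, amp in bumps:
        wave += amp * np.exp(-0.5 * ((t - lat) / width) ** 2)
    return wave, int(round(-t0 * fs))


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    white = rng.normal(0.0, 1.0, size=n)
    lo, hi = _BAND
    hi = min(hi, 0.45 * fs)
    sos = sp_signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    shaped = sp_signal.sosfiltfilt(sos, white)
    s = shaped.std()
    return shaped * (sd / s) if s > 0 else shaped


def synthesize_segment(params: RhythmParams, fs: float, duration: float,
                       seed: int) -> EcgSegment:
    """Render one labeled ECG segment at sampling rate ``fs``.

    Beats are placed at the simulated RR onsets; AF adds a frequency- and
    amplitude-jittered sinusoid at ``f_wave_freq``; the noise class is pure
    band-limited noise with no beat structure.  Output is clipped to
    ±5 mV and is bit-identical for identical arguments.
    """
    if not (1.0 <= duration <= 120.0):
        raise ValueError(f"duration {duration} s outside the supported range [1, 120] s")
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration))
    x = np.zeros(n)
    if params.rhythm_label != "noise":
        rr = simulate_rr(params, duration, seed=int(rng.integers(2**31)))
        r_times = 0.35 + np.concatenate([[0.0], np.cumsum(rr)])
        wave, r_idx = beat_template(
            fs, include_p=params.p_wave_amplitude > 0,
            p_amplitude=params.p_wave_amplitude,
        )
        amp_jitter = 1.0 + 0.05 * rng.standard_normal(len(r_times))
        for rt, aj in zip(r_times, amp_jitter):
            c = int(round(rt * fs))
            lo = c - r_idx
            hi = lo + len(wave)
            wlo = max(0, -lo)
            whi = len(wave) - max(0, hi - n)
            if whi <= wlo:
                continue
            x[max(0, lo) : max(0, lo) + (whi - wlo)] += aj * wave[wlo:whi]
        if params.f_wave_amplitude > 0:
            t = np.arange(n) / fs
            phase = rng.uniform(0, 2 * np.pi)
            fm = 0.4 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
            am = 1.0 + 0.3 * np.sin(2 * np.pi * 0.2 * t + rng.uniform(0, 2 * np.pi))
            x += params.f_wave_amplitude * am * np.sin(
                2 * np.pi * params.f_wave_freq * t + phase + fm
            )
    if params.noise_sd > 0:
        x += _band_limited_noise(rng, n, fs, params.noise_sd)
    x = np.clip(x, -MAX_AMPLITUDE_MV, MAX_AMPLITUDE_MV)
    return EcgSegment(samples=x, fs=fs, label=params.rhythm_label, duration=duration)


def make_dataset(
    n_per_class: int,
    classes: list[str] | tuple[str, ...] = ("af", "normal"),
    fs: float = 250.0,
    duration_policy: float | tuple[float, float] = 10.0,
    seed: int = 0,
    params: dict[str, RhythmParams] | None = None,
) -> list[EcgSegment]:
    """Balanced labeled dataset covering both recording regimes.

    ``duration_policy`` is either a fixed duration in seconds (e.g. ``10.0``
    with ``fs=250`` for Holter-style windows) or a ``(lo, hi)`` range
    (e.g. ``(9, 30)`` with ``fs=300`` for handheld-device records, drawn
    uniformly).  Per-segment seeds derive deterministically from ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    params = params or DEFAULT_PARAMS
    for c in classes:
        if c not in params:
            raise ValueError(f"unknown class {c!r}; known: {sorted(params)}")
    n_total = n_per_class * len(classes)
    ss = np.random.SeedSequence(seed)
    child_seeds = (ss.generate_state(2 * n_total) >> 1).astype(np.int64)
    rng = np.random.default_rng(int(child_seeds[0]))
    segments: list[EcgSegment] = []
    i = 0
    for c in classes:
        for _ in range(n_per_class):
            if isinstance(duration_policy, (int, float)):
                dur = float(duration_policy)
            else:
                lo, hi = duration_policy
                dur = float(rng.uniform(lo, hi))
            seg_seed = int(child_seeds[n_total + i])
            segments.append(synthesize_segment(params[c], fs, dur, seg_seed))
            i += 1
    return segments


def rr_cv_estimate(segment: EcgSegment, min_distance_s: float = 0.25) -> float:
    """Coefficient of variation of detected R-peak intervals (NaN if < 3 peaks).

    A simple amplitude-threshold peak detector; used by the separability
    check and by tests, not by the networks.
    """
    x = segment.samples
    thresh = 0.5 * np.percentile(x, 99.5)
    peaks, _ = sp_signal.find_peaks(
        x, height=max(thresh, 0.2), distance=int(min_distance_s * segment.fs)
    )
    if len(peaks) < 3:
        return float("nan")
    rr = np.diff(peaks) / segment.fs
    return float(np.std(rr) / np.mean(rr))


def count_r_peaks(segment: EcgSegment) -> int:
    """Number of plausible R peaks found by the simple detector.

    The height threshold adapts to the robust (median-absolute-deviation)
    noise level, so structureless noise records yield essentially no peaks.
    """
    x = segment.samples
    sigma = 1.4826 * np.median(np.abs(x - np.median(x)))
    thr = max(0.45, 4.0 * sigma)
    peaks, _ = sp_signal.find_peaks(
        x, height=thr, prominence=thr, distance=int(0.25 * segment.fs)
    )
    return int(len(peaks))
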