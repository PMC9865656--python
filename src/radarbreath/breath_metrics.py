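"""Instantaneous breaths-per-minute and motion-corruption detection.

Both quantities derive from the band-passed breathing signal.  A per-signal
sliding window ``W`` is set to twice the mean distance between detected
breathing peaks (about two full inhale/exhale cycles); the instantaneous bpm
at each window position is the peak count in the window rescaled to
breaths/minute.  Corruption is scored with a shorter window (0.75*W): the
window is mean-centred and its raw lagged autocorrelation maximum is compared
against an absolute threshold of ``0.001 * W`` — calibrated for signals
normalized to [0, 1], where a periodic window comfortably clears it and a
motion-scrambled or flat one does not.  The flag mean gives the session
corruption fraction ``gamma`` and its complement ``tau = 1 - gamma``; these
weight the learning loss and the final fused prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sps

log = logging.getLogger(__name__)

CORRUPTION_THRESHOLD_PER_SAMPLE = 0.001
"""Autocorrelation threshold per sliding-window sample (signals in [0, 1])."""

FALLBACK_BAND_CENTER_HZ = 0.3
"""Band-centre breathing rate used for the window fallback when peaks are scarce."""


class WindowTooLongError(ValueError):
    pass


class DegenerateWindowError(ValueError):
    pass


@dataclass
class BreathMetrics:
    """Per-session breathing metrics and corruption summary."""

    filtered: np.ndarray        # band-passed signal
    peaks: np.ndarray           # sample indices of detected breathing peaks
    window_bpm: int             # W, samples
    window_ac: int              # autocorrelation window, round(0.75*W)
    bpm: np.ndarray             # instantaneous breaths/min per window start
    flags: np.ndarray           # binary corruption flags c(m), per window start
    corruption_fraction: float  # gamma = mean(c)
    tau: float                  # 1 - gamma


def detect_peaks(signal: np.ndarray, fs: float) -> np.ndarray:
    """Breathing peaks: local maxima at least 1 s apart (half the fastest
    breath period) with prominence >= 10% of the signal range."""
    signal = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(signal)):
        raise ValueError("non-finite signal")
    rng = float(np.ptp(signal))
    if rng == 0.0:
        return np.array([], dtype=int)
    min_dist = max(1, int(round(fs * 1.0)))
    peaks, _ = sps.find_peaks(signal, distance=min_dist, prominence=0.1 * rng)
    return peaks


def sliding_window(peaks: np.ndarray, fs: float = 20.0) -> int:
    """W = round(2 * mean consecutive peak distance), in samples.

    With fewer than two peaks there is no distance to average; fall back to
    two cycles at the band-centre rate and log a warning.
    """
    peaks = np.asarray(peaks)
    if peaks.size < 2:
        w = int(round(2.0 * fs / FALLBACK_BAND_CENTER_HZ))
        log.warning("fewer than 2 peaks; falling back to W=%d samples", w)
        return w
    return int(round(2.0 * float(np.mean(np.diff(peaks)))))


def instantaneous_bpm(signal: np.ndarray, peaks: np.ndarray, w: int, fs: float) -> np.ndarray:
    """Peaks counted in each length-``w`` window, rescaled to breaths/minute.

    ``bpm[t] = #peaks in [t, t+w) * 60 * fs / w``; one value per window start.
    """
    n = len(signal)
    if w > n:
        raise WindowTooLongError(f"window {w} exceeds signal length {n}")
    starts = np.arange(n - w + 1)
    in_win = np.zeros(n + 1)
    np.add.at(in_win, np.asarray(peaks, dtype=int), 1.0)
    csum = np.cumsum(in_win)
    counts = csum[starts + w] - csum[starts]
    return counts * 60.0 * fs / w


def corruption_flags(signal: np.ndarray, w: int) -> np.ndarray:
    """Binary motion-corruption flags from windowed autocorrelation.

    Window length ``round(0.75*w)``; each window is mean-centred, its raw
    (unnormalized) autocorrelation over lags 1..len-1 maximized, and the flag
    set when that maximum falls below ``0.001*w``.  Flags are indexed by
    window start.
    """
    signal = np.asarray(signal, dtype=float)
    w_ac = int(round(0.75 * w))
    if w_ac < 4:
        raise DegenerateWindowError(f"autocorrelation window {w_ac} < 4")
    n = len(signal)
    if w_ac > n:
        raise WindowTooLongError(f"autocorrelation window {w_ac} exceeds signal length {n}")
    threshold = CORRUPTION_THRESHOLD_PER_SAMPLE * w
    n_pos = n - w_ac + 1
    flags = np.zeros(n_pos, dtype=np.int8)
    for t in range(n_pos):
        win = signal[t : t + w_ac]
        win = win - win.mean()
        ac = np.correlate(win, win, mode="full")[w_ac:]  # lags 1 .. w_ac-1
        flags[t] = 1 if ac.max(initial=-np.inf) < threshold else 0
    return flags


def corruption_summary(flags: np.ndarray) -> Tuple[float, float]:
    """(tau, gamma) with gamma = mean(flags), tau = 1 - gamma."""
    flags = np.asarray(flags)
    gamma = float(flags.mean()) if flags.size else 0.0
    return 1.0 - gamma, gamma


def compute_breath_metrics(
    signal: np.ndarray,
    fs: float,
    fc: Optional[float] = None,
    prefiltered: bool = False,
) -> BreathMetrics:
    """Full metric chain for one signal.

    ``signal`` should be normalized to [0, 1]; unless ``prefiltered``, it is
    first band-passed with the two-stage biquad cascade at ``fc`` (required in
    that case).  The filtered signal is re-normalized to [0, 1] before the
    corruption threshold is applied, as the threshold calibration assumes.
    """
    from radarbreath.breath_band import apply_cascade
    from radarbreath.range_phase import normalize_trace

    signal = np.asarray(signal, dtype=float)
    if prefiltered:
        filtered = signal
    else:
        if fc is None:
            raise ValueError("fc is required when the signal is not prefiltered")
        filtered = apply_cascade(signal, fc, fs=fs)
    norm = normalize_trace(filtered)
    peaks = detect_peaks(norm, fs)
    w = sliding_window(peaks, fs)
    w = min(w, len(norm))
    bpm = instantaneous_bpm(norm, peaks, w, fs)
    flags = corruption_flags(norm, w)
    tau, gamma = corruption_summary(flags)
    return BreathMetrics(
        filtered=filtered,
        peaks=peaks,
        window_bpm=w,
        window_ac=int(round(0.75 * w)),
        bpm=bpm,
        flags=flags,
        corruption_fraction=gamma,
        tau=tau,
    )
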