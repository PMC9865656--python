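"""Respiration band-pass filtering and central-frequency (Fc) labeling.

The breathing signal is isolated with two cascaded second-order recursive
(biquad) band-pass filters centred at the session's respiration frequency Fc
(quality factor Q = 2, slow-time sampling rate fs = 20 Hz).  The biquad
recurrence is

    O[n] = a0*I[n] + a1*I[n-1] + a2*I[n-2] - b1*O[n-1] - b2*O[n-2]

with the constant-0 dB-peak-gain band-pass design: for ``w0 = 2*pi*fc/fs`` and
``aq = sin(w0)/(2*Q)``, feed-forward ``(aq, 0, -aq)`` and feedback
``(-2*cos(w0), 1-aq)``, all divided by ``1+aq`` — unity gain at Fc, zeros at
DC and Nyquist.

Two labeling procedures produce the reference Fc inside the physiological
band [0.1, 0.5] Hz (6–30 breaths/min):

* ``belt_fc_reference`` — the dominant peak of the belt-trace power spectrum
  in band (the training label).
* ``correlation_fc_label`` — grid search over candidate Fc maximizing the
  Pearson correlation between the band-passed radar phase and the belt
  (diagnostic alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal as sps

from radarbreath.synthetic_scene import FC_BAND

DEFAULT_Q = 2.0
DEFAULT_FS = 20.0
DEFAULT_STAGES = 2


class NyquistError(ValueError):
    """Filter centre frequency at or above fs/2."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (zero-variance input)."""


@dataclass(frozen=True)
class BiquadCoeffs:
    """Biquad filter weights in the recurrence convention above."""

    a0: float
    a1: float
    a2: float
    b1: float
    b2: float
    fc: float
    q: float
    fs: float

    @property
    def ba(self) -> tuple[np.ndarray, np.ndarray]:
        """(b, a) polynomial form for scipy (a normalized to leading 1)."""
        return (np.array([self.a0, self.a1, self.a2]),
                np.array([1.0, self.b1, self.b2]))

    def poles(self) -> np.ndarray:
        return np.roots([1.0, self.b1, self.b2])

    def gain_at(self, f_hz: float) -> float:
        b, a = self.ba
        _, h = sps.freqz(b, a, worN=[2.0 * np.pi * f_hz / self.fs])
        return float(np.abs(h[0]))


@dataclass(frozen=True)
class FcLabel:
    """A central-frequency label and the procedure that produced it."""

    fc: float
    method: Literal["belt_spectrum", "max_correlation"]

    def __post_init__(self) -> None:
        if not (FC_BAND[0] <= self.fc <= FC_BAND[1]):
            raise ValueError(f"fc={self.fc} outside the band {FC_BAND}")


def design_biquad(fc: float, q: float = DEFAULT_Q, fs: float = DEFAULT_FS) -> BiquadCoeffs:
    """Peak-normalized band-pass biquad centred at ``fc``."""
    if not (0.0 < fc < fs / 2.0):
        raise NyquistError(f"fc={fc} must lie strictly in (0, fs/2={fs / 2})")
    if q <= 0:
        raise ValueError(f"q must be positive, got {q}")
    w0 = 2.0 * np.pi * fc / fs
    aq = np.sin(w0) / (2.0 * q)
    norm = 1.0 + aq
    return BiquadCoeffs(
        a0=aq / norm, a1=0.0, a2=-aq / norm,
        b1=-2.0 * np.cos(w0) / norm, b2=(1.0 - aq) / norm,
        fc=fc, q=q, fs=fs,
    )


def apply_cascade(
    x: np.ndarray,
    fc: float,
    q: float = DEFAULT_Q,
    fs: float = DEFAULT_FS,
    stages: int = DEFAULT_STAGES,
) -> np.ndarray:
    """Run the biquad recurrence ``stages`` times in series, zero initial state."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    coeffs = design_biquad(fc, q, fs)
    b, a = coeffs.ba
    out = x
    for _ in range(stages):
        out = sps.lfilter(b, a, out)
    return out


def belt_fc_reference(belt: np.ndarray, fs: float = DEFAULT_FS, pad_factor: int = 4) -> FcLabel:
    """Dominant in-band peak of the belt power spectrum.

    The trace is mean-removed, zero-padded ``pad_factor``-fold for grid
    refinement (no taper), and the magnitude-squared FFT is scanned over
    [0.1, 0.5] Hz.
    """
    belt = np.asarray(belt, dtype=float)
    min_len = int(np.ceil(2.0 / FC_BAND[0] * fs))
    if belt.size < min_len:
        raise ValueError(
            f"belt trace of {belt.size} samples is too short: need >= {min_len} "
            "(two cycles at the slowest breathing rate)"
        )
    n = belt.size * pad_factor
    spec = np.abs(np.fft.rfft(belt - belt.mean(), n=n)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    in_band = (freqs >= FC_BAND[0]) & (freqs <= FC_BAND[1])
    idx = np.flatnonzero(in_band)
    best = idx[int(np.argmax(spec[idx]))]
    return FcLabel(fc=float(freqs[best]), method="belt_spectrum")


def correlation_fc_label(
    x: np.ndarray,
    belt: np.ndarray,
    grid_step: float = 0.01,
    q: float = DEFAULT_Q,
    fs: float = DEFAULT_FS,
) -> FcLabel:
    """Fc maximizing the correlation of band-passed phase with the belt.

    For every candidate on the [0.1, 0.5] Hz grid the phase trace is filtered
    with the two-stage biquad cascade and Pearson-correlated with the
    mean-removed belt; ties break toward the lowest Fc.
    """
    x = np.asarray(x, dtype=float)
    belt = np.asarray(belt, dtype=float)
    if x.shape != belt.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {belt.shape}")
    if np.ptp(x) == 0 or np.ptp(belt) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    belt_c = belt - belt.mean()
    belt_norm = np.linalg.norm(belt_c)
    grid = np.arange(FC_BAND[0], FC_BAND[1] + grid_step / 2.0, grid_step)
    best_fc, best_r = grid[0], -np.inf
    for fc in grid:
        filt = apply_cascade(x, fc, q=q, fs=fs)
        filt_c = filt - filt.mean()
        denom = np.linalg.norm(filt_c) * belt_norm
        # |r|: the phase's sign convention (range shrinks on inhale) may
        # invert it relative to the belt force
        r = float(abs(filt_c @ belt_c) / denom) if denom > 0 else 0.0
        if r > best_r:  # strict: ties keep the lowest fc
            best_fc, best_r = float(fc), r
    return FcLabel(fc=round(best_fc, 10), method="max_correlation")
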