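"""FMCW radar configuration and range geometry.

An FMCW radar transmits linear frequency sweeps (chirps) of bandwidth ``Bw``
and duration ``tc``; mixing the echo with the transmitted reference yields an
intermediate-frequency (IF) tone whose frequency is proportional to target
range.  Two derived quantities govern the range axis:

* range resolution ``dr = c / (2 Bw)``
* maximum unambiguous range ``Rmax = (dr / 2) * ns``

where ``ns`` is the number of fast-time ADC samples per chirp.  Chest
displacement during breathing is millimetres — far below ``dr`` — and is
observed in the *phase* of the selected range bin over slow time
(micro-Doppler), with ``phase = 4*pi*R / lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

C_LIGHT = 3.0e8
"""Propagation speed used throughout, m/s (plane-wave speed of light in air)."""


class InvalidConfigError(ValueError):
    """Raised when a radar configuration violates a physical constraint."""


@dataclass(frozen=True)
class RadarConfig:
    """Waveform and acquisition parameters of the radar front end.

    Defaults are the 60 GHz desk-monitoring profile: 1 Tx / 3 Rx, 2 chirps per
    frame, 200 fast-time samples, 4 GHz sweep, 2 MHz ADC rate, 150 us chirps,
    20 frames per second.
    """

    n_tx: int = 1
    n_rx: int = 3
    n_chirps: int = 2
    n_samples: int = 200
    f0: float = 60.0e9
    fs_adc: float = 2.0e6
    frame_rate: float = 20.0
    t_chirp: float = 150.0e-6
    bandwidth: float = 4.0e9
    c_light: float = C_LIGHT

    def __post_init__(self) -> None:
        for name in ("n_tx", "n_rx", "n_chirps", "n_samples"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.bandwidth <= 0:
            raise InvalidConfigError(f"bandwidth must be positive, got {self.bandwidth}")
        if self.f0 <= 0:
            raise InvalidConfigError(f"f0 must be positive, got {self.f0}")
        if self.fs_adc <= 0 or self.frame_rate <= 0 or self.t_chirp <= 0:
            raise InvalidConfigError("fs_adc, frame_rate and t_chirp must be positive")
        if self.t_chirp < self.n_samples / self.fs_adc:
            raise InvalidConfigError(
                "fast-time sampling does not fit within the chirp: "
                f"t_chirp={self.t_chirp} < n_samples/fs_adc={self.n_samples / self.fs_adc}"
            )

    def with_(self, **kwargs) -> "RadarConfig":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


def range_resolution(cfg: RadarConfig) -> float:
    """Theoretical range resolution ``dr = c / (2 Bw)`` in metres."""
    return cfg.c_light / (2.0 * cfg.bandwidth)


def max_range(cfg: RadarConfig) -> float:
    """Maximum detection range ``Rmax = (dr / 2) * ns`` in metres."""
    return range_resolution(cfg) / 2.0 * cfg.n_samples


def wavelength(cfg: RadarConfig) -> float:
    """Carrier wavelength ``lambda = c / f0`` in metres."""
    return cfg.c_light / cfg.f0


def fft_bin_spacing(cfg: RadarConfig) -> float:
    """Range spacing of the fast-time FFT grid, in metres.

    The ADC observes only ``ns / fs_adc`` seconds of the ``t_chirp`` sweep, so
    the effective swept bandwidth is ``Bw * ns / (fs_adc * t_chirp)`` and one
    FFT bin spans ``c * fs_adc * t_chirp / (2 * Bw * ns)`` metres.  With the
    default profile this is 5.625 cm, coarser than the theoretical ``dr``.
    """
    return cfg.c_light * cfg.fs_adc * cfg.t_chirp / (2.0 * cfg.bandwidth * cfg.n_samples)


def beat_frequency(cfg: RadarConfig, target_range: float) -> float:
    """IF tone frequency for a target at ``target_range`` metres: 2*Bw*R/(c*tc)."""
    return 2.0 * cfg.bandwidth * target_range / (cfg.c_light * cfg.t_chirp)
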