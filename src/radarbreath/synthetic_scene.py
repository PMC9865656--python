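"""Synthetic desk-workplace breathing scenes.

Real recordings for this problem — a subject sitting 20–40 cm from a 60 GHz
FMCW board with a force-sensing respiration belt as reference — are not
publicly distributable, so this module is a first-class simulator that plays
the role of the recording campaign: 24 users x 20 sessions x 30 s, half of
each user's sessions at each of two chest-to-board distance classes.

Physics of the emulation, per chirp:  a chest at range ``R`` produces an IF
tone at beat frequency ``2*Bw*R/(c*tc)`` with slow-time phase ``4*pi*R/lambda``.
``R(t) = base_range - d(t)`` where ``d(t)`` is a raised-cosine breathing
waveform (asymmetric inhale/exhale halves; a pure sinusoid is the symmetric
special case) plus sparse random-walk motion bursts that mimic arm/torso
movements.  Static clutter tones, a DC offset and white ADC noise complete the
frame cube.  The belt sees breathing (not arm motion, which barely couples to
a chest-mounted sensor) through a linear gain and is quantized to its 0.1 N
force resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

from radarbreath.radar_model import (
    RadarConfig,
    beat_frequency,
    max_range,
    wavelength,
)

FC_BAND = (0.1, 0.5)
"""Physiological breathing-frequency search band, Hz (6–30 breaths/min)."""

BELT_RESOLUTION_N = 0.1
"""Force resolution of the reference respiration belt, Newtons."""

NOMINAL_FRAMES = 660
"""Frames per standardized session (10% above the nominal 600 = 20 fps * 30 s)."""


class InvalidProfileError(ValueError):
    """A user profile violates a physical or band constraint."""


class OutOfRangeError(ValueError):
    """The simulated chest excursion leaves the radar's unambiguous range."""


@dataclass(frozen=True)
class UserProfile:
    """Breathing and geometry parameters of one simulated subject."""

    user_id: str
    fc_true: float            # central breathing frequency, Hz, in [0.1, 0.5]
    breath_amp: float         # peak chest displacement, m (order 1–10 mm)
    duty_asymmetry: float     # inhale fraction of the cycle, in (0, 1)
    base_range: float         # chest-to-board distance, m
    motion_rate: float        # expected motion bursts per session
    belt_gain: float = 1000.0  # Newtons of belt force per metre of displacement

    def __post_init__(self) -> None:
        if not (FC_BAND[0] <= self.fc_true <= FC_BAND[1]):
            raise InvalidProfileError(
                f"fc_true={self.fc_true} outside the breathing band {FC_BAND}"
            )
        if not (0.0 < self.duty_asymmetry < 1.0):
            raise InvalidProfileError("duty_asymmetry must lie in (0, 1)")
        if self.breath_amp < 0 or self.base_range <= 0 or self.motion_rate < 0:
            raise InvalidProfileError("breath_amp/base_range/motion_rate out of range")

    def with_(self, **kwargs) -> "UserProfile":
        return replace(self, **kwargs)


@dataclass
class NoiseSpec:
    """Nuisance components added to the ideal chest echo.

    ``clutter`` is a sequence of (range_m, amplitude) static reflectors
    (desk edge, monitor, wall).  Amplitudes are in the same arbitrary ADC
    units as ``target_amp``.
    """

    target_amp: float = 100.0
    adc_noise_std: float = 5.0
    dc_offset: float = 30.0
    clutter: Sequence[Tuple[float, float]] = ((0.55, 60.0), (0.95, 40.0), (1.6, 25.0))
    belt_noise_std: float = 0.05
    quantize_adc: bool = False  # optional 12-bit rounding of raw counts


@dataclass
class SessionRecord:
    """One recording session: raw radar frame cube, belt trace, ground truth."""

    frames: np.ndarray          # [Nm, Nc, NRx, ns] real ADC counts
    belt: np.ndarray            # [Nm] Newtons, multiples of 0.1
    user_id: str
    distance_class: int         # 30 or 40 (cm)
    frame_rate: float           # Hz
    displacement: Optional[np.ndarray] = None  # [Nm] true chest displacement, m
    motion_mask: Optional[np.ndarray] = None   # [Nm] 1 during motion bursts
    fc_true: Optional[float] = None            # Hz

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def make_user(seed: int, overrides: Optional[dict] = None) -> UserProfile:
    """Draw a deterministic user profile.

    fc_true ~ U[0.12, 0.48] Hz (centred on the 7–9 breaths/30 s norm),
    breath_amp ~ log-uniform on [1, 8] mm, duty_asymmetry ~ U[0.35, 0.5],
    base_range ~ U[0.2, 0.4] m, motion_rate ~ U[3, 6] gestures/session —
    desk users type, laugh and gesture, so most sessions carry some motion
    corruption, as in real at-desk recording campaigns.
    """
    rng = np.random.default_rng(seed)
    params = dict(
        user_id=f"user{seed:05d}",
        fc_true=float(rng.uniform(0.12, 0.48)),
        breath_amp=float(np.exp(rng.uniform(np.log(1e-3), np.log(8e-3)))),
        duty_asymmetry=float(rng.uniform(0.35, 0.5)),
        base_range=float(rng.uniform(0.2, 0.4)),
        motion_rate=float(rng.uniform(3.0, 6.0)),
    )
    if overrides:
        params.update(overrides)
    return UserProfile(**params)


def breath_waveform(t: np.ndarray, fc: float, duty: float) -> np.ndarray:
    """Asymmetric raised-cosine breathing cycle, unit amplitude in [0, 1].

    The inhale occupies a fraction ``duty`` of the period (rising half-cosine),
    the exhale the remainder (falling half-cosine); ``duty = 0.5`` gives a pure
    sinusoid up to phase.
    """
    u = np.mod(t * fc, 1.0)
    out = np.where(
        u < duty,
        0.5 * (1.0 - np.cos(np.pi * u / duty)),
        0.5 * (1.0 + np.cos(np.pi * (u - duty) / (1.0 - duty))),
    )
    return out


def _motion_bursts(
    n_frames: int,
    frame_rate: float,
    motion_rate: float,
    rng: np.random.Generator,
    amplitude: float = 0.012,
    intensity: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sparse desk-gesture bursts and their radar-visible consequences.

    A gesture ("movement of the hands toward the desk", typing, a lean) does
    three things to the radar scene for 3–8 s:

    * the torso shifts slightly — an out-and-back sin^2 bump of about a
      centimetre, rate-capped below lambda/4 per frame so it unwraps cleanly;
    * the limb becomes a strong reflector near the chest range, capturing the
      processing window; its micro-motion (typing tremor, ~0.3 mm per frame)
      is far above the respiration band, so the band-pass leaves near-silence
      — the low-local-power signature the autocorrelation detector flags;
    * the limb partially occludes the chest echo, removing the breathing
      phasor from the captured bin.

    ``intensity`` scales how strongly the limb echo dominates (0 disables the
    capture and occlusion, leaving only the small torso bump).  Returns
    ``(displacement_m, occlusion in [0,1], limb_amp ratio, limb_range_m,
    mask)``; the belt, strapped to the chest, sees none of it.
    """
    motion = np.zeros(n_frames)
    occlusion = np.zeros(n_frames)
    limb_amp = np.zeros(n_frames)
    limb_range = np.zeros(n_frames)
    mask = np.zeros(n_frames, dtype=np.int8)
    n_bursts = rng.poisson(motion_rate)
    for _ in range(n_bursts):
        span = max(8, int(round(rng.uniform(5.0, 14.0) * frame_rate)))
        start = int(rng.integers(0, max(1, n_frames - span)))
        stop = min(n_frames, start + span)
        n = stop - start
        # flat-top envelope: ~1 s cosine ramps, full capture in between
        ramp = max(2, min(int(round(frame_rate)), n // 3))
        env = np.ones(n)
        env[:ramp] = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[n - ramp:] = env[:ramp][::-1]
        bump = np.sin(np.pi * np.arange(n) / n) ** 2
        amp_cap = 1.2e-3 * n / np.pi          # unwrap-rate cap on the bump
        amp = min(amplitude, amp_cap) * rng.uniform(0.6, 1.0)
        walk = np.cumsum(rng.normal(0.0, 0.3e-3, n))
        motion[start:stop] += amp * bump + (walk - np.linspace(0.0, walk[-1], n)) * env
        occlusion[start:stop] = np.maximum(
            occlusion[start:stop], np.clip(intensity, 0.0, 1.0) * rng.uniform(0.9, 1.0) * env
        )
        limb_amp[start:stop] = np.maximum(
            limb_amp[start:stop], 3.0 * intensity * rng.uniform(0.8, 1.2) * env
        )
        limb_range[start:stop] = rng.uniform(-0.03, 0.08)  # offset from chest, m
        mask[start:stop] = 1
    return motion, np.clip(occlusion, 0.0, 1.0), limb_amp, limb_range, mask


def simulate_session(
    profile: UserProfile,
    cfg: RadarConfig = RadarConfig(),
    duration: float = 30.0,
    seed: int = 0,
    noise: Optional[NoiseSpec] = None,
    overrun: float = 0.1,
    distance_class: Optional[int] = None,
    motion_amplitude: float = 0.012,
    motion_intensity: float = 1.0,
) -> SessionRecord:
    """Simulate one recording session.

    The device streams ``overrun`` (default 10%) past the nominal stop, so a
    nominal 30 s session carries 660 frames at exact ``1/frame_rate`` spacing —
    the standardized per-session length downstream.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    noise = noise if noise is not None else NoiseSpec()
    rng = np.random.default_rng(seed)

    n_frames = int(round(duration * cfg.frame_rate * (1.0 + overrun)))
    t = np.arange(n_frames) / cfg.frame_rate

    d_breath = profile.breath_amp * breath_waveform(t, profile.fc_true, profile.duty_asymmetry)
    d_motion, occlusion, limb_amp, limb_off, mask = _motion_bursts(
        n_frames, cfg.frame_rate, profile.motion_rate, rng, motion_amplitude,
        motion_intensity,
    )
    displacement = d_breath + d_motion
    chest_range = profile.base_range - d_breath + d_motion

    rmax = max_range(cfg)
    if np.any(chest_range >= rmax) or np.any(chest_range <= 0):
        raise OutOfRangeError(
            f"chest range excursion [{chest_range.min():.3f}, {chest_range.max():.3f}] m "
            f"leaves (0, Rmax={rmax:.3f}) m"
        )

    lam = wavelength(cfg)
    t_fast = np.arange(cfg.n_samples) / cfg.fs_adc

    # target IF tone per frame: beat frequency and phase both track R(t);
    # the chest echo fades with occlusion during motion bursts
    f_beat = 2.0 * cfg.bandwidth * chest_range / (cfg.c_light * cfg.t_chirp)
    arg = 2.0 * np.pi * f_beat[:, None] * t_fast[None, :] + 4.0 * np.pi * chest_range[:, None] / lam
    target = (noise.target_amp * (1.0 - occlusion))[:, None] * np.cos(arg)  # [Nm, ns]

    clutter = np.zeros(cfg.n_samples)
    for c_range, c_amp in noise.clutter:
        arg_c = 2.0 * np.pi * beat_frequency(cfg, c_range) * t_fast + 4.0 * np.pi * c_range / lam
        clutter += c_amp * np.cos(arg_c)

    # limb echo during gestures: strong reflector near the chest range whose
    # tremor (~0.3 mm/frame) lies far above the respiration band
    if np.any(limb_amp > 0):
        r_limb = profile.base_range + limb_off + rng.normal(0.0, 0.3e-3, n_frames)
        f_limb = 2.0 * cfg.bandwidth * r_limb / (cfg.c_light * cfg.t_chirp)
        arg_l = (2.0 * np.pi * f_limb[:, None] * t_fast[None, :]
                 + 4.0 * np.pi * r_limb[:, None] / lam)
        target = target + (noise.target_amp * limb_amp)[:, None] * np.cos(arg_l)

    shape = (n_frames, cfg.n_chirps, cfg.n_rx, cfg.n_samples)
    frames = np.broadcast_to(
        target[:, None, None, :] + clutter[None, None, None, :] + noise.dc_offset, shape
    ).copy()
    if noise.adc_noise_std > 0:
        frames += rng.normal(0.0, noise.adc_noise_std, shape)
    if noise.quantize_adc:
        frames = np.clip(np.round(frames), -2048, 2047)

    belt = profile.belt_gain * d_breath
    if noise.belt_noise_std > 0:
        belt = belt + rng.normal(0.0, noise.belt_noise_std, n_frames)
    belt = np.round(belt / BELT_RESOLUTION_N) * BELT_RESOLUTION_N

    if distance_class is None:
        distance_class = 30 if profile.base_range <= 0.3 else 40

    return SessionRecord(
        frames=np.asarray(frames, dtype=np.float32),
        belt=belt,
        user_id=profile.user_id,
        distance_class=distance_class,
        frame_rate=cfg.frame_rate,
        displacement=displacement,
        motion_mask=mask,
        fc_true=profile.fc_true,
    )


def build_meta_dataset(
    out_dir: str | Path,
    n_train_users: int = 14,
    n_test_users: int = 10,
    sessions_per_user: int = 20,
    cfg: RadarConfig = RadarConfig(),
    seed: int = 0,
    duration: float = 30.0,
    noise: Optional[NoiseSpec] = None,
):
    """Generate the full episodic protocol and write it to disk.

    Defaults reproduce the study conditions: 14 training + 10 test users,
    20 x 30 s sessions each (4 h of signal in total), half of every user's
    sessions at the <=30 cm distance class and half at <=40 cm.

    Writes one HDF5 container per session plus ``manifest.csv`` with columns
    (session_path, user_id, split, distance_class).  Returns a pandas
    DataFrame view of the manifest.
    """
    import pandas as pd

    from radarbreath.workbench import write_session

    if n_train_users < 1 or sessions_per_user < 1 or n_test_users < 0:
        raise ValueError("user and session counts must be positive")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    n_users = n_train_users + n_test_users
    user_seeds = ss.generate_state(n_users * (sessions_per_user + 1)).reshape(
        n_users, sessions_per_user + 1
    ) % (2**31)

    rows = []
    for u in range(n_users):
        split = "train" if u < n_train_users else "test"
        profile = make_user(int(user_seeds[u, 0]), overrides={"user_id": f"u{u:03d}"})
        for s in range(sessions_per_user):
            # half of the sessions at each distance class
            if s < sessions_per_user // 2 or sessions_per_user == 1:
                base = 0.20 + 0.10 * (int(user_seeds[u, 1 + s]) % 1000) / 1000.0
                dclass = 30
            else:
                base = 0.30 + 0.10 * (int(user_seeds[u, 1 + s]) % 1000) / 1000.0
                dclass = 40
            rec = simulate_session(
                profile.with_(base_range=base),
                cfg=cfg,
                duration=duration,
                seed=int(user_seeds[u, 1 + s]),
                noise=noise,
                distance_class=dclass,
            )
            path = out_dir / f"{profile.user_id}_s{s:02d}.h5"
            write_session(path, rec)
            rows.append(
                {
                    "session_path": str(path),
                    "user_id": profile.user_id,
                    "split": split,
                    "distance_class": dclass,
                }
            )

    manifest = pd.DataFrame(rows, columns=["session_path", "user_id", "split", "distance_class"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
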