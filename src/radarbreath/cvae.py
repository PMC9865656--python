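"""Fc-constrained convolutional variational autoencoder.

The network maps the normalized unwrapped radar phase ``x`` (length 660) to
the respiration-belt reference ``x_belt``:  a two-block 1-D convolutional
encoder produces a Gaussian latent ``z ~ N(mu, sigma)``; a mirrored decoder
(dense projection, two up-sampled deconvolution blocks, sigmoid output)
reconstructs the belt trace; a single linear neuron regresses the central
breathing frequency ``y_hat`` from ``z``, constraining the latent space to
respiration information.

Loss (per sample, sums over the 660 output samples and the latent dims):

    L  = BCE(x_hat_belt, x_belt) + KL[N(mu, sigma) || N(0, 1)] + K*(y - y_hat)^2

with equalization coefficient ``K = 1000``.  The corruption-weighted variant
re-balances reconstruction against Fc supervision by the session's
motion-corruption split ``tau + gamma = 1``:

    L* = tau*BCE + KL + gamma*K*(y - y_hat)^2

and the fused breathing estimate combines the reconstruction with the
phase band-passed at the predicted Fc:

    x_star = (tau*x_hat_belt + gamma*eps*biquad(x, y_hat)) / (tau + gamma*eps),

``eps = 2`` making the Fc route dominant under heavy corruption.

Everything is written against ``autograd.numpy`` so that gradients — and
gradients of gradients, needed by second-order meta-learning — come from
automatic differentiation of the plain numpy forward pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import autograd.numpy as anp
import numpy as np

K_COEFF = 1000.0     # Fc-term equalization coefficient
EPS_FUSION = 2.0     # Fc-route dominance factor in the fused estimate
LOGVAR_CLIP = 10.0   # |log variance| bound for numerical stability
BCE_EPS = 1e-7       # prediction clamp inside the cross-entropy logs


@dataclass(frozen=True)
class CvaeArchitecture:
    """Topology description; sizes of every layer follow from these fields."""

    input_len: int = 660
    latent_dim: int = 32
    enc_filters: Tuple[int, int] = (32, 64)
    kernel: int = 5
    stride: int = 2
    fc_from_mu: bool = False   # regress Fc from mu instead of z

    @property
    def down_len(self) -> int:
        L = self.input_len
        for _ in self.enc_filters:
            L = -(-L // self.stride)  # ceil division, 'same' padding
        return L

    @property
    def flat_len(self) -> int:
        return self.down_len * self.enc_filters[1]


def _param_shapes(arch: CvaeArchitecture) -> Dict[str, Tuple[int, ...]]:
    k, (f1, f2), d = arch.kernel, arch.enc_filters, arch.latent_dim
    F = arch.flat_len
    return {
        "enc1_w": (k * 1, f1), "enc1_b": (f1,),
        "enc2_w": (k * f1, f2), "enc2_b": (f2,),
        "mu_w": (F, d), "mu_b": (d,),
        "lv_w": (F, d), "lv_b": (d,),
        "dec_w": (d, F), "dec_b": (F,),
        "dcv1_w": (k * f2, f1), "dcv1_b": (f1,),
        "dcv2_w": (k * f1, 1), "dcv2_b": (1,),
        "fc_w": (d, 1), "fc_b": (1,),
    }


def count_parameters(arch: CvaeArchitecture) -> int:
    """Total trainable parameter count (affine in the latent dimension)."""
    return sum(int(np.prod(s)) for s in _param_shapes(arch).values())


_IM2COL_CACHE: Dict[Tuple[int, int, int], Tuple[np.ndarray, int, int]] = {}


def _im2col_idx(length: int, kernel: int, stride: int) -> Tuple[np.ndarray, int, int]:
    """'same'-padded gather indices (L_out, k) into the padded axis."""
    key = (length, kernel, stride)
    if key not in _IM2COL_CACHE:
        l_out = -(-length // stride)
        pad_total = max((l_out - 1) * stride + kernel - length, 0)
        pad_left = pad_total // 2
        starts = np.arange(l_out) * stride
        idx = starts[:, None] + np.arange(kernel)[None, :]
        _IM2COL_CACHE[key] = (idx, pad_left, pad_total - pad_left)
    return _IM2COL_CACHE[key]


def _conv1d(x, w, b, stride: int):
    """'same' 1-D convolution: x (L, Cin) -> (ceil(L/stride), Cout)."""
    length, c_in = x.shape[0], x.shape[1]
    k = w.shape[0] // c_in
    idx, pl, pr = _im2col_idx(length, k, stride)
    xp = anp.concatenate([anp.zeros((pl, c_in)), x, anp.zeros((pr, c_in))], axis=0)
    cols = anp.reshape(xp[idx], (idx.shape[0], k * c_in))
    return anp.dot(cols, w) + b


def _relu(h):
    return anp.maximum(h, 0.0)


def _sigmoid(h):
    # pre-activation clamp: saturated beyond +-30 anyway, keeps exp finite
    h = anp.clip(h, -30.0, 30.0)
    return 1.0 / (1.0 + anp.exp(-h))


class Cvae:
    """The autoencoder: parameter layout, initialization and forward passes.

    Parameters live in a single flat vector so optimizers and meta-learning
    updates are plain vector arithmetic; ``self.slices`` maps layer names to
    views.  All forward methods take the flat vector explicitly and are pure,
    which keeps them differentiable (to second order) by autograd.
    """

    def __init__(self, arch: CvaeArchitecture = CvaeArchitecture()):
        self.arch = arch
        self.shapes = _param_shapes(arch)
        self.slices: Dict[str, slice] = {}
        off = 0
        for name, shape in self.shapes.items():
            size = int(np.prod(shape))
            self.slices[name] = slice(off, off + size)
            off += size
        self.n_params = off

    def grad_scale(self) -> np.ndarray:
        """Per-coordinate diagonal preconditioner for inner-loop descent.

        Weight gradients are scaled by 1/fan_in (biases by 1), equalizing the
        effective per-output step across layers: without it, the wide
        flatten-to-dense layers (fan-in ~ thousands) make plain gradient
        descent at the episodic learning rates super-critical and every inner
        loop oscillates divergently.  The matrix is constant, so meta-
        gradients differentiate through preconditioned steps exactly.
        """
        scale = np.ones(self.n_params)
        for name, shape in self.shapes.items():
            if not name.endswith("_b"):
                scale[self.slices[name]] = 1.0 / shape[0]
        return scale

    def init_params(self, seed: int = 0) -> np.ndarray:
        """Glorot-uniform weights, zero biases, deterministic per seed."""
        rng = np.random.default_rng(seed)
        theta = np.zeros(self.n_params)
        for name, shape in self.shapes.items():
            if name.endswith("_b"):
                continue
            fan_in, fan_out = shape[0], shape[1]
            bound = math.sqrt(6.0 / (fan_in + fan_out))
            theta[self.slices[name]] = rng.uniform(-bound, bound, int(np.prod(shape)))
        return theta

    def _p(self, theta, name: str):
        return anp.reshape(theta[self.slices[name]], self.shapes[name])

    # ---- forward passes -------------------------------------------------

    def encode(self, theta, x) -> Tuple[anp.ndarray, anp.ndarray]:
        """x (input_len,) in [0,1] -> (mu, sigma), sigma = exp(logvar/2)."""
        if x.shape[0] != self.arch.input_len:
            raise ValueError(f"input length {x.shape[0]} != {self.arch.input_len}")
        h = anp.reshape(x, (-1, 1))
        h = _relu(_conv1d(h, self._p(theta, "enc1_w"), self._p(theta, "enc1_b"), self.arch.stride))
        h = _relu(_conv1d(h, self._p(theta, "enc2_w"), self._p(theta, "enc2_b"), self.arch.stride))
        flat = anp.reshape(h, (-1,))
        mu = anp.dot(flat, self._p(theta, "mu_w")) + self._p(theta, "mu_b")
        logvar = anp.dot(flat, self._p(theta, "lv_w")) + self._p(theta, "lv_b")
        logvar = anp.clip(logvar, -LOGVAR_CLIP, LOGVAR_CLIP)
        sigma = anp.exp(0.5 * logvar)
        return mu, sigma

    def decode(self, theta, z):
        """z (latent_dim,) -> sigmoid reconstruction (input_len,)."""
        if z.shape[0] != self.arch.latent_dim:
            raise ValueError(f"latent length {z.shape[0]} != {self.arch.latent_dim}")
        f1, f2 = self.arch.enc_filters
        h = _relu(anp.dot(z, self._p(theta, "dec_w")) + self._p(theta, "dec_b"))
        h = anp.reshape(h, (self.arch.down_len, f2))
        h = anp.repeat(h, self.arch.stride, axis=0)  # up-sample
        h = _relu(_conv1d(h, self._p(theta, "dcv1_w"), self._p(theta, "dcv1_b"), 1))
        h = anp.repeat(h, self.arch.stride, axis=0)
        h = h[: self.arch.input_len]
        h = _conv1d(h, self._p(theta, "dcv2_w"), self._p(theta, "dcv2_b"), 1)
        return _sigmoid(anp.reshape(h, (-1,)))

    def regress_fc(self, theta, z):
        """Single linear neuron: latent -> predicted Fc (Hz)."""
        return anp.dot(z, self._p(theta, "fc_w"))[0] + self._p(theta, "fc_b")[0]

    def forward(self, theta, x, eta) -> "CvaeOutput":
        """Full pass with a fixed reparameterization draw ``eta``."""
        mu, sigma = self.encode(theta, x)
        z = mu + sigma * eta
        z_fc = mu if self.arch.fc_from_mu else z
        return CvaeOutput(
            x_hat_belt=self.decode(theta, z),
            mu=mu, sigma=sigma, z=z,
            y_hat=self.regress_fc(theta, z_fc),
        )

    def elbo_loss(self, theta, x, x_belt, y, tau=1.0, gamma=0.0, eta=None):
        """Scalar corruption-weighted loss L*, differentiable in ``theta``.

        ``eta`` is the (fixed) standard-normal draw for the latent sample;
        ``None`` uses the mean (eta = 0).  (tau, gamma) = (1, 0) gives L.
        """
        if eta is None:
            eta = np.zeros(self.arch.latent_dim)
        out = self.forward(theta, x, eta)
        return (
            tau * bce_term(out.x_hat_belt, x_belt)
            + kl_term(out.mu, out.sigma)
            + gamma * K_COEFF * (y - out.y_hat) ** 2
        )


@dataclass
class CvaeOutput:
    """One forward pass: reconstruction, latent statistics, Fc estimate."""

    x_hat_belt: anp.ndarray   # (input_len,), in (0, 1)
    mu: anp.ndarray           # (latent_dim,)
    sigma: anp.ndarray        # (latent_dim,), > 0
    z: anp.ndarray            # (latent_dim,)
    y_hat: float              # Hz


@dataclass
class LossTerms:
    """L / L* decomposition; ``total`` always reproduces the weighted sum."""

    bce: float
    kl: float
    mse_fc: float
    k_coeff: float = K_COEFF
    tau: float = 1.0
    gamma: float = 0.0
    eps_fusion: float = EPS_FUSION
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.tau * self.bce + self.kl + self.gamma * self.k_coeff * self.mse_fc


def reparameterize(mu, sigma, seed: Optional[int] = None,
                   rng: Optional[np.random.Generator] = None):
    """z = mu + sigma * eta with a seeded standard-normal draw."""
    sigma = anp.asarray(sigma) if not hasattr(sigma, "shape") else sigma
    if np.any(np.asarray(sigma) < 0):
        raise ValueError("sigma must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    eta = rng.standard_normal(np.shape(mu))
    return mu + sigma * eta


def bce_term(x_hat, x_ref):
    """Binary cross-entropy summed over samples; prediction clamped away
    from {0, 1} so the logs stay finite."""
    if x_hat.shape != x_ref.shape:
        raise ValueError(f"length mismatch: {x_hat.shape} vs {x_ref.shape}")
    p = anp.clip(x_hat, BCE_EPS, 1.0 - BCE_EPS)
    return anp.sum(-x_ref * anp.log(p) - (1.0 - x_ref) * anp.log(1.0 - p))


def kl_term(mu, sigma):
    """KL[N(mu, sigma) || N(0, 1)] summed over latent dimensions."""
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be strictly positive")
    return anp.sum(0.5 * (mu ** 2 + sigma ** 2 - 1.0) - anp.log(sigma))


def loss_L(out: CvaeOutput, x_belt, y, k_coeff: float = K_COEFF) -> LossTerms:
    """Unweighted loss: BCE + KL + K*(y - y_hat)^2 (both weights at 1)."""
    return LossTerms(
        bce=float(bce_term(out.x_hat_belt, x_belt)),
        kl=float(kl_term(out.mu, out.sigma)),
        mse_fc=float((y - out.y_hat) ** 2),
        k_coeff=k_coeff,
        tau=1.0,
        gamma=1.0,
    )


def loss_Lstar(out: CvaeOutput, x_belt, y, tau: float, gamma: float,
               k_coeff: float = K_COEFF) -> LossTerms:
    """Corruption-weighted loss: tau*BCE + KL + gamma*K*(y - y_hat)^2."""
    if not (0.0 <= tau <= 1.0 and 0.0 <= gamma <= 1.0):
        raise ValueError(f"tau={tau}, gamma={gamma} must lie in [0, 1]")
    if abs(tau + gamma - 1.0) > 1e-9:
        raise ValueError(f"tau + gamma must equal 1, got {tau + gamma}")
    return LossTerms(
        bce=float(bce_term(out.x_hat_belt, x_belt)),
        kl=float(kl_term(out.mu, out.sigma)),
        mse_fc=float((y - out.y_hat) ** 2),
        k_coeff=k_coeff,
        tau=tau,
        gamma=gamma,
    )


def fuse_prediction(x_hat_belt, x, y_hat: float, tau: float, gamma: float,
                    eps: float = EPS_FUSION, fs: float = 20.0):
    """Corruption-weighted fusion of reconstruction and Fc-filtered phase.

    ``x_star = (tau*x_hat_belt + gamma*eps*biquad(x, y_hat)) / (tau + gamma*eps)``;
    the biquad route is the two-stage respiration band-pass centred at the
    predicted Fc.  Raises if ``y_hat`` cannot parameterize a filter.
    """
    from radarbreath.breath_band import apply_cascade

    if abs(tau + gamma - 1.0) > 1e-9:
        raise ValueError(f"tau + gamma must equal 1, got {tau + gamma}")
    phase_route = apply_cascade(np.asarray(x, dtype=float), float(y_hat), fs=fs) \
        if gamma > 0 else np.zeros_like(np.asarray(x, dtype=float))
    return (tau * np.asarray(x_hat_belt, dtype=float) + gamma * eps * phase_route) / (
        tau + gamma * eps
    )
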