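# radarbreath

Non-contact breathing-signal estimation from a 60 GHz FMCW radar, with
few-shot adaptation to new users.

A person sitting 20–40 cm from a desk-mounted frequency-modulated
continuous-wave (FMCW) radar modulates the phase of their range bin with
millimetre-scale chest motion (micro-Doppler).  This package turns raw radar
frame cubes into that breathing signal and meta-learns a model that maps it
onto a chest-belt reference, so that a single labelled session suffices to
personalize the system to a new user.  The real recordings such systems are
developed on are rarely shareable, so a physics-based synthetic scene
generator — chest echo, static clutter, desk-gesture artifacts, quantized
belt — is a first-class part of the package and the substrate for all tests.

## What it computes

**Preprocessing.** For a session of `Nm = 660` frames: DC removal,
averaging over chirps and Rx channels, fast-time FFT to the range spectrum
`SR(m, s)`; the subject's bin is tracked with an 8-frame moving average and
a 12-bin window; static clutter is estimated per bin by moving-target
indication, `S̄ ← α·SR + (1−α)·S̄` with `α = 0.4`; per frame the window bin
with the largest squared deviation from the clutter is selected, its phase
unwrapped and min–max normalized to the model input `x ∈ [0,1]`.
Displacement follows as `d = φ·λ/(4π)`.

**Respiration band and labels.** Two cascaded biquad band-pass stages
(quality factor `Q = 2`, `fs = 20` Hz, unit gain at the centre) isolate the
breathing component; the training label `y` is the dominant peak of the belt
power spectrum in `[0.1, 0.5]` Hz (6–30 breaths/min).

**Corruption score.** A sliding window `W` (twice the mean inter-peak
distance) yields instantaneous breaths/min; a `0.75·W` window's raw
autocorrelation maximum below `0.001·W` flags motion-corrupted spans.  The
flag mean `γ` and its complement `τ = 1 − γ` weight everything downstream.

**Model and losses.** A convolutional variational autoencoder encodes `x`
into `z ~ N(μ, σ)` (latent 32 by default), reconstructs the belt trace
`x̂_belt` through a sigmoid decoder, and regresses `ŷ = Fc` from `z` with a
single linear neuron:

    L  = BCE(x̂_belt, x_belt) + KL[N(μ,σ) ‖ N(0,1)] + K·(y − ŷ)²,   K = 1000
    L* = τ·BCE + KL + γ·K·(y − ŷ)²

so corrupted sessions supervise the breathing frequency rather than the
unreliable waveform.  The fused output is

    x̂* = (τ·x̂_belt + γ·ε·biquad(x, ŷ)) / (τ + γ·ε),   ε = 2.

**Episodic learning.** Second-order MAML (plus first-order MAML, Reptile and
a stabilized MAML variant with multi-step loss, derivative-order annealing
and cosine outer-rate annealing) trains the initialization across users:
four inner gradient epochs on `k ∈ {1, 5, 10}` support sessions, an outer
Adam(β₁=0, β₂=0.5) step from the post-adaptation query loss.  Adapting to a
new user is four first-order epochs on the support — and nothing else.
All gradients, including the gradients-of-gradients second-order MAML
needs, come from automatic differentiation of the plain-numpy forward pass.

## Worked example

`python examples/02_phase_pipeline.py` (clean simulated user):

```
selected range bin(s): [6] (chest at 0.32 m)
true chest amplitude   1.64 mm
displacement RMSE      0.025 mm (1.5% of the amplitude)
spectral Fc estimate   0.152 Hz (truth 0.151 Hz)
```

The tracked bin sits at the simulated chest range; the unwrapped phase,
rescaled by `λ/4π`, reproduces the millimetre chest trajectory to within a
few percent; its spectrum recovers the user's breathing rate to a few mHz.
The other examples cover scene simulation (`01`), bpm and corruption
scoring (`03`), the two Fc-labeling procedures (`04`) and the scaled
episodic experiment with one-shot adaptation (`05`).

A thin CLI mirrors the library for shell use:
`radarbreath simulate|preprocess|label|metrics|train|adapt|predict|evaluate`.

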