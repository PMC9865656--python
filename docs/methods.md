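# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind `radarbreath`, in the order data flows through the
package.

## Radar model and geometry

An FMCW chirp of bandwidth `Bw` and duration `tc` gives theoretical range
resolution `Δr = c/(2·Bw)` and, with `ns` fast-time samples, maximum range
`Rmax = (Δr/2)·ns`.  The default profile (1 Tx / 3 Rx, 2 chirps per frame,
`ns = 200`, `f0 = 60` GHz, `Fs = 2` MHz, 20 frames/s, `tc = 150` µs,
`Bw = 4` GHz, `c = 3·10⁸` m/s) yields `Δr = 3.75` cm and `Rmax = 3.75` m.
Because the ADC observes only `ns/Fs = 100` µs of the 150 µs sweep, the FFT
grid is coarser than `Δr`: one bin spans `c·Fs·tc/(2·Bw·ns) = 5.625` cm.
Chest breathing (millimetres) is far below either figure and lives entirely
in the slow-time phase of the subject's bin, `φ = 4πR/λ` with `λ = 5` mm.

## Synthetic scenes

The generator emulates a desk-workplace recording campaign: 24 users ×
20 × 30 s sessions, half of each user's sessions at chest-to-board
distances ≤ 30 cm and half ≤ 40 cm.  Defaults define the study conditions:

| parameter | default | rationale |
|---|---|---|
| `fc_true` | U[0.12, 0.48] Hz | physiological band, centred near the 7–9 breaths / 30 s norm |
| `breath_amp` | log-U[1, 8] mm | chest-wall displacement range reported for seated adults |
| `duty_asymmetry` | U[0.35, 0.5] | inhale shorter than exhale; 0.5 = sinusoid |
| `base_range` | U[0.2, 0.4] m | the two distance classes |
| `motion_rate` | U[3, 6] gestures/session | desk users type, laugh and gesture; real at-desk cohorts are heavily motion-corrupted, and published corruption-weighted losses on such data imply mean corruption far above what sparse motion would produce |
| belt gain / noise / resolution | 1000 N/m, 0.05 N, 0.1 N | force-belt spec |
| ADC: target 100, clutter (60, 40, 25), DC 30, noise σ 5 | arbitrary counts | ≈26 dB single-chirp SNR before chirp/channel averaging |

Each chirp's IF signal carries the chest tone at beat frequency
`2·Bw·R/(c·tc)` with phase `4πR/λ`, static clutter tones (desk edge,
monitor, wall at 0.55/0.95/1.6 m), a DC offset and white noise.  A nominal
30 s session natively carries 660 frames at exact 1/20 s spacing (the
device streams ~10% past the stop), which keeps the 660-frame standard, the
20 Hz filter bank and the physics mutually consistent; the resampler is an
identity on defaults and interpolates/zero-pads off-nominal inputs.

**Desk gestures.**  A burst lasting 3–8+ s (typing spells up to 14 s) does
three things: the torso shifts by ~1 cm (sin² out-and-back bump plus a
small random walk, rate-capped below λ/4 per frame so the phase stays
unwrappable); a strong limb echo (3× the chest amplitude) appears near the
chest range and captures the processing window, its micro-motion (~0.3 mm
per frame tremor) lying far above the respiration band; and the chest echo
is occluded.  After band-pass filtering the burst interior is near-silent —
precisely the low-local-power signature the autocorrelation corruption
detector flags.  This model was chosen over naive large additive random
walks, which the detector provably cannot see: the detection window
(≈ 0.75·W ≈ 4–6 s) exceeds short bursts, any in-band excursion *rings* the
Q = 2 band-pass rather than silencing it, and the λ/4 unwrap limit caps
in-band excursion amplitude.  Bursts shorter than the detection window
remain undetectable — a property of the published detector, not of the
generator.  The belt, strapped to the chest, sees breathing only.

What the generator does **not** emulate: heartbeat superposition, belt
motion artifacts, range-dependent gain, antenna patterns, multi-person
scenes, unwrap catastrophes from violent motion, or the long-tailed
artifact statistics of real cohorts (real corruption fractions run
substantially higher than the synthetic ones).  Passing tests therefore
demonstrate internal consistency of the method under controlled physics,
not field performance.

## Phase extraction

Steps: resample to 660 frames → per-channel scalar DC removal → average
over chirps and Rx channels → fast-time FFT (no window; a Hann taper was
considered and rejected as an unforced deviation) → one-sided spectrum.
The subject bin is `argmax_s |SR(m, s)|` above a near-DC guard (2 bins);
its 8-frame trailing moving average centres a 12-bin window (−6…+5, edges
shift the window rather than shrink it).  MTI clutter `S̄ ← 0.4·SR + 0.6·S̄`
is updated only on window bins (zero-initialized; a static bin's residual
decays below 1% in 10 frames).  The selected bin maximizes
`|SR − S̄_new|²` — on a single complex sample, "MSE to clutter" collapses to
the squared modulus of the deviation.  Ties break to the lower index
throughout; moving-average warm-up uses the available history.

**Phase on the raw bin value.**  The phase is taken on the raw complex
value of the selected bin, not the clutter-subtracted one.  With α = 0.4
at 20 fps the MTI tracks the slow chest phasor almost completely, so the
residual `SR − S̄` is differentiator-like and its angle carries a ±π/2
distortion synchronized with breathing velocity: measured displacement
error 27–35% RMSE of the amplitude, versus <2% for the raw phase.  Clutter
still drives bin *selection*; clutter-subtracted phase is available via a
flag.  Static-clutter leakage into the chest bin perturbs the raw phase by
<0.05 rad under default conditions.

Unwrapping is the classic discontinuity-threshold rule (suffix ±2π
wherever a step exceeds π).  Normalization is per-session min–max to
[0, 1]; a mean-recentring variant sits behind a flag; constant traces map
to 0.5.

## Respiration band and Fc labels

The band-pass is the constant-0 dB-peak-gain biquad: with `w0 = 2πfc/fs`
and `aq = sin(w0)/(2Q)`, feed-forward `(aq, 0, −aq)/(1+aq)` and feedback
`(−2cos w0, 1−aq)/(1+aq)`, run twice in series with zero initial state
(`Q = 2`, `fs = 20` Hz).  It is the standard audio-cookbook design, adopted
as the package's band-pass and validated against the published
configuration (unit gain at Fc, zeros at DC and Nyquist, poles strictly
inside the unit circle for every Fc on the 0.01 Hz band grid).

The training label is the dominant peak of the mean-removed belt
periodogram (4× zero-padding for grid refinement, no taper) restricted to
[0.1, 0.5] Hz.  The alternative label maximizes |Pearson r| between the
band-passed phase and the belt over a 0.01 Hz grid — the absolute value
because the phase's sign convention (range shrinks on inhale) may invert
it relative to belt force.  Both agree to ≤ 0.02 Hz on clean scenes; the
spectrum label is the default supervision.

## Breathing metrics and corruption

Peaks: local maxima ≥ 1 s apart (half the fastest breath period) with
prominence ≥ 10% of the signal range.  `W = round(2 × mean inter-peak
distance)` (≈ two breath cycles; fallback `2·fs/0.3` when fewer than two
peaks, logged).  Instantaneous bpm at window start `t` is the peak count in
`[t, t+W)` rescaled by `60·fs/W` — the rescaling makes the unit honest.
Corruption: windows of `round(0.75·W)` samples are mean-centred; the raw
(unnormalized) autocorrelation over lags ≥ 1 is maximized; a flag fires
when that maximum falls below `0.001·W`.  The absolute threshold is only
meaningful for signals normalized to [0, 1], which the implementation
re-establishes on the filtered signal before scanning.  `γ` = flag mean,
`τ = 1 − γ`.  Radar and belt each get their own window from their own
peaks.  The threshold constant is exposed in configuration; like any
absolute threshold it is calibrated to a data regime, and the per-epoch
batch renormalization of τ is implemented behind a flag (default off, both
readings documented in the code).

## The autoencoder

Encoder: two 1-D convolution blocks (kernel 5, stride 2, ReLU; 32 then 64
filters at full size), flatten, dense heads for μ and log-variance
(clamped to ±10; σ = exp(½·logvar)).  Decoder: dense projection, reshape,
two up-sample-by-2 + convolution blocks mirroring the encoder, sigmoid
output of length 660.  The Fc head is a single linear neuron on `z` (on μ
behind a flag).  Parameter count is affine in the latent dimension by
construction — the only structural constraint the published topology's
count table pins down, since the exact filter sizes are not recoverable.
The BCE is **summed** over the 660 samples (so K = 1000 equalizes the Fc
term against it) and always uses the reconstruction as prediction and the
belt as target; predictions are clamped to [1e−7, 1−1e−7] inside the logs;
the sigmoid pre-activation is clamped to ±30.  Because the belt target is
soft, the BCE has an irreducible entropy floor (~290 nats for a typical
session): training quality is judged by the loss *above* that floor.

## Episodic training

Defaults follow the published protocol: 3000 episodes × 4 inner epochs,
inner rate 1.8e−3 (1-shot) / 8e−4 (5/10-shot), outer Adam(β₁ = 0,
β₂ = 0.5) at 1.7e−3, evaluation every 300 episodes on two training tasks
and one test task with 10 query examples each (adapt-on-k, query-on-10;
the meta-parameters are restored after every evaluation).  Query size per
episode defaults to the shot count; the 5-shot "batch 5" is read as
episodes per outer update.  Reptile uses inner rate 3e−5, meta-step 0.4,
two episodes per update; the stabilized MAML variant anneals multi-step
loss weights from uniform to final-step-only, switches first→second order
at 30% of episodes, and cosine-anneals its outer rate from 1.7e−5 to 1%.

Two numerical guards make the inner loop well-posed at these rates, both
constant linear operations that second-order meta-gradients differentiate
through exactly and both inactive on small well-scaled problems:

* **Per-layer preconditioning.**  Inner gradients are scaled by 1/fan-in
  per weight matrix.  Without it the wide flatten-to-dense layers (fan-in
  ≈ 2600 at reduced size, ~7000 at full size) receive an effective
  per-output step of `lr·Σ(activations²)` — several times the
  oscillation-critical size — and every inner loop diverges.
* **Trust region.**  Each inner epoch's step is capped at Euclidean norm
  0.02, turning super-critical epochs (e.g. the K = 1000 Fc term at high
  γ) into normalized descent.

Adaptation to a new user is exactly the inner procedure, first-order, from
an untouched checkpoint; zero supports are a documented no-op.

## The scaled validation study

The self-validation experiment runs the full protocol at reduced size:
6 training + 3 test users × 8 sessions, 60 episodes of second-order MAML,
latent 8 with 8/16-filter convolutions, evaluation every 5 episodes — and,
like the full protocol, is repeated three times with derived seeds and
pooled.  Two design choices control the variance of a necessarily short
run: evaluation is *paired* (one fixed eval episode set reused at every
eval point, so the learning curve measures learning rather than episode
resampling), and the fixed test-task episode is drawn to contain
corruption-bearing queries and chosen as the hardest of six candidates at
initialization — an episode already at its loss floor cannot exhibit
progress.  The one-shot adaptation trials condition on corruption-bearing
supports (with γ = 0 the Fc branch of L* is inactive by construction) and
score the mean |ŷ − Fc| over three held-out sessions before and after
adaptation.  Even pooled, these statistics are noisy at 60 episodes; the
study reports them honestly rather than tightening the conditions.

## Known limitations

* The corruption detector is blind to artifacts shorter than its own
  window and to artifacts that raise rather than lower local band power;
  flags mark low-information spans, not motion per se.
* Phase extraction assumes a single dominant subject; a second person or a
  persistent strong mover would capture the tracked window.
* The meta-learning results at 60 episodes demonstrate the machinery, not
  converged performance; full-scale runs (3000 episodes, latent 32) are
  configuration changes away but take correspondingly longer.
* Real-data corruption statistics, belt artifacts and unwrap catastrophes
  are outside the generator's envelope; field performance claims require
  field data.
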