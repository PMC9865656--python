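"""Episodic meta-learning for few-shot user adaptation.

Each episode samples one training user (a task), adapts the autoencoder to
that user with a few gradient-descent epochs on ``k`` support sessions
(inner step), and updates the shared initialization from the post-adaptation
loss on held-out query sessions of the same user (outer step).  Algorithms:

* MAML 2nd — the outer gradient is taken through the inner trajectory
  (second-order, via autograd's grad-of-grad);
* MAML 1st — gradients stop at the adapted parameters;
* Reptile  — the initialization moves a meta-step fraction toward the
  adapted parameters, no query set;
* MAML+    — MAML stabilized with multi-step loss (MSL), derivative-order
  annealing (DA) and cosine-annealed outer learning rate (CA).

The outer optimizer is Adam with the unconventional (beta1, beta2) = (0, 0.5)
used in this training protocol.  Adapting to a *new* user after meta-training
always uses plain first-order descent for four epochs, leaving the trained
initialization untouched.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import autograd.numpy as anp
import numpy as np
from autograd import grad

from radarbreath.cvae import Cvae, CvaeArchitecture
from radarbreath.workbench import EvalRecord

log = logging.getLogger(__name__)


class EpisodeAbortError(RuntimeError):
    """Raised when an episode produces a non-finite loss."""


class InsufficientSessionsError(ValueError):
    pass


@dataclass(frozen=True)
class MetaConfig:
    """Episodic training protocol parameters.

    Learning rates and optimizer betas follow the radar breath-sensing
    protocol: 3000 episodes at 4 epochs per episode, inner rate 1.8e-3 for
    1-shot (8e-4 for 5/10-shot), outer rate 1.7e-3, Adam(0, 0.5), evaluation
    every 300 episodes on two training tasks and one test task with 10 query
    examples each.
    """

    algorithm: str = "maml2"            # maml2 | maml1 | reptile | mamlplus
    episodes: int = 3000
    epochs_per_episode: int = 4
    shots: int = 1
    query_size: Optional[int] = None    # defaults to shots
    batch_size: Optional[int] = None    # episodes per outer update; 1 for 1-shot else 5
    inner_lr: Optional[float] = None    # 1.8e-3 for 1-shot, 8e-4 otherwise
    outer_lr: float = 1.7e-3
    adam_beta1: float = 0.0
    adam_beta2: float = 0.5
    adam_eps: float = 1e-8
    eval_every: int = 300
    eval_examples: int = 10
    reptile_meta_step: float = 0.4
    reptile_inner_lr: float = 3e-5
    reptile_batch: int = 2
    mamlplus_outer_lr0: float = 1.7e-5
    mamlplus_da_fraction: float = 0.3   # first-order until this episode fraction
    mamlplus_lr_floor_ratio: float = 0.01
    normalize_tau: bool = False         # per-batch tau renormalization (off by default)
    inner_trust_radius: float = 0.02    # inner-loop per-epoch step-norm cap
    paired_eval: bool = False           # reuse one fixed eval episode set at every
                                        # eval point (variance-controlled learning curve)

    def __post_init__(self) -> None:
        if self.shots not in (1, 5, 10):
            raise ValueError(f"shots must be 1, 5 or 10, got {self.shots}")
        if self.episodes > 0 and self.eval_every > 0 and self.episodes % self.eval_every:
            raise ValueError("eval_every must divide episodes")

    @property
    def effective_inner_lr(self) -> float:
        if self.inner_lr is not None:
            return self.inner_lr
        return 1.8e-3 if self.shots == 1 else 8e-4

    @property
    def effective_batch_size(self) -> int:
        if self.batch_size is not None:
            return self.batch_size
        return 1 if self.shots == 1 else 5

    @property
    def effective_query_size(self) -> int:
        return self.shots if self.query_size is None else self.query_size


@dataclass
class Sample:
    """One prepared training example: phase in, belt + Fc + corruption out."""

    x: np.ndarray        # normalized unwrapped radar phase, [0, 1]
    x_belt: np.ndarray   # normalized belt trace, [0, 1]
    y: float             # reference Fc, Hz
    tau: float
    gamma: float
    fc_true: Optional[float] = None
    peak_count: Optional[int] = None


@dataclass
class TaskData:
    """All prepared sessions of one user."""

    user_id: str
    samples: List[Sample]


@dataclass
class EpisodeBatch:
    """Support/query split of one task plus fixed latent draws per sample."""

    task_user: str
    support: List[Sample]
    query: List[Sample]
    support_etas: np.ndarray   # (len(support), latent_dim)
    query_etas: np.ndarray     # (len(query), latent_dim)


def session_to_sample(record, cfg=None) -> Sample:
    """Preprocess one session into a training sample.

    Runs the phase pipeline, normalizes the belt, labels Fc from the belt
    spectrum, and scores motion corruption on the phase band-passed at the
    reference Fc.
    """
    from radarbreath.breath_band import belt_fc_reference
    from radarbreath.breath_metrics import compute_breath_metrics
    from radarbreath.radar_model import RadarConfig
    from radarbreath.range_phase import extract_phase_trace, normalize_trace, resample_session

    cfg = cfg if cfg is not None else RadarConfig()
    record = resample_session(record)
    trace = extract_phase_trace(record, cfg)
    belt_norm = normalize_trace(record.belt)
    label = belt_fc_reference(record.belt, fs=record.frame_rate)
    metrics = compute_breath_metrics(trace.x, fs=trace.fs, fc=label.fc)
    return Sample(
        x=trace.x,
        x_belt=belt_norm,
        y=label.fc,
        tau=metrics.tau,
        gamma=metrics.corruption_fraction,
        fc_true=record.fc_true,
        peak_count=int(len(metrics.peaks)),
    )


def prepare_tasks(manifest, split: str, cfg=None) -> List[TaskData]:
    """Load and preprocess every session of a manifest split, grouped by user."""
    from radarbreath.workbench import read_session

    tasks: Dict[str, List[Sample]] = {}
    sub = manifest[manifest["split"] == split]
    for _, row in sub.iterrows():
        rec = read_session(row["session_path"])
        tasks.setdefault(row["user_id"], []).append(session_to_sample(rec, cfg))
    return [TaskData(user_id=u, samples=s) for u, s in sorted(tasks.items())]


def sample_episode(
    tasks: Sequence[TaskData],
    shots: int,
    rng: np.random.Generator,
    query_size: Optional[int] = None,
    latent_dim: int = 32,
) -> EpisodeBatch:
    """Uniform task choice; disjoint support/query sessions from that user."""
    query_size = query_size if query_size is not None else shots
    task = tasks[int(rng.integers(len(tasks)))]
    n = len(task.samples)
    if n < shots + 1:
        raise InsufficientSessionsError(
            f"user {task.user_id} has {n} sessions; needs > {shots} for a query set"
        )
    q = min(query_size, n - shots)
    order = rng.permutation(n)
    support = [task.samples[i] for i in order[:shots]]
    query = [task.samples[i] for i in order[shots : shots + q]]
    return EpisodeBatch(
        task_user=task.user_id,
        support=support,
        query=query,
        support_etas=rng.standard_normal((shots, latent_dim)),
        query_etas=rng.standard_normal((q, latent_dim)),
    )


def _batch_weights(samples: Sequence[Sample], normalize_tau: bool) -> List[Tuple[float, float]]:
    taus = np.array([s.tau for s in samples])
    if normalize_tau and taus.mean() > 0:
        taus = np.clip(taus / taus.mean(), 0.0, 1.0)
    return [(float(t), float(1.0 - t)) for t in taus]


def batch_loss(model: Cvae, theta, samples: Sequence[Sample], etas,
               normalize_tau: bool = False):
    """Mean corruption-weighted loss L* over a sample batch (autograd-safe)."""
    weights = _batch_weights(samples, normalize_tau)
    total = 0.0
    for s, eta, (tau, gamma) in zip(samples, etas, weights):
        total = total + model.elbo_loss(theta, s.x, s.x_belt, s.y, tau, gamma, eta)
    return total / len(samples)


INNER_TRUST_RADIUS = 0.02
"""Inner-loop trust region: per-epoch parameter step is capped at this
Euclidean norm.  The summed losses put parts of the landscape (the K = 1000
Fc term, the wide flatten-to-dense layers) far past the oscillation-critical
step size at the episodic learning rates; capping the step norm turns those
epochs into normalized descent while leaving small-gradient regions exact
plain GD."""


def inner_adapt(
    model: Cvae,
    theta,
    support: Sequence[Sample],
    inner_lr: float,
    epochs: int,
    etas=None,
    normalize_tau: bool = False,
    return_trajectory: bool = False,
    trust_radius: float = INNER_TRUST_RADIUS,
    precondition: bool = True,
):
    """``epochs`` full-batch gradient-descent steps on the mean support L*.

    Pure in ``theta`` and built from autograd ops, so calling it inside an
    outer ``grad`` retains the computation graph through every inner step
    (second-order meta-gradients); calling it normally just runs the
    arithmetic.  Gradients are norm-clipped at ``grad_clip`` — a stability
    guard against rare exploding inner steps that stays inactive at the
    gradient scales of healthy sessions.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if etas is None:
        etas = np.zeros((len(support), model.arch.latent_dim))
    g_fn = grad(lambda th: batch_loss(model, th, support, etas, normalize_tau))
    scale = model.grad_scale() if precondition and hasattr(model, "grad_scale") else None
    trajectory = []
    for _ in range(epochs):
        g = g_fn(theta)
        if scale is not None:
            g = g * scale
        step = inner_lr * g
        if trust_radius is not None:
            norm = anp.sqrt(anp.sum(step * step) + 1e-60)
            step = step * anp.minimum(1.0, trust_radius / norm)
        theta = theta - step
        trajectory.append(theta)
    return trajectory if return_trajectory else theta


@dataclass
class AdamState:
    """Adam moment estimates for the outer step."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0

    @classmethod
    def zeros(cls, n: int) -> "AdamState":
        return cls(m=np.zeros(n), v=np.zeros(n))


def adam_update(state: AdamState, theta: np.ndarray, g: np.ndarray,
                lr: float, beta1: float, beta2: float, eps: float = 1e-8):
    state.t += 1
    state.m = beta1 * state.m + (1.0 - beta1) * g
    state.v = beta2 * state.v + (1.0 - beta2) * g * g
    m_hat = state.m / (1.0 - beta1 ** state.t)
    v_hat = state.v / (1.0 - beta2 ** state.t)
    return theta - lr * m_hat / (np.sqrt(v_hat) + eps)


def maml_meta_gradient(model: Cvae, theta, episode: EpisodeBatch, cfg: MetaConfig,
                       order: int = 2) -> np.ndarray:
    """Meta-gradient of the post-adaptation query loss w.r.t. ``theta``.

    order=2 differentiates through the inner trajectory; order=1 evaluates the
    query gradient at the adapted parameters (gradient stopped).
    """
    if order == 2:
        def meta_loss(th):
            adapted = inner_adapt(model, th, episode.support, cfg.effective_inner_lr,
                                  cfg.epochs_per_episode, episode.support_etas,
                                  cfg.normalize_tau, trust_radius=cfg.inner_trust_radius)
            return batch_loss(model, adapted, episode.query, episode.query_etas,
                              cfg.normalize_tau)

        g = grad(meta_loss)(theta)
    else:
        adapted = inner_adapt(model, theta, episode.support, cfg.effective_inner_lr,
                              cfg.epochs_per_episode, episode.support_etas,
                              cfg.normalize_tau, trust_radius=cfg.inner_trust_radius)
        g = grad(lambda th: batch_loss(model, th, episode.query, episode.query_etas,
                                       cfg.normalize_tau))(adapted)
    if not np.all(np.isfinite(g)):
        raise EpisodeAbortError(f"non-finite meta-gradient on task {episode.task_user}")
    return g


def meta_step_maml(model: Cvae, theta, opt: AdamState, episodes: Sequence[EpisodeBatch],
                   cfg: MetaConfig, order: int = 2, lr: Optional[float] = None):
    """One outer Adam step from the mean meta-gradient of an episode batch."""
    g = np.mean([maml_meta_gradient(model, theta, ep, cfg, order) for ep in episodes], axis=0)
    return adam_update(opt, theta, g, lr if lr is not None else cfg.outer_lr,
                       cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps)


def meta_step_reptile(model: Cvae, theta, episodes: Sequence[EpisodeBatch], cfg: MetaConfig):
    """theta <- theta + meta_step * mean(adapted - theta)."""
    deltas = []
    for ep in episodes:
        adapted = inner_adapt(model, theta, ep.support, cfg.reptile_inner_lr,
                              cfg.epochs_per_episode, ep.support_etas, cfg.normalize_tau,
                              trust_radius=cfg.inner_trust_radius)
        if not np.all(np.isfinite(adapted)):
            raise EpisodeAbortError(f"non-finite adapted parameters on task {ep.task_user}")
        deltas.append(adapted - theta)
    return theta + cfg.reptile_meta_step * np.mean(deltas, axis=0)


def msl_weights(episode_index: int, total_episodes: int, n_steps: int) -> np.ndarray:
    """Multi-step-loss weights annealed from uniform toward final-step-only."""
    p = episode_index / max(1, total_episodes - 1) if total_episodes > 1 else 1.0
    uniform = np.full(n_steps, 1.0 / n_steps)
    onehot = np.zeros(n_steps)
    onehot[-1] = 1.0
    return (1.0 - p) * uniform + p * onehot


def cosine_lr(episode_index: int, total_episodes: int, lr0: float,
              floor_ratio: float = 0.01) -> float:
    """Cosine decay from ``lr0`` at episode 0 to ``lr0*floor_ratio`` at the end."""
    floor = lr0 * floor_ratio
    if total_episodes <= 1:
        return floor
    c = 0.5 * (1.0 + math.cos(math.pi * episode_index / (total_episodes - 1)))
    return floor + (lr0 - floor) * c


def meta_step_mamlplus(model: Cvae, theta, opt: AdamState, episodes: Sequence[EpisodeBatch],
                       cfg: MetaConfig, episode_index: int):
    """MAML+ outer step: MSL over per-epoch query losses, DA order switch,
    cosine-annealed outer learning rate."""
    order = 1 if episode_index < cfg.mamlplus_da_fraction * cfg.episodes else 2
    weights = msl_weights(episode_index, cfg.episodes, cfg.epochs_per_episode)
    lr = cosine_lr(episode_index, cfg.episodes, cfg.mamlplus_outer_lr0,
                   cfg.mamlplus_lr_floor_ratio)

    def msl_loss(th, ep: EpisodeBatch):
        traj = inner_adapt(model, th, ep.support, cfg.effective_inner_lr,
                           cfg.epochs_per_episode, ep.support_etas, cfg.normalize_tau,
                           return_trajectory=True, trust_radius=cfg.inner_trust_radius)
        total = 0.0
        for w, th_i in zip(weights, traj):
            total = total + w * batch_loss(model, th_i, ep.query, ep.query_etas,
                                           cfg.normalize_tau)
        return total

    grads = []
    for ep in episodes:
        if order == 2:
            g = grad(lambda th: msl_loss(th, ep))(theta)
        else:
            # first-order: weight the query gradients evaluated at each
            # adapted point, gradients stopped at the trajectory
            traj = inner_adapt(model, theta, ep.support, cfg.effective_inner_lr,
                               cfg.epochs_per_episode, ep.support_etas, cfg.normalize_tau,
                               return_trajectory=True, trust_radius=cfg.inner_trust_radius)
            g = sum(
                w * grad(lambda th: batch_loss(model, th, ep.query, ep.query_etas,
                                               cfg.normalize_tau))(th_i)
                for w, th_i in zip(weights, traj)
            )
        if not np.all(np.isfinite(g)):
            raise EpisodeAbortError(f"non-finite meta-gradient on task {ep.task_user}")
        grads.append(g)
    return adam_update(opt, theta, np.mean(grads, axis=0), lr,
                       cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps)


def adapt_to_user(model: Cvae, theta, support: Sequence[Sample], cfg: MetaConfig,
                  etas=None):
    """Few-shot adaptation to a new user: 4 epochs of first-order descent on
    the supports' L*.  Returns new parameters; the checkpoint is untouched.
    An empty support returns the checkpoint unchanged."""
    if len(support) == 0:
        return np.array(theta, copy=True)
    return inner_adapt(model, np.array(theta, copy=True), support,
                       cfg.effective_inner_lr, cfg.epochs_per_episode, etas,
                       cfg.normalize_tau, trust_radius=cfg.inner_trust_radius)


class MetaTrainer:
    """Runs the full episodic protocol and the periodic evaluation loop."""

    def __init__(self, model: Cvae, cfg: MetaConfig = MetaConfig(), seed: int = 0):
        self.model = model
        self.cfg = cfg
        self.seed = seed

    def _evaluate(self, theta, tasks: Sequence[TaskData], split: str,
                  episode_index: int, rng: np.random.Generator,
                  episode: Optional[EpisodeBatch] = None) -> EvalRecord:
        """Adapt on k shots of a task, score L* on held-out query examples."""
        cfg = self.cfg
        ep = episode if episode is not None else sample_episode(
            tasks, cfg.shots, rng, query_size=cfg.eval_examples,
            latent_dim=self.model.arch.latent_dim)
        adapted = adapt_to_user(self.model, theta, ep.support, cfg, ep.support_etas)
        losses = [
            float(self.model.elbo_loss(adapted, s.x, s.x_belt, s.y, s.tau, s.gamma, eta))
            for s, eta in zip(ep.query, ep.query_etas)
        ]
        return EvalRecord(episode_index=episode_index, split=split,
                          losses=np.asarray(losses))

    def train(self, train_tasks: Sequence[TaskData], test_tasks: Sequence[TaskData]):
        """Run ``episodes`` episodes; returns (theta, eval history).

        Every ``eval_every`` episodes the model is evaluated on two training
        tasks and one test task (adapt on k shots, query ``eval_examples``);
        evaluation adapts a copy, so the meta-parameters are never mutated.
        """
        cfg = self.cfg
        if len(train_tasks) < 1 or (cfg.episodes > 0 and len(train_tasks) < 2):
            raise ValueError("need at least 2 training tasks")
        rng = np.random.default_rng(self.seed)
        theta = self.model.init_params(int(rng.integers(2**31)))
        opt = AdamState.zeros(self.model.n_params)
        history: List[EvalRecord] = []

        d = self.model.arch.latent_dim
        fixed_evals = None
        if cfg.paired_eval:
            # fixed eval episodes; the Tv episode is drawn to contain
            # corruption-bearing queries so the statistic tracks the
            # corruption-weighted objective rather than the BCE floor alone
            eval_rng = np.random.default_rng(self.seed + 1)
            tv_eval = []
            if test_tasks:
                candidates = []
                for _ in range(50):
                    ep = sample_episode(test_tasks, cfg.shots, eval_rng,
                                        cfg.eval_examples, d)
                    if ep.support[0].gamma > 0 and any(s.gamma > 0 for s in ep.query):
                        candidates.append(ep)
                    if len(candidates) == 6:
                        break
                if not candidates:
                    candidates = [sample_episode(test_tasks, cfg.shots, eval_rng,
                                                 cfg.eval_examples, d)]
                # keep the episode the initialization handles worst: a task
                # already at its loss floor cannot show meta-learning progress
                init_losses = [
                    self._evaluate(theta, test_tasks, "test_task", 0, eval_rng,
                                   episode=ep).mean
                    for ep in candidates
                ]
                tv_eval = [candidates[int(np.argmax(init_losses))]]
            fixed_evals = (
                [sample_episode(train_tasks, cfg.shots, eval_rng,
                                cfg.eval_examples, d) for _ in range(2)],
                tv_eval,
            )
        for e in range(cfg.episodes):
            n_ep = cfg.reptile_batch if cfg.algorithm == "reptile" else cfg.effective_batch_size
            batch = [
                sample_episode(train_tasks, cfg.shots, rng,
                               cfg.effective_query_size, d)
                for _ in range(n_ep)
            ]
            if cfg.algorithm == "maml2":
                theta = meta_step_maml(self.model, theta, opt, batch, cfg, order=2)
            elif cfg.algorithm == "maml1":
                theta = meta_step_maml(self.model, theta, opt, batch, cfg, order=1)
            elif cfg.algorithm == "reptile":
                theta = meta_step_reptile(self.model, theta, batch, cfg)
            elif cfg.algorithm == "mamlplus":
                theta = meta_step_mamlplus(self.model, theta, opt, batch, cfg, e)
            else:
                raise ValueError(f"unknown algorithm {cfg.algorithm!r}")

            if cfg.eval_every > 0 and (e + 1) % cfg.eval_every == 0:
                for i in range(2):
                    history.append(self._evaluate(
                        theta, train_tasks, "train_task", e + 1, rng,
                        episode=fixed_evals[0][i] if fixed_evals else None))
                if test_tasks:
                    history.append(self._evaluate(
                        theta, test_tasks, "test_task", e + 1, rng,
                        episode=fixed_evals[1][0] if fixed_evals else None))
                log.info("episode %d: last test-task mean L* = %.2f", e + 1,
                         history[-1].mean)
        return theta, history
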