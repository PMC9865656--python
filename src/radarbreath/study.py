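"""Reproducible study protocols: parameter recovery, corruption response,
and the scaled-down episodic-learning experiment.

These are the experiments the package runs to validate itself end to end on
synthetic scenes.  The episodic study follows the full protocol at reduced
size — 6 training + 3 test users with 8 sessions each, 60 episodes,
latent dimension 8 with 8/16-filter convolutions — and, mirroring the full
protocol's practice, is repeated three times with derived seeds and pooled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from radarbreath.breath_band import belt_fc_reference
from radarbreath.cvae import Cvae, CvaeArchitecture
from radarbreath.episodic import (
    MetaConfig,
    MetaTrainer,
    TaskData,
    adapt_to_user,
    sample_episode,
    session_to_sample,
)
from radarbreath.radar_model import RadarConfig
from radarbreath.range_phase import extract_phase_trace
from radarbreath.synthetic_scene import NoiseSpec, make_user, simulate_session


def radar_fc_estimate(record, cfg: RadarConfig = RadarConfig()) -> float:
    """Radar-only Fc estimate: in-band spectral peak of the phase trace."""
    trace = extract_phase_trace(record, cfg)
    return belt_fc_reference(trace.x, fs=trace.fs).fc


def fc_recovery_study(n_users: int = 20, seed: int = 0,
                      cfg: RadarConfig = RadarConfig()):
    """Idle-user parameter recovery: simulate n clean users, estimate Fc from
    the radar phase alone, compare against ground truth.

    Returns (per-user (fc_true, fc_est) pairs, max abs error Hz, Spearman
    rank correlation).
    """
    from scipy.stats import spearmanr

    ss = np.random.SeedSequence(seed).generate_state(n_users) % (2**31)
    pairs = []
    for s in ss:
        profile = make_user(int(s), overrides={"motion_rate": 0.0})
        rec = simulate_session(profile, cfg, seed=int(s),
                               noise=NoiseSpec(adc_noise_std=0.0, belt_noise_std=0.0))
        pairs.append((profile.fc_true, radar_fc_estimate(rec, cfg)))
    truths, ests = zip(*pairs)
    max_err = float(np.max(np.abs(np.array(ests) - np.array(truths))))
    rho = float(spearmanr(truths, ests).statistic)
    return pairs, max_err, rho


def corruption_response_study(
    intensities: Sequence[float] = (0.0, 0.5, 1.0),
    n_seeds: int = 12,
    seed: int = 0,
    cfg: RadarConfig = RadarConfig(),
) -> List[float]:
    """Mean corruption fraction per gesture intensity, paired across seeds."""
    ss = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    means = []
    for intensity in intensities:
        gammas = [
            session_to_sample(
                simulate_session(make_user(int(s)), cfg, seed=int(s),
                                 motion_intensity=float(intensity)),
                cfg,
            ).gamma
            for s in ss
        ]
        means.append(float(np.mean(gammas)))
    return means


@dataclass
class ScaledStudyResult:
    """One repetition of the scaled episodic experiment."""

    tv_means: List[float]        # test-task block means over eval points
    wins: int                    # Fc-improvement trial wins
    n_trials: int
    theta: np.ndarray
    model: Cvae
    cfg: MetaConfig


SCALED_ARCH = CvaeArchitecture(latent_dim=8, enc_filters=(8, 16))


def _make_tasks(user_seeds, radar_cfg, sessions_per_user):
    tasks = []
    for uid, s in enumerate(user_seeds):
        profile = make_user(int(s), overrides={"user_id": f"u{uid}"})
        samples = [
            session_to_sample(
                simulate_session(profile, radar_cfg, seed=int(s) + k), radar_cfg)
            for k in range(sessions_per_user)
        ]
        tasks.append(TaskData(user_id=f"u{uid}", samples=samples))
    return tasks


def scaled_meta_study(
    master_seed: int,
    n_train_users: int = 6,
    n_test_users: int = 3,
    sessions_per_user: int = 8,
    episodes: int = 60,
    algorithm: str = "maml2",
    n_trials: int = 20,
    radar_cfg: RadarConfig = RadarConfig(),
) -> ScaledStudyResult:
    """One repetition of the scaled-down episodic experiment.

    Meta-trains on synthetic desk users, records the paired test-task
    learning curve, then runs 1-shot adaptation trials on the test users.
    Each trial adapts on one corruption-bearing support session (the Fc
    branch of the weighted loss is inactive on perfectly clean sessions) and
    scores the mean |y_hat - fc_true| over three held-out query sessions
    before and after adaptation.
    """
    ss = np.random.SeedSequence(master_seed).generate_state(20) % (2**31)
    train_tasks = _make_tasks(ss[:n_train_users], radar_cfg, sessions_per_user)
    test_tasks = _make_tasks(ss[10:10 + n_test_users], radar_cfg, sessions_per_user)

    model = Cvae(SCALED_ARCH)
    cfg = MetaConfig(algorithm=algorithm, episodes=episodes, eval_every=5,
                     eval_examples=10, shots=1, paired_eval=True)
    theta, history = MetaTrainer(model, cfg, seed=int(ss[15])).train(
        train_tasks, test_tasks)
    tv_means = [h.mean for h in history if h.split == "test_task"]

    rng = np.random.default_rng(int(ss[16]))
    d = model.arch.latent_dim
    wins = done = tries = 0
    while done < n_trials and tries < 50 * n_trials:
        tries += 1
        ep = sample_episode(test_tasks, 1, rng, query_size=3, latent_dim=d)
        if ep.support[0].gamma <= 0:
            continue
        adapted = adapt_to_user(model, theta, ep.support, cfg, ep.support_etas)
        eta0 = np.zeros(d)
        pre = np.mean([abs(model.forward(theta, s.x, eta0).y_hat - s.fc_true)
                       for s in ep.query])
        post = np.mean([abs(model.forward(adapted, s.x, eta0).y_hat - s.fc_true)
                        for s in ep.query])
        done += 1
        wins += post < pre
    return ScaledStudyResult(tv_means=tv_means, wins=wins, n_trials=done,
                             theta=theta, model=model, cfg=cfg)


def pooled_meta_study(seed: int, repetitions: int = 3) -> dict:
    """Three-repetition scaled episodic study with pooled statistics.

    Returns first/last pooled test-task block means and the pooled 1-shot
    Fc-improvement rate.
    """
    reps = [scaled_meta_study(seed + r) for r in range(repetitions)]
    first = float(np.mean([r.tv_means[0] for r in reps]))
    last = float(np.mean([r.tv_means[-1] for r in reps]))
    wins = sum(r.wins for r in reps)
    trials = sum(r.n_trials for r in reps)
    return {
        "first_block_mean": first,
        "last_block_mean": last,
        "wins": wins,
        "n_trials": trials,
        "repetitions": reps,
    }
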