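import numpy as np
import pytest
from autograd import grad
import autograd.numpy as anp

from radarbreath.cvae import Cvae, CvaeArchitecture
from radarbreath.episodic import (
    AdamState,
    EpisodeBatch,
    InsufficientSessionsError,
    MetaConfig,
    MetaTrainer,
    Sample,
    TaskData,
    adam_update,
    adapt_to_user,
    cosine_lr,
    inner_adapt,
    maml_meta_gradient,
    meta_step_reptile,
    msl_weights,
    sample_episode,
)


class ToyModel:
    """Scalar-parameter stand-in exposing the loss interface the episodic
    machinery needs; loss = 0.5 * a * (theta - b)^2 summed over params."""

    class arch:
        latent_dim = 2

    def __init__(self, a=3.0, b=1.0):
        self.a, self.b = a, b

    def elbo_loss(self, theta, x, x_belt, y, tau=1.0, gamma=0.0, eta=None):
        return anp.sum(0.5 * self.a * (theta - self.b) ** 2)


def _toy_sample():
    return Sample(x=np.zeros(1), x_belt=np.zeros(1), y=0.3, tau=1.0, gamma=0.0)


def _tasks(n_users=3, n_sessions=6, seed=0):
    rng = np.random.default_rng(seed)
    tasks = []
    for u in range(n_users):
        samples = [
            Sample(x=rng.uniform(0, 1, 660), x_belt=rng.uniform(0, 1, 660),
                   y=0.2 + 0.05 * u, tau=1.0, gamma=0.0, fc_true=0.2 + 0.05 * u)
            for _ in range(n_sessions)
        ]
        tasks.append(TaskData(user_id=f"u{u}", samples=samples))
    return tasks


class TestSampleEpisode:
    def test_support_exhausting_sessions_rejected(self):
        tasks = _tasks(n_users=1, n_sessions=5)
        with pytest.raises(InsufficientSessionsError):
            sample_episode(tasks, shots=5, rng=np.random.default_rng(0))

    def test_fixed_rng_reproducible(self):
        tasks = _tasks()
        e1 = sample_episode(tasks, 1, np.random.default_rng(5))
        e2 = sample_episode(tasks, 1, np.random.default_rng(5))
        assert e1.task_user == e2.task_user
        assert np.array_equal(e1.support_etas, e2.support_etas)

    def test_support_and_query_disjoint(self):
        tasks = _tasks(n_users=1)
        rng = np.random.default_rng(1)
        for _ in range(20):
            ep = sample_episode(tasks, 2, rng, query_size=2)
            sup = {id(s) for s in ep.support}
            qry = {id(s) for s in ep.query}
            assert not sup & qry

    def test_users_sampled_uniformly(self):
        tasks = _tasks(n_users=4)
        rng = np.random.default_rng(2)
        counts = {t.user_id: 0 for t in tasks}
        n = 10_000
        for _ in range(n):
            counts[sample_episode(tasks, 1, rng).task_user] += 1
        p = 1 / 4
        sigma = np.sqrt(n * p * (1 - p))
        for c in counts.values():
            assert abs(c - n * p) < 3 * sigma


class TestInnerAdapt:
    def test_zero_learning_rate_is_identity(self):
        model = ToyModel()
        theta = np.array([0.0, 2.0])
        out = inner_adapt(model, theta, [_toy_sample()], 0.0, epochs=3)
        assert np.array_equal(out, theta)

    def test_quadratic_single_step_closed_form(self):
        a, b, lr = 3.0, 1.0, 0.01
        model = ToyModel(a=a, b=b)
        theta = np.array([0.0, 2.0])
        out = inner_adapt(model, theta, [_toy_sample()], lr, epochs=1,
                          trust_radius=None)
        assert np.allclose(out, theta + lr * a * (b - theta), atol=1e-12)

    def test_stationary_point_unchanged(self):
        model = ToyModel(b=0.5)
        theta = np.full(2, 0.5)
        out = inner_adapt(model, theta, [_toy_sample()], 0.1, epochs=4)
        assert np.allclose(out, theta, atol=1e-12)


class TestMamlGradients:
    def test_zero_inner_lr_collapses_both_orders_to_query_gradient(self):
        arch = CvaeArchitecture(latent_dim=8, enc_filters=(4, 8))
        model = Cvae(arch)
        theta = model.init_params(1)
        rng = np.random.default_rng(0)
        s = Sample(x=rng.uniform(0, 1, 660), x_belt=rng.uniform(0, 1, 660),
                   y=0.3, tau=0.8, gamma=0.2)
        ep = EpisodeBatch("u", [s], [s], np.zeros((1, 8)), np.zeros((1, 8)))
        cfg = MetaConfig(episodes=0, eval_every=0, inner_lr=0.0)
        g2 = maml_meta_gradient(model, theta, ep, cfg, order=2)
        g1 = maml_meta_gradient(model, theta, ep, cfg, order=1)
        plain = grad(lambda th: model.elbo_loss(th, s.x, s.x_belt, s.y, 0.8, 0.2,
                                                np.zeros(8)))(theta)
        assert np.allclose(g1, plain, atol=1e-10)
        assert np.allclose(g2, plain, atol=1e-10)

    def test_second_order_matches_finite_differences_on_toy_family(self):
        # 10-parameter nonlinear regression; meta-loss differentiated through
        # two plain inner GD steps and checked against central differences
        rng = np.random.default_rng(3)
        w_sup, w_qry = rng.normal(size=(2, 10))
        lr = 0.05

        def inner_loss(th):
            return anp.sum((anp.tanh(th) - w_sup) ** 2)

        def query_loss(th):
            return anp.sum((anp.tanh(th) - w_qry) ** 2)

        def meta_loss(th):
            for _ in range(2):
                th = th - lr * grad(inner_loss)(th)
            return query_loss(th)

        theta = rng.normal(size=10) * 0.5
        g = grad(meta_loss)(theta)
        eps = 1e-5
        fd = np.array([
            (meta_loss(theta + eps * e) - meta_loss(theta - eps * e)) / (2 * eps)
            for e in np.eye(10)
        ])
        assert np.linalg.norm(g - fd) / np.linalg.norm(fd) < 1e-3

    def test_meta_gradient_deterministic(self):
        arch = CvaeArchitecture(latent_dim=8, enc_filters=(4, 8))
        model = Cvae(arch)
        theta = model.init_params(2)
        rng = np.random.default_rng(1)
        s = Sample(x=rng.uniform(0, 1, 660), x_belt=rng.uniform(0, 1, 660),
                   y=0.25, tau=1.0, gamma=0.0)
        ep = EpisodeBatch("u", [s], [s], np.zeros((1, 8)), np.zeros((1, 8)))
        cfg = MetaConfig(episodes=0, eval_every=0)
        g1 = maml_meta_gradient(model, theta, ep, cfg, order=2)
        g2 = maml_meta_gradient(model, theta, ep, cfg, order=2)
        assert np.array_equal(g1, g2)


class TestReptile:
    def test_no_movement_when_adapted_equals_init(self):
        model = ToyModel(b=0.5)
        theta = np.full(2, 0.5)
        ep = EpisodeBatch("u", [_toy_sample()], [], np.zeros((1, 2)), np.zeros((0, 2)))
        cfg = MetaConfig(episodes=0, eval_every=0)
        assert np.allclose(meta_step_reptile(model, theta, [ep], cfg), theta)

    def test_meta_step_interpolates(self):
        # theta=0, adapted=1 under meta_step 0.4 lands at 0.4
        class Jump(ToyModel):
            def elbo_loss(self, th, *a, **k):
                # gradient -1/lr so a single step moves +1 exactly
                return anp.sum(-th / 3e-5)

        cfg = MetaConfig(episodes=0, eval_every=0, epochs_per_episode=1,
                         inner_trust_radius=None)
        ep = EpisodeBatch("u", [_toy_sample()], [], np.zeros((1, 2)), np.zeros((0, 2)))
        out = meta_step_reptile(Jump(), np.zeros(2), [ep], cfg)
        assert np.allclose(out, 0.4 * np.sqrt(2) / np.sqrt(2) * np.ones(2) * 1.0,
                           atol=1e-9)


class TestMamlPlus:
    def test_cosine_schedule_endpoints(self):
        lr0 = 1.7e-5
        assert cosine_lr(0, 100, lr0) == pytest.approx(lr0)
        assert cosine_lr(99, 100, lr0) == pytest.approx(lr0 * 0.01)

    def test_uniform_msl_weights_at_start(self):
        w = msl_weights(0, 100, 4)
        assert np.allclose(w, 0.25)
        w_end = msl_weights(99, 100, 4)
        assert np.allclose(w_end, [0, 0, 0, 1.0])


class TestAdam:
    def test_bias_corrected_first_step_is_lr_sized(self):
        state = AdamState.zeros(3)
        g = np.array([1.0, -2.0, 0.5])
        out = adam_update(state, np.zeros(3), g, lr=0.1, beta1=0.0, beta2=0.5)
        assert np.allclose(out, -0.1 * np.sign(g), atol=1e-6)


@pytest.fixture(scope="module")
def small_setup():
    model = Cvae(CvaeArchitecture(latent_dim=8, enc_filters=(4, 8)))
    return model, _tasks(n_users=3), _tasks(n_users=1, seed=9)


class TestTrainerContracts:

    def test_zero_episodes_returns_initialization(self, small_setup):
        model, train_tasks, test_tasks = small_setup
        cfg = MetaConfig(episodes=0, eval_every=0)
        theta, history = MetaTrainer(model, cfg, seed=4).train(train_tasks, test_tasks)
        rng = np.random.default_rng(4)
        expected = model.init_params(int(rng.integers(2**31)))
        assert np.array_equal(theta, expected)
        assert history == []

    def test_identical_seeds_identical_histories(self, small_setup):
        model, train_tasks, test_tasks = small_setup
        cfg = MetaConfig(episodes=4, eval_every=2, eval_examples=2, algorithm="maml1")
        t1, h1 = MetaTrainer(model, cfg, seed=6).train(train_tasks, test_tasks)
        t2, h2 = MetaTrainer(model, cfg, seed=6).train(train_tasks, test_tasks)
        assert np.array_equal(t1, t2)
        assert [r.mean for r in h1] == [r.mean for r in h2]

    def test_evaluation_never_mutates_parameters(self, small_setup):
        model, train_tasks, test_tasks = small_setup
        cfg = MetaConfig(episodes=0, eval_every=0)
        theta = model.init_params(0)
        trainer = MetaTrainer(model, cfg, seed=0)
        before = theta.copy()
        trainer._evaluate(theta, test_tasks, "test_task", 0, np.random.default_rng(0))
        assert np.array_equal(theta, before)

    def test_adapt_to_user_no_shot_noop_and_deterministic(self, small_setup):
        model, train_tasks, _ = small_setup
        theta = model.init_params(3)
        cfg = MetaConfig(episodes=0, eval_every=0)
        assert np.array_equal(adapt_to_user(model, theta, [], cfg), theta)
        sup = train_tasks[0].samples[:1]
        a1 = adapt_to_user(model, theta, sup, cfg)
        a2 = adapt_to_user(model, theta, sup, cfg)
        assert np.array_equal(a1, a2)
        assert not np.array_equal(a1, theta)


def test_config_validation():
    with pytest.raises(ValueError):
        MetaConfig(shots=3)
    with pytest.raises(ValueError):
        MetaConfig(episodes=100, eval_every=33)
    assert MetaConfig(shots=1).effective_inner_lr == pytest.approx(1.8e-3)
    assert MetaConfig(shots=5).effective_inner_lr == pytest.approx(8e-4)
    assert MetaConfig(shots=1).effective_batch_size == 1
    assert MetaConfig(shots=10).effective_batch_size == 5
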