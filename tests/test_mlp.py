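"""Classifier contracts: forward-pass oracle equivalence, decision rule,
loss arithmetic, LM training behavior, accuracy counting, and transfer."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neckernet import mlp
from neckernet.preprocess import Trial


def oracle_forward(params: mlp.MLPParams, x: np.ndarray) -> float:
    """Brute-force per-neuron forward pass (independent of the vectorized
    implementation): explicit loops over layers, neurons, and inputs."""

    def f(eta):
        return 1.0 / (1.0 + np.exp(-eta))

    h0, h1, h2 = params.sizes
    a1 = np.empty(h1)
    for i in range(h1):
        s = 0.0
        for p in range(h0):
            s += params.w1[p, i] * x[p]
        a1[i] = f(s - params.th1[i])
    a2 = np.empty(h2)
    for i in range(h2):
        s = 0.0
        for p in range(h1):
            s += params.w2[p, i] * a1[p]
        a2[i] = f(s - params.th2[i])
    s = 0.0
    for p in range(h2):
        s += params.w3[p] * a2[p]
    return f(s - params.th3)


def random_trial(rng, label="L", n=40, p=19):
    return Trial(
        data=rng.uniform(-1, 1, size=(p, n)), label=label, g=0.5,
        subject_id=1, fs=250.0,
    )


def zero_params(sizes=(19, 19, 5)):
    h0, h1, h2 = sizes
    return mlp.MLPParams(
        np.zeros((h0, h1)), np.zeros(h1), np.zeros((h1, h2)),
        np.zeros(h2), np.zeros(h2), 0.0,
    )


class TestForward:
    def test_zero_network_outputs_half(self, rng):
        x = rng.uniform(-1, 1, 19)
        assert mlp.forward_sample(zero_params(), x) == pytest.approx(0.5)

    def test_large_threshold_closed_form(self, rng):
        p = zero_params()
        p.th3 = 20.0
        u = mlp.forward_sample(p, rng.uniform(-1, 1, 19))
        assert u == pytest.approx(1.0 / (1.0 + np.exp(20.0)), rel=1e-9)

    def test_matches_per_neuron_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            params = mlp.MLPParams.random(rng, (19, 19, 5), scale=2.0)
            x = rng.uniform(-1, 1, 19)
            assert mlp.forward_sample(params, x) == pytest.approx(
                oracle_forward(params, x), abs=1e-12
            )

    def test_output_in_open_unit_interval(self, rng):
        params = mlp.MLPParams.random(rng, scale=5.0)
        u = mlp.forward_sample(params, rng.uniform(-1, 1, 19))
        assert 0.0 < u < 1.0

    def test_nonfinite_input_rejected(self):
        x = np.zeros(19)
        x[0] = np.nan
        with pytest.raises(ValueError):
            mlp.forward_sample(zero_params(), x)


class TestForwardTrial:
    def test_zero_network_trial_statistic(self, rng):
        assert mlp.forward_trial(zero_params(), random_trial(rng)) == pytest.approx(0.25)

    def test_saturated_network_approaches_one(self, rng):
        params = zero_params()
        params.w3 = np.full(5, 4.0)
        params.th3 = -4.0
        y = mlp.forward_trial(params, random_trial(rng))
        assert 0.99 < y < 1.0

    def test_matches_per_sample_oracle(self):
        rng = np.random.default_rng(7)
        params = mlp.MLPParams.random(rng)
        tr = random_trial(rng, n=30)
        expected = np.mean(
            [oracle_forward(params, tr.data[:, i]) ** 2 for i in range(30)]
        )
        assert mlp.forward_trial(params, tr) == pytest.approx(expected, abs=1e-12)

    def test_empty_trial_rejected(self, rng):
        with pytest.raises(ValueError):
            mlp.forward_trial(zero_params(), random_trial(rng, n=0))


class TestClassify:
    @pytest.mark.parametrize("y,expected", [(0.5, "L"), (0.9, "L"), (0.1, "R")])
    def test_decision_rule(self, y, expected):
        assert mlp.classify(y) == expected

    @pytest.mark.parametrize("y", [-0.1, 1.1])
    def test_out_of_range_rejected(self, y):
        with pytest.raises(ValueError):
            mlp.classify(y)


class TestLoss:
    def test_perfect_predictions_zero_loss(self, rng):
        trials = [random_trial(rng, "L"), random_trial(rng, "R")]
        params = zero_params()
        y = [mlp.forward_trial(params, t) for t in trials]
        assert mlp.loss(params, trials, np.array(y)) == pytest.approx(0.0)

    def test_arithmetic(self, rng):
        # y = 0.25 for the zero network; d = (1, 0)
        trials = [random_trial(rng), random_trial(rng)]
        mu = mlp.loss(zero_params(), trials, np.array([1.0, 0.0]))
        assert mu == pytest.approx(((1 - 0.25) ** 2 + 0.25**2) / 2)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(3)
        params = mlp.MLPParams.random(rng)
        trials = [random_trial(rng, n=20) for _ in range(5)]
        d = rng.integers(0, 2, 5).astype(float)
        direct = np.mean(
            [(d[k] - mlp.forward_trial(params, trials[k])) ** 2 for k in range(5)]
        )
        assert mlp.loss(params, trials, d) == pytest.approx(direct, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mlp.loss(zero_params(), [], np.array([]))


@pytest.fixture(scope="module")
def tiny_training_set():
    """Small separable problem: class L has channel 0 shifted up in half
    the samples, class R down."""
    rng = np.random.default_rng(11)
    trials, labels = [], []
    for k in range(16):
        lab = "L" if k % 2 == 0 else "R"
        data = rng.uniform(-0.4, 0.4, size=(19, 30))
        shift = 0.55 if lab == "L" else -0.55
        data[0, :15] += shift
        data[2, 15:] -= shift
        trials.append(Trial(np.clip(data, -1, 1), lab, 0.5, 1, 250.0))
        labels.append(lab)
    return trials, labels


class TestTraining:
    def test_zero_iteration_budget_returns_init(self, tiny_training_set):
        trials, labels = tiny_training_set
        cfg = mlp.TrainConfig(n_restarts=2, max_iter=0, seed=1)
        res = mlp.train_lm(trials, labels, cfg)
        assert all(not r.converged and r.iterations == 0 for r in res.restarts)
        assert all(r.mu > 0 for r in res.restarts)

    def test_accepted_mu_sequence_non_increasing(self, tiny_training_set):
        trials, labels = tiny_training_set
        cfg = mlp.TrainConfig(n_restarts=3, max_iter=30, seed=2)
        res = mlp.train_lm(trials, labels, cfg)
        for r in res.restarts:
            assert all(b <= a + 1e-15 for a, b in zip(r.mu_history, r.mu_history[1:]))
            assert r.mu == pytest.approx(r.mu_history[-1])

    def test_training_reduces_loss(self, tiny_training_set):
        trials, labels = tiny_training_set
        cfg = mlp.TrainConfig(n_restarts=3, max_iter=30, seed=3)
        res = mlp.train_lm(trials, labels, cfg)
        best = res.restarts[res.best_index]
        assert best.mu < best.mu_history[0]

    def test_deterministic_given_seed(self, tiny_training_set):
        trials, labels = tiny_training_set
        cfg = mlp.TrainConfig(n_restarts=2, max_iter=10, seed=4)
        r1 = mlp.train_lm(trials, labels, cfg)
        r2 = mlp.train_lm(trials, labels, cfg)
        np.testing.assert_array_equal(
            r1.restarts[0].params.to_vector(), r2.restarts[0].params.to_vector()
        )
        assert r1.best_index == r2.best_index

    def test_single_class_rejected(self, rng):
        trials = [random_trial(rng, "L") for _ in range(4)]
        with pytest.raises(ValueError, match="both classes"):
            mlp.train_lm(trials, ["L"] * 4)

    def test_select_best_is_argmin_with_ties_to_lowest_index(self):
        p = zero_params()
        mk = lambda mu: mlp.RestartResult(p, mu, 0, 1, True)
        res = mlp.TrainingResult([mk(0.3), mk(0.1), mk(0.2)], best_index=1)
        assert mlp.select_best(res) is res.restarts[1].params
        mus = np.array([0.2, 0.1, 0.3, 0.1])
        assert int(np.argmin(mus)) == 1  # documented tie-break: first argmin

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            mlp.select_best(mlp.TrainingResult([], 0))


class TestAccuracy:
    def test_all_correct(self, rng):
        params = zero_params()  # y = 0.25 -> predicts R always
        trials = [random_trial(rng, "R") for _ in range(8)]
        rep = mlp.accuracy(params, trials)
        assert rep.rho == 100.0 and rep.n_correct == 8

    def test_counting_matches_confusion_oracle(self, rng):
        params = mlp.MLPParams.random(rng)
        trials = [random_trial(rng, "L" if i % 3 else "R") for i in range(12)]
        rep = mlp.accuracy(params, trials)
        n_correct = sum(
            mlp.classify(mlp.forward_trial(params, t)) == t.label for t in trials
        )
        assert rep.n_correct == n_correct
        assert rep.rho == pytest.approx(100.0 * n_correct / 12)
        assert rep.n_L + rep.n_R == rep.n_total == 12

    def test_fraction_arithmetic(self, rng):
        # zero network predicts R; 7 R + 3 L trials -> 70 %
        trials = [random_trial(rng, "R") for _ in range(7)]
        trials += [random_trial(rng, "L") for _ in range(3)]
        assert mlp.accuracy(zero_params(), trials).rho == pytest.approx(70.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mlp.accuracy(zero_params(), [])

    @given(st.integers(0, 2**31 - 1))
    def test_inference_is_deterministic(self, seed):
        rng = np.random.default_rng(seed)
        params = mlp.MLPParams.random(rng)
        tr = random_trial(rng, n=10)
        y1 = mlp.forward_trial(params, tr)
        y2 = mlp.forward_trial(params, tr)
        assert y1 == y2 and mlp.classify(y1) == mlp.classify(y2)


class TestSplitAndTransfer:
    def test_split_is_balanced_and_disjoint(self, small_trials):
        train, test = mlp.split_trials(small_trials, n_per_class=10, seed=0)
        assert sum(t.label == "L" for t in train) == 10
        assert sum(t.label == "R" for t in train) == 10
        assert len(train) + len(test) == len(small_trials)
        train_ids = {id(t) for t in train}
        assert all(id(t) not in train_ids for t in test)

    def test_split_insufficient_trials_rejected(self, small_trials):
        with pytest.raises(ValueError, match="not enough"):
            mlp.split_trials(small_trials, n_per_class=1000)

    def test_cross_subject_diagonal_is_within_subject(self, rng):
        params = {1: mlp.MLPParams.random(rng), 2: mlp.MLPParams.random(rng)}
        data = {
            1: [random_trial(rng, "L"), random_trial(rng, "R")],
            2: [random_trial(rng, "R"), random_trial(rng, "R")],
        }
        mat = mlp.cross_subject_matrix(params, data)
        for sid in (1, 2):
            assert mat.loc[sid, sid] == pytest.approx(
                mlp.accuracy(params[sid], data[sid]).rho
            )

    def test_identical_subjects_give_identical_rows(self, rng):
        p = mlp.MLPParams.random(rng)
        trials = [random_trial(rng, "L"), random_trial(rng, "R")]
        mat = mlp.cross_subject_matrix({1: p, 2: p}, {1: trials, 2: trials})
        assert mat.loc[1, 2] == mat.loc[1, 1] == mat.loc[2, 2] == mat.loc[2, 1]

    def test_mismatched_subject_sets_rejected(self, rng):
        with pytest.raises(ValueError):
            mlp.cross_subject_matrix(
                {1: mlp.MLPParams.random(rng)}, {2: [random_trial(rng)]}
            )


class TestSerialization:
    def test_json_roundtrip(self, rng):
        params = mlp.MLPParams.random(rng)
        back = mlp.MLPParams.from_json(params.to_json())
        np.testing.assert_array_equal(back.to_vector(), params.to_vector())


@pytest.fixture(scope="module")
def separable_session():
    import neckernet as nn

    profile = nn.generate_subject_profile(
        71, 1, overrides={"class_effect_amp": 40.0}
    )
    rec, events = nn.generate_session(profile, 100)
    return rec, events


class TestSweep:
    def test_duration_and_capacity_trends(self, separable_session):
        """Trials too short to cover the 0.2-0.8 s class signature give
        lower accuracy than 1-s trials, and the wider second hidden
        layer is not materially worse than a single-unit one.

        Causal filtering is used here so that a trial window contains no
        information smeared in from outside the window (zero-phase
        filtering spreads evoked energy symmetrically in time, which
        would let even pre-signature windows classify above chance).
        """
        cfg = mlp.TrainConfig(n_restarts=3, max_iter=40, seed=1)
        table = mlp.sweep_topology_and_duration(
            [separable_session],
            h1_grid=(19,),
            h2_grid=(1, 5),
            t_grid=(0.1, 1.0),
            config=cfg,
            n_per_class=20,
            preprocess_kwargs={"zero_phase": False},
        )
        t_rows = table[table["axis"] == "T"].set_index("value")["mean_rho"]
        assert t_rows[0.1] < t_rows[1.0]
        h2_rows = table[table["axis"] == "H2"].set_index("value")["mean_rho"]
        assert h2_rows[5] >= h2_rows[1] - 2.0

    def test_single_grid_point_matches_direct_run(self, separable_session):
        """A one-point sweep reproduces the directly computed mean
        held-out accuracy with the same seeds."""
        import neckernet as nn

        cfg = mlp.TrainConfig(n_restarts=2, max_iter=10, seed=2)
        table = mlp.sweep_topology_and_duration(
            [separable_session], h1_grid=(19,), h2_grid=(), t_grid=(),
            config=cfg, n_per_class=20,
        )
        rec, events = separable_session
        trials = nn.preprocess_session(rec, events, T=1.0)
        train, test = mlp.split_trials(trials, 20, seed=cfg.seed)
        res = mlp.train_lm(train, [t.label for t in train], cfg)
        expected = np.mean([mlp.accuracy(r.params, test).rho for r in res.restarts])
        assert table["mean_rho"].iloc[0] == pytest.approx(expected)
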