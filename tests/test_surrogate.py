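import json
import math

import numpy as np
import pytest

from dissolvenn.design import Formulation
from dissolvenn.profiles import DissolutionProfile, STANDARD_TIMES
from dissolvenn.simulate import GeneratorConfig, generate_study
from dissolvenn.surrogate import (
    MLPSurrogate,
    SurrogateModel,
    TrainConfig,
    _init_params,
    _mlp_jacobian,
    _mlp_residual,
    denormalize,
    fit_norm,
    forward,
    levenberg_marquardt,
    load_model,
    normalize,
    regression_metrics,
    save_model,
    split_data,
    study_matrices,
    train_lm,
)


def random_model(rng, k=6, m=10, n=10, identity_norm=False):
    if identity_norm:
        in_rng = (np.full(k, -1.0), np.full(k, 1.0))
        out_rng = (np.full(n, -1.0), np.full(n, 1.0))
    else:
        in_rng = (rng.uniform(0, 10, k), rng.uniform(20, 80, k))
        out_rng = (rng.uniform(0, 10, n), rng.uniform(50, 100, n))
    return SurrogateModel(
        hidden_weights=rng.normal(size=(m, k)),
        hidden_biases=rng.normal(size=m),
        output_weights=rng.normal(size=(n, m)),
        output_biases=rng.normal(size=n),
        input_min=in_rng[0], input_max=in_rng[1],
        output_min=out_rng[0], output_max=out_rng[1],
    )


class TestSplitData:
    def test_17_samples_split_11_3_3(self):
        """round(17·0.15) = 3 for validation and test (17·0.15 lands just
        above 2.55 in binary floating point); the remainder trains."""
        tr, va, te = split_data(17, TrainConfig(seed=0))
        assert (len(tr), len(va), len(te)) == (11, 3, 3)

    def test_exact_multiples_split_cleanly(self):
        tr, va, te = split_data(20, TrainConfig(seed=0))
        assert (len(tr), len(va), len(te)) == (14, 3, 3)

    def test_partition_is_disjoint_and_exhaustive(self):
        tr, va, te = split_data(17, TrainConfig(seed=4))
        combined = np.concatenate([tr, va, te])
        assert sorted(combined.tolist()) == list(range(17))

    def test_seed_contract(self):
        a = split_data(17, TrainConfig(seed=1))
        b = split_data(17, TrainConfig(seed=1))
        c = split_data(17, TrainConfig(seed=2))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))
        assert tuple(map(len, a)) == tuple(map(len, c))

    def test_empty_subset_raises_actionable_error(self):
        with pytest.raises(ValueError, match="more\\s+samples"):
            split_data(3, TrainConfig(seed=0))


class TestNormalization:
    def test_endpoints_and_midpoint(self):
        mins, maxs = np.array([0.0]), np.array([10.0])
        assert normalize(np.array([0.0]), mins, maxs)[0] == -1.0
        assert normalize(np.array([10.0]), mins, maxs)[0] == 1.0
        assert normalize(np.array([5.0]), mins, maxs)[0] == 0.0

    def test_degenerate_dimension_maps_to_zero_and_back_to_min(self):
        mins = maxs = np.array([3.0])
        assert normalize(np.array([3.0]), mins, maxs)[0] == 0.0
        assert denormalize(np.array([0.7]), mins, maxs)[0] == 3.0

    def test_round_trip_is_identity(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(-50, 50, size=(40, 6))
        mins, maxs = fit_norm(data)
        back = denormalize(normalize(data, mins, maxs), mins, maxs)
        np.testing.assert_allclose(back, data, atol=1e-12)


class TestForward:
    def test_zero_network_outputs_target_midpoints(self):
        rng = np.random.default_rng(1)
        model = random_model(rng)
        zero = SurrogateModel(
            hidden_weights=np.zeros_like(model.hidden_weights),
            hidden_biases=np.zeros_like(model.hidden_biases),
            output_weights=np.zeros_like(model.output_weights),
            output_biases=np.zeros_like(model.output_biases),
            input_min=model.input_min, input_max=model.input_max,
            output_min=model.output_min, output_max=model.output_max,
        )
        y = forward(zero, rng.uniform(5, 15, 6))
        np.testing.assert_allclose(
            y, (model.output_min + model.output_max) / 2, atol=1e-12
        )

    def test_minimal_identity_network(self):
        model = SurrogateModel(
            hidden_weights=np.array([[1.0]]),
            hidden_biases=np.array([0.0]),
            output_weights=np.array([[1.0]]),
            output_biases=np.array([0.0]),
            input_min=np.array([-1.0]), input_max=np.array([1.0]),
            output_min=np.array([-1.0]), output_max=np.array([1.0]),
        )
        assert forward(model, np.array([0.0]))[0] == 0.0

    def test_matches_scalar_loop_oracle(self):
        """Vectorized pass equals an explicit per-neuron summation."""
        rng = np.random.default_rng(2)
        model = random_model(rng)
        X = rng.uniform(5, 75, size=(5, 6))
        got = forward(model, X)
        for i in range(5):
            xn = [
                2 * (X[i, l] - model.input_min[l])
                / (model.input_max[l] - model.input_min[l]) - 1
                for l in range(6)
            ]
            a = [
                math.tanh(
                    sum(model.hidden_weights[h, l] * xn[l] for l in range(6))
                    + model.hidden_biases[h]
                )
                for h in range(10)
            ]
            for j in range(10):
                yn = (
                    sum(model.output_weights[j, h] * a[h] for h in range(10))
                    + model.output_biases[j]
                )
                y = (yn + 1) / 2 * (
                    model.output_max[j] - model.output_min[j]
                ) + model.output_min[j]
                assert got[i, j] == pytest.approx(y, abs=1e-10)

    def test_dimension_mismatch_reports_shapes(self):
        model = random_model(np.random.default_rng(3))
        with pytest.raises(ValueError, match="6 features"):
            forward(model, np.ones(4))


class TestLevenbergMarquardt:
    def test_linear_problem_solved_like_gauss_newton(self):
        """Fitting y = 2x from 3 points: LM with vanishing damping is
        Gauss–Newton, which solves a linear LS problem outright."""
        x = np.array([1.0, 2.0, 3.0])
        y = 2.0 * x
        theta, trace, stop = levenberg_marquardt(
            lambda th: th[0] * x - y,
            lambda th: x[:, None],
            np.array([0.0]),
            mu_init=1e-12,
            sse_goal=1e-20,
            max_epochs=50,
        )
        assert theta[0] == pytest.approx(2.0, abs=1e-8)
        assert stop == "mse_goal"

    def test_jacobian_matches_central_finite_differences(self):
        """Backprop Jacobian of a 3-4-2 net vs central differences, 1e-4
        relative on every non-negligible entry."""
        rng = np.random.default_rng(5)
        k, m, n = 3, 4, 2
        theta = rng.normal(size=m * k + m + n * m + n)
        xn = rng.uniform(-1, 1, size=(6, k))
        tn = rng.uniform(-1, 1, size=(6, n))
        J = _mlp_jacobian(theta, xn, k, m, n)
        h = 1e-6
        J_fd = np.empty_like(J)
        for p in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[p] += h
            tm[p] -= h
            J_fd[:, p] = (
                _mlp_residual(tp, xn, tn, k, m, n)
                - _mlp_residual(tm, xn, tn, k, m, n)
            ) / (2 * h)
        scale = np.abs(J_fd) + 1e-8
        assert np.max(np.abs(J - J_fd) / scale) < 1e-4

    def test_noiseless_linear_target_fits_to_tiny_mse(self, study_batches):
        """A linear composition→release map is inside the model class, so
        training error collapses below 1e-6 quickly."""
        rng = np.random.default_rng(6)
        X = np.vstack([f.as_array() for _, f in study_batches])
        W = rng.uniform(-1, 1, size=(6, 10))
        Y = 50 + (X - X.mean(axis=0)) @ W
        est = MLPSurrogate(
            n_hidden=6, random_state=0, max_epochs=200,
            mse_goal=1e-8, patience=200,
        ).fit(X, Y)
        assert est.report_.epochs[-1].train_mse < 1e-6

    def test_interpolates_a_known_network_exactly_enough(self, study_batches):
        """Noiseless data from a random 6-10-10 net is refit to training
        MSE below 1e-4 — the 17-sample problem is over-parameterized."""
        rng = np.random.default_rng(7)
        X = np.vstack([f.as_array() for _, f in study_batches])
        truth = random_model(rng)
        Y = forward(truth, X)
        est = MLPSurrogate(
            random_state=1, max_epochs=500, mse_goal=1e-6, patience=500,
        ).fit(X, Y)
        assert est.report_.epochs[-1].train_mse < 1e-4

    def test_accepted_steps_strictly_decrease_training_sse(
        self, trained_surrogate
    ):
        _, report = trained_surrogate
        path = report.train_mse_path
        assert len(path) >= 2
        assert np.all(np.diff(path) < 0)

    def test_training_is_bit_deterministic(self, default_study):
        m1, r1 = train_lm(default_study, TrainConfig(seed=3))
        m2, r2 = train_lm(default_study, TrainConfig(seed=3))
        np.testing.assert_array_equal(m1.hidden_weights, m2.hidden_weights)
        np.testing.assert_array_equal(m1.output_weights, m2.output_weights)
        assert r1.stop_reason == r2.stop_reason
        assert [e.train_mse for e in r1.epochs] == [
            e.train_mse for e in r2.epochs
        ]
        assert r1.partition == r2.partition

    def test_training_fit_is_tight_for_most_seeds(self, study_batches):
        """On the default synthetic study the training-set regression
        coefficient reaches 0.95 for at least 8 of 10 seeds."""
        forms = [f for _, f in study_batches]
        hits = 0
        for seed in range(10):
            study = generate_study(forms, GeneratorConfig(seed=seed))
            _, report = train_lm(study, TrainConfig(seed=seed))
            if report.r_values["train"] >= 0.95:
                hits += 1
        assert hits >= 8

    def test_too_few_samples_rejected(self):
        times = np.array(STANDARD_TIMES)
        data = [
            (Formulation(50, 10, 15, 33.5, 15.73, 40),
             DissolutionProfile(times=times, release=np.linspace(5, 80, 10)))
        ] * 2
        with pytest.raises(ValueError, match="at least 3"):
            train_lm(data)


class TestRegressionMetrics:
    def test_perfect_predictions_score_one(self):
        rng = np.random.default_rng(8)
        model = random_model(rng)
        X = rng.uniform(5, 75, size=(10, 6))
        Y = forward(model, X)
        r = regression_metrics(
            model, X, Y, {"train": list(range(10))}
        )
        assert r["train"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(9)
        model = random_model(rng)
        X = rng.uniform(5, 75, size=(8, 6))
        Y = forward(model, X) + rng.normal(0, 5, size=(8, 10))
        r = regression_metrics(model, X, Y, {"train": list(range(8))})
        p = forward(model, X).ravel()
        t = Y.ravel()
        expected = (
            ((p - p.mean()) * (t - t.mean())).sum()
            / math.sqrt(((p - p.mean()) ** 2).sum() * ((t - t.mean()) ** 2).sum())
        )
        assert r["train"] == pytest.approx(expected, abs=1e-12)

    def test_undersized_subset_reports_none(self):
        rng = np.random.default_rng(10)
        model = random_model(rng, n=1)
        X = rng.uniform(5, 75, size=(3, 6))
        Y = forward(model, X).reshape(3, 1)
        r = regression_metrics(model, X, Y, {"test": [0], "train": [1, 2]})
        assert r["test"] is None


class TestSerialization:
    def test_round_trip_reproduces_forward_bit_exactly(
        self, tmp_path, trained_surrogate
    ):
        model, _ = trained_surrogate
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        rng = np.random.default_rng(11)
        X = rng.uniform(5, 75, size=(20, 6))
        np.testing.assert_array_equal(forward(model, X), forward(back, X))
        np.testing.assert_array_equal(model.times, back.times)

    def test_document_is_plain_json_with_layer_sizes(
        self, tmp_path, trained_surrogate
    ):
        model, _ = trained_surrogate
        path = tmp_path / "model.json"
        save_model(model, path)
        doc = json.loads(path.read_text())
        assert doc["layer_sizes"] == [6, 10, 10]


class TestStudyMatrices:
    def test_shapes_are_6x17_and_10x17(self, default_study):
        X, Y, times = study_matrices(default_study)
        assert X.T.shape == (6, 17)
        assert Y.T.shape == (10, 17)
        assert times.shape == (10,)

    def test_mixed_time_grids_rejected(self, default_study):
        form, prof = default_study[0]
        bad = DissolutionProfile(
            times=prof.times + 0.5, release=prof.release
        )
        with pytest.raises(ValueError, match="different time grid"):
            study_matrices([default_study[1], (form, bad)])


def test_train_config_validation():
    with pytest.raises(ValueError, match="sum"):
        TrainConfig(train_frac=0.8, val_frac=0.15, test_frac=0.15)
    with pytest.raises(ValueError, match="positive"):
        TrainConfig(mu_init=0.0)
    with pytest.raises(ValueError, match="patience"):
        TrainConfig(patience=0)
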