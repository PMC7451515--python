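import itertools

import numpy as np
import pytest

from elicitopt.anfis import (AnfisConfig, MembershipParams, RuleBase,
                             backprop_premise, firing_strengths, from_json,
                             initialize_model, lse_consequents, mf_value,
                             normalize_firing, predict, premise_gradient,
                             to_json, train_hybrid, _forward_internal)
from elicitopt.metrics import r_squared, rmse
from elicitopt.synthetic import (DesignSpec, SyntheticSurfaceSpec,
                                 generate_dataset)
from elicitopt.data_model import to_design_matrix


def naive_forward(model, x):
    """Independent rule-by-rule evaluation of the five-layer network.

    Walks every rule with scalar arithmetic only — no shared code with the
    vectorized forward pass beyond mf_value itself re-derived here.
    """
    xn = []
    for j, (lo, hi) in enumerate(model.input_ranges):
        width = (hi - lo) if hi > lo else 1.0
        xn.append((x[j] - lo) / width if model.config.normalize_inputs else x[j])
    w = []
    for rule in model.rulebase.rules:
        strength = 1.0
        for j, mf_idx in enumerate(rule):
            a, b, c = model.premise[j][mf_idx]
            if model.config.mf_form == "bell_eq3":
                mu = 1.0 / (1.0 + abs((xn[j] - c) / a) ** (2.0 * b))
            else:
                mu = np.exp(-((xn[j] - c) ** 2) / (2.0 * a ** 2))
            strength *= mu
        w.append(strength)
    total = sum(w)
    out = 0.0
    for k, rule in enumerate(model.rulebase.rules):
        f_k = sum(model.consequents[k][j] * xn[j] for j in range(model.d))
        f_k += model.consequents[k][model.d]
        out += (w[k] / total) * f_k
    return model.y_offset + model.y_scale * out


def random_model(rng, d=None, form="bell_eq3"):
    d = d or rng.integers(1, 5)
    counts = tuple(int(rng.integers(2, 4)) for _ in range(d))
    cfg = AnfisConfig(mfs_per_input=counts, mf_form=form)
    model = initialize_model(cfg, [(0.0, 1.0)] * d)
    for j in range(d):
        p = model.premise[j]
        p[:, 0] = rng.uniform(0.1, 0.8, p.shape[0])
        p[:, 1] = rng.uniform(1.0, 3.0, p.shape[0])
        p[:, 2] = rng.uniform(0.0, 1.0, p.shape[0])
    model.consequents = rng.normal(0, 2, (model.rulebase.n_rules, d + 1))
    model.y_offset = float(rng.normal())
    model.y_scale = float(rng.uniform(0.5, 3.0))
    return model


class TestMembership:
    @pytest.mark.parametrize("form", ["bell_eq3", "gaussian"])
    def test_unity_at_center(self, form):
        assert mf_value(0.7, MembershipParams(0.3, 2.0, 0.7), form) == 1.0

    def test_bell_half_width(self):
        p = MembershipParams(a=0.4, b=3.0, c=0.2)
        assert mf_value(0.6, p, "bell_eq3") == pytest.approx(0.5)

    def test_bell_direct_substitution(self):
        assert mf_value(2.0, MembershipParams(1.0, 1.0, 0.0)) == pytest.approx(0.2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MembershipParams(a=-1.0, b=2.0, c=0.0)
        with pytest.raises(ValueError):
            mf_value(0.0, MembershipParams(1.0, 1.0, 0.0), "triangle")


class TestRuleBase:
    def test_full_cartesian_product(self):
        rb = RuleBase((2, 3))
        assert rb.n_rules == 6
        assert len({tuple(r) for r in rb.rules}) == 6

    def test_rules_cover_all_combinations(self):
        rb = RuleBase((2, 2, 2))
        assert {tuple(r) for r in rb.rules} == set(
            itertools.product(range(2), repeat=3))


class TestForwardPass:
    def test_normalize_firing(self):
        assert normalize_firing([1.0, 3.0]) == pytest.approx([0.25, 0.75])
        w = normalize_firing([1e6, 1.0])
        assert w.sum() == pytest.approx(1.0)
        assert w[0] == pytest.approx(1.0, abs=1e-5)
        with pytest.raises(ValueError):
            normalize_firing([0.0, 0.0])

    def test_firing_strength_is_membership_product(self, rng):
        model = random_model(rng, d=2)
        x = rng.uniform(0, 1, 2)
        w = firing_strengths(x, model)
        for k, rule in enumerate(model.rulebase.rules):
            expected = 1.0
            for j, mf_idx in enumerate(rule):
                a, b, c = model.premise[j][mf_idx]
                expected *= mf_value(x[j], MembershipParams(a, b, c))
            assert w[k] == pytest.approx(expected, rel=1e-12)

    def test_constant_consequents_give_constant_output(self, rng):
        model = random_model(rng, d=3)
        model.consequents = np.zeros_like(model.consequents)
        model.consequents[:, -1] = 5.0
        model.y_offset, model.y_scale = 0.0, 1.0
        for _ in range(5):
            assert predict(rng.uniform(0, 1, 3), model) == pytest.approx(5.0)

    def test_output_within_rule_output_hull(self, rng):
        model = random_model(rng, d=2)
        model.y_offset, model.y_scale = 0.0, 1.0
        for _ in range(20):
            x = rng.uniform(0, 1, 2)
            f = [model.consequents[k, :2] @ x + model.consequents[k, 2]
                 for k in range(model.rulebase.n_rules)]
            y = predict(x, model)
            assert min(f) - 1e-9 <= y <= max(f) + 1e-9

    @pytest.mark.parametrize("form", ["bell_eq3", "gaussian"])
    def test_matches_naive_rule_by_rule_evaluation(self, rng, form):
        for _ in range(60):
            model = random_model(rng, form=form)
            x = rng.uniform(-0.2, 1.2, model.d)
            assert predict(x, model) == pytest.approx(
                naive_forward(model, x), abs=1e-10)

    def test_continuity_in_x(self, rng):
        model = random_model(rng, d=2)
        x = rng.uniform(0, 1, 2)
        base = predict(x, model)
        for delta in (1e-3, 1e-5, 1e-7):
            moved = predict(x + delta, model)
            assert abs(moved - base) < 1e3 * delta + 1e-12


class TestLseConsequents:
    def test_exact_recovery_of_generating_consequents(self, rng):
        model = random_model(rng, d=2)
        X = rng.uniform(0, 1, (200, 2))
        y_true = predict(X, model)
        from dataclasses import replace
        fit = initialize_model(replace(model.config, ridge=0.0),
                               model.input_ranges)
        fit.premise = [p.copy() for p in model.premise]
        fit.y_offset, fit.y_scale = model.y_offset, model.y_scale
        lse_consequents(fit, X, y_true)
        assert rmse(predict(X, fit), y_true) < 1e-6

    def test_constant_response_fits_exactly(self, rng):
        from dataclasses import replace
        model = random_model(rng, d=2)
        model.config = replace(model.config, ridge=0.0)
        model.y_offset, model.y_scale = 0.0, 1.0
        X = rng.uniform(0, 1, (50, 2))
        lse_consequents(model, X, np.full(50, 7.0))
        assert rmse(predict(X, model), np.full(50, 7.0)) < 1e-8

    def test_residual_orthogonal_to_regressors_without_ridge(self, rng):
        cfg = AnfisConfig(ridge=0.0)
        model = initialize_model(cfg, [(0.0, 1.0)] * 2)
        X = rng.uniform(0, 1, (100, 2))
        y = rng.normal(0, 1, 100)
        lse_consequents(model, X, y)
        from elicitopt.anfis import _regressor_matrix
        Phi = _regressor_matrix(model, model._normalize(X))
        resid = Phi @ model.consequents.ravel() - y
        assert np.max(np.abs(Phi.T @ resid)) < 1e-6

    def test_random_perturbations_never_beat_lse(self, rng):
        model = random_model(rng, d=2)
        X = rng.uniform(0, 1, (80, 2))
        y = rng.normal(0, 1, 80)
        lse_consequents(model, X, y)
        yn = (y - model.y_offset) / model.y_scale
        base_sse = np.sum((_forward_internal(model, model._normalize(X)) - yn) ** 2)
        theta0 = model.consequents.copy()
        for _ in range(200):
            model.consequents = theta0 + rng.normal(0, 1e-3, theta0.shape)
            sse = np.sum((_forward_internal(model, model._normalize(X)) - yn) ** 2)
            assert sse >= base_sse - 1e-9
        model.consequents = theta0


class TestPremiseGradient:
    @pytest.mark.parametrize("form", ["bell_eq3", "gaussian"])
    def test_matches_central_finite_differences(self, rng, form):
        cfg = AnfisConfig(mfs_per_input=2, mf_form=form)
        model = initialize_model(cfg, [(0.0, 1.0)] * 2)
        for j in range(2):
            model.premise[j][:, 0] *= rng.uniform(0.7, 1.3, 2)
            model.premise[j][:, 2] += rng.uniform(-0.1, 0.1, 2)
        X = rng.uniform(0, 1, (30, 2))
        y = rng.normal(0, 1, 30)
        lse_consequents(model, X, y)

        def sse():
            yn = (y - model.y_offset) / model.y_scale
            r = _forward_internal(model, model._normalize(X)) - yn
            return float(r @ r)

        grads = premise_gradient(model, X, y)
        h = 1e-6
        for j in range(2):
            for mf in range(2):
                for k in range(3):
                    orig = model.premise[j][mf, k]
                    model.premise[j][mf, k] = orig + h
                    f1 = sse()
                    model.premise[j][mf, k] = orig - h
                    f2 = sse()
                    model.premise[j][mf, k] = orig
                    assert grads[j][mf, k] == pytest.approx(
                        (f1 - f2) / (2 * h), abs=1e-4)

    def test_zero_learning_rate_leaves_premises_unchanged(self, rng):
        model = random_model(rng, d=2)
        X = rng.uniform(0, 1, (20, 2))
        y = rng.normal(size=20)
        before = [p.copy() for p in model.premise]
        backprop_premise(model, X, y, learning_rate=0.0)
        for b, a in zip(before, model.premise):
            assert np.array_equal(b, a)


class TestTrainHybrid:
    def test_history_length_equals_epochs(self, rng):
        X = rng.uniform(0, 1, (30, 2))
        y = rng.normal(size=30)
        for epochs in (1, 2, 5):
            m = train_hybrid(AnfisConfig(epochs=epochs), X, y)
            assert len(m.training_history) == epochs

    def test_linear_map_fit_exactly(self, rng):
        X = rng.uniform(0, 4, (60, 1))
        y = 2.0 * X[:, 0] + 3.0
        m = train_hybrid(AnfisConfig(epochs=3), X, y)
        assert rmse(predict(X, m), y) < 1e-3

    def test_noiseless_surface_high_r2(self):
        surf = SyntheticSurfaceSpec(sigma_block=0.0, sigma_eps=0.0)
        dm = to_design_matrix(generate_dataset(surface=surf, seed=1), "CE")
        m = train_hybrid(AnfisConfig(epochs=100), dm.X, dm.y)
        assert r_squared(predict(dm.X, m), dm.y) > 0.95

    def test_final_rmse_no_worse_than_initial(self, trained_anfis,
                                              default_matrix, default_split):
        tr = list(default_split.train_indices)
        final = rmse(predict(default_matrix.X[tr], trained_anfis),
                     default_matrix.y[tr])
        assert final <= trained_anfis.training_history[0] + 1e-9

    def test_deterministic_for_fixed_config(self, rng):
        X = rng.uniform(0, 1, (40, 2))
        y = np.sin(4 * X[:, 0]) + rng.normal(0, 0.1, 40)
        m1 = train_hybrid(AnfisConfig(epochs=10), X, y)
        m2 = train_hybrid(AnfisConfig(epochs=10), X, y)
        assert np.array_equal(m1.consequents, m2.consequents)
        assert all(np.array_equal(a, b)
                   for a, b in zip(m1.premise, m2.premise))

    def test_non_finite_data_rejected(self):
        with pytest.raises(ValueError):
            train_hybrid(AnfisConfig(), np.array([[np.nan], [1.0]]),
                         np.array([1.0, 2.0]))


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, trained_anfis,
                                                   default_matrix):
        reloaded = from_json(to_json(trained_anfis))
        X = default_matrix.X[:25]
        np.testing.assert_allclose(predict(X, reloaded),
                                   predict(X, trained_anfis), rtol=0,
                                   atol=1e-12)
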