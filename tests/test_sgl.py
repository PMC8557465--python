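"""Solver correctness: objective, proximal maps, FISTA, model selection."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, strategies as st
from scipy.optimize import minimize

import evosparse as ev
from evosparse.sgl import BitGroups, FitError, _intercept_only


def random_problem(S=12, c=8, seed=0, groups_of=4):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(S, c)).astype(float)
    y = np.where(rng.random(S) < 0.5, 1.0, -1.0)
    if np.all(y > 0) or np.all(y < 0):
        y[0] *= -1
    rv = ev.ResponseVector(taxa=[f"s{i}" for i in range(S)], y=y)
    slices = [np.arange(i, min(i + groups_of, c)) for i in range(0, c, groups_of)]
    bg = BitGroups(
        names=[f"g{k}" for k in range(len(slices))],
        slices=slices,
        weights=np.sqrt([s.size for s in slices]),
    )
    return X, rv, bg


class TestLogisticObjective:
    def test_loss_at_zero_is_log2(self):
        X, rv, _ = random_problem(seed=1)
        loss, _, _ = ev.logistic_objective(0.0, np.zeros(X.shape[1]), X, rv.y,
                                           rv.weights)
        assert loss == pytest.approx(np.log(2.0))

    def test_gradient_matches_finite_differences(self):
        X, rv, _ = random_problem(S=10, c=6, seed=2)
        rng = np.random.default_rng(3)
        b0, b = rng.normal(size=1)[0], rng.normal(size=6)

        def f(theta):
            loss, _, _ = ev.logistic_objective(theta[0], theta[1:], X, rv.y,
                                               rv.weights)
            return loss

        theta = np.concatenate(([b0], b))
        _, g0, g = ev.logistic_objective(b0, b, X, rv.y, rv.weights)
        grad = np.concatenate(([g0], g))
        h = 1e-6
        for i in range(theta.size):
            e = np.zeros_like(theta)
            e[i] = h
            fd = (f(theta + e) - f(theta - e)) / (2 * h)
            assert fd == pytest.approx(grad[i], rel=1e-5, abs=1e-8)

    def test_separating_direction_drives_loss_to_zero(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        rv = ev.ResponseVector(taxa=["a", "b"], y=np.array([1.0, -1.0]))
        beta = np.array([1.0, -1.0])
        losses = [
            ev.logistic_objective(0.0, s * beta, X, rv.y, rv.weights)[0]
            for s in (1.0, 10.0, 100.0)
        ]
        assert losses[0] > losses[1] > losses[2]
        assert losses[2] < 1e-3

    def test_dimension_mismatch_rejected(self):
        X, rv, _ = random_problem()
        with pytest.raises(FitError):
            ev.logistic_objective(0.0, np.zeros(3), X, rv.y, rv.weights)


class TestProxL1:
    @pytest.mark.parametrize(
        "v,t,expected",
        [(0.5, 0.2, 0.3), (-0.1, 0.2, 0.0), (-0.7, 0.2, -0.5), (0.4, 0.0, 0.4)],
    )
    def test_closed_form(self, v, t, expected):
        assert ev.prox_l1(np.array([v]), t)[0] == pytest.approx(expected)

    def test_negative_threshold_rejected(self):
        with pytest.raises(FitError):
            ev.prox_l1(np.array([1.0]), -0.1)

    @given(st.integers(0, 2**31 - 1))
    def test_nonexpansive_and_shrinking(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=5)
        out = ev.prox_l1(v, 0.3)
        assert np.all(np.abs(out) <= np.abs(v))
        assert np.all(np.sign(out[out != 0]) == np.sign(v[out != 0]))


class TestProxSparseGroup:
    def test_group_shrinkage_closed_form(self):
        v = np.array([3.0, 4.0])
        out = ev.prox_sparse_group(v, 0.0, 2.5, [np.arange(2)], np.array([1.0]))
        assert out == pytest.approx([1.5, 2.0])  # ||v||=5, factor 1-2.5/5

    def test_group_zeroed_when_threshold_exceeds_norm(self):
        v = np.array([0.3, -0.4])
        out = ev.prox_sparse_group(v, 0.1, 1.0, [np.arange(2)], np.array([1.0]))
        assert np.all(out == 0.0)

    def test_matches_numerical_prox_oracle(self):
        """Brute-force minimization of ½‖x−v‖² + penalty."""
        rng = np.random.default_rng(8)
        v = rng.normal(size=6)
        slices = [np.arange(0, 3), np.arange(3, 6)]
        wg = np.array([1.0, 1.7])
        t1, t2 = 0.15, 0.4

        def objective(x):
            pen = t1 * np.abs(x).sum() + t2 * sum(
                w * np.linalg.norm(x[s]) for s, w in zip(slices, wg)
            )
            return 0.5 * np.sum((x - v) ** 2) + pen

        ref = minimize(objective, np.zeros(6), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14,
                                "maxiter": 20000}).x
        out = ev.prox_sparse_group(v, t1, t2, slices, wg)
        assert out == pytest.approx(ref, abs=1e-5)
        assert objective(out) <= objective(ref) + 1e-10

    def test_singleton_groups_compose_l1_shrinkage(self):
        """With one-column groups and w=1 the prox is soft(soft(v,t1),t2)."""
        v = np.array([2.0, -0.5, 0.1])
        slices = [np.array([0]), np.array([1]), np.array([2])]
        out = ev.prox_sparse_group(v, 0.3, 0.2, slices, np.ones(3))
        expected = ev.prox_l1(ev.prox_l1(v, 0.3), 0.2)
        assert out == pytest.approx(expected)

    def test_zero_l1_equals_pure_group_prox(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=4)
        slices = [np.arange(0, 2), np.arange(2, 4)]
        wg = np.array([1.0, 2.0])
        out = ev.prox_sparse_group(v, 0.0, 0.5, slices, wg)
        manual = v.copy()
        for s, w in zip(slices, wg):
            nrm = np.linalg.norm(v[s])
            manual[s] = v[s] * max(1 - 0.5 * w / nrm, 0.0)
        assert out == pytest.approx(manual)

    def test_overlapping_slices_rejected(self):
        with pytest.raises(FitError, match="partition"):
            ev.prox_sparse_group(np.zeros(3), 0.1, 0.1,
                                 [np.array([0, 1]), np.array([1, 2])],
                                 np.ones(2))


class TestFit:
    def test_lambda_at_max_gives_null_model(self):
        X, rv, bg = random_problem(S=16, c=10, seed=4)
        lmax = ev.lambda_max(X, rv)
        model = ev.fit(X, rv, bg, ev.FitOptions(lam1=1.01 * lmax, lam2=0.0),
                       penalty="lasso")
        assert np.all(model.beta == 0.0)
        assert model.intercept == pytest.approx(_intercept_only(rv.y, rv.weights))

    def test_unregularized_fit_matches_reference_optimizer(self):
        """λ1=λ2=0 agrees with a generic BFGS fit on an 8×6 toy problem."""
        X, rv, bg = random_problem(S=8, c=6, seed=5)

        ridge = 1e-2  # keeps the near-separable toy strictly convex

        def f(theta):
            loss, g0, g = ev.logistic_objective(theta[0], theta[1:], X, rv.y,
                                                rv.weights)
            return (loss + ridge * theta[1:] @ theta[1:],
                    np.concatenate(([g0], g + 2 * ridge * theta[1:])))

        ref = minimize(f, np.zeros(7), jac=True, method="BFGS",
                       options={"gtol": 1e-12}).x
        model = ev.fit(X, rv, bg, ev.FitOptions(lam1=0.0, lam2=0.0,
                                                tolerance=1e-12),
                       penalty="ridge", ridge_lam=ridge)
        assert model.intercept == pytest.approx(ref[0], abs=1e-4)
        assert model.beta == pytest.approx(ref[1:], abs=1e-4)

    def test_planted_column_attains_largest_coefficient(self):
        rng = np.random.default_rng(6)
        S = 40
        y = np.concatenate([np.ones(15), -np.ones(25)])
        X = rng.integers(0, 2, size=(S, 51)).astype(float)
        X[:, 0] = (y > 0).astype(float)  # perfectly diagnostic column
        rv = ev.balance(
            ev.ResponseVector(taxa=[f"s{i}" for i in range(S)], y=y),
            mode="class_weights",
        )
        lmax = ev.lambda_max(X, rv)
        model = ev.fit(X, rv, None, ev.FitOptions(lam1=0.1 * lmax, lam2=0.0),
                       penalty="lasso")
        assert np.argmax(np.abs(model.beta)) == 0

    def test_objective_history_non_increasing(self):
        X, rv, bg = random_problem(S=20, c=12, seed=7)
        model = ev.fit(X, rv, bg, ev.FitOptions(lam1=0.01, lam2=0.01))
        h = np.array(model.objective_history)
        assert np.all(np.diff(h) <= 1e-12)
        assert model.objective <= h[0]

    def test_kkt_conditions_at_convergence(self):
        """Subgradient optimality of the lasso fit."""
        X, rv, _ = random_problem(S=20, c=12, seed=8)
        lam1 = 0.3 * ev.lambda_max(X, rv)
        tol = 1e-12
        model = ev.fit(X, rv, None,
                       ev.FitOptions(lam1=lam1, lam2=0.0, tolerance=tol),
                       penalty="lasso")
        _, g0, g = ev.logistic_objective(model.intercept, model.beta, X, rv.y,
                                         rv.weights)
        assert abs(g0) < 1e-6
        nz = model.beta != 0
        assert np.all(np.abs(g[nz] + lam1 * np.sign(model.beta[nz])) < 1e-5)
        assert np.all(np.abs(g[~nz]) <= lam1 + 1e-5)

    def test_sparsity_monotone_in_lambda(self):
        X, rv, bg = random_problem(S=30, c=20, seed=9)
        lmax = ev.lambda_max(X, rv)
        n_small = np.count_nonzero(
            ev.fit(X, rv, bg, ev.FitOptions(lam1=0.02 * lmax, lam2=0.0)).beta)
        n_large = np.count_nonzero(
            ev.fit(X, rv, bg, ev.FitOptions(lam1=0.2 * lmax, lam2=0.0)).beta)
        assert n_large <= n_small

    def test_empty_design_rejected(self):
        rv = ev.ResponseVector(taxa=["a", "b"], y=np.array([1.0, -1.0]))
        with pytest.raises(FitError, match="empty design"):
            ev.fit(np.zeros((2, 0)), rv, None, ev.FitOptions())

    def test_fixed_lipschitz_step_rule(self):
        X, rv, bg = random_problem(S=14, c=8, seed=10)
        m1 = ev.fit(X, rv, bg, ev.FitOptions(lam1=0.05, lam2=0.05,
                                             step_rule="lipschitz"))
        m2 = ev.fit(X, rv, bg, ev.FitOptions(lam1=0.05, lam2=0.05))
        assert m1.objective == pytest.approx(m2.objective, rel=1e-4)


class TestLambdaMax:
    def test_self_consistency(self):
        X, rv, _ = random_problem(S=25, c=15, seed=11)
        r = ev.lambda_max(X, rv)
        null = ev.fit(X, rv, None, ev.FitOptions(lam1=1.01 * r, lam2=0.0),
                      penalty="lasso")
        assert np.count_nonzero(null.beta) == 0
        dense = ev.fit(X, rv, None, ev.FitOptions(lam1=0.5 * r, lam2=0.0),
                       penalty="lasso")
        assert np.count_nonzero(dense.beta) >= 1

    def test_grid_spans_three_decades(self):
        grid = ev.default_lambda_grid(2.0)
        assert grid.size == 20
        assert grid[0] == pytest.approx(2.0)
        assert grid[-1] == pytest.approx(2e-3)


class TestCrossValidate:
    def test_null_grid_gives_log2_loss(self):
        X, rv, bg = random_problem(S=24, c=10, seed=12)
        # make classes balanced so the held-out null loss is exactly log 2
        rv = ev.ResponseVector(taxa=rv.taxa,
                               y=np.array([1.0, -1.0] * 12))
        lmax = ev.lambda_max(X, rv)
        l1, l2, table = ev.cross_validate(X, rv, bg, [2 * lmax], [0.0], k=3,
                                          seed=1)
        assert l1 == pytest.approx(2 * lmax)
        assert table["mean_cv_loss"].iloc[0] == pytest.approx(np.log(2), rel=1e-6)

    def test_duplicated_grid_points_identical(self):
        X, rv, bg = random_problem(S=24, c=10, seed=13)
        _, _, table = ev.cross_validate(X, rv, bg, [0.05, 0.05], [0.02], k=3,
                                        seed=2)
        assert table["mean_cv_loss"].iloc[0] == pytest.approx(
            table["mean_cv_loss"].iloc[1], rel=1e-9)

    def test_recovers_planted_gene(self, noisy_sim, noisy_design):
        X, y, bg = noisy_design
        lmax = ev.lambda_max(X, y)
        l1, l2, _ = ev.cross_validate(
            X, y, bg, lmax * np.array([0.5, 0.05]), lmax * np.array([0.05]),
            k=3, seed=3)
        model = ev.fit(X, y, bg, ev.FitOptions(lam1=l1, lam2=l2))
        assert set(noisy_sim.truth.diagnostic_genes) <= set(
            model.nonzero_groups(bg))

    def test_stratification_guard(self):
        X, rv, bg = random_problem(S=10, c=6, seed=14)
        rv = ev.ResponseVector(taxa=rv.taxa,
                               y=np.array([1.0] * 2 + [-1.0] * 8))
        with pytest.raises(FitError, match="stratify"):
            ev.cross_validate(X, rv, bg, [0.1], [0.1], k=5, seed=0)


class TestStabilitySelect:
    def test_planted_gene_high_frequency(self, noisy_sim, noisy_design):
        X, y, bg = noisy_design
        opts = ev.default_options(X, y)
        freq = ev.stability_select(X, y, bg, opts, subsample_fraction=0.5,
                                   reps=50, seed=4)
        planted = noisy_sim.truth.diagnostic_genes[0]
        assert freq[planted] >= 0.9

    def test_noise_frequencies_below_planted(self, noise_sim, noisy_sim,
                                             noisy_design):
        X, y, bg = noisy_design
        opts = ev.default_options(X, y)
        planted_freq = ev.stability_select(X, y, bg, opts, reps=25, seed=5)[
            noisy_sim.truth.diagnostic_genes[0]]
        Xn, bgn = ev.prepare_design(noise_sim.alignment, noise_sim.groups)
        yn = ev.balance(ev.build_response(noise_sim.alignment.taxa,
                                          noise_sim.positives))
        lmax = ev.lambda_max(Xn, yn)
        strong = ev.FitOptions(lam1=0.3 * lmax, lam2=0.3 * lmax)
        noise_freq = ev.stability_select(Xn, yn, bgn, strong, reps=25, seed=5)
        assert noise_freq.max() < planted_freq

    def test_seed_determinism(self, noisy_design):
        X, y, bg = noisy_design
        opts = ev.default_options(X, y)
        a = ev.stability_select(X, y, bg, opts, reps=2, seed=6)
        b = ev.stability_select(X, y, bg, opts, reps=2, seed=6)
        assert a.equals(b)


class TestRefitSelected:
    def setup_models(self, noisy_design):
        X, y, bg = noisy_design
        opts = ev.default_options(X, y)
        select = ev.fit(X, y, bg, opts)
        selected = select.nonzero_groups(bg)
        return X, y, bg, opts, select, selected

    def test_refit_does_not_increase_training_loss(self, noisy_design):
        X, y, bg, opts, select, selected = self.setup_models(noisy_design)
        refit = ev.refit_selected(X, y, bg, selected, opts=opts)
        loss_sel, _, _ = ev.logistic_objective(select.intercept, select.beta,
                                               X.X, y.y, y.weights)
        loss_ref, _, _ = ev.logistic_objective(refit.intercept, refit.beta,
                                               X.X, y.y, y.weights)
        assert loss_ref <= loss_sel + 1e-9

    def test_refit_support_within_selection(self, noisy_design):
        X, y, bg, opts, select, selected = self.setup_models(noisy_design)
        refit = ev.refit_selected(X, y, bg, selected, opts=opts)
        assert set(refit.nonzero_groups(bg)) <= set(selected)

    def test_zero_lambda_group_lasso_is_unpenalized(self):
        X, rv, bg = random_problem(S=20, c=8, seed=15)
        refit = ev.refit_selected(X, rv, bg, ["g0", "g1"], lam_refit=0.0,
                                  opts=ev.FitOptions(tolerance=1e-10))
        plain = ev.fit(X, rv, bg, ev.FitOptions(lam1=0.0, lam2=0.0,
                                                tolerance=1e-10),
                       penalty="none")
        assert refit.intercept == pytest.approx(plain.intercept, abs=1e-3)
        assert refit.beta == pytest.approx(plain.beta, abs=1e-3)

    def test_strong_ridge_shrinks_to_log_odds(self):
        X, rv, bg = random_problem(S=20, c=8, seed=16)
        refit = ev.refit_selected(X, rv, bg, ["g0", "g1"], lam_refit=1e6,
                                  mode="ridge")
        assert np.max(np.abs(refit.beta)) < 1e-4
        assert refit.intercept == pytest.approx(
            _intercept_only(rv.y, rv.weights), abs=1e-3)

    def test_empty_selection_rejected(self):
        X, rv, bg = random_problem()
        with pytest.raises(FitError, match="empty"):
            ev.refit_selected(X, rv, bg, [])


def test_model_json_roundtrip_metadata(noisy_design):
    X, y, bg = noisy_design
    model = ev.fit(X, y, bg, ev.default_options(X, y))
    import json

    blob = json.loads(model.to_json())
    assert blob["penalty"] == "sparse_group"
    assert len(blob["coefficients"]) == model.beta.size
    assert blob["coefficients"][0].keys() == {"position", "state", "group", "beta"}
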