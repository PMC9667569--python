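"""Unit tests for the factorization building blocks and solver."""

import dataclasses

import numpy as np
import pytest

from screenmf.data import StateMatrix, TimeGrid, WeightMatrix
from screenmf.factorization import (
    FactorizationConfig,
    build_weights,
    fit,
    make_regularizer,
    mle_theta,
    objective,
    reconstruction_error,
    search_shifts,
    shift_profiles,
    shifted_latent,
    update_coefficients,
    update_profiles,
    variant_config,
)
from screenmf.synthetic import discretize_states

from conftest import model_from_latent, random_state_matrix


class TestRegularizer:
    def test_difference_annihilates_constants(self):
        r = make_regularizer("difference", 6)
        assert np.allclose(r.matrix @ np.ones(6), 0.0)

    def test_difference_of_profile(self):
        r = make_regularizer("difference", 3)
        assert np.allclose(r.matrix @ np.array([1.0, 3.0, 6.0]), [2.0, 3.0])

    def test_damped_neighbor_factor(self):
        # K at |i-j| = 1 carries a factor e^-1
        d = make_regularizer("difference", 5).matrix
        kd = make_regularizer("damped_difference", 5, gamma=1.0).matrix
        k = kd @ np.linalg.pinv(d)
        assert np.isclose(k[0, 1], np.exp(-1.0))
        assert np.isclose(k[0, 0], 1.0)

    def test_damped_requires_gamma(self):
        with pytest.raises(ValueError):
            make_regularizer("damped_difference", 5)

    def test_gamma_limit_recovers_difference(self):
        """As gamma grows the damped operator converges to the plain
        forward difference (relative gap < 1e-6 at gamma = 50)."""
        rng = np.random.default_rng(0)
        v = rng.standard_normal((12, 3))
        d = make_regularizer("difference", 12).matrix
        kd = make_regularizer("damped_difference", 12, gamma=50.0).matrix
        a = np.sum((d @ v) ** 2)
        b = np.sum((kd @ v) ** 2)
        assert abs(a - b) / a < 1e-6


class TestWeights:
    def test_uniform_is_mask(self, small_matrix):
        w = build_weights(small_matrix, "uniform")
        assert np.array_equal(w.weights, small_matrix.mask.astype(float))

    def test_inverse_propensity_arithmetic(self):
        grid = TimeGrid(4)
        m = StateMatrix(
            np.array([[1, 0, 2, 0]]), np.array([[True, False, True, False]]), grid
        )
        w = build_weights(
            m,
            "inverse_propensity",
            propensity_table=np.array([0.5, 0.5, 0.25, 0.5]),
            state_confidence_table={1: 1.0, 2: 1.0},
        )
        assert w.weights[0, 0] == 2.0  # 1.0 / 0.5
        assert w.weights[0, 2] == 4.0  # 1.0 / 0.25

    def test_unobserved_cells_zero_in_all_modes(self, small_matrix):
        for mode in ("uniform", "inverse_propensity"):
            w = build_weights(small_matrix, mode)
            assert np.all(w.weights[~small_matrix.mask] == 0.0)

    def test_nonpositive_propensity_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            build_weights(
                small_matrix,
                "inverse_propensity",
                propensity_table=np.zeros(small_matrix.n_bins),
            )


class TestObjective:
    def test_zero_factors_leave_weighted_data_term(self, small_matrix):
        w = build_weights(small_matrix, "uniform")
        model = model_from_latent(np.zeros(small_matrix.values.shape))
        model.U = np.zeros_like(model.U)
        model.V = np.zeros_like(model.V)
        expected = float(np.sum((w.weights * small_matrix.values) ** 2))
        assert np.isclose(objective(small_matrix, w, model), expected)

    def test_perfect_fit_zero_coefficients_is_zero(self, small_matrix):
        w = build_weights(small_matrix, "uniform")
        model = model_from_latent(small_matrix.values.astype(float))
        model.config = dataclasses.replace(model.config, reg_coefficients=(0.0, 0.0, 0.0))
        assert objective(small_matrix, w, model) == 0.0

    def test_matches_term_by_term_oracle(self):
        """Objective equals an independent cell-by-cell summation on a
        3x4, rank-2 fixture with weights, shifts and R = KD."""
        rng = np.random.default_rng(3)
        n, t, r = 3, 4, 2
        vals = rng.integers(1, 5, (n, t))
        mask = rng.random((n, t)) < 0.8
        mask[:, 0] = True
        m = StateMatrix(np.where(mask, vals, 0), mask, TimeGrid(t))
        w = np.where(mask, rng.uniform(0.5, 1.5, (n, t)), 0.0)
        U = rng.standard_normal((n, r))
        V = rng.standard_normal((t, r))
        shifts = np.array([0, 1, -1])
        reg = make_regularizer("damped_difference", t, gamma=0.7)
        b = (0.3, 0.4, 0.5)

        total = 0.0
        for i in range(n):
            for j in range(t):
                latent = 0.0
                if 0 <= j - shifts[i] < t:
                    for k in range(r):
                        latent += U[i, k] * V[j - shifts[i], k]
                y = vals[i, j] if mask[i, j] else 0.0
                total += (w[i, j] * (y - latent)) ** 2
        for i in range(n):
            for k in range(r):
                total += b[0] * U[i, k] ** 2
        for j in range(t):
            for k in range(r):
                total += b[1] * V[j, k] ** 2
        rv = reg.matrix @ V
        for j in range(t - 1):
            for k in range(r):
                total += b[2] * rv[j, k] ** 2

        model = model_from_latent(np.zeros((n, t)))
        model.U, model.V, model.shifts = U, V, shifts
        model.regularizer = reg
        model.config = dataclasses.replace(
            model.config, reg_coefficients=b, rank=r
        )
        got = objective(m, WeightMatrix(w), model)
        assert np.isclose(got, total, rtol=1e-12)


class TestBlockUpdates:
    def test_coefficient_update_least_squares_identity(self, rng):
        # full observation, unit weights, orthonormal profiles, beta1 = 0
        n, t, r = 5, 8, 2
        vals = rng.integers(1, 5, (n, t))
        m = StateMatrix(vals, np.ones((n, t), bool), TimeGrid(t))
        w = build_weights(m, "uniform")
        v, _ = np.linalg.qr(rng.standard_normal((t, r)))
        u = update_coefficients(m, w, v, np.zeros(n, dtype=int), 0.0)
        assert np.allclose(u, vals @ v)

    def test_profile_update_least_squares_identity(self, rng):
        n, t, r = 8, 5, 2
        vals = rng.integers(1, 5, (n, t))
        m = StateMatrix(vals, np.ones((n, t), bool), TimeGrid(t))
        w = build_weights(m, "uniform")
        u, _ = np.linalg.qr(rng.standard_normal((n, r)))
        reg = make_regularizer("damped_difference", t, gamma=1.0)
        v = update_profiles(m, w, u, np.zeros(n, dtype=int), 0.0, 0.0, reg)
        assert np.allclose(v, vals.T @ u)

    def test_large_penalties_shrink_to_zero(self, small_matrix, rng):
        w = build_weights(small_matrix, "uniform")
        v = rng.standard_normal((small_matrix.n_bins, 2))
        z = np.zeros(small_matrix.n_subjects, dtype=int)
        u = update_coefficients(small_matrix, w, v, z, 1e12)
        assert np.all(np.abs(u) < 1e-6)
        u2 = rng.standard_normal((small_matrix.n_subjects, 2))
        reg = make_regularizer("difference", small_matrix.n_bins)
        v2 = update_profiles(small_matrix, w, u2, z, 1e12, 0.0, reg)
        assert np.all(np.abs(v2) < 1e-6)

    def test_singular_coefficient_update_advises_ridge(self, rng):
        t = 6
        vals = np.ones((2, t), dtype=int)
        mask = np.ones((2, t), bool)
        mask[1] = False  # second subject entirely unobserved
        m = StateMatrix(np.where(mask, vals, 0), mask, TimeGrid(t))
        w = build_weights(m, "uniform")
        v = rng.standard_normal((t, 2))
        with pytest.raises(ValueError, match="beta1"):
            update_coefficients(m, w, v, np.zeros(2, dtype=int), 0.0)

    def test_singular_profile_update_advises_ridge(self, rng):
        t = 6
        mask = np.ones((3, t), bool)
        mask[:, 3] = False  # one time bin never observed
        vals = np.where(mask, 2, 0)
        m = StateMatrix(vals, mask, TimeGrid(t))
        w = build_weights(m, "uniform")
        u = rng.standard_normal((3, 2))
        reg = make_regularizer("difference", t)
        with pytest.raises(ValueError, match="beta2"):
            update_profiles(m, w, u, np.zeros(3, dtype=int), 0.0, 0.0, reg)


class TestShiftSearch:
    def test_zero_bound_gives_zero_shifts(self, small_matrix, rng):
        w = build_weights(small_matrix, "uniform")
        u = rng.standard_normal((small_matrix.n_subjects, 2))
        v = rng.standard_normal((small_matrix.n_bins, 2))
        assert np.all(search_shifts(small_matrix, w, u, v, 0) == 0)

    def test_recovers_known_offset_noiselessly(self):
        """A row equal to the profile translated by +2 bins is assigned
        shift +2 by exhaustive search (enumeration oracle)."""
        t = 20
        profile = np.clip(1 + np.bincount([8, 9, 10, 11], minlength=t) * 2, 1, 4).astype(float)
        v = profile[:, None]
        u = np.ones((1, 1))
        row = np.full(t, 1.0)
        row[2:] = profile[: t - 2]  # profile translated +2, baseline at the edge
        m = StateMatrix(row[None, :].astype(int), np.ones((1, t), bool), TimeGrid(t))
        w = build_weights(m, "uniform")
        z = search_shifts(m, w, u, v, 4)
        # independent oracle: enumerate all candidate offsets
        best = min(
            range(-4, 5),
            key=lambda c: (np.sum((row - (u @ shift_profiles(v, c).T)[0]) ** 2), abs(c), c > 0),
        )
        assert z[0] == 2 == best

    def test_tie_breaks_toward_zero_then_negative(self):
        t = 6
        vals = np.ones((1, t), dtype=int)
        m = StateMatrix(vals, np.ones((1, t), bool), TimeGrid(t))
        w = build_weights(m, "uniform")
        # constant profile: every shift ties (up to boundary padding);
        # interior-safe constant row -> shift 0 wins the tie
        u = np.ones((1, 1))
        v = np.ones((t, 1))
        assert search_shifts(m, w, u, v, 2)[0] == 0

    def test_bound_validation(self, small_matrix, rng):
        u = rng.standard_normal((small_matrix.n_subjects, 1))
        v = rng.standard_normal((small_matrix.n_bins, 1))
        w = build_weights(small_matrix, "uniform")
        with pytest.raises(ValueError):
            search_shifts(small_matrix, w, u, v, 13)


class TestFit:
    def test_recovers_noiseless_rank_one(self):
        u = np.array([1, 2, 1, 2, 1])
        v = np.array([1, 2, 1, 2, 1, 2, 1, 2])
        vals = np.outer(u, v)
        m = StateMatrix(vals, np.ones(vals.shape, bool), TimeGrid(8))
        config = FactorizationConfig(
            rank=1, reg_coefficients=(1e-8, 1e-8, 1e-8), regularizer="difference",
            max_iter=200, seed=0,
        )
        model = fit(m, config)
        rel = np.linalg.norm(model.latent() - vals) / np.linalg.norm(vals)
        assert rel < 1e-3

    def test_objective_monotone_and_converged(self, small_matrix):
        model = fit(small_matrix, variant_config("CMF", rank=2, max_iter=500, seed=0))
        obj = model.objective_history
        assert np.all(np.diff(obj) <= 1e-10 * np.abs(obj[:-1]))
        assert model.converged

    def test_same_seed_identical_model(self, small_matrix):
        cfg = variant_config("SCMF", rank=2, max_iter=40, seed=7)
        a, b = fit(small_matrix, cfg), fit(small_matrix, cfg)
        assert np.array_equal(a.U, b.U)
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.shifts, b.shifts)
        assert a.theta == b.theta

    def test_non_convergence_flagged(self, small_matrix):
        model = fit(small_matrix, variant_config("CMF", rank=2, max_iter=2, seed=0))
        assert not model.converged

    def test_common_shift_recovery_matches_generating_discrepancy(self):
        """Data built from a known model with a constant shift: the fitted
        model's discrepancy on observed cells is within 1% of (or better
        than) the generating model's."""
        rng = np.random.default_rng(5)
        n, t = 30, 30
        base = 1.0 + 2.5 * np.exp(-0.02 * (np.arange(t) - 12.0) ** 2)
        u_true = rng.uniform(0.8, 1.2, (n, 1))
        v_true = base[:, None]
        z_true = np.full(n, 3)
        latent = shifted_latent(u_true, v_true, z_true)
        vals = discretize_states(np.clip(latent, 1, 4), theta=20.0, seed=1)
        mask = rng.random((n, t)) < 0.6
        mask[:, 0] = True
        m = StateMatrix(np.where(mask, vals, 0), mask, TimeGrid(t))
        gen_disc = float(np.sum(((vals - latent) * mask) ** 2))
        cfg = FactorizationConfig(
            rank=1, reg_coefficients=(1e-6, 1e-6, 1e-6), max_shift_bins=6,
            max_iter=100, seed=0,
        )
        model = fit(m, cfg)
        fit_disc = float(np.sum(((vals - model.latent()) * mask) ** 2))
        assert fit_disc <= 1.01 * gen_disc


class TestThetaMLE:
    def test_closed_form_unit_residuals(self):
        grid = TimeGrid(4)
        m = StateMatrix(
            np.array([[1, 2, 1, 2]]), np.ones((1, 4), bool), grid
        )
        latent = np.array([[2.0, 1.0, 2.0, 1.0]])  # residuals all +-1
        assert mle_theta(m, latent) == pytest.approx(4 / (2 * 4))

    def test_quarter_scaling_law(self, small_matrix, rng):
        latent = small_matrix.values + np.where(small_matrix.mask, 0.1, 0.0)
        t1 = mle_theta(small_matrix, latent)
        latent2 = small_matrix.values + np.where(small_matrix.mask, 0.2, 0.0)
        assert mle_theta(small_matrix, latent2) == pytest.approx(t1 / 4)

    def test_degenerate_perfect_fit_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="degenerate"):
            mle_theta(small_matrix, small_matrix.values.astype(float))


class TestReconstructionError:
    def test_zero_when_exact(self, rng):
        truth = rng.standard_normal((4, 6))
        mask = rng.random((4, 6)) < 0.5
        assert reconstruction_error(truth, truth, mask) == 0.0

    def test_constant_residual_squares(self, rng):
        truth = rng.standard_normal((4, 6))
        mask = np.zeros((4, 6), bool)
        mask[0, 0] = True
        est = truth + 0.3
        assert reconstruction_error(truth, est, mask) == pytest.approx(0.3**2)

    def test_matches_loop_oracle(self, rng):
        truth = rng.standard_normal((5, 6))
        est = rng.standard_normal((5, 6))
        mask = rng.random((5, 6)) < 0.4
        total, count = 0.0, 0
        for i in range(5):
            for j in range(6):
                if not mask[i, j]:
                    total += (truth[i, j] - est[i, j]) ** 2
                    count += 1
        assert reconstruction_error(truth, est, mask) == pytest.approx(total / count)

    def test_full_observation_rejected(self, rng):
        truth = rng.standard_normal((3, 3))
        with pytest.raises(ValueError):
            reconstruction_error(truth, truth, np.ones((3, 3), bool))
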