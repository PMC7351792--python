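import numpy as np
import pytest

from otdr import popdata
from otdr.popdata import Condition, ConditionDesign, PopulationResponse, TrialCounts
from otdr.otdr_core import (EpochSpec, RegressionAxes, epoch_average,
                            fit_static_axes, fit_previous_trial_axes)


def make_population(tensor, bin_width=0.1, t0=0.0, conditions=None):
    tensor = np.asarray(tensor, dtype=float)
    N, C, T = tensor.shape
    if conditions is None:
        conditions = [Condition(o, ch) for ch in (0, 1)
                      for o in (0, 1, 2, 4, 8)][:C]
    return PopulationResponse(
        tensor=tensor, cc=tensor.mean(axis=1), mean_subtracted=False,
        bin_starts=t0 + bin_width * np.arange(T), bin_width=bin_width,
        alignment="offer", condition_index=conditions,
        zmean=np.zeros(N), zstd=np.ones(N))


def wls_per_unit(R, P, w):
    """Independent closed-form weighted least-squares oracle (one epoch)."""
    X = np.column_stack([np.ones(P.shape[0]), P])
    B = np.zeros((R.shape[0], P.shape[1]))
    B0 = np.zeros(R.shape[0])
    for n in range(R.shape[0]):
        W = np.diag(w[n] ** 2)
        coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ R[n])
        B0[n], B[n] = coef[0], coef[1:]
    return B, B0


class TestEpochAverage:
    def test_single_bin_epoch_returns_slice(self):
        tensor = np.random.default_rng(0).normal(size=(3, 4, 5))
        pop = make_population(tensor)
        np.testing.assert_array_equal(epoch_average(pop, [2]), tensor[:, :, 2])

    def test_three_bin_arithmetic_mean(self):
        tensor = np.zeros((2, 2, 3))
        tensor[:, :, 0] = 1.0
        tensor[:, :, 1] = 2.0
        tensor[:, :, 2] = 6.0
        pop = make_population(tensor)
        np.testing.assert_allclose(epoch_average(pop, [0, 1, 2]), 3.0)

    def test_empty_bin_set_rejected(self):
        pop = make_population(np.zeros((2, 2, 3)))
        with pytest.raises(ValueError, match="empty"):
            epoch_average(pop, [])


class TestStaticAxes:
    def _design(self, C=9, K=1, seed=0, correlated=False):
        rng = np.random.default_rng(seed)
        P = rng.random((C, K))
        if correlated and K >= 2:
            P[:, 1] = 0.8 * P[:, 0] + 0.2 * P[:, 1]
        P = (P - P.min(0)) / (P.max(0) - P.min(0))
        conds = [Condition(o, ch) for ch in (0, 1) for o in (0, 1, 2, 4, 8)][:C]
        names = ["benefit", "choice", "expected_reward"][:K]
        return ConditionDesign(P, names, conds)

    def test_noiseless_single_variable_exact_recovery(self):
        """Data built exactly as b0 1' + b p' is recovered to machine precision."""
        rng = np.random.default_rng(1)
        N, C, T = 8, 9, 6
        design = self._design(C)
        b = rng.normal(size=N)
        b0 = rng.normal(size=N)
        slab = b0[:, None] + np.outer(b, design.P[:, 0])
        tensor = np.repeat(slab[:, :, None], T, axis=2)
        pop = make_population(tensor, conditions=design.conditions)
        M = TrialCounts(np.full((N, C), 7), design.conditions)
        spec = EpochSpec(epochs={"all": (0.0, 0.6)},
                         assignment={"benefit": "all"})
        axes = fit_static_axes(pop, design, M, spec)
        assert axes.objective_value == pytest.approx(0.0, abs=1e-8)
        cos = abs(axes.B[:, 0] @ (b / np.linalg.norm(b)))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_unconstrained_matches_wls_oracle(self):
        """K=1 with unequal M equals closed-form per-unit WLS."""
        rng = np.random.default_rng(2)
        N, C, T = 6, 9, 4
        design = self._design(C, seed=3)
        tensor = rng.normal(size=(N, C, T))
        pop = make_population(tensor, conditions=design.conditions)
        Mmat = rng.integers(5, 60, size=(N, C))
        M = TrialCounts(Mmat, design.conditions)
        spec = EpochSpec(epochs={"all": (0.0, 0.4)},
                         assignment={"benefit": "all"})
        axes = fit_static_axes(pop, design, M, spec, orthogonalize=False)
        R = tensor.mean(axis=2)
        B_or, _ = wls_per_unit(R, design.P, np.sqrt(Mmat))
        expect = B_or[:, 0] / np.linalg.norm(B_or[:, 0])
        got = axes.B[:, 0]
        if got @ expect < 0:
            expect = -expect
        np.testing.assert_allclose(got, expect, atol=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_constrained_beats_random_frames(self, seed):
        """N=4, C=6, K=2 correlated predictors: the solver's objective is no
        worse than the best of many random orthonormal frames, each given the
        optimal constants and scalings."""
        rng = np.random.default_rng(seed)
        N, C = 4, 6
        design = self._design(C, K=2, seed=seed, correlated=True)
        tensor = rng.normal(size=(N, C, 1))
        pop = make_population(tensor, conditions=design.conditions)
        Mmat = rng.integers(5, 30, size=(N, C))
        M = TrialCounts(Mmat, design.conditions)
        spec = EpochSpec(epochs={"all": (0.0, 0.1)},
                         assignment={"benefit": "all", "choice": "all"})
        axes = fit_static_axes(pop, design, M, spec, restarts=10, seed=seed)
        assert axes.orthogonalized
        # brute-force lower bound over random orthonormal frames
        R = tensor[:, :, 0]
        w = np.sqrt(Mmat)
        best = np.inf
        X = np.column_stack([np.ones(C), design.P])
        for _ in range(10_000):
            Q, _r = np.linalg.qr(rng.standard_normal((N, 2)))
            # optimal (b0 per unit, s shared) by exact linear solve
            A_rows, b_rows = [], []
            n_unk = 2 + N
            A = np.zeros((N * C, n_unk))
            y = np.zeros(N * C)
            for n in range(N):
                sl = slice(n * C, (n + 1) * C)
                y[sl] = R[n] * w[n]
                A[sl, 0] = Q[n, 0] * design.P[:, 0] * w[n]
                A[sl, 1] = Q[n, 1] * design.P[:, 1] * w[n]
                A[sl, 2 + n] = w[n]
            sol, res, *_ = np.linalg.lstsq(A, y, rcond=None)
            sse = float(np.sum((A @ sol - y) ** 2))
            best = min(best, sse)
        assert axes.objective_value <= best + 1e-9

    def test_orthogonality_constraint_enforced(self):
        rng = np.random.default_rng(4)
        N, C = 12, 9
        design = self._design(C, K=2, seed=5, correlated=True)
        tensor = rng.normal(size=(N, C, 3))
        pop = make_population(tensor, conditions=design.conditions)
        M = TrialCounts(np.full((N, C), 10), design.conditions)
        spec = EpochSpec(epochs={"all": (0.0, 0.3)},
                         assignment={"benefit": "all", "choice": "all"})
        con = fit_static_axes(pop, design, M, spec, restarts=3, seed=0)
        unc = fit_static_axes(pop, design, M, spec, orthogonalize=False)
        assert abs(con.B[:, 0] @ con.B[:, 1]) <= 1e-6
        # constraining can never decrease the optimum
        assert con.objective_value >= unc.objective_value - 1e-9

    def test_weighting_unchanged_by_doubling_trials(self):
        rng = np.random.default_rng(6)
        N, C = 5, 9
        design = self._design(C, K=2, seed=7)
        tensor = rng.normal(size=(N, C, 2))
        pop = make_population(tensor, conditions=design.conditions)
        M1 = TrialCounts(rng.integers(5, 40, size=(N, C)), design.conditions)
        M2 = TrialCounts(2 * M1.M, design.conditions)
        spec = EpochSpec(epochs={"all": (0.0, 0.2)},
                         assignment={"benefit": "all", "choice": "all"})
        a1 = fit_static_axes(pop, design, M1, spec, restarts=3, seed=1)
        a2 = fit_static_axes(pop, design, M2, spec, restarts=3, seed=1)
        np.testing.assert_allclose(np.abs(a1.B.T @ a2.B),
                                   np.eye(2), atol=1e-4)

    def test_multivariate_ols_equivalence_constant_M(self):
        """One epoch, constant M, no constraint: column-normalized ordinary
        least squares coefficients."""
        rng = np.random.default_rng(8)
        N, C = 7, 9
        design = self._design(C, K=3, seed=9)
        tensor = rng.normal(size=(N, C, 2))
        pop = make_population(tensor, conditions=design.conditions)
        M = TrialCounts(np.full((N, C), 13), design.conditions)
        spec = EpochSpec(epochs={"all": (0.0, 0.2)},
                         assignment={v: "all" for v in design.variables})
        axes = fit_static_axes(pop, design, M, spec, orthogonalize=False)
        X = np.column_stack([np.ones(C), design.P])
        coefs = np.linalg.lstsq(X, tensor.mean(axis=2).T, rcond=None)[0][1:]
        for j in range(3):
            expect = coefs[j] / np.linalg.norm(coefs[j])
            got = axes.B[:, j]
            if got @ expect < 0:
                expect = -expect
            np.testing.assert_allclose(got, expect, atol=1e-6)

    def test_rank_deficient_design_rejected(self):
        conds = [Condition(o, 1) for o in (0, 1, 2, 4, 8)]
        P = np.column_stack([np.linspace(0, 1, 5), np.linspace(0, 1, 5)])
        design = ConditionDesign(P, ["benefit", "expected_reward"], conds)
        pop = make_population(np.random.default_rng(0).normal(size=(4, 5, 2)),
                              conditions=conds)
        M = TrialCounts(np.full((4, 5), 8), conds)
        spec = EpochSpec(epochs={"all": (0.0, 0.2)},
                         assignment={"benefit": "all", "expected_reward": "all"})
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_static_axes(pop, design, M, spec)


class TestPreviousTrialAxes:
    def test_matches_present_fit_on_same_window(self):
        """With identical inputs, the previous-trial entry point reduces to a
        single-epoch present fit on T3."""
        rng = np.random.default_rng(10)
        N, C = 6, 9
        conds = [Condition(o, ch) for ch in (0, 1) for o in (0, 1, 2, 4, 8)][:C]
        design = popdata.build_design(
            conds, ("prev_benefit", "prev_choice", "experienced_reward"))
        tensor = rng.normal(size=(N, C, 10))
        pop = make_population(tensor, t0=-0.5, conditions=conds)
        M = TrialCounts(np.full((N, C), 9), conds)
        prev = fit_previous_trial_axes(pop, design, M, t3_window=(-0.5, 0.0),
                                       restarts=2, seed=0)
        spec = EpochSpec(epochs={"T3": (-0.5, 0.0)},
                         assignment={v: "T3" for v in design.variables})
        direct = fit_static_axes(pop, design, M, spec, restarts=2, seed=0)
        np.testing.assert_allclose(prev.B, direct.B, atol=1e-8)
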