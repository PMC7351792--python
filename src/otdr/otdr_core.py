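"""Static regression axes (sRAs) by optimal targeted dimensionality reduction.

A single trial-count-weighted least-squares objective is solved over all
temporal epochs at once:

    min_{B, B0}  sum_e || (Rbar^(e) - b0^(e) 1' - sum_k b_k P_k') . sqrt(M) ||_F^2

optionally subject to mutual orthogonality of a group of coefficient columns.
The orthogonality constraint makes the problem non-convex; the constrained
column block is parameterized as Q diag(s) with Q an orthonormal frame
(a point on the Stiefel manifold), and the solver alternates an exact linear
solve for (B0, s, unconstrained columns) with a projected Riemannian gradient
step on Q (QR retraction, backtracking line search).  Unconstrained fits have
a closed form (per-unit weighted least squares) and skip the iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .popdata import ConditionDesign, PopulationResponse, TrialCounts

__all__ = [
    "EpochSpec", "RegressionAxes", "ConvergenceError",
    "epoch_average", "fit_static_axes", "fit_previous_trial_axes",
]


class ConvergenceError(RuntimeError):
    """Solver failed to converge; carries the best iterate found."""

    def __init__(self, msg, axes=None, grad_norm=None):
        super().__init__(msg)
        self.axes = axes
        self.grad_norm = grad_norm


@dataclass
class EpochSpec:
    """Which time bins define each epoch, and which variable is fit where.

    ``epochs`` maps epoch name -> (t_start, t_stop) in seconds (left-closed,
    right-open, relative to the alignment event).  ``assignment`` maps each
    fitted variable to the epoch(s) it is fit in; a variable fit in several
    epochs gets one coefficient column per (variable, epoch) pair.
    ``orthogonality`` lists groups of columns (referenced by variable name)
    constrained to be mutually orthogonal; ``None`` means all columns form a
    single group.  ``denoise_D`` optionally projects the axes onto the top-D
    principal components of the full-trial data (off by default).
    """

    epochs: dict
    assignment: dict
    orthogonality: list | None = None
    denoise_D: int | None = None

    def bins(self, name: str, bin_starts: np.ndarray, bin_width: float) -> np.ndarray:
        t0, t1 = self.epochs[name]
        centers = bin_starts + bin_width / 2
        idx = np.nonzero((centers >= t0) & (centers < t1))[0]
        if idx.size == 0:
            raise ValueError(f"epoch {name!r} contains no time bins")
        return idx

    def columns(self) -> list:
        """Fitted columns as (variable, epoch) pairs, in declaration order."""
        cols = []
        for var, eps in self.assignment.items():
            for ep in ([eps] if isinstance(eps, str) else eps):
                if ep not in self.epochs:
                    raise ValueError(f"unknown epoch {ep!r} for variable {var!r}")
                cols.append((var, ep))
        return cols

    def orthogonal_group(self) -> list:
        """Column indices constrained mutually orthogonal."""
        cols = self.columns()
        if self.orthogonality is None:
            return list(range(len(cols)))
        group = []
        for var in self.orthogonality:
            group.extend(i for i, (v, _) in enumerate(cols) if v == var)
        return group


@dataclass
class RegressionAxes:
    """Unit-norm static regression axes with per-epoch constants."""

    B: np.ndarray                 # N x K, unit-norm columns
    B0: np.ndarray                # N x E constants
    columns: list                 # (variable, epoch) per column of B
    epoch_names: list             # per column of B0
    orthogonalized: bool
    objective_value: float
    spec: EpochSpec | None = None
    design_variables: list = field(default_factory=list)

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.B, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("sRA columns must be unit vectors")

    def axis(self, variable: str) -> np.ndarray:
        for j, (v, _) in enumerate(self.columns):
            if v == variable:
                return self.B[:, j]
        raise KeyError(variable)


# ---------------------------------------------------------------------------


def epoch_average(pop: PopulationResponse, bins: np.ndarray) -> np.ndarray:
    """Mean over the epoch's time bins -> N x C response matrix."""
    bins = np.asarray(bins, dtype=int)
    if bins.size == 0:
        raise ValueError("empty bin set")
    if bins.min() < 0 or bins.max() >= pop.n_bins:
        raise ValueError("epoch bins out of range")
    return pop.tensor[:, :, bins].mean(axis=2)


def _epoch_matrices(pop, design, M, spec):
    """Per-epoch (Rbar, sqrtM, P columns) restricted to design conditions."""
    cond_idx = [pop.condition_index.index(c) for c in design.conditions]
    sqrtM = np.sqrt(M.M[:, [M.conditions.index(c) for c in design.conditions]])
    cols = spec.columns()
    out = {}
    for name in spec.epochs:
        bins = spec.bins(name, pop.bin_starts, pop.bin_width)
        R = epoch_average(pop, bins)[:, cond_idx]
        k_idx = [j for j, (_, ep) in enumerate(cols) if ep == name]
        P = np.column_stack([design.column(cols[j][0]) for j in k_idx]) \
            if k_idx else np.zeros((len(design.conditions), 0))
        out[name] = (R, P, k_idx)
    return out, sqrtM, cols


def _objective(mats, sqrtM, B, B0, epoch_names):
    f = 0.0
    for e, name in enumerate(epoch_names):
        R, P, k_idx = mats[name]
        resid = R - B0[:, [e]] - (B[:, k_idx] @ P.T if k_idx else 0.0)
        f += float(np.sum((resid * sqrtM) ** 2))
    return f


def _unconstrained_wls(mats, sqrtM, epoch_names, n_units, n_cols):
    """Closed-form per-unit weighted least squares, per epoch."""
    B = np.zeros((n_units, n_cols))
    B0 = np.zeros((n_units, len(epoch_names)))
    for e, name in enumerate(epoch_names):
        R, P, k_idx = mats[name]
        X = np.column_stack([np.ones(P.shape[0]), P])
        for n in range(n_units):
            w = sqrtM[n]
            coef, *_ = np.linalg.lstsq(X * w[:, None], R[n] * w, rcond=None)
            B0[n, e] = coef[0]
            for j, k in enumerate(k_idx):
                B[n, k] = coef[1 + j]
    return B, B0


def _linear_subproblem(mats, sqrtM, epoch_names, Q, group, free, n_units):
    """Exact solve for (B0, scalings of constrained columns, free columns).

    Unknowns: s (len(group)) shared across units; per unit, one constant per
    epoch and one coefficient per free column.  Weighted least squares
    assembled densely; the problem is small (N*(E+F)+|group| unknowns).
    """
    E = len(epoch_names)
    F = len(free)
    n_s = len(group)
    n_per_unit = E + F
    n_unknown = n_s + n_units * n_per_unit
    rows = []
    rhs = []
    col_in_group = {k: a for a, k in enumerate(group)}
    col_in_free = {k: a for a, k in enumerate(free)}
    for e, name in enumerate(epoch_names):
        R, P, k_idx = mats[name]
        C = P.shape[0]
        # rows for all units of this epoch, built blockwise
        A = np.zeros((n_units * C, n_unknown))
        b = np.zeros(n_units * C)
        for n in range(n_units):
            w = sqrtM[n]
            r0 = n * C
            b[r0:r0 + C] = R[n] * w
            base = n_s + n * n_per_unit
            A[r0:r0 + C, base + e] = w  # constant for this epoch
            for j, k in enumerate(k_idx):
                if k in col_in_group:
                    A[r0:r0 + C, col_in_group[k]] += Q[n, col_in_group[k]] * P[:, j] * w
                else:
                    A[r0:r0 + C, base + E + col_in_free[k]] = P[:, j] * w
        rows.append(A)
        rhs.append(b)
    A = np.vstack(rows)
    b = np.concatenate(rhs)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    s = sol[:n_s]
    per_unit = sol[n_s:].reshape(n_units, n_per_unit)
    B0 = per_unit[:, :E]
    B_free = per_unit[:, E:]
    return s, B0, B_free


def _assemble_B(Q, s, B_free, group, free, n_units, n_cols):
    B = np.zeros((n_units, n_cols))
    for a, k in enumerate(group):
        B[:, k] = Q[:, a] * s[a]
    for a, k in enumerate(free):
        B[:, k] = B_free[:, a]
    return B


def _stiefel_grad(mats, sqrtM, epoch_names, Q, s, B0, B_free, group, free,
                  n_units, n_cols):
    """Riemannian gradient of the objective w.r.t. the orthonormal frame Q."""
    B = _assemble_B(Q, s, B_free, group, free, n_units, n_cols)
    f0 = _objective(mats, sqrtM, B, B0, epoch_names)
    G = np.zeros_like(Q)
    for e, name in enumerate(epoch_names):
        R, P, k_idx = mats[name]
        resid = (R - B0[:, [e]] - (B[:, k_idx] @ P.T if k_idx else 0.0)) * sqrtM ** 2
        for j, k in enumerate(k_idx):
            if k in group:
                a = group.index(k)
                G[:, a] += -2.0 * (resid @ P[:, j]) * s[a]
    QtG = Q.T @ G
    grad = G - Q @ ((QtG + QtG.T) / 2)
    return f0, grad


def _retract(Q, step, grad):
    cand, r = np.linalg.qr(Q - step * grad)
    return cand * np.sign(np.diag(r))  # fix QR sign ambiguity


def _stiefel_descent(mats, sqrtM, epoch_names, Q, s, B0, B_free, group, free,
                     n_units, n_cols, max_inner=50, tol=1e-12):
    """Projected gradient descent on the frame with Barzilai-Borwein steps."""
    f, grad = _stiefel_grad(mats, sqrtM, epoch_names, Q, s, B0, B_free,
                            group, free, n_units, n_cols)
    step = 1.0 / max(np.linalg.norm(grad), 1e-12)
    prev = None
    for _ in range(max_inner):
        gnorm = np.linalg.norm(grad)
        if gnorm < 1e-12:
            break
        improved = False
        trial = step
        for _bt in range(40):
            cand = _retract(Q, trial, grad)
            fc, gc = _stiefel_grad(mats, sqrtM, epoch_names, cand, s, B0,
                                   B_free, group, free, n_units, n_cols)
            if fc < f:
                improved = True
                break
            trial *= 0.5
        if not improved:
            break
        dQ, dG = cand - Q, gc - grad
        denom = float(np.sum(dG * dG))
        step = abs(float(np.sum(dQ * dG))) / denom if denom > 0 else trial
        step = min(max(step, 1e-12), 1e6)
        done = f - fc <= tol * max(1.0, abs(f))
        Q, f, grad = cand, fc, gc
        if done:
            break
    return Q, f, float(np.linalg.norm(grad))


def _polar_orthonormalize(Bg: np.ndarray) -> np.ndarray:
    U, _s, Vt = np.linalg.svd(Bg, full_matrices=False)
    return U @ Vt


def _pca_basis(pop: PopulationResponse, D: int) -> np.ndarray:
    X = pop.unfold(exclude_singleton=True)
    X = X - X.mean(axis=1, keepdims=True)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :D]


def fit_static_axes(
    pop: PopulationResponse,
    design: ConditionDesign,
    M: TrialCounts,
    spec: EpochSpec,
    orthogonalize: bool = True,
    restarts: int = 10,
    probe_frames: int | None = None,
    tol: float = 1e-9,
    max_iter: int = 5000,
    seed: int | None = 0,
) -> RegressionAxes:
    """Fit the sRAs for all variables/epochs in one weighted objective.

    Returns unit-normalized axes with a deterministic sign convention: each
    axis is flipped so the correlation between its epoch-average projection
    and its on-target variable is non-negative.
    """
    X_full = np.column_stack([np.ones(len(design.conditions)), design.P])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient design; collinear columns among "
                         f"{design.variables}")
    mats, sqrtM, cols = _epoch_matrices(pop, design, M, spec)
    epoch_names = list(spec.epochs)
    n_units, n_cols = pop.n_units, len(cols)
    if (sqrtM == 0).any():
        raise ValueError("M must be strictly positive on included cells")

    B_ols, B0_ols = _unconstrained_wls(mats, sqrtM, epoch_names, n_units, n_cols)
    group = spec.orthogonal_group() if orthogonalize else []
    free = [k for k in range(n_cols) if k not in group]

    if not group or len(group) == 1:
        B, B0 = B_ols, B0_ols
        obj = _objective(mats, sqrtM, B, B0, epoch_names)
    else:
        rng = np.random.default_rng(seed)
        inits = [_polar_orthonormalize(B_ols[:, group])]
        for _ in range(restarts):
            Z = rng.standard_normal((n_units, len(group)))
            inits.append(np.linalg.qr(Z)[0])
        # cheap basin probing: score many random frames by the exact linear
        # subproblem and keep the best as extra descent starts (the
        # constraint set is non-convex and alternation can settle in a
        # suboptimal basin)
        if probe_frames is None:
            probe_frames = 1000 if n_units <= 25 else 100
        if probe_frames:
            scored = []
            for _ in range(probe_frames):
                Q = np.linalg.qr(rng.standard_normal((n_units, len(group))))[0]
                s, B0p, B_freep = _linear_subproblem(
                    mats, sqrtM, epoch_names, Q, group, free, n_units)
                Bp = _assemble_B(Q, s, B_freep, group, free, n_units, n_cols)
                scored.append((_objective(mats, sqrtM, Bp, B0p, epoch_names), Q))
            scored.sort(key=lambda t: t[0])
            inits.extend(Q for _, Q in scored[:5])
        best = None
        for Q in inits:
            s, B0, B_free = _linear_subproblem(
                mats, sqrtM, epoch_names, Q, group, free, n_units)
            f_prev = np.inf
            gnorm = np.inf
            for it in range(max_iter):
                Q, f, gnorm = _stiefel_descent(
                    mats, sqrtM, epoch_names, Q, s, B0, B_free, group, free,
                    n_units, n_cols)
                s, B0, B_free = _linear_subproblem(
                    mats, sqrtM, epoch_names, Q, group, free, n_units)
                B = _assemble_B(Q, s, B_free, group, free, n_units, n_cols)
                f = _objective(mats, sqrtM, B, B0, epoch_names)
                if f_prev - f <= tol * max(1.0, abs(f_prev)):
                    break
                f_prev = f
            else:
                raise ConvergenceError(
                    f"no convergence in {max_iter} iterations",
                    axes=B, grad_norm=gnorm)
            if best is None or f < best[0]:
                best = (f, B, B0)
        obj, B, B0 = best

    if spec.denoise_D is not None:
        U = _pca_basis(pop, spec.denoise_D)
        B = U @ (U.T @ B)

    norms = np.linalg.norm(B, axis=0)
    if (norms == 0).any():
        raise ConvergenceError("degenerate zero-norm axis", axes=B)
    B = B / norms

    # sign convention: epoch-average projection correlates positively with
    # the on-target variable
    for j, (var, ep) in enumerate(cols):
        R, P, k_idx = mats[ep]
        proj = R.T @ B[:, j]
        p = design.column(var)
        r = np.corrcoef(proj, p)[0, 1]
        if np.isfinite(r) and r < 0:
            B[:, j] = -B[:, j]

    return RegressionAxes(B, B0, cols, epoch_names,
                          orthogonalized=bool(group and len(group) > 1),
                          objective_value=obj, spec=spec,
                          design_variables=list(design.variables))


def fit_previous_trial_axes(
    pop_prev: PopulationResponse,
    design_prev: ConditionDesign,
    M: TrialCounts,
    t3_window: tuple = (-0.5, 0.0),
    **kwargs,
) -> RegressionAxes:
    """Fit all previous-trial sRAs in the single pre-trial epoch T3."""
    spec = EpochSpec(
        epochs={"T3": tuple(t3_window)},
        assignment={v: "T3" for v in design_prev.variables},
    )
    return fit_static_axes(pop_prev, design_prev, M, spec, **kwargs)
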