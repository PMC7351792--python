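"""Dynamic regression axes: per-time-bin ridge regression with per-unit
leave-one-out cross-validated penalties.

Each 200 ms time bin gets its own set of axes (one per task variable), fit
independently by weighted ridge regression at the individual-unit level.
The penalty lambda_n(t) is chosen per unit and time bin by leave-one-out
cross-validation over conditions; when the error is minimized by the
infinite-penalty sentinel the unit's coefficients are set exactly to zero.
The resulting axes are deliberately NOT orthogonalized.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .popdata import ConditionDesign, PopulationResponse, TrialCounts

__all__ = [
    "DRATimeSeries", "default_lambda_grid",
    "pca_denoise", "auto_dimension", "rebin_200ms", "fit_dra", "fit_dra_series",
]

#: logarithmic grid 1e-4 ... 1e4 (25 steps); np.inf is the shut-off sentinel
def default_lambda_grid() -> np.ndarray:
    return np.concatenate([np.logspace(-4, 4, 25), [np.inf]])


@dataclass
class DRATimeSeries:
    """Time series of unit-norm dynamic regression axes.

    ``axes`` is (N, K, T'); ``magnitudes`` (K, T') holds the pre-normalization
    coefficient-vector norms; ``lam`` (N, T') the selected penalties (np.inf
    allowed); ``D`` the number of principal components retained upstream.
    """

    axes: np.ndarray
    magnitudes: np.ndarray
    lam: np.ndarray
    variables: list
    bin_centers: np.ndarray
    D: int | None = None

    def axis(self, variable: str, t: int) -> np.ndarray:
        return self.axes[:, self.variables.index(variable), t]


# ---------------------------------------------------------------------------
# noise reduction and re-binning
# ---------------------------------------------------------------------------

def pca_denoise(pop: PopulationResponse, D: int) -> tuple[PopulationResponse, float]:
    """Reconstruct the tensor within the top-D PC subspace.

    PCs are computed on the N x (T*C) unfolding (columns centered), so they
    capture variance related either to time or to task condition.  Returns
    the noise-reduced response and the cumulative fraction of variance the
    retained subspace explains.
    """
    if not (0 < D <= pop.n_units):
        raise ValueError(f"D must be in 1..{pop.n_units}")
    X = pop.unfold()
    mu = X.mean(axis=1, keepdims=True)
    Xc = X - mu
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    var = S ** 2
    explained = float(var[:D].sum() / var.sum()) if var.sum() > 0 else 1.0
    UD = U[:, :D]
    Xr = UD @ (UD.T @ Xc) + mu
    tensor = Xr.reshape(pop.tensor.shape)
    return _dc_replace(pop, tensor=tensor), explained


def auto_dimension(pop: PopulationResponse, max_D: int | None = None) -> int:
    """Pick D at the inflection of the log-eigenvalue scree.

    Implemented as the point of maximum (negative) curvature of the
    log variance-explained curve, i.e. the largest second difference of the
    log eigenvalues.
    """
    X = pop.unfold()
    Xc = X - X.mean(axis=1, keepdims=True)
    S = np.linalg.svd(Xc, compute_uv=False)
    ev = S ** 2
    ev = ev[ev > 1e-12 * ev[0]]
    if max_D is not None:
        ev = ev[:max_D]
    if len(ev) < 3:
        return len(ev)
    log_ev = np.log(ev)
    curv = log_ev[:-2] - 2 * log_ev[1:-1] + log_ev[2:]
    return int(np.argmax(curv) + 2)  # curvature at index i+1, 1-based count


def rebin_200ms(pop: PopulationResponse) -> PopulationResponse:
    """Average adjacent 100 ms bins into 200 ms bins that never straddle t=0.

    Bins are paired outward from t = 0 on each side; an unpaired leftover bin
    (farthest from 0 on its side) is dropped.
    """
    starts = pop.bin_starts
    w = pop.bin_width
    if not np.allclose(np.diff(starts), w):
        raise ValueError("bins must be contiguous for re-binning")
    if not np.any(np.isclose(np.round(starts / w) * w, 0.0)) and \
       not np.isclose(starts[0] % w, 0.0):
        raise ValueError("bin edges must fall on multiples of the bin width")
    neg = np.nonzero(starts < -w / 2)[0]
    pos = np.nonzero(starts >= -w / 2)[0]
    pairs = []
    # negative side: pair starting adjacent to 0 moving left
    rev = list(neg[::-1])
    for i in range(0, len(rev) - 1, 2):
        pairs.append((rev[i + 1], rev[i]))
    pairs = pairs[::-1]
    for i in range(0, len(pos) - 1, 2):
        pairs.append((pos[i], pos[i + 1]))
    if not pairs:
        raise ValueError("too few bins to re-bin")
    idx_lo = np.array([p[0] for p in pairs])
    idx_hi = np.array([p[1] for p in pairs])
    tensor = (pop.tensor[:, :, idx_lo] + pop.tensor[:, :, idx_hi]) / 2
    cc = (pop.cc[:, idx_lo] + pop.cc[:, idx_hi]) / 2
    return _dc_replace(pop, tensor=tensor, cc=cc,
                       bin_starts=starts[idx_lo], bin_width=2 * w)


# ---------------------------------------------------------------------------
# per-bin ridge fits
# ---------------------------------------------------------------------------

def _ridge_solve(G: np.ndarray, h: np.ndarray, lam: float,
                 penalize_intercept: bool) -> np.ndarray:
    """Ridge normal-equations solve from Gram form (G = X'X, h = X'y)."""
    p = G.shape[0]
    if np.isinf(lam):
        beta = np.zeros(p)
        if not penalize_intercept and G[0, 0] > 0:
            beta[0] = h[0] / G[0, 0]
        return beta
    pen = np.eye(p) * lam
    if not penalize_intercept:
        pen[0, 0] = 0.0
    return np.linalg.solve(G + pen, h)


def _fit_dra_bins(Y, design, sqrtM, lambda_grid, penalize_intercept):
    """LOO-ridge fits for all requested time bins at once.

    ``Y`` is (N, C, T) over the design's conditions.  The Gram matrices (and
    their leave-one-out downdates) do not depend on the time bin, so their
    eigendecompositions are computed once and reused for every bin and every
    finite penalty on the grid.  Returns (axes N x K x T unit-norm,
    magnitudes K x T, selected lambda N x T).
    """
    N, C, T = Y.shape
    K = design.P.shape[1]
    p = K + 1
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    finite = np.isfinite(lambda_grid)
    lam_fin = lambda_grid[finite]
    X0 = np.column_stack([np.ones(C), design.P])       # C x p
    Xw = X0[None, :, :] * sqrtM[:, :, None]            # N x C x p
    Yw = Y * sqrtM[:, :, None]                         # N x C x T
    G_full = np.einsum("ncp,ncq->npq", Xw, Xw)         # N x p x p
    h_full = np.einsum("ncp,nct->ntp", Xw, Yw)         # N x T x p
    G_loo = G_full[:, None] - np.einsum("ncp,ncq->ncpq", Xw, Xw)
    h_loo = h_full[:, None] - Xw[:, :, None, :] * Yw[:, :, :, None]  # N,C,T,p

    errs = np.zeros((N, T, len(lambda_grid)))
    if penalize_intercept:
        d, V = np.linalg.eigh(G_loo.reshape(N * C, p, p))
        d = d.reshape(N, C, p)
        V = V.reshape(N, C, p, p)
        hv = np.einsum("ncpq,nctp->nctq", V, h_loo)    # V' h per held-out fold
        xv = np.einsum("ncpq,ncp->ncq", V, Xw)         # V' x_c
        inv = 1.0 / (d[..., None] + lam_fin)           # N x C x p x L
        pred = np.einsum("ncpl,nctp->nctl", inv * xv[..., None], hv)
        errs[:, :, finite] = ((pred - Yw[..., None]) ** 2).sum(axis=1)
        errs[:, :, ~finite] = (Yw ** 2).sum(axis=1)[..., None]
    else:
        for n in range(N):
            for c in range(C):
                for g, lam in enumerate(lambda_grid):
                    for t in range(T):
                        beta = _ridge_solve(G_loo[n, c], h_loo[n, c, t], lam,
                                            penalize_intercept)
                        errs[n, t, g] += (Xw[n, c] @ beta - Yw[n, c, t]) ** 2

    g_best = np.argmin(errs, axis=2)                   # N x T
    lam_sel = lambda_grid[g_best]
    coefs = np.zeros((N, T, p))
    if penalize_intercept:
        df, Vf = np.linalg.eigh(G_full)                # N x p, N x p x p
        hvf = np.einsum("npq,ntp->ntq", Vf, h_full)
        beta_all = np.einsum("npq,ntql->ntpl",
                             Vf, hvf[..., None] / (df[:, None, :, None] + lam_fin))
        for g, lam in enumerate(lam_fin):
            pick = lam_sel == lam
            coefs[pick] = beta_all[..., g][pick]
        # infinite-penalty sentinel leaves coefficients at exactly 0
    else:
        for n in range(N):
            for t in range(T):
                coefs[n, t] = _ridge_solve(G_full[n], h_full[n, t],
                                           lam_sel[n, t], penalize_intercept)
    Bk = coefs[:, :, 1:].transpose(0, 2, 1)            # N x K x T
    mags = np.linalg.norm(Bk, axis=0)                  # K x T
    axes = np.divide(Bk, mags, out=np.zeros_like(Bk), where=mags > 0)
    return axes, mags, lam_sel


def fit_dra(
    pop: PopulationResponse,
    design: ConditionDesign,
    M: TrialCounts,
    t: int,
    lambda_grid: np.ndarray | None = None,
    penalize_intercept: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Axes at a single (200 ms) time bin.

    Per unit n: responses and predictors are scaled by sqrt(M_n(c)) and the
    ridge solution is computed on the closed-form normal equations; the
    penalty minimizing the leave-one-out (over conditions) squared error is
    selected per unit, with an infinite-penalty sentinel that zeroes the
    unit's coefficients outright.  Returns (axes N x K unit-norm,
    pre-normalization magnitudes K, selected lambda per unit).
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    cond_idx = [pop.condition_index.index(c) for c in design.conditions]
    C, K = design.P.shape
    if C < K + 2:
        raise ValueError("need at least K+2 conditions for LOO ridge")
    Y = pop.tensor[:, cond_idx, t][:, :, None]
    sqrtM = np.sqrt(M.M[:, [M.conditions.index(c) for c in design.conditions]])
    axes, mags, lam = _fit_dra_bins(Y, design, sqrtM, lambda_grid,
                                    penalize_intercept)
    return axes[:, :, 0], mags[:, 0], lam[:, 0]


def fit_dra_series(
    pop: PopulationResponse,
    design: ConditionDesign,
    M: TrialCounts,
    D: int | str | None = "auto",
    lambda_grid: np.ndarray | None = None,
    penalize_intercept: bool = True,
    rebin: bool = True,
) -> DRATimeSeries:
    """Full dRA pipeline: PCA noise reduction, 200 ms re-binning, per-bin fits."""
    if D == "auto":
        D = auto_dimension(pop)
    if D is not None:
        pop, _ = pca_denoise(pop, int(D))
    if rebin:
        pop = rebin_200ms(pop)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    C, K = design.P.shape
    if C < K + 2:
        raise ValueError("need at least K+2 conditions for LOO ridge")
    cond_idx = [pop.condition_index.index(c) for c in design.conditions]
    sqrtM = np.sqrt(M.M[:, [M.conditions.index(c) for c in design.conditions]])
    axes, mags, lam = _fit_dra_bins(pop.tensor[:, cond_idx, :], design, sqrtM,
                                    lambda_grid, penalize_intercept)
    centers = pop.bin_starts + pop.bin_width / 2
    return DRATimeSeries(axes, mags, lam, list(design.variables), centers,
                         D=None if D is None else int(D))
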