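"""Projection of the population response onto axes and the decomposition of
the explained cross-condition variance into relevant and irrelevant parts.

V_k(t) is the variance of the projection across conditions, as a percentage
of the total cross-condition variance summed over units.  The relevant
signal variance RSV_{k,q}(t) is the part of V_k(t) linearly related to
variable q: for the axis's own (on-target) variable it is V * r^2 with r the
Pearson correlation between projection and variable; for off-target
variables a semi-partial correlation removes the part of q already explained
by the on-target variable, so that correlated predictors (e.g. benefit and
expected reward, r = 0.54 over the included conditions) are not double
counted.  The irrelevant signal variance ISV_k = V_k - RSV_k is computed for
on-target variables only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .popdata import ConditionDesign, PopulationResponse
from .otdr_core import RegressionAxes

__all__ = [
    "VarianceProfile", "project", "project_axes", "variance_explained",
    "semi_partial", "rsv_isv", "variance_profile", "pc_rsv",
]


@dataclass
class VarianceProfile:
    """Per-axis, per-time variance decomposition.

    ``V`` (K, T) percent of total cross-condition variance; ``RSV`` maps
    (axis variable, target variable) -> (T,) profile; ``ISV`` (K, T)
    on-target only; ``pvals`` optionally holds empirical one-sided
    probabilities per axis and time (filled in by the null-model workflow).
    """

    proj: np.ndarray
    V: np.ndarray
    RSV: dict
    ISV: np.ndarray
    variables: list
    bin_centers: np.ndarray
    pvals: np.ndarray | None = None


def project(pop: PopulationResponse, axes: np.ndarray) -> np.ndarray:
    """proj_k(c, t) = sum_n Rbar_n(c, t) * beta_{k,n}.

    ``axes`` is (N,) or (N, K); returns (C, T) or (K, C, T).  Singleton
    conditions present in the tensor are projected like any other even
    though they are excluded from axis fitting.
    """
    axes = np.asarray(axes, dtype=float)
    if axes.shape[0] != pop.n_units:
        raise ValueError("axis dimension does not match unit count")
    if axes.ndim == 1:
        return np.einsum("nct,n->ct", pop.tensor, axes)
    return np.einsum("nct,nk->kct", pop.tensor, axes)


def project_axes(pop: PopulationResponse, axes: RegressionAxes) -> np.ndarray:
    return project(pop, axes.B)


def variance_explained(proj: np.ndarray, pop: PopulationResponse,
                       conditions: list | None = None) -> np.ndarray:
    """V_k(t): projection variance across conditions as % of total.

    ``conditions`` restricts both numerator and denominator to a condition
    subset (the included, non-singleton set in practice).  Times with zero
    total cross-condition variance are returned as NaN.
    """
    proj = np.asarray(proj, dtype=float)
    squeeze = proj.ndim == 2
    if squeeze:
        proj = proj[None]
    tensor = pop.tensor
    if conditions is not None:
        idx = [pop.condition_index.index(c) for c in conditions]
        tensor = tensor[:, idx, :]
        proj = proj[:, idx, :]
    if tensor.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    num = proj.var(axis=1)                       # K x T
    den = tensor.var(axis=1).sum(axis=0)         # T
    V = np.full(num.shape, np.nan)
    ok = den > 0
    V[:, ok] = num[:, ok] / den[ok] * 100.0
    return V[0] if squeeze else V


def semi_partial(r_pq: float, r_pk: float, r_kq: float) -> float:
    """Semi-partial correlation of p with the part of q not explained by k."""
    if abs(r_kq) >= 1.0 - 1e-12:
        raise ValueError("|r_kq| = 1: q is fully explained by k; "
                         "semi-partial correlation undefined")
    return (r_pq - r_pk * r_kq) / np.sqrt(1.0 - r_kq ** 2)


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def rsv_isv(proj_k: np.ndarray, V_k: np.ndarray, design: ConditionDesign,
            on_target: str, off_targets: list | None = None) -> tuple[dict, np.ndarray]:
    """RSV per target variable and on-target ISV for one axis.

    ``proj_k`` is (C, T) over the design's conditions.  On-target RSV uses
    the plain squared correlation; off-target RSV uses the squared
    semi-partial correlation of the projection with the off-target variable
    controlling for the on-target variable.  At times where the projection
    has zero variance RSV and ISV are defined as 0.
    """
    proj_k = np.asarray(proj_k)
    T = proj_k.shape[1]
    if off_targets is None:
        off_targets = [v for v in design.variables if v != on_target]
    pk = design.column(on_target)
    rsv = {q: np.zeros(T) for q in [on_target, *off_targets]}
    isv = np.zeros(T)
    for t in range(T):
        p = proj_k[:, t]
        v = V_k[t]
        if not np.isfinite(v) or np.std(p) == 0:
            continue
        r_on = _corr(p, pk)
        rsv[on_target][t] = v * r_on ** 2
        isv[t] = v * (1.0 - r_on ** 2)
        for q in off_targets:
            pq = design.column(q)
            r_kq = _corr(pk, pq)
            rho = semi_partial(_corr(p, pq), r_on, r_kq)
            rsv[q][t] = v * rho ** 2
    return rsv, isv


def variance_profile(pop: PopulationResponse, axes: RegressionAxes,
                     design: ConditionDesign) -> VarianceProfile:
    """Full per-axis decomposition over the design's (included) conditions."""
    proj = project(pop, axes.B)
    V = variance_explained(proj, pop, conditions=design.conditions)
    idx = [pop.condition_index.index(c) for c in design.conditions]
    proj_inc = proj[:, idx, :]
    RSV, ISV = {}, np.zeros_like(V)
    for j, (var, _) in enumerate(axes.columns):
        rsv_j, ISV[j] = rsv_isv(proj_inc[j], V[j], design, var)
        for q, prof in rsv_j.items():
            RSV[(var, q)] = prof
    centers = pop.bin_starts + pop.bin_width / 2
    return VarianceProfile(proj, V, RSV, ISV,
                           [v for v, _ in axes.columns], centers)


def pc_rsv(pop: PopulationResponse, design: ConditionDesign, variable: str,
           n_pcs: int) -> tuple[np.ndarray, int]:
    """Per-PC RSV for one task variable, with on-target PC selection.

    PCs come from the N x (T*C) unfolding.  The on-target PC d' is the one
    with the greatest cumulative (plain, Eq.-10-style) RSV across time; all
    other PCs are then assigned off-target RSV via the semi-partial
    correlation of their projection with the variable, controlling for the
    on-target PC's projection.  Returns (RSV array n_pcs x T, d' index).
    """
    X = pop.unfold(exclude_singleton=True)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, _, _ = np.linalg.svd(Xc, full_matrices=False)
    U = U[:, :n_pcs]
    proj = project(pop, U)                       # n_pcs x C x T
    idx = [pop.condition_index.index(c) for c in design.conditions]
    proj = proj[:, idx, :]
    V = variance_explained(project(pop, U), pop, conditions=design.conditions)
    pk = design.column(variable)
    T = proj.shape[2]
    plain = np.zeros((n_pcs, T))
    for d in range(n_pcs):
        for t in range(T):
            if np.isfinite(V[d, t]) and np.std(proj[d, :, t]) > 0:
                plain[d, t] = V[d, t] * _corr(proj[d, :, t], pk) ** 2
    d_on = int(np.argmax(plain.sum(axis=1)))
    out = np.zeros((n_pcs, T))
    out[d_on] = plain[d_on]
    for d in range(n_pcs):
        if d == d_on:
            continue
        for t in range(T):
            if not np.isfinite(V[d, t]) or np.std(proj[d, :, t]) == 0:
                continue
            p, a = proj[d, :, t], proj[d_on, :, t]
            r_ak = _corr(a, pk)
            if abs(r_ak) >= 1 - 1e-12:
                out[d, t] = 0.0
                continue
            rho = semi_partial(_corr(p, pk), _corr(p, a), r_ak)
            out[d, t] = V[d, t] * rho ** 2
    return out, d_on
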