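"""Null models for population representations.

Two bespoke controls: (1) random dimensions aligned to the covariance
(dimensionality) of the recorded population, against which projection-based
metrics are calibrated; and (2) surrogate firing-rate ensembles drawn from a
Kronecker-separable (neurons x time) matrix-normal distribution — the
maximum-entropy distribution matching the data's inter-unit and temporal
covariances — which preserve dimensionality and temporal smoothness but
carry no relation to the task design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .popdata import PopulationResponse

__all__ = [
    "RandomDimensionSet", "SurrogateEnsemble",
    "random_aligned_dimensions", "empirical_pvalue", "surrogate_data",
]


@dataclass
class RandomDimensionSet:
    """Unit-norm random dimensions aligned to a source covariance."""

    V: np.ndarray          # N x n_dims, unit-norm columns
    sigma: np.ndarray      # N x N source covariance
    seed: int | None

    @property
    def n_dims(self) -> int:
        return self.V.shape[1]


@dataclass
class SurrogateEnsemble:
    """Ensemble of design-free synthetic response tensors (n_sets, N, C, T)."""

    sets: np.ndarray
    sigma_units: np.ndarray
    sigma_time: np.ndarray
    seed: int | None

    @property
    def n_sets(self) -> int:
        return self.sets.shape[0]

    def as_population(self, template: PopulationResponse, i: int) -> PopulationResponse:
        """View surrogate i with the metadata of the original response."""
        return _dc_replace(template, tensor=self.sets[i])


def _data_covariance(pop: PopulationResponse) -> np.ndarray:
    X = pop.unfold(exclude_singleton=True)
    Xc = X - X.mean(axis=1, keepdims=True)
    return Xc @ Xc.T / Xc.shape[1]


def random_aligned_dimensions(pop: PopulationResponse, n: int,
                              seed: int | None = None,
                              sigma: np.ndarray | None = None) -> RandomDimensionSet:
    """Random unit dimensions whose density follows the data covariance.

    Each draw is v = U sqrt(S) z / ||U sqrt(S) z|| with z standard normal and
    (U, S) the eigendecomposition of the covariance of the N x (T*C)
    unfolding, so directions the population actually occupies are sampled
    proportionally more often than rarely visited ones.
    """
    if sigma is None:
        sigma = _data_covariance(pop)
    if np.trace(sigma) <= 0:
        raise ValueError("degenerate covariance (zero trace)")
    evals, U = np.linalg.eigh(sigma)
    evals = np.clip(evals, 0.0, None)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((sigma.shape[0], n))
    W = U @ (np.sqrt(evals)[:, None] * (U.T @ Z))
    norms = np.linalg.norm(W, axis=0)
    if (norms == 0).any():
        raise ValueError("degenerate draw with zero norm")
    return RandomDimensionSet(W / norms, sigma, seed)


def empirical_pvalue(observed: float, null: np.ndarray) -> float:
    """One-sided add-one empirical probability (1 + #{null >= obs}) / (1 + n).

    The add-one rule keeps p > 0; with 9,999 null draws an observation above
    every one of them yields p = 1e-4.
    """
    null = np.asarray(null, dtype=float)
    null = null[np.isfinite(null)]
    if null.size == 0:
        raise ValueError("empty null distribution")
    if null.size < 100:
        warnings.warn("fewer than 100 null draws; empirical p-value is coarse",
                      stacklevel=2)
    return float((1 + np.sum(null >= observed)) / (1 + null.size))


def _shrink(S: np.ndarray, weight: float) -> np.ndarray:
    return (1 - weight) * S + weight * np.diag(np.diag(S))


def _psd_sqrt(S: np.ndarray, name: str) -> np.ndarray:
    evals, U = np.linalg.eigh(S)
    if evals.min() < -1e-10 * max(evals.max(), 1.0):
        warnings.warn(f"{name} estimate not PSD; clipping negative eigenvalues",
                      stacklevel=3)
    evals = np.clip(evals, 0.0, None)
    return U @ (np.sqrt(evals)[:, None] * U.T)


def surrogate_data(pop: PopulationResponse, n_sets: int = 1000,
                   seed: int | None = None, shrinkage: float = 0.01,
                   match_condition_power: bool = True) -> SurrogateEnsemble:
    """Matrix-normal surrogate ensembles matched to the data's covariances.

    The inter-unit covariance Sigma_N pools (condition, time) samples; the
    temporal covariance Sigma_T pools (unit, condition) samples of the
    across-condition-mean-subtracted tensor.  Sigma_T is rescaled to unit
    mean diagonal so the per-entry variance scale lives in Sigma_N.  Each
    condition's N x T slab is drawn independently as A Z B' with A A' =
    Sigma_N, B B' = Sigma_T; sets are conditionally independent given the
    estimated covariances.

    With ``match_condition_power`` (default) each condition's slab is scaled
    so its mean squared amplitude matches that condition's share of power in
    the data (scales normalized to mean 1, so the pooled covariances are
    unchanged).  Trial-average tensors are strongly heteroscedastic across
    conditions — rare conditions are averaged over fewer trials — and a
    homoscedastic surrogate understates the cross-condition variance such
    conditions contribute.
    """
    tensor = pop.tensor
    if not pop.mean_subtracted:
        tensor = tensor - tensor.mean(axis=1, keepdims=True)
    N, C, T = tensor.shape
    X_nt = tensor.transpose(0, 2, 1).reshape(N, -1)      # N x (T*C)
    sigma_units = _shrink(X_nt @ X_nt.T / X_nt.shape[1], shrinkage)
    X_t = tensor.reshape(N * C, T)
    sigma_time = _shrink(X_t.T @ X_t / X_t.shape[0], shrinkage)
    scale = np.mean(np.diag(sigma_time))
    if scale <= 0 or np.trace(sigma_units) <= 0:
        raise ValueError("degenerate covariance estimates")
    sigma_time = sigma_time / scale
    sets = sample_matrix_normal(sigma_units, sigma_time, n_sets, C, seed)
    if match_condition_power:
        s2 = (tensor ** 2).mean(axis=(0, 2))
        s2 = s2 / s2.mean()
        sets *= np.sqrt(s2)[None, None, :, None]
    return SurrogateEnsemble(sets, sigma_units, sigma_time, seed)


def sample_matrix_normal(sigma_units: np.ndarray, sigma_time: np.ndarray,
                         n_sets: int, n_conditions: int,
                         seed: int | None = None) -> np.ndarray:
    """Draw (n_sets, N, C, T) tensors of zero-mean matrix-normal slabs.

    Each (set, condition) slab is A Z B with A, B the symmetric square roots
    of the unit and temporal covariances and Z i.i.d. standard normal; with
    both covariances equal to the identity the entries are i.i.d. N(0, 1).
    """
    A = _psd_sqrt(np.asarray(sigma_units, dtype=float), "unit covariance")
    B = _psd_sqrt(np.asarray(sigma_time, dtype=float), "temporal covariance")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_sets, n_conditions, A.shape[0], B.shape[0]))
    sets = np.einsum("nm,scmt,ut->scnu", A, Z, B, optimize=True)
    return np.ascontiguousarray(sets.transpose(0, 2, 1, 3))
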