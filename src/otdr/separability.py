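"""Bootstrap reliability of regression axes, the attenuation-corrected
separability test, per-unit coefficient significance, and the
mixed-selectivity proportion test.

Two representations are *separable* when their observed correlation is
significantly below the correlation expected for perfectly correlated true
axes corrupted by independent estimation noise.  Spearman's attenuation
formula, |r_AB| = |r_A'B'| sqrt(r_AA r_BB), ties the observed correlation to
the bootstrap reliabilities r_AA and r_BB; under the null |r_A'B'| = 1 the
null-hypothetical correlation is sqrt(r_AA r_BB).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .popdata import (ConditionDesign, TrialTable, build_population_response)
from .otdr_core import EpochSpec, fit_static_axes

__all__ = [
    "BootstrapEnsemble", "SeparabilityResult",
    "bootstrap_axes", "reliability_and_null", "separability_test",
    "unit_significance", "mixed_selectivity_test", "separability_analysis",
]


@dataclass
class BootstrapEnsemble:
    """S resampled, non-orthogonalized axis sets (S, N, K)."""

    axes: np.ndarray
    variables: list
    seed: int | None
    scheme: str = "per-unit-per-condition trial resampling with replacement"

    @property
    def S(self) -> int:
        return self.axes.shape[0]


@dataclass
class SeparabilityResult:
    observed_r: dict                 # pair -> |r_AB|
    reliability: dict                # variable -> (S^2-S)/2 correlations
    null: dict                       # pair -> |r_hat_AB| draws (NaN-free)
    excluded_fraction: dict          # pair -> fraction dropped (negative product)
    pvalues: dict                    # pair -> one-tailed t-test p
    separable: dict = field(default_factory=dict)


def bootstrap_axes(
    table: TrialTable,
    design: ConditionDesign,
    spec: EpochSpec,
    S: int = 700,
    seed: int | None = 0,
    sort_by: str = "present",
    zmean: np.ndarray | None = None,
    zstd: np.ndarray | None = None,
) -> BootstrapEnsemble:
    """Fit non-orthogonalized sRAs on S trial resamples.

    Trials are resampled with replacement independently per (unit,
    condition), keeping each cell's trial count identical to the original.
    Resampled data are z-scored with the full-data per-unit statistics, so
    trial-to-trial fluctuations depress (rather than inflate) reliability.
    """
    rng = np.random.default_rng(seed)
    if zmean is None or zstd is None:
        pop_full, _ = build_population_response(table, sort_by=sort_by)
        zmean, zstd = pop_full.zmean, pop_full.zstd
    labels = table.condition_of_trials(sort_by)
    observed = ~np.isnan(table.rates).all(axis=2)
    conds = table.conditions(sort_by)
    cond_trials = {c: np.nonzero(np.asarray(labels.apply(lambda x: x == c)))[0]
                   for c in conds}
    out = None
    for s in range(S):
        resampled = table.rates.copy()
        for c in conds:
            tr = cond_trials[c]
            for n in range(table.n_units):
                obs = tr[observed[n, tr]]
                if obs.size == 0:
                    raise ValueError(f"unit {table.unit_ids[n]} has no trials "
                                     f"in condition {c}")
                pick = rng.choice(obs, size=obs.size, replace=True)
                resampled[n, obs, :] = table.rates[n, pick, :]
        boot = TrialTable(resampled, table.trials.copy(), table.unit_ids,
                          table.bin_starts, table.bin_width, table.alignment,
                          list(table.excluded_conditions))
        pop, M = build_population_response(boot, sort_by=sort_by,
                                           zmean=zmean, zstd=zstd)
        axes = fit_static_axes(pop, design, M, spec, orthogonalize=False)
        if out is None:
            out = np.zeros((S, *axes.B.shape))
            variables = [v for v, _ in axes.columns]
        out[s] = axes.B
    return BootstrapEnsemble(out, variables, seed)


def reliability_and_null(ensemble: BootstrapEnsemble) -> tuple[dict, dict, dict]:
    """Within-variable reliability distributions and the null |r_hat_AB|.

    Returns (reliability r_AA per variable, null distribution per pair,
    excluded fraction per pair).  Reliabilities are all (S^2-S)/2 pairwise
    correlations between resampled axes of one variable; the null pairs them
    elementwise as sqrt(r_AA * r_BB), dropping (and counting) entries whose
    product is negative.
    """
    if ensemble.S < 2:
        raise ValueError("need at least 2 resamples")
    iu = np.triu_indices(ensemble.S, k=1)
    rel = {}
    for k, var in enumerate(ensemble.variables):
        R = np.corrcoef(ensemble.axes[:, :, k])
        rel[var] = R[iu]
    null, excluded = {}, {}
    vars_ = ensemble.variables
    for i in range(len(vars_)):
        for j in range(i + 1, len(vars_)):
            prod = rel[vars_[i]] * rel[vars_[j]]
            neg = prod < 0
            null[(vars_[i], vars_[j])] = np.sqrt(prod[~neg])
            excluded[(vars_[i], vars_[j])] = float(neg.mean())
    return rel, null, excluded


def separability_test(observed_r: float, null: np.ndarray) -> float:
    """One-tailed t-test that the null sqrt(r_AA r_BB) draws exceed |r_AB|.

    Small p means the observed between-variable correlation sits below what
    perfectly correlated but noisy axes would produce: the representations
    are separable.  A zero-variance null degenerates to an exact comparison.
    """
    null = np.asarray(null, dtype=float)
    null = null[np.isfinite(null)]
    if null.size == 0:
        raise ValueError("empty null distribution")
    if np.std(null) == 0:
        return 0.0 if null.mean() > observed_r else 1.0
    res = stats.ttest_1samp(null, popmean=observed_r, alternative="greater")
    return float(res.pvalue)


def unit_significance(ensemble: BootstrapEnsemble) -> np.ndarray:
    """Two-tailed z-test per (unit, variable) that the bootstrap coefficient
    distribution excludes zero.  Returns an (N, K) array of p-values."""
    if ensemble.S < 30:
        raise ValueError("z approximation needs S >= 30")
    mean = ensemble.axes.mean(axis=0)      # N x K
    sd = ensemble.axes.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = np.nonzero(sd == 0)
        raise ValueError(f"zero-s.d. coefficient distribution at {bad}")
    z = mean / sd
    return 2 * stats.norm.sf(np.abs(z))


def mixed_selectivity_test(unit_pvalues: np.ndarray, alpha: float = 0.05) -> dict:
    """Is the proportion of multi-variable units more than specialization
    predicts, and consistent with independent selectivity?

    (a) Specialized null: every unit truly codes at most one variable, so a
    second significant call is a false positive; the count of >=2-variable
    units is compared to Binomial(N, 1-(1-alpha)^(K-1)) with alternative
    'greater' (rejecting says overlap exceeds what specialization allows).
    (b) Independence null: per-variable marginal rates are as observed and
    independent across variables; the overlap count is compared two-sided to
    Binomial(N, P(>=2 | independent marginals)).
    """
    P = np.asarray(unit_pvalues)
    if P.ndim != 2 or P.shape[1] < 2:
        raise ValueError("need per-unit p-values for at least 2 variables")
    N, K = P.shape
    sig = P < alpha
    n_multi = int((sig.sum(axis=1) >= 2).sum())
    # (a) specialized: true variable detected, others only by false positives
    p_spec = 1 - (1 - alpha) ** (K - 1)
    test_a = stats.binomtest(n_multi, N, p_spec, alternative="greater")
    # (b) independent selectivity at the observed marginal rates
    rates = sig.mean(axis=0)
    p_none = np.prod(1 - rates)
    p_one = sum(rates[k] * np.prod(np.delete(1 - rates, k)) for k in range(K))
    p_multi = max(1.0 - p_none - p_one, 0.0)
    test_b = stats.binomtest(n_multi, N, p_multi, alternative="two-sided") \
        if 0 < p_multi < 1 else None
    return {
        "n_units": N,
        "n_multi": n_multi,
        "marginal_rates": rates,
        "p_specialized": float(test_a.pvalue),
        "expected_specialized": N * p_spec,
        "p_independent": float(test_b.pvalue) if test_b else float("nan"),
        "expected_independent": N * p_multi,
    }


def separability_analysis(observed_axes: np.ndarray, variables: list,
                          ensemble: BootstrapEnsemble) -> SeparabilityResult:
    """Full pairwise separability workflow from full-data axes + ensemble.

    ``observed_axes`` are the non-orthogonalized full-data sRAs (N, K); the
    observed |r_AB| per pair is their column correlation.
    """
    rel, null, excluded = reliability_and_null(ensemble)
    observed_r, pvals, sep = {}, {}, {}
    for i in range(len(variables)):
        for j in range(i + 1, len(variables)):
            pair = (variables[i], variables[j])
            r = abs(float(np.corrcoef(observed_axes[:, i],
                                      observed_axes[:, j])[0, 1]))
            observed_r[pair] = r
            pvals[pair] = separability_test(r, null[pair])
            sep[pair] = pvals[pair] < 0.05
    return SeparabilityResult(observed_r, rel, null, excluded, pvals, sep)
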