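"""Saturating-logistic choice model, likelihood-ratio model selection, and
rejection hazard-rate estimation.

The probability of accepting an offer is P(accept) = delta / (1 + exp(-Z))
with Z = beta0 + beta1 * benefit^gamma, benefit pre-scaled to [0, 1];
0 <= delta <= 1 caps the psychometric curve (lapse rate), and the optional
exponent gamma implements a non-linear utility function.  Nested variants
(gamma free vs gamma = 1) are compared across sessions by a one-sided
Kolmogorov-Smirnov test of the log-likelihood-ratio distribution against
its chi-squared reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .popdata import OFFER_DOMAIN

__all__ = [
    "ChoiceModelFit", "HazardCurve",
    "fit_choice_model", "lr_model_selection", "hazard_rate",
]

_MAX_OFFER = float(max(OFFER_DOMAIN))


@dataclass
class ChoiceModelFit:
    beta0: float
    beta1: float
    delta: float
    gamma: float
    gamma_free: bool
    logL: float
    n_trials: int
    converged: bool
    se: np.ndarray | None = None      # asymptotic s.e. of the free parameters
    param_names: tuple = ()

    @property
    def df(self) -> int:
        return 3 + int(self.gamma_free)

    def predict(self, offers: np.ndarray) -> np.ndarray:
        """P(accept) per raw offer size."""
        b = np.asarray(offers, dtype=float) / _MAX_OFFER
        z = self.beta0 + self.beta1 * b ** self.gamma
        return self.delta / (1 + np.exp(-z))


def _nll(params, b, y, gamma_free):
    beta0, beta1, delta = params[:3]
    gamma = np.exp(params[3]) if gamma_free else 1.0
    z = beta0 + beta1 * b ** gamma
    p = delta / (1 + np.exp(-z))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))


def fit_choice_model(offers: np.ndarray, choices: np.ndarray,
                     gamma_free: bool = False,
                     singleton: np.ndarray | None = None,
                     n_starts: int = 5, seed: int | None = 0) -> ChoiceModelFit:
    """Maximum-likelihood fit of the saturating logistic choice model.

    ``offers`` are raw drop counts {0,1,2,4,8}; ``choices`` binary accepts.
    Singleton trials (flagged via ``singleton``) are excluded from the fit.
    gamma is searched on a log scale within [0.1, 5] from multiple starting
    points because the likelihood is flat in gamma.
    """
    offers = np.asarray(offers, dtype=float)
    choices = np.asarray(choices, dtype=float)
    if singleton is not None:
        keep = ~np.asarray(singleton, dtype=bool)
        offers, choices = offers[keep], choices[keep]
    if not np.isin(choices, (0.0, 1.0)).all():
        raise ValueError("choices must be binary")
    b = offers / _MAX_OFFER
    bounds = [(-30, 30), (-60, 60), (0.0, 1.0)]
    starts = [np.array([-1.0, 3.0, 0.9]), np.array([0.0, 1.0, 0.99]),
              np.array([-3.0, 6.0, 0.8])]
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts:
        starts.append(np.array([rng.uniform(-5, 2), rng.uniform(0, 10),
                                rng.uniform(0.5, 1.0)]))
    if gamma_free:
        bounds.append((np.log(0.1), np.log(5.0)))
        starts = [np.append(s, np.log(g))
                  for s in starts for g in (0.5, 1.0, 2.0)]
    best = None
    for x0 in starts:
        res = optimize.minimize(_nll, x0, args=(b, choices, gamma_free),
                                method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if not best.success:
        warnings.warn("choice-model optimizer did not report convergence "
                      "(possible complete separation); returning bounded "
                      "best iterate", stacklevel=2)
    se = _asymptotic_se(best.x, b, choices, gamma_free)
    names = ("beta0", "beta1", "delta") + (("gamma",) if gamma_free else ())
    return ChoiceModelFit(
        beta0=float(best.x[0]), beta1=float(best.x[1]), delta=float(best.x[2]),
        gamma=float(np.exp(best.x[3])) if gamma_free else 1.0,
        gamma_free=gamma_free, logL=-float(best.fun), n_trials=len(choices),
        converged=bool(best.success), se=se, param_names=names)


def _asymptotic_se(x, b, y, gamma_free, eps=1e-4):
    """Numerical observed-information standard errors (gamma on natural scale)."""
    k = len(x)
    H = np.zeros((k, k))
    f = lambda p: _nll(p, b, y, gamma_free)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            H[i, j] = H[j, i] = (f(x + ei + ej) - f(x + ei - ej)
                                 - f(x - ei + ej) + f(x - ei - ej)) / (4 * eps ** 2)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    var = np.diag(cov).copy()
    if gamma_free:
        # delta method from log-gamma to gamma
        var[3] = var[3] * np.exp(x[3]) ** 2
    with np.errstate(invalid="ignore"):
        return np.sqrt(np.where(var > 0, var, np.nan))


def lr_model_selection(fits_complex: list, fits_simple: list,
                       alpha: float = 0.05) -> dict:
    """Across-session likelihood-ratio model selection.

    Per session LR = 2 (logL_complex - logL_simple); under the null the LRs
    follow a chi-squared with df_complex - df_simple degrees of freedom.  A
    one-sided KS test asks whether the empirical LR distribution is
    right-shifted relative to that reference; the complex model is selected
    for all sessions when p < alpha.
    """
    if len(fits_complex) != len(fits_simple):
        raise ValueError("need paired per-session fits")
    ddf = fits_complex[0].df - fits_simple[0].df
    if ddf <= 0:
        raise ValueError("models are not nested (df_a must exceed df_b)")
    lr = np.array([2 * (a.logL - bfit.logL)
                   for a, bfit in zip(fits_complex, fits_simple)])
    lr = np.clip(lr, 0.0, None)  # numerical guard: nested MLE cannot be worse
    ks = stats.ks_1samp(lr, stats.chi2(ddf).cdf, alternative="less")
    return {
        "lr": lr,
        "median_lr": float(np.median(lr)),
        "df": ddf,
        "p": float(ks.pvalue),
        "select_complex": bool(ks.pvalue < alpha),
    }


@dataclass
class HazardCurve:
    """Discrete-time rejection hazard per offer size."""

    bin_edges: np.ndarray        # len T+1, seconds
    hazard: np.ndarray           # per bin, in [0, 1]
    sd: np.ndarray               # binomial s.e. per bin
    at_risk: np.ndarray          # trials alive entering each bin
    rejections: np.ndarray
    offer: int | None = None

    def survival(self) -> np.ndarray:
        return np.cumprod(1.0 - self.hazard)


def hazard_rate(reject_times: np.ndarray, censor_time: float,
                bin_width: float = 0.1, offer: int | None = None) -> HazardCurve:
    """Discrete-time hazard of rejection with binomial standard errors.

    ``reject_times`` holds the rejection time in seconds per trial, NaN for
    accepted trials (censored at ``censor_time``, the end of the work
    period).  hazard(t) = rejections in bin t / trials still at risk at the
    start of bin t.
    """
    rt = np.asarray(reject_times, dtype=float)
    n_bins = int(np.ceil(censor_time / bin_width - 1e-9))
    edges = np.arange(n_bins + 1) * bin_width
    hazard = np.zeros(n_bins)
    sd = np.zeros(n_bins)
    rejections = np.zeros(n_bins, dtype=int)
    at_risk = np.zeros(n_bins, dtype=int)
    alive = len(rt)
    for t in range(n_bins):
        at_risk[t] = alive
        in_bin = np.sum((rt >= edges[t]) & (rt < edges[t + 1]))
        rejections[t] = in_bin
        if alive > 0:
            h = in_bin / alive
            hazard[t] = h
            sd[t] = np.sqrt(h * (1 - h) / alive)
        alive -= in_bin
    return HazardCurve(edges, hazard, sd, at_risk, rejections, offer)
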