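"""Synthetic trial-structured population data with planted coding axes.

The generator emulates the study conditions every other module is tested
against: five offer sizes {0,1,2,4,8} crossed with a binary accept/reject
choice drawn from the saturating-logistic choice model (so trial counts are
naturally unbalanced), condition-dependent linear coding along planted
unit-norm axes with time-varying gains, temporally smooth Gaussian noise
with non-trivial inter-unit covariance, and optional previous-trial coding
during the pre-offer window.  Rates are in spikes/s per 100 ms bin aligned
to offer onset; population size, trial count and noise level default to the
regime the analyses are designed for (100 units, 2000 trials, moderate
noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .popdata import OFFER_DOMAIN, Condition, TrialTable

__all__ = ["SynthSpec", "GroundTruth", "generate", "plant_stability_profile"]

_MAX_OFFER = float(max(OFFER_DOMAIN))


@dataclass
class SynthSpec:
    """Generative parameters for one synthetic session.

    Time runs from ``t_pre`` to ``t_post`` seconds around offer onset in
    ``bin_width`` bins.  ``amplitude`` scales the planted coding (spikes/s
    for a unit with planted loading 1 and predictor value 1); per-variable
    gain profiles modulate it over time (benefit during the offer period
    with an exponential tail, choice and expected reward ramping on during
    the work period, previous-trial variables during the pre-offer window).
    ``noise_sd`` is the per-trial, per-bin rate s.d. before temporal
    smoothing; ``noise_time_const`` the Gaussian smoothing kernel s.d. in
    seconds; ``noise_unit_corr`` the weight of the shared low-rank component
    generating inter-unit noise correlations.
    """

    n_units: int = 100
    n_trials: int = 2000
    t_pre: float = -0.5
    t_post: float = 3.5
    bin_width: float = 0.1
    offer_epoch: tuple = (0.0, 0.5)
    amplitude: float = 8.0
    prev_amplitude: float = 8.0
    cc_amplitude: float = 4.0
    baseline_range: tuple = (5.0, 20.0)
    noise_sd: float = 2.0
    noise_time_const: float = 0.15
    noise_unit_corr: float = 0.3
    noise_unit_rank: int = 5
    beta0: float = -3.0
    beta1: float = 6.0
    delta: float = 0.95
    gamma: float = 1.0
    reject_hazard: float = 0.08       # per 100 ms bin, scaled by offer
    singleton_fraction: float = 0.0   # of 8-reward offers
    axis_angle: float | None = None   # None -> orthogonal planted axes
    gain_overrides: dict | None = None  # variable -> callable(centers)->gain
    seed: int = 0


@dataclass
class GroundTruth:
    """What was planted: axes, gains, behavioral parameters."""

    axes: np.ndarray                  # N x 3 (benefit, choice, expected reward)
    prev_axes: np.ndarray             # N x 3 previous-trial analogues
    gains: dict                       # variable -> (T,) profile
    variables: list = field(default_factory=lambda: [
        "benefit", "choice", "expected_reward"])
    behavior: dict = field(default_factory=dict)
    baselines: np.ndarray | None = None
    regimes: list | None = None


def _offer_sequence(n_trials: int, rng) -> np.ndarray:
    """Pseudorandom offers: every 10 trials contain each offer exactly twice."""
    block = np.repeat(OFFER_DOMAIN, 2)
    out = np.concatenate([rng.permutation(block)
                          for _ in range(int(np.ceil(n_trials / 10)))])
    return out[:n_trials]


def _accept_probability(offers, spec: SynthSpec) -> np.ndarray:
    b = offers / _MAX_OFFER
    z = spec.beta0 + spec.beta1 * b ** spec.gamma
    return spec.delta / (1 + np.exp(-z))


def _gain_profiles(spec: SynthSpec, centers: np.ndarray) -> dict:
    """Smooth, graded per-variable gains.

    Benefit coding rises quickly at offer onset and decays slowly through the
    work period; choice and expected-reward coding ramp on after the offer
    and saturate; previous-trial coding is strongest before the offer and
    fades after it.
    """
    on, off = spec.offer_epoch
    t = centers - on
    rise = np.where(t > 0, 1 - np.exp(-np.clip(t, 0, None) / 0.05), 0.0)
    benefit = rise * np.exp(-np.clip(t - (off - on), 0, None) / 1.2)
    work = 1.0 / (1 + np.exp(-(centers - (off + 0.3)) / 0.15))
    pre = np.where(centers < on, 1.0,
                   np.exp(-np.clip(centers - on, 0, None) / 0.2))
    gains = {
        "benefit": benefit,
        "choice": work,
        "expected_reward": work,
        "prev_benefit": pre,
        "prev_choice": pre,
        "experienced_reward": pre,
    }
    if spec.gain_overrides:
        for var, fn in spec.gain_overrides.items():
            if var not in gains:
                raise ValueError(f"unknown variable {var!r}")
            gains[var] = np.asarray(fn(centers), dtype=float)
    return gains


def _planted_axes(spec: SynthSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    if spec.n_units < 6:
        raise ValueError("need at least 6 units to plant 6 orthogonal axes")
    Q, _ = np.linalg.qr(rng.standard_normal((spec.n_units, 6)))
    axes, prev_axes = Q[:, :3].copy(), Q[:, 3:].copy()
    if spec.axis_angle is not None:
        # rotate axis 2 toward axis 1 so their angle equals axis_angle
        th = np.radians(spec.axis_angle)
        axes[:, 1] = np.cos(th) * axes[:, 0] + np.sin(th) * axes[:, 1]
    return axes, prev_axes


def _smooth_noise(shape, spec: SynthSpec, rng) -> np.ndarray:
    """(N, R, T) noise, unit marginal s.d., smooth in t, correlated across units."""
    from scipy.signal import fftconvolve

    N, R, T = shape
    sigma_bins = spec.noise_time_const / spec.bin_width
    half = int(np.ceil(4 * sigma_bins))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma_bins) ** 2)
    k /= np.sqrt(np.sum(k ** 2))          # preserve marginal variance

    def smooth(x):
        # generate extra samples at both ends so the smoothed series keeps
        # unit variance at the edges, then crop back to T bins
        return fftconvolve(x, k[None, None, :], mode="valid", axes=-1)

    sm = smooth(rng.standard_normal((N, R, T + 2 * half)))
    c = spec.noise_unit_corr
    if c > 0 and spec.noise_unit_rank > 0:
        G = rng.standard_normal((N, spec.noise_unit_rank)) / np.sqrt(
            spec.noise_unit_rank)
        shared = smooth(rng.standard_normal(
            (spec.noise_unit_rank, R, T + 2 * half)))
        sm = np.sqrt(1 - c) * sm + np.sqrt(c) * np.einsum(
            "nm,mrt->nrt", G, shared)
    return spec.noise_sd * sm


def _predictor_values(offers, choices) -> dict:
    b = offers / _MAX_OFFER
    return {"benefit": b, "choice": choices.astype(float),
            "expected_reward": b * choices}


def generate(spec: SynthSpec) -> tuple[TrialTable, GroundTruth]:
    """Draw one synthetic session.

    Choices come from the saturating-logistic model given the offer; firing
    rates are baseline + sum_k gain_k(t) * amplitude * axis_{k,n} * P_k(r)
    (+ previous-trial terms during the pre-offer window) + smooth correlated
    Gaussian noise, floored at zero.
    """
    rng = np.random.default_rng(spec.seed)
    offers = _offer_sequence(spec.n_trials, rng)
    p_acc = _accept_probability(offers, spec)
    choices = (rng.random(spec.n_trials) < p_acc).astype(int)
    singleton = np.zeros(spec.n_trials, dtype=bool)
    if spec.singleton_fraction > 0:
        eight = np.nonzero(offers == 8)[0]
        pick = rng.random(eight.size) < spec.singleton_fraction
        singleton[eight[pick]] = True

    centers = np.arange(spec.t_pre + spec.bin_width / 2, spec.t_post,
                        spec.bin_width)
    bin_starts = centers - spec.bin_width / 2
    T = len(centers)
    gains = _gain_profiles(spec, centers)
    axes, prev_axes = _planted_axes(spec, rng)
    baselines = rng.uniform(*spec.baseline_range, size=spec.n_units)

    P = _predictor_values(offers, choices)
    rates = np.broadcast_to(baselines[:, None, None],
                            (spec.n_units, spec.n_trials, T)).copy()
    # condition-independent event-locked dynamics (the common-condition
    # response): per-unit random mix of an offer transient and a sustained
    # work-period component
    if spec.cc_amplitude > 0:
        transient = np.where(centers >= 0,
                             np.exp(-np.clip(centers, 0, None) / 0.4), 0.0)
        sustained = np.clip(centers / 1.0, 0, 1)
        W = rng.standard_normal((spec.n_units, 2)) * spec.cc_amplitude
        cc = W @ np.vstack([transient, sustained])
        rates += cc[:, None, :]
    for k, var in enumerate(("benefit", "choice", "expected_reward")):
        rates += (spec.amplitude * axes[:, k][:, None, None]
                  * P[var][None, :, None] * gains[var][None, None, :])
    if spec.prev_amplitude > 0:
        prev_offers = np.roll(offers, 1).astype(float)
        prev_choices = np.roll(choices, 1).astype(float)
        prev_offers[0] = np.nan
        prev_choices[0] = np.nan
        Pp = {"prev_benefit": prev_offers / _MAX_OFFER,
              "prev_choice": prev_choices,
              "experienced_reward": prev_offers / _MAX_OFFER * prev_choices}
        for k, var in enumerate(("prev_benefit", "prev_choice",
                                 "experienced_reward")):
            vals = np.nan_to_num(Pp[var])
            rates += (spec.prev_amplitude * prev_axes[:, k][:, None, None]
                      * vals[None, :, None] * gains[var][None, None, :])
    else:
        prev_offers = np.roll(offers, 1).astype(float)
        prev_choices = np.roll(choices, 1).astype(float)
        prev_offers[0] = np.nan
        prev_choices[0] = np.nan

    rates += _smooth_noise(rates.shape, spec, rng)
    np.clip(rates, 0.0, None, out=rates)

    # rejection timing: constant per-bin hazard, lower for larger offers
    work_bins = np.nonzero(centers >= 0)[0]
    reject_time = np.full(spec.n_trials, np.nan)
    for r in np.nonzero(choices == 0)[0]:
        h = spec.reject_hazard * (1.5 - offers[r] / _MAX_OFFER)
        h = min(max(h, 1e-3), 0.95)
        # truncated geometric over the work-period bins
        probs = h * (1 - h) ** np.arange(len(work_bins))
        probs /= probs.sum()
        j = rng.choice(len(work_bins), p=probs)
        reject_time[r] = centers[work_bins[j]] - spec.bin_width / 2

    trials = pd.DataFrame({
        "trial_id": np.arange(spec.n_trials),
        "session_id": 0,
        "offer": offers,
        "choice": choices,
        "singleton": singleton,
        "prev_offer": prev_offers,
        "prev_choice": prev_choices,
        "reject_time": reject_time,
    })
    table = TrialTable(rates, trials, list(range(spec.n_units)), bin_starts,
                       spec.bin_width, "offer")
    truth = GroundTruth(
        axes=axes, prev_axes=prev_axes, gains=gains,
        behavior={"beta0": spec.beta0, "beta1": spec.beta1,
                  "delta": spec.delta, "gamma": spec.gamma},
        baselines=baselines)
    return table, truth


def plant_stability_profile(spec: SynthSpec, regimes: list) -> tuple[TrialTable, GroundTruth]:
    """Plant per-window coding axes for one variable to test stability metrics.

    ``regimes`` is a list of ((t_start, t_stop), axis) pairs for the benefit
    variable; windows must not overlap.  The axis identity switches between
    windows while choice behavior and noise are generated as in
    :func:`generate`.
    """
    spans = sorted(w for w, _ in regimes)
    for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
        if s1 < e0:
            raise ValueError("overlapping regime windows for one variable")
    base = replace(spec, amplitude=0.0, prev_amplitude=0.0)
    table, truth = generate(base)
    rng = np.random.default_rng(spec.seed + 1)
    centers = table.bin_starts + table.bin_width / 2
    offers = table.trials["offer"].to_numpy(dtype=float)
    Pb = offers / _MAX_OFFER
    rates = table.rates
    planted = []
    for (t0, t1), axis in regimes:
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        win = ((centers >= t0) & (centers < t1)).astype(float)
        rates += (spec.amplitude * axis[:, None, None]
                  * Pb[None, :, None] * win[None, None, :])
        planted.append(((t0, t1), axis))
    np.clip(rates, 0.0, None, out=rates)
    truth.regimes = planted
    return table, truth
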