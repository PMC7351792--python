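# Methods

## The analysis problem

Serially recorded units from a cost-benefit decision task are combined into
a pseudo-population. On each trial the animal sees an offer of 0, 1, 2, 4 or
8 juice drops and either accepts it (by holding fixation through a work
period) or rejects it (by breaking fixation). Three task variables are
defined per trial: **benefit** (offer size, scaled to [0, 1]), **choice**
(reject = 0, accept = 1), and **expected reward** (benefit x choice, scaled
to [0, 1]). The package discovers low-dimensional linear representations of
these variables in the population response and supplies the statistics
needed to interpret them.

## Preprocessing

Firing rates are binned in non-overlapping 100 ms bins aligned to offer
onset (left-closed / right-open, a bin edge at t = 0). Units are excluded
when recorded for fewer than 60 trials, when any included condition has
fewer than 5 trials, or when the trial-average rate s.d. across conditions
and bins falls below 0.5 spikes/s (such units would be grossly over-weighted
by z-scoring). Runs of 5+ consecutive trials on which a unit is absent
(mean rate < 0.1 spikes/s) are struck for that unit. Conditions in which
fewer than 40% of units reach the 5-trial floor are dropped globally — with
the synthetic defaults this typically leaves 9 or 10 of the 10 offer x
choice conditions. The rules are applied unit-first, then the condition
rule, then the per-condition floor is re-checked; the filter is idempotent.

Trial-average responses per condition are z-scored per unit across all
(condition, time) entries, and the common-condition response (the
across-condition mean time course) is subtracted unless requested
otherwise. Bootstrap resamples reuse the full-data z statistics, which
deliberately depresses resample-to-resample reliability and makes the
separability test more conservative.

## Static regression axes (sRAs)

All model assumptions are combined in one objective,

    min_{B, B0}  sum_e || (Rbar^(e) - b0^(e) 1' - sum_k b_k P_k') . sqrt(M) ||_F^2 ,

with one coefficient column per (variable, epoch), a per-epoch constant
that is never part of any constraint, and element-wise sqrt-trial-count
weighting (the trial-average problem scaled this way is equivalent to the
single-trial regression, so better-sampled conditions properly dominate).
In the study configuration benefit is fit on the offer epoch T1 = [0, 0.5 s)
and choice and expected reward are fit together on the work epoch T2, where
they compete for shared variance; all three axes are constrained mutually
orthogonal so that projections are independent readouts.

The constraint set (mutually orthogonal columns with free norms) is
parameterized as Q diag(s) with Q an orthonormal frame. The solver
alternates (a) an exact dense least-squares solve for the constants, the
scalings s and any unconstrained columns given Q, with (b) projected
Riemannian gradient descent on Q (QR retraction, Barzilai-Borwein step,
backtracking). The problem is non-convex: besides the polar-decomposition
initialization from the unconstrained fit and 10 random restarts, the
solver scores a batch of random frames (1000 when N <= 25, else 100) by the
exact linear subproblem and descends from the best five. Convergence is a
relative objective change below 1e-9 (cap 5000 outer iterations). Axis
signs are fixed so the epoch-average projection correlates positively with
the on-target variable. The optional top-D PC pre-projection of the axes is
off by default. Unconstrained fits skip all of this and use the per-unit
closed form.

## Dynamic regression axes (dRAs)

Per 200 ms bin (adjacent 100 ms bins averaged pairwise, never straddling
t = 0; an unpaired bin next to t = 0 is dropped), each unit's response is
regressed on the three predictors with an L2 penalty, after an optional PCA
noise-reduction step on the N x (T*C) unfolding (D chosen at the maximum
curvature of the log-eigenvalue scree when set to "auto"). The penalty
lambda_n(t) is picked per unit and bin by leave-one-out cross-validation
over conditions on a logarithmic grid (1e-4 … 1e4, 25 points) plus an
infinite-penalty sentinel that zeroes the unit's coefficients outright.
Following the regularization term as written, the intercept is penalized
together with the coefficients; `penalize_intercept=False` restores the
conventional treatment. The weighted Gram matrices and their leave-one-out
downdates do not depend on the time bin, so their eigendecompositions are
computed once and shared across bins and penalties. dRAs are never
orthogonalized and never projected onto.

## Variance decomposition

V_k(t) is the cross-condition variance of the projection onto axis k as a
percentage of the summed cross-condition variance of all units. On-target
relevant signal variance is RSV_k = V_k r^2 (r the Pearson correlation of
the projection with the variable across included conditions, per bin);
irrelevant signal variance is ISV_k = V_k - RSV_k, computed on-target only.
Off-target RSV replaces r with the semi-partial correlation of the
projection with the off-target variable controlling for the on-target one,
so that correlated predictors (benefit and expected reward correlate at
r = 0.54 over the 9 included conditions) are not double counted. When the
projection has zero variance at a bin, RSV and ISV are defined as 0. For
PCs, the on-target PC is the one with the greatest cumulative plain RSV
across time; remaining PCs get off-target RSV conditioned on the on-target
PC's projection.

## Geometry and stability

Axis similarity uses the folded angle arccos(|b_i . b_j|) in [0, 90]
(anti-parallel axes are identical representations) and, exclusively to
track sign reversals, the unfolded angle arccos(b_i . b_j), defined only
when the dot product is negative (range [90, 180], NaN otherwise). Subspace
overlap uses the alignment index Tr(U1' U2 U2' U1) / min(D1, D2) in [0, 1].

Periods of putative stability are found by fitting a single boxcar (height
h over [a, b], zero outside) to 90 deg - theta_i. for each reference bin i,
by exhaustive search over all spans with the closed-form optimal height
(diagonal excluded; ties broken longest-then-earliest). Significance is
assessed against surrogate ensembles. The default null statistic is
**selection-matched**: every surrogate row is fit with its own best boxcar
and contributes that height. Because each surrogate undergoes exactly the
span-selection step the observed row did, p-values are uniform under
exchangeability; measured on pure surrogate data the false-flag rate at
p < 0.01 is 0/432 rows. The fixed-span alternative (surrogate mean
similarity over the observed span; `null="span"`) ignores the selection
step and flags ~9% of pure-noise rows, and is kept only for comparison.

## Null models

*Covariance-aligned random dimensions.* v = U sqrt(S) z / ||.|| with (U, S)
the eigendecomposition of the covariance of the N x (T*C) unfolding and z
standard normal: directions the population occupies often are sampled
proportionally more often. P-values from these dimensions are conservative
relative to isotropic ones on anisotropic data.

*Surrogate ensembles.* Design-free tensors drawn per condition from a
Kronecker-separable matrix normal whose unit covariance (pooled over
conditions and time) and temporal covariance (pooled over units and
conditions, rescaled to unit mean diagonal) match the mean-subtracted data;
0.01 diagonal shrinkage stabilizes the estimates. Because trial-average
tensors are strongly heteroscedastic across conditions (rare conditions are
averaged over ~10x fewer trials), each condition slab is additionally
scaled to the condition's observed share of power, with the scales
normalized to mean one so the pooled covariance targets are unchanged.
Without this the surrogate null under-disperses and rejects a
data-independent query axis at ~8% instead of <= 5%.

Empirical p-values use the add-one rule (1 + #{null >= obs}) / (1 + n).

A caution that applies to any fixed-dimension null: the on-target RSV of an
axis *refit on the data under test* is strongly selection-biased (with
N >> C a regression can align with a predictor at r ~ 0.8 on pure noise),
and neither null models that selection. Calibration statements here
therefore concern data-independent query axes; an axis refit on null data
will look "significant" against both nulls and must be interpreted against
a refit-matched null instead.

## Separability and mixed selectivity

Axes are refit without orthogonalization on S bootstrap resamples (trials
redrawn with replacement within each unit x condition cell, counts
preserved, full-data z statistics reused; default S = 700). Within-variable
reliabilities r_AA are all (S^2-S)/2 between-resample correlations; under
the null hypothesis of perfectly correlated true axes, Spearman's
attenuation identity gives the null-hypothetical |r_AB| = sqrt(r_AA r_BB)
elementwise (negative products are excluded and counted). A one-tailed
t-test asks whether the observed full-data |r_AB| falls below that null;
the test treats the dependent bootstrap pairs as a sample and is therefore
anti-conservative near the H0 boundary — in simulations with truly
identical axes it rejects far above the nominal rate, while the identity
itself holds tightly (mean observed / mean null = 0.997-1.000 across noise
levels). Separability conclusions should rest on observed correlations
well below the null mass, as in practice they do.

Per-unit significance is a two-tailed z-test on the unit's bootstrap
coefficient distribution. The mixed-selectivity proportion test compares
the count of units significant on 2+ variables against (a) a specialized
null, Binomial(N, 1-(1-alpha)^(K-1)) — overlap from false positives only —
and (b) an independence null at the observed marginal rates.

## Choice behavior

P(accept) = delta / (1 + exp(-(beta0 + beta1 benefit^gamma))) with
0 <= delta <= 1 the saturation (lapse) ceiling and gamma an optional
utility exponent searched on a log scale in [0.1, 5] (the likelihood is
flat in gamma, hence multistart L-BFGS-B). Singleton-offer trials are
excluded from fits. Nested variants are compared per session by
LR = 2(logL_complex - logL_simple) and across sessions by a one-sided KS
test of the LR sample against chi-squared(df difference); the complex model
is adopted when p < 0.05. Standard errors come from the numerical observed
information (delta method for gamma). The rejection hazard is the
discrete-time rate rejections/at-risk per 100 ms bin with binomial standard
errors; accepts are censored at the end of the work period, and the product
of (1 - hazard) equals the empirical survival fraction exactly.

## Synthetic data

The generator emulates the study conditions: offers scheduled so each size
appears twice per 10 trials; choices drawn from the saturating-logistic
model (beta0 = -3, beta1 = 6, delta = 0.95, gamma = 1), which makes trial
counts per condition naturally unbalanced (~10x between common and rare
conditions); rates = baseline + condition-independent event-locked dynamics
(an offer transient plus a sustained component with random per-unit
weights — without these, real-data exclusion rules built around response
variability would remove most units) + planted unit-norm orthogonal axes
per variable with smooth time-varying gains + previous-trial coding in the
pre-offer window + temporally smoothed (Gaussian kernel, s.d. 0.15 s)
Gaussian noise with a low-rank shared component across units, floored at
zero. Defaults are N = 100 units, 2000 trials, coding amplitude 8 spikes/s
and per-trial noise s.d. 2 spikes/s. The noise level and the benefit-gain
decay constant (1.2 s) were chosen together so the planted structure is
identifiable at this scale: the benefit tail must stay resolvable late in
the trial for the dynamic-axis magnitude to track it, yet short enough that
benefit bleed into the work epoch does not distort the choice and
expected-reward axes through the r = 0.54 predictor correlation.

What the generator does *not* emulate: spiking (rates are Gaussian),
session-to-session drift, true simultaneous recording constraints, and
per-unit idiosyncratic tuning nonlinearity. Passing tests therefore show
the estimators behave correctly in the model class the analyses assume,
not that real OFC data satisfy that class.

Planted-axis recovery is always evaluated in the analysis (z-scored) space:
the rate-space axis is divided elementwise by the per-unit z-scoring s.d.
and renormalized before comparison, since regression coefficients are
defined on normalized responses. Note that per-unit rescaling does not
preserve orthogonality, so axes planted orthonormal in rate space are not
exactly orthogonal in the analysis space; stability benchmarks use
disjoint-support axes, which stay orthogonal under any diagonal rescaling.

## Numerical choices and degenerate inputs

- Unit-norm tolerances: 1e-8 on stored axes, 1e-6 on angle inputs.
- Orthogonality violation of constrained pairs <= 1e-6.
- Zero-variance guard: V at bins with no cross-condition variance is NaN;
  RSV/ISV of a zero-variance projection are 0 by definition.
- Degenerate separability null (zero variance) falls back to exact
  comparison.
- Non-PSD covariance estimates are eigenvalue-clipped at zero with a
  warning.
- Boxcar ties are broken deterministically (longest span, then earliest).
- All stochastic procedures take explicit seeds and are bit-reproducible.

## Problem sizes used in the test suite

Unit tests run on populations of 6-30 units and a few hundred trials.
The end-to-end benchmarks use the generator defaults (100 units, 2000
trials, ten seeds) for axis recovery; 100 sessions of 5000 trials for
choice-model coverage; 200 zero-signal populations of 40 units against
1000 aligned dimensions and 200 surrogates for null calibration; and 100
planted-switch simulations of 60 units, 1500 trials and 200 surrogates for
stability detection.
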