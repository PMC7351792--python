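import numpy as np
import pytest

from otdr import popdata, separability as sep
from otdr.otdr_core import EpochSpec
from otdr.separability import BootstrapEnsemble
from otdr.synth import SynthSpec, generate

from conftest import make_trial_table


def synthetic_ensemble(true_axes, noise_sd, S, seed=0):
    """Ensemble of noisy copies of true axes — bypasses the neural fitting."""
    rng = np.random.default_rng(seed)
    N, K = true_axes.shape
    axes = true_axes[None] + rng.normal(0, noise_sd, size=(S, N, K))
    return BootstrapEnsemble(axes, [f"v{k}" for k in range(K)], seed)


@pytest.fixture(scope="module")
def small_boot():
    table, _ = generate(SynthSpec(n_units=12, n_trials=300, t_post=1.5, seed=21))
    table, _ = popdata.filter_units(table)
    pop, M = popdata.build_population_response(table)
    design = popdata.build_design(
        [c for c in pop.condition_index if not c.singleton])
    spec = EpochSpec(epochs={"T1": (0.0, 0.5), "T2": (0.5, 1.5)},
                     assignment={"benefit": "T1", "choice": "T2",
                                 "expected_reward": "T2"})
    boot = sep.bootstrap_axes(table, design, spec, S=40, seed=3,
                              zmean=pop.zmean, zstd=pop.zstd)
    return table, pop, M, design, spec, boot


class TestBootstrap:
    def test_zero_noise_data_gives_unit_reliability(self):
        """With duplicated identical trials every resample is identical and
        r_AA is exactly 1."""
        def plant(rates, offers, choices):
            rates[:] = 1.0
            base = np.linspace(1, 2, rates.shape[0])
            for u in range(rates.shape[0]):
                rates[u] += base[u] * offers[:, None] * 0.3
                rates[u] += (u % 2) * choices[:, None] * 0.7
                rates[u, :, :2] += 0.5 * u  # time structure for the s.d. rule
            return rates
        table = make_trial_table(n_units=6, n_trials=400, seed=30,
                                 rate_fn=lambda r, o, c: plant(np.zeros_like(r), o, c))
        table, _ = popdata.filter_units(table)
        pop, M = popdata.build_population_response(table)
        design = popdata.build_design(
            [c for c in pop.condition_index if not c.singleton])
        spec = EpochSpec(epochs={"all": (-0.2, 0.6)},
                         assignment={v: "all" for v in design.variables})
        boot = sep.bootstrap_axes(table, design, spec, S=8, seed=0,
                                  zmean=pop.zmean, zstd=pop.zstd)
        rel, null, _ = sep.reliability_and_null(boot)
        for var in boot.variables:
            np.testing.assert_allclose(rel[var], 1.0, atol=1e-10)
        for pair in null:
            np.testing.assert_allclose(null[pair], 1.0, atol=1e-10)

    def test_resampling_preserves_trial_counts(self, small_boot):
        table, pop, M, design, spec, boot = small_boot
        assert boot.S == 40
        assert boot.axes.shape == (40, pop.n_units, 3)
        # determinism under the seed
        boot2 = sep.bootstrap_axes(table, design, spec, S=40, seed=3,
                                   zmean=pop.zmean, zstd=pop.zstd)
        np.testing.assert_array_equal(boot.axes, boot2.axes)

    def test_reliability_decreases_with_noise(self):
        """Mean within-variable reliability is monotone in axis noise."""
        rng = np.random.default_rng(1)
        true = rng.normal(size=(20, 2))
        means = []
        for noise in (0.05, 0.2, 0.8):
            ens = synthetic_ensemble(true, noise, S=60, seed=5)
            rel, _, _ = sep.reliability_and_null(ens)
            means.append(np.mean([rel[v].mean() for v in ens.variables]))
        assert means[0] > means[1] > means[2]


class TestReliabilityAndNull:
    def test_pair_count_identity(self):
        ens = synthetic_ensemble(np.random.default_rng(0).normal(size=(5, 2)),
                                 0.1, S=700, seed=1)
        rel, null, _ = sep.reliability_and_null(ens)
        assert len(rel["v0"]) == 244_650
        assert len(null[("v0", "v1")]) <= 244_650

    def test_constant_reliabilities_give_constant_null(self):
        # hand-built reliability product: sqrt(0.64 * 0.81) = 0.72
        assert np.sqrt(0.64 * 0.81) == pytest.approx(0.72)
        ens = synthetic_ensemble(np.random.default_rng(2).normal(size=(40, 2)),
                                 1e-9, S=20, seed=2)
        _, null, excl = sep.reliability_and_null(ens)
        np.testing.assert_allclose(null[("v0", "v1")], 1.0, atol=1e-6)
        assert excl[("v0", "v1")] == 0.0

    def test_negative_products_excluded_and_counted(self):
        ens = synthetic_ensemble(np.zeros((30, 2)), 1.0, S=40, seed=3)
        _, null, excl = sep.reliability_and_null(ens)
        pair = ("v0", "v1")
        assert np.all(np.isfinite(null[pair]))
        assert np.all(null[pair] >= 0)
        assert excl[pair] > 0  # pure-noise reliabilities straddle zero


class TestSeparabilityTest:
    def test_observed_far_below_null_rejects(self):
        null = np.random.default_rng(0).normal(0.8, 0.02, size=1000)
        assert sep.separability_test(0.2, null) < 1e-10

    def test_observed_at_null_mean_is_half(self):
        null = np.random.default_rng(1).normal(0.8, 0.05, size=2000)
        p = sep.separability_test(float(null.mean()), null)
        assert p == pytest.approx(0.5, abs=0.02)

    def test_degenerate_null_exact_comparison(self):
        assert sep.separability_test(0.5, np.full(10, 0.9)) == 0.0
        assert sep.separability_test(0.95, np.full(10, 0.9)) == 1.0

    def test_attenuation_lock_step_for_identical_axes(self):
        """For truly identical representations the observed between-variable
        correlation and the attenuation-corrected null move in lock-step:
        their means agree to a few percent at every noise level (Spearman's
        identity), both decrease monotonically with noise, and the fraction
        of spurious separability calls does not grow with noise."""
        import pandas as pd
        from otdr.popdata import TrialTable
        from otdr.otdr_core import fit_static_axes

        def one(seed, noise):
            rng = np.random.default_rng(seed)
            n_units, n_trials, n_bins = 12, 200, 6
            offers = rng.choice([0, 1, 2, 4, 8], size=n_trials)
            choices = rng.integers(0, 2, size=n_trials)
            a = rng.normal(size=n_units)
            a /= np.linalg.norm(a)
            # one axis codes BOTH variables: |r_A'B'| = 1 by construction
            drive = (offers / 8.0 + choices)[None, :, None]
            rates = 8.0 + 4 * a[:, None, None] * drive \
                + rng.normal(0, noise, size=(n_units, n_trials, n_bins)) \
                + np.linspace(0, 2, n_bins)[None, None, :] \
                * rng.uniform(0.5, 1.5, n_units)[:, None, None]
            trials = pd.DataFrame({
                "trial_id": np.arange(n_trials), "session_id": 0,
                "offer": offers, "choice": choices, "singleton": False,
                "prev_offer": np.nan, "prev_choice": np.nan})
            table = TrialTable(np.clip(rates, 0, None), trials,
                               list(range(n_units)), 0.1 * np.arange(n_bins))
            table, _ = popdata.filter_units(table)
            pop, M = popdata.build_population_response(table)
            design = popdata.build_design(
                [c for c in pop.condition_index if not c.singleton],
                ("benefit", "choice"))
            spec = EpochSpec(epochs={"all": (0.0, 0.6)},
                             assignment={"benefit": "all", "choice": "all"})
            free = fit_static_axes(pop, design, M, spec, orthogonalize=False)
            boot = sep.bootstrap_axes(table, design, spec, S=20, seed=seed + 1,
                                      zmean=pop.zmean, zstd=pop.zstd)
            _, null, _ = sep.reliability_and_null(boot)
            r = abs(np.corrcoef(free.B[:, 0], free.B[:, 1])[0, 1])
            nd = null[("benefit", "choice")]
            return r, nd.mean(), np.percentile(nd, 5)

        stats = {}
        for noise in (0.5, 1.0, 2.5):
            res = np.array([one(400 + s, noise) for s in range(30)])
            stats[noise] = (res[:, 0].mean(), res[:, 1].mean(),
                            (res[:, 0] < res[:, 2]).mean())
        for noise, (obs, null_mean, _) in stats.items():
            assert obs / null_mean == pytest.approx(1.0, abs=0.05)
        assert stats[0.5][0] > stats[2.5][0]          # attenuation of observed
        assert stats[0.5][1] > stats[2.5][1]          # null follows in lock-step
        assert stats[2.5][2] <= stats[0.5][2] + 0.15  # decisions conserved

    def test_orthogonal_axes_detected_as_separable(self):
        rng = np.random.default_rng(5)
        a = np.zeros(30); a[:15] = rng.normal(size=15)
        b = np.zeros(30); b[15:] = rng.normal(size=15)
        true = np.column_stack([a / np.linalg.norm(a), b / np.linalg.norm(b)])
        ens = synthetic_ensemble(true, 0.05, S=40, seed=6)
        _, null, _ = sep.reliability_and_null(ens)
        r = abs(np.corrcoef(true[:, 0], true[:, 1])[0, 1])
        assert sep.separability_test(r, null[("v0", "v1")]) < 1e-6


class TestUnitSignificance:
    def test_strong_coder_and_null_unit_rates(self):
        rng = np.random.default_rng(6)
        S, N = 200, 40
        axes = rng.normal(0, 0.1, size=(S, N, 1))
        axes[:, 0, 0] += 2.0  # planted strong coder
        ens = BootstrapEnsemble(axes, ["v0"], 0)
        p = sep.unit_significance(ens)
        assert p[0, 0] < 1e-6
        # non-coding units reject at roughly the nominal rate
        assert (p[1:, 0] < 0.05).mean() < 0.15

    def test_small_ensemble_rejected(self):
        ens = synthetic_ensemble(np.zeros((5, 1)), 1.0, S=10)
        with pytest.raises(ValueError, match="S >= 30"):
            sep.unit_significance(ens)

    def test_zero_sd_distribution_flagged(self):
        axes = np.ones((50, 4, 1))
        ens = BootstrapEnsemble(axes, ["v0"], 0)
        with pytest.raises(ValueError, match="zero-s.d."):
            sep.unit_significance(ens)


class TestMixedSelectivity:
    def test_independent_selectivity_consistent_with_b_rejects_a(self):
        rng = np.random.default_rng(7)
        N, K, alpha = 400, 3, 0.05
        # independent selectivity at strong marginal rates
        coding = rng.random((N, K)) < 0.4
        p = np.where(coding, 1e-6, rng.random((N, K)))
        res = sep.mixed_selectivity_test(p, alpha)
        assert res["p_specialized"] < 1e-6       # (a) rejected
        assert res["p_independent"] > 0.05       # (b) consistent

    def test_categorical_population_matches_binomial_overlap(self):
        rng = np.random.default_rng(8)
        N, K, alpha = 600, 3, 0.05
        # each unit codes exactly one variable
        owner = rng.integers(0, K, size=N)
        p = rng.random((N, K))
        p[np.arange(N), owner] = 1e-9
        res = sep.mixed_selectivity_test(p, alpha)
        # overlap stays near the specialized expectation alpha-driven level
        assert res["p_specialized"] > 0.01
        assert res["n_multi"] <= 2 * res["expected_specialized"] + 5

    def test_all_units_code_everything(self):
        p = np.full((50, 3), 1e-9)
        res = sep.mixed_selectivity_test(p)
        assert res["n_multi"] == 50


class TestCrossModuleConsistency:
    def test_observed_r_matches_full_data_axes(self, small_boot):
        from otdr.otdr_core import fit_static_axes
        table, pop, M, design, spec, boot = small_boot
        free = fit_static_axes(pop, design, M, spec, orthogonalize=False)
        res = sep.separability_analysis(free.B, [v for v, _ in free.columns],
                                        boot)
        for (a, b), r in res.observed_r.items():
            i = [v for v, _ in free.columns].index(a)
            j = [v for v, _ in free.columns].index(b)
            expect = abs(np.corrcoef(free.B[:, i], free.B[:, j])[0, 1])
            assert r == pytest.approx(expect, abs=1e-12)
        for p in res.pvalues.values():
            assert 0 <= p <= 1
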