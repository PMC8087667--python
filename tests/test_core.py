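import numpy as np
import pytest
from dataclasses import replace

from scdbm.core import (
    EPS_BIAS,
    GibbsState,
    ScDBMParams,
    ScDBMTrainConfig,
    apply_constraints,
    energy,
    generate,
    load_params,
    sample_hidden1,
    sample_hidden2,
    sample_visible,
    save_params,
    train_scdbm,
    visible_conditional,
    _gibbs_sweep,
    _h1_patterns,
    _h1_prior,
    _pattern_stats,
)
from scdbm.data_io import CountMatrix
from scdbm.dispersion import sample_nb


def small_params(seed=0, M=3, K=2, L=2):
    rng = np.random.default_rng(seed)
    return ScDBMParams(
        a=-np.abs(rng.normal(0.8, 0.2, M)) - 0.05,
        b1=rng.normal(0, 0.5, K),
        b2=rng.normal(0, 0.5, L),
        W1=-np.abs(rng.normal(0, 0.3, (M, K))),
        W2=rng.normal(0, 0.5, (K, L)),
        theta=np.abs(rng.normal(2.0, 0.5, M)) + 0.5,
    )


class TestEnergy:
    def test_zero_state_zero_energy(self):
        p = small_params()
        state = GibbsState(np.zeros(3, int), np.zeros(2, int), np.zeros(2, int))
        assert energy(state, p) == pytest.approx(0.0)

    def test_zero_params_zero_state(self):
        p = ScDBMParams(
            a=np.full(3, -1.0), b1=np.zeros(2), b2=np.zeros(2),
            W1=np.zeros((3, 2)), W2=np.zeros((2, 2)), theta=np.ones(3),
        )
        state = GibbsState(np.zeros(3, int), np.zeros(2, int), np.zeros(2, int))
        assert energy(state, p) == pytest.approx(0.0)

    def test_matches_high_precision_oracle(self):
        # term-by-term evaluation with mpmath log-gamma
        import mpmath as mp

        p = small_params(seed=5)
        rng = np.random.default_rng(1)
        x = rng.integers(0, 8, 3)
        h1 = rng.integers(0, 2, 2)
        h2 = rng.integers(0, 2, 2)
        expected = mp.mpf(0)
        for m in range(3):
            expected -= mp.mpf(p.a[m]) * int(x[m])
            expected -= (
                mp.loggamma(int(x[m]) + mp.mpf(p.theta[m]))
                - mp.loggamma(mp.mpf(p.theta[m]))
                - mp.loggamma(int(x[m]) + 1)
            )
        for k in range(2):
            expected -= mp.mpf(p.b1[k]) * int(h1[k])
        for l in range(2):
            expected -= mp.mpf(p.b2[l]) * int(h2[l])
        for m in range(3):
            for k in range(2):
                expected -= mp.mpf(p.W1[m, k]) * int(x[m]) * int(h1[k])
        for k in range(2):
            for l in range(2):
                expected -= mp.mpf(p.W2[k, l]) * int(h1[k]) * int(h2[l])
        got = energy(GibbsState(x, h1, h2), p)
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_dimension_mismatch(self):
        p = small_params()
        with pytest.raises(ValueError):
            energy(GibbsState(np.zeros(4, int), np.zeros(2, int), np.zeros(2, int)), p)


class TestConditionals:
    def test_visible_mean_formula(self):
        # a_hat = log(1/2), theta = 3 -> mu_hat = 3 * (1/2) / (1/2) = 3
        p = ScDBMParams(
            a=np.full(1, np.log(0.5)), b1=np.zeros(1), b2=np.zeros(1),
            W1=np.zeros((1, 1)), W2=np.zeros((1, 1)), theta=np.full(1, 3.0),
        )
        mu, theta = visible_conditional(np.zeros(1), p)
        assert mu[0] == pytest.approx(3.0)
        assert theta[0] == pytest.approx(3.0)

    def test_visible_mean_vanishes_for_large_negative_bias(self):
        p = ScDBMParams(
            a=np.full(1, -40.0), b1=np.zeros(1), b2=np.zeros(1),
            W1=np.zeros((1, 1)), W2=np.zeros((1, 1)), theta=np.full(1, 2.0),
        )
        mu, _ = visible_conditional(np.zeros(1), p)
        assert mu[0] < 1e-15

    def test_zero_hidden_gives_bias_only(self):
        p = small_params()
        mu0, _ = visible_conditional(np.zeros(2), p)
        e = np.exp(p.a)
        np.testing.assert_allclose(mu0, p.theta * e / (1 - e))

    def test_invalid_region_error(self):
        p = small_params()
        bad = replace(p, a=np.array([0.1, -1.0, -1.0]))
        with pytest.raises(ValueError, match="a_hat"):
            visible_conditional(np.zeros(2), bad)

    def test_visible_sampling_moments(self):
        # NB moments: mean mu, variance mu + mu^2/theta
        rng = np.random.default_rng(0)
        mu_t, theta_t = 3.0, 3.0
        p = ScDBMParams(
            a=np.full(1, np.log(mu_t / (mu_t + theta_t))), b1=np.zeros(1),
            b2=np.zeros(1), W1=np.zeros((1, 1)), W2=np.zeros((1, 1)),
            theta=np.full(1, theta_t),
        )
        draws = sample_visible(np.zeros((100_000, 1)), p, rng)[:, 0]
        var_t = mu_t + mu_t**2 / theta_t  # = 6
        se_mean = np.sqrt(var_t / draws.size)
        assert abs(draws.mean() - mu_t) < 3 * se_mean
        assert abs(draws.var() - var_t) < 0.1 * var_t

    def test_poisson_limit_of_visible_units(self):
        rng = np.random.default_rng(1)
        theta_t, mu_t = 1e6, 4.0
        p = ScDBMParams(
            a=np.full(1, np.log(mu_t / (mu_t + theta_t))), b1=np.zeros(1),
            b2=np.zeros(1), W1=np.zeros((1, 1)), W2=np.zeros((1, 1)),
            theta=np.full(1, theta_t),
        )
        draws = sample_visible(np.zeros((100_000, 1)), p, rng)[:, 0]
        assert abs(draws.var() / draws.mean() - 1.0) < 0.02

    @pytest.mark.parametrize("which", ["h1", "h2"])
    def test_hidden_rate_half_at_zero_activation(self, which):
        p = ScDBMParams(
            a=np.full(2, -1.0), b1=np.zeros(2), b2=np.zeros(2),
            W1=np.zeros((2, 2)), W2=np.zeros((2, 2)), theta=np.ones(2),
        )
        rng = np.random.default_rng(2)
        n = 100_000
        if which == "h1":
            draws = sample_hidden1(np.zeros((n, 2)), np.zeros((n, 2)), p, rng)
        else:
            draws = sample_hidden2(np.zeros((n, 2)), p, rng)
        se = np.sqrt(0.25 / n)
        assert np.all(np.abs(draws.mean(0) - 0.5) < 3 * se)

    def test_hidden_rate_matches_sigmoid(self):
        from scipy.special import expit

        p = small_params(seed=7)
        rng = np.random.default_rng(3)
        x = np.array([2.0, 0.0, 5.0])
        h2 = np.array([1.0, 0.0])
        target = expit(p.b1 + x @ p.W1 + h2 @ p.W2.T)
        n = 100_000
        draws = sample_hidden1(np.tile(x, (n, 1)), np.tile(h2, (n, 1)), p, rng)
        se = np.sqrt(target * (1 - target) / n)
        assert np.all(np.abs(draws.mean(0) - target) < 3 * se + 1e-12)


class TestConstraints:
    def test_positive_bias_clipped(self):
        p = small_params()
        q = apply_constraints(replace(p, a=np.array([0.3, -1.0, -2.0])))
        assert q.a[0] == -EPS_BIAS
        assert q.a[1] == -1.0

    def test_feasible_weight_unchanged_and_idempotent(self):
        p = small_params()
        q = apply_constraints(p)
        np.testing.assert_array_equal(q.W1, p.W1)
        q2 = apply_constraints(q)
        for f in ("a", "b1", "b2", "W1", "W2", "theta"):
            np.testing.assert_array_equal(getattr(q, f), getattr(q2, f))

    def test_positive_weight_clipped(self):
        p = small_params()
        W1 = p.W1.copy()
        W1[0, 0] = 0.7
        q = apply_constraints(replace(p, W1=W1))
        assert q.W1[0, 0] == 0.0


def single_population(n=400, M=30, mu=5.0, theta=2.0, seed=0):
    rng = np.random.default_rng(seed)
    counts = sample_nb(np.full((n, M), mu), theta, rng)
    return CountMatrix(counts, [f"c{i}" for i in range(n)], [f"g{j}" for j in range(M)])


class TestTraining:
    def test_zero_epochs_returns_initialization(self):
        cm = single_population()
        cfg = ScDBMTrainConfig(epochs=0, seed=0, n_hidden1=2, n_hidden2=2)
        p = train_scdbm(cm, cfg)
        p.validate()
        assert np.all(p.theta > 0)

    def test_single_population_moment_recovery(self):
        cm = single_population()
        cfg = ScDBMTrainConfig(epochs=400, seed=0, n_hidden1=2, n_hidden2=2)
        p = train_scdbm(cm, cfg)
        syn = generate(p, 4000, seed=1)
        rel = np.abs(syn.counts.mean(0) - cm.counts.mean(0)) / cm.counts.mean(0)
        assert rel.max() < 0.2

    def test_constraints_hold_after_training(self):
        cm = single_population(n=200, M=10)
        p = train_scdbm(cm, ScDBMTrainConfig(epochs=50, seed=0, n_hidden1=2, n_hidden2=2))
        assert np.all(p.a <= -EPS_BIAS)
        assert np.all(p.W1 <= 0)

    def test_reconstruction_error_non_increasing_over_epochs(self):
        # exact model mean vs data mean; same seed makes the shorter run a
        # prefix of the longer one (constant lr)
        cm = single_population()
        errs = []
        for ep in (10, 15, 20):
            cfg = ScDBMTrainConfig(
                epochs=ep, seed=0, n_hidden1=2, n_hidden2=2, lr_decay=False,
                theta_refresh_every=5,
            )
            p = train_scdbm(cm, cfg)
            H = _h1_patterns(2)
            stats = _pattern_stats(p, H)
            q = _h1_prior(p, H, stats)
            model_mean = q @ stats[0]
            errs.append(np.abs(model_mean - cm.counts.mean(0)).mean())
        assert errs[2] <= errs[0] + 1e-6

    def test_two_population_recovery_via_evaluation(self, two_pop):
        from scdbm.data_io import subsample_plates
        from scdbm.evaluation import (
            ReferenceClusteringConfig,
            adjusted_rand,
            reference_clustering,
            transfer_labels_raw,
        )

        cm, truth = two_pop
        pilot = subsample_plates(cm, 1, 384, seed=0)
        p = train_scdbm(pilot, ScDBMTrainConfig(epochs=1500, seed=0, n_hidden1=2, n_hidden2=2))
        syn = generate(p, 2000, seed=1, gene_ids=cm.gene_ids)
        ref = reference_clustering(cm, ReferenceClusteringConfig(seed=0),)
        qc = ref.projector.transform(syn)
        transferred = transfer_labels_raw(ref, qc)
        denovo = reference_clustering(syn, ReferenceClusteringConfig(seed=0))
        assert adjusted_rand(transferred, denovo.labels.labels) >= 0.8


class TestGenerate:
    def test_empty_generation(self):
        p = small_params()
        out = generate(p, 0, seed=0)
        assert out.counts.shape == (0, 3)

    def test_deterministic_under_seed(self):
        p = small_params()
        a = generate(p, 50, seed=42)
        b = generate(p, 50, seed=42)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_invalid_params_rejected_before_sampling(self):
        p = small_params()
        bad = replace(p, a=np.abs(p.a))
        with pytest.raises(ValueError):
            generate(bad, 10, seed=0)

    def test_zero_weight_marginal_is_nb(self):
        # with W1 = W2 = 0 each gene is marginally NB(mu_hat(bias), theta):
        # chi-square goodness of fit on 50000 draws, alpha = 0.01
        from scipy.stats import chisquare
        from scdbm.dispersion import nb_logpmf

        mu_t, theta_t = 4.0, 2.0
        p = ScDBMParams(
            a=np.full(1, np.log(mu_t / (mu_t + theta_t))), b1=np.zeros(2),
            b2=np.zeros(2), W1=np.zeros((1, 2)), W2=np.zeros((2, 2)),
            theta=np.full(1, theta_t),
        )
        draws = generate(p, 50_000, gibbs_steps=2, seed=3).counts[:, 0]
        hi = int(np.quantile(draws, 0.999)) + 1
        obs = np.bincount(np.minimum(draws, hi), minlength=hi + 1)
        probs = np.exp(nb_logpmf(np.arange(hi + 1), mu_t, theta_t))
        probs[hi] = 1.0 - probs[:hi].sum()
        stat, pval = chisquare(obs, probs * draws.size)
        assert pval > 0.01

    def test_gibbs_matches_exhaustive_boltzmann(self):
        # tiny machine (M=2 genes truncated to 0..10, K=L=2): the empirical
        # joint from long Gibbs runs must match exp(-E)/Z enumerated over
        # the truncated state space within TV < 0.02
        from itertools import product

        p = ScDBMParams(
            a=np.log(np.array([0.25, 0.35]) / (np.array([0.25, 0.35]) + np.array([1.5, 2.5]))),
            b1=np.array([0.3, -0.2]),
            b2=np.array([-0.1, 0.2]),
            W1=np.array([[-0.4, -0.1], [-0.2, -0.5]]),
            W2=np.array([[0.6, -0.4], [-0.3, 0.5]]),
            theta=np.array([1.5, 2.5]),
        )
        # exact probabilities by enumeration
        states = list(product(range(11), range(11), range(2), range(2), range(2), range(2)))
        logp = np.array(
            [
                -energy(
                    GibbsState(np.array(s[:2]), np.array(s[2:4]), np.array(s[4:6])), p
                )
                for s in states
            ]
        )
        logp -= logp.max()
        exact = np.exp(logp)
        exact /= exact.sum()

        rng = np.random.default_rng(0)
        n_chains, burn, keep = 4000, 200, 200
        h1 = np.zeros((n_chains, 2), dtype=np.int8)
        x = sample_visible(h1, p, rng).astype(float)
        h2 = sample_hidden2(h1, p, rng)
        counts = np.zeros(len(states))
        idx_of = {s: i for i, s in enumerate(states)}
        kept = 0
        for sweep in range(burn + keep):
            x, h1, h2 = _gibbs_sweep(x, h1, h2, p, rng)
            if sweep >= burn:
                ok = (x[:, 0] <= 10) & (x[:, 1] <= 10)
                codes = (
                    x[:, 0].astype(int) * 11 * 16
                    + x[:, 1].astype(int) * 16
                    + h1[:, 0] * 8 + h1[:, 1] * 4 + h2[:, 0] * 2 + h2[:, 1]
                )
                # states enumerated in the same mixed-radix order
                counts += np.bincount(codes[ok], minlength=len(states))
                kept += ok.sum()
        emp = counts / kept
        tv = 0.5 * np.abs(emp - exact).sum()
        assert tv < 0.02


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        p = small_params()
        f = tmp_path / "model.npz"
        save_params(p, f, config={"epochs": 5}, seed=1)
        q = load_params(f)
        for field in ("a", "b1", "b2", "W1", "W2", "theta"):
            np.testing.assert_array_equal(getattr(p, field), getattr(q, field))
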