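"""Negative-binomial deep Boltzmann machine (scDBM).

A three-layer Boltzmann machine whose visible layer models UMI counts for M
genes with negative-binomial units (an exponential-family harmonium), and
whose two hidden layers are binary.  The energy of a state
``{x, h1, h2}`` is

    E = -a'x - sum_m log[(x_m+theta_m-1)! / ((theta_m-1)! x_m!)]
        - b1'h1 - b2'h2 - x'W1 h1 - h1'W2 h2

with parameters Theta = (theta, a, b1, b2, W1, W2).  Because the visible
bias acts on the natural-parameter (log) scale of the NB distribution, the
model is kept in its valid region by the constraints ``a_m <= -eps`` and
``W1 <= 0``; then the effective visible bias ``a_hat = a + W1 h1`` is
always negative and the conditional NB mean

    mu_hat_m = theta_m * exp(a_hat_m) / (1 - exp(a_hat_m))

is finite and positive.  Training follows the standard DBM recipe:
greedy layer-wise pretraining, then stochastic gradient with a mean-field
positive phase and a persistent-contrastive-divergence negative phase,
interleaved with regularized Fisher-scoring refreshes of the per-gene
inverse dispersion theta.  Synthetic cells are generated by Gibbs sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln, expit

from .data_io import CountMatrix
from .dispersion import FisherScoringConfig, estimate_theta, moment_theta

__all__ = [
    "ScDBMParams",
    "GibbsState",
    "ScDBMTrainConfig",
    "energy",
    "visible_conditional",
    "sample_visible",
    "sample_hidden1",
    "sample_hidden2",
    "apply_constraints",
    "train_scdbm",
    "generate",
    "save_params",
    "load_params",
]

EPS_BIAS = 1e-10  # visible bias kept at or below -EPS_BIAS

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ScDBMParams:
    """Model parameters Theta of the scDBM.

    a: visible (per-gene) bias on log scale, constrained <= -1e-10.
    b1, b2: hidden-layer biases.
    W1: visible-to-hidden weights (M x K), constrained <= 0.
    W2: hidden-to-hidden weights (K x L), unconstrained.
    theta: per-gene inverse dispersion, > 0.
    """

    a: np.ndarray
    b1: np.ndarray
    b2: np.ndarray
    W1: np.ndarray
    W2: np.ndarray
    theta: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.a.shape[0]

    @property
    def n_hidden1(self) -> int:
        return self.b1.shape[0]

    @property
    def n_hidden2(self) -> int:
        return self.b2.shape[0]

    def validate(self) -> None:
        M, K, L = self.n_genes, self.n_hidden1, self.n_hidden2
        if self.W1.shape != (M, K) or self.W2.shape != (K, L):
            raise ValueError("weight shapes inconsistent with biases")
        if self.theta.shape != (M,):
            raise ValueError("theta must have one entry per gene")
        if np.any(self.a > -EPS_BIAS):
            raise ValueError("visible bias must be <= -1e-10")
        if np.any(self.W1 > 0):
            raise ValueError("W1 entries must be <= 0")
        if np.any(self.theta <= 0):
            raise ValueError("theta must be positive")


@dataclass(frozen=True)
class GibbsState:
    """One joint state {x, h1, h2} of the machine."""

    x: np.ndarray
    h1: np.ndarray
    h2: np.ndarray


@dataclass(frozen=True)
class ScDBMTrainConfig:
    epochs: int = 2000
    learning_rate: float = 1e-3
    batch_size: int = 64
    cd_steps: int = 3
    pretrain_epochs: int = 15
    theta_refresh_every: int = 5
    lambda_reg: float = 5.0
    seed: int = 0
    n_hidden1: int = 3
    n_hidden2: int = 3
    algorithm: str = "exact"  # "exact" (enumerated gradients) or "pcd"
    init: str = "kmeans"  # "kmeans" (cluster-profile seeding) or "random"
    n_chains: int = 100
    hidden_lr_scale: float = 50.0  # lr multiplier for b1/b2/W2 (O(1) stats vs count scale)
    lr_decay: bool = True  # linear decay over the second half of training
    mean_field_iters: int = 10
    mean_field_tol: float = 1e-4
    theta_mu_mode: str = "reconstruction"  # or "empirical"
    theta_ceiling: float = 1000.0

    def __post_init__(self) -> None:
        if self.theta_refresh_every < 1:
            raise ValueError("theta_refresh_every must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.theta_mu_mode not in ("reconstruction", "empirical"):
            raise ValueError("theta_mu_mode must be 'reconstruction' or 'empirical'")
        if self.algorithm not in ("exact", "pcd"):
            raise ValueError("algorithm must be 'exact' or 'pcd'")
        if self.algorithm == "exact" and self.n_hidden1 > 10:
            raise ValueError("exact training enumerates 2^K patterns; needs n_hidden1 <= 10")


def _log_nb_binom(x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    # log[(x+theta-1)! / ((theta-1)! x!)] via log-gamma, valid for real theta
    return gammaln(x + theta) - gammaln(theta) - gammaln(x + 1.0)


def energy(state: GibbsState, p: ScDBMParams) -> float:
    """Energy of a single joint state under parameters ``p``."""
    p.validate()
    x = np.asarray(state.x, dtype=float)
    h1 = np.asarray(state.h1, dtype=float)
    h2 = np.asarray(state.h2, dtype=float)
    if x.shape != (p.n_genes,) or h1.shape != (p.n_hidden1,) or h2.shape != (p.n_hidden2,):
        raise ValueError("state dimensions do not match parameters")
    return float(
        -p.a @ x
        - _log_nb_binom(x, p.theta).sum()
        - p.b1 @ h1
        - p.b2 @ h2
        - x @ p.W1 @ h1
        - h1 @ p.W2 @ h2
    )


def visible_conditional(h1: np.ndarray, p: ScDBMParams):
    """NB parameters of p(x | h1): per-gene mean mu_hat and theta.

    ``a_hat = a + W1 h1`` (rows of h1 may be batched); requires
    ``a_hat < 0`` so the geometric factor ``exp(a_hat)`` stays below 1.
    """
    h1 = np.asarray(h1, dtype=float)
    a_hat = p.a + h1 @ p.W1.T
    if np.any(a_hat >= 0):
        raise ValueError("effective visible bias a_hat >= 0: invalid model region")
    e = np.exp(a_hat)
    mu_hat = p.theta * e / (1.0 - e)
    return mu_hat, np.broadcast_to(p.theta, mu_hat.shape)


def sample_visible(h1: np.ndarray, p: ScDBMParams, rng: np.random.Generator) -> np.ndarray:
    """Draw x ~ prod_m NB(mu_hat_m, theta_m) given the first hidden layer."""
    mu_hat, theta = visible_conditional(h1, p)
    return rng.negative_binomial(theta, theta / (theta + mu_hat))


def sample_hidden1(
    x: np.ndarray, h2: np.ndarray, p: ScDBMParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw h1 ~ prod_k Bern(sigmoid(b1 + W1'x + W2 h2))."""
    act = hidden1_activation(x, h2, p)
    return (rng.random(act.shape) < act).astype(np.int8)


def hidden1_activation(x: np.ndarray, h2: np.ndarray, p: ScDBMParams) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    return expit(p.b1 + x @ p.W1 + h2 @ p.W2.T)


def sample_hidden2(h1: np.ndarray, p: ScDBMParams, rng: np.random.Generator) -> np.ndarray:
    """Draw h2 ~ prod_l Bern(sigmoid(b2 + W2'h1))."""
    act = hidden2_activation(h1, p)
    return (rng.random(act.shape) < act).astype(np.int8)


def hidden2_activation(h1: np.ndarray, p: ScDBMParams) -> np.ndarray:
    h1 = np.asarray(h1, dtype=float)
    return expit(p.b2 + h1 @ p.W2)


def apply_constraints(p: ScDBMParams) -> ScDBMParams:
    """Clip a to <= -1e-10 and W1 to <= 0; idempotent."""
    return replace(
        p,
        a=np.minimum(p.a, -EPS_BIAS),
        W1=np.minimum(p.W1, 0.0),
    )


# ---------------------------------------------------------------------------
# training


def _init_params(counts: np.ndarray, cfg: ScDBMTrainConfig, rng: np.random.Generator) -> ScDBMParams:
    M = counts.shape[1]
    theta = np.empty(M)
    for m in range(M):
        theta[m] = moment_theta(counts[:, m], (0.01, cfg.theta_ceiling))
    mu = np.maximum(counts.mean(axis=0), 1e-3)
    if cfg.init == "kmeans" and counts.shape[0] > cfg.n_hidden1:
        # seed the hidden code from a coarse k-means partition, as mixture
        # models are initialized: unit k's "on" state maps genes to the
        # profile of cluster k.  a is set to the elementwise-max profile, so
        # every W1 column (log-scale drop from the ceiling to a cluster
        # profile) is automatically <= 0, satisfying the sign constraint.
        from sklearn.cluster import KMeans

        lib = np.maximum(counts.sum(axis=1).astype(float), 1.0)
        logx = np.log1p(counts / lib[:, None] * np.median(lib))
        km = KMeans(
            n_clusters=cfg.n_hidden1,
            n_init=5,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(logx)
        prof = np.stack(
            [
                np.maximum(counts[km.labels_ == k].mean(axis=0), 1e-3)
                if np.any(km.labels_ == k)
                else mu
                for k in range(cfg.n_hidden1)
            ]
        )  # K x M
        ceiling = np.maximum(prof.max(axis=0), mu)
        a = np.log(ceiling / (ceiling + theta))
        W1 = (np.log(prof / (prof + theta)) - a).T  # M x K, <= 0
        W2 = rng.normal(0.0, 0.5, size=(cfg.n_hidden1, cfg.n_hidden2))
        b2 = -0.5 * W2.sum(axis=0)
        # balance the hidden prior: the all-off "ceiling" pattern has the
        # largest NB normalizer and would otherwise absorb all prior mass;
        # set b1 so each one-hot pattern starts at its k-means proportion,
        # a couple of nats above the ceiling pattern
        props = np.maximum(
            np.bincount(km.labels_, minlength=cfg.n_hidden1) / len(km.labels_), 1e-3
        )
        H = _h1_patterns(cfg.n_hidden1)
        tmp = ScDBMParams(np.minimum(a, -EPS_BIAS), np.zeros(cfg.n_hidden1), b2,
                          np.minimum(W1, 0.0), W2, theta)
        _, _, t, logz = _pattern_stats(tmp, H)
        s0 = t[0] + logz[0]
        b1 = np.array(
            [
                s0 - (t[1 << k] + logz[1 << k]) + np.log(props[k]) + 2.0
                for k in range(cfg.n_hidden1)
            ]
        )
        return apply_constraints(ScDBMParams(a, b1, b2, W1, W2, theta))
    a = np.log(mu / (mu + theta))  # matches bias-only NB mean to the data mean
    W1 = -np.abs(rng.normal(0.0, 0.01, size=(M, cfg.n_hidden1)))
    # center hidden biases so units start half-on at the data mean; a
    # cold (all-off) start makes the hidden-unit gradients vanish and
    # training stalls in a quasi-unimodal local optimum
    b1 = -mu @ W1
    # larger scale breaks the permutation symmetry of the top layer; without
    # it W2 settles into a degenerate always-on solution that cannot encode
    # anti-correlated hidden cluster codes
    W2 = rng.normal(0.0, 0.5, size=(cfg.n_hidden1, cfg.n_hidden2))
    b2 = -0.5 * W2.sum(axis=0)
    return apply_constraints(ScDBMParams(a, b1, b2, W1, W2, theta))


def mean_field(x: np.ndarray, p: ScDBMParams, n_iter: int = 10, tol: float = 1e-4):
    """Fixed-point mean-field posterior (mu1, mu2) over hidden layers given x."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    mu2 = np.full((x.shape[0], p.n_hidden2), 0.5)
    mu1 = expit(p.b1 + x @ p.W1 + mu2 @ p.W2.T)
    for _ in range(n_iter):
        mu2_new = expit(p.b2 + mu1 @ p.W2)
        mu1_new = expit(p.b1 + x @ p.W1 + mu2_new @ p.W2.T)
        delta = max(np.abs(mu1_new - mu1).max(), np.abs(mu2_new - mu2).max())
        mu1, mu2 = mu1_new, mu2_new
        if delta < tol:
            break
    return mu1, mu2


def _gibbs_sweep(x, h1, h2, p, rng):
    h1 = sample_hidden1(x, h2, p, rng)
    h2 = sample_hidden2(h1, p, rng)
    x = sample_visible(h1, p, rng)
    return x, h1, h2


def _check_finite(p: ScDBMParams, epoch: int, batch: int) -> None:
    for name in ("a", "b1", "b2", "W1", "W2"):
        if not np.all(np.isfinite(getattr(p, name))):
            raise FloatingPointError(
                f"non-finite parameter {name} at epoch {epoch}, batch {batch}"
            )


def _pretrain_rbm1(counts, p, cfg, rng):
    """Greedy pretraining of the NB-visible / h1 restricted machine via PCD."""
    a, b1, W1 = p.a.copy(), p.b1.copy(), p.W1.copy()
    theta = p.theta
    n = counts.shape[0]
    chains_x = counts[rng.integers(0, n, size=cfg.n_chains)].astype(float)
    chains_h1 = (rng.random((cfg.n_chains, cfg.n_hidden1)) < 0.5).astype(np.int8)
    lr = cfg.learning_rate
    for epoch in range(cfg.pretrain_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            xb = counts[order[start : start + cfg.batch_size]].astype(float)
            pos_h1 = expit(b1 + xb @ W1)
            for _ in range(cfg.cd_steps):
                sub = ScDBMParams(a, b1, p.b2, W1, np.zeros_like(p.W2), theta)
                act = expit(b1 + chains_x @ W1)
                chains_h1 = (rng.random(act.shape) < act).astype(np.int8)
                chains_x = sample_visible(chains_h1, sub, rng).astype(float)
            neg_h1 = expit(b1 + chains_x @ W1)
            a += lr * (xb.mean(0) - chains_x.mean(0))
            b1 += lr * (pos_h1.mean(0) - neg_h1.mean(0))
            W1 += lr * (xb.T @ pos_h1 / len(xb) - chains_x.T @ neg_h1 / len(chains_x))
            a = np.minimum(a, -EPS_BIAS)
            W1 = np.minimum(W1, 0.0)
    return replace(p, a=a, b1=b1, W1=W1)


def _pretrain_rbm2(counts, p, cfg, rng):
    """Pretrain the binary h1/h2 machine on sampled first-layer activations."""
    b1, b2, W2 = p.b1.copy(), p.b2.copy(), p.W2.copy()
    acts = expit(b1 + counts.astype(float) @ p.W1)
    data_h1 = (rng.random(acts.shape) < acts).astype(float)
    n = data_h1.shape[0]
    chains_h1 = data_h1[rng.integers(0, n, size=cfg.n_chains)].copy()
    lr = cfg.learning_rate * cfg.hidden_lr_scale
    # the top machine is tiny, so generous pretraining is cheap; it must
    # carve the joint structure of the first-layer code before joint PCD
    for epoch in range(cfg.pretrain_epochs * 20):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            hb = data_h1[order[start : start + cfg.batch_size]]
            pos_h2 = expit(b2 + hb @ W2)
            for _ in range(cfg.cd_steps):
                h2s = (rng.random((cfg.n_chains, cfg.n_hidden2)) <
                       expit(b2 + chains_h1 @ W2)).astype(float)
                chains_h1 = (rng.random((cfg.n_chains, cfg.n_hidden1)) <
                             expit(b1 + h2s @ W2.T)).astype(float)
            neg_h2 = expit(b2 + chains_h1 @ W2)
            b2 += lr * (pos_h2.mean(0) - neg_h2.mean(0))
            W2 += lr * (hb.T @ pos_h2 / len(hb) - chains_h1.T @ neg_h2 / cfg.n_chains)
    return replace(p, b2=b2, W2=W2)


def _refresh_theta(counts, p, cfg):
    """Re-estimate per-gene theta by regularized Fisher scoring.

    mu per cell/gene comes from the mean-field reconstruction (expected h1
    plugged into the visible conditional) or the empirical gene mean.
    """
    fcfg = FisherScoringConfig(
        lambda_reg=cfg.lambda_reg, theta_bounds=(0.01, cfg.theta_ceiling)
    )
    if cfg.theta_mu_mode == "reconstruction":
        mu1, _ = mean_field(counts.astype(float), p, cfg.mean_field_iters, cfg.mean_field_tol)
        a_hat = p.a + mu1 @ p.W1.T
        e = np.exp(np.minimum(a_hat, -EPS_BIAS))
        mu = p.theta * e / (1.0 - e)  # n_cells x M
        mu = np.maximum(mu, 1e-8)
    else:
        mu = np.maximum(counts.mean(axis=0), 1e-8)[None, :].repeat(counts.shape[0], 0)
    theta = p.theta.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for m in range(counts.shape[1]):
            x = counts[:, m]
            if np.all(x == 0):
                theta[m] = cfg.theta_ceiling
                continue
            theta[m] = estimate_theta(x, mu[:, m], fcfg).theta
    return replace(p, theta=theta)


# ---------------------------------------------------------------------------
# exact (enumerated) expectations: with K hidden units in the first layer,
# both x and h2 marginalize analytically, so p(h1) is a softmax over 2^K
# patterns and all sufficient-statistic expectations are exact sums.


def _h1_patterns(K: int) -> np.ndarray:
    P = 1 << K
    return ((np.arange(P)[:, None] >> np.arange(K)[None, :]) & 1).astype(float)


def _pattern_stats(p: ScDBMParams, H: np.ndarray):
    """Per-pattern quantities: a_hat (P x M), E[x|h1], E[h2|h1], softplus term."""
    a_hat = p.a + H @ p.W1.T
    a_hat = np.minimum(a_hat, -EPS_BIAS)
    e = np.exp(a_hat)
    mu = p.theta * e / (1.0 - e)
    U = expit(p.b2 + H @ p.W2)  # E[h2 | h1]
    t = np.logaddexp(0.0, p.b2 + H @ p.W2).sum(axis=1)  # h2 marginalized
    # NB log-normalizer per gene: -theta * log(1 - exp(a_hat))
    logz_x = -(p.theta * np.log(-np.expm1(a_hat))).sum(axis=1)
    return mu, U, t, logz_x


def _h1_prior(p: ScDBMParams, H: np.ndarray, stats=None) -> np.ndarray:
    """Exact model marginal p(h1) over all 2^K patterns."""
    if stats is None:
        stats = _pattern_stats(p, H)
    _, _, t, logz_x = stats
    s = H @ p.b1 + t + logz_x
    s -= s.max()
    q = np.exp(s)
    return q / q.sum()


def _h1_posterior(p: ScDBMParams, H: np.ndarray, x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Exact p(h1 | x) for each row of x (B x 2^K), h2 marginalized."""
    s = x @ p.W1 @ H.T + p.b1 @ H.T + t
    s -= s.max(axis=1, keepdims=True)
    r = np.exp(s)
    return r / r.sum(axis=1, keepdims=True)


def _train_exact(counts: np.ndarray, p: ScDBMParams, cfg: ScDBMTrainConfig,
                 rng: np.random.Generator) -> ScDBMParams:
    H = _h1_patterns(cfg.n_hidden1)
    n = counts.shape[0]
    X = counts.astype(float)
    for epoch in range(cfg.epochs):
        # full step for the first half, then linear decay: lets the moment
        # matching settle instead of orbiting the optimum under SGD noise
        decay = min(1.0, 2.0 * (1.0 - epoch / cfg.epochs)) if cfg.lr_decay else 1.0
        lr = cfg.learning_rate * decay
        lrh = lr * cfg.hidden_lr_scale
        order = rng.permutation(n)
        for bi, start in enumerate(range(0, n, cfg.batch_size)):
            xb = X[order[start : start + cfg.batch_size]]
            B = len(xb)
            stats = _pattern_stats(p, H)
            mu_pat, U, t, _ = stats
            q = _h1_prior(p, H, stats)
            r = _h1_posterior(p, H, xb, t)
            # positive phase (exact posterior)
            pos_h1 = r @ H                      # B x K
            pos_h2 = r @ U                      # B x L
            c = r.mean(axis=0)                  # pattern weights, data side
            # negative phase (exact prior)
            neg_h1 = q @ H
            neg_h2 = q @ U
            neg_x = q @ mu_pat
            p = replace(
                p,
                a=p.a + lr * (xb.mean(0) - neg_x),
                b1=p.b1 + lrh * (pos_h1.mean(0) - neg_h1),
                b2=p.b2 + lrh * (pos_h2.mean(0) - neg_h2),
                W1=p.W1 + lr * (xb.T @ pos_h1 / B - mu_pat.T @ (q[:, None] * H)),
                W2=p.W2 + lrh * (H.T @ ((c - q)[:, None] * U)),
            )
            p = apply_constraints(p)
            _check_finite(p, epoch, bi)
        if (epoch + 1) % cfg.theta_refresh_every == 0:
            p = _refresh_theta(counts, p, cfg)
    return p


def train_scdbm(cm: CountMatrix, cfg: ScDBMTrainConfig) -> ScDBMParams:
    """Fit an scDBM to a count matrix.

    Stages: (i) per-gene theta by method of moments; (ii) greedy layer-wise
    pretraining of the two restricted machines (pcd algorithm only);
    (iii) joint training, with constraints re-applied after every gradient
    step; (iv) theta refreshed by regularized Fisher scoring every
    ``theta_refresh_every`` epochs.

    Two joint-training algorithms are available.  ``exact`` (default)
    computes both the data-side and model-side sufficient-statistic
    expectations exactly by enumerating the 2^K first-hidden-layer patterns
    (x and h2 are marginalized analytically) — feasible because the latent
    space is deliberately small (K = 2..4).  ``pcd`` is the standard
    deep-Boltzmann recipe: mean-field positive phase, persistent
    contrastive-divergence negative phase.
    """
    counts = cm.counts
    if counts.size == 0:
        raise ValueError("count matrix is empty")
    rng = np.random.default_rng(cfg.seed)
    p = _init_params(counts, cfg, rng)
    if cfg.epochs == 0:
        return p
    kmeans_seeded = cfg.init == "kmeans" and counts.shape[0] > cfg.n_hidden1
    if cfg.pretrain_epochs > 0 and not kmeans_seeded:
        # greedy layer-wise pretraining carves the first-layer code; without
        # it joint training sits on the W1 ~ 0 plateau for a long time.
        # (the k-means profile init plays the same role and must not be
        # overwritten, so pretraining only runs from a random init)
        p = _pretrain_rbm1(counts, p, cfg, rng)
        p = _pretrain_rbm2(counts, p, cfg, rng)
        p = apply_constraints(p)
    if cfg.algorithm == "exact":
        return _train_exact(counts, p, cfg, rng)

    n = counts.shape[0]
    chains_x = counts[rng.integers(0, n, size=cfg.n_chains)].astype(float)
    chains_h2 = (rng.random((cfg.n_chains, cfg.n_hidden2)) < 0.5).astype(np.int8)
    chains_h1 = sample_hidden1(chains_x, chains_h2, p, rng)
    lr = cfg.learning_rate
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for bi, start in enumerate(range(0, n, cfg.batch_size)):
            xb = counts[order[start : start + cfg.batch_size]].astype(float)
            mu1, mu2 = mean_field(xb, p, cfg.mean_field_iters, cfg.mean_field_tol)
            for _ in range(cfg.cd_steps):
                chains_x, chains_h1, chains_h2 = _gibbs_sweep(
                    chains_x, chains_h1, chains_h2, p, rng
                )
            nb, nc = len(xb), cfg.n_chains
            lrh = lr * cfg.hidden_lr_scale
            p = replace(
                p,
                a=p.a + lr * (xb.mean(0) - chains_x.mean(0)),
                b1=p.b1 + lrh * (mu1.mean(0) - chains_h1.mean(0)),
                b2=p.b2 + lrh * (mu2.mean(0) - chains_h2.mean(0)),
                W1=p.W1 + lr * (xb.T @ mu1 / nb - chains_x.T @ chains_h1 / nc),
                W2=p.W2 + lrh * (mu1.T @ mu2 / nb - chains_h1.T @ chains_h2 / nc),
            )
            p = apply_constraints(p)
            _check_finite(p, epoch, bi)
        if (epoch + 1) % cfg.theta_refresh_every == 0:
            p = _refresh_theta(counts, p, cfg)
    return p


# ---------------------------------------------------------------------------
# generation


def generate(
    p: ScDBMParams,
    n_cells: int,
    gibbs_steps: int = 1,
    burn_in: int = 100,
    seed: int = 0,
    gene_ids: list[str] | None = None,
    exact_init: bool | None = None,
) -> CountMatrix:
    """Generate synthetic cells by Gibbs sampling, one chain per cell.

    When the first hidden layer is small (the default architecture),
    chains are initialized by an exact draw from the enumerated model
    marginal p(h1) — an equilibrium sample, so only ``gibbs_steps`` sweeps
    (h1 -> h2 -> x) follow.  Otherwise chains start from a bias-only NB
    draw and run ``burn_in`` extra sweeps first.
    """
    p.validate()
    if gibbs_steps < 1:
        raise ValueError("gibbs_steps must be >= 1")
    rng = np.random.default_rng(seed)
    M = p.n_genes
    if gene_ids is None:
        gene_ids = [f"gene{m}" for m in range(M)]
    if n_cells == 0:
        return CountMatrix(np.zeros((0, M), dtype=np.int64), cell_ids=[], gene_ids=gene_ids)
    if exact_init is None:
        exact_init = p.n_hidden1 <= 10
    if exact_init:
        H = _h1_patterns(p.n_hidden1)
        q = _h1_prior(p, H)
        h1 = H[rng.choice(len(H), size=n_cells, p=q)].astype(np.int8)
        h2 = sample_hidden2(h1, p, rng)
        x = sample_visible(h1, p, rng).astype(float)
        n_sweeps = gibbs_steps
    else:
        h1 = np.zeros((n_cells, p.n_hidden1), dtype=np.int8)
        x = sample_visible(h1, p, rng).astype(float)
        h2 = sample_hidden2(sample_hidden1(x, np.zeros((n_cells, p.n_hidden2)), p, rng), p, rng)
        n_sweeps = burn_in + gibbs_steps
    for _ in range(n_sweeps):
        x, h1, h2 = _gibbs_sweep(x, h1, h2, p, rng)
    return CountMatrix(
        np.asarray(x, dtype=np.int64),
        cell_ids=[f"synthetic{i}" for i in range(n_cells)],
        gene_ids=gene_ids,
    )


# ---------------------------------------------------------------------------
# checkpoints


def save_params(p: ScDBMParams, path, config: dict | None = None, seed: int | None = None):
    """Write all six parameter arrays plus config/seed to one .npz archive."""
    import json

    np.savez(
        path,
        version=CHECKPOINT_VERSION,
        a=p.a,
        b1=p.b1,
        b2=p.b2,
        W1=p.W1,
        W2=p.W2,
        theta=p.theta,
        config=json.dumps(config or {}),
        seed=-1 if seed is None else seed,
    )


def load_params(path) -> ScDBMParams:
    with np.load(path, allow_pickle=False) as z:
        if int(z["version"]) != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {z['version']}")
        p = ScDBMParams(z["a"], z["b1"], z["b2"], z["W1"], z["W2"], z["theta"])
    p.validate()
    return p
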