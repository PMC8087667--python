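"""Minimal negative-binomial variational autoencoder.

A reduced single-cell VAE: no batch covariate and no zero-inflation.  The
generative model draws a latent cell state z (dimension ``latent_dim``) and
a one-dimensional log library size l; a one-hidden-layer decoder maps z to
a softmax vector of per-gene expression proportions rho, and counts follow
NB(rho_m * exp(l), theta_m) with a learned per-gene inverse dispersion.
The encoder (one hidden ReLU layer on log1p counts) parametrizes Gaussian
posteriors q(z|x) and q(l|x); training maximizes the evidence lower bound

    E_q[log p(x|z,l)] - KL(q(z|x) || N(0,I)) - KL(q(l|x) || N(l_mu, l_sd^2))

by stochastic gradient with the reparameterization trick.  All gradients
are computed in closed form (NumPy; Adam updates).

Two generation modes are offered.  Posterior sampling replicates the input
cells as often as needed ("replicate and stack") and decodes latents drawn
from q(z|x); prior sampling draws z ~ N(0, I) and l ~ N(l_mu, 1) and never
touches the training cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma

from .data_io import CountMatrix
from .dispersion import nb_logpmf, sample_nb

__all__ = [
    "NBVAEParams",
    "NBVAETrainConfig",
    "train_vae",
    "sample_posterior",
    "sample_prior",
    "elbo_terms",
    "save_vae",
    "load_vae",
]

_WEIGHT_KEYS = (
    "We", "be", "Wmz", "bmz", "Wvz", "bvz", "Wml", "bml", "Wvl", "bvl",
    "Wd", "bd", "Wo", "bo", "log_theta",
)


@dataclass
class NBVAEParams:
    """Fitted encoder/decoder weights plus dispersion and library prior."""

    weights: dict[str, np.ndarray]
    latent_dim: int
    l_mu: float
    l_sd: float
    gene_ids: list[str] | None = None

    @property
    def theta(self) -> np.ndarray:
        return np.exp(self.weights["log_theta"])

    @property
    def n_genes(self) -> int:
        return self.weights["We"].shape[0]


@dataclass(frozen=True)
class NBVAETrainConfig:
    epochs: int = 400
    learning_rate: float = 1e-3
    batch_size: int = 128
    hidden_width: int = 128
    latent_dim: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epochs", "learning_rate", "batch_size", "hidden_width", "latent_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _init_weights(M: int, H: int, d: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    def glorot(fan_in, fan_out):
        s = math.sqrt(2.0 / (fan_in + fan_out))
        return rng.normal(0.0, s, size=(fan_in, fan_out))

    return {
        "We": glorot(M, H), "be": np.zeros(H),
        "Wmz": glorot(H, d), "bmz": np.zeros(d),
        "Wvz": glorot(H, d), "bvz": np.zeros(d),
        "Wml": glorot(H, 1), "bml": np.zeros(1),
        "Wvl": glorot(H, 1), "bvl": np.zeros(1),
        "Wd": glorot(d, H), "bd": np.zeros(H),
        "Wo": glorot(H, M), "bo": np.zeros(M),
        "log_theta": np.zeros(M),
    }


def _encode(w, xlog):
    h = np.maximum(xlog @ w["We"] + w["be"], 0.0)
    return (
        h,
        h @ w["Wmz"] + w["bmz"],
        np.clip(h @ w["Wvz"] + w["bvz"], -10.0, 10.0),
        h @ w["Wml"] + w["bml"],
        np.clip(h @ w["Wvl"] + w["bvl"], -10.0, 10.0),
    )


def _decode_rho(w, z):
    hd = np.maximum(z @ w["Wd"] + w["bd"], 0.0)
    logits = hd @ w["Wo"] + w["bo"]
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return hd, e / e.sum(axis=1, keepdims=True)


def elbo_terms(p: NBVAEParams, counts: np.ndarray, rng: np.random.Generator):
    """One-sample Monte-Carlo ELBO decomposition (per-cell means).

    Returns (reconstruction log-likelihood, KL of z, KL of l).
    """
    w = p.weights
    x = np.asarray(counts, dtype=float)
    _, mz, lvz, ml, lvl = _encode(w, np.log1p(x))
    z = mz + rng.standard_normal(mz.shape) * np.exp(0.5 * lvz)
    l = ml + rng.standard_normal(ml.shape) * np.exp(0.5 * lvl)
    _, rho = _decode_rho(w, z)
    mu = np.maximum(rho * np.exp(l), 1e-10)
    rec = nb_logpmf(x, mu, p.theta).sum(axis=1).mean()
    klz = 0.5 * (mz**2 + np.exp(lvz) - 1.0 - lvz).sum(axis=1).mean()
    kll = 0.5 * (
        (np.exp(lvl) + (ml - p.l_mu) ** 2) / p.l_sd**2
        - 1.0
        + 2.0 * math.log(p.l_sd)
        - lvl
    ).sum(axis=1).mean()
    return float(rec), float(klz), float(kll)


class _Adam:
    def __init__(self, keys, lr):
        self.lr, self.b1, self.b2, self.eps = lr, 0.9, 0.999, 1e-8
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.t = 0

    def step(self, w, grads):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            w[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _batch_grads(w, xb, l_mu, l_sd, rng):
    """Forward pass + closed-form backprop of the negative ELBO for one batch."""
    B = xb.shape[0]
    xlog = np.log1p(xb)
    h, mz, lvz, ml, lvl = _encode(w, xlog)
    eps_z = rng.standard_normal(mz.shape)
    eps_l = rng.standard_normal(ml.shape)
    sd_z = np.exp(0.5 * lvz)
    sd_l = np.exp(0.5 * lvl)
    z = mz + eps_z * sd_z
    l = ml + eps_l * sd_l
    hd, rho = _decode_rho(w, z)
    L = np.exp(l)  # per-cell library size
    theta = np.exp(w["log_theta"])
    mu = np.maximum(rho * L, 1e-10)

    rec = nb_logpmf(xb, mu, theta).sum(axis=1).mean()
    klz = 0.5 * (mz**2 + np.exp(lvz) - 1.0 - lvz).sum(axis=1).mean()
    kll = 0.5 * (
        (np.exp(lvl) + (ml - l_mu) ** 2) / l_sd**2 - 1.0 + 2.0 * math.log(l_sd) - lvl
    ).sum(axis=1).mean()
    loss = -(rec - klz - kll)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite loss")

    g = {}
    # d(-rec)/dmu, averaged over batch
    dmu = -(xb / mu - (xb + theta) / (mu + theta)) / B
    # mean path: mu = rho * L
    drho = dmu * L
    dl_rec = (dmu * mu).sum(axis=1, keepdims=True)  # dmu/dl = mu
    # softmax backprop
    dlogits = rho * (drho - (drho * rho).sum(axis=1, keepdims=True))
    g["Wo"] = hd.T @ dlogits
    g["bo"] = dlogits.sum(axis=0)
    dhd = (dlogits @ w["Wo"].T) * (hd > 0)
    g["Wd"] = z.T @ dhd
    g["bd"] = dhd.sum(axis=0)
    dz = dhd @ w["Wd"].T
    # theta gradient of -rec (log-parametrized)
    dtheta = -(
        digamma(xb + theta)
        - digamma(theta)
        + np.log(theta / (theta + mu))
        + 1.0
        - (xb + theta) / (theta + mu)
    ).sum(axis=0) / B
    g["log_theta"] = dtheta * theta

    # KL gradients (z)
    dmz = dz + mz / B
    dlvz = dz * eps_z * 0.5 * sd_z + 0.5 * (np.exp(lvz) - 1.0) / B
    # KL gradients (l)
    dml = dl_rec + (ml - l_mu) / l_sd**2 / B
    dlvl = dl_rec * eps_l * 0.5 * sd_l + 0.5 * (np.exp(lvl) / l_sd**2 - 1.0) / B

    g["Wmz"] = h.T @ dmz
    g["bmz"] = dmz.sum(axis=0)
    g["Wvz"] = h.T @ dlvz
    g["bvz"] = dlvz.sum(axis=0)
    g["Wml"] = h.T @ dml
    g["bml"] = dml.sum(axis=0)
    g["Wvl"] = h.T @ dlvl
    g["bvl"] = dlvl.sum(axis=0)
    dh = (dmz @ w["Wmz"].T + dlvz @ w["Wvz"].T + dml @ w["Wml"].T + dlvl @ w["Wvl"].T) * (h > 0)
    g["We"] = xlog.T @ dh
    g["be"] = dh.sum(axis=0)
    return g, (rec, klz, kll)


def train_vae(cm: CountMatrix, cfg: NBVAETrainConfig | None = None) -> NBVAEParams:
    """Fit the NB-VAE by Adam on minibatches; deterministic under cfg.seed."""
    if cfg is None:
        cfg = NBVAETrainConfig()
    counts = cm.counts.astype(float)
    if counts.size == 0:
        raise ValueError("count matrix is empty")
    rng = np.random.default_rng(cfg.seed)
    lib = np.maximum(counts.sum(axis=1), 1.0)
    l_mu = float(np.mean(np.log(lib)))
    l_sd = float(max(np.std(np.log(lib)), 1e-3))
    w = _init_weights(cm.n_genes, cfg.hidden_width, cfg.latent_dim, rng)
    opt = _Adam(_WEIGHT_KEYS, cfg.learning_rate)
    n = counts.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            xb = counts[order[start : start + cfg.batch_size]]
            try:
                grads, _ = _batch_grads(w, xb, l_mu, l_sd, rng)
            except FloatingPointError as err:
                raise FloatingPointError(f"{err} at epoch {epoch}") from err
            opt.step(w, grads)
    return NBVAEParams(w, cfg.latent_dim, l_mu, l_sd, gene_ids=list(cm.gene_ids))


def _decode_counts(p: NBVAEParams, z: np.ndarray, l: np.ndarray, rng) -> np.ndarray:
    _, rho = _decode_rho(p.weights, z)
    mu = np.maximum(rho * np.exp(l), 1e-12)
    return sample_nb(mu, p.theta, rng)


def sample_posterior(p: NBVAEParams, cm: CountMatrix, n_target: int, seed: int = 0) -> CountMatrix:
    """Replicate-and-stack posterior sampling.

    The input cells are passed through the encoder ceil(n_target / n_cells)
    times; each pass draws fresh z ~ q(z|x) and l ~ q(l|x) and decodes NB
    counts.  The first ``n_target`` rows are returned.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if cm.n_cells == 0:
        raise ValueError("empty input")
    rng = np.random.default_rng(seed)
    n_pass = math.ceil(n_target / cm.n_cells)
    blocks = []
    x = cm.counts.astype(float)
    for _ in range(n_pass):
        _, mz, lvz, ml, lvl = _encode(p.weights, np.log1p(x))
        z = mz + rng.standard_normal(mz.shape) * np.exp(0.5 * lvz)
        l = ml + rng.standard_normal(ml.shape) * np.exp(0.5 * lvl)
        blocks.append(_decode_counts(p, z, l, rng))
    counts = np.concatenate(blocks, axis=0)[:n_target]
    gene_ids = p.gene_ids or list(cm.gene_ids)
    return CountMatrix(counts, [f"posterior{i}" for i in range(n_target)], gene_ids)


def sample_prior(p: NBVAEParams, n_target: int, seed: int = 0) -> CountMatrix:
    """Generate from the prior: z ~ N(0, I), l ~ N(l_mu, 1); no input cells."""
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_target, p.latent_dim))
    l = rng.normal(p.l_mu, 1.0, size=(n_target, 1))
    counts = _decode_counts(p, z, l, rng)
    gene_ids = p.gene_ids or [f"gene{m}" for m in range(p.n_genes)]
    return CountMatrix(counts, [f"prior{i}" for i in range(n_target)], gene_ids)


def save_vae(p: NBVAEParams, path) -> None:
    np.savez(
        path,
        version=1,
        latent_dim=p.latent_dim,
        l_mu=p.l_mu,
        l_sd=p.l_sd,
        gene_ids=np.asarray(p.gene_ids or [], dtype=str),
        **{f"w_{k}": v for k, v in p.weights.items()},
    )


def load_vae(path) -> NBVAEParams:
    with np.load(path, allow_pickle=False) as z:
        w = {k[2:]: z[k] for k in z.files if k.startswith("w_")}
        gene_ids = [str(g) for g in z["gene_ids"]] or None
        return NBVAEParams(w, int(z["latent_dim"]), float(z["l_mu"]), float(z["l_sd"]), gene_ids)
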