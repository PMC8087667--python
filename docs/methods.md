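# Methods

## Model

The scDBM is a three-layer Boltzmann machine. The visible layer holds UMI
counts for M genes as negative-binomial units in the exponential-family
harmonium form; two binary hidden layers (K and L units) encode cell state.
The NB parametrization is by mean μ and inverse dispersion θ
(variance μ + μ²/θ; smaller θ = more cell-to-cell heterogeneity). Because
the visible bias a acts on the natural-parameter (log) scale, the model is
valid only while the effective bias â = a + W¹h¹ is negative; the
constraints aₘ ≤ −10⁻¹⁰ and W¹ ≤ 0 (re-applied after every gradient step)
guarantee this. W² is left unconstrained: only the visible-layer weights
need the sign restriction, and the top layer must be able to carve both
attractive and repulsive interactions between first-layer units (the
anti-correlated "exactly one program active" structure of well-separated
cell types requires opposite-sign W² columns).

## Training

Per-gene θ is initialized by method of moments (mean²/(var−mean), clipped
to [0.01, 1000]; genes with var ≤ mean get the ceiling) and re-estimated
every `theta_refresh_every` epochs (default 5) by regularized Fisher
scoring with λ = 5 (the penalty λ/θ² pushes small θ upward, so cluster
structure and excess zeros are not absorbed into baseline dispersion; the
update uses the observed information, which we verify against finite
differences). The μ fed to the estimator is the model's mean-field
reconstruction per cell, falling back to the empirical gene mean
(`theta_mu_mode`).

Two joint-training algorithms are implemented:

* **exact** (default): with the deliberately small first hidden layer
  (K = 2..4), both the visible layer and the top layer marginalize
  analytically — p(h¹) is a softmax over the 2ᴷ first-layer patterns and
  p(h¹|x) over the same patterns with the NB normalizer replaced by the
  data term. All sufficient-statistic expectations on both the data and
  the model side are therefore exact sums over at most 16 patterns, and
  training is plain (projected) stochastic gradient ascent on the exact
  likelihood. We chose this as the default after observing that the
  standard sampling-based recipe repeatedly converged to a degenerate top
  layer at this architecture scale (see below); with exact gradients the
  failure is attributable and fixable by initialization rather than by
  sampler mixing.
* **pcd**: the standard deep-Boltzmann recipe — greedy layer-wise RBM
  pretraining, then a mean-field positive phase (10 fixed-point
  iterations, tolerance 1e−4) with a persistent-contrastive-divergence
  negative phase (100 persistent chains, `cd_steps` Gibbs sweeps per
  update). Retained for larger hidden layers and as the reference
  implementation of the classical algorithm.

Initialization matters more than the algorithm. A cold start (W¹ ≈ 0,
hidden units almost always off) leaves the hidden-unit gradients vanishingly
small and training settles into a quasi-unimodal model that matches marginal
means but not the joint cluster structure. The default `init="kmeans"`
therefore seeds the code from a coarse k-means partition of log-normalized
counts: unit k's "on" state maps to cluster k's expression profile, the
visible bias is the elementwise-max ("ceiling") profile — which makes every
W¹ column automatically ≤ 0 — and b¹ is set so that each one-hot pattern
starts at its k-means proportion a couple of nats above the ceiling pattern
(whose NB normalizer would otherwise absorb all prior mass). W² starts at
N(0, 0.5): a small symmetric init leaves the top layer in a permutation-
symmetric basin where it cannot learn anti-correlated codes.

Count-scale statistics (for a, W¹) are an order of magnitude larger than
the O(1) hidden statistics, so b¹, b², W² use the base learning rate
(10⁻³) times `hidden_lr_scale` (default 50). The learning rate is held
constant for the first half of training and decays linearly to zero over
the second half; without the decay, SGD orbits the optimum and the model's
hidden-unit means can sit ~10% away from the data-side means, which
directly distorts generated cluster proportions.

Defaults: 2000 epochs, batch 64, K = L = 3 (2 for explicitly two-cluster
data). Training a 384-cell, 50-gene pilot takes ~30 s on one CPU.

## Generation

Synthetic cells are independent Gibbs chains (h¹ → h² → x sweeps). When
2ᴷ is small the chain is initialized by an exact draw from the enumerated
marginal p(h¹) followed by factorial draws of h² and x — an equilibrium
sample, so only `gibbs_steps` sweeps follow. For larger K the chains start
from a bias-only NB draw and run `burn_in` (default 100) extra sweeps.
The Gibbs kernel itself is validated against exhaustive enumeration of
exp(−E)/Z on a truncated two-gene machine (total variation < 0.02).

## NB-VAE

The reduced single-cell VAE has one hidden ReLU layer (width 128) in both
encoder and decoder, a 10-dimensional Gaussian latent z, and a
one-dimensional Gaussian log library size l whose prior location/scale are
the mean/SD of log total counts of the training cells. The decoder softmax
gives per-gene expression proportions ρ; counts are NB(ρₘ·e^l, θₘ) with a
log-parametrized free θ vector. The ELBO (reconstruction − KL(z) − KL(l))
is maximized with the reparameterization trick; all gradients are derived
in closed form and optimized with Adam (NumPy implementation, deterministic
under the seed). Posterior generation replicates the input cells
ceil(n_target/n_cells) times and decodes fresh q(z|x), q(l|x) draws; prior
generation uses z ~ N(0, I) and l ~ N(l_μ, 1) exactly. The unit-variance
library prior inflates prior-sample means by ≈ e^0.5 relative to the data —
a property of the procedure, visible in the examples. Prior samples also
interpolate between clusters; at fixture scale a community detection run on
them may merge clusters even though label transfer shows both populations
covered.

## Evaluation

The reference workflow is a pluggable provider; the default mirrors a
typical analysis: counts scaled to the median library size, log1p, PCA
(20 components), Leiden communities on the 15-nearest-neighbor graph of the
PCA space (resolution 0.1 — chosen so a clearly two-population dataset
yields two communities), and a 2-d UMAP fitted on the PCA coordinates.
User-supplied labels/coordinates pass through verbatim, so externally
produced clusterings can be dropped in. Synthetic cells are projected by
the fitted normalizer → PCA → UMAP transform and each takes the label of
its nearest reference cell (Euclidean distance, ties to the lowest index).

Indices: the Davies–Bouldin index is computed with p = q = 2 (S_k is the
RMS distance to the centroid) on the embedding coordinates; both the
classical (Sᵢ+Sⱼ)/Mᵢⱼ numerator and an (Sᵢ−Sⱼ)/Mᵢⱼ variant are implemented
behind `dbi_variant`-style flags, classical being the default. The adjusted
Rand index uses exact integer binomial sums. The package's reported ARI
compares the transferred labels of the synthetic cells against a de-novo
clustering of the synthetic data by the same provider — this makes "would
the synthetic data, analysed on its own, reproduce the reference partition"
a well-defined question. Cluster-proportion MAD is the mean over the union
of cluster ids of |count_ref − count_syn|. Per-gene MADs compare medians,
IQRs, coefficients of variation (genes with zero mean excluded, count
reported) and zero fractions on raw counts. The zero-preservation check
compares per-gene zero fractions of generated vs corrupted training data
and flags genes whose zero fraction dropped by more than a margin
(default 0.1) as evidence of imputation.

## Synthetic-data generator

`simulate_nb_mixture` draws cells from a K-cluster NB mixture: fixed
cluster proportions, per-cluster mean vectors, per-gene θ, lognormal
library-size factors, optional uniform extra zeros. The standard fixture is
2000 cells × 50 genes, two equal clusters, 10 marker genes at 8-fold
change (base mean 2, θ = 2, library-size log-SD 0.1). It emulates the NB
count structure and cluster separation the models assume; it does not
emulate batch effects, gene–gene correlation beyond cluster membership,
ambient RNA, doublets, or the extreme sparsity of droplet data — passing
tests on it shows the machinery is correct and that structure recoverable
in principle is recovered, not that performance transfers to any real
dataset.

## Pilot workflow

`run_pilot_experiment` freezes the reference clustering once on the full
original data, then for every plate size × repeat × generator subsamples a
pilot (seed = base_seed + repeat; training and generation reuse the same
seed), trains, generates `target_n` cells and evaluates. Rows carry full
provenance, failures are recorded per row, and a directory cache keyed by
(generator, plate size, repeat) makes sweeps resumable. The noise baseline
adds, per cell and replicate, Poisson counts whose rate is a single gamma
variate with scale ~ U(0,5) and shape ~ U(0,10) (a per-gene-rate variant is
available behind `noise_per_gene`), stacking ceil(target/pilot) noisy
copies. The baseline needs no training and bounds pure sampling-bias
effects.

## Numerical choices and limitations

* All NB quantities go through log-gamma; the pmf normalizes to 1 within
  1e−8 over the first 10⁴ counts for the parameter ranges tested.
* Fisher scoring clips θ into [0.01, 1000]; an all-zero gene gets the
  ceiling with a warning; a non-positive curvature triggers a damped step.
* The Fisher-scoring update adds the penalty exactly in the form used by
  the scoring algorithm (numerator +2λ/θ³), which corresponds to adding
  −λ/θ² to the log-likelihood; this is the only sign convention under
  which small θ is pushed upward.
* The exact trainer is limited to K ≤ 10 first-layer units (2ᴷ pattern
  enumeration); beyond that use `algorithm="pcd"`.
* Problem sizes throughout the test suite and the acceptance script
  (2000-cell fixtures, 384-cell pilots, two sweep repeats) are the
  package's fixture-scale defaults, chosen so the full pipeline exercises
  every component in minutes on a single CPU.
* Default DBI space is the 2-d embedding in which labels were transferred;
  an expression-space variant is a one-line change via the coordinates
  passed to `davies_bouldin`.
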