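"""Pilot-study experiment orchestration.

Emulates the planning workflow: subsample plate-sized pilot datasets from a
large reference, train each generative approach on the pilot, generate a
synthetic dataset of the original size, and score it against the frozen
reference clustering.  Repeats over plate sizes and random subsamples give
the sampling distribution of each quality index.

Also houses the negative-binomial noise baseline (noisy copies of the pilot
merged up to the target size — an upper bound for pure sampling bias) and
the artificial-zeros corruption used to probe whether generators impute
zeros.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, nb_vae
from .data_io import CountMatrix, subsample_plates
from .evaluation import (
    ClusteredEmbedding,
    ReferenceClusteringConfig,
    evaluate_synthetic,
    reference_clustering,
)
from .simulate import MixtureSpec, simulate_nb_mixture, two_cluster_spec  # noqa: F401  (re-export)

log = logging.getLogger("scdbm.pilot")

__all__ = [
    "PilotDesign",
    "PilotConfigs",
    "noise_baseline",
    "add_artificial_zeros",
    "run_pilot_experiment",
    "MixtureSpec",
    "simulate_nb_mixture",
    "two_cluster_spec",
]

GENERATORS = ("scdbm", "vae-prior", "vae-posterior", "baseline")


@dataclass(frozen=True)
class PilotDesign:
    plate_sizes: tuple[int, ...] = (384, 768, 1152, 1536, 1920, 2304)
    n_repeats: int = 30
    generators: tuple[str, ...] = GENERATORS
    base_seed: int = 0
    target_n: int | None = None  # None: use the original dataset size

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.plate_sizes):
            raise ValueError("plate sizes must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        unknown = set(self.generators) - set(GENERATORS)
        if unknown:
            raise ValueError(f"unknown generators: {sorted(unknown)}")


@dataclass(frozen=True)
class PilotConfigs:
    scdbm: core.ScDBMTrainConfig = field(default_factory=core.ScDBMTrainConfig)
    vae: nb_vae.NBVAETrainConfig = field(default_factory=nb_vae.NBVAETrainConfig)
    clustering: ReferenceClusteringConfig = field(default_factory=ReferenceClusteringConfig)
    gibbs_burn_in: int = 100
    gibbs_steps: int = 1
    noise_per_gene: bool = False


def noise_baseline(
    pilot: CountMatrix, target_n: int, seed: int = 0, per_gene: bool = False
) -> CountMatrix:
    """NB-noise baseline: merged noisy replicates of the pilot.

    Each replicate adds, per cell, a Poisson count per gene whose rate is a
    single gamma variate with scale ~ Uniform(0,5) and shape ~ Uniform(0,10)
    (``per_gene=True`` draws an independent gamma rate per gene instead).
    Replicates are stacked until ``target_n`` cells are reached.
    """
    if target_n < pilot.n_cells:
        raise ValueError(
            f"target_n={target_n} smaller than pilot size {pilot.n_cells}"
        )
    rng = np.random.default_rng(seed)
    n_rep = -(-target_n // pilot.n_cells)
    blocks = []
    for _ in range(n_rep):
        scale = rng.uniform(0.0, 5.0, size=pilot.n_cells)
        shape = rng.uniform(0.0, 10.0, size=pilot.n_cells)
        if per_gene:
            rate = rng.gamma(shape[:, None], scale[:, None], size=pilot.counts.shape)
        else:
            rate = rng.gamma(shape, scale)[:, None]
        noise = rng.poisson(np.broadcast_to(rate, pilot.counts.shape))
        blocks.append(pilot.counts + noise)
    counts = np.concatenate(blocks, axis=0)[:target_n]
    return CountMatrix(
        counts,
        [f"baseline{i}" for i in range(counts.shape[0])],
        pilot.gene_ids,
    )


def add_artificial_zeros(cm: CountMatrix, fraction: float = 0.2, seed: int = 0) -> CountMatrix:
    """Set a uniformly random fraction of all matrix entries to zero."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0.0:
        return cm
    rng = np.random.default_rng(seed)
    mask = rng.random(cm.counts.shape) < fraction
    return CountMatrix(np.where(mask, 0, cm.counts), cm.cell_ids, cm.gene_ids)


def _generate_synthetic(
    generator: str,
    pilot: CountMatrix,
    target_n: int,
    seed: int,
    cfgs: PilotConfigs,
) -> CountMatrix:
    from dataclasses import replace

    if generator == "baseline":
        return noise_baseline(pilot, target_n, seed, per_gene=cfgs.noise_per_gene)
    if generator == "scdbm":
        params = core.train_scdbm(pilot, replace(cfgs.scdbm, seed=seed))
        return core.generate(
            params,
            target_n,
            gibbs_steps=cfgs.gibbs_steps,
            burn_in=cfgs.gibbs_burn_in,
            seed=seed,
            gene_ids=pilot.gene_ids,
        )
    if generator in ("vae-prior", "vae-posterior"):
        params = nb_vae.train_vae(pilot, replace(cfgs.vae, seed=seed))
        if generator == "vae-prior":
            return nb_vae.sample_prior(params, target_n, seed=seed)
        return nb_vae.sample_posterior(params, pilot, target_n, seed=seed)
    raise ValueError(f"unknown generator {generator!r}")


def run_pilot_experiment(
    original: CountMatrix,
    design: PilotDesign,
    configs: PilotConfigs | None = None,
    reference: ClusteredEmbedding | None = None,
    cache_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run the full plate-size x repeat x generator sweep.

    The reference clustering is computed once on the full original data and
    frozen across all runs.  The subsample for repeat r uses seed
    ``base_seed + r``; training and generation reuse the same seed.  Rows
    are cached on disk (keyed by generator/plate size/repeat) when
    ``cache_dir`` is given, and individual run failures are recorded in the
    ``error`` column rather than aborting the sweep.
    """
    if configs is None:
        configs = PilotConfigs()
    target_n = design.target_n or original.n_cells
    if max(design.plate_sizes) > original.n_cells:
        raise ValueError("largest plate size exceeds the original dataset")
    if reference is None:
        reference = reference_clustering(original, configs.clustering)
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    rows = []
    for plate_size in design.plate_sizes:
        for repeat in range(design.n_repeats):
            seed = design.base_seed + repeat
            pilot = subsample_plates(original, 1, plate_size, seed=seed)
            for gen in design.generators:
                key = f"{gen}_{plate_size}_{repeat}"
                row = {
                    "generator": gen,
                    "plate_size": plate_size,
                    "repeat": repeat,
                    "seed": seed,
                    "error": "",
                }
                cached = cache / f"{key}.json" if cache else None
                if cached and cached.exists():
                    rows.append(json.loads(cached.read_text()))
                    continue
                t0 = time.time()
                try:
                    syn = _generate_synthetic(gen, pilot, target_n, seed, configs)
                    report = evaluate_synthetic(reference, original, syn, configs.clustering)
                    row.update(report.to_dict())
                except Exception as err:  # noqa: BLE001 — per-row fault isolation
                    log.warning("run %s failed: %s", key, err)
                    row["error"] = f"{type(err).__name__}: {err}"
                row["runtime_s"] = round(time.time() - t0, 2)
                log.info("run %s done in %.1fs", key, row["runtime_s"])
                if cached:
                    cached.write_text(json.dumps(row))
                rows.append(row)
    return pd.DataFrame(rows)
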