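"""Train an scDBM on a one-plate pilot and generate synthetic cells.

A 384-cell pilot is drawn from the 2000-cell fixture; the negative-binomial
deep Boltzmann machine is fit and then sampled to the original study size.
The generated data should reproduce both per-gene means and the
anti-correlation between the two clusters' marker blocks.
"""

import numpy as np

from scdbm.core import ScDBMTrainConfig, generate, train_scdbm
from scdbm.data_io import subsample_plates
from scdbm.simulate import simulate_nb_mixture, two_cluster_spec

cm, labels = simulate_nb_mixture(two_cluster_spec(seed=3))
pilot = subsample_plates(cm, n_plates=1, plate_size=384, seed=0)
print(f"pilot: {pilot.n_cells} of {cm.n_cells} cells")

params = train_scdbm(pilot, ScDBMTrainConfig(seed=0, n_hidden1=2, n_hidden2=2))
syn = generate(params, cm.n_cells, seed=1, gene_ids=cm.gene_ids)

rel = np.abs(syn.counts.mean(0) - cm.counts.mean(0)) / cm.counts.mean(0)
print(f"per-gene mean relative error: median {np.median(rel):.3f}")
c_orig = np.corrcoef(cm.counts[:, 0], cm.counts[:, 5])[0, 1]
c_syn = np.corrcoef(syn.counts[:, 0].astype(float), syn.counts[:, 5].astype(float))[0, 1]
print(f"marker anti-correlation (gene0 vs gene5): original {c_orig:.2f}, synthetic {c_syn:.2f}")
print("negative values mean the two cluster programs were learned, not averaged")
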