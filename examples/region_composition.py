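"""Cluster brain regions by cell-type composition and pick k by elbow.

Density rows are normalized to fractions, embedded in 2D, and K-means is
run for k = 1..10; the elbow (max second difference of the WCSS curve)
selects the cluster count. Two clusterings over the same regions are
compared with a row-stochastic overlap matrix."""

import numpy as np

from voxatlas import composition as comp
from voxatlas import synthetic as syn

truth = syn.make_brain(seed=1)
m = comp.composition_matrix(truth.densities)

emb = comp.embed_2d(m, seed=0, method="pca")
curve, k, labels = comp.elbow_kmeans(emb, k_max=10, seed=0)
print(f"{len(m)} regions embedded; WCSS curve {np.round(curve.to_numpy(), 2)}")
print(f"elbow selects k={k}; cluster sizes {labels.value_counts().to_dict()}")

# compare with a clustering of neuron-only composition
m_neuron = comp.composition_matrix(
    truth.densities[[c for c in truth.densities if truth.taxonomy.loc[c, "class"]
                     in ("Glut", "GABA", "Mod")]]
)
emb2 = comp.embed_2d(m_neuron, seed=0, method="pca")
_, k2, labels2 = comp.elbow_kmeans(emb2, k_max=10, seed=0)
ov = comp.overlap_matrix(labels, labels2.reindex(labels.index))
print(f"overlap matrix (rows sum to 100):\n{ov.round(1)}")

region = m.index[0]
prof = comp.composition_profile(m, region, threshold=0.05)
print(f"region {region} composition above 5%: "
      + ", ".join(f"{t} {f:.0%}" for t, f in prof))
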