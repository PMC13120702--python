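"""Assign m-types from topological morphology descriptors.

Each neuron's axonal and dendritic trees become persistence barcodes
(one bar per branch: birth at the branch's maximal radial distance from
the soma, death where it merges into an older branch), rasterized into
persistence images and clustered with K-means — pyramidal cells (PC) and
interneurons (IN) separately. Labels follow {class}_DEND_{d}_AX_{a}."""

from collections import Counter

from voxatlas import morphotypes as mt
from voxatlas import synthetic as syn

truth = syn.make_brain(seed=1)
ps = syn.make_patchseq(truth, n_cells_per_ttype=30, seed=1)

barcodes = {cid: (mt.tmd_barcode(t, "dendrite"), mt.tmd_barcode(t, "axon"))
            for cid, t in ps.morphologies.items()}
first = next(iter(barcodes.values()))[0]
print(f"{len(barcodes)} morphologies; first dendritic barcode has "
      f"{len(first)} bars (== leaf count), max radial extent "
      f"{first.bars[:, 0].max():.0f} µm")

db = mt.barcode_bounds([b for b, _ in barcodes.values()])
ab = mt.barcode_bounds([a for _, a in barcodes.values()])
images = [(cid,
           mt.persistence_image(b, resolution=30, bounds=db),
           mt.persistence_image(a, resolution=30, bounds=ab))
          for cid, (b, a) in barcodes.items()]

classes = ps.cells["neuron_class"].to_dict()
labels, model = mt.cluster_mtypes(images, classes, k_dend=3, k_ax=3, seed=0)
common = Counter(str(l) for l in labels.values()).most_common(4)
print("most common m-types:", ", ".join(f"{l} ({n})" for l, n in common))
print(f"schema with 10x10 clusters and 2 classes spans "
      f"{mt.MTypeModel(k_dend=10, k_ax=10).n_potential_labels()} potential m-types")
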