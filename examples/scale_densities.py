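"""Apply the three density-scaling methods.

Global scaling drives group neuron totals to the literature limits
(12,618,420 cortex / 41,825,100 cerebellum / 16,446,480 rest = 70.89 M
neurons; 108.69 M cells with glia); transplanted entries stay fixed;
Nissl scaling pins the highest-intensity region at 4e6 cells/mm^3."""

import pandas as pd

from voxatlas import densities as dm
from voxatlas import synthetic as syn

truth = syn.make_brain(seed=1)
atlas = truth.truth_atlas()
cfg = dm.ScalingConfig()

# transplant a literature value, then scale globally: the pin survives
rid = atlas.densities.index[0]
planted = dm.transplant(atlas, [{"region": rid, "type": "Pvalb_GABA", "density": 5000.0}])
scaled = dm.global_scale(planted, cfg, truth.hierarchy, truth.taxonomy)

counts = scaled.cell_counts()
neurons = truth.taxonomy[truth.taxonomy["class"].isin(cfg.neuron_classes)].index
groups = pd.Series({r: truth.hierarchy.group_of(r, cfg.group_acronyms)
                    for r in counts.index})
for g in ("cerebral_cortex", "cerebellum", "rest"):
    tot = counts.loc[groups[groups == g].index, neurons].sum().sum()
    print(f"{g:15s} neurons after scaling: {tot:>14,.0f}")
print(f"{'all cells':15s} after scaling: {counts.sum().sum():>17,.0f}")
print(f"transplanted density still {scaled.densities.loc[rid, 'Pvalb_GABA']:.0f} cells/mm^3")

# Nissl scaling: totals proportional to mean staining intensity
nscaled = dm.nissl_scale(atlas, truth.nissl, truth.annotation, anchor="max",
                         anchor_density=4e6)
means = truth.nissl.region_means(truth.annotation)
top = means.idxmax()
print(f"highest-intensity region {top}: total density "
      f"{nscaled.densities.loc[top].sum():,.0f} cells/mm^3 (anchored)")
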