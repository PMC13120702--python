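"""Build P(me-type | t-type) and convert t-type densities to me-types.

The e route goes through 20 shared feature clusters (P(e|t) = sum_k
P(e|C_k) P(C_k|t)); the m route is the empirical conditional from labeled
morphologies; the joint is their outer product under conditional
independence. Uncovered t-types are extrapolated by inverse-distance kNN
in a me-predictive gene subspace, and the reduction is validated by
comparing mRNA densities computed via t-types against the me route
(correction factor (N_me/N_t)^2)."""

import numpy as np

from voxatlas import etypes, memap
from voxatlas import synthetic as syn
from voxatlas.densities import DensityAtlas

truth = syn.make_brain(seed=1)
ps = syn.make_patchseq(truth, n_cells_per_ttype=60, seed=1)

# e route: clean -> cluster -> cluster-mediated conditionals
clean = etypes.clean_standardize(ps.efeatures)
assign = etypes.cluster_efeatures(clean, k=20)
pe = etypes.p_e_given_t(assign, clean, e_types=list(ps.p_e_given_t.columns))

# m route: empirical frequencies of (t, m) label pairs
pm = memap.p_m_given_t(ps.cells.rename(columns={"m_archetype": "m_type"}))

pme = memap.p_me_given_t(pm, pe)
print(f"P(me|t): {pme.shape[0]} t-types x {pme.shape[1]} me-labels, "
      f"row sums all 1: {np.allclose(pme.sum(axis=1), 1.0)}")

# extrapolate rows for t-types never patched (here: hold two out)
covered = pme.iloc[:-2]
full, flags = memap.extrapolate_knn(covered, ps.ref_expression, k=3)
print(f"extrapolated rows: {(flags == 'extrapolated').sum()}, "
      f"still row-stochastic: {np.allclose(full.sum(axis=1), 1.0)}")

# me densities by linearity; per-region neuron totals are conserved
atlas = truth.truth_atlas()
neuronal = list(pme.index)
sub = DensityAtlas(densities=atlas.densities[neuronal], counts=atlas.counts[neuronal])
me_atlas = memap.me_densities(full, sub)
print(f"regional totals conserved: "
      f"{np.allclose(me_atlas.densities.sum(axis=1), sub.densities.sum(axis=1))}")

# mRNA validation of a type-space reduction (here 8 t-types -> 5 e-types):
# the correction (N_e/N_t)^2 compensates the density inflation of applying
# the map twice; the residual error quantifies expression homogenization
val = memap.mrna_validate(sub.densities, pe, ps.ref_expression.loc[neuronal])
print(f"correction factor ({pe.shape[1]}/{pe.shape[0]})^2 = {val.correction:.4f}; "
      f"median relative mRNA error {np.nanmedian(val.relative_error.to_numpy()):.3f}")
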