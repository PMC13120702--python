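# voxatlas

Voxel-scale 3D cell-type density atlases from spatially registered
single-cell data, with probabilistic conversion between cell-type
classification systems.

Spatial transcriptomics (MERFISH-style) gives per-cell positions and
transcriptomic type (t-type) labels on brain sections, but modelers need
*densities* — cells/mm³ per region and per voxel — and they often need
them in the older morphological/electrophysiological (m-, e-, me-type)
vocabularies that circuit models consume. `voxatlas` covers that path
end-to-end for a hierarchically annotated brain volume:

- **Ontology & volumes** — load/extend an Allen-style region hierarchy so
  every voxel resolves to a leaf region (including cerebellar
  granular/molecular/Purkinje layer splits with their cell-routing
  rules), and compute per-section region volumes.
- **Registration** — estimate each section's cutting angles and coronal
  position against a 3D template by exhaustive normalized-mutual-
  information search; resample volumes along tilted planes.
- **Densities** — estimate density(r, t) = Σ cells / Σ sampled volume
  with explicit N/A-vs-zero semantics; scale by literature totals
  (globally, by density transplantation, or by Nissl intensity); add
  voxel-level granularity; project to 3D volumes (NIfTI).
- **Cross-modal mapping** — persistence-barcode morphology clustering
  (m-types), feature-cluster-mediated P(e-type|t-type), the joint
  P(me|t) = P(m|t) ⊗ P(e|t) under conditional independence, kNN
  extrapolation to unsampled t-types in a me-predictive gene subspace,
  and me-type densities by linearity:
  `Densities(me_i) = Σ_j P(me_i|t_j) · Densities(t_j)`.
- **Composition** — cluster regions by type composition with
  elbow-selected K-means and compare clusterings via overlap matrices.
- **Synthetic brain** — a first-class generator of every input above with
  known ground truth, used throughout the test suite for recovery checks.

## Worked example

`examples/scale_densities.py` builds a synthetic brain, transplants one
literature density, and applies the global scaling method:

```
cerebral_cortex neurons after scaling:     12,618,420
cerebellum      neurons after scaling:     41,825,100
rest            neurons after scaling:     16,446,480
all cells       after scaling:       108,690,000
transplanted density still 5000 cells/mm^3
highest-intensity region 15: total density 4,000,000 cells/mm^3 (anchored)
```

Group neuron totals land exactly on the primate-scaling-rule limits
(summing to 70.89 M neurons; 108.69 M cells with glia), the transplanted
entry is untouched by scaling, and the max-anchored Nissl variant pins the
highest-intensity region at 4×10⁶ cells/mm³. The other scripts in
`examples/` walk the remaining capabilities one at a time (density
estimation and recovery, section registration, morphology typing, the
cross-modal map, region composition); each prints the quantities it
computes and a line on what they mean.

A thin CLI wraps the file-oriented entry points:

```sh
voxatlas simulate --seed 1 -o data/          # synthetic inputs + truth
voxatlas ontology-extend --ontology o.json --rules rules.yaml -o ext.json
voxatlas register --slice s.nii.gz --template t.nii.gz --grid g.json -o geom.json
voxatlas scale --densities d.csv --ontology o.json --taxonomy tax.csv \
               --annotation a.nii.gz -o scaled.csv
```

See `docs/methods.md` for the models, assumptions, parameter defaults and
limitations.

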