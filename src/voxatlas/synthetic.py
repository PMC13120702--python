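"""Synthetic brain generator with known ground truth.

Every input the pipeline consumes can be emulated here: a hierarchical
region ontology with cortex / cerebellum (lobules split into granular,
molecular and Purkinje layers) / rest-of-brain groups, an annotation
volume of leaf-region cuboids, a Nissl-like intensity volume, per-cell
tables produced by Poisson placement inside tilted section planes,
negative-binomial gene expression per transcriptomic type, parametric
neuron morphologies per m-type archetype, and Gaussian
electrophysiological features per e-type. All generating parameters are
retained as ground truth so recovery can be asserted.

One master seed fans out to per-artifact child streams via
``np.random.default_rng([seed, artifact_index])`` so each artifact is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .densities import DensityAtlas, NisslVolume
from .errors import VoxAtlasError
from .morphotypes import NeuronTree
from .ontology import AnnotationVolume, RegionHierarchy, RegionNode
from .registration import SliceGeometry, plane_points, resample_plane

__all__ = [
    "BrainSpec",
    "SyntheticBrainTruth",
    "PatchSeqData",
    "default_taxonomy",
    "make_brain",
    "make_cells",
    "make_patchseq",
]

# stream indices for seed fan-out
_S_DENSITY, _S_NISSL, _S_CELLS, _S_EXPR, _S_MORPH, _S_EFEAT, _S_LABELS = range(7)


def default_taxonomy() -> pd.DataFrame:
    """Transcriptomic taxonomy of the synthetic brain.

    Class is the neurotransmitter-level grouping (Glut/GABA excitatory/
    inhibitory neurons, Mod modulatory, Glia and Other non-neuronal);
    subclass carries the marker names the cerebellar split rules key on
    (Purkinje, Bergmann, Golgi, Microglia).
    """
    rows = [
        # t_type, class, subclass
        ("CTX_Exc_1", "Glut", "IT_Glut"),
        ("CTX_Exc_2", "Glut", "ET_Glut"),
        ("CB_Granule_Glut", "Glut", "Granule_Glut"),
        ("Pvalb_GABA", "GABA", "Pvalb_GABA"),
        ("Sst_GABA", "GABA", "Sst_GABA"),
        ("Golgi_GABA", "GABA", "Golgi_GABA"),
        ("Purkinje_GABA", "GABA", "Purkinje_GABA"),
        ("Sero_Mod", "Mod", "Serotonergic"),
        ("Astro_Glia", "Glia", "Astro"),
        ("Bergmann_Glia", "Glia", "Bergmann_Glia"),
        ("Microglia_Glia", "Glia", "Microglia"),
        ("Oligo_Glia", "Glia", "Oligo"),
    ]
    tax = pd.DataFrame(rows, columns=["t_type", "class", "subclass"]).set_index("t_type")
    tax["cluster"] = tax.index
    return tax


@dataclass
class BrainSpec:
    """Size and composition of the synthetic brain.

    Defaults are desk-scale: a 64×48×48 grid of 25 µm voxels (a
    1.6×1.2×1.2 mm block), ~20 leaf regions, 12 t-types.
    """

    shape: tuple = (64, 48, 48)
    voxel_size_um: float = 25.0
    n_cortex: int = 6
    n_rest: int = 6
    n_lobules: int = 2
    margin: int = 3  # voxels of out-of-brain padding; 48-2·3=42 divides
    # evenly by the default 2×3 cortex grid, 3×3 rest grid and 3 layers,
    # so sibling regions get exactly equal voxel shares
    density_range: tuple = (2_000.0, 40_000.0)  # cells/mm³ per (region, type)


@dataclass
class SyntheticBrainTruth:
    """Ground truth behind one synthetic brain."""

    spec: BrainSpec
    seed: int
    hierarchy: RegionHierarchy
    annotation: AnnotationVolume
    nissl: NisslVolume
    densities: pd.DataFrame  # leaf region × t-type, cells/mm³
    taxonomy: pd.DataFrame
    region_kind: pd.Series  # leaf -> cortex|granular|molecular|purkinje|rest|wm

    def region_volumes(self) -> pd.Series:
        return self.annotation.region_volumes()

    def truth_atlas(self) -> DensityAtlas:
        """The generating densities packaged as a DensityAtlas."""
        vols = self.region_volumes()
        dens = self.densities.copy()
        counts = dens.mul(vols.reindex(dens.index), axis=0)
        return DensityAtlas(
            densities=dens, counts=counts, region_volumes=vols, provenance="truth"
        )


# mask of which classes may live in which region kind; mirrors the
# cerebellar layer rules so that layer splitting is self-consistent
_ALLOWED = {
    "cortex": {"CTX_Exc_1", "CTX_Exc_2", "Pvalb_GABA", "Sst_GABA", "Sero_Mod",
               "Astro_Glia", "Microglia_Glia", "Oligo_Glia"},
    "rest": {"CTX_Exc_2", "Pvalb_GABA", "Sst_GABA", "Sero_Mod",
             "Astro_Glia", "Microglia_Glia", "Oligo_Glia"},
    "granular": {"CB_Granule_Glut", "Golgi_GABA", "Astro_Glia",
                 "Microglia_Glia", "Oligo_Glia"},
    "molecular": {"Pvalb_GABA", "Sst_GABA", "Microglia_Glia"},
    "purkinje": {"Purkinje_GABA", "Bergmann_Glia", "Microglia_Glia"},
    "wm": {"Oligo_Glia", "Astro_Glia", "Microglia_Glia", "CTX_Exc_2"},
}


def make_brain(spec: BrainSpec | None = None, seed: int = 0) -> SyntheticBrainTruth:
    """Build hierarchy, annotation volume, Nissl volume and true densities.

    The brain is a padded box split along the coronal x-axis into three
    group slabs (cerebral cortex CTX, cerebellum CB, rest RST); within a
    slab, leaf regions tile the y-z cross-section as cuboids and extend
    through the slab, so every coronal section intersects several leaves.
    Cerebellar lobules are split into granular/molecular/Purkinje layer
    leaves stacked along y. Nissl intensity is the region's total density
    (rescaled) plus voxel noise. Deterministic per seed.
    """
    spec = spec or BrainSpec()
    if spec.n_cortex + spec.n_rest + spec.n_lobules < 2:
        raise VoxAtlasError("need at least 2 regions")
    tax = default_taxonomy()
    nx, ny, nz = spec.shape
    m = spec.margin
    if nx - 2 * m < 6 or ny - 2 * m < 6 or nz - 2 * m < 6:
        raise VoxAtlasError("volume too small for the requested packing")

    nodes = [
        RegionNode(1, "root", "synthetic brain root", None),
        RegionNode(2, "CTX", "cerebral cortex", 1),
        RegionNode(3, "CB", "cerebellum", 1),
        RegionNode(4, "RST", "rest of brain", 1),
    ]
    next_id = 10
    region_kind: dict[int, str] = {}

    def add_leaf(parent: int, acr: str, name: str, kind: str) -> int:
        nonlocal next_id
        nodes.append(RegionNode(next_id, acr, name, parent))
        region_kind[next_id] = kind
        next_id += 1
        return next_id - 1

    ctx_leaves = [
        add_leaf(2, f"CTX{i+1}", f"cortical area {i+1}", "cortex")
        for i in range(spec.n_cortex)
    ]
    lobule_layers: dict[int, list[int]] = {}
    for j in range(spec.n_lobules):
        nodes.append(RegionNode(next_id, f"CBL{j+1}", f"cerebellar lobule {j+1}", 3))
        lob = next_id
        next_id += 1
        lobule_layers[lob] = [
            add_leaf(lob, f"CBL{j+1}gr", f"cerebellar lobule {j+1}, granular layer", "granular"),
            add_leaf(lob, f"CBL{j+1}mo", f"cerebellar lobule {j+1}, molecular layer", "molecular"),
            add_leaf(lob, f"CBL{j+1}pu", f"cerebellar lobule {j+1}, Purkinje layer", "purkinje"),
        ]
    rest_leaves = [
        add_leaf(4, f"RST{i+1}", f"rest region {i+1}", "rest")
        for i in range(spec.n_rest - 1)
    ]
    # one white-matter tract, annotated at parent level in real atlases
    nodes.append(RegionNode(next_id, "fxs", "fiber tract system", 4))
    wm_parent = next_id
    next_id += 1
    wm_leaves = [
        add_leaf(wm_parent, "fxs-a", "fiber tract system, anterior limb", "wm"),
        add_leaf(wm_parent, "fxs-p", "fiber tract system, posterior limb", "wm"),
    ]
    # wire children
    by_id = {n.region_id: n for n in nodes}
    for n in nodes:
        if n.parent_id is not None:
            by_id[n.parent_id].children.append(n.region_id)
    hierarchy = RegionHierarchy.from_nodes(nodes)

    # --- annotation volume: group slabs along x, leaf cuboids in (y, z)
    grid = np.zeros(spec.shape, dtype=np.int32)
    x0, x1 = m, nx - m
    bounds = np.linspace(x0, x1, 4).round().astype(int)
    slabs = {"ctx": (bounds[0], bounds[1]), "cb": (bounds[1], bounds[2]), "rst": (bounds[2], bounds[3])}

    def tile_yz(leaves: list[int], xa: int, xb: int) -> None:
        k = len(leaves)
        ncol = int(np.ceil(np.sqrt(k)))
        nrow = int(np.ceil(k / ncol))
        ys = np.linspace(m, ny - m, nrow + 1).round().astype(int)
        zs = np.linspace(m, nz - m, ncol + 1).round().astype(int)
        for idx, leaf in enumerate(leaves):
            r, c = divmod(idx, ncol)
            grid[xa:xb, ys[r]:ys[r + 1], zs[c]:zs[c + 1]] = leaf

    tile_yz(ctx_leaves, *slabs["ctx"])
    tile_yz(rest_leaves + wm_leaves, *slabs["rst"])
    # cerebellum: lobules tile (z); layers stacked along y inside a lobule
    xa, xb = slabs["cb"]
    zs = np.linspace(m, nz - m, spec.n_lobules + 1).round().astype(int)
    for j, (lob, layers) in enumerate(lobule_layers.items()):
        ys = np.linspace(m, ny - m, 4).round().astype(int)
        for li, leaf in enumerate(layers):
            grid[xa:xb, ys[li]:ys[li + 1], zs[j]:zs[j + 1]] = leaf

    annotation = AnnotationVolume(grid=grid, voxel_size_um=spec.voxel_size_um)
    annotation.validate_against(hierarchy)

    # --- true densities
    rng = np.random.default_rng([seed, _S_DENSITY])
    leaves = sorted(region_kind)
    lo, hi = spec.density_range
    dens = pd.DataFrame(0.0, index=leaves, columns=list(tax.index))
    for leaf in leaves:
        allowed = _ALLOWED[region_kind[leaf]]
        for tt in tax.index:
            if tt in allowed:
                dens.loc[leaf, tt] = rng.uniform(lo, hi)

    # --- Nissl volume: intensity tracks total density within each region
    rng_n = np.random.default_rng([seed, _S_NISSL])
    totals = dens.sum(axis=1)
    base = totals / totals.max()
    nissl_grid = np.zeros(spec.shape, dtype=float)
    for leaf in leaves:
        mask = grid == leaf
        noise = rng_n.normal(1.0, 0.08, size=int(mask.sum())).clip(0.5, 1.5)
        nissl_grid[mask] = base[leaf] * noise
    nissl = NisslVolume(grid=nissl_grid, voxel_size_um=spec.voxel_size_um)

    return SyntheticBrainTruth(
        spec=spec,
        seed=seed,
        hierarchy=hierarchy,
        annotation=annotation,
        nissl=nissl,
        densities=dens,
        taxonomy=tax,
        region_kind=pd.Series(region_kind),
    )


def make_cells(
    truth: SyntheticBrainTruth,
    n_slices: int = 8,
    tilt: tuple = (0.0, 0.0),
    thickness_um: float = 25.0,
    qc_fail_fraction: float = 0.02,
    n_zero_coord: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[SliceGeometry]]:
    """Place cells by Poisson sampling inside tilted section planes.

    For every section the annotation is resampled along the cutting plane;
    each (region, section) slab contributes ``Poisson(density × pixel_area
    × thickness)`` cells per type, positioned uniformly over the region's
    plane pixels. A fraction of extra cells is flagged ``qc_pass=False``
    and a few pass-QC cells with zero coordinates are injected, both to be
    removed by the QC filter.
    """
    rng = np.random.default_rng([truth.seed, _S_CELLS, seed])
    nx = truth.annotation.grid.shape[0]
    vx = truth.annotation.voxel_size_um
    positions = np.linspace(0.15, 0.85, n_slices) * (nx - 1) * vx
    geoms = [
        SliceGeometry(tilt[0], tilt[1], float(p), thickness_um) for p in positions
    ]
    area_mm2 = (vx * 1e-3) ** 2
    thick_mm = thickness_um * 1e-3
    types = list(truth.densities.columns)
    tax = truth.taxonomy

    rows = []
    cid = 0
    for sid, geom in enumerate(geoms):
        plane = resample_plane(truth.annotation, geom, kind="labels")
        pts = plane_points(truth.annotation, geom)  # (3, h, w) voxel coords
        flat_ids = plane.grid.ravel()
        flat_pts = pts.reshape(3, -1).T * vx  # µm
        for rid in np.unique(flat_ids[flat_ids != 0]):
            sel = np.flatnonzero(flat_ids == rid)
            vol = len(sel) * area_mm2 * thick_mm
            for tt in types:
                lam = truth.densities.loc[rid, tt] * vol
                n = int(rng.poisson(lam)) if lam > 0 else 0
                if n == 0:
                    continue
                pick = rng.choice(sel, size=n, replace=True)
                jitter = rng.uniform(-0.5, 0.5, size=(n, 3)) * vx
                xyz = flat_pts[pick] + jitter
                for p in xyz:
                    rows.append(
                        (cid, p[0], p[1], p[2], sid, int(rid), tt,
                         tax.loc[tt, "class"], tax.loc[tt, "subclass"], True)
                    )
                    cid += 1
    cols = ["cell_id", "x_um", "y_um", "z_um", "slice_id", "region_id",
            "t_type", "class", "subclass", "qc_pass"]
    cells = pd.DataFrame(rows, columns=cols)

    # inject QC failures and zero-coordinate cells
    n_fail = int(round(qc_fail_fraction * len(cells)))
    if n_fail and len(cells):
        src = cells.sample(n=n_fail, random_state=int(rng.integers(2**31)))
        fail = src.copy()
        fail["cell_id"] = np.arange(cid, cid + n_fail)
        cid += n_fail
        fail["qc_pass"] = False
        cells = pd.concat([cells, fail], ignore_index=True)
    if n_zero_coord and len(cells):
        src = cells.sample(n=n_zero_coord, random_state=int(rng.integers(2**31)))
        zz = src.copy()
        zz["cell_id"] = np.arange(cid, cid + n_zero_coord)
        zz[["x_um", "y_um"]] = 0.0
        zz["qc_pass"] = True
        cells = pd.concat([cells, zz], ignore_index=True)
    return cells, geoms


# ---------------------------------------------------------------------------
# patch-seq-like data


@dataclass
class PatchSeqData:
    """Synthetic patch-seq bundle with its generating truth."""

    cells: pd.DataFrame  # cell_id, t_type, m_archetype, e_type, region
    expression: pd.DataFrame  # cell × gene raw counts
    ref_expression: pd.DataFrame  # t-type × gene trimmed-mean-like counts
    efeatures: pd.DataFrame  # cell × e-feature (+ metadata columns)
    morphologies: dict  # cell_id -> NeuronTree
    p_m_given_t: pd.DataFrame
    p_e_given_t: pd.DataFrame
    m_archetypes: pd.DataFrame
    e_feature_means: pd.DataFrame
    gene_means: pd.DataFrame


_EFEATURES = [
    "ap_amplitude_mv", "ap_width_ms", "isi_cv", "adaptation_index",
    "input_resistance_mohm", "sag_ratio",
]


def _archetype_table(rng: np.random.Generator) -> pd.DataFrame:
    """Parametric morphology archetypes: tree depth and segment length
    control the persistence barcode's bar count and extent."""
    rows = []
    for cls, n_arch in (("PC", 3), ("IN", 3)):
        for a in range(n_arch):
            rows.append(
                {
                    "archetype": f"{cls}_arch{a}",
                    "class": cls,
                    "dend_depth": 2 + a,
                    "dend_seg_um": 40.0 + 35.0 * a,
                    "ax_depth": 4 - a,
                    "ax_seg_um": 60.0 + 25.0 * (2 - a),
                }
            )
    return pd.DataFrame(rows).set_index("archetype")


def _grow_tree(
    rng: np.random.Generator, arch: pd.Series
) -> NeuronTree:
    """Binary-branching tree per archetype: one axon and one dendrite
    stem from a 3-point soma."""
    ids, types, xyz, radius, parents = [], [], [], [], []

    def add(t, p, parent):
        ids.append(len(ids) + 1)
        types.append(t)
        xyz.append(p)
        radius.append(1.0)
        parents.append(parent)
        return ids[-1]

    for p in ([0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]):
        add(1, p, -1 if not ids else 1)

    def grow(kind_type, depth, seg, direction):
        stack = [(1, np.zeros(3), np.asarray(direction, dtype=float), 0)]
        while stack:
            parent, pos, dirn, lvl = stack.pop()
            if lvl >= depth:
                continue
            length = seg * rng.uniform(0.85, 1.15)
            new = pos + dirn * length
            nid = add(kind_type, new.tolist(), parent)
            if lvl + 1 < depth:
                for sign in (1.0, -1.0):
                    rot = dirn + sign * 0.45 * np.array([dirn[1], -dirn[0], 0.3])
                    rot = rot / np.linalg.norm(rot)
                    stack.append((nid, new, rot, lvl + 1))

    grow(3, int(arch["dend_depth"]), float(arch["dend_seg_um"]), [0, 1, 0])
    grow(2, int(arch["ax_depth"]), float(arch["ax_seg_um"]), [0, -1, 0])
    return NeuronTree(
        ids=np.asarray(ids),
        types=np.asarray(types),
        xyz=np.asarray(xyz, dtype=float),
        radius=np.asarray(radius, dtype=float),
        parents=np.asarray(parents),
    )


def make_patchseq(
    truth: SyntheticBrainTruth,
    n_cells_per_ttype: int = 30,
    n_ref_cells_per_etype: int = 20,
    n_genes: int = 60,
    nb_dispersion: float = 4.0,
    efeature_sd: float = 0.25,
    seed: int = 0,
) -> PatchSeqData:
    """Generate linked expression / morphology / e-feature data per cell.

    Each patch-seq cell draws a neuronal t-type, then an m-archetype from
    the true P(m|t) and an e-type from the true P(e|t); expression follows
    a negative binomial around per-t-type gene means, morphology a
    parametric tree of the m-archetype, e-features a Gaussian around the
    e-type's mean vector. Reference e-cells with canonical e-type labels
    are emitted alongside.
    """
    tax = truth.taxonomy
    neuronal = [t for t in tax.index if tax.loc[t, "class"] in ("Glut", "GABA", "Mod")]
    rng_l = np.random.default_rng([truth.seed, _S_LABELS, seed])
    arch = _archetype_table(rng_l)

    # truth conditionals: excitatory t-types use PC archetypes and the
    # pyramidal e-type; others the interneuron pools
    e_exc = ["cADpyr"]
    e_inh = ["bAC", "cAC", "cNAC", "bNAC"]
    pm_rows = {}
    pe_rows = {}
    for i, tt in enumerate(neuronal):
        is_exc = tax.loc[tt, "class"] == "Glut"
        m_pool = [a for a in arch.index if arch.loc[a, "class"] == ("PC" if is_exc else "IN")]
        e_pool = e_exc if is_exc else e_inh
        alpha_m = np.full(len(m_pool), 0.4)
        alpha_m[i % len(m_pool)] = 5.0
        pm = rng_l.dirichlet(alpha_m)
        alpha_e = np.full(len(e_pool), 0.4)
        alpha_e[i % len(e_pool)] = 5.0
        pe = rng_l.dirichlet(alpha_e)
        pm_rows[tt] = pd.Series(pm, index=m_pool)
        pe_rows[tt] = pd.Series(pe, index=e_pool)
    all_m = list(arch.index)
    all_e = e_exc + e_inh
    p_m = pd.DataFrame(0.0, index=neuronal, columns=all_m)
    p_e = pd.DataFrame(0.0, index=neuronal, columns=all_e)
    for tt in neuronal:
        p_m.loc[tt, pm_rows[tt].index] = pm_rows[tt]
        p_e.loc[tt, pe_rows[tt].index] = pe_rows[tt]

    # gene expression truth: each t-type over-expresses a private gene block
    rng_x = np.random.default_rng([truth.seed, _S_EXPR, seed])
    genes = [f"gene_{g:03d}" for g in range(n_genes)]
    gene_means = pd.DataFrame(
        rng_x.uniform(0.5, 3.0, size=(len(neuronal), n_genes)),
        index=neuronal, columns=genes,
    )
    block = max(1, n_genes // (2 * len(neuronal)))
    for i, tt in enumerate(neuronal):
        start = (i * block) % n_genes
        gene_means.iloc[i, start:start + block] += rng_x.uniform(20.0, 40.0, size=min(block, n_genes - start))

    def nb_sample(mean_row: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        r = nb_dispersion
        p = r / (r + mean_row)
        return rng.negative_binomial(r, p)

    # e-feature truth
    rng_e = np.random.default_rng([truth.seed, _S_EFEAT, seed])
    e_means = pd.DataFrame(
        rng_e.uniform(-2.0, 2.0, size=(len(all_e), len(_EFEATURES))),
        index=all_e, columns=_EFEATURES,
    )

    rng_m = np.random.default_rng([truth.seed, _S_MORPH, seed])
    leaves = list(truth.densities.index)
    cells_rows = []
    expr_rows = []
    efeat_rows = []
    morph: dict = {}
    cid = 0
    for tt in neuronal:
        for _ in range(n_cells_per_ttype):
            cell_id = f"ps_{cid:05d}"
            cid += 1
            m_lab = rng_l.choice(all_m, p=p_m.loc[tt].to_numpy())
            e_lab = rng_l.choice(all_e, p=p_e.loc[tt].to_numpy())
            region = leaves[int(rng_l.integers(len(leaves)))]
            cells_rows.append((cell_id, tt, m_lab, e_lab, region, arch.loc[m_lab, "class"]))
            expr_rows.append(nb_sample(gene_means.loc[tt].to_numpy(), rng_x))
            efeat_rows.append(
                e_means.loc[e_lab].to_numpy() + rng_e.normal(0, efeature_sd, len(_EFEATURES))
            )
            morph[cell_id] = _grow_tree(rng_m, arch.loc[m_lab])
    cells = pd.DataFrame(
        cells_rows,
        columns=["cell_id", "t_type", "m_archetype", "e_type", "region", "neuron_class"],
    ).set_index("cell_id")
    expression = pd.DataFrame(expr_rows, index=cells.index, columns=genes)
    efeat = pd.DataFrame(efeat_rows, index=cells.index, columns=_EFEATURES)
    efeat.insert(0, "source", "patchseq")
    efeat.insert(1, "t_type", cells["t_type"].to_numpy())

    ref_rows = []
    ref_idx = []
    for e_lab in all_e:
        for j in range(n_ref_cells_per_etype):
            ref_idx.append(f"ref_{e_lab}_{j:03d}")
            ref_rows.append(
                e_means.loc[e_lab].to_numpy() + rng_e.normal(0, efeature_sd, len(_EFEATURES))
            )
    ref = pd.DataFrame(ref_rows, index=ref_idx, columns=_EFEATURES)
    ref.insert(0, "source", "reference")
    ref.insert(1, "e_type", [i.split("_")[1] for i in ref_idx])
    efeatures = pd.concat([efeat, ref])

    return PatchSeqData(
        cells=cells,
        expression=expression,
        ref_expression=gene_means.round(3),
        efeatures=efeatures,
        morphologies=morph,
        p_m_given_t=p_m,
        p_e_given_t=p_e,
        m_archetypes=arch,
        e_feature_means=e_means,
        gene_means=gene_means,
    )
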