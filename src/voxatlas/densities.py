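"""Cell-type density estimation and scaling.

Densities are estimated per (leaf region, cell type) as the total number of
cells observed in that region across all aligned sections divided by the
summed sampled region volume (section cross-section area × thickness),
giving cells/mm³. A region sampled by no section has density N/A (encoded
as NaN) — distinct from an observed zero, which is biological information.

Three scaling methods adjust the raw estimates toward literature totals:

* **global scaling** — within each anatomical group (cerebral cortex,
  cerebellum, rest of brain) a single multiplier drives the group's
  neuron count to a literature target, preserving relative differences;
  a cerebellar exception scales granular-layer excitatory neurons while
  holding inhibitory counts constant. A second multiplier then brings the
  all-cells (glia included) total to its target.
* **density transplantation** — selected region/type densities are
  overwritten with literature values and held fixed through any later
  scaling.
* **Nissl-based scaling** — per-region total densities are set
  proportional to mean Nissl staining intensity, anchored at a reference
  region (e.g. the highest-intensity region pinned to 4×10⁶ cells/mm³),
  with within-region type ratios preserved.

Optionally, Nissl intensity also provides voxel-level granularity inside a
region while conserving the region's mean density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ScalingError, VoxAtlasError
from .ontology import AnnotationVolume, RegionHierarchy

__all__ = [
    "DensityAtlas",
    "ScalingConfig",
    "NisslVolume",
    "qc_filter",
    "estimate_densities",
    "global_scale",
    "transplant",
    "nissl_scale",
    "nissl_granularity",
    "project_to_volume",
    "aggregate_types",
]

# Literature-derived defaults: neuron totals per group from primate scaling
# rules, all-cells consensus total.
DEFAULT_GROUP_TARGETS = {
    "cerebral_cortex": 12_618_420.0,
    "cerebellum": 41_825_100.0,
    "rest": 16_446_480.0,
}
DEFAULT_ALL_CELLS_TOTAL = 108_690_000.0


@dataclass
class ScalingConfig:
    """Configuration of the scaling step.

    ``group_acronyms`` maps group name -> ancestor acronym in the region
    hierarchy; any region under neither falls in the ``rest`` group.
    ``neuron_classes`` are the taxonomy classes counted as neurons.
    """

    group_targets: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_TARGETS))
    all_cells_total: float = DEFAULT_ALL_CELLS_TOTAL
    group_acronyms: dict = field(default_factory=lambda: {"cerebral_cortex": "CTX", "cerebellum": "CB"})
    neuron_classes: tuple = ("Glut", "GABA", "Mod")
    excitatory_classes: tuple = ("Glut",)
    granular_name_token: str = "granular"


@dataclass
class DensityAtlas:
    """Region × type density matrix (cells/mm³) with N/A-vs-zero semantics.

    ``densities`` uses NaN for N/A (no sampled volume). ``counts`` holds the
    observed cell counts behind each estimate. ``region_volumes`` is the
    *total* region volume from the full annotation (mm³), used to convert
    densities to whole-region cell counts for scaling. ``fixed`` flags
    transplanted entries that scaling must not touch.
    """

    densities: pd.DataFrame
    counts: pd.DataFrame
    region_volumes: pd.Series | None = None
    fixed: pd.DataFrame | None = None
    provenance: str = "unscaled"

    def __post_init__(self):
        if self.fixed is None:
            self.fixed = pd.DataFrame(
                False, index=self.densities.index, columns=self.densities.columns
            )

    def copy(self) -> "DensityAtlas":
        return DensityAtlas(
            densities=self.densities.copy(),
            counts=self.counts.copy(),
            region_volumes=None if self.region_volumes is None else self.region_volumes.copy(),
            fixed=self.fixed.copy(),
            provenance=self.provenance,
        )

    def cell_counts(self) -> pd.DataFrame:
        """Whole-region cell counts: density × total region volume."""
        if self.region_volumes is None:
            raise VoxAtlasError("region_volumes required to compute counts")
        vols = self.region_volumes.reindex(self.densities.index)
        return self.densities.mul(vols, axis=0)

    def to_csv(self, path) -> None:
        self.densities.to_csv(path, na_rep="")

    @property
    def types(self) -> list:
        return list(self.densities.columns)


def qc_filter(cells: pd.DataFrame, bounds_um: tuple | None = None) -> pd.DataFrame:
    """Drop cells failing quality control or with degenerate coordinates.

    Removes rows with ``qc_pass == False``, rows with any coordinate
    exactly 0 (a known failure mode of upstream registration), and — when
    volume bounds are given — rows outside the volume.
    """
    out = cells
    if "qc_pass" in out.columns:
        out = out[out["qc_pass"].astype(bool)]
    coord_cols = ["x_um", "y_um", "z_um"]
    zero = (out[coord_cols] == 0).any(axis=1)
    out = out[~zero]
    if bounds_um is not None:
        for col, hi in zip(coord_cols, bounds_um):
            out = out[(out[col] >= 0) & (out[col] <= hi)]
    return out.copy()


def estimate_densities(
    cells: pd.DataFrame,
    volumes: pd.DataFrame,
    all_regions: list | None = None,
    all_types: list | None = None,
    region_volumes: pd.Series | None = None,
) -> DensityAtlas:
    """Estimate density(r, t) = Σ_slices count(r, t, s) / Σ_slices volume(r, s).

    ``volumes`` is the per-(region, slice) sampled-volume table. Regions in
    ``all_regions`` never intersected by a section get N/A rows. Cells in
    regions with no volume rows are dropped with a warning; a region with
    cells but zero summed volume is an input inconsistency.
    """
    sampled = volumes.groupby("region_id")["volume_mm3"].sum()
    types = sorted(all_types if all_types is not None else cells["t_type"].unique())
    regions = sorted(
        set(all_regions) if all_regions is not None else set(sampled.index) | set(cells["region_id"])
    )

    orphan = ~cells["region_id"].isin(sampled.index)
    if orphan.any():
        warnings.warn(
            f"{int(orphan.sum())} cells lie in regions with no sampled volume; dropped"
        )
        cells = cells[~orphan]

    counts = (
        cells.groupby(["region_id", "t_type"]).size().unstack(fill_value=0)
        .reindex(index=regions, columns=types, fill_value=0)
        .astype(float)
    )
    dens = pd.DataFrame(np.nan, index=regions, columns=types)
    for rid in sampled.index:
        if rid not in dens.index:
            continue
        vol = sampled[rid]
        if vol <= 0:
            if counts.loc[rid].sum() > 0:
                raise VoxAtlasError(f"region {rid} has cells but zero sampled volume")
            continue
        dens.loc[rid] = counts.loc[rid] / vol
    counts[dens.isna()] = np.nan
    return DensityAtlas(densities=dens, counts=counts, region_volumes=region_volumes)


def transplant(atlas: DensityAtlas, entries: list[dict]) -> DensityAtlas:
    """Overwrite selected densities with literature values and pin them.

    Each entry is ``{"region": id, "type": label, "density": cells/mm³}``.
    Pinned entries are excluded from the scalable mass of every later
    scaling step and never change again.
    """
    out = atlas.copy()
    bad = [
        e for e in entries
        if e["region"] not in out.densities.index or e["type"] not in out.densities.columns
    ]
    if bad:
        raise ScalingError(f"unknown region/type in transplant entries: {bad}")
    for e in entries:
        out.densities.loc[e["region"], e["type"]] = float(e["density"])
        out.fixed.loc[e["region"], e["type"]] = True
    if entries:
        out.provenance = out.provenance + "+transplant"
    return out


def _region_groups(
    regions, hierarchy: RegionHierarchy, cfg: ScalingConfig
) -> pd.Series:
    return pd.Series(
        {r: hierarchy.group_of(r, cfg.group_acronyms) for r in regions}, dtype="object"
    )


def global_scale(
    atlas: DensityAtlas,
    cfg: ScalingConfig,
    hierarchy: RegionHierarchy,
    taxonomy: pd.DataFrame,
) -> DensityAtlas:
    """Scale neuron densities to per-group literature targets, then
    non-neuronal densities to the all-cells target.

    One multiplier per group preserves within-group ratios. Cerebellar
    exception: the multiplier is applied to excitatory types in
    granular-layer leaves only, inhibitory (and modulatory) neuron numbers
    stay constant; their mass is subtracted from the target first.
    Transplanted entries never change and their contribution is removed
    from the target before the multiplier is computed. Applying the
    function twice is the identity.
    """
    if atlas.region_volumes is None:
        raise ScalingError("global scaling needs total region volumes")
    out = atlas.copy()
    type_class = taxonomy["class"].reindex(out.densities.columns)
    if type_class.isna().any():
        raise ScalingError(
            f"types missing from taxonomy: {list(type_class[type_class.isna()].index)}"
        )
    neuron_types = type_class[type_class.isin(cfg.neuron_classes)].index
    exc_types = type_class[type_class.isin(cfg.excitatory_classes)].index
    nn_types = type_class[~type_class.isin(cfg.neuron_classes)].index

    groups = _region_groups(out.densities.index, hierarchy, cfg)
    counts = out.cell_counts()

    for group, target in cfg.group_targets.items():
        members = groups[groups == group].index
        if len(members) == 0:
            warnings.warn(f"scaling group {group!r} has no regions; skipped")
            continue
        sub_c = counts.loc[members, neuron_types]
        sub_fixed = out.fixed.loc[members, neuron_types]
        fixed_mass = float(sub_c.where(sub_fixed).sum().sum())
        if group == "cerebellum":
            granular = [
                r for r in members
                if cfg.granular_name_token in hierarchy.nodes[r].name.lower()
            ]
            scalable_cols = exc_types
            scalable_rows = granular if granular else list(members)
            held = sub_c.drop(columns=exc_types)
            held_mass = float(held.where(~sub_fixed[held.columns]).sum().sum())
            off_granular = sub_c.loc[[r for r in members if r not in scalable_rows], exc_types]
            held_mass += float(
                off_granular.where(~out.fixed.loc[off_granular.index, exc_types]).sum().sum()
            )
        else:
            scalable_cols = neuron_types
            scalable_rows = list(members)
            held_mass = 0.0
        mass_tbl = counts.loc[scalable_rows, scalable_cols]
        mass = float(mass_tbl.where(~out.fixed.loc[scalable_rows, scalable_cols]).sum().sum())
        residual = target - fixed_mass - held_mass
        if residual < 0:
            raise ScalingError(
                f"group {group!r}: fixed+held neuron mass exceeds target {target}"
            )
        if mass <= 0:
            if residual > 0:
                warnings.warn(f"group {group!r} has no scalable neuron mass; skipped")
            continue
        factor = residual / mass
        block = out.densities.loc[scalable_rows, scalable_cols]
        free = ~out.fixed.loc[scalable_rows, scalable_cols]
        out.densities.loc[scalable_rows, scalable_cols] = block.where(~free, block * factor)

    # second pass: non-neuronal types share one multiplier so the all-cells
    # total (glia included) meets its target
    counts = out.cell_counts()
    neuron_total = float(counts[neuron_types].sum().sum())
    nn_c = counts[nn_types]
    nn_fixed = out.fixed[nn_types]
    nn_fixed_mass = float(nn_c.where(nn_fixed).sum().sum())
    nn_mass = float(nn_c.where(~nn_fixed).sum().sum())
    residual = cfg.all_cells_total - neuron_total - nn_fixed_mass
    if residual < 0:
        raise ScalingError("all-cells target below scaled neuron + fixed mass")
    if nn_mass > 0:
        factor = residual / nn_mass
        block = out.densities[nn_types]
        free = ~nn_fixed
        out.densities[nn_types] = block.where(~free, block * factor)
    elif residual > 0:
        warnings.warn("no scalable non-neuronal mass; all-cells target not reachable")
    out.provenance = atlas.provenance + "+global_scale"
    return out


@dataclass
class NisslVolume:
    """Nissl-like staining intensity volume aligned to the annotation."""

    grid: np.ndarray
    voxel_size_um: float

    def region_means(self, annotation: AnnotationVolume) -> pd.Series:
        ids = annotation.grid.ravel()
        vals = self.grid.ravel().astype(float)
        df = pd.DataFrame({"id": ids, "v": vals})
        means = df[df["id"] != 0].groupby("id")["v"].mean()
        means.index = means.index.astype(int)
        return means


def nissl_scale(
    atlas: DensityAtlas,
    nissl: NisslVolume,
    annotation: AnnotationVolume,
    anchor: str | int = "max",
    anchor_density: float | None = 4_000_000.0,
) -> DensityAtlas:
    """Scale per-region total densities proportionally to mean Nissl
    intensity, anchored at a reference region.

    ``anchor='max'`` pins the highest-mean-intensity region to
    ``anchor_density`` (default 4×10⁶ cells/mm³); ``anchor='min'`` pins the
    lowest-intensity region to its *current* total density (pass
    ``anchor_density=None``); an explicit region id pins that region.
    Within each region the relative cell type ratios determine the final
    type densities.
    """
    out = atlas.copy()
    means = nissl.region_means(annotation).reindex(out.densities.index)
    totals = out.densities.sum(axis=1, min_count=1)
    if anchor == "max":
        anchor_region = means.idxmax()
    elif anchor == "min":
        anchor_region = means.idxmin()
    else:
        anchor_region = anchor
    anchor_int = means[anchor_region]
    if not anchor_int or np.isnan(anchor_int):
        raise ScalingError(f"anchor region {anchor_region} has zero/NaN mean intensity")
    if anchor_density is None:
        anchor_density = totals[anchor_region]
        if not np.isfinite(anchor_density) or anchor_density <= 0:
            raise ScalingError(f"anchor region {anchor_region} has no current density")

    new_totals = anchor_density * means / anchor_int
    for rid in out.densities.index:
        cur = totals[rid]
        if np.isnan(new_totals[rid]):
            continue
        if not np.isfinite(cur) or cur <= 0:
            warnings.warn(f"region {rid} has no type ratios; Nissl total not applied")
            continue
        out.densities.loc[rid] *= new_totals[rid] / cur
    out.provenance = atlas.provenance + f"+nissl_{anchor}"
    return out


def nissl_granularity(
    vol3d: np.ndarray,
    nissl: NisslVolume,
    annotation: AnnotationVolume,
) -> np.ndarray:
    """Modulate a region-constant density volume voxel-wise by Nissl
    intensity normalized to the region mean.

    ``voxel <- region_density × intensity(voxel) / mean_intensity(region)``,
    so each region's mean density is conserved. Regions with zero mean
    intensity stay uniform.
    """
    if vol3d.shape != nissl.grid.shape or vol3d.shape != annotation.grid.shape:
        raise VoxAtlasError("volumes must share one grid")
    out = vol3d.astype(float).copy()
    ids = annotation.grid
    for rid in np.unique(ids[ids != 0]):
        mask = ids == rid
        mean_i = float(nissl.grid[mask].mean())
        if mean_i == 0:
            warnings.warn(f"region {rid} has zero mean Nissl intensity; left uniform")
            continue
        out[mask] = vol3d[mask] * (nissl.grid[mask] / mean_i)
    return out


def project_to_volume(
    atlas: DensityAtlas,
    annotation: AnnotationVolume,
    type_label: str | None = None,
    values: pd.Series | None = None,
) -> np.ndarray:
    """Paint per-region values into the annotation grid.

    Every voxel of region *r* receives the region's density of
    ``type_label`` (or an arbitrary per-region ``values`` series). N/A and
    out-of-brain voxels are NaN — distinguishable from true zeros.
    """
    if values is None:
        values = atlas.densities[type_label]
    uniq, inv = np.unique(annotation.grid, return_inverse=True)
    lut = values.reindex(uniq).to_numpy(dtype=float)
    lut[uniq == 0] = np.nan
    missing = int(((~np.isin(uniq, values.index)) & (uniq != 0)).sum())
    if missing:
        warnings.warn(f"{missing} annotation ids missing from atlas; painted NaN")
    return lut[inv].reshape(annotation.grid.shape)


def aggregate_types(
    atlas: DensityAtlas, taxonomy: pd.DataFrame, level: str
) -> DensityAtlas:
    """Sum type densities up a taxonomy level (class/subclass/...).

    The result is N/A only where *all* member types are N/A, so additivity
    holds across levels.
    """
    mapping = taxonomy[level].reindex(atlas.densities.columns)
    if mapping.isna().any():
        raise VoxAtlasError(
            f"unmapped type labels: {list(mapping[mapping.isna()].index)}"
        )
    dens = atlas.densities.T.groupby(mapping).sum(min_count=1).T
    counts = atlas.counts.T.groupby(mapping).sum(min_count=1).T
    return DensityAtlas(
        densities=dens,
        counts=counts,
        region_volumes=None if atlas.region_volumes is None else atlas.region_volumes.copy(),
        provenance=atlas.provenance + f"+agg:{level}",
    )
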