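"""Hierarchical brain-region ontology and annotation volumes.

The region ontology is a tree in the Allen structure-graph dialect: every
node carries an integer id, an acronym, a name and a parent id; *leaf
regions* are the deepest nodes and every annotated voxel must resolve to
exactly one of them. The module loads/saves the tree, extends it with new
leaf layers (cerebellar granular/molecular/Purkinje layers, the olfactory
glomerular layer), applies the layer-splitting rules to cell tables, and
computes per-slice region volumes from an annotation volume.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import GeometryError, OntologyError

__all__ = [
    "RegionNode",
    "RegionHierarchy",
    "AnnotationVolume",
    "load_hierarchy",
    "extend_hierarchy",
    "region_volumes_per_slice",
    "split_cell_rules",
    "inherit_white_matter",
    "DEFAULT_SPLIT_RULES",
]


@dataclass
class RegionNode:
    """One region of the ontology tree."""

    region_id: int
    acronym: str
    name: str
    parent_id: int | None
    children: list[int] = field(default_factory=list)
    hierarchy_level: int = 0

    @property
    def is_leaf(self) -> bool:
        return not self.children


class RegionHierarchy:
    """Validated tree of :class:`RegionNode` keyed by region id.

    Exactly one root (``parent_id is None``), no cycles; every referenced
    parent must exist. Constructed via :func:`load_hierarchy`,
    :meth:`from_nodes` or :meth:`from_json_dict`.
    """

    def __init__(self, nodes: dict[int, RegionNode]):
        self.nodes = nodes
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_nodes(cls, nodes: list[RegionNode]) -> "RegionHierarchy":
        seen: dict[int, RegionNode] = {}
        for n in nodes:
            if n.region_id in seen:
                raise OntologyError(f"duplicate region id {n.region_id}")
            seen[n.region_id] = n
        return cls(seen)

    @classmethod
    def from_json_dict(cls, obj: dict | list) -> "RegionHierarchy":
        """Parse Allen-style structure-graph JSON (nested or ``msg`` list)."""
        if isinstance(obj, dict) and "msg" in obj:
            roots = obj["msg"]
        elif isinstance(obj, dict):
            roots = [obj]
        else:
            roots = obj
        nodes: dict[int, RegionNode] = {}

        def walk(rec: dict, parent_id: int | None, level: int) -> None:
            rid = int(rec["id"])
            if rid in nodes:
                raise OntologyError(f"duplicate region id {rid}")
            nodes[rid] = RegionNode(
                region_id=rid,
                acronym=str(rec.get("acronym", str(rid))),
                name=str(rec.get("name", str(rid))),
                parent_id=parent_id,
                children=[],
                hierarchy_level=level,
            )
            if parent_id is not None:
                nodes[parent_id].children.append(rid)
            for child in rec.get("children", []) or []:
                walk(child, rid, level + 1)

        for root in roots:
            parent = root.get("parent_structure_id")
            walk(root, int(parent) if parent is not None else None, 0)
        # flat lists reference parents by parent_structure_id; wire them up
        for rid, node in nodes.items():
            if node.parent_id is not None and rid not in nodes[node.parent_id].children:
                nodes[node.parent_id].children.append(rid)
        return cls(nodes)

    def _validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise OntologyError(f"expected exactly one root, found {len(roots)}")
        for node in self.nodes.values():
            if node.parent_id is not None and node.parent_id not in self.nodes:
                raise OntologyError(
                    f"orphan: region {node.region_id} references missing parent "
                    f"{node.parent_id}"
                )
        # cycle check by walking to root from every node
        for node in self.nodes.values():
            seen = set()
            cur: int | None = node.region_id
            while cur is not None:
                if cur in seen:
                    raise OntologyError(f"cycle through region {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent_id
        self._recompute_levels()

    def _recompute_levels(self) -> None:
        def level(rid: int) -> int:
            n = self.nodes[rid]
            return 0 if n.parent_id is None else 1 + level(n.parent_id)

        for rid in self.nodes:
            self.nodes[rid].hierarchy_level = level(rid)

    # -- queries -----------------------------------------------------------

    @property
    def root(self) -> RegionNode:
        return next(n for n in self.nodes.values() if n.parent_id is None)

    @property
    def leaves(self) -> list[int]:
        return [rid for rid, n in self.nodes.items() if n.is_leaf]

    def descendants(self, rid: int) -> list[int]:
        out: list[int] = []
        stack = list(self.nodes[rid].children)
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(self.nodes[cur].children)
        return out

    def leaves_under(self, rid: int) -> list[int]:
        node = self.nodes[rid]
        if node.is_leaf:
            return [rid]
        return [d for d in self.descendants(rid) if self.nodes[d].is_leaf]

    def ancestors(self, rid: int) -> list[int]:
        out = []
        cur = self.nodes[rid].parent_id
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent_id
        return out

    def find_by_acronym(self, acronym: str) -> RegionNode:
        for n in self.nodes.values():
            if n.acronym == acronym:
                return n
        raise OntologyError(f"no region with acronym {acronym!r}")

    def resolve(self, key: int | str) -> RegionNode:
        if isinstance(key, str) and not key.isdigit():
            return self.find_by_acronym(key)
        return self.nodes[int(key)]

    def group_of(self, rid: int, group_acronyms: dict[str, str]) -> str:
        """Assign a region to a named group by ancestor acronym, else 'rest'."""
        lineage = {self.nodes[a].acronym for a in [rid] + self.ancestors(rid)}
        for group, acr in group_acronyms.items():
            if acr in lineage:
                return group
        return "rest"

    # -- serialization -----------------------------------------------------

    def to_json_dict(self) -> dict:
        def emit(rid: int) -> dict:
            n = self.nodes[rid]
            return {
                "id": n.region_id,
                "acronym": n.acronym,
                "name": n.name,
                "parent_structure_id": n.parent_id,
                "children": [emit(c) for c in n.children],
            }

        return {"msg": [emit(self.root.region_id)]}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    def copy(self) -> "RegionHierarchy":
        return RegionHierarchy(copy.deepcopy(self.nodes))


def load_hierarchy(path: str | Path) -> RegionHierarchy:
    """Load an ontology JSON file (Allen structure-graph dialect)."""
    return RegionHierarchy.from_json_dict(json.loads(Path(path).read_text()))


@dataclass
class AnnotationVolume:
    """3D grid of region ids. 0 marks voxels outside the brain.

    Voxel indices are 0-based; world coordinates are voxel centers in µm
    with axis order x = anterior->posterior (coronal axis), y = dorsal->
    ventral, z = left->right, recorded in ``metadata``.
    """

    grid: np.ndarray
    voxel_size_um: float
    metadata: dict = field(default_factory=lambda: {"axes": "xyz", "origin": "voxel-center"})

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um * 1e-3) ** 3

    def region_voxel_counts(self) -> pd.Series:
        ids, counts = np.unique(self.grid[self.grid != 0], return_counts=True)
        return pd.Series(counts, index=ids.astype(int), name="voxel_count")

    def region_volumes(self) -> pd.Series:
        s = self.region_voxel_counts() * self.voxel_volume_mm3
        s.name = "volume_mm3"
        return s

    def validate_against(self, hierarchy: RegionHierarchy) -> None:
        ids = set(np.unique(self.grid)) - {0}
        unknown = ids - set(hierarchy.nodes)
        if unknown:
            raise OntologyError(f"annotation ids missing from hierarchy: {sorted(unknown)[:10]}")


# ---------------------------------------------------------------------------
# hierarchy extension


def extend_hierarchy(
    hierarchy: RegionHierarchy,
    rules: list[dict],
) -> RegionHierarchy:
    """Append new leaf children under named parent regions.

    Each rule is ``{"parent": acronym-or-id, "leaves": [name, ...]}``. New
    ids are allocated above the current maximum so original ids are
    untouched. Typical use: adding granular/molecular/Purkinje layers under
    every cerebellar lobule and a glomerular layer under the olfactory bulb.
    """
    h = hierarchy.copy()
    next_id = max(h.nodes) + 1
    for rule in rules:
        parent = h.resolve(rule["parent"])
        for leaf_name in rule["leaves"]:
            acr = rule.get("acronym_prefix", parent.acronym) + "-" + leaf_name[:4].lower()
            h.nodes[next_id] = RegionNode(
                region_id=next_id,
                acronym=acr,
                name=f"{parent.name}, {leaf_name}",
                parent_id=parent.region_id,
                children=[],
                hierarchy_level=parent.hierarchy_level + 1,
            )
            h.nodes[parent.region_id].children.append(next_id)
            next_id += 1
    h._recompute_levels()
    return h


# ---------------------------------------------------------------------------
# per-slice region volumes


def region_volumes_per_slice(
    annotation: AnnotationVolume,
    slices: list,
    pixel_size_um: float | None = None,
) -> pd.DataFrame:
    """Voxelized region size per slice times section thickness.

    For each slice geometry the annotation is resampled in the cutting
    plane (nearest neighbor); the sampled volume of region *r* in slice *s*
    is ``pixel_count × pixel_area × thickness``. Returns a table with
    columns region_id, slice_id, voxel_count, volume_mm3.
    """
    from .registration import resample_plane  # local import avoids a cycle

    pixel_size_um = pixel_size_um or annotation.voxel_size_um
    rows = []
    for sid, geom in enumerate(slices):
        try:
            plane = resample_plane(annotation, geom, pixel_size_um, kind="labels")
        except GeometryError:
            warnings.warn(f"slice {sid} entirely outside volume; no rows emitted")
            continue
        ids, counts = np.unique(plane.grid[plane.grid != 0], return_counts=True)
        area_mm2 = (pixel_size_um * 1e-3) ** 2
        thick_mm = geom.thickness_um * 1e-3
        for rid, cnt in zip(ids.astype(int), counts):
            rows.append(
                {
                    "region_id": rid,
                    "slice_id": sid,
                    "voxel_count": int(cnt),
                    "volume_mm3": float(cnt) * area_mm2 * thick_mm,
                }
            )
    return pd.DataFrame(rows, columns=["region_id", "slice_id", "voxel_count", "volume_mm3"])


# ---------------------------------------------------------------------------
# layer-splitting rules

# The rule table is data, not code: it can be serialized to YAML and edited.
# Each block applies to parents whose name contains `match_parent`
# (case-insensitive); `layers` names the child leaves (matched by substring
# against child names); `assign` is an ordered list of predicates, first
# match wins. `split: equal` shares the matched cells equally among the
# listed layers (seeded shuffle + round-robin).
DEFAULT_SPLIT_RULES: dict = {
    "cerebellar_cortex": {
        "match_parent": "lobule",
        "layers": ["Purkinje", "molecular", "granular"],
        "assign": [
            {"where": {"t_type_contains": "Purkinje"}, "to": ["Purkinje"]},
            {"where": {"t_type_contains": "Bergmann"}, "to": ["Purkinje"]},
            {
                "where": {"t_type_contains": "Microglia"},
                "to": ["Purkinje", "molecular", "granular"],
                "split": "equal",
            },
            {"where": {"class_is": "Glut"}, "to": ["granular"]},
            {"where": {"class_is": "GABA", "t_type_contains": "Golgi"}, "to": ["granular"]},
            {"where": {"class_is": "GABA"}, "to": ["molecular"]},
            {"where": {}, "to": ["granular"]},
        ],
    },
    "olfactory_bulb": {
        "match_parent": "olfactory bulb",
        "layers": ["glomerular"],
        "assign": [{"where": {}, "to": ["glomerular"]}],
    },
}


def load_split_rules(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def save_split_rules(rules: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(rules))


def _match(cell: pd.Series, where: dict) -> bool:
    for key, val in where.items():
        if key == "class_is":
            if str(cell.get("class", "")) != val:
                return False
        elif key == "t_type_contains":
            hay = f"{cell.get('t_type', '')} {cell.get('subclass', '')}"
            if val.lower() not in hay.lower():
                return False
        else:
            raise OntologyError(f"unknown predicate {key!r} in split rules")
    return True


def split_cell_rules(
    region_id: int,
    cells: pd.DataFrame,
    hierarchy: RegionHierarchy,
    rules: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Reassign cells of a split parent region to its child leaf layers.

    Cerebellar lobules: the Purkinje layer gets all Purkinje cells and all
    Bergmann glia plus an equal share of microglia; molecular layers are
    purely inhibitory (no Purkinje/Bergmann/Glut); granular layers get every
    remaining type, with Golgi the only GABA type. The olfactory-bulb
    glomerular layer inherits all cells of the unassigned parent. Cells no
    rule can place are flagged ``unassigned`` and keep the parent id.
    """
    rules = rules if rules is not None else DEFAULT_SPLIT_RULES
    parent = hierarchy.nodes[region_id]
    block = None
    for blk in rules.values():
        if blk["match_parent"].lower() in parent.name.lower():
            block = blk
            break
    if block is None:
        raise OntologyError(f"region {region_id} ({parent.name!r}) matches no split rule")

    layer_ids: dict[str, int] = {}
    for layer in block["layers"]:
        hits = [
            c for c in parent.children if layer.lower() in hierarchy.nodes[c].name.lower()
        ]
        if len(hits) != 1:
            raise OntologyError(
                f"parent {region_id} has {len(hits)} children matching layer {layer!r}"
            )
        layer_ids[layer] = hits[0]

    out = cells.copy()
    out["unassigned"] = False
    if out.empty:
        return out
    rng = np.random.default_rng(seed)
    assigned = pd.Series(pd.NA, index=out.index, dtype="object")
    claimed = pd.Series(False, index=out.index)
    for rule in block["assign"]:
        mask = out.apply(lambda c: _match(c, rule["where"]), axis=1) & ~claimed
        idx = out.index[mask]
        if len(idx) == 0:
            continue
        targets = rule["to"]
        if rule.get("split") == "equal" and len(targets) > 1:
            order = rng.permutation(len(idx))
            for pos, i in enumerate(order):
                assigned[idx[i]] = targets[pos % len(targets)]
        else:
            assigned[idx] = targets[0]
        claimed[idx] = True
    unmatched = assigned.isna()
    if unmatched.any():
        warnings.warn(f"{int(unmatched.sum())} cells matched no split rule; flagged unassigned")
        out.loc[unmatched, "unassigned"] = True
    out.loc[~unmatched, "region_id"] = assigned[~unmatched].map(layer_ids).astype(int)
    return out


def inherit_white_matter(atlas, hierarchy: RegionHierarchy, wm_parents: list) -> "object":
    """Copy each white-matter parent's density row to all its leaf regions.

    White-matter substructures annotated only at the parent level are
    treated as homogeneous: leaves inherit the parent row verbatim (N/A
    stays N/A, zero stays zero).
    """
    out = atlas.copy()
    for key in wm_parents:
        parent = hierarchy.resolve(key)
        if parent.is_leaf:
            raise OntologyError(f"white-matter parent {key!r} has no children")
        if parent.region_id not in out.densities.index:
            continue
        row_d = out.densities.loc[parent.region_id]
        row_c = out.counts.loc[parent.region_id] if parent.region_id in out.counts.index else None
        for leaf in hierarchy.leaves_under(parent.region_id):
            out.densities.loc[leaf] = row_d
            if row_c is not None:
                out.counts.loc[leaf] = row_c
    return out
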