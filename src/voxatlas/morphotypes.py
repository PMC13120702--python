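"""Topological morphology descriptors and m-type assignment.

A neuronal tree is summarized by its persistence barcode under the radial
filtration: each branch contributes a bar whose *birth* is the largest
radial distance (from the soma center) the branch reaches and whose
*death* is the radial distance of the branch point where it merges into an
older branch (elder rule: at a merge, the component with the larger birth
survives). The surviving root component dies at the soma (distance 0), so
the number of bars equals the number of leaves. Barcodes are rasterized
into persistence images (sums of isotropic Gaussians on a (birth, death)
grid) and vectorized for K-means clustering — one clustering of dendritic
images and one of axonal images, run separately for pyramidal cells (PC)
and interneurons (IN). An m-type is the composite label
``{class}_DEND_{d}_AX_{a}``; with 2 classes and 10×10 clusters this
schema spans 200 potential m-types.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .errors import VoxAtlasError

__all__ = [
    "NeuronTree",
    "PersistenceBarcode",
    "PersistenceImage",
    "MTypeLabel",
    "load_swc",
    "tmd_barcode",
    "persistence_image",
    "barcode_bounds",
    "MTypeModel",
    "cluster_mtypes",
]

SOMA, AXON, BASAL, APICAL = 1, 2, 3, 4
NEURITE_KINDS = {"axon": {AXON}, "dendrite": {BASAL, APICAL}}


@dataclass
class NeuronTree:
    """Flat SWC-style morphology: parallel arrays over sample points."""

    ids: np.ndarray
    types: np.ndarray
    xyz: np.ndarray  # (n, 3) in µm
    radius: np.ndarray
    parents: np.ndarray  # parent sample id, -1 for roots

    @property
    def soma_center(self) -> np.ndarray:
        mask = self.types == SOMA
        if not mask.any():  # no soma samples: fall back to first point
            return self.xyz[0]
        return self.xyz[mask].mean(axis=0)


def load_swc(path: str | Path) -> NeuronTree:
    """Read a standard 7-column SWC file."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise VoxAtlasError(f"malformed SWC line: {line!r}")
        rows.append([float(p) for p in parts])
    arr = np.asarray(rows)
    if arr.size == 0:
        raise VoxAtlasError(f"empty SWC file: {path}")
    return NeuronTree(
        ids=arr[:, 0].astype(int),
        types=arr[:, 1].astype(int),
        xyz=arr[:, 2:5],
        radius=arr[:, 5],
        parents=arr[:, 6].astype(int),
    )


def save_swc(tree: NeuronTree, path: str | Path) -> None:
    lines = []
    for i in range(len(tree.ids)):
        x, y, z = tree.xyz[i]
        lines.append(
            f"{tree.ids[i]} {tree.types[i]} {x:.3f} {y:.3f} {z:.3f} "
            f"{tree.radius[i]:.3f} {tree.parents[i]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PersistenceBarcode:
    """Multiset of (birth, death) radial distances for one neurite kind."""

    bars: np.ndarray  # (n, 2)
    neurite_kind: str

    def __post_init__(self):
        self.bars = np.asarray(self.bars, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.bars)


def tmd_barcode(tree: NeuronTree, kind: str) -> PersistenceBarcode:
    """Elder-rule persistence barcode of one neurite kind.

    Leaves are born at their radial distance from the soma center; at each
    branch point the component with the larger birth survives and the
    others die at the branch point's radial distance; each neurite's root
    component dies at the soma (0). One bar per leaf.
    """
    if kind not in NEURITE_KINDS:
        raise VoxAtlasError(f"unknown neurite kind {kind!r}")
    wanted = NEURITE_KINDS[kind]
    soma = tree.soma_center
    id_to_idx = {int(i): k for k, i in enumerate(tree.ids)}
    in_kind = np.isin(tree.types, list(wanted))
    radial = np.linalg.norm(tree.xyz - soma, axis=1)

    children: dict[int, list[int]] = {}
    roots: list[int] = []
    for k in np.flatnonzero(in_kind):
        p = int(tree.parents[k])
        pi = id_to_idx.get(p, -1)
        if pi >= 0 and in_kind[pi]:
            children.setdefault(pi, []).append(k)
        else:
            roots.append(k)
    if not roots:
        warnings.warn(f"tree has no {kind} neurite; empty barcode")
        return PersistenceBarcode(np.empty((0, 2)), kind)

    bars: list[tuple[float, float]] = []
    for root in roots:
        # iterative post-order: value of a node = birth of the surviving
        # component among its children (or its own radial distance at a leaf)
        value: dict[int, float] = {}
        stack = [(root, False)]
        while stack:
            node, done = stack.pop()
            kids = children.get(node, [])
            if not done:
                stack.append((node, True))
                stack.extend((c, False) for c in kids)
                continue
            if not kids:
                value[node] = radial[node]
                continue
            vals = sorted((value[c] for c in kids), reverse=True)
            d = radial[node]
            for v in vals[1:]:
                bars.append((v, d))
            value[node] = vals[0]
        bars.append((value[root], 0.0))
    return PersistenceBarcode(np.asarray(bars), kind)


@dataclass
class PersistenceImage:
    grid: np.ndarray
    bounds: tuple  # (birth_min, birth_max, death_min, death_max)
    sigma: float

    def vector(self) -> np.ndarray:
        return self.grid.ravel()


def barcode_bounds(barcodes: list[PersistenceBarcode], margin: float = 0.05) -> tuple:
    """Global (birth, death) bounds over a training set, with a margin."""
    pts = np.vstack([b.bars for b in barcodes if len(b)] or [np.zeros((1, 2))])
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    lo = lo - margin * span
    hi = hi + margin * span
    return (float(lo[0]), float(hi[0]), float(lo[1]), float(hi[1]))


def persistence_image(
    barcode: PersistenceBarcode,
    resolution: int = 100,
    sigma: float | None = None,
    bounds: tuple | None = None,
) -> PersistenceImage:
    """Rasterize a barcode as a sum of isotropic Gaussians.

    Each bar contributes a unit-mass Gaussian (so the unnormalized image
    sums to the bar count up to grid truncation). ``sigma`` defaults to
    1/20 of the larger bound span. An empty barcode yields a zero image.
    """
    if resolution < 4:
        raise VoxAtlasError("resolution must be >= 4")
    if bounds is None:
        bounds = barcode_bounds([barcode])
    b0, b1, d0, d1 = bounds
    if sigma is None:
        sigma = max(b1 - b0, d1 - d0) / 20.0
    if sigma <= 0:
        raise VoxAtlasError("sigma must be positive")
    bx = np.linspace(b0, b1, resolution)
    dy = np.linspace(d0, d1, resolution)
    grid = np.zeros((resolution, resolution))
    if len(barcode):
        X, Y = np.meshgrid(bx, dy, indexing="ij")
        pix = (bx[1] - bx[0]) * (dy[1] - dy[0])
        for birth, death in barcode.bars:
            grid += (
                np.exp(-((X - birth) ** 2 + (Y - death) ** 2) / (2 * sigma**2))
                / (2 * np.pi * sigma**2)
                * pix
            )
    return PersistenceImage(grid=grid, bounds=bounds, sigma=float(sigma))


@dataclass(frozen=True)
class MTypeLabel:
    neuron_class: str  # "PC" or "IN"
    dendritic_cluster: int
    axonal_cluster: int

    def __str__(self) -> str:
        return f"{self.neuron_class}_DEND_{self.dendritic_cluster}_AX_{self.axonal_cluster}"


@dataclass
class MTypeModel:
    """Persisted K-means centroids: (class, stream) -> centroid matrix."""

    centroids: dict = field(default_factory=dict)
    k_dend: int = 10
    k_ax: int = 10

    def n_potential_labels(self) -> int:
        classes = {c for c, _ in self.centroids} or {"PC", "IN"}
        return len(classes) * self.k_dend * self.k_ax

    def assign_one(self, neuron_class: str, dend_vec: np.ndarray, ax_vec: np.ndarray) -> MTypeLabel:
        d = self._nearest(neuron_class, "dend", dend_vec)
        a = self._nearest(neuron_class, "ax", ax_vec)
        return MTypeLabel(neuron_class, d, a)

    def _nearest(self, neuron_class: str, stream: str, vec: np.ndarray) -> int:
        cents = self.centroids[(neuron_class, stream)]
        dist = np.linalg.norm(cents - vec[None, :], axis=1)
        return int(np.argmin(dist))  # argmin takes the lowest index on ties

    def save(self, path: str | Path) -> None:
        obj = {
            "k_dend": self.k_dend,
            "k_ax": self.k_ax,
            "centroids": {
                f"{c}:{s}": m.tolist() for (c, s), m in self.centroids.items()
            },
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def load(cls, path: str | Path) -> "MTypeModel":
        obj = json.loads(Path(path).read_text())
        cents = {
            tuple(k.split(":")): np.asarray(v) for k, v in obj["centroids"].items()
        }
        return cls(centroids=cents, k_dend=obj["k_dend"], k_ax=obj["k_ax"])


def cluster_mtypes(
    images: list[tuple],
    class_labels: dict,
    k_dend: int = 10,
    k_ax: int = 10,
    seed: int = 0,
) -> tuple[dict, MTypeModel]:
    """Assign m-types by K-means on vectorized persistence images.

    ``images`` is a list of ``(cell_id, dendritic PersistenceImage-or-
    vector, axonal ...)``; ``class_labels`` maps cell_id -> "PC"/"IN".
    Pyramidal cells and interneurons are clustered independently, and the
    dendritic and axonal streams independently within each class
    (k-means++, 10 restarts, seeded). Returns cell_id -> MTypeLabel and
    the fitted model for assigning new morphologies by nearest centroid.
    """

    def vec(img):
        return img.vector() if isinstance(img, PersistenceImage) else np.asarray(img).ravel()

    labels: dict = {}
    model = MTypeModel(k_dend=k_dend, k_ax=k_ax)
    by_class: dict[str, list] = {}
    for cell_id, dimg, aimg in images:
        by_class.setdefault(class_labels[cell_id], []).append((cell_id, vec(dimg), vec(aimg)))
    for cls, rows in sorted(by_class.items()):
        for stream, k, col in (("dend", k_dend, 1), ("ax", k_ax, 2)):
            mat = np.vstack([r[col] for r in rows])
            if len(rows) < k:
                raise VoxAtlasError(
                    f"class {cls}: {len(rows)} cells < k={k}; use a smaller k"
                )
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(mat)
            model.centroids[(cls, stream)] = km.cluster_centers_
        for cell_id, dvec, avec in rows:
            labels[cell_id] = model.assign_one(cls, dvec, avec)
    return labels, model
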