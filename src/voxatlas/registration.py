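"""Slice-to-volume registration by normalized mutual information.

Coronal sections are cut at a tilt: an *axial* angle (rotation of the
cutting-plane normal about the dorsoventral y-axis, i.e. a horizontal
tilt) and a *vertical* angle (rotation about the left-right z-axis). The
cutting position is the distance of the plane from the volume origin along
the coronal x-axis, in µm. Registration resamples a 3D template along a
candidate plane and scores it against the 2D section with NMI
(``2·I(A;B)/(H(A)+H(B))``, bounded in [0, 1]); the geometry is recovered
by exhaustive grid search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .ontology import AnnotationVolume

__all__ = [
    "SliceGeometry",
    "Slice2D",
    "nmi",
    "plane_points",
    "resample_plane",
    "estimate_slice_geometry",
    "default_search_grid",
]


@dataclass(frozen=True)
class SliceGeometry:
    """Cutting plane of one section."""

    axial_angle_deg: float = 0.0
    vertical_angle_deg: float = 0.0
    coronal_position_um: float = 0.0
    thickness_um: float = 10.0

    def __post_init__(self):
        if self.thickness_um <= 0:
            raise GeometryError("thickness_um must be positive")
        for a in (self.axial_angle_deg, self.vertical_angle_deg):
            if not -90.0 < a < 90.0:
                raise GeometryError("angles must lie in (-90, 90) degrees")


@dataclass
class Slice2D:
    """2D section sampled from a volume (region ids or intensities)."""

    grid: np.ndarray
    pixel_size_um: float
    geometry: SliceGeometry = field(default_factory=SliceGeometry)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi(a: Slice2D | np.ndarray, b: Slice2D | np.ndarray, n_bins: int = 64) -> float:
    """Normalized mutual information ``2 I(A;B) / (H(A) + H(B))``.

    Symmetric and in [0, 1]; equals 1 for identical non-constant images.
    A constant image carries zero entropy; by convention the score is 0
    then (with a warning). Histogramming uses ``n_bins`` equal-width bins
    per image over each image's own range.
    """
    ga = a.grid if isinstance(a, Slice2D) else np.asarray(a)
    gb = b.grid if isinstance(b, Slice2D) else np.asarray(b)
    if ga.shape != gb.shape:
        raise GeometryError(f"image shapes differ: {ga.shape} vs {gb.shape}")
    if n_bins < 2:
        raise GeometryError("n_bins must be >= 2")
    ga = ga.ravel().astype(float)
    gb = gb.ravel().astype(float)
    joint, _, _ = np.histogram2d(ga, gb, bins=n_bins)
    pj = joint / joint.sum()
    ha = _entropy(pj.sum(axis=1))
    hb = _entropy(pj.sum(axis=0))
    if ha == 0.0 or hb == 0.0:
        warnings.warn("constant image has zero entropy; NMI set to 0")
        return 0.0
    hj = _entropy(pj.ravel())
    mi = ha + hb - hj
    return float(2.0 * mi / (ha + hb))


def _plane_basis(geometry: SliceGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotated orthonormal frame: normal plus two in-plane axes."""
    a = np.deg2rad(geometry.axial_angle_deg)
    v = np.deg2rad(geometry.vertical_angle_deg)
    ry = np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]])
    rz = np.array([[np.cos(v), -np.sin(v), 0], [np.sin(v), np.cos(v), 0], [0, 0, 1]])
    rot = ry @ rz
    return rot[:, 0], rot[:, 1], rot[:, 2]  # normal, in-plane u, in-plane w


def plane_points(
    volume: AnnotationVolume, geometry: SliceGeometry, pixel_size_um: float | None = None
) -> np.ndarray:
    """Voxel-space coordinates (3, h, w) of the cutting-plane pixel centers."""
    pixel_size_um = pixel_size_um or volume.voxel_size_um
    nx, ny, nz = volume.grid.shape
    s = pixel_size_um / volume.voxel_size_um
    h = int(round(ny / s))
    w = int(round(nz / s))
    _, u, wv = _plane_basis(geometry)
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    center = np.array([geometry.coronal_position_um / volume.voxel_size_um, cy, cz])
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    di = (ii - (h - 1) / 2.0) * s
    dj = (jj - (w - 1) / 2.0) * s
    return (
        center[:, None, None]
        + u[:, None, None] * di[None]
        + wv[:, None, None] * dj[None]
    )


def resample_plane(
    volume: AnnotationVolume,
    geometry: SliceGeometry,
    pixel_size_um: float | None = None,
    kind: str = "auto",
) -> Slice2D:
    """Sample a volume along a tilted cutting plane.

    Label volumes use nearest-neighbor sampling (region ids cannot be
    averaged), intensity volumes trilinear. ``kind='auto'`` picks by dtype.
    Pixels falling outside the volume are 0. The output grid spans the
    volume's y-z extent; at zero angles and a position on a voxel plane the
    result is exactly the corresponding array slice.
    """
    pixel_size_um = pixel_size_um or volume.voxel_size_um
    if kind == "auto":
        kind = "labels" if np.issubdtype(volume.grid.dtype, np.integer) else "intensity"
    order = 0 if kind == "labels" else 1
    nx, ny, nz = volume.grid.shape
    pts = plane_points(volume, geometry, pixel_size_um)
    inside = (
        (pts[0] > -0.5) & (pts[0] < nx - 0.5)
        & (pts[1] > -0.5) & (pts[1] < ny - 0.5)
        & (pts[2] > -0.5) & (pts[2] < nz - 0.5)
    )
    if not inside.any():
        raise GeometryError("cutting plane does not intersect the volume")
    grid = ndimage.map_coordinates(
        volume.grid.astype(float) if order else volume.grid,
        pts,
        order=order,
        mode="constant",
        cval=0,
        prefilter=False,
    )
    if kind == "labels":
        grid = grid.astype(volume.grid.dtype)
    return Slice2D(grid=grid, pixel_size_um=pixel_size_um, geometry=geometry)


def default_search_grid(volume: AnnotationVolume) -> dict:
    """Exhaustive default search: axial ±45° step 0.5°, vertical ±10° step
    0.25°, positions at every voxel plane."""
    nx = volume.grid.shape[0]
    return {
        "axial_deg": np.arange(-45.0, 45.0 + 1e-9, 0.5),
        "vertical_deg": np.arange(-10.0, 10.0 + 1e-9, 0.25),
        "position_um": np.arange(nx) * volume.voxel_size_um,
    }


def estimate_slice_geometry(
    section: Slice2D,
    template: AnnotationVolume,
    search: dict,
    n_bins: int = 64,
    thickness_um: float = 10.0,
) -> tuple[SliceGeometry, float]:
    """Recover cutting angles and position by maximizing NMI over a grid.

    Candidates are visited in tie-break order — smallest
    (|axial|, |vertical|, position) lexicographically — so the first
    maximum wins ties. Returns the best geometry and its NMI score.
    """
    axial = np.atleast_1d(np.asarray(search["axial_deg"], dtype=float))
    vertical = np.atleast_1d(np.asarray(search["vertical_deg"], dtype=float))
    positions = np.atleast_1d(np.asarray(search["position_um"], dtype=float))
    if axial.size == 0 or vertical.size == 0 or positions.size == 0:
        raise GeometryError("empty search grid")

    if np.ptp(section.grid) == 0:
        warnings.warn("section is constant; registration score will be 0")

    candidates = sorted(
        ((a, v, p) for a in axial for v in vertical for p in positions),
        key=lambda t: (abs(t[0]), abs(t[1]), t[2]),
    )
    best: tuple[SliceGeometry, float] | None = None
    for a, v, p in candidates:
        geom = SliceGeometry(a, v, p, thickness_um)
        try:
            resampled = resample_plane(template, geom, section.pixel_size_um, kind="intensity")
        except GeometryError:
            continue
        if resampled.grid.shape != section.grid.shape:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            score = nmi(section.grid, resampled.grid, n_bins)
        if best is None or score > best[1] + 1e-12:
            best = (geom, score)
    if best is None:
        raise GeometryError("no candidate plane intersects the template")
    return best
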