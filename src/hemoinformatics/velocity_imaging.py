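"""Velocity field to 3D image-like data (magnitude + direction).

The single-time-point (peak systole) velocity field inside the aneurysm sac
is resampled from its unstructured mesh onto a uniform voxel grid; the
voxel speed is 5-95% percentile-normalized into the MVelocity image, and
the voxel direction is quantized against an equal-area sphere partition
into the DVelocity image whose integer gray level encodes alignment with
the downstream flow axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError, cKDTree

from .io_formats import UnstructuredVectorField
from .sphere_partition import SpherePartition, assign_direction

__all__ = [
    "VectorImage",
    "ScalarImage",
    "resample_to_grid",
    "magnitude_image",
    "direction_image",
]


@dataclass
class VectorImage:
    """3-component field on a uniform grid (array shape (*grid, 3))."""

    array: np.ndarray
    spacing: np.ndarray  # mm per axis (array-index order)
    origin: np.ndarray  # mm, position of voxel (0,...,0) centre
    mask: np.ndarray  # bool, grid shape

    def __post_init__(self):
        self.array = np.asarray(self.array, dtype=float)
        self.spacing = np.atleast_1d(np.asarray(self.spacing, dtype=float))
        self.origin = np.atleast_1d(np.asarray(self.origin, dtype=float))
        self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")


@dataclass
class ScalarImage:
    """Scalar (or integer-label) image on a uniform grid with a mask."""

    array: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.array = np.asarray(self.array)
        self.spacing = np.atleast_1d(np.asarray(self.spacing, dtype=float))
        self.origin = np.atleast_1d(np.asarray(self.origin, dtype=float))
        self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if np.issubdtype(self.array.dtype, np.floating) and self.mask.any():
            if not np.all(np.isfinite(np.asarray(self.array)[self.mask])):
                raise ValueError("masked values must be finite")

    @property
    def ndim(self) -> int:
        return self.mask.ndim

    def masked_values(self) -> np.ndarray:
        return np.asarray(self.array)[self.mask]


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def _tet_interpolate(points, cells, values, query):
    """Barycentric-linear interpolation on a given tetrahedral mesh.

    Returns (values_at_query, inside_mask).  Voxels are located by testing
    candidate tetrahedra found through a KD-tree on tet centroids.
    """
    pts = np.asarray(points, float)
    tets = np.asarray(cells, np.int64)
    vals = np.asarray(values, float)
    q = np.asarray(query, float)

    verts = pts[tets]  # (m, 4, 3)
    centroids = verts.mean(axis=1)
    radii = np.linalg.norm(verts - centroids[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(centroids)
    r_query = radii.max() * 1.0000001

    out = np.full((len(q), vals.shape[1] if vals.ndim > 1 else 1), np.nan)
    inside = np.zeros(len(q), dtype=bool)
    # affine maps for barycentric coordinates, precomputed per tet
    T = np.transpose(verts[:, 1:, :] - verts[:, :1, :], (0, 2, 1))  # (m, 3, 3)
    Tinv = np.linalg.inv(T)

    neighbours = tree.query_ball_point(q, r_query)
    for qi, cand in enumerate(neighbours):
        for ti in cand:
            b = Tinv[ti] @ (q[qi] - verts[ti, 0])
            if b.min() >= -1e-10 and b.sum() <= 1 + 1e-10:
                w = np.concatenate(([1.0 - b.sum()], b))
                out[qi] = w @ vals[tets[ti]]
                inside[qi] = True
                break
    return out, inside


def resample_to_grid(
    field: UnstructuredVectorField,
    spacing: float | None = None,
    target_resolution: int = 64,
    pad_voxels: int = 1,
) -> VectorImage:
    """Resample the ROI of an unstructured velocity field to a uniform grid.

    The grid covers the ROI bounding box padded by one voxel.  When the
    field carries tetrahedra, interpolation is barycentric-linear on those
    cells; otherwise Delaunay-based linear scattered-data interpolation over
    the ROI point cloud is used.  Voxels outside the interpolatable support
    are masked out.

    Parameters
    ----------
    spacing : float, optional
        Absolute isotropic voxel size in mm.  When omitted, the spacing is
        chosen so the longest ROI axis spans ``target_resolution`` voxels.
    """
    if field.field_kind != "velocity":
        raise ValueError("resample_to_grid expects a velocity field")
    roi = field.roi_mask if field.roi_mask is not None else np.ones(field.n_points, bool)
    if not roi.any():
        raise ValueError("empty ROI")
    pts = field.points[roi]
    if len(pts) < 4 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 3:
        raise ValueError("need at least 4 non-coplanar ROI points")
    vecs = field.vectors[roi]

    lo, hi = pts.min(axis=0), pts.max(axis=0)
    if spacing is None:
        spacing = float((hi - lo).max()) / target_resolution
    spacing3 = np.full(3, float(spacing))
    lo = lo - pad_voxels * spacing3
    hi = hi + pad_voxels * spacing3
    shape = np.maximum(np.ceil((hi - lo) / spacing3).astype(int) + 1, 2)

    axes = [lo[d] + spacing3[d] * np.arange(shape[d]) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    query = grid.reshape(-1, 3)

    if field.cells is not None and field.cells.shape[1] == 4:
        # restrict to tets fully inside the ROI
        tet_roi = roi[field.cells].all(axis=1)
        tets = field.cells[tet_roi]
        if len(tets) == 0:
            raise ValueError("no tetrahedra fully inside the ROI")
        vals, inside = _tet_interpolate(field.points, tets, field.vectors, query)
    else:
        try:
            interp = LinearNDInterpolator(pts, vecs)
        except QhullError as exc:  # pragma: no cover - degenerate clouds
            raise ValueError("ROI point cloud is degenerate") from exc
        # cheap KD-tree prefilter: grid voxels far from every ROI point are
        # outside the interpolatable support, and skipping them avoids the
        # expensive outside-hull walk in the simplex search
        tree = cKDTree(pts)
        nn = tree.query(pts[:: max(len(pts) // 512, 1)], k=2)[0][:, 1]
        reach = float(nn.max()) + 2.0 * float(spacing)
        near = tree.query(query, distance_upper_bound=reach)[0] <= reach
        vals = np.zeros((len(query), 3))
        inside = np.zeros(len(query), dtype=bool)
        if near.any():
            got = interp(query[near])
            ok = np.all(np.isfinite(got), axis=1)
            vals[near] = np.where(np.isfinite(got), got, 0.0)
            inside[near] = ok

    arr = vals.reshape(*shape, 3)
    mask = inside.reshape(shape)
    arr[~mask] = 0.0
    return VectorImage(array=arr, spacing=spacing3, origin=lo, mask=mask)


# ---------------------------------------------------------------------------
# magnitude / direction images
# ---------------------------------------------------------------------------


def normalize_magnitudes(m: np.ndarray, p_lo: float = 5.0, p_hi: float = 95.0) -> np.ndarray:
    """Clip magnitudes to their [p_lo, p_hi] percentiles and rescale to [0, 1].

    Percentiles use the linear-interpolation definition.  A constant input
    (degenerate percentile window) maps to all zeros.
    """
    m = np.asarray(m, dtype=float)
    q_lo, q_hi = np.percentile(m, [p_lo, p_hi])
    # treat a window that is zero up to rounding as constant
    if q_hi - q_lo <= 1e-12 * max(abs(q_hi), abs(q_lo), 1e-30):
        return np.zeros_like(m)
    return (np.clip(m, q_lo, q_hi) - q_lo) / (q_hi - q_lo)


def magnitude_image(vimg: VectorImage, p_lo: float = 5.0, p_hi: float = 95.0) -> ScalarImage:
    """MVelocity: per-voxel speed, 5-95% percentile normalized into [0, 1]."""
    if not vimg.mask.any():
        raise ValueError("empty mask")
    m = np.linalg.norm(vimg.array, axis=-1)
    out = np.zeros(vimg.mask.shape, dtype=float)
    out[vimg.mask] = normalize_magnitudes(m[vimg.mask], p_lo, p_hi)
    return ScalarImage(array=out, spacing=vimg.spacing, origin=vimg.origin, mask=vimg.mask.copy())


def direction_image(vimg: VectorImage, partition: SpherePartition) -> ScalarImage:
    """DVelocity: per-voxel direction gray level (1..n); level 0 unmasked."""
    if not vimg.mask.any():
        raise ValueError("empty mask")
    labels = np.zeros(vimg.mask.shape, dtype=np.int64)
    labels[vimg.mask] = assign_direction(vimg.array[vimg.mask], partition)
    mask = vimg.mask & (labels > 0)
    labels[~mask] = 0
    return ScalarImage(array=labels, spacing=vimg.spacing, origin=vimg.origin, mask=mask)
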