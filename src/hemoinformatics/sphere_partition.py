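"""Equal-area partition of the unit sphere and direction quantization.

The recursive zonal equal-area construction divides the sphere into a north
polar cap, a stack of collar bands each split into a whole number of
equal-azimuth regions, and a south polar cap, with every region having
spherical area exactly ``4*pi/n``.  Each region is represented by its
*regional vector* — the unit vector from the sphere centre to the region's
area centroid — and an arbitrary 3D direction is quantized to the region
whose regional vector it is most closely aligned with (largest dot product).

Region indices run 1..n from the pole opposite the flow axis ("upstream")
to the pole aligned with it ("downstream"), so that a HIGH gray level means
a vector pointing downstream (aorta to iliac) and a LOW gray level means a
reversed, upstream-pointing vector.  Index 0 is reserved for degenerate
(zero-norm) vectors and acts as background in the derived images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Band", "SpherePartition", "build_partition", "assign_direction"]

_DEGENERATE_NORM = 1e-12


@dataclass(frozen=True)
class Band:
    """One colatitude band of the partition (cap or collar).

    Colatitudes are measured from the partition's own north pole (the
    upstream direction, i.e. ``-axis``).  ``n_azimuthal == 1`` for caps.
    """

    colat_lo: float
    colat_hi: float
    n_azimuthal: int


@dataclass(frozen=True)
class SpherePartition:
    """Equal-area sphere partition with ordered regional vectors."""

    n_regions: int
    bands: tuple[Band, ...]
    regional_vectors: np.ndarray  # (n_regions, 3), unit norm, world frame
    axis: np.ndarray  # unit downstream axis, world frame
    rotation: np.ndarray = field(repr=False, default=None)  # local->world

    def region_area(self) -> float:
        return 4.0 * np.pi / self.n_regions

    def rotated(self, R: np.ndarray) -> "SpherePartition":
        """The same partition rigidly rotated by matrix R (world frame)."""
        R = np.asarray(R, dtype=float)
        return SpherePartition(
            n_regions=self.n_regions,
            bands=self.bands,
            regional_vectors=self.regional_vectors @ R.T,
            axis=R @ self.axis,
            rotation=R @ self.rotation if self.rotation is not None else None,
        )

    def to_table(self):
        """Partition layout as a pandas DataFrame (index, band, bounds, centroid)."""
        import pandas as pd

        rows = []
        idx = 1
        for b_i, band in enumerate(self.bands):
            width = 2.0 * np.pi / band.n_azimuthal
            for k in range(band.n_azimuthal):
                cx, cy, cz = self.regional_vectors[idx - 1]
                rows.append(
                    {
                        "region": idx,
                        "band": b_i,
                        "colat_lo": band.colat_lo,
                        "colat_hi": band.colat_hi,
                        "azim_lo": k * width,
                        "azim_hi": (k + 1) * width,
                        "centroid_x": cx,
                        "centroid_y": cy,
                        "centroid_z": cz,
                    }
                )
                idx += 1
        return pd.DataFrame(rows)


def _cap_colatitude(k: int, n: int) -> float:
    """Colatitude whose spherical cap holds exactly k of the n equal areas."""
    # cap area 2*pi*(1-cos(theta)) == k * 4*pi/n
    return float(np.arccos(np.clip(1.0 - 2.0 * k / n, -1.0, 1.0)))


def _band_layout(n: int) -> list[Band]:
    """Recursive zonal equal-area band structure in the canonical frame."""
    if n == 1:
        return [Band(0.0, np.pi, 1)]
    if n == 2:
        return [Band(0.0, np.pi / 2.0, 1), Band(np.pi / 2.0, np.pi, 1)]
    if n == 3:
        # caps plus one full-azimuth equatorial ring
        c = _cap_colatitude(1, 3)
        return [Band(0.0, c, 1), Band(c, np.pi - c, 1), Band(np.pi - c, np.pi, 1)]

    theta_c = _cap_colatitude(1, n)
    ideal_angle = np.sqrt(4.0 * np.pi / n)  # side of a square of one region's area
    n_collars = max(1, int(round((np.pi - 2.0 * theta_c) / ideal_angle)))
    fitting = (np.pi - 2.0 * theta_c) / n_collars

    # ideal (real-valued) region counts per collar, then rounding that
    # preserves the cumulative sum so all n regions are placed
    ideal_counts = []
    for i in range(n_collars):
        lo = theta_c + i * fitting
        hi = theta_c + (i + 1) * fitting
        area = 2.0 * np.pi * (np.cos(lo) - np.cos(hi))
        ideal_counts.append(area / (4.0 * np.pi / n))
    counts = []
    residual = 0.0
    for y in ideal_counts:
        m = max(1, int(round(y + residual)))
        residual += y - m
        counts.append(m)
    # rounding drift guard: force the exact total
    drift = (n - 2) - sum(counts)
    if drift != 0:
        counts[-1] += drift

    # recompute collar boundaries so each region's area is exactly 4*pi/n
    bands = [Band(0.0, theta_c, 1)]
    cum = 1
    lo = theta_c
    for m in counts:
        cum += m
        hi = _cap_colatitude(cum, n)
        bands.append(Band(lo, hi, m))
        lo = hi
    bands.append(Band(lo, np.pi, 1))
    return bands


def _collar_centroid(colat_lo, colat_hi, azim_lo, azim_hi):
    """Closed-form area centroid of a colatitude-azimuth rectangle on S2."""
    dz = 0.5 * (np.cos(colat_lo) ** 2 - np.cos(colat_hi) ** 2) * (azim_hi - azim_lo)
    sin2 = 0.5 * (colat_hi - colat_lo) - 0.25 * (
        np.sin(2 * colat_hi) - np.sin(2 * colat_lo)
    )
    dx = (np.sin(azim_hi) - np.sin(azim_lo)) * sin2
    dy = (np.cos(azim_lo) - np.cos(azim_hi)) * sin2
    v = np.array([dx, dy, dz])
    nrm = np.linalg.norm(v)
    if nrm < _DEGENERATE_NORM:  # hemispherically symmetric band: degenerate
        return np.array([0.0, 0.0, 1.0])
    return v / nrm


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking canonical +z to `axis` (deterministic choice)."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, axis))
    if c > 1.0 - 1e-14:
        return np.eye(3)
    if c < -1.0 + 1e-14:
        # pi rotation about x
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, axis)
    s = np.linalg.norm(v)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def build_partition(n: int, axis) -> SpherePartition:
    """Build an n-region equal-area partition oriented along a flow axis.

    Parameters
    ----------
    n : int
        Number of regions (360 by default elsewhere in the package).
    axis : array-like, shape (3,)
        Downstream flow direction.  The partition is oriented so the region
        with the HIGHEST index sits at the pole aligned with ``axis``.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    axis = np.asarray(axis, dtype=float)
    if axis.shape != (3,) or not np.all(np.isfinite(axis)):
        raise ValueError("axis must be a finite 3-vector")
    nrm = np.linalg.norm(axis)
    if nrm < _DEGENERATE_NORM:
        raise ValueError("axis must be nonzero")
    axis = axis / nrm

    bands = _band_layout(n)

    # canonical-frame centroids, north pole at +z (local colatitude 0)
    centroids = []
    for band in bands:
        if band.n_azimuthal == 1 and (band.colat_lo == 0.0 or band.colat_hi >= np.pi - 1e-15):
            if band.colat_lo == 0.0 and band.colat_hi >= np.pi - 1e-15:
                centroids.append(np.array([0.0, 0.0, 1.0]))  # n=1 degenerate: whole sphere
            elif band.colat_lo == 0.0:
                centroids.append(np.array([0.0, 0.0, 1.0]))
            else:
                centroids.append(np.array([0.0, 0.0, -1.0]))
            continue
        width = 2.0 * np.pi / band.n_azimuthal
        for k in range(band.n_azimuthal):
            centroids.append(
                _collar_centroid(band.colat_lo, band.colat_hi, k * width, (k + 1) * width)
            )
    local = np.array(centroids)

    # local north pole (index 1) must map to the UPSTREAM direction -axis
    rot = _rotation_to(-axis)
    world = local @ rot.T
    world /= np.linalg.norm(world, axis=1, keepdims=True)
    if n == 1:  # degenerate single region: represent by the downstream axis
        world = axis[None, :].copy()
    return SpherePartition(
        n_regions=n,
        bands=tuple(bands),
        regional_vectors=world,
        axis=axis,
        rotation=rot,
    )


def assign_direction(vectors, partition: SpherePartition) -> np.ndarray:
    """Quantize 3D vectors to region indices 1..n (0 for degenerate vectors).

    Each vector is assigned to the region whose regional vector has the
    smallest angular difference to it (argmax of the dot product with the
    normalized input).  Ties break toward the smallest region index; vectors
    with norm below 1e-12 map to 0.
    """
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    norms = np.linalg.norm(v, axis=1)
    out = np.zeros(len(v), dtype=np.int64)
    ok = norms >= _DEGENERATE_NORM
    if np.any(ok):
        unit = v[ok] / norms[ok, None]
        dots = unit @ partition.regional_vectors.T
        out[ok] = np.argmax(dots, axis=1) + 1
    return out
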