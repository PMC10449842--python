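"""WSS field on the lumen surface to 2D image-like data (MWSS + DWSS).

The triangulated lumen surface carrying per-vertex wall shear stress is
(1) cut open along a shortest seam if it has tube topology, (2) flattened
to a rectangle by a discrete harmonic (cotangent-weight) parameterization
whose boundary is placed by arc length, and (3) rasterized onto a uniform
pixel grid.  Direction gray levels are assigned from the ORIGINAL 3D WSS
vectors before any flattening — the planar map only decides where a vertex
lands, never what its label is.  Magnitude is 5-95% percentile-normalized
exactly as for velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .sphere_partition import SpherePartition, assign_direction
from .velocity_imaging import ScalarImage, normalize_magnitudes

__all__ = [
    "SurfaceMesh",
    "FlatMap",
    "TopologyError",
    "cut_seam",
    "flatten_conformal",
    "rasterize_surface_field",
    "wss_images",
]


class TopologyError(ValueError):
    """Raised for surfaces the flattening pipeline cannot handle."""


@dataclass
class SurfaceMesh:
    """Triangulated lumen surface with per-vertex WSS vectors."""

    vertices: np.ndarray  # (n, 3) mm
    triangles: np.ndarray  # (m, 3) vertex indices
    wss: np.ndarray | None = None  # (n, 3) Pa
    roi_mask: np.ndarray | None = None  # (n,) bool
    corner_hint: tuple | None = None  # 4 boundary vertices for the rectangle

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.wss is not None:
            self.wss = np.asarray(self.wss, dtype=float)
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def boundary_edges(self) -> np.ndarray:
        e = np.vstack([self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]])
        key = np.sort(e, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return key[idx[counts == 1]]

    def boundary_loops(self) -> list[list[int]]:
        """Ordered vertex cycles of the boundary."""
        edges = self.boundary_edges()
        adj: dict[int, list[int]] = {}
        for a, b in edges:
            adj.setdefault(int(a), []).append(int(b))
            adj.setdefault(int(b), []).append(int(a))
        seen = set()
        loops = []
        for start in adj:
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            prev, cur = None, start
            while True:
                nxts = [v for v in adj[cur] if v != prev]
                if not nxts:
                    break
                nxt = nxts[0]
                if nxt == start:
                    break
                loop.append(nxt)
                seen.add(nxt)
                prev, cur = cur, nxt
            loops.append(loop)
        return loops

    def euler_characteristic(self) -> int:
        e = np.vstack([self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]])
        n_edges = len(np.unique(np.sort(e, axis=1), axis=0))
        return self.n_vertices - n_edges + len(self.triangles)


@dataclass
class FlatMap:
    """Planar (u, v) parameterization of a disk-topology surface mesh."""

    uv: np.ndarray  # (n, 2), u in [0, 1], v in [0, aspect]
    triangles: np.ndarray
    aspect: float
    angle_distortion: np.ndarray = dc_field(default=None)  # per-triangle, degrees
    _finder: object = dc_field(default=None, repr=False, compare=False)

    def locate(self, u, v) -> np.ndarray:
        """Containing-triangle index per query point (-1 when outside)."""
        if self._finder is None:
            from matplotlib.tri import Triangulation

            tri = Triangulation(self.uv[:, 0], self.uv[:, 1], self.triangles)
            object.__setattr__(self, "_finder", tri.get_trifinder())
        return np.asarray(self._finder(np.asarray(u, float), np.asarray(v, float)))

    def n_flipped(self) -> int:
        a = self.uv[self.triangles]
        cross = (a[:, 1, 0] - a[:, 0, 0]) * (a[:, 2, 1] - a[:, 0, 1]) - (
            a[:, 1, 1] - a[:, 0, 1]
        ) * (a[:, 2, 0] - a[:, 0, 0])
        signs = np.sign(cross)
        majority = 1.0 if (signs > 0).sum() >= (signs < 0).sum() else -1.0
        return int(np.sum(signs == -majority))


# ---------------------------------------------------------------------------
# seam cutting
# ---------------------------------------------------------------------------


def _shortest_path_between(mesh: SurfaceMesh, src: list[int], dst: list[int]) -> list[int]:
    tris = mesh.triangles
    e = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    g = sp.coo_matrix((np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])), shape=(n, n)).tocsr()
    dist, pred = csgraph.dijkstra(g, indices=src, return_predecessors=True)
    dst = np.asarray(dst)
    best = np.unravel_index(np.argmin(dist[:, dst]), (len(src), len(dst)))
    s_i, d_v = best[0], int(dst[best[1]])
    path = [d_v]
    while path[-1] != src[s_i]:
        p = pred[s_i, path[-1]]
        if p < 0:
            raise TopologyError("boundary loops are not connected through the surface")
        path.append(int(p))
    return path[::-1]


def cut_seam(mesh: SurfaceMesh) -> SurfaceMesh:
    """Cut a tube-topology surface into a disk along a shortest seam path.

    A disk input is returned unchanged.  The seam is the edge-weighted
    shortest path between the two boundary loops; seam vertices are
    duplicated (carrying identical WSS/ROI values) so the result has disk
    topology (Euler characteristic 1).  ``corner_hint`` records the four
    copies of the seam endpoints for rectangle flattening.
    """
    loops = mesh.boundary_loops()
    if len(loops) == 0:
        raise TopologyError("closed surface: no boundary to flatten from")
    if len(loops) == 1:
        return mesh
    if len(loops) > 2 or mesh.euler_characteristic() != 0:
        raise TopologyError("unsupported topology (expected a disk or a tube)")

    path = _shortest_path_between(mesh, loops[0], loops[1])
    path_edges = {frozenset((path[i], path[i + 1])) for i in range(len(path) - 1)}
    path_set = set(path)

    verts = list(mesh.vertices)
    wss = list(mesh.wss) if mesh.wss is not None else None
    roi = list(mesh.roi_mask) if mesh.roi_mask is not None else None
    tris = mesh.triangles.copy()

    boundary_edge_set = {frozenset((int(a), int(b))) for a, b in mesh.boundary_edges()}
    dup_of: dict[int, int] = {}
    orig_of: dict[int, int] = {}  # duplicate index -> original index

    for v in path:
        incident = np.nonzero((tris == v).any(axis=1))[0]
        # fan adjacency between incident triangles via shared edges through v,
        # not crossing the seam or the boundary
        comp = {t: t for t in incident}

        def find(t):
            while comp[t] != t:
                comp[t] = comp[comp[t]]
                t = comp[t]
            return t

        edge_owner: dict[frozenset, int] = {}
        for t in incident:
            for o in tris[t]:
                if o == v:
                    continue
                o_can = orig_of.get(int(o), int(o))
                ek = frozenset((int(v), o_can))
                if ek in path_edges or ek in boundary_edge_set:
                    continue
                ek = frozenset((int(v), int(o)))
                if ek in edge_owner:
                    ra, rb = find(edge_owner[ek]), find(t)
                    comp[ra] = rb
                else:
                    edge_owner[ek] = t
        groups: dict[int, list[int]] = {}
        for t in incident:
            groups.setdefault(find(t), []).append(t)
        if len(groups) < 2:
            continue  # seam endpoint whose fan is not actually split
        # duplicate v for every group beyond the first (deterministic order)
        ordered = sorted(groups.values(), key=lambda g: min(g))
        for g in ordered[1:]:
            new_idx = len(verts)
            verts.append(mesh.vertices[v].copy())
            if wss is not None:
                wss.append(mesh.wss[v].copy())
            if roi is not None:
                roi.append(mesh.roi_mask[v])
            dup_of.setdefault(v, new_idx)
            orig_of[new_idx] = v
            for t in g:
                tris[t][tris[t] == v] = new_idx

    out = SurfaceMesh(
        vertices=np.array(verts),
        triangles=tris,
        wss=np.array(wss) if wss is not None else None,
        roi_mask=np.array(roi) if roi is not None else None,
    )
    v0, v1 = path[0], path[-1]
    out.corner_hint = (v0, dup_of.get(v0, v0), v1, dup_of.get(v1, v1))
    if out.euler_characteristic() != 1:
        raise TopologyError("seam cut did not produce a disk")
    return out


# ---------------------------------------------------------------------------
# conformal (harmonic) flattening
# ---------------------------------------------------------------------------


def _cotangent_weights(mesh: SurfaceMesh) -> sp.csr_matrix:
    V, T = mesh.vertices, mesh.triangles
    ii, jj, ww = [], [], []
    for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        # cotangent at corner c weights edge (a, b)
        u = V[T[:, a]] - V[T[:, c]]
        v = V[T[:, b]] - V[T[:, c]]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cot = np.einsum("ij,ij->i", u, v) / np.maximum(cross, 1e-300)
        ii.extend([T[:, a], T[:, b]])
        jj.extend([T[:, b], T[:, a]])
        ww.extend([0.5 * cot, 0.5 * cot])
    n = mesh.n_vertices
    W = sp.coo_matrix((np.concatenate(ww), (np.concatenate(ii), np.concatenate(jj))), shape=(n, n)).tocsr()
    return W


def _triangle_angles(P: np.ndarray) -> np.ndarray:
    """Interior angles (radians) of triangles given corner coordinates (m,3,d)."""
    out = np.empty((len(P), 3))
    for k, (a, b, c) in enumerate(((0, 1, 2), (1, 2, 0), (2, 0, 1))):
        u = P[:, b] - P[:, a]
        v = P[:, c] - P[:, a]
        nu = np.linalg.norm(u, axis=-1)
        nv = np.linalg.norm(v, axis=-1)
        cosang = np.einsum("ij,ij->i", u, v) / np.maximum(nu * nv, 1e-300)
        out[:, k] = np.arccos(np.clip(cosang, -1.0, 1.0))
    return out


def flatten_conformal(mesh: SurfaceMesh, corners=None) -> FlatMap:
    """Flatten a disk-topology mesh to a rectangle by a harmonic map.

    The boundary loop is split at four corner vertices and each arc is
    mapped to one rectangle side by arc length; interior vertices solve the
    cotangent-weight Laplace equation (the discrete conformal-energy
    minimizer with fixed boundary).  Per-triangle angle distortion (max
    absolute angle deviation, degrees) is reported; flipped triangles raise.
    """
    loops = mesh.boundary_loops()
    if len(loops) != 1 or mesh.euler_characteristic() != 1:
        raise TopologyError("flatten_conformal requires disk topology")
    V, T = mesh.vertices, mesh.triangles

    areas = 0.5 * np.linalg.norm(
        np.cross(V[T[:, 1]] - V[T[:, 0]], V[T[:, 2]] - V[T[:, 0]]), axis=1
    )
    bad = np.nonzero(areas < 1e-12)[0]
    if len(bad):
        raise ValueError(f"degenerate triangles (area < 1e-12 mm^2): {bad.tolist()[:20]}")

    loop = loops[0]
    if corners is None:
        corners = mesh.corner_hint
    if corners is None:
        pos = V[loop]
        nb = len(loop)
        # prefer sharp geometric corners (large boundary turning angle);
        # fall back to arc-length quartering on smooth boundaries
        prv = pos[np.arange(nb) - 1]
        nxt = pos[(np.arange(nb) + 1) % nb]
        e_in = pos - prv
        e_out = nxt - pos
        cosang = np.einsum("ij,ij->i", e_in, e_out) / np.maximum(
            np.linalg.norm(e_in, axis=1) * np.linalg.norm(e_out, axis=1), 1e-300
        )
        turn = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        sharp = np.nonzero(turn > 30.0)[0]
        if len(sharp) == 4:
            corners = [loop[k] for k in sharp]
        else:
            seg = np.linalg.norm(np.diff(np.vstack([pos, pos[:1]]), axis=0), axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            total = cum[-1]
            corners = [loop[int(np.searchsorted(cum, q * total))] for q in (0.0, 0.25, 0.5, 0.75)]

    ci = sorted(loop.index(c) for c in corners)
    if len(set(ci)) != 4:
        raise TopologyError("need four distinct boundary corners")
    arcs = []
    for k in range(4):
        a, b = ci[k], ci[(k + 1) % 4]
        arcs.append(loop[a : b + 1] if b > a else loop[a:] + loop[: b + 1])

    def arc_len(arc):
        p = V[arc]
        return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())

    lens = [arc_len(a) for a in arcs]
    width = 0.5 * (lens[0] + lens[2])
    height = 0.5 * (lens[1] + lens[3])
    aspect = height / width

    # rectangle corner targets (u, v), traversed in loop order
    targets = [(0.0, 0.0), (1.0, 0.0), (1.0, aspect), (0.0, aspect)]
    uv = np.zeros((mesh.n_vertices, 2))
    fixed = np.zeros(mesh.n_vertices, dtype=bool)
    for k, arc in enumerate(arcs):
        p0 = np.array(targets[k])
        p1 = np.array(targets[(k + 1) % 4])
        p = V[arc]
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        t = np.concatenate([[0.0], np.cumsum(seg)])
        t = t / max(t[-1], 1e-300)
        for v_idx, tv in zip(arc, t):
            uv[v_idx] = p0 + tv * (p1 - p0)
            fixed[v_idx] = True

    W = _cotangent_weights(mesh)
    d = np.asarray(W.sum(axis=1)).ravel()
    L = sp.diags(d) - W
    free = ~fixed
    if free.any():
        A = L[free][:, free].tocsc()
        B = L[free][:, fixed]
        rhs = -B @ uv[fixed]
        uv[free] = spla.spsolve(A, rhs).reshape(-1, 2)

    ang3d = _triangle_angles(V[T])
    ang2d = _triangle_angles(uv[T])
    distortion = np.degrees(np.abs(ang2d - ang3d).max(axis=1))

    flat = FlatMap(uv=uv, triangles=T, aspect=aspect, angle_distortion=distortion)
    if flat.n_flipped() > 0:
        raise ValueError(f"{flat.n_flipped()} flipped triangles after harmonic solve")
    return flat


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def rasterize_surface_field(
    flat: FlatMap,
    values: np.ndarray,
    pixel: float | None = None,
    target_resolution: int = 256,
    categorical: bool = False,
) -> ScalarImage:
    """Rasterize per-vertex values over the flattened rectangle.

    Continuous values are barycentrically interpolated inside the containing
    triangle; ``categorical=True`` instead copies the label of the vertex
    with the largest barycentric weight (nearest vertex), which keeps
    integer gray levels intact.  Pixels outside every triangle are masked.
    """
    values = np.asarray(values)
    w_u, w_v = 1.0, flat.aspect
    if pixel is None:
        pixel = max(w_u, w_v) / target_resolution
    nu = max(int(np.ceil(w_u / pixel)), 2)
    nv = max(int(np.ceil(w_v / pixel)), 2)
    # array axis 0 = v (rows), axis 1 = u (cols); pixel centres
    us = (np.arange(nu) + 0.5) * pixel
    vs = (np.arange(nv) + 0.5) * pixel

    gu, gv = np.meshgrid(us, vs)  # (nv, nu)
    tri_idx = flat.locate(gu.ravel(), gv.ravel()).reshape(nv, nu)
    mask = tri_idx >= 0
    out = np.zeros((nv, nu), dtype=float if not categorical else np.int64)
    if mask.any():
        t = flat.triangles[tri_idx[mask]]  # (k, 3)
        p = flat.uv[t]  # (k, 3, 2)
        du = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=-1)  # (k, 2, 2)
        det = du[:, 0, 0] * du[:, 1, 1] - du[:, 0, 1] * du[:, 1, 0]
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        ru = gu[mask] - p[:, 0, 0]
        rv = gv[mask] - p[:, 0, 1]
        b1 = (du[:, 1, 1] * ru - du[:, 0, 1] * rv) / det
        b2 = (-du[:, 1, 0] * ru + du[:, 0, 0] * rv) / det
        b0 = 1.0 - b1 - b2
        bary = np.stack([b0, b1, b2], axis=1)  # (k, 3)
        if categorical:
            pick = np.argmax(bary, axis=1)
            out[mask] = values[t[np.arange(len(t)), pick]]
        else:
            out[mask] = np.einsum("kj,kj->k", bary, values[t])

    return ScalarImage(
        array=out,
        spacing=np.array([pixel, pixel]),
        origin=np.array([vs[0], us[0]]),
        mask=mask,
    )


# ---------------------------------------------------------------------------
# full WSS pipeline
# ---------------------------------------------------------------------------


def wss_images(
    mesh: SurfaceMesh,
    partition: SpherePartition,
    pixel: float | None = None,
    target_resolution: int = 256,
    p_lo: float = 5.0,
    p_hi: float = 95.0,
) -> tuple[ScalarImage, ScalarImage]:
    """Compute the (MWSS, DWSS) image pair for a lumen surface.

    Direction labels come from the original 3D WSS vectors (quantized
    before flattening); magnitudes are percentile-normalized over ROI
    vertices.  MWSS is rasterized barycentrically, DWSS by nearest-vertex
    label.  Both images are masked to the ROI (sac) region.
    """
    if mesh.wss is None:
        raise ValueError("mesh has no WSS vectors")
    roi = mesh.roi_mask if mesh.roi_mask is not None else np.ones(mesh.n_vertices, bool)
    if not roi.any():
        raise ValueError("empty ROI")

    disk = cut_seam(mesh)
    flat = flatten_conformal(disk)
    roi_d = disk.roi_mask if disk.roi_mask is not None else np.ones(disk.n_vertices, bool)

    labels = assign_direction(disk.wss, partition)
    mags = np.linalg.norm(disk.wss, axis=1)
    norm = np.zeros_like(mags)
    norm[roi_d] = normalize_magnitudes(mags[roi_d], p_lo, p_hi)

    mwss = rasterize_surface_field(flat, norm, pixel, target_resolution)
    dwss = rasterize_surface_field(flat, labels, mwss.spacing[0], categorical=True)
    roi_img = rasterize_surface_field(flat, roi_d.astype(float), mwss.spacing[0])

    roi_px = roi_img.mask & (roi_img.array >= 0.5)
    mwss.mask &= roi_px
    dwss_mask = dwss.mask & roi_px & (np.asarray(dwss.array) > 0)
    dwss.array = np.where(dwss_mask, dwss.array, 0)
    dwss.mask = dwss_mask
    mwss.array = np.where(mwss.mask, mwss.array, 0.0)
    return mwss, dwss
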