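"""Synthetic aneurysm-flow phantom cohort generator.

Each case is a straight vessel with a Gaussian bulge (the sac), an
analytic velocity field (Poiseuille axial flow plus a parameterized
recirculation cell inside the bulge), and a per-vertex WSS field that
points downstream except inside seeded "reversed" patches.  The class
structure follows the effect direction the analysis is built to detect:
slowly-growing cases carry stronger recirculation (kappa) and a larger
reversed-WSS area fraction (phi) than fast-growing cases, while all
geometric parameters are drawn from the same distributions for both
classes so the signal is purely hemodynamic.

This is an analytic phantom, not a CFD solution: it reproduces the
statistical signatures (recirculation, reversed wall shear) the texture
pipeline measures, at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_formats import UnstructuredVectorField
from .wss_imaging import SurfaceMesh

__all__ = ["CaseSpec", "make_geometry", "make_velocity", "make_wss", "make_case", "make_cohort"]

BLOOD_VISCOSITY_PA_S = 0.004  # dynamic viscosity used for the WSS scale


@dataclass(frozen=True)
class CaseSpec:
    """Parameters of one synthetic case.

    Geometry: tube radius ``r0`` (mm), bulge amplitude ``bulge_amp`` (mm),
    bulge width ``bulge_width`` (mm), length ``length`` (mm).  Flow: peak
    axial speed ``u_peak`` (m/s), recirculation strength ``kappa`` in
    [0, 1], reversed-WSS area fraction ``phi`` in [0, 0.5], noise level
    ``noise`` as a fraction of ``u_peak``.
    """

    label: str  # "fast" | "slow"
    r0: float = 10.0
    bulge_amp: float = 8.0
    bulge_width: float = 8.0
    length: float = 80.0
    u_peak: float = 0.6
    kappa: float = 0.5
    phi: float = 0.25
    noise: float = 0.05
    n_theta: int = 48
    n_z: int = 80
    seed: int = 0
    case_id: str = "case"

    def __post_init__(self):
        if min(self.r0, self.bulge_width, self.length) <= 0:
            raise ValueError("r0, bulge_width, length must be positive")
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError("kappa must be in [0, 1]")
        if not (0.0 <= self.phi <= 0.5):
            raise ValueError("phi must be in [0, 0.5]")

    def radius_at(self, z):
        z = np.asarray(z, dtype=float)
        return self.r0 + self.bulge_amp * np.exp(
            -((z - self.length / 2.0) ** 2) / (2.0 * self.bulge_width**2)
        )

    def radius_slope_at(self, z):
        z = np.asarray(z, dtype=float)
        return (
            self.bulge_amp
            * np.exp(-((z - self.length / 2.0) ** 2) / (2.0 * self.bulge_width**2))
            * (-(z - self.length / 2.0) / self.bulge_width**2)
        )

    def bulge_interval(self) -> tuple[float, float]:
        return (self.length / 2.0 - 2.0 * self.bulge_width, self.length / 2.0 + 2.0 * self.bulge_width)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def make_geometry(spec: CaseSpec) -> tuple[SurfaceMesh, UnstructuredVectorField]:
    """Build the lumen surface and an interior point scaffold.

    The surface is a structured theta-z grid of the revolution profile
    R(z), triangulated with tube topology (two open ends).  The interior
    scaffold fills the lumen with rings of points (plus axis points) and
    carries zero vectors until :func:`make_velocity` fills them in.  ROI =
    the bulge region |z - L/2| <= 2w, for both surface and interior.
    """
    nt, nz = spec.n_theta, spec.n_z
    zs = np.linspace(0.0, spec.length, nz)
    thetas = np.linspace(0.0, 2.0 * np.pi, nt, endpoint=False)
    R = spec.radius_at(zs)

    tt, zz = np.meshgrid(thetas, zs)  # (nz, nt)
    rr = np.repeat(R[:, None], nt, axis=1)
    verts = np.stack([rr * np.cos(tt), rr * np.sin(tt), zz], axis=-1).reshape(-1, 3)

    tris = []
    for i in range(nz - 1):
        for j in range(nt):
            a = i * nt + j
            b = i * nt + (j + 1) % nt
            c = (i + 1) * nt + j
            d = (i + 1) * nt + (j + 1) % nt
            tris.append((a, b, d))
            tris.append((a, d, c))
    tris = np.array(tris, dtype=np.int64)

    z_lo, z_hi = spec.bulge_interval()
    surf_roi = (verts[:, 2] >= z_lo) & (verts[:, 2] <= z_hi)
    surface = SurfaceMesh(vertices=verts, triangles=tris, roi_mask=surf_roi)

    # interior: rings at radial fractions + axis line
    radial_fracs = np.array([0.0, 0.25, 0.45, 0.65, 0.8, 0.92])
    ring_counts = np.array([1, 8, 12, 16, 20, 24])
    pts = []
    for z, r_wall in zip(zs, R):
        for f, cnt in zip(radial_fracs, ring_counts):
            if cnt == 1:
                pts.append((0.0, 0.0, z))
            else:
                ang = np.linspace(0.0, 2.0 * np.pi, cnt, endpoint=False)
                r = f * r_wall
                for a in ang:
                    pts.append((r * np.cos(a), r * np.sin(a), z))
    pts = np.array(pts)
    vol_roi = (pts[:, 2] >= z_lo) & (pts[:, 2] <= z_hi)
    scaffold = UnstructuredVectorField(
        points=pts,
        vectors=np.zeros_like(pts),
        field_kind="velocity",
        roi_mask=vol_roi,
        case_id=spec.case_id,
    )
    return surface, scaffold


# ---------------------------------------------------------------------------
# velocity
# ---------------------------------------------------------------------------


def make_velocity(spec: CaseSpec, scaffold: UnstructuredVectorField | None = None) -> UnstructuredVectorField:
    """Analytic intra-luminal velocity field.

    Axial Poiseuille profile ``u_z = U (1 - (r/R(z))^2)`` plus, inside the
    bulge, a recirculation cell derived from the axisymmetric stream
    function ``psi = kappa U r^2 (1 - r/R) sin(pi (z - z1) / (2 w))`` via
    ``u_z += (1/r) d(psi)/dr``, ``u_r = -(1/r) d(psi)/dz``, plus isotropic
    Gaussian noise of scale ``noise * U``.  With ``kappa = 0`` the axial
    velocity is nonnegative everywhere; with strong ``kappa`` the flow
    reverses near the wall of the sac.
    """
    if scaffold is None:
        _, scaffold = make_geometry(spec)
    rng = np.random.default_rng(spec.seed)
    pts = scaffold.points
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    r = np.hypot(x, y)
    R = spec.radius_at(z)
    Rp = spec.radius_slope_at(z)
    U = spec.u_peak

    u_z = U * (1.0 - (r / R) ** 2)
    u_r = np.zeros_like(u_z)

    z1, z2 = spec.bulge_interval()
    w = spec.bulge_width
    in_bulge = (z > z1) & (z < z2)
    if spec.kappa > 0 and in_bulge.any():
        S = np.sin(np.pi * (z - z1) / (2.0 * w))
        Sp = (np.pi / (2.0 * w)) * np.cos(np.pi * (z - z1) / (2.0 * w))
        # u_z contribution: (1/r) d(psi)/dr with psi = k U r^2 (1 - r/R) S
        du_z = spec.kappa * U * (2.0 - 3.0 * r / R) * S
        # u_r contribution: -(1/r) d(psi)/dz
        du_r = -spec.kappa * U * (r**2 * Rp / R**2 * S + r * (1.0 - r / R) * Sp)
        u_z = np.where(in_bulge, u_z + du_z, u_z)
        u_r = np.where(in_bulge, du_r, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.where(r > 0, x / np.maximum(r, 1e-300), 1.0)
        sin_t = np.where(r > 0, y / np.maximum(r, 1e-300), 0.0)
    vec = np.stack([u_r * cos_t, u_r * sin_t, u_z], axis=-1)
    if spec.noise > 0:
        vec = vec + rng.normal(0.0, spec.noise * U, size=vec.shape)
    return replace_vectors(scaffold, vec)


def replace_vectors(field: UnstructuredVectorField, vectors: np.ndarray) -> UnstructuredVectorField:
    return UnstructuredVectorField(
        points=field.points,
        vectors=vectors,
        field_kind=field.field_kind,
        cells=field.cells,
        roi_mask=field.roi_mask,
        case_id=field.case_id,
    )


# ---------------------------------------------------------------------------
# WSS
# ---------------------------------------------------------------------------


def make_wss(spec: CaseSpec, surface: SurfaceMesh | None = None) -> SurfaceMesh:
    """Per-vertex WSS on the lumen surface.

    Base vector: downstream surface tangent with magnitude
    ``4 mu U / R(z)`` modulated by multiplicative noise; inside seeded
    elliptical (theta, z) patches totalling a fraction ``phi`` of the bulge
    area the tangent is reversed.  Magnitudes stay strictly positive.
    """
    if surface is None:
        surface, _ = make_geometry(spec)
    rng = np.random.default_rng(spec.seed + 1)
    V = surface.vertices
    z = V[:, 2]
    theta = np.mod(np.arctan2(V[:, 1], V[:, 0]), 2.0 * np.pi)
    R = spec.radius_at(z)
    Rp = spec.radius_slope_at(z)

    # downstream tangent of the surface of revolution: d/dz (R cos, R sin, z)
    tang = np.stack([Rp * np.cos(theta), Rp * np.sin(theta), np.ones_like(z)], axis=-1)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)

    mag = 4.0 * BLOOD_VISCOSITY_PA_S * spec.u_peak / (R * 1e-3)  # R mm -> m
    mag = mag * np.clip(1.0 + rng.normal(0.0, spec.noise, size=len(z)), 0.05, None)

    reversed_mask = np.zeros(len(z), dtype=bool)
    z_lo, z_hi = spec.bulge_interval()
    in_bulge = (z >= z_lo) & (z <= z_hi)
    if spec.phi > 0 and in_bulge.any():
        n_patches = 3
        # patch semi-axes start from an equal split of the target fraction,
        # then rescale to hit the realized vertex-fraction target
        span_z = z_hi - z_lo
        # n ellipses of area pi*a_th*a_z covering phi of the 2*pi x span_z band,
        # with shape proportional to the band: a_z/span_z == a_th/(2*pi)
        a_th = np.sqrt(4.0 * np.pi * spec.phi / n_patches)
        a_z = a_th * span_z / (2.0 * np.pi)
        centers = []
        attempts = 0
        while len(centers) < n_patches and attempts < 200:
            attempts += 1
            c_th = rng.uniform(0.0, 2.0 * np.pi)
            c_z = rng.uniform(z_lo + a_z, z_hi - a_z) if z_hi - a_z > z_lo + a_z else 0.5 * (z_lo + z_hi)
            ok = all(
                min(abs(c_th - t0), 2.0 * np.pi - abs(c_th - t0)) > 1.6 * a_th
                or abs(c_z - z0) > 1.6 * a_z
                for t0, z0 in centers
            )
            if ok:
                centers.append((c_th, c_z))
        scale = 1.0
        for _ in range(6):
            m = np.zeros(len(z), dtype=bool)
            for c_th, c_z in centers:
                d_th = np.minimum(np.abs(theta - c_th), 2.0 * np.pi - np.abs(theta - c_th))
                m |= (d_th / (scale * a_th)) ** 2 + ((z - c_z) / (scale * a_z)) ** 2 <= 1.0
            m &= in_bulge
            frac = m.sum() / max(in_bulge.sum(), 1)
            if frac > 0:
                scale *= np.sqrt(spec.phi / frac)
            else:
                scale *= 1.5
            reversed_mask = m
        # final evaluation at the converged scale
        m = np.zeros(len(z), dtype=bool)
        for c_th, c_z in centers:
            d_th = np.minimum(np.abs(theta - c_th), 2.0 * np.pi - np.abs(theta - c_th))
            m |= (d_th / (scale * a_th)) ** 2 + ((z - c_z) / (scale * a_z)) ** 2 <= 1.0
        reversed_mask = m & in_bulge

    sign = np.where(reversed_mask, -1.0, 1.0)
    wss = tang * (sign * mag)[:, None]
    out = SurfaceMesh(
        vertices=surface.vertices,
        triangles=surface.triangles,
        wss=wss,
        roi_mask=surface.roi_mask,
    )
    return out


# ---------------------------------------------------------------------------
# cases and cohorts
# ---------------------------------------------------------------------------


def make_case(spec: CaseSpec) -> tuple[SurfaceMesh, UnstructuredVectorField]:
    """Full synthetic case: WSS-bearing surface + velocity field."""
    surface, scaffold = make_geometry(spec)
    velocity = make_velocity(spec, scaffold)
    surface = make_wss(spec, surface)
    return surface, velocity


def make_cohort(
    n_slow: int = 48,
    n_fast: int = 22,
    delta_kappa: float = 0.0,
    delta_phi: float = 0.0,
    noise: float = 0.05,
    seed: int = 0,
) -> list[CaseSpec]:
    """Draw class-conditional case specs for a cohort.

    Slow cases: kappa ~ N(0.5 + delta_kappa, 0.1), phi ~ N(0.25 +
    delta_phi, 0.05); fast cases mirror with the deltas subtracted; both
    clipped to their valid ranges.  Geometry and flow-speed parameters are
    drawn identically for both classes.  Fully deterministic given seed.
    """
    if n_slow < 1 or n_fast < 1:
        raise ValueError("need at least one case per class")
    rng = np.random.default_rng(seed)
    specs = []
    labels = ["slow"] * n_slow + ["fast"] * n_fast
    for k, label in enumerate(labels):
        sgn = 1.0 if label == "slow" else -1.0
        kappa = float(np.clip(rng.normal(0.5 + sgn * delta_kappa, 0.1), 0.0, 1.0))
        phi = float(np.clip(rng.normal(0.25 + sgn * delta_phi, 0.05), 0.0, 0.5))
        specs.append(
            CaseSpec(
                label=label,
                r0=float(np.clip(rng.normal(10.0, 1.0), 6.0, 14.0)),
                bulge_amp=float(np.clip(rng.normal(8.0, 1.5), 3.0, 14.0)),
                bulge_width=float(np.clip(rng.normal(8.0, 1.0), 5.0, 12.0)),
                length=80.0,
                u_peak=float(np.clip(rng.normal(0.6, 0.05), 0.3, 1.0)),
                kappa=kappa,
                phi=phi,
                noise=noise,
                seed=int(rng.integers(0, 2**31 - 1)),
                case_id=f"{label}_{k:03d}",
            )
        )
    return specs
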