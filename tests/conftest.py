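"""Shared fixtures: small meshes, phantom cases, and cohort feature tables.

The two 70-case cohort tables (null-effect and strong-effect) are expensive,
so they are built once per session at a reduced imaging resolution
(velocity grid 24 voxels along the longest axis, WSS raster 96 pixels);
the texture statistics they feed are resolution-controlled, not
resolution-defined, so the class structure they carry is unchanged.
"""

from __future__ import annotations

import numpy as np
import pytest

from hemoinformatics.cli_app import build_feature_table
from hemoinformatics.synthetic_cohort import CaseSpec, make_case, make_cohort
from hemoinformatics.wss_imaging import SurfaceMesh

COHORT_VELOCITY_RES = 24
COHORT_WSS_RES = 96


def tube_mesh(n_theta=40, n_z=30, radius=8.0, length=50.0, radius_fn=None):
    """Structured triangulated tube (two open ends), optionally bulged."""
    thetas = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    zs = np.linspace(0.0, length, n_z)
    tt, zz = np.meshgrid(thetas, zs)
    rr = radius_fn(zz) if radius_fn is not None else np.full_like(zz, radius)
    verts = np.stack([rr * np.cos(tt), rr * np.sin(tt), zz], axis=-1).reshape(-1, 3)
    tris = []
    for i in range(n_z - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            tris.append((a, b, d))
            tris.append((a, d, c))
    return SurfaceMesh(vertices=verts, triangles=np.array(tris, dtype=np.int64))


@pytest.fixture
def cylinder_mesh():
    return tube_mesh()


@pytest.fixture
def bulged_tube_mesh():
    return tube_mesh(radius_fn=lambda z: 8.0 + 6.0 * np.exp(-((z - 25.0) ** 2) / 50.0))


@pytest.fixture
def phantom_case():
    spec = CaseSpec(label="slow", kappa=0.8, phi=0.3, seed=7, case_id="phantom")
    surface, velocity = make_case(spec)
    return spec, surface, velocity


@pytest.fixture(scope="session")
def null_cohort_table():
    """48 slow / 22 fast with zero class effect: features carry no signal."""
    specs = make_cohort(n_slow=48, n_fast=22, delta_kappa=0.0, delta_phi=0.0, seed=101)
    return build_feature_table(
        specs, velocity_resolution=COHORT_VELOCITY_RES, wss_resolution=COHORT_WSS_RES
    )


@pytest.fixture(scope="session")
def effect_cohort_table():
    """48 slow / 22 fast with the strong class effect (dk=0.3, dphi=0.15)."""
    specs = make_cohort(n_slow=48, n_fast=22, delta_kappa=0.3, delta_phi=0.15, seed=202)
    return build_feature_table(
        specs, velocity_resolution=COHORT_VELOCITY_RES, wss_resolution=COHORT_WSS_RES
    )
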