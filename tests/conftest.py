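"""Shared fixtures: small meshes and profiles kept cheap enough for tight loops."""
import numpy as np
import pytest

from synbuckle.energy import ModelParams
from synbuckle.mesh import build_reference_mesh


@pytest.fixture(scope="session")
def disc_mesh_coarse():
    """Flat disc, radius 100 nm, ~10 nm edges (N ~ 350)."""
    return build_reference_mesh(100.0, 10.0, "disc")


@pytest.fixture(scope="session")
def disc_mesh_fine():
    """Flat disc, radius 100 nm, 3 nm edges (N ~ 3500) for identity checks."""
    return build_reference_mesh(100.0, 3.0, "disc")


@pytest.fixture()
def random_state_mesh():
    """Small disc with a reproducible random (clamped-positive) height field."""
    mesh = build_reference_mesh(50.0, 10.0, "disc").copy()
    rng = np.random.default_rng(42)
    mesh.height = np.where(mesh.pinned_mask, 0.0, rng.uniform(0.0, 8.0, mesh.n_vertices))
    return mesh


@pytest.fixture(scope="session")
def uniform_params():
    return ModelParams(kappa1=300.0, kappa2=300.0, kappa3=300.0, Pi=0.0)


def spherical_cap_heights(mesh, sphere_radius, depth, center=(0.0, 0.0)):
    """Impose h = spherical cap of given parent-sphere radius and depth."""
    r = np.hypot(mesh.reference_vertices[:, 0] - center[0],
                 mesh.reference_vertices[:, 1] - center[1])
    rim = np.sqrt(depth * (2.0 * sphere_radius - depth))
    h = np.where(
        r < rim,
        np.sqrt(np.maximum(sphere_radius**2 - r * r, 0.0)) - (sphere_radius - depth),
        0.0,
    )
    h[mesh.pinned_mask] = 0.0
    return h
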