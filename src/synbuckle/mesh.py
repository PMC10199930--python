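"""Triangulated Monge-gauge membrane patch and its discrete geometry operators.

The membrane is represented as a single-valued height field ``h(x, y) >= 0``
over a fixed planar reference triangulation (Monge gauge).  Positive heights
point toward the cytoplasm.  The embedded surface is the piecewise-linear
graph ``(x, y, h(x, y))``; all geometric quantities (area, enclosed volume,
mean curvature) are exact properties of that piecewise-linear surface or
consistent finite-element estimates on it.

Material sub-domains (fused-vesicle discs, the soft active zone, the
actin-stiffened periactive annulus) are carried as per-face integer labels
fixed in reference coordinates; the outer boundary loop is pinned at h = 0.

Conventions
-----------
* lengths in nm, areas in nm^2, volumes in nm^3, curvature in 1/nm;
* mean curvature Omega = (k1 + k2) / 2 is *positive* for surfaces bending
  toward the cytoplasm: a dome with h > 0 has Omega > 0 at its apex.  In
  Monge gauge this is Omega = -div(grad h / sqrt(1 + |grad h|^2)) / 2.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay

from .errors import InvalidResolutionError, InwardOnlyError, MeshQualityError

# Material labels (per face).  Vesicle i carries label VESICLE_BASE + i.
ACTIVE_ZONE = 0
PERIACTIVE = 1
VESICLE_BASE = 2


def vesicle_label(i: int) -> int:
    """Face label of fused vesicle ``i`` (0-based)."""
    return VESICLE_BASE + int(i)


class _MeshOperators:
    """Precomputed sparse operators of the reference triangulation.

    ``Gx``, ``Gy`` map vertex values to the (constant) in-plane gradient of
    their linear interpolant on each face; they depend only on the reference
    coordinates and are shared between height-field copies of a mesh.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        nv = len(vertices)
        nf = len(faces)
        a = vertices[faces[:, 0]]
        b = vertices[faces[:, 1]]
        c = vertices[faces[:, 2]]
        # signed reference area; orientation is normalized by the builder
        cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
        area = 0.5 * cross
        if np.any(area <= 0):
            raise MeshQualityError("non-positively-oriented or degenerate reference triangle")
        if area.min() < 1e-12 * area.max():
            raise MeshQualityError("degenerate (zero-area) reference triangle")
        self.ref_face_area = area

        # gradient of the linear shape function of vertex v on face f:
        # grad phi_a = perp(c - b) / (2A), perp(v) = (-v_y, v_x)
        rows = np.repeat(np.arange(nf), 3)
        cols = faces.ravel()
        gx = np.empty((nf, 3))
        gy = np.empty((nf, 3))
        for k, (p, q) in enumerate(((b, c), (c, a), (a, b))):
            e = q - p
            gx[:, k] = -e[:, 1] / (2.0 * area)
            gy[:, k] = e[:, 0] / (2.0 * area)
        self.Gx = sp.csr_matrix((gx.ravel(), (rows, cols)), shape=(nf, nv))
        self.Gy = sp.csr_matrix((gy.ravel(), (rows, cols)), shape=(nf, nv))
        # face -> vertex sum incidence (used to spread per-face weights)
        self.S = sp.csr_matrix((np.ones(3 * nf), (rows, cols)), shape=(nf, nv))

        # lumped per-vertex reference area: one third of incident faces
        self.vertex_ref_area = np.asarray(self.S.T @ (area / 3.0)).ravel()
        if np.any(self.vertex_ref_area <= 0):
            raise MeshQualityError("isolated vertex (no incident faces)")

        # boundary detection: edges incident to exactly one face
        edges = np.sort(
            np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
        )
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        if np.any(counts > 2):
            raise MeshQualityError("non-manifold edge")
        bnd_edges = uniq[counts == 1]
        self.boundary_mask = np.zeros(nv, dtype=bool)
        self.boundary_mask[bnd_edges.ravel()] = True

        # vertex adjacency graph (for pit component labelling)
        i = np.concatenate([uniq[:, 0], uniq[:, 1]])
        j = np.concatenate([uniq[:, 1], uniq[:, 0]])
        self.vertex_adjacency = sp.csr_matrix(
            (np.ones(len(i), dtype=np.int8), (i, j)), shape=(nv, nv)
        )

        # reference edge lengths (mesh-quality reporting, dt heuristics)
        ev = vertices[uniq[:, 1]] - vertices[uniq[:, 0]]
        self.ref_edge_lengths = np.hypot(ev[:, 0], ev[:, 1])
        self._edge_index = uniq


@dataclass
class SurfaceMesh:
    """Monge-gauge membrane patch.

    Attributes
    ----------
    reference_vertices : (N, 2) float array, nm
    faces : (F, 3) int array, CCW triangles
    height : (N,) float array, nm, h >= 0 (toward cytoplasm)
    material_label : (F,) int array
    pinned_mask : (N,) bool array, True on the anchored outer boundary
    """

    reference_vertices: np.ndarray
    faces: np.ndarray
    height: np.ndarray
    material_label: np.ndarray
    pinned_mask: np.ndarray
    _ops: _MeshOperators | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.reference_vertices = np.ascontiguousarray(self.reference_vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        self.height = np.ascontiguousarray(self.height, dtype=float)
        self.material_label = np.ascontiguousarray(self.material_label, dtype=np.int64)
        self.pinned_mask = np.ascontiguousarray(self.pinned_mask, dtype=bool)
        if self._ops is None:
            self._ops = _MeshOperators(self.reference_vertices, self.faces)

    # -- shared-operator plumbing -------------------------------------------------
    @property
    def ops(self) -> _MeshOperators:
        return self._ops

    def copy(self) -> "SurfaceMesh":
        """Copy sharing the (immutable) reference operators."""
        return SurfaceMesh(
            self.reference_vertices,
            self.faces,
            self.height.copy(),
            self.material_label.copy(),
            self.pinned_mask,
            _ops=self._ops,
        )

    @property
    def n_vertices(self) -> int:
        return len(self.reference_vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def vertex_reference_area(self) -> np.ndarray:
        """Lumped per-vertex reference area (one third of incident faces), nm^2."""
        return self._ops.vertex_ref_area

    @property
    def boundary_mask(self) -> np.ndarray:
        return self._ops.boundary_mask

    def embedded_vertices(self) -> np.ndarray:
        """(N, 3) embedded coordinates (x, y, h)."""
        return np.column_stack([self.reference_vertices, self.height])

    # -- geometry -----------------------------------------------------------------
    def face_slopes(self, height: np.ndarray | None = None):
        """Per-face in-plane gradient components (p, q) of the height field."""
        h = self.height if height is None else height
        return self._ops.Gx @ h, self._ops.Gy @ h

    def face_area_embedded(self, height: np.ndarray | None = None) -> np.ndarray:
        """Embedded (3D) triangle areas, nm^2: A_ref * sqrt(1 + |grad h|^2)."""
        p, q = self.face_slopes(height)
        return self._ops.ref_face_area * np.sqrt(1.0 + p * p + q * q)

    def embedded_edge_min(self) -> float:
        """Smallest embedded edge length, nm (adaptive-timestep input)."""
        e = self._ops._edge_index
        xyz = self.embedded_vertices()
        d = xyz[e[:, 1]] - xyz[e[:, 0]]
        return float(np.sqrt((d * d).sum(axis=1)).min())

    def validate(self, tol: float = 1e-9):
        """Raise if the inward-only or pinned invariants are violated."""
        if self.height.min() < -tol:
            raise InwardOnlyError(f"negative height {self.height.min():.3g} nm present")
        if np.any(np.abs(self.height[self.pinned_mask]) > tol):
            raise InwardOnlyError("pinned vertex with nonzero height")


# -----------------------------------------------------------------------------
# geometry operators
# -----------------------------------------------------------------------------

def surface_area(mesh: SurfaceMesh, per_material: bool = False):
    """Total embedded membrane area in nm^2, optionally broken down by label.

    Returns ``total`` or ``(total, {label: area})``.
    """
    fa = mesh.face_area_embedded()
    total = float(fa.sum())
    if not per_material:
        return total
    labels = mesh.material_label
    breakdown = {int(l): float(fa[labels == l].sum()) for l in np.unique(labels)}
    return total, breakdown


def enclosed_volume(mesh: SurfaceMesh) -> float:
    """Volume sandwiched between the surface and the flat h = 0 baseline, nm^3.

    Prismatic rule: integral of h over the reference domain, which for the
    linear interpolant equals the lumped-area weighted sum of vertex heights.
    """
    if mesh.height.min() < -1e-9 * max(1.0, abs(mesh.height).max()):
        raise InwardOnlyError("negative height: enclosed volume undefined under inward-only rule")
    return float(mesh.vertex_reference_area @ mesh.height)


def _cross3(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Row-wise cross product of (F, 3) arrays (faster than np.cross)."""
    out = np.empty_like(u)
    out[:, 0] = u[:, 1] * v[:, 2] - u[:, 2] * v[:, 1]
    out[:, 1] = u[:, 2] * v[:, 0] - u[:, 0] * v[:, 2]
    out[:, 2] = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    return out


def curvature_field(mesh: SurfaceMesh, height: np.ndarray | None = None) -> dict:
    """Discrete curvature-normal construction on the embedded surface.

    The per-vertex curvature normal K_v = dA/dx_v (the cotangent-Laplacian
    applied to the embedding, assembled here as the exact 3D gradient of the
    total embedded area) is projected on the area-weighted vertex normal and
    divided by twice the lumped embedded vertex area:

        Omega_v = (K_v . n_v) / (2 A_v)

    This is the single curvature convention used by the energy, the pit
    observables, and the exports.  Positive for surfaces bending toward the
    cytoplasm (dome apex with h > 0 has Omega > 0).  Boundary vertices lack
    a full stencil and report 0.

    Returns a dict of intermediates reused by the energy gradient.
    """
    faces = mesh.faces
    xyz = np.column_stack(
        [mesh.reference_vertices, mesh.height if height is None else height]
    )
    a, b, c = xyz[faces[:, 0]], xyz[faces[:, 1]], xyz[faces[:, 2]]
    n_raw = _cross3(b - a, c - a)  # per-face non-unit normal, |n| = 2A
    two_area = np.sqrt((n_raw * n_raw).sum(axis=1))
    if np.any(two_area <= 0):
        raise MeshQualityError("degenerate embedded triangle")
    nhat = n_raw / two_area[:, None]
    face_area = 0.5 * two_area

    nv = mesh.n_vertices
    # corner-wise area gradients: dA_f/dx_corner = 0.5 * nhat x opposite_edge
    corner_k = np.empty((len(faces), 3, 3))
    corner_k[:, 0] = 0.5 * _cross3(nhat, c - b)
    corner_k[:, 1] = 0.5 * _cross3(nhat, a - c)
    corner_k[:, 2] = 0.5 * _cross3(nhat, b - a)

    idx = faces.ravel()
    K = np.zeros((nv, 3))
    M = np.zeros((nv, 3))  # area-weighted normal accumulator
    wgt = (face_area / 3.0)[:, None] * nhat
    for comp in range(3):
        K[:, comp] = np.bincount(idx, weights=corner_k[:, :, comp].ravel(), minlength=nv)
        M[:, comp] = np.bincount(
            idx, weights=np.repeat(wgt[:, comp], 3), minlength=nv
        )
    vertex_area = np.bincount(idx, weights=np.repeat(face_area / 3.0, 3), minlength=nv)
    m_norm = np.sqrt((M * M).sum(axis=1))
    vn = M / m_norm[:, None]
    omega = (K * vn).sum(axis=1) / (2.0 * vertex_area)
    omega[mesh.boundary_mask] = 0.0
    return {
        "xyz": xyz,
        "nhat": nhat,
        "face_area": face_area,
        "corner_k": corner_k,
        "K": K,
        "M": M,
        "m_norm": m_norm,
        "vertex_normal": vn,
        "vertex_area": vertex_area,
        "omega": omega,
    }


def mean_curvature(mesh: SurfaceMesh, height: np.ndarray | None = None) -> np.ndarray:
    """Per-vertex mean curvature Omega, 1/nm; boundary vertices report 0.

    See :func:`curvature_field` for the construction and sign convention.
    """
    return curvature_field(mesh, height)["omega"]


def area_height_gradient(mesh: SurfaceMesh, height: np.ndarray | None = None) -> np.ndarray:
    """Exact gradient dA/dh_v of the discrete embedded area (all vertices)."""
    ops = mesh.ops
    p, q = mesh.face_slopes(height)
    beta = np.sqrt(1.0 + p * p + q * q)
    coef = ops.ref_face_area / beta
    return np.asarray(ops.Gx.T @ (coef * p) + ops.Gy.T @ (coef * q)).ravel()


# -----------------------------------------------------------------------------
# reference-mesh builders
# -----------------------------------------------------------------------------

def build_reference_mesh(domain_half_width: float, target_edge: float, shape: str = "disc") -> SurfaceMesh:
    """Flat reference mesh: disc of radius ``domain_half_width`` or square of
    that half-width, triangulated at edge lengths within +-50% of
    ``target_edge``.  Heights start at 0, the boundary loop is pinned, and all
    faces carry the ACTIVE_ZONE placeholder label.
    """
    if target_edge >= domain_half_width:
        raise InvalidResolutionError(
            f"target_edge {target_edge} nm must be much smaller than the "
            f"domain half-width {domain_half_width} nm"
        )
    if target_edge <= 0:
        raise InvalidResolutionError("target_edge must be positive")
    if shape == "disc":
        verts = _disc_points(domain_half_width, target_edge)
        tri = Delaunay(verts)
        faces = tri.simplices
    elif shape == "square":
        verts, faces = _square_grid(domain_half_width, target_edge)
    else:
        raise ValueError(f"unknown shape {shape!r}")

    faces = _orient_ccw(verts, faces)
    mesh = SurfaceMesh(
        reference_vertices=verts,
        faces=faces,
        height=np.zeros(len(verts)),
        material_label=np.full(len(faces), ACTIVE_ZONE),
        pinned_mask=np.zeros(len(verts), dtype=bool),
    )
    mesh.pinned_mask = mesh.boundary_mask.copy()
    return mesh


def _disc_points(radius: float, target_edge: float) -> np.ndarray:
    """Concentric-ring point set: ring k at radius k*dr with 6k points, which
    triangulates into near-equilateral elements of edge ~ dr."""
    n_rings = max(3, int(round(radius / target_edge)))
    dr = radius / n_rings
    pts = [np.zeros((1, 2))]
    for k in range(1, n_rings + 1):
        n = 6 * k
        theta = 2.0 * np.pi * (np.arange(n) + 0.5 * (k % 2)) / n
        r = k * dr
        pts.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    return np.concatenate(pts)


def _square_grid(half_width: float, target_edge: float):
    n = max(3, int(round(2 * half_width / target_edge)))
    xs = np.linspace(-half_width, half_width, n + 1)
    X, Y = np.meshgrid(xs, xs)
    verts = np.column_stack([X.ravel(), Y.ravel()])
    faces = []
    for i in range(n):
        for j in range(n):
            v00 = i * (n + 1) + j
            v01 = v00 + 1
            v10 = v00 + (n + 1)
            v11 = v10 + 1
            if (i + j) % 2 == 0:
                faces.append([v00, v01, v11])
                faces.append([v00, v11, v10])
            else:
                faces.append([v00, v01, v10])
                faces.append([v01, v11, v10])
    return verts, np.array(faces)


def _orient_ccw(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    flip = cross < 0
    faces = faces.copy()
    faces[flip] = faces[flip][:, [0, 2, 1]]
    keep = np.abs(cross) > 1e-12 * np.abs(cross).max()
    return faces[keep]
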