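"""Initial conditions: active-zone disc, periactive annulus, fused-vesicle
domes, and named presets for the simulated experiments.

Geometry conventions: the reference-plane origin is the active-zone center;
the active zone is the disc of diameter ``L`` (it includes the endocytic
zone, which shares its soft modulus), surrounded by the actin-stiffened
periactive band of width ``w`` whose outer rim (radius L/2 + w) is pinned.
Fused vesicles are spherical-cap domes (default: hemispheres of depth
26 nm, the nearly-halfway-collapsed state of a 40-nm vesicle) imprinted at
specified centers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    FUSE_VESICLE,
    RELEASE_AREA_CONSERVATION,
    RESUME_AREA_CONSERVATION,
    Event,
    SimState,
)
from .energy import ModelParams
from .errors import ConfigurationError, OverhangError
from .mesh import ACTIVE_ZONE, PERIACTIVE, SurfaceMesh, build_reference_mesh, surface_area, vesicle_label


@dataclass
class VesicleSpec:
    """A fused vesicle: dome center (nm, reference plane), native vesicle
    diameter (nm), and the dome's initial apex depth d0 (nm).  The dome is a
    spherical cap of rim radius ``rim_radius`` (default: equal to the depth,
    i.e. a hemisphere)."""

    center: tuple[float, float]
    diameter: float = 40.0
    apex_depth: float = 26.0
    rim_radius: float | None = None

    def __post_init__(self):
        if self.rim_radius is None:
            self.rim_radius = self.apex_depth
        if self.rim_radius < self.apex_depth:
            raise OverhangError(
                f"dome rim {self.rim_radius} nm < depth {self.apex_depth} nm: "
                "overhanging neck not representable as a height field"
            )


@dataclass
class ScenarioSpec:
    """Full scenario: geometry, vesicle placement, moduli, event schedule,
    and mesh resolution."""

    L: float = 500.0  # active-zone linear dimension (diameter), nm
    w: float = 100.0  # periactive band width, nm
    vesicles: list[VesicleSpec] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    params: ModelParams = field(default_factory=ModelParams)
    target_edge: float = 8.0  # nm
    shape: str = "disc"

    @property
    def rim_radius(self) -> float:
        """Pinned-rim radius L/2 + w, nm."""
        return self.L / 2.0 + self.w

    def validate(self):
        if not (50.0 <= self.L <= 1000.0):
            raise ConfigurationError(f"active-zone size L={self.L} nm out of supported range")
        if self.w <= 0:
            raise ConfigurationError("periactive width must be positive")
        for v in self.vesicles:
            r = float(np.hypot(*v.center))
            if r + v.rim_radius > self.L / 2.0 + 1e-9:
                raise ConfigurationError(
                    f"vesicle at {v.center} (rim {v.rim_radius} nm) extends beyond the "
                    f"active zone of radius {self.L / 2:.0f} nm"
                )
        for i, vi in enumerate(self.vesicles):
            for vj in self.vesicles[i + 1 :]:
                d = float(np.hypot(vi.center[0] - vj.center[0], vi.center[1] - vj.center[1]))
                if d < vi.rim_radius + vj.rim_radius:
                    raise ConfigurationError(
                        f"vesicle footprints at {vi.center} and {vj.center} overlap"
                    )


def dome_profile(apex_depth: float, rim_radius: float | None = None):
    """Spherical-cap radial profile.

    Returns ``(profile, excess_area)`` where ``profile(r)`` is the height in
    nm at radial distance r from the dome center and ``excess_area`` is the
    cap area minus its flat footprint, exactly pi*d^2.
    """
    if apex_depth < 0:
        raise ConfigurationError("apex depth must be non-negative")
    d = float(apex_depth)
    a = d if rim_radius is None else float(rim_radius)
    if a < d:
        raise OverhangError("rim radius smaller than depth: overhanging cap")
    if d == 0.0:
        return (lambda r: np.zeros_like(np.asarray(r, dtype=float))), 0.0
    R = (a * a + d * d) / (2.0 * d)  # parent-sphere radius

    def profile(r):
        r = np.asarray(r, dtype=float)
        return np.where(r < a, np.sqrt(np.maximum(R * R - r * r, 0.0)) - (R - d), 0.0)

    return profile, np.pi * d * d


def imprint_vesicle(mesh: SurfaceMesh, ves: VesicleSpec, index: int | None = None):
    """Overwrite heights inside the vesicle footprint with its dome profile
    (taking the pointwise max with the current surface) and relabel the
    footprint faces.  Used at construction and by FUSE_VESICLE events."""
    from .mesh import VESICLE_BASE

    if index is None:
        existing = mesh.material_label[mesh.material_label >= VESICLE_BASE]
        index = 0 if len(existing) == 0 else int(existing.max()) - VESICLE_BASE + 1
    cx, cy = ves.center
    r_vert = np.hypot(mesh.reference_vertices[:, 0] - cx, mesh.reference_vertices[:, 1] - cy)
    centroids = mesh.reference_vertices[mesh.faces].mean(axis=1)
    r_face = np.hypot(centroids[:, 0] - cx, centroids[:, 1] - cy)
    in_face = r_face < ves.rim_radius
    if np.any(mesh.material_label[in_face] >= VESICLE_BASE):
        raise ConfigurationError("new vesicle footprint overlaps an existing vesicle domain")
    profile, _ = dome_profile(ves.apex_depth, ves.rim_radius)
    dome_h = profile(r_vert)
    mesh.height[:] = np.maximum(mesh.height, dome_h)
    mesh.height[mesh.pinned_mask] = 0.0
    mesh.material_label[in_face] = vesicle_label(index)
    return index


def build_scenario(spec: ScenarioSpec) -> SimState:
    """Construct the initial simulation state for a scenario.

    Faces are labeled vesicle/active-zone/periactive by reference position
    (centroid rule), domes are imprinted, the rim is pinned, and the area
    target A0 is set to the *meshed* initial area so the constraint is
    exactly satisfiable on the discrete surface.
    """
    spec.validate()
    mesh = build_reference_mesh(spec.rim_radius, spec.target_edge, spec.shape)
    centroids = mesh.reference_vertices[mesh.faces].mean(axis=1)
    r_face = np.hypot(centroids[:, 0], centroids[:, 1])
    mesh.material_label[:] = np.where(r_face <= spec.L / 2.0, ACTIVE_ZONE, PERIACTIVE)
    for i, ves in enumerate(spec.vesicles):
        imprint_vesicle(mesh, ves, index=i)
    state = SimState(
        mesh=mesh,
        params=spec.params,
        area_target=surface_area(mesh),
        conservation_on=True,
    )
    return state


# presets -----------------------------------------------------------------------

_TRIANGLE = ((0.0, 60.0), (60.0, -60.0), (-60.0, -60.0))


def _vesicle_ring(n: int, radius: float = 60.0) -> list[VesicleSpec]:
    """Placement rule for n fused vesicles (the 3-vesicle case is the
    isosceles triangle; other counts sit on a ring of the same 60 nm scale
    at equal angles)."""
    if n == 1:
        return [VesicleSpec(center=(0.0, 0.0))]
    if n == 2:
        return [VesicleSpec(center=(-radius, 0.0)), VesicleSpec(center=(radius, 0.0))]
    if n == 3:
        return [VesicleSpec(center=c) for c in _TRIANGLE]
    angles = np.pi / 2 + 2 * np.pi * np.arange(n) / n
    return [
        VesicleSpec(center=(radius * np.cos(t), radius * np.sin(t))) for t in angles
    ]


def preset(name: str, **kw) -> ScenarioSpec:
    """Named scenario presets.

    nominal_three          three vesicles, L=500, C=D=60, nominal moduli
    single_vesicle         one centered vesicle (axisymmetric)
    two_vesicle            two vesicles 120 nm apart, L configurable (default 300)
    n_vesicles             N vesicles in an active zone of size L
    moduli_sweep_point     nominal geometry at given (kappa1, kappa2)
    spacing                three vesicles at (0, D), (C, -C), (-C, -C)
    release                nominal + area-conservation release at t_off_ms
    sequential             one dome; second fuses when the first reaches depth_trigger_nm
    late_second_fusion     conservation relaxed, first dome flattens, then the
                           second fuses with conservation resumed
    """
    builders = {
        "nominal_three": _nominal_three,
        "single_vesicle": _single_vesicle,
        "two_vesicle": _two_vesicle,
        "n_vesicles": _n_vesicles,
        "moduli_sweep_point": _moduli_sweep_point,
        "spacing": _spacing,
        "release": _release,
        "sequential": _sequential,
        "late_second_fusion": _late_second_fusion,
    }
    if name not in builders:
        raise ConfigurationError(f"unknown preset {name!r}; options: {sorted(builders)}")
    return builders[name](**kw)


def _nominal_three(L=500.0, target_edge=8.0, params=None):
    return ScenarioSpec(
        L=L,
        vesicles=[VesicleSpec(center=c) for c in _TRIANGLE],
        params=params or ModelParams(),
        target_edge=target_edge,
    )


def _single_vesicle(L=500.0, target_edge=8.0, params=None):
    return ScenarioSpec(
        L=L,
        vesicles=[VesicleSpec(center=(0.0, 0.0))],
        params=params or ModelParams(),
        target_edge=target_edge,
    )


def _two_vesicle(L=300.0, target_edge=8.0, params=None):
    return ScenarioSpec(
        L=L,
        vesicles=_vesicle_ring(2),
        params=params or ModelParams(),
        target_edge=target_edge,
    )


def _n_vesicles(n=3, L=500.0, target_edge=8.0, params=None):
    return ScenarioSpec(
        L=L,
        vesicles=_vesicle_ring(n),
        params=params or ModelParams(),
        target_edge=target_edge,
    )


def _moduli_sweep_point(kappa1=300.0, kappa2=20.0, L=500.0, target_edge=8.0):
    return _nominal_three(L=L, target_edge=target_edge, params=ModelParams(kappa1=kappa1, kappa2=kappa2))


def _spacing(C=60.0, D=60.0, L=500.0, target_edge=8.0, params=None):
    vesicles = [
        VesicleSpec(center=(0.0, D)),
        VesicleSpec(center=(C, -C)),
        VesicleSpec(center=(-C, -C)),
    ]
    return ScenarioSpec(L=L, vesicles=vesicles, params=params or ModelParams(), target_edge=target_edge)


def _release(t_off_ms=5.0, uniform_kappa=20.0, L=500.0, target_edge=8.0, params=None):
    spec = _nominal_three(L=L, target_edge=target_edge, params=params)
    spec.events = [
        Event(kind=RELEASE_AREA_CONSERVATION, time_ms=t_off_ms, uniform_kappa=uniform_kappa)
    ]
    return spec


def _sequential(depth_trigger_nm=10.0, L=500.0, target_edge=8.0, params=None):
    spec = ScenarioSpec(
        L=L,
        vesicles=[VesicleSpec(center=(-60.0, 0.0))],
        params=params or ModelParams(),
        target_edge=target_edge,
    )
    spec.events = [
        Event(
            kind=FUSE_VESICLE,
            depth_trigger_nm=depth_trigger_nm,
            watch_vesicle=0,
            vesicle=VesicleSpec(center=(60.0, 0.0)),
        )
    ]
    return spec


def _late_second_fusion(flatten_depth_nm=0.5, L=500.0, target_edge=8.0, params=None):
    """First dome flattens fully under relaxed conservation (moduli kept);
    conservation is then resumed and the second vesicle fused."""
    spec = ScenarioSpec(
        L=L,
        vesicles=[VesicleSpec(center=(-60.0, 0.0))],
        params=params or ModelParams(),
        target_edge=target_edge,
    )
    spec.events = [
        Event(kind=RELEASE_AREA_CONSERVATION, time_ms=0.0, uniform_kappa=None),
        Event(
            kind=RESUME_AREA_CONSERVATION,
            depth_trigger_nm=flatten_depth_nm,
            watch_vesicle=0,
        ),
        Event(
            kind=FUSE_VESICLE,
            depth_trigger_nm=flatten_depth_nm,
            watch_vesicle=0,
            vesicle=VesicleSpec(center=(60.0, 0.0)),
        ),
    ]
    return spec
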