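"""Endocytic-pit detection, success classification, and parameter sweeps.

A pit is a connected component of membrane deflected more than ``delta_pit``
(default 2 nm) toward the cytoplasm on non-vesicle membrane (vesicle domains
plus a 1-ring margin are excluded: the collapsing exocytic domes themselves
are not endocytic structures).  Pit formation is called successful when the
maximal pit mean curvature exceeds the threshold c* (0.03 1/nm by default),
the curvature at which curvature-sensing endocytic proteins are assumed to
take over; the comparison is a strict inequality, evaluated at the time of
maximal pit depth when a time trace is available.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .energy import ModelParams
from .mesh import ACTIVE_ZONE, PERIACTIVE, VESICLE_BASE, SurfaceMesh, mean_curvature


@dataclass
class Pit:
    centroid: tuple[float, float]  # nm, reference plane
    max_depth: float  # nm
    max_mean_curvature: float  # 1/nm
    interface_distance: float  # nm, |r_centroid - L/2|


@dataclass
class PitReport:
    pits: list[Pit] = field(default_factory=list)
    count: int = 0
    success: bool = False


@dataclass
class PhaseDiagram:
    """Grid of per-cell outcomes from a parameter sweep."""

    axes: dict  # name -> list of values
    table: pd.DataFrame  # one row per cell: axis values + outcome columns
    resolution: float  # mesh target_edge, nm
    metadata: dict = field(default_factory=dict)


def interface_radius(mesh: SurfaceMesh) -> float:
    """Radius of the active-zone/periactive interface, recovered from the
    face labels (midpoint between the outermost soft face and the innermost
    stiff-annulus face)."""
    centroids = mesh.reference_vertices[mesh.faces].mean(axis=1)
    r = np.hypot(centroids[:, 0], centroids[:, 1])
    az = mesh.material_label != PERIACTIVE
    r_in = r[az].max() if az.any() else 0.0
    r_out = r[~az].min() if (~az).any() else r_in
    return 0.5 * (r_in + r_out)


def detect_pits(
    state_or_mesh,
    delta_pit: float = 2.0,
    c_star: float | None = None,
    r_interface: float | None = None,
) -> PitReport:
    """Detect pits on the current surface.

    Accepts a SimState or a bare SurfaceMesh.  ``c_star`` defaults to the
    model parameters when a state is given, else 0.03 1/nm.  ``r_interface``
    (nm) can be passed to avoid recomputing the label geometry in tight
    loops.
    """
    if isinstance(state_or_mesh, SurfaceMesh):
        mesh = state_or_mesh
        cs = 0.03 if c_star is None else c_star
    else:
        mesh = state_or_mesh.mesh
        cs = state_or_mesh.params.c_star if c_star is None else c_star

    h = mesh.height
    labels = mesh.material_label
    adj = mesh.ops.vertex_adjacency

    vesicle_vertices = np.zeros(mesh.n_vertices, dtype=bool)
    ves_faces = labels >= VESICLE_BASE
    if ves_faces.any():
        vesicle_vertices[np.unique(mesh.faces[ves_faces])] = True
        # 1-ring dilation
        vesicle_vertices |= np.asarray(adj @ vesicle_vertices, dtype=bool)
        # physical margin: a fully flattened cap of rim a covers a footprint
        # of radius sqrt(2)*a (its conserved area spread flat), so membrane
        # inside that circle is vesicle-derived material, not an endocytic pit
        cent = mesh.reference_vertices[mesh.faces].mean(axis=1)
        areas = mesh.ops.ref_face_area
        for lab in np.unique(labels[ves_faces]):
            sel = labels == lab
            w = areas[sel]
            cx, cy = (w[:, None] * cent[sel]).sum(axis=0) / w.sum()
            rim = np.hypot(cent[sel, 0] - cx, cent[sel, 1] - cy).max()
            rv = np.hypot(mesh.reference_vertices[:, 0] - cx,
                          mesh.reference_vertices[:, 1] - cy)
            vesicle_vertices |= rv <= np.sqrt(2.0) * rim

    mask = (h > delta_pit) & ~vesicle_vertices
    report = PitReport()
    if not mask.any():
        return report

    idx = np.where(mask)[0]
    sub = adj[idx][:, idx]
    n_comp, comp = connected_components(sub, directed=False)
    omega = mean_curvature(mesh)
    r_if = interface_radius(mesh) if r_interface is None else r_interface
    areas = mesh.vertex_reference_area
    for ci in range(n_comp):
        vv = idx[comp == ci]
        wsum = areas[vv].sum()
        cx, cy = (areas[vv][:, None] * mesh.reference_vertices[vv]).sum(axis=0) / wsum
        pit = Pit(
            centroid=(float(cx), float(cy)),
            max_depth=float(h[vv].max()),
            max_mean_curvature=float(omega[vv].max()),
            interface_distance=float(abs(np.hypot(cx, cy) - r_if)),
        )
        report.pits.append(pit)
    report.count = len(report.pits)
    report.success = any(p.max_mean_curvature > cs for p in report.pits)
    return report


def classify_success(report: PitReport, params: ModelParams) -> bool:
    """Strict threshold: success iff some pit's max mean curvature > c*."""
    return any(p.max_mean_curvature > params.c_star for p in report.pits)


def pit_metrics_over_time(trace: pd.DataFrame) -> dict:
    """The headline observable: pit curvature at the time of maximal pit depth.

    Returns {'time_ms', 'max_pit_depth', 'curvature_at_max_depth', 'success'};
    zero-curvature failure record if no pit was ever detected.
    """
    if len(trace) == 0 or trace["max_pit_depth"].max() <= 0:
        return {
            "time_ms": float("nan"),
            "max_pit_depth": 0.0,
            "curvature_at_max_depth": 0.0,
            "success": False,
        }
    i = int(trace["max_pit_depth"].idxmax())
    return {
        "time_ms": float(trace.loc[i, "time_ms"]),
        "max_pit_depth": float(trace.loc[i, "max_pit_depth"]),
        "curvature_at_max_depth": float(trace.loc[i, "max_pit_curvature"]),
        "success": bool(trace.loc[i, "max_pit_curvature"] > 0.03),
    }


# sweeps -------------------------------------------------------------------------

def run_cell(spec, stop=None) -> dict:
    """Run one sweep cell to steady state and summarize its outcome."""
    from .dynamics import run
    from .scenarios import build_scenario

    state = build_scenario(spec)
    trace, state = run(state, events=spec.events, stop=stop)
    metrics = pit_metrics_over_time(trace)
    report = detect_pits(state)
    cstar = state.params.c_star
    success = metrics["curvature_at_max_depth"] > cstar
    return {
        "success": success,
        "max_curvature": metrics["curvature_at_max_depth"],
        "pit_count": report.count,
        "steady": trace.attrs.get("stop_reason") == "steady_state",
        "time_of_max_depth_ms": metrics["time_ms"],
    }


def sweep(axes: dict, spec_factory, resolution: float = 8.0, stop=None, progress=None,
          skip=None) -> PhaseDiagram:
    """Full-grid sweep: one run per cell.

    ``axes`` maps axis names to value lists; ``spec_factory(**point)`` builds
    the ScenarioSpec of one cell (its target_edge is overridden by
    ``resolution``).  Cells are independent; per-cell failures are recorded
    rather than fatal.  ``skip(point) -> bool`` omits already-computed cells
    (resumability).
    """
    names = list(axes)
    rows = []
    for values in itertools.product(*(axes[n] for n in names)):
        point = dict(zip(names, values))
        if skip is not None and skip(point):
            continue
        try:
            spec = spec_factory(**point)
            spec.target_edge = resolution
            out = run_cell(spec, stop=stop)
            err = ""
        except Exception as exc:  # per-cell failure is data, not fatal
            out = {"success": False, "max_curvature": np.nan, "pit_count": 0, "steady": False,
                   "time_of_max_depth_ms": np.nan}
            err = f"{type(exc).__name__}: {exc}"
        rows.append({**point, **out, "error": err, "resolution": resolution})
        if progress is not None:
            progress(rows[-1])
    return PhaseDiagram(
        axes=axes,
        table=pd.DataFrame(rows),
        resolution=resolution,
        metadata={"stop": repr(stop)},
    )


def threshold_scan(values, success_fn, refine: int = 0, assume_monotone: bool = True):
    """Locate a failure/success boundary along a 1D grid.

    ``success_fn(v) -> bool`` is assumed monotone along the scan direction
    (failures first, then successes); a binary search over the grid finds
    the transition, optionally refined by ``refine`` continuous bisections.
    With ``assume_monotone=False`` every grid value is evaluated and the
    first transition is used.

    Returns ``(last_failing, first_succeeding, evaluations)``; either
    endpoint is None if the scan never fails / never succeeds.
    """
    values = list(values)
    evals = {}

    def ev(v):
        if v not in evals:
            evals[v] = bool(success_fn(v))
        return evals[v]

    if assume_monotone:
        lo_i, hi_i = -1, len(values) - 1
        if not ev(values[-1]):  # never succeeds
            return values[-1], None, evals
        if ev(values[0]):  # succeeds everywhere
            return None, values[0], evals
        # invariant: values[lo_i] fails (lo_i == 0 after the check above)
        lo_i = 0
        while hi_i - lo_i > 1:
            mid = (lo_i + hi_i) // 2
            if ev(values[mid]):
                hi_i = mid
            else:
                lo_i = mid
        lo, hi = values[lo_i], values[hi_i]
    else:
        for v in values:
            ev(v)
        lo = hi = None
        for v in values:
            if evals[v]:
                hi = v
                break
            lo = v
        if hi is None:
            return values[-1], None, evals
        if lo is None:
            return None, hi, evals

    for _ in range(refine):
        mid = 0.5 * (lo + hi)
        if ev(mid):
            hi = mid
        else:
            lo = mid
    return lo, hi, evals
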