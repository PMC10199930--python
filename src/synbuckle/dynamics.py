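"""Constrained gradient-flow integration of the membrane height field.

The height field follows the overdamped descent

    eta * dh/dt = -dE/dh   (+ tension * dA/dh, inward-only clamp)

with the membrane tension as the Lagrange multiplier of total-area
conservation, the outer rim pinned, and h >= 0 enforced by clamping.

Two steppers are provided.  ``explicit`` is plain forward-Euler descent in
the drag metric with the biharmonic stability bound on dt
(:func:`adaptive_timestep`).  The default ``semi_implicit`` stepper solves

    (eta*M + dt*B) delta = -dt * (g - lambda * a)

per step, where B is the bending stiffness linearized at the flat state; it
is a consistent first-order integrator of the same flow that remains stable
at timesteps far above the explicit bound, which is what makes desk-scale
runs of stiff, finely meshed patches practical.  Both steppers accept a step
only if the discrete energy does not increase (backtracking on dt), so
energy descent holds along every accepted trajectory.

Physical time is integrated in units of eta*nm^4/k_BT; the module constant
``DEFAULT_MS_PER_TIME`` converts it to milliseconds.  It was calibrated once
so that the nominal three-vesicle scenario first satisfies the pit-curvature
criterion near 30 ms, and is held fixed for every other scenario.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .energy import (
    EnergyBreakdown,
    ModelParams,
    area_gradient,
    energy_gradient,
    project_tension,
    total_energy,
)
from .errors import ConfigurationError, NumericalFailureError, StagnationError
from .mesh import VESICLE_BASE, SurfaceMesh, surface_area

log = logging.getLogger(__name__)

#: milliseconds per simulation time unit (eta*nm^4/k_BT), fixed by the
#: one-time calibration of the nominal three-vesicle run (pit criterion
#: first met near 30 ms).
DEFAULT_MS_PER_TIME = 2.237e-3

# events -----------------------------------------------------------------------

RELEASE_AREA_CONSERVATION = "RELEASE_AREA_CONSERVATION"
RESUME_AREA_CONSERVATION = "RESUME_AREA_CONSERVATION"
FUSE_VESICLE = "FUSE_VESICLE"


@dataclass
class Event:
    """Mid-run state change.

    Triggered either at a calibrated time (``time_ms``) or when the apex
    height of vesicle ``watch_vesicle`` first drops below
    ``depth_trigger_nm``.  Each event fires at most once.

    ``uniform_kappa`` is the soft modulus assigned to the active and
    periactive zones on RELEASE (None keeps the current moduli);
    ``vesicle`` is the dome specification for FUSE_VESICLE.
    """

    kind: str
    time_ms: float | None = None
    depth_trigger_nm: float | None = None
    watch_vesicle: int = 0
    uniform_kappa: float | None = 20.0
    vesicle: object = None
    fired: bool = field(default=False, compare=False)

    def __post_init__(self):
        if self.kind not in (RELEASE_AREA_CONSERVATION, RESUME_AREA_CONSERVATION, FUSE_VESICLE):
            raise ConfigurationError(f"unknown event kind {self.kind!r}")
        if (self.time_ms is None) == (self.depth_trigger_nm is None):
            raise ConfigurationError("event needs exactly one of time_ms / depth_trigger_nm")


@dataclass
class StopCriteria:
    """Stopping rule for :func:`run`: hard time limit plus steady-state
    detection (relative energy change below ``eps_E`` across a window of
    ``window`` accepted steps)."""

    t_max_ms: float = 120.0
    eps_E: float = 1e-8
    window: int = 200


@dataclass
class SimState:
    """Evolving simulation state."""

    mesh: SurfaceMesh
    params: ModelParams
    time: float = 0.0  # units of eta*nm^4/k_BT
    area_target: float = 0.0
    conservation_on: bool = True
    step_count: int = 0
    tension: float = 0.0
    energy: EnergyBreakdown = None
    ms_per_time: float = DEFAULT_MS_PER_TIME

    def __post_init__(self):
        if self.energy is None:
            self.energy = total_energy(self.mesh, self.params)
        if self.area_target == 0.0:
            self.area_target = surface_area(self.mesh)

    @property
    def time_ms(self) -> float:
        return self.time * self.ms_per_time

    def vesicle_apex_depths(self) -> dict[int, float]:
        """Current apex height (nm) of each fused-vesicle dome."""
        out = {}
        labels = self.mesh.material_label
        for lab in np.unique(labels[labels >= VESICLE_BASE]):
            verts = np.unique(self.mesh.faces[labels == lab])
            out[int(lab - VESICLE_BASE)] = float(self.mesh.height[verts].max())
        return out


# timestep ----------------------------------------------------------------------

def adaptive_timestep(state: SimState, safety: float = 0.1) -> float:
    """Explicit stability bound dt = safety * eta * l_min^4 / kappa_max.

    l_min is the smallest embedded edge length, so as elements shrink during
    shape change the admissible step shrinks with the fourth power (explicit
    biharmonic scaling).  Backtracking in the stepper additionally halves dt
    until the trial step is energy-non-increasing.
    """
    l_min = state.mesh.embedded_edge_min()
    p = state.params
    kappa_max = max(p.kappa1, p.kappa2, p.kappa3)
    return safety * p.eta * l_min ** 4 / kappa_max


# area constraint ----------------------------------------------------------------

def _rescale_to_area(mesh: SurfaceMesh, area_target: float, rtol: float = 1e-12) -> float:
    """Scale the free heights uniformly so the total area matches the target.

    Area is strictly increasing in the scale factor (for non-flat fields);
    a bracketed secant converges in a few iterations.  Returns the factor.
    """
    free = ~mesh.pinned_mask
    h0 = mesh.height.copy()

    def area_of(scale):
        h = h0.copy()
        h[free] = scale * h0[free]
        return mesh.face_area_embedded(h).sum()

    s0, s1 = 1.0, 1.0
    f1 = area_of(1.0) - area_target
    if abs(f1) <= rtol * area_target:
        return 1.0
    s0, f0 = 1.0, f1
    s1 = 1.0 + (0.01 if f1 < 0 else -0.01)
    for _ in range(100):
        f1 = area_of(s1) - area_target
        if abs(f1) <= rtol * area_target:
            break
        if f1 == f0:
            raise NumericalFailureError("area rescaling stalled (flat surface?)")
        s0, s1, f0 = s1, s1 - f1 * (s1 - s0) / (f1 - f0), f1
        s1 = min(max(s1, 0.0), 1e3)
    else:
        raise NumericalFailureError("area rescaling did not converge")
    mesh.height[free] = s1 * h0[free]
    return s1


def _constrained_update(mesh: SurfaceMesh, descent: np.ndarray, area_dir: np.ndarray,
                        lam0: float, area_target: float, free_idx: np.ndarray) -> float:
    """Apply h <- clamp(h + descent + lam*area_dir) with the tension lam
    chosen so the clamped update conserves the total area.

    Solving for lam *through* the inward-only clamp (rather than clamping
    after a linear projection) keeps the multiplier consistent with the
    active constraint set, which is what makes the descent property hold
    near the clamp.  A uniform-rescale polish removes the residual.
    """
    h0 = mesh.height.copy()

    def apply(lam):
        h = h0.copy()
        h[free_idx] += descent + lam * area_dir
        np.maximum(h, 0.0, out=h)
        return h

    def f(lam):
        return mesh.face_area_embedded(apply(lam)).sum() - area_target

    lo = hi = lam0
    flo = fhi = f(lam0)
    span = max(abs(lam0), 1e-8)
    # expand a bracket around the linear-projection estimate
    for _ in range(80):
        if flo <= 0.0 <= fhi or flo >= 0.0 >= fhi:
            break
        if abs(flo) < abs(fhi):
            lo -= span
            flo = f(lo)
        else:
            hi += span
            fhi = f(hi)
        span *= 2.0
    if not (min(flo, fhi) <= 0.0 <= max(flo, fhi)):
        # target area unreachable within this step (e.g. near-flat start with
        # a large area deficit): take the closer end; the uniform rescale
        # below closes the remaining gap and the energy check arbitrates
        lam = lo if abs(flo) < abs(fhi) else hi
        mesh.height[:] = apply(lam)
        mesh.height[mesh.pinned_mask] = 0.0
        _rescale_to_area(mesh, area_target)
        return lam
    if lo == hi:
        lam = lo
    else:
        from scipy.optimize import brentq

        lam = brentq(f, min(lo, hi), max(lo, hi), xtol=1e-12 * max(abs(lo), abs(hi), 1e-6),
                     rtol=8.9e-16, maxiter=100)
    mesh.height[:] = apply(lam)
    mesh.height[mesh.pinned_mask] = 0.0
    _rescale_to_area(mesh, area_target)
    return lam


# steppers ----------------------------------------------------------------------

def step(state: SimState, dt: float) -> SimState:
    """One explicit descent step: h += dt * direction / (eta * a_v), then the
    inward-only clamp and (if conservation is on) the exact area correction.

    Mutates and returns ``state``; energy is recomputed.
    """
    mesh = state.mesh
    g = energy_gradient(mesh, state.params)
    a = area_gradient(mesh)
    free_idx = np.where(~mesh.pinned_mask)[0]
    mobility = dt / (state.params.eta * mesh.vertex_reference_area[free_idx])
    if state.conservation_on:
        lam0, _ = project_tension(g, a, mesh, state.params.eta)
        lam = _constrained_update(
            mesh, -g[free_idx] * mobility, a[free_idx] * mobility, lam0,
            state.area_target, free_idx,
        )
    else:
        lam = 0.0
        mesh.height[free_idx] -= g[free_idx] * mobility
        np.maximum(mesh.height, 0.0, out=mesh.height)
        mesh.height[mesh.pinned_mask] = 0.0
    if not np.all(np.isfinite(mesh.height)):
        raise NumericalFailureError("non-finite heights after step")
    state.tension = lam
    state.time += dt
    state.step_count += 1
    state.energy = total_energy(mesh, state.params, tension_lambda=lam)
    return state


class _SemiImplicitStepper:
    """Factorized (eta*M + dt*B) solver; rebuilt when dt or moduli change."""

    def __init__(self, state: SimState):
        self.state = state
        self._solve = None
        self._dt = None
        self._cache = {}
        self._build_stiffness()

    def _build_stiffness(self):
        mesh = self.state.mesh
        ops = mesh.ops
        p = self.state.params
        # reference-plane stiffness  L = G^T A G  and the linearized bending
        # Hessian  B = L^T diag(kappa_v / a_v) L  (kappa_v: stiffest incident
        # face, scaled by the metric factor beta^3 of the current slopes --
        # steep regions are effectively much stiffer than the flat-state
        # linearization, and underestimating them collapses the usable dt)
        A = sp.diags(ops.ref_face_area)
        L = (ops.Gx.T @ A @ ops.Gx + ops.Gy.T @ A @ ops.Gy).tocsr()
        px, py = mesh.face_slopes()
        # capped: the initial dome rims are near-vertical and would otherwise
        # freeze their vertices in the preconditioner
        beta3 = np.minimum((1.0 + px * px + py * py) ** 1.5, 10.0)
        kappa_f = p.face_kappa(mesh.material_label) * beta3
        kv = np.zeros(mesh.n_vertices)
        np.maximum.at(kv, mesh.faces.ravel(), np.repeat(kappa_f, 3))
        self._beta_ref = float(beta3.max())
        B = (L.T @ sp.diags(kv / ops.vertex_ref_area) @ L).tocsr()
        free = ~mesh.pinned_mask
        self._free = np.where(free)[0]
        self._B = B[self._free][:, self._free].tocsc()
        # tension stiffness (surface-tension-like, lambda * k^2): included
        # implicitly with the current quantized tension so the admissible
        # step is not capped at dt ~ eta/(lambda k_max^2)
        self._L = L[self._free][:, self._free].tocsc()
        self._M = p.eta * ops.vertex_ref_area[self._free]
        self._lam_quant = 0.0
        self._dt = None  # force refactor
        self._cache.clear()

    def invalidate(self):
        """Call after moduli or mesh labels change."""
        self._build_stiffness()

    def maybe_refresh(self):
        """Rebuild the stiffness when the slope metric has drifted."""
        px, py = self.state.mesh.face_slopes()
        b3 = float(((1.0 + px * px + py * py) ** 1.5).max())
        if b3 > 2.0 * self._beta_ref or b3 < 0.5 * self._beta_ref:
            self._build_stiffness()

    def update_tension(self, lam: float):
        """Quantize the tension used in the implicit operator (powers of 4,
        zero below a threshold) to keep the factorization cache small."""
        if lam <= 1e-4:
            q = 0.0
        else:
            q = 4.0 ** np.ceil(np.log2(lam) / 2.0)
        if q != self._lam_quant:
            self._lam_quant = q
            self._dt = None

    def _factorize(self, dt):
        key = (dt, self._lam_quant)
        if key not in self._cache:
            if len(self._cache) > 40:
                self._cache.clear()
            P = sp.diags(self._M) + dt * (self._B + self._lam_quant * self._L)
            self._cache[key] = spla.factorized(P.tocsc())
        self._solve = self._cache[key]
        self._dt = dt

    def apply(self, dt: float):
        """One constrained semi-implicit update of the mesh heights.

        Returns ``(lambda, predicted_decrease)``: the tension and the
        first-order energy decrease g . dh of the move actually applied
        (diagnostic for the dt controller)."""
        self.update_tension(self.state.tension)
        if dt != self._dt:
            self._factorize(dt)
        state = self.state
        mesh = state.mesh
        h_before = mesh.height.copy()
        g = energy_gradient(mesh, state.params)[self._free]
        x = self._solve(g)
        if state.conservation_on:
            a = area_gradient(mesh)[self._free]
            y = self._solve(a)
            denom = float(a @ y)
            lam0 = float(a @ x) / denom if denom != 0 else 0.0
            lam = _constrained_update(
                mesh, -dt * x, dt * y, lam0, state.area_target, self._free
            )
        else:
            lam = 0.0
            mesh.height[self._free] -= dt * x
            np.maximum(mesh.height, 0.0, out=mesh.height)
            mesh.height[mesh.pinned_mask] = 0.0
        pred = float(g @ (mesh.height[self._free] - h_before[self._free]))
        return lam, pred


# run loop -----------------------------------------------------------------------

def run(
    state: SimState,
    events: list[Event] | None = None,
    stop: StopCriteria | None = None,
    method: str = "semi_implicit",
    trace_callback: Callable | None = None,
    dt_growth_every: int = 3,
    dt_max_frac: float | None = None,
    pit_delta_nm: float = 2.0,
    pit_every: int = 1,
) -> tuple[pd.DataFrame, SimState]:
    """Integrate to steady state or ``t_max``, firing events on the way.

    Returns the per-accepted-step trace and the final state.  The trace
    carries the energy breakdown, area error, tension, per-vesicle apex
    depths and running pit metrics (depth, curvature, count).
    """
    from . import pits as pits_mod

    events = list(events or [])
    stop = stop or StopCriteria()
    t_max = stop.t_max_ms / state.ms_per_time
    mesh = state.mesh

    descent_tol = 1e-10
    dt0 = adaptive_timestep(state)
    stepper = _SemiImplicitStepper(state) if method == "semi_implicit" else None
    if method not in ("semi_implicit", "explicit"):
        raise ConfigurationError(f"unknown integration method {method!r}")
    # the semi-implicit stepper is stable far above the explicit bound;
    # start moderately above it and let backtracking correct
    dt = dt0 if method == "explicit" else 64.0 * dt0

    rows = []
    e_hist = []
    t_hist = []
    accept_streak = 0
    last_probe_step = -10**9
    stop_reason = "t_max"

    def pending_time_events():
        return [e for e in events if not e.fired and e.time_ms is not None]

    r_interface = pits_mod.interface_radius(mesh)
    pit_cache = {"n": 0, "report": None}

    def record():
        apexes = state.vesicle_apex_depths()
        if pit_cache["report"] is None or pit_cache["n"] % max(pit_every, 1) == 0:
            pit_cache["report"] = pits_mod.detect_pits(
                state, delta_pit=pit_delta_nm, r_interface=r_interface
            )
        pit_cache["n"] += 1
        report = pit_cache["report"]
        area = surface_area(mesh)
        row = {
            "step": state.step_count,
            "time": state.time,
            "time_ms": state.time_ms,
            "dt": dt,
            "E_total": state.energy.total,
            "E_bend_vesicle": state.energy.bending_per_domain.get("vesicle", 0.0),
            "E_bend_az": state.energy.bending_per_domain.get("active_zone", 0.0),
            "E_bend_paz": state.energy.bending_per_domain.get("periactive", 0.0),
            "E_pressure": state.energy.pressure_term,
            "lambda": state.tension,
            "area": area,
            "area_error": abs(area - state.area_target) / state.area_target
            if state.conservation_on
            else np.nan,
            "max_pit_depth": max((p.max_depth for p in report.pits), default=0.0),
            "max_pit_curvature": max((p.max_mean_curvature for p in report.pits), default=0.0),
            "n_pits": report.count,
        }
        for i, d in apexes.items():
            row[f"apex_depth_{i}"] = d
        rows.append(row)
        if trace_callback is not None:
            trace_callback(state, row)

    record()  # initial condition

    while state.time < t_max:
        # fire due events
        fired_any = False
        apexes = None
        for ev in events:
            if ev.fired:
                continue
            due = False
            if ev.time_ms is not None:
                due = state.time_ms >= ev.time_ms - 1e-12
            else:
                if apexes is None:
                    apexes = state.vesicle_apex_depths()
                depth = apexes.get(ev.watch_vesicle)
                due = depth is not None and depth <= ev.depth_trigger_nm
            if due:
                apply_event(state, ev)
                fired_any = True
        if fired_any and stepper is not None:
            stepper.invalidate()
            e_hist.clear()
            t_hist.clear()

        # cap dt: scheduled events are hit closely, and the step never
        # exceeds a fraction of the elapsed time (logarithmic resolution of
        # the relaxation trajectory -- backtracking enforces descent but not
        # fidelity, and quasi-Newton-sized steps can hop over transients)
        dt_cap = t_max - state.time
        if dt_max_frac is not None:
            dt_cap = min(dt_cap, max(64.0 * dt0, dt_max_frac * state.time))
        for ev in pending_time_events():
            dt_cap = min(dt_cap, max(ev.time_ms / state.ms_per_time - state.time, dt0))
        dt_try = min(dt, dt_cap)

        # trial / backtracking loop
        h_before = mesh.height.copy()
        e_before = state.energy.total
        accepted = False
        for _ in range(60):
            if method == "explicit":
                bound = adaptive_timestep(state)
                dt_try = min(dt_try, bound)
                step(state, dt_try)
            else:
                lam, pred = stepper.apply(dt_try)
                state.tension = lam
                state.time += dt_try
                state.step_count += 1
                state.energy = total_energy(mesh, state.params, tension_lambda=lam)
            e_after = state.energy.total
            if e_after <= e_before + descent_tol * abs(e_before):
                accepted = True
                break
            # reject: restore and halve dt
            mesh.height[:] = h_before
            state.time -= dt_try
            state.step_count -= 1
            dt_try *= 0.5
            if dt_try < 1e-12 * dt0:
                # no admissible descent left.  At the discrete minimum the
                # achievable decrease drops below the arithmetic noise of the
                # constraint projection; a flat recent energy history
                # distinguishes convergence from a genuine failure.
                w = min(len(e_hist), stop.window)
                if w >= 5 and abs(e_hist[-1] - e_hist[-w]) <= 1e-5 * max(abs(e_hist[-1]), 1e-30):
                    break
                raise StagnationError(
                    "timestep underflow during backtracking",
                    diagnostics={"time": state.time, "energy": e_before},
                )
        if not accepted:
            state.energy = total_energy(mesh, state.params, tension_lambda=state.tension)
            stop_reason = "gradient_floor"
            break

        dt = dt_try
        if stepper is not None and state.step_count % 50 == 0:
            stepper.maybe_refresh()
        # dt controller: grow on clean streaks; shrink when the realized
        # decrease is far below the first-order prediction (the constraint
        # projection is cancelling the move -- a large-dt stall, not a minimum)
        stalled = (
            method == "semi_implicit"
            and pred < -1e-14 * max(abs(e_before), 1.0)
            and (e_before - state.energy.total) < 0.02 * (-pred)
        )
        accept_streak += 1
        if stalled and dt > 4.0 * dt0:
            dt *= 0.5
            accept_streak = 0
        elif accept_streak >= dt_growth_every:
            dt *= 2.0
            accept_streak = 0
        record()

        # steady-state detection (suspended while time events are pending).
        # The window must also span a finite fraction of the elapsed time:
        # an adaptive-dt flow can crawl (tiny dt, tiny dE per step) without
        # being anywhere near its minimum.
        e_hist.append(state.energy.total)
        t_hist.append(state.time)
        if not pending_time_events() and len(e_hist) > stop.window:
            e_old = e_hist[-1 - stop.window]
            span_ok = t_hist[-1] - t_hist[-1 - stop.window] >= 0.05 * t_hist[-1]
            if span_ok and abs(e_hist[-1] - e_old) <= stop.eps_E * max(abs(e_hist[-1]), 1e-30):
                stop_reason = "steady_state"
                break

    trace = pd.DataFrame(rows)
    trace.attrs["stop_reason"] = stop_reason
    return trace, state


# events -------------------------------------------------------------------------

def apply_event(state: SimState, event: Event) -> SimState:
    """Fire an event: release/resume area conservation or fuse a vesicle."""
    if event.kind == RELEASE_AREA_CONSERVATION:
        state.conservation_on = False
        if event.uniform_kappa is not None:
            state.params = replace(
                state.params, kappa2=event.uniform_kappa, kappa3=event.uniform_kappa
            )
        log.info("event RELEASE at t=%.3g ms (uniform kappa=%s)", state.time_ms, event.uniform_kappa)
    elif event.kind == RESUME_AREA_CONSERVATION:
        state.area_target = surface_area(state.mesh)
        state.conservation_on = True
        log.info("event RESUME at t=%.3g ms (A0=%.6g nm^2)", state.time_ms, state.area_target)
    elif event.kind == FUSE_VESICLE:
        from .scenarios import imprint_vesicle

        area_before = surface_area(state.mesh)
        imprint_vesicle(state.mesh, event.vesicle)
        area_after = surface_area(state.mesh)
        if state.conservation_on:
            state.area_target += area_after - area_before
        log.info(
            "event FUSE at t=%.3g ms (+%.4g nm^2 membrane)",
            state.time_ms,
            area_after - area_before,
        )
    event.fired = True
    state.energy = total_energy(state.mesh, state.params, tension_lambda=state.tension)
    return state
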