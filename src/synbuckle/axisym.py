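"""Independent 1D axisymmetric minimizer for a single centered vesicle.

This is the internal brute-force oracle for the 2D solver: the same
Helfrich-like energy (bending with domain-wise moduli + osmotic pressure),
the same constraints (total surface-of-revolution area conserved via a
tension multiplier, pinned rim, inward-only heights), reduced to a radial
profile h(r) on a dense 1D grid.  With node spacings well below the 2D
target edge length its discretization error is negligible relative to the
2D solver's, so steady-state energies and apex depths of the two solvers
can be compared directly.

Discretization: piecewise-linear h(r); segment areas are exact frustum
areas of the revolved surface; mean curvature is the exact gradient of the
discrete area divided by twice the lumped radial mass (the same
area-gradient convention as the 2D solver); gradients of the discrete
energy are exact (hand-written chain rule), so the minimizer uses the same
backtracking semi-implicit descent as the 2D code.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .energy import EnergyBreakdown, ModelParams
from .errors import NumericalFailureError, StagnationError
from .scenarios import dome_profile


@dataclass
class RadialProfile:
    """Axisymmetric height profile on radial nodes 0..rim (nm)."""

    r: np.ndarray  # (M+1,) strictly increasing, r[0] = 0
    h: np.ndarray  # (M+1,) heights, >= 0, h[-1] = 0 (pinned rim)
    params: ModelParams
    vesicle_rim: float  # nm; material breakpoint r < a -> vesicle modulus
    az_radius: float  # nm; a <= r < L/2 -> active zone, beyond -> periactive

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.r[0] != 0 or np.any(np.diff(self.r) <= 0):
            raise ValueError("radial nodes must start at 0 and increase")

    def copy(self):
        return RadialProfile(self.r.copy(), self.h.copy(), self.params,
                             self.vesicle_rim, self.az_radius)


def uniform_profile(rim: float, dr: float, params: ModelParams,
                    vesicle_rim: float, az_radius: float,
                    apex_depth: float = 0.0) -> RadialProfile:
    """Dense uniform grid (dr <= 0.25 nm recommended) with an optional
    spherical-cap dome of the given apex depth imprinted at the center."""
    n = max(8, int(round(rim / dr)))
    r = np.linspace(0.0, rim, n + 1)
    h = np.zeros_like(r)
    if apex_depth > 0:
        prof, _ = dome_profile(apex_depth, vesicle_rim)
        h = prof(r)
    h[-1] = 0.0
    return RadialProfile(r, h, params, vesicle_rim, az_radius)


# -- discrete geometry ----------------------------------------------------------

def _segment_quantities(r, h):
    dr = np.diff(r)
    rm = 0.5 * (r[:-1] + r[1:])
    p = np.diff(h) / dr
    beta = np.sqrt(1.0 + p * p)
    seg_area = 2.0 * np.pi * rm * dr * beta  # exact frustum area
    return dr, rm, p, beta, seg_area


def radial_mass(r) -> np.ndarray:
    """Lumped node masses: exact hat-function integrals of 2*pi*r dr."""
    d = np.diff(r)
    m = np.zeros_like(r)
    # left-sided piece of node j+1 over [r_j, r_{j+1}]
    m[1:] += 2.0 * np.pi * (r[:-1] * d / 2.0 + d * d / 3.0)
    # right-sided piece of node j over [r_j, r_{j+1}]
    m[:-1] += 2.0 * np.pi * (r[:-1] * d / 2.0 + d * d / 6.0)
    return m


def curvature_mass(r) -> np.ndarray:
    """Node masses for the curvature estimate Omega = (dA/dh) / (2 m).

    Identical to :func:`radial_mass` except on the symmetry axis, where
    pi dr^2 / 4 (not the hat integral pi dr^2 / 3) makes the estimator exact
    for a parabolic cap; without it the axis node reads 3/4 of the true
    curvature."""
    m = radial_mass(r)
    m[0] = np.pi * (r[1] - r[0]) ** 2 / 4.0
    return m


def profile_area(profile: RadialProfile) -> float:
    """Total revolved surface area, nm^2."""
    return float(_segment_quantities(profile.r, profile.h)[4].sum())


def profile_volume(profile: RadialProfile) -> float:
    """Enclosed volume between the profile and the flat baseline, nm^3."""
    return float(radial_mass(profile.r) @ profile.h)


def area_gradient_1d(profile: RadialProfile) -> np.ndarray:
    dr, rm, p, beta, _ = _segment_quantities(profile.r, profile.h)
    q = 2.0 * np.pi * rm * p / beta
    w = np.zeros_like(profile.h)
    w[:-1] -= q
    w[1:] += q
    return w


def mean_curvature_1d(profile: RadialProfile) -> np.ndarray:
    """Node mean curvature (area-gradient convention, positive toward the
    cytoplasm for a dome); the pinned rim reports 0."""
    w = area_gradient_1d(profile)
    omega = w / (2.0 * curvature_mass(profile.r))
    omega[-1] = 0.0
    return omega


def _segment_kappa(profile: RadialProfile) -> np.ndarray:
    rm = 0.5 * (profile.r[:-1] + profile.r[1:])
    p = profile.params
    kappa = np.full(rm.shape, p.kappa2)
    kappa[rm < profile.vesicle_rim] = p.kappa1
    kappa[rm >= profile.az_radius] = p.kappa3
    return kappa


def profile_energy(profile: RadialProfile, tension_lambda: float = 0.0) -> EnergyBreakdown:
    """Energy breakdown of the axisymmetric profile."""
    par = profile.params
    dr, rm, p, beta, seg_area = _segment_quantities(profile.r, profile.h)
    omega = mean_curvature_1d(profile)
    u = (omega - par.omega0) ** 2
    u[-1] = 0.0
    kappa = _segment_kappa(profile)
    # spread each segment's area over its non-rim nodes
    n_int = np.full(len(rm), 2.0)
    n_int[-1] = 1.0
    e_seg = 2.0 * kappa * seg_area * (u[:-1] + u[1:]) / n_int
    groups = np.full(len(rm), 1)
    groups[rm < profile.vesicle_rim] = 0
    groups[rm >= profile.az_radius] = 2
    sums = np.bincount(groups, weights=e_seg, minlength=3)
    press = par.Pi * profile_volume(profile)
    bend = {"vesicle": float(sums[0]), "active_zone": float(sums[1]), "periactive": float(sums[2])}
    return EnergyBreakdown(
        bending_per_domain=bend,
        pressure_term=press,
        total=float(sums.sum()) + press,
        tension_lambda=tension_lambda,
    )


def energy_gradient_1d(profile: RadialProfile) -> np.ndarray:
    """Exact gradient of the discrete 1D energy w.r.t. node heights
    (zero at the pinned rim)."""
    par = profile.params
    r, h = profile.r, profile.h
    dr, rm, p, beta, seg_area = _segment_quantities(r, h)
    mass = curvature_mass(r)
    w = area_gradient_1d(profile)
    omega = w / (2.0 * mass)
    omega[-1] = 0.0
    u = (omega - par.omega0) ** 2
    u[-1] = 0.0
    kappa = _segment_kappa(profile)
    n_int = np.full(len(rm), 2.0)
    n_int[-1] = 1.0
    c_seg = 2.0 * kappa * seg_area / n_int  # weight of each node's u

    # rho_j = dE/du_j: sum of adjacent segment weights (rim excluded)
    rho = np.zeros_like(h)
    rho[:-1] += c_seg
    rho[1:] += c_seg
    rho[-1] = 0.0
    omega_bar = 2.0 * (omega - par.omega0) * rho
    omega_bar[-1] = 0.0
    w_bar = omega_bar / (2.0 * mass)

    # w = scatter(+-q), q_j = 2 pi rm_j p_j / beta_j
    q_bar = w_bar[1:] - w_bar[:-1]
    # segment-area adjoint from the energy weights c_seg
    u_pair = u[:-1] + u[1:]
    seg_area_bar = 2.0 * kappa * u_pair / n_int
    beta_bar = 2.0 * np.pi * rm * dr * seg_area_bar
    p_bar = 2.0 * np.pi * rm * q_bar / beta ** 3 + beta_bar * p / beta

    grad = np.zeros_like(h)
    grad[1:] += p_bar / dr
    grad[:-1] -= p_bar / dr
    grad += par.Pi * radial_mass(r)
    grad[-1] = 0.0
    if not np.all(np.isfinite(grad)):
        raise NumericalFailureError("non-finite 1D gradient")
    return grad


# -- minimization -----------------------------------------------------------------

def minimize_axisymmetric(
    profile: RadialProfile,
    constraint_on: bool = True,
    max_steps: int = 20000,
    eps_E: float = 1e-10,
    window: int = 200,
) -> tuple[RadialProfile, EnergyBreakdown]:
    """Minimize the axisymmetric energy under the same constraints as the
    2D solver (area conservation via tension, pinned rim, h >= 0).

    Returns the relaxed profile and its energy breakdown.
    """
    prof = profile.copy()
    r, h = prof.r, prof.h
    n = len(h)
    mass = radial_mass(r)
    m_curv = curvature_mass(r)
    area_target = profile_area(prof)

    # linearized stiffness for the semi-implicit operator
    dr = np.diff(r)
    rm = 0.5 * (r[:-1] + r[1:])
    rows, cols, vals = [], [], []
    coef = 2.0 * np.pi * rm / dr
    for j in range(n - 1):
        for (ri, si) in ((j, -1.0), (j + 1, 1.0)):
            for (rj, sj) in ((j, -1.0), (j + 1, 1.0)):
                rows.append(ri)
                cols.append(rj)
                vals.append(coef[j] * si * sj)
    L1 = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    kappa_seg = _segment_kappa(prof)
    kv = np.zeros(n)
    np.maximum.at(kv, np.arange(n - 1), kappa_seg)
    np.maximum.at(kv, np.arange(1, n), kappa_seg)
    B = (L1.T @ sp.diags(kv / m_curv) @ L1).tocsr()
    free = np.arange(n - 1)  # rim pinned
    Bf = B[free][:, free].tocsc()
    Lf = L1[free][:, free].tocsc()
    Mf = prof.params.eta * mass[free]

    cache = {}

    def solver(dt, lam_q):
        key = (dt, lam_q)
        if key not in cache:
            if len(cache) > 40:
                cache.clear()
            cache[key] = spla.factorized((sp.diags(Mf) + dt * (Bf + lam_q * Lf)).tocsc())
        return cache[key]

    def area_of(hh):
        return _segment_quantities(r, hh)[4].sum()

    e_prev = profile_energy(prof).total
    dt = 0.1 * prof.params.eta * dr.min() ** 4 / kv.max() * 64.0
    lam = 0.0
    e_hist = []
    streak = 0
    for it in range(max_steps):
        g = energy_gradient_1d(prof)[free]
        lam_q = 0.0 if lam <= 1e-4 else 4.0 ** np.ceil(np.log2(lam) / 2.0)
        solve = solver(dt, lam_q)
        x = solve(g)
        accepted = False
        for _ in range(60):
            if constraint_on:
                a = area_gradient_1d(prof)[free]
                y = solve(a)
                denom = float(a @ y)
                lam0 = float(a @ x) / denom if denom != 0 else 0.0

                def clamped(lmb):
                    hh = h.copy()
                    hh[free] += dt * (-x + lmb * y)
                    return np.maximum(hh, 0.0)

                lo = hi = lam0
                flo = fhi = area_of(clamped(lam0)) - area_target
                span = max(abs(lam0), 1e-8)
                for _k in range(80):
                    if min(flo, fhi) <= 0.0 <= max(flo, fhi):
                        break
                    if abs(flo) < abs(fhi):
                        lo -= span
                        flo = area_of(clamped(lo)) - area_target
                    else:
                        hi += span
                        fhi = area_of(clamped(hi)) - area_target
                    span *= 2.0
                if fhi < flo:
                    lo, hi = hi, lo
                lam_new = lam0
                for _k in range(80):
                    lam_new = 0.5 * (lo + hi)
                    fm = area_of(clamped(lam_new)) - area_target
                    if abs(fm) <= 1e-10 * area_target:
                        break
                    if fm < 0.0:
                        lo = lam_new
                    else:
                        hi = lam_new
                h_new = clamped(lam_new)
            else:
                lam_new = 0.0
                h_new = h.copy()
                h_new[free] -= dt * x
                np.maximum(h_new, 0.0, out=h_new)
            h_new[-1] = 0.0
            e_new = profile_energy(
                RadialProfile(r, h_new, prof.params, prof.vesicle_rim, prof.az_radius)
            ).total
            if e_new <= e_prev + 1e-11 * abs(e_prev):
                accepted = True
                break
            dt *= 0.5
            solve = solver(dt, lam_q)
            x = solve(g)
            if dt < 1e-15:
                raise StagnationError("1D minimizer timestep underflow")
        if not accepted:
            break
        h[:] = h_new
        prof.h = h
        e_prev = e_new
        lam = lam_new
        streak += 1
        if streak >= 3:
            dt *= 2.0
            streak = 0
        e_hist.append(e_new)
        if len(e_hist) > window:
            if abs(e_hist[-1] - e_hist[-1 - window]) <= eps_E * max(abs(e_new), 1e-30):
                break
    return prof, profile_energy(prof, tension_lambda=lam)
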