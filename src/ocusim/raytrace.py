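"""Exact sequential 3-D raytracing.

Kernels: conic-asphere sag and Newton intersection, vector Snell refraction,
fixed-step RK4 integration of the gradient-index ray equation
d/ds (n dr/ds) = grad n, rigid-body element transforms, and an iterative
stop-plane aiming solver.  Everything is vectorized over bundles of rays
stored as (N, 3) position/direction arrays with per-ray accumulated optical
path (n * ds, in mm) and an ``alive`` mask; vignetted rays stay in the arrays
but are excluded from all downstream statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .eye_model import (ConicSurface, EyeSystem, GeometryError, Medium,
                        MisalignmentState, OpticalElement)

log = logging.getLogger(__name__)

GRIN_STEP_MM = 0.01          # default RK4 arc-length step inside GRIN media
_NEWTON_TOL_MM = 1e-10
_NEWTON_MAX_ITER = 50
_AIM_TOL_MM = 1e-9


@dataclass
class Ray:
    """A single ray: position (mm), unit direction, optical path (um)."""

    position: np.ndarray
    direction: np.ndarray
    optical_path_um: float = 0.0
    alive: bool = True


@dataclass
class TraceResult:
    """Outcome of tracing a bundle through a system.

    ``exit_*`` arrays hold the ray state just after the last element (before
    the final propagation to the image plane); ``image_*`` are filled when the
    system has an image plane.  ``surface_points`` (optional) records the
    intersection points per surface for debugging.
    """

    exit_positions: np.ndarray
    exit_directions: np.ndarray
    exit_opl_mm: np.ndarray
    alive: np.ndarray
    n_image: float
    image_positions: np.ndarray | None = None
    image_opl_mm: np.ndarray | None = None
    surface_points: list = field(default_factory=list)

    @property
    def n_launched(self) -> int:
        return int(self.alive.size)

    @property
    def n_vignetted(self) -> int:
        return int(self.alive.size - np.count_nonzero(self.alive))

    def propagate_to_plane(self, z_mm: float) -> tuple[np.ndarray, np.ndarray]:
        """Extend the exit rays to the plane ``z = z_mm``.

        Returns (points (N,3), optical path in mm at the plane).  Cheap: used
        by the best-focus search to move the image plane without re-tracing.
        """
        t = (z_mm - self.exit_positions[:, 2]) / self.exit_directions[:, 2]
        pts = self.exit_positions + t[:, None] * self.exit_directions
        return pts, self.exit_opl_mm + self.n_image * t


# ---------------------------------------------------------------------------
# Surface kernels
# ---------------------------------------------------------------------------

def sag(surface: ConicSurface, r):
    """Surface sag z(r) (mm) relative to the vertex; raises on domain error."""
    r = np.asarray(r, dtype=float)
    c, q = surface.curvature, surface.conic
    arg = 1.0 - (1.0 + q) * c * c * r * r
    if np.any(arg <= 0.0):
        raise GeometryError(
            f"sag undefined at r={float(np.max(r)):.4f} mm for surface "
            f"R={surface.radius_mm} mm, Q={q}")
    base = c * r * r / (1.0 + np.sqrt(arg))
    return base + surface.a4 * r ** 4 + surface.a6 * r ** 6


def _sag_safe(surface: ConicSurface, r_sq):
    """Vectorized sag and radial slope, clipped outside the conic domain.

    Returns (sag, dz/dr / r, valid): the slope is returned divided by r so
    the r -> 0 limit is regular.  Out-of-domain samples are flagged invalid
    (they can only occur beyond the clear aperture and end up vignetted).
    """
    c, q = surface.curvature, surface.conic
    arg = 1.0 - (1.0 + q) * c * c * r_sq
    valid = arg > 1e-14
    arg = np.where(valid, arg, 1e-14)
    root = np.sqrt(arg)
    z = c * r_sq / (1.0 + root) + surface.a4 * r_sq ** 2 + surface.a6 * r_sq ** 3
    slope_over_r = c / root + 4.0 * surface.a4 * r_sq + 6.0 * surface.a6 * r_sq ** 2
    return z, slope_over_r, valid


def intersect_conic(p: np.ndarray, u: np.ndarray, surface: ConicSurface):
    """Newton intersection of rays (p, u) with a conic-asphere surface.

    Starts from the vertex-plane intersection and iterates on the path
    parameter t with f(t) = z(t) - vertex - sag(r(t)) until |f| < 1e-10 mm.
    Returns (points (N,3), unit normals (N,3), ok mask); rays that do not
    converge or land outside the semi-aperture are flagged not-ok.
    """
    p = np.atleast_2d(p)
    u = np.atleast_2d(u)
    zv = surface.vertex_z_mm
    t = (zv - p[:, 2]) / u[:, 2]
    ok = np.isfinite(t)
    for _ in range(_NEWTON_MAX_ITER):
        q = p + t[:, None] * u
        r_sq = q[:, 0] ** 2 + q[:, 1] ** 2
        zs, slope_over_r, dom = _sag_safe(surface, r_sq)
        f = q[:, 2] - zv - zs
        # df/dt = u_z - (dz/dr)(dr/dt); dr/dt = (x ux + y uy)/r
        dfdt = u[:, 2] - slope_over_r * (q[:, 0] * u[:, 0] + q[:, 1] * u[:, 1])
        done = np.abs(f) < _NEWTON_TOL_MM
        if np.all(done | ~ok):
            break
        step = np.where(np.abs(dfdt) > 1e-14, f / np.where(dfdt == 0, 1.0, dfdt), 0.0)
        t = np.where(done, t, t - step)
    q = p + t[:, None] * u
    r_sq = q[:, 0] ** 2 + q[:, 1] ** 2
    zs, slope_over_r, dom = _sag_safe(surface, r_sq)
    f = q[:, 2] - zv - zs
    ok &= (np.abs(f) < 10 * _NEWTON_TOL_MM) & dom
    ok &= r_sq <= surface.semi_aperture_mm ** 2 * (1.0 + 1e-12)
    # outward normal from grad F, F = z - zv - sag(r):  (-z' x/r, -z' y/r, 1)
    nx = -slope_over_r * q[:, 0]
    ny = -slope_over_r * q[:, 1]
    nz = np.ones_like(nx)
    norm = np.sqrt(nx * nx + ny * ny + 1.0)
    normals = np.stack([nx / norm, ny / norm, nz / norm], axis=1)
    return q, normals, ok, t


def refract(direction: np.ndarray, normal: np.ndarray, n1, n2):
    """Vector Snell refraction; returns (unit directions, TIR mask).

    The normal may point either way; it is flipped internally to oppose the
    incident direction.  Total internal reflection marks the ray (tir=True)
    and leaves its direction unchanged.
    """
    d = np.atleast_2d(direction).astype(float)
    n = np.atleast_2d(normal).astype(float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    cosi = -np.sum(d * n, axis=1)
    flip = cosi < 0.0
    n = np.where(flip[:, None], -n, n)
    cosi = np.abs(cosi)
    eta = n1 / n2
    sin2t = eta * eta * (1.0 - cosi * cosi)
    tir = sin2t > 1.0
    cost = np.sqrt(np.clip(1.0 - sin2t, 0.0, None))
    t = eta[..., None] * d + (eta * cosi - cost)[:, None] * n
    t = np.where(tir[:, None], d, t)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    return t, tir


# ---------------------------------------------------------------------------
# GRIN integration
# ---------------------------------------------------------------------------

def _grin_rhs(grin, p, T):
    """Right-hand side of the GRIN ray equation in state (r, T, opl)."""
    w_sq = p[:, 0] ** 2 + p[:, 1] ** 2
    n = grin.index(w_sq, p[:, 2])
    dp = T / n[:, None]
    zz = p[:, 2] - grin.origin_z_mm
    dT = np.stack([2.0 * grin.b1 * p[:, 0],
                   2.0 * grin.b1 * p[:, 1],
                   grin.a1 + 2.0 * grin.a2 * zz], axis=1)
    return dp, dT, n


def _rk4_step(grin, p, T, opl, h):
    """One RK4 step of arc length h (h may be a per-ray array)."""
    h = np.asarray(h, dtype=float)
    hc = h[:, None] if h.ndim else h
    k1p, k1T, k1n = _grin_rhs(grin, p, T)
    k2p, k2T, k2n = _grin_rhs(grin, p + 0.5 * hc * k1p, T + 0.5 * hc * k1T)
    k3p, k3T, k3n = _grin_rhs(grin, p + 0.5 * hc * k2p, T + 0.5 * hc * k2T)
    k4p, k4T, k4n = _grin_rhs(grin, p + hc * k3p, T + hc * k3T)
    p1 = p + hc / 6.0 * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
    T1 = T + hc / 6.0 * (k1T + 2.0 * k2T + 2.0 * k3T + k4T)
    opl1 = opl + h / 6.0 * (k1n + 2.0 * k2n + 2.0 * k3n + k4n)
    return p1, T1, opl1


def _surface_f(surface: ConicSurface, p):
    """Implicit surface function F = z - vertex - sag(r); negative before."""
    r_sq = p[:, 0] ** 2 + p[:, 1] ** 2
    zs, _, _ = _sag_safe(surface, r_sq)
    return p[:, 2] - surface.vertex_z_mm - zs


def trace_grin_segment(p, u, opl, alive, grin, exit_surface: ConicSurface,
                       step_mm: float = GRIN_STEP_MM, semi_aperture_mm=None):
    """Integrate rays through a GRIN medium until they cross ``exit_surface``.

    Fixed-step 4th-order Runge-Kutta on (r, T=n dr/ds, opl); the crossing of
    the implicit exit-surface function is detected by sign change and the
    final partial step is bisected to |F| < 1e-9 mm.  Rays leaving the lens
    laterally are vignetted.  Returns (p, u, opl, alive) with u the unit
    direction at the exit surface (before refraction).
    """
    p = p.copy()
    u = u.copy()
    opl = opl.copy()
    alive = alive.copy()
    w_sq = p[:, 0] ** 2 + p[:, 1] ** 2
    n0 = grin.index(w_sq, p[:, 2])
    T = u * n0[:, None]
    sa = semi_aperture_mm if semi_aperture_mm is not None \
        else exit_surface.semi_aperture_mm

    active = alive.copy()
    f_prev = _surface_f(exit_surface, p)
    # a ray already past the surface (should not happen sequentially) ends now
    active &= f_prev < 0.0

    max_steps = int(np.ceil((grin.valid_thickness_mm + 2.0) / step_mm)) + 10
    for _ in range(max_steps):
        if not np.any(active):
            break
        idx = np.nonzero(active)[0]
        p1, T1, opl1 = _rk4_step(grin, p[idx], T[idx], opl[idx], step_mm)
        f1 = _surface_f(exit_surface, p1)
        crossed = f1 >= 0.0
        keep = ~crossed
        # lateral escape beyond the clear aperture
        lateral = (p1[:, 0] ** 2 + p1[:, 1] ** 2) > sa * sa
        esc = keep & lateral
        if np.any(esc):
            gi = idx[esc]
            alive[gi] = False
            active[gi] = False
        ki = idx[keep & ~lateral]
        p[ki], T[ki], opl[ki] = p1[keep & ~lateral], T1[keep & ~lateral], \
            opl1[keep & ~lateral]
        ci = idx[crossed]
        if ci.size:
            # bisect the final step length from the pre-crossing state
            lo = np.zeros(ci.size)
            hi = np.full(ci.size, step_mm)
            pc, Tc, oc = p[ci], T[ci], opl[ci]
            for _ in range(45):
                mid = 0.5 * (lo + hi)
                pm, Tm, om = _rk4_step(grin, pc, Tc, oc, mid)
                fm = _surface_f(exit_surface, pm)
                hi = np.where(fm >= 0.0, mid, hi)
                lo = np.where(fm >= 0.0, lo, mid)
            hfin = 0.5 * (lo + hi)
            pm, Tm, om = _rk4_step(grin, pc, Tc, oc, hfin)
            p[ci], T[ci], opl[ci] = pm, Tm, om
            active[ci] = False
    # any ray still active never reached the exit surface
    alive[active] = False
    Tn = np.linalg.norm(T, axis=1, keepdims=True)
    u = T / np.where(Tn == 0.0, 1.0, Tn)
    return p, u, opl, alive


# ---------------------------------------------------------------------------
# Element / system tracing
# ---------------------------------------------------------------------------

def rotation_y(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _to_local(p, u, m: MisalignmentState):
    """World -> element-local: local = R^T (world - pivot - d) + pivot."""
    if m.is_identity:
        return p, u
    rot = rotation_y(m.tilt_y_deg)
    pivot = np.array([0.0, 0.0, m.pivot_z_mm])
    shift = pivot + np.array([m.decentration_x_mm, 0.0, 0.0])
    pl = (p - shift) @ rot + pivot      # (R^T x)_i = x @ rot row-vector form
    ul = u @ rot
    return pl, ul


def _to_world(p, u, m: MisalignmentState):
    if m.is_identity:
        return p, u
    rot = rotation_y(m.tilt_y_deg)
    pivot = np.array([0.0, 0.0, m.pivot_z_mm])
    shift = pivot + np.array([m.decentration_x_mm, 0.0, 0.0])
    pw = (p - pivot) @ rot.T + shift
    uw = u @ rot.T
    return pw, uw


def trace_element(p, u, opl, alive, element: OpticalElement,
                  n_in: float, medium_out: Medium,
                  grin_step_mm: float = GRIN_STEP_MM, record=None):
    """Trace a bundle through one (possibly misaligned) element.

    ``n_in`` is the homogeneous index of the medium in front of the element;
    ``medium_out`` the medium behind it (its index at the exit point is used
    for the final refraction).  All work happens in the element-local frame.
    """
    m = element.misalignment
    p, u = _to_local(p, u, m)
    n_tir_total = 0
    for j, surf in enumerate(element.surfaces):
        med_prev = Medium(index=n_in) if j == 0 else element.media[j - 1]
        if med_prev.is_grin:
            p, u, opl, alive = trace_grin_segment(
                p, u, opl, alive, med_prev.grin, surf, grin_step_mm,
                semi_aperture_mm=surf.semi_aperture_mm)
            q = p
            r_sq = q[:, 0] ** 2 + q[:, 1] ** 2
            _, slope_over_r, _ = _sag_safe(surf, r_sq)
            nx = -slope_over_r * q[:, 0]
            ny = -slope_over_r * q[:, 1]
            norm = np.sqrt(nx * nx + ny * ny + 1.0)
            normals = np.stack([nx / norm, ny / norm, 1.0 / norm], axis=1)
            n1 = med_prev.grin.index(r_sq, q[:, 2])
        else:
            q, normals, ok, t = intersect_conic(p, u, surf)
            nval = med_prev.index
            opl = np.where(alive & ok, opl + nval * t, opl)
            alive = alive & ok
            p = np.where(alive[:, None], q, p)
            r_sq = q[:, 0] ** 2 + q[:, 1] ** 2
            n1 = np.full(q.shape[0], nval)
        med_next = element.media[j] if j < len(element.surfaces) - 1 \
            else medium_out
        n2 = np.asarray(med_next.index_at(r_sq, q[:, 2]), dtype=float)
        if n2.ndim == 0:
            n2 = np.full(q.shape[0], float(n2))
        u_new, tir = refract(u, normals, n1, n2)
        n_tir = int(np.count_nonzero(tir & alive))
        if n_tir:
            n_tir_total += n_tir
            alive = alive & ~tir
        u = np.where(alive[:, None], u_new, u)
        if record is not None:
            pw, _ = _to_world(p, u, m)
            record.append(pw.copy())
    if n_tir_total:
        log.warning("total internal reflection on %d rays in element '%s'",
                    n_tir_total, element.label)
    p, u = _to_world(p, u, m)
    return p, u, opl, alive


def _clip_at_stop(p, u, opl, alive, system: EyeSystem, n_current: float):
    """Propagate to the stop plane and clip at the (decentred) aperture."""
    stop = system.stop
    t = (stop.z_mm - p[:, 2]) / u[:, 2]
    q = p + t[:, None] * u
    opl = opl + n_current * t
    r_sq = (q[:, 0] - stop.decentration_x_mm) ** 2 + q[:, 1] ** 2
    inside = r_sq <= stop.semi_aperture_mm ** 2 * (1.0 + 1e-12)
    return q, u, opl, alive & inside


def trace_system(system: EyeSystem, positions, directions, opl=None,
                 *, to_image: bool = True, grin_step_mm: float = GRIN_STEP_MM,
                 record_surfaces: bool = False) -> TraceResult:
    """Trace a bundle through the full system.

    ``opl`` may carry pre-accumulated optical path (e.g. the plane-wave phase
    reference of a tilted collimated beam).  The stop is applied in the world
    frame between the elements that bracket its z position (before an element
    whose front vertex coincides with it).
    """
    p = np.atleast_2d(np.asarray(positions, dtype=float)).copy()
    u = np.atleast_2d(np.asarray(directions, dtype=float)).copy()
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    opl = np.zeros(p.shape[0]) if opl is None else np.asarray(opl, float).copy()
    alive = np.ones(p.shape[0], dtype=bool)

    record: list | None = [] if record_surfaces else None
    stop_done = False
    n_current = system.ambient.index
    for i, el in enumerate(system.elements):
        if (not stop_done
                and system.stop.z_mm <= el.front_vertex_z_mm + 1e-9):
            p, u, opl, alive = _clip_at_stop(p, u, opl, alive, system,
                                             n_current)
            stop_done = True
        p, u, opl, alive = trace_element(p, u, opl, alive, el, n_current,
                                         system.media_after[i], grin_step_mm,
                                         record)
        n_current = float(system.media_after[i].index_at(0.0,
                                                         el.back_vertex_z_mm))
    if not stop_done:
        p, u, opl, alive = _clip_at_stop(p, u, opl, alive, system, n_current)

    res = TraceResult(exit_positions=p, exit_directions=u, exit_opl_mm=opl,
                      alive=alive, n_image=n_current,
                      surface_points=record or [])
    if to_image and system.image_plane_z_mm is not None:
        res.image_positions, res.image_opl_mm = res.propagate_to_plane(
            system.image_plane_z_mm)
    return res


def trace_ray(system: EyeSystem, ray: Ray, **kwargs) -> Ray:
    """Single-ray convenience wrapper around :func:`trace_system`."""
    res = trace_system(system, ray.position[None, :], ray.direction[None, :],
                       opl=np.array([ray.optical_path_um / 1000.0]), **kwargs)
    if res.image_positions is not None:
        pos, opl = res.image_positions[0], res.image_opl_mm[0]
    else:
        pos, opl = res.exit_positions[0], res.exit_opl_mm[0]
    return Ray(position=pos, direction=res.exit_directions[0],
               optical_path_um=opl * 1000.0, alive=bool(res.alive[0]))


# ---------------------------------------------------------------------------
# Ray aiming
# ---------------------------------------------------------------------------

def beam_direction(field_angle_deg: float) -> np.ndarray:
    """Unit direction of the incoming collimated beam (tilt in the x-z plane)."""
    a = np.deg2rad(field_angle_deg)
    return np.array([np.sin(a), 0.0, np.cos(a)])


def _pre_stop_system(system: EyeSystem) -> tuple[list, list, float]:
    """Elements entirely in front of the stop, their exit media and indices."""
    els, meds = [], []
    for i, el in enumerate(system.elements):
        if el.front_vertex_z_mm < system.stop.z_mm - 1e-9:
            els.append(el)
            meds.append(system.media_after[i])
    return els, meds, system.ambient.index


def _trace_to_stop(system: EyeSystem, xy0: np.ndarray, z_launch: float,
                   u0: np.ndarray):
    """Stop-plane hit coordinates for rays launched at (x0, y0, z_launch)."""
    n = xy0.shape[0]
    p = np.column_stack([xy0[:, 0], xy0[:, 1], np.full(n, z_launch)])
    u = np.broadcast_to(u0, (n, 3)).copy()
    opl = p @ u0  # plane-wave phase reference through the origin (n_air = 1)
    alive = np.ones(n, dtype=bool)
    els, meds, n_current = _pre_stop_system(system)
    for el, med in zip(els, meds):
        p, u, opl, alive = trace_element(p, u, opl, alive, el, n_current, med)
        n_current = float(med.index_at(0.0, el.back_vertex_z_mm))
    t = (system.stop.z_mm - p[:, 2]) / u[:, 2]
    q = p + t[:, None] * u
    return q[:, :2], alive


class AimingError(RuntimeError):
    """The stop-plane aiming solver failed to converge."""


def aim_rays(system: EyeSystem, stop_targets_xy: np.ndarray,
             z_launch: float | None = None,
             tol_mm: float = _AIM_TOL_MM, max_iter: int = 12):
    """Find launch coordinates so each ray hits its target on the stop plane.

    Returns (launch positions (N,3), shared unit direction, initial opl (mm),
    converged mask).  2-D Newton with a shared finite-difference Jacobian
    perturbation; the mapping through the cornea is nearly linear, so a
    handful of iterations reaches 1e-9 mm.
    """
    targets = np.atleast_2d(np.asarray(stop_targets_xy, dtype=float))
    u0 = beam_direction(system.field_angle_deg)
    if z_launch is None:
        z_launch = system.elements[0].front_vertex_z_mm - 5.0
    # straight-line initial guess (ignores the pre-stop refraction)
    dz = system.stop.z_mm - z_launch
    xy = targets - (dz / u0[2]) * u0[:2]
    eps = 1e-6
    converged = np.zeros(targets.shape[0], dtype=bool)
    for _ in range(max_iter):
        hit, alive = _trace_to_stop(system, xy, z_launch, u0)
        res = hit - targets
        err = np.linalg.norm(res, axis=1)
        converged = (err < tol_mm) & alive
        if np.all(converged):
            break
        hx, _ = _trace_to_stop(system, xy + np.array([eps, 0.0]), z_launch, u0)
        hy, _ = _trace_to_stop(system, xy + np.array([0.0, eps]), z_launch, u0)
        j11 = (hx[:, 0] - hit[:, 0]) / eps
        j21 = (hx[:, 1] - hit[:, 1]) / eps
        j12 = (hy[:, 0] - hit[:, 0]) / eps
        j22 = (hy[:, 1] - hit[:, 1]) / eps
        det = j11 * j22 - j12 * j21
        det = np.where(np.abs(det) < 1e-14, 1.0, det)
        dx = (j22 * res[:, 0] - j12 * res[:, 1]) / det
        dy = (-j21 * res[:, 0] + j11 * res[:, 1]) / det
        upd = ~converged
        xy[upd, 0] -= dx[upd]
        xy[upd, 1] -= dy[upd]
    n = targets.shape[0]
    p0 = np.column_stack([xy[:, 0], xy[:, 1], np.full(n, z_launch)])
    opl0 = p0 @ u0
    return p0, u0, opl0, converged
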