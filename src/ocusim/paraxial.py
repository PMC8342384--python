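"""Paraxial 2x2 (refraction/transfer) matrix tools.

This module is deliberately independent of the exact raytracer: it shares no
intersection, refraction or integration kernels with :mod:`ocusim.raytrace`
and serves as the independent cross-check (and as the source of paraxial
bookkeeping quantities such as the exit-pupil position).

Convention: ray state (y, n*u) with reduced angles; translation over a
distance d in index n is [[1, d/n], [0, 1]]; refraction with surface power
phi (per mm) is [[1, 0], [-phi, 1]].  A gradient-index medium is approximated
as a stack of thin slabs using its axial index profile; each slab additionally
carries the paraxial radial-gradient power d_phi = -2*b1*dz of the
n = ... + b1*w^2 term (exact in the homogeneous limit b1 = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eye_model import EyeSystem, Medium

_GRIN_SLABS = 200  # >= 100 thin slabs per gradient-index half


@dataclass(frozen=True)
class _Op:
    """One primitive paraxial operation located on the axis."""

    kind: str       # 'T' translation, 'R' refraction
    z0_mm: float
    z1_mm: float    # == z0 for refractions
    value: float    # index n for 'T', power per mm for 'R'

    def matrix(self) -> np.ndarray:
        if self.kind == "T":
            return np.array([[1.0, (self.z1_mm - self.z0_mm) / self.value],
                             [0.0, 1.0]])
        return np.array([[1.0, 0.0], [-self.value, 1.0]])


def _axial_index(medium: Medium, z_mm: float) -> float:
    """Axial refractive index of a medium at world z (nominal alignment)."""
    return float(medium.index_at(0.0, z_mm))


def primitive_ops(system: EyeSystem, grin_slabs: int = _GRIN_SLABS) -> list[_Op]:
    """Ordered primitive operations from the first to the last surface."""
    ops: list[_Op] = []
    z = system.elements[0].front_vertex_z_mm
    medium = system.ambient
    for i, el in enumerate(system.elements):
        for j, surf in enumerate(el.surfaces):
            zv = surf.vertex_z_mm
            if zv > z + 1e-12:
                if medium.is_grin:
                    g = medium.grin
                    edges = np.linspace(z, zv, grin_slabs + 1)
                    for za, zb in zip(edges[:-1], edges[1:]):
                        zm = 0.5 * (za + zb)
                        ops.append(_Op("T", za, zb, g.index(0.0, zm)))
                        # paraxial power of the radial-gradient term over dz
                        ops.append(_Op("R", zb, zb, -2.0 * g.b1 * (zb - za)))
                else:
                    ops.append(_Op("T", z, zv, medium.index))
            next_medium = el.media[j] if j < len(el.surfaces) - 1 \
                else system.media_after[i]
            n1 = _axial_index(medium, zv)
            n2 = _axial_index(next_medium, zv)
            ops.append(_Op("R", zv, zv, (n2 - n1) * surf.curvature))
            z, medium = zv, next_medium
    return ops


def matrix_between(ops: list[_Op], z_from: float, z_to: float) -> np.ndarray:
    """Accumulated matrix for the axial interval (z_from, z_to].

    Translations are clipped to the interval; refractions at exactly z_from
    are included (so a stop coinciding with a surface vertex sees that
    surface's refraction on its image side).
    """
    m = np.eye(2)
    for op in ops:
        if op.kind == "R":
            if z_from - 1e-9 < op.z0_mm <= z_to + 1e-9:
                m = op.matrix() @ m
        else:
            a = max(op.z0_mm, z_from)
            b = min(op.z1_mm, z_to)
            if b > a + 1e-15:
                m = _Op("T", a, b, op.value).matrix() @ m
    return m


def system_matrix(system: EyeSystem, grin_slabs: int = _GRIN_SLABS) -> np.ndarray:
    """Matrix from just before the first surface to just after the last."""
    ops = primitive_ops(system, grin_slabs)
    z0 = system.elements[0].front_vertex_z_mm
    z1 = system.elements[-1].back_vertex_z_mm
    return matrix_between(ops, z0 - 1e-6, z1)


def equivalent_power_dpt(system: EyeSystem, grin_slabs: int = _GRIN_SLABS) -> float:
    """Equivalent (effective) power of the system in diopters."""
    return -system_matrix(system, grin_slabs)[1, 0] * 1000.0


def back_focal_distance_mm(system: EyeSystem,
                           grin_slabs: int = _GRIN_SLABS) -> float:
    """Distance from the last surface vertex to the paraxial focus of a
    collimated input, measured in the image medium."""
    m = system_matrix(system, grin_slabs)
    a, c = m[0, 0], m[1, 0]
    n_img = _axial_index(system.image_medium,
                         system.elements[-1].back_vertex_z_mm)
    if c == 0.0:
        return np.inf
    return -a / c * n_img


def paraxial_focus_z_mm(system: EyeSystem,
                        grin_slabs: int = _GRIN_SLABS) -> float:
    """World z of the paraxial focus for a collimated input beam."""
    return system.elements[-1].back_vertex_z_mm + back_focal_distance_mm(
        system, grin_slabs)


def exit_pupil_z_mm(system: EyeSystem, grin_slabs: int = _GRIN_SLABS) -> float:
    """World z of the exit pupil: the paraxial image of the stop formed by the
    optics that follow it (virtual positions are allowed)."""
    ops = primitive_ops(system, grin_slabs)
    z_stop = system.stop.z_mm
    z_last = system.elements[-1].back_vertex_z_mm
    m = matrix_between(ops, z_stop, z_last)
    b, d = m[0, 1], m[1, 1]
    n_img = _axial_index(system.image_medium, z_last)
    if d == 0.0:
        return np.inf
    # imaging condition: B + tau*D = 0 with reduced distance tau after the
    # last surface
    return z_last - b / d * n_img


def paraxial_oracle(system: EyeSystem,
                    grin_slabs: int = _GRIN_SLABS) -> tuple[float, float]:
    """(equivalent power in dpt, back focal distance in mm) for a system.

    The independent check used by the test-suite against the exact raytracer.
    """
    return (equivalent_power_dpt(system, grin_slabs),
            back_focal_distance_mm(system, grin_slabs))
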