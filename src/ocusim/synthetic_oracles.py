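"""Degenerate optical systems and phase screens with closed-form behavior.

Every stage of the pipeline is testable against these without external data:
a single refracting sphere (closed-form focus), a thin lens (lensmaker), a
homogeneous "GRIN" (straight-line limit), and pure-Zernike phase screens
(exact fit round-trips).  The paraxial matrix oracle lives in
:mod:`ocusim.paraxial` and shares no kernels with the exact raytracer.
"""

from __future__ import annotations

import numpy as np

from .eye_model import (ConicSurface, EyeSystem, GrinMedium, Medium,
                        MisalignmentState, OpticalElement, Stop)
from .paraxial import paraxial_oracle  # noqa: F401  (re-export: oracle entry)
from .wavefront import OPDMap, make_zernike_screen  # noqa: F401  (re-export)


def make_single_sphere_eye(radius_mm: float = 8.0, n1: float = 1.0,
                           n2: float = 4.0 / 3.0,
                           pupil_diameter_mm: float = 2.0,
                           semi_aperture_mm: float = 4.0,
                           stigmatic: bool = False,
                           at_focus: bool = True) -> EyeSystem:
    """One refracting surface imaging a collimated beam.

    The paraxial focus is f' = n2 R / (n2 - n1) behind the vertex.  With
    ``stigmatic=True`` the surface conic is set to -(n1/n2)^2, the Cartesian
    conic that focuses a collimated beam to a perfect (aberration-free) point.
    """
    if not (n2 > n1 > 0 and radius_mm > 0):
        raise ValueError("need n2 > n1 > 0 and positive radius")
    conic = -(n1 / n2) ** 2 if stigmatic else 0.0
    surf = ConicSurface(radius_mm=radius_mm, conic=conic,
                        semi_aperture_mm=semi_aperture_mm, vertex_z_mm=0.0)
    element = OpticalElement(label="sphere", surfaces=(surf,), media=(),
                             misalignment=MisalignmentState(0, 0, 0.0),
                             is_lens=True)
    system = EyeSystem(
        elements=(element,),
        media_after=(Medium(index=n2),),
        stop=Stop(z_mm=0.0, semi_aperture_mm=0.5 * pupil_diameter_mm),
        ambient=Medium(index=n1),
        field_angle_deg=0.0,
        wavelength_um=0.5,
        metadata={"eye_kind": "toy_single_sphere",
                  "analytic_focus_mm": analytic_sphere_focus_mm(radius_mm, n1, n2)},
    )
    if at_focus:
        system.image_plane_z_mm = system.metadata["analytic_focus_mm"]
    return system


def analytic_sphere_focus_mm(radius_mm: float, n1: float, n2: float) -> float:
    """Closed-form paraxial focus of a single refracting sphere."""
    return n2 * radius_mm / (n2 - n1)


def make_thin_lens_eye(focal_length_mm: float = 30.0,
                       index: float = 1.5,
                       thickness_mm: float = 0.2,
                       pupil_diameter_mm: float = 0.5,
                       semi_aperture_mm: float = 3.0) -> EyeSystem:
    """Symmetric biconvex lens in air whose thick-lens focal length equals
    ``focal_length_mm`` (closed-form radii from the lensmaker equation)."""
    n, t = index, thickness_mm
    # solve 1/f = (n-1) [2/R - (n-1) t / (n R^2)] for R (quadratic in 1/R)
    a = -(n - 1.0) ** 2 * t / n
    b = 2.0 * (n - 1.0)
    c = -1.0 / focal_length_mm
    inv_r = (-b + np.sqrt(b * b - 4.0 * a * c)) / (2.0 * a)
    radius = 1.0 / inv_r
    front = ConicSurface(radius, 0.0, semi_aperture_mm, 0.0)
    back = ConicSurface(-radius, 0.0, semi_aperture_mm, t)
    element = OpticalElement(label="thin_lens", surfaces=(front, back),
                             media=(Medium(index=n),),
                             misalignment=MisalignmentState(0, 0, 0.0),
                             is_lens=True)
    return EyeSystem(
        elements=(element,),
        media_after=(Medium(index=1.0),),
        stop=Stop(z_mm=0.0, semi_aperture_mm=0.5 * pupil_diameter_mm),
        ambient=Medium(index=1.0),
        field_angle_deg=0.0,
        wavelength_um=0.5,
        metadata={"eye_kind": "toy_thin_lens",
                  "focal_length_mm": focal_length_mm},
    )


def make_homogeneous_grin_eye(index: float = 1.42,
                              pupil_diameter_mm: float = 2.0) -> EyeSystem:
    """A biconvex lens whose interior is a GRIN medium with all gradient
    coefficients zero: the exact-raytrace result must match a homogeneous
    lens, exercising the GRIN integrator in its closed-form limit."""
    sa = 4.0
    front = ConicSurface(15.0, 0.0, sa, 0.0)
    mid = ConicSurface(np.inf, 0.0, sa, 2.0)
    back = ConicSurface(-15.0, 0.0, sa, 4.0)
    g1 = GrinMedium(n00=index, valid_thickness_mm=2.0, origin_z_mm=0.0)
    g2 = GrinMedium(n00=index, valid_thickness_mm=2.0, origin_z_mm=2.0)
    element = OpticalElement(label="hgrin", surfaces=(front, mid, back),
                             media=(Medium(grin=g1), Medium(grin=g2)),
                             misalignment=MisalignmentState(0, 0, 0.0),
                             is_lens=True)
    return EyeSystem(
        elements=(element,),
        media_after=(Medium(index=1.0),),
        stop=Stop(z_mm=0.0, semi_aperture_mm=0.5 * pupil_diameter_mm),
        ambient=Medium(index=1.0),
        field_angle_deg=0.0,
        wavelength_um=0.5,
        metadata={"eye_kind": "toy_homogeneous_grin"},
    )


def make_homogeneous_twin(grin_eye: EyeSystem) -> EyeSystem:
    """Replace the zero-gradient GRIN media of a toy eye by plain homogeneous
    media with the same index (the reference trace for the GRIN limit)."""
    out = grin_eye.copy()
    elements = []
    for el in out.elements:
        media = tuple(Medium(index=m.grin.n00) if m.is_grin else m
                      for m in el.media)
        from dataclasses import replace
        elements.append(replace(el, media=media))
    out.elements = tuple(elements)
    return out


def random_zernike_screen(rng: np.random.Generator, max_order: int = 4,
                          amplitude_um: float = 0.3, grid_n: int = 64,
                          pupil_radius_mm: float = 2.0) -> tuple[OPDMap, dict]:
    """Seeded random phase screen; returns the map and its exact coefficients."""
    from .wavefront import zernike_nm_list
    coeffs = {}
    for n, m in zernike_nm_list(max_order):
        if n == 0:
            continue
        coeffs[(n, m)] = float(rng.uniform(-amplitude_um, amplitude_um))
    screen = make_zernike_screen(coeffs, pupil_radius_mm=pupil_radius_mm,
                                 grid_n=grid_n)
    return screen, coeffs
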