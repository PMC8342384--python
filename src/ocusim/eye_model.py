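"""Schematic model eyes: domain types, the built-in non-centered eye, and builders.

Coordinate convention (fixed for the whole package): right-handed frame,
+z runs from the corneal vertex toward the retina, +y is up, +x is horizontal;
the built-in prescription describes a right eye.  The incoming collimated beam
lies in the x-z plane, tilted by ``field_angle_deg`` (the angle-alpha tilt of
the visual axis).  Positive lens decentration moves the lens toward +x and
positive tilt rotates it about the vertical (+y) axis; these signs are chosen
so that the largest positive induced defocus/astigmatism/coma occur at
(+decentration, +tilt), which disambiguates the otherwise arbitrary handedness
of "horizontal" in the literature.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq


class ConfigurationError(ValueError):
    """A required model constant or configuration entry is missing/invalid."""


class GeometryError(ValueError):
    """Element geometry is physically impossible (overlap, no axial space...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConicSurface:
    """One refracting conic-asphere interface in its element-local frame.

    Sag (surface height along +z at radial distance ``r`` from the local axis):

        z(r) = c r^2 / (1 + sqrt(1 - (1+Q) c^2 r^2)) + a4 r^4 + a6 r^6

    with curvature ``c = 1/radius_mm``.  ``radius_mm`` is signed: positive
    means the centre of curvature lies on the image (+z) side.  ``math.inf``
    encodes a plane.
    """

    radius_mm: float
    conic: float = 0.0
    semi_aperture_mm: float = 5.0
    vertex_z_mm: float = 0.0
    a4: float = 0.0  # even-asphere terms, mm^-3 and mm^-5
    a6: float = 0.0

    def __post_init__(self) -> None:
        if not self.semi_aperture_mm > 0:
            raise ConfigurationError(
                f"semi_aperture_mm must be positive, got {self.semi_aperture_mm}")
        c = self.curvature
        # sag must stay real on the full aperture: (1+Q) c^2 r^2 < 1
        if (1.0 + self.conic) * c * c * self.semi_aperture_mm ** 2 >= 1.0:
            raise ConfigurationError(
                f"conic surface (R={self.radius_mm} mm, Q={self.conic}) has no real "
                f"sag at semi-aperture {self.semi_aperture_mm} mm")

    @property
    def curvature(self) -> float:
        return 0.0 if math.isinf(self.radius_mm) else 1.0 / self.radius_mm

    @property
    def is_plane(self) -> bool:
        return self.curvature == 0.0 and self.a4 == 0.0 and self.a6 == 0.0


@dataclass(frozen=True)
class GrinMedium:
    """Polynomial gradient-index field of one crystalline-lens half.

    n(w, z) = n00 + a1*z + a2*z^2 + b1*w^2

    ``z`` is the axial distance (mm) from the half's front vertex (element-local
    z minus ``origin_z_mm``); ``w`` is the radial distance (mm) from the local
    axis.  ``valid_thickness_mm`` is the axial extent of the half.
    """

    n00: float
    a1: float = 0.0
    a2: float = 0.0
    b1: float = 0.0
    valid_thickness_mm: float = 0.0
    origin_z_mm: float = 0.0

    def index(self, w_sq, z):
        """Refractive index at radial-distance-squared ``w_sq`` and local z (mm)."""
        zz = z - self.origin_z_mm
        return self.n00 + self.a1 * zz + self.a2 * zz * zz + self.b1 * w_sq

    def axial_index(self, z):
        """n(0, z) with z measured from the half's own front vertex."""
        return self.n00 + self.a1 * z + self.a2 * z * z


@dataclass(frozen=True)
class Medium:
    """Homogeneous medium (``index``) or a gradient-index medium (``grin``)."""

    index: float | None = None
    grin: GrinMedium | None = None

    def __post_init__(self) -> None:
        if (self.index is None) == (self.grin is None):
            raise ConfigurationError("Medium needs exactly one of index / grin")

    @property
    def is_grin(self) -> bool:
        return self.grin is not None

    def index_at(self, w_sq, z):
        if self.grin is not None:
            return self.grin.index(w_sq, z)
        return self.index


@dataclass(frozen=True)
class MisalignmentState:
    """Rigid-body misalignment of one element: horizontal decentration plus
    rotation about the vertical axis through the pivot point (0, 0, pivot_z).

    Composition order (fixed): the element is first decentred along x, then
    tilted; equivalently world = R_y(tilt) @ (local - pivot) + pivot + (dx,0,0).
    """

    decentration_x_mm: float = 0.0
    tilt_y_deg: float = 0.0
    pivot_z_mm: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.decentration_x_mm) > 1.5:
            warnings.warn(
                f"decentration {self.decentration_x_mm} mm exceeds the soft bound "
                "of 1.5 mm; results are extrapolations", stacklevel=2)
        if abs(self.tilt_y_deg) > 15.0:
            warnings.warn(
                f"tilt {self.tilt_y_deg} deg exceeds the soft bound of 15 deg; "
                "results are extrapolations", stacklevel=2)

    @property
    def is_identity(self) -> bool:
        return self.decentration_x_mm == 0.0 and self.tilt_y_deg == 0.0


@dataclass(frozen=True)
class OpticalElement:
    """A group of surfaces sharing one rigid-body misalignment transform.

    ``media`` holds the internal media between consecutive surfaces
    (``len(media) == len(surfaces) - 1``).  Surface vertex positions are given
    in the element-local frame, which coincides with the world frame at zero
    misalignment.
    """

    label: str
    surfaces: tuple[ConicSurface, ...]
    media: tuple[Medium, ...] = ()
    misalignment: MisalignmentState = field(default_factory=MisalignmentState)
    is_lens: bool = False

    def __post_init__(self) -> None:
        if len(self.media) != len(self.surfaces) - 1:
            raise ConfigurationError(
                f"element '{self.label}': need len(media) == len(surfaces)-1")
        zs = [s.vertex_z_mm for s in self.surfaces]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise GeometryError(
                f"element '{self.label}': surfaces must be strictly ordered in z")

    @property
    def front_vertex_z_mm(self) -> float:
        return self.surfaces[0].vertex_z_mm

    @property
    def back_vertex_z_mm(self) -> float:
        return self.surfaces[-1].vertex_z_mm


@dataclass(frozen=True)
class Stop:
    """The aperture stop: a clipping circle in the (world) plane z = z_mm."""

    z_mm: float
    semi_aperture_mm: float
    decentration_x_mm: float = 0.0

    def __post_init__(self) -> None:
        if not self.semi_aperture_mm > 0:
            raise ConfigurationError("stop semi-aperture must be positive "
                                     "(empty stop)")


@dataclass
class EyeSystem:
    """Ordered sequential optical system: elements, stop, image plane.

    ``media_after[i]`` is the medium following element ``i`` (the medium before
    the first element is ``ambient``).  ``image_plane_z_mm`` is None until a
    focus has been solved or assigned.
    """

    elements: tuple[OpticalElement, ...]
    media_after: tuple[Medium, ...]
    stop: Stop
    ambient: Medium = field(default_factory=lambda: Medium(index=1.0))
    field_angle_deg: float = 0.0
    wavelength_um: float = 0.555
    image_plane_z_mm: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.media_after) != len(self.elements):
            raise ConfigurationError("need one media_after entry per element")
        if not self.wavelength_um > 0:
            raise ConfigurationError("wavelength_um must be positive")
        if not math.isfinite(self.field_angle_deg):
            raise ConfigurationError("field_angle_deg must be finite")
        n_lens = sum(e.is_lens for e in self.elements)
        if n_lens > 1:
            raise ConfigurationError("at most one element may be flagged as lens")

    @property
    def lens_element(self) -> OpticalElement:
        for e in self.elements:
            if e.is_lens:
                return e
        raise ConfigurationError("system has no lens element")

    @property
    def lens_index(self) -> int:
        for i, e in enumerate(self.elements):
            if e.is_lens:
                return i
        raise ConfigurationError("system has no lens element")

    @property
    def image_medium(self) -> Medium:
        return self.media_after[-1]

    def copy(self) -> "EyeSystem":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class IOLDesign:
    """An intraocular lens prescription.

    Surfaces are conic aspheres with optional even-asphere terms; the haptic
    plane (the plane of the support loops, aligned to the natural-lens equator
    when implanted in the capsular bag) sits ``haptic_plane_offset_mm`` behind
    the front vertex (default: mid-thickness).
    """

    front_radius_mm: float
    back_radius_mm: float
    central_thickness_mm: float
    material_index: float
    labelled_power_dpt: float
    front_conic: float = 0.0
    back_conic: float = 0.0
    front_a4: float = 0.0
    front_a6: float = 0.0
    back_a4: float = 0.0
    back_a6: float = 0.0
    haptic_plane_offset_mm: float | None = None
    optic_semi_aperture_mm: float = 3.0
    label: str = "iol"

    def __post_init__(self) -> None:
        if not self.central_thickness_mm > 0:
            raise ConfigurationError("IOL central_thickness_mm must be positive")

    @property
    def haptic_offset_mm(self) -> float:
        if self.haptic_plane_offset_mm is None:
            return 0.5 * self.central_thickness_mm
        return self.haptic_plane_offset_mm

    def paraxial_power_dpt(self, ambient_index: float = 1.336) -> float:
        """Thick-lens equivalent power (dpt) in a homogeneous ambient medium."""
        n, na, t = self.material_index, ambient_index, self.central_thickness_mm
        p1 = (n - na) / self.front_radius_mm if math.isfinite(self.front_radius_mm) else 0.0
        p2 = (na - n) / self.back_radius_mm if math.isfinite(self.back_radius_mm) else 0.0
        return 1000.0 * (p1 + p2 - p1 * p2 * t / n)

    def validate_power(self, ambient_index: float = 1.336, tol_dpt: float = 0.5) -> None:
        p = self.paraxial_power_dpt(ambient_index)
        if abs(p - self.labelled_power_dpt) > tol_dpt:
            raise ConfigurationError(
                f"IOL paraxial power {p:.3f} dpt deviates from labelled "
                f"{self.labelled_power_dpt:.3f} dpt by more than {tol_dpt} dpt")


# ---------------------------------------------------------------------------
# Built-in prescription: Liou & Brennan (1997) finite schematic eye
# ---------------------------------------------------------------------------
# Each constant names its source row in Table 1 of Liou & Brennan,
# "The anatomically accurate, finite model eye", JOSA A 14(8):1684 (1997).

LIOU_BRENNAN: dict = {
    # --- cornea ---
    "cornea_front_radius_mm": 7.77,      # Table 1, surface 1 (anterior cornea) radius
    "cornea_front_conic": -0.18,         # Table 1, surface 1 asphericity Q
    "cornea_thickness_mm": 0.50,         # Table 1, surface 1 thickness
    "cornea_index": 1.376,               # Table 1, cornea refractive index (555 nm)
    "cornea_back_radius_mm": 6.40,       # Table 1, surface 2 (posterior cornea) radius
    "cornea_back_conic": -0.60,          # Table 1, surface 2 asphericity Q
    # --- anterior chamber ---
    "anterior_chamber_depth_mm": 3.16,   # Table 1, surface 2 thickness (aqueous depth)
    "aqueous_index": 1.336,              # Table 1, aqueous refractive index
    # --- crystalline lens (two gradient-index halves) ---
    "lens_front_radius_mm": 12.40,       # Table 1, surface 3 (anterior lens) radius
    "lens_front_conic": -0.94,           # Table 1, surface 3 asphericity Q
    "lens_anterior_thickness_mm": 1.59,  # Table 1, surface 3 thickness (grin I)
    "lens_posterior_thickness_mm": 2.43, # Table 1, surface 4 thickness (grin II)
    "lens_back_radius_mm": -8.10,        # Table 1, surface 5 (posterior lens) radius
    "lens_back_conic": 0.96,             # Table 1, surface 5 asphericity Q
    # n(w,z) = 1.368 + 0.049057 z - 0.015427 z^2 - 0.001978 w^2   (grin I)
    "grin_anterior": {"n00": 1.368, "a1": 0.049057, "a2": -0.015427, "b1": -0.001978},
    # n(w,z) = 1.407 - 0.006605 z^2 - 0.001978 w^2                (grin II)
    "grin_posterior": {"n00": 1.407, "a1": 0.0, "a2": -0.006605, "b1": -0.001978},
    # --- vitreous / axial length ---
    "vitreous_index": 1.336,             # Table 1, vitreous refractive index
    "vitreous_length_mm": 16.27,         # axial length 23.95 mm minus preceding thicknesses
    # --- non-centered features ---
    "field_angle_deg": 5.0,              # visual axis tilted 5 deg nasally (angle alpha)
    "pupil_decentration_x_mm": -0.5,     # pupil decentred 0.5 mm nasally (Table 1 note);
                                         # nasal is -x for the right eye in our frame
    # --- apertures (clear-aperture bookkeeping; generous, not limiting) ---
    "cornea_semi_aperture_mm": 6.0,
    "lens_semi_aperture_mm": 4.8,
}


def _get(constants: dict, key: str):
    try:
        return constants[key]
    except KeyError:
        raise ConfigurationError(f"missing model constant '{key}'") from None


def lens_equator_z_mm(constants: dict | None = None) -> float:
    """World z of the crystalline-lens equatorial plane (junction of the halves)."""
    c = LIOU_BRENNAN if constants is None else constants
    return (_get(c, "cornea_thickness_mm") + _get(c, "anterior_chamber_depth_mm")
            + _get(c, "lens_anterior_thickness_mm"))


def build_phakic_eye(model_constants: dict | None = None,
                     pupil_diameter_mm: float = 4.0,
                     wavelength_um: float = 0.5,
                     *,
                     center_stop: bool = False) -> EyeSystem:
    """Build the phakic non-centered schematic eye.

    Parameters
    ----------
    model_constants:
        Full prescription dictionary; defaults to the built-in Liou-Brennan
        transcription.  A missing key raises :class:`ConfigurationError`
        naming the field.
    pupil_diameter_mm:
        Aperture-stop diameter in the pupil plane (anterior lens vertex).
    wavelength_um:
        Monochromatic design wavelength.
    center_stop:
        If True the nominal pupil decentration of the published model is
        zeroed (the stop is centred on the symmetry axis).  Default keeps the
        published decentration; the choice is recorded in ``metadata``.

    The returned system carries zero lens misalignment and no image plane;
    call :func:`ocusim.wavefront.find_best_focus` (or ``focus_system``) to
    freeze the best-focus plane before analysing wavefronts.
    """
    c = LIOU_BRENNAN if model_constants is None else model_constants
    if not pupil_diameter_mm > 0:
        raise ConfigurationError("pupil_diameter_mm must be positive (empty stop)")

    z_cornea_back = _get(c, "cornea_thickness_mm")
    z_lens_front = z_cornea_back + _get(c, "anterior_chamber_depth_mm")
    t_ant = _get(c, "lens_anterior_thickness_mm")
    t_post = _get(c, "lens_posterior_thickness_mm")
    z_equator = z_lens_front + t_ant
    z_lens_back = z_equator + t_post
    z_image = z_lens_back + _get(c, "vitreous_length_mm")

    sa_cornea = _get(c, "cornea_semi_aperture_mm")
    sa_lens = _get(c, "lens_semi_aperture_mm")

    cornea = OpticalElement(
        label="cornea",
        surfaces=(
            ConicSurface(_get(c, "cornea_front_radius_mm"), _get(c, "cornea_front_conic"),
                         sa_cornea, 0.0),
            ConicSurface(_get(c, "cornea_back_radius_mm"), _get(c, "cornea_back_conic"),
                         sa_cornea, z_cornea_back),
        ),
        media=(Medium(index=_get(c, "cornea_index")),),
    )

    ga = _get(c, "grin_anterior")
    gp = _get(c, "grin_posterior")
    grin_ant = GrinMedium(n00=_get(ga, "n00"), a1=_get(ga, "a1"), a2=_get(ga, "a2"),
                          b1=_get(ga, "b1"), valid_thickness_mm=t_ant,
                          origin_z_mm=z_lens_front)
    grin_post = GrinMedium(n00=_get(gp, "n00"), a1=_get(gp, "a1"), a2=_get(gp, "a2"),
                           b1=_get(gp, "b1"), valid_thickness_mm=t_post,
                           origin_z_mm=z_equator)

    lens = OpticalElement(
        label="crystalline_lens",
        surfaces=(
            ConicSurface(_get(c, "lens_front_radius_mm"), _get(c, "lens_front_conic"),
                         sa_lens, z_lens_front),
            ConicSurface(math.inf, 0.0, sa_lens, z_equator),   # equatorial junction plane
            ConicSurface(_get(c, "lens_back_radius_mm"), _get(c, "lens_back_conic"),
                         sa_lens, z_lens_back),
        ),
        media=(Medium(grin=grin_ant), Medium(grin=grin_post)),
        # tilt pivot at the lens-group front vertex: the location of the
        # tilt/decenter transform in a sequential raytracer's surface list
        misalignment=MisalignmentState(0.0, 0.0, pivot_z_mm=z_lens_front),
        is_lens=True,
    )

    stop_dx = 0.0 if center_stop else _get(c, "pupil_decentration_x_mm")
    stop = Stop(z_mm=z_lens_front, semi_aperture_mm=0.5 * pupil_diameter_mm,
                decentration_x_mm=stop_dx)

    system = EyeSystem(
        elements=(cornea, lens),
        media_after=(Medium(index=_get(c, "aqueous_index")),
                     Medium(index=_get(c, "vitreous_index"))),
        stop=stop,
        ambient=Medium(index=1.0),
        field_angle_deg=_get(c, "field_angle_deg"),
        wavelength_um=wavelength_um,
        metadata={
            "eye_kind": "phakic",
            "model": "liou_brennan_1997" if model_constants is None else "custom",
            "center_stop": center_stop,
            "stop_decentration_x_mm": stop_dx,
            "lens_equator_z_mm": z_equator,
            "anatomical_axial_length_mm": z_image,
        },
    )
    return system


def build_pseudophakic_eye(phakic: EyeSystem, iol: IOLDesign,
                           *, solve_focus: bool = True,
                           focus_grid_n: int = 48) -> EyeSystem:
    """Replace the crystalline lens of ``phakic`` by an IOL.

    The IOL's haptic plane is aligned to the crystalline-lens equatorial plane
    (the junction of the anterior and posterior gradient-index halves), as a
    capsular-bag implant sits; aqueous fills the former lens volume outside
    the IOL.  The image plane is re-solved to best focus (unless
    ``solve_focus=False``); the phakic image plane, if solved, is kept in
    ``metadata['phakic_image_plane_z_mm']``.
    """
    iol.validate_power(ambient_index=phakic.media_after[0].index_at(0.0, 0.0))

    lens = phakic.lens_element
    z_equator = lens.surfaces[1].vertex_z_mm if len(lens.surfaces) >= 3 else \
        phakic.metadata.get("lens_equator_z_mm", 0.5 * (lens.front_vertex_z_mm
                                                        + lens.back_vertex_z_mm))
    z_front = z_equator - iol.haptic_offset_mm
    z_back = z_front + iol.central_thickness_mm
    if z_front < lens.front_vertex_z_mm - 1e-9 or z_back > lens.back_vertex_z_mm + 1e-9:
        raise GeometryError(
            f"IOL (front {z_front:.3f}..back {z_back:.3f} mm) does not fit in the "
            f"former lens volume ({lens.front_vertex_z_mm:.3f}.."
            f"{lens.back_vertex_z_mm:.3f} mm)")

    iol_element = OpticalElement(
        label=iol.label,
        surfaces=(
            ConicSurface(iol.front_radius_mm, iol.front_conic,
                         iol.optic_semi_aperture_mm, z_front,
                         a4=iol.front_a4, a6=iol.front_a6),
            ConicSurface(iol.back_radius_mm, iol.back_conic,
                         iol.optic_semi_aperture_mm, z_back,
                         a4=iol.back_a4, a6=iol.back_a6),
        ),
        media=(Medium(index=iol.material_index),),
        misalignment=MisalignmentState(0.0, 0.0, pivot_z_mm=z_front),
        is_lens=True,
    )

    elements = list(phakic.elements)
    media_after = list(phakic.media_after)
    li = phakic.lens_index
    elements[li] = iol_element
    # aqueous fills the capsular bag outside the IOL; the medium behind keeps
    # the phakic vitreous index
    metadata = dict(phakic.metadata)
    metadata.update({
        "eye_kind": "pseudophakic",
        "iol_label": iol.label,
        "iol_labelled_power_dpt": iol.labelled_power_dpt,
        "phakic_image_plane_z_mm": phakic.image_plane_z_mm,
    })
    system = EyeSystem(
        elements=tuple(elements),
        media_after=tuple(media_after),
        stop=phakic.stop,
        ambient=phakic.ambient,
        field_angle_deg=phakic.field_angle_deg,
        wavelength_um=phakic.wavelength_um,
        image_plane_z_mm=None,
        metadata=metadata,
    )
    if solve_focus:
        from . import wavefront  # deferred: wavefront imports this module
        wavefront.focus_system(system, grid_n=focus_grid_n)
    return system


def equiconvex_radius_for_power(power_dpt: float, material_index: float,
                                ambient_index: float, thickness_mm: float) -> float:
    """Radius R (mm) of an equiconvex thick lens (front +R, back -R) with the
    requested paraxial power in the ambient medium.

    Root-solved to < 1e-6 dpt.  Powers below 0.01 dpt have no usefully finite
    radius and raise :class:`ConfigurationError`.
    """
    if power_dpt < 0.01:
        raise ConfigurationError("power below 0.01 dpt: equiconvex radius diverges")
    if not material_index > ambient_index:
        raise ConfigurationError("material_index must exceed ambient_index")

    n, na, t = material_index, ambient_index, thickness_mm

    def power_of(radius):
        p1 = (n - na) / radius
        p2 = (n - na) / radius  # back surface -R contributes the same sign
        return 1000.0 * (p1 + p2 - p1 * p2 * t / n) - power_dpt

    r_thin = 2.0 * (n - na) / (power_dpt / 1000.0)
    lo, hi = 0.05 * r_thin, 10.0 * r_thin
    if power_of(lo) * power_of(hi) > 0:
        raise ConfigurationError("no real equiconvex solution for requested power")
    return brentq(power_of, lo, hi, xtol=1e-10, rtol=1e-14)


def make_equiconvex_iol(power_dpt: float = 21.0, material_index: float = 1.458,
                        ambient_index: float = 1.336, thickness_mm: float = 1.2,
                        optic_semi_aperture_mm: float = 3.0) -> IOLDesign:
    """Equiconvex spherical IOL with the given labelled power (comparison lens)."""
    r = equiconvex_radius_for_power(power_dpt, material_index, ambient_index,
                                    thickness_mm)
    return IOLDesign(front_radius_mm=r, back_radius_mm=-r,
                     central_thickness_mm=thickness_mm,
                     material_index=material_index, labelled_power_dpt=power_dpt,
                     optic_semi_aperture_mm=optic_semi_aperture_mm,
                     label="spherical_equiconvex")


_IOL_DESIGN_CACHE: dict = {}


def design_aberration_correcting_iol(model_constants: dict | None = None,
                                     power_dpt: float = 21.0,
                                     material_index: float = 1.458,
                                     thickness_mm: float = 1.2,
                                     design_optic_diameter_mm: float = 6.0,
                                     grid_n: int = 48) -> IOLDesign:
    """Solve a generic aberration-correcting conic-asphere IOL.

    Starts from the equiconvex radii for the labelled power and solves the
    front-surface conic constant so that the pseudophakic eye's spherical
    aberration (orthonormal Zernike c4^0) vanishes over the full optic
    diameter of an on-axis, centred-stop design eye — the design condition of
    high-correction aspheric IOLs, which null the eye's spherical aberration
    across their whole optic rather than at one analysis pupil.  The exact
    commercial prescription is patent-specific; a user-supplied
    :class:`IOLDesign` can be used instead.
    """
    key = (id(model_constants) if model_constants is not None else None,
           power_dpt, material_index, thickness_mm,
           design_optic_diameter_mm, grid_n)
    if key in _IOL_DESIGN_CACHE:
        return _IOL_DESIGN_CACHE[key]

    from . import wavefront  # deferred import, see build_pseudophakic_eye

    design_eye = build_phakic_eye(model_constants,
                                  pupil_diameter_mm=design_optic_diameter_mm,
                                  center_stop=True)
    design_eye.field_angle_deg = 0.0
    ambient = design_eye.media_after[0].index_at(0.0, 0.0)
    r = equiconvex_radius_for_power(power_dpt, material_index, ambient,
                                    thickness_mm)

    def c40_of(conic: float) -> float:
        iol = IOLDesign(front_radius_mm=r, back_radius_mm=-r,
                        central_thickness_mm=thickness_mm,
                        material_index=material_index,
                        labelled_power_dpt=power_dpt,
                        front_conic=conic,
                        # slightly oversized so the design bundle is unclipped
                        optic_semi_aperture_mm=0.5 * design_optic_diameter_mm + 0.2,
                        label="design_candidate")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pseudo = build_pseudophakic_eye(design_eye, iol, solve_focus=True,
                                            focus_grid_n=grid_n)
            opd = wavefront.sample_wavefront(pseudo, grid_n=grid_n)
            coeffs = wavefront.fit_zernike(opd, max_order=6)
        return coeffs.get(4, 0)

    lo, hi = -80.0, 5.0
    if c40_of(lo) * c40_of(hi) > 0:
        raise ConfigurationError("cannot bracket zero spherical aberration; "
                                 "adjust IOL starting design")
    conic = brentq(c40_of, lo, hi, xtol=1e-3)
    iol = IOLDesign(front_radius_mm=r, back_radius_mm=-r,
                    central_thickness_mm=thickness_mm,
                    material_index=material_index, labelled_power_dpt=power_dpt,
                    front_conic=conic, label="aberration_correcting")
    _IOL_DESIGN_CACHE[key] = iol
    return iol


def set_misalignment(system: EyeSystem, decentration_x_mm: float,
                     tilt_y_deg: float, *, relative: bool = False) -> EyeSystem:
    """Return a system whose lens element carries the given misalignment.

    With ``relative=True`` the values are added to the current state (so
    applying (d, t) then (-d, -t) recovers the original frames exactly).
    All other geometry is untouched.
    """
    li = system.lens_index
    lens = system.elements[li]
    cur = lens.misalignment
    if relative:
        decentration_x_mm = cur.decentration_x_mm + decentration_x_mm
        tilt_y_deg = cur.tilt_y_deg + tilt_y_deg
    new_state = MisalignmentState(decentration_x_mm, tilt_y_deg,
                                  pivot_z_mm=cur.pivot_z_mm)
    elements = list(system.elements)
    elements[li] = replace(lens, misalignment=new_state)
    out = copy.copy(system)
    out.elements = tuple(elements)
    out.metadata = dict(system.metadata)
    return out


def mirror_lr(system: EyeSystem) -> EyeSystem:
    """Mirror the system in the vertical (y-z) plane: the left-eye analogue.

    All surfaces are rotationally symmetric, so mirroring negates exactly the
    signed horizontal quantities: field angle, stop decentration, lens
    decentration and tilt.
    """
    out = system.copy()
    out.field_angle_deg = -system.field_angle_deg
    out.stop = replace(system.stop,
                       decentration_x_mm=-system.stop.decentration_x_mm)
    li = out.lens_index
    lens = out.elements[li]
    m = lens.misalignment
    elements = list(out.elements)
    elements[li] = replace(lens, misalignment=MisalignmentState(
        -m.decentration_x_mm, -m.tilt_y_deg, pivot_z_mm=m.pivot_z_mm))
    out.elements = tuple(elements)
    out.metadata = dict(out.metadata, mirrored=True)
    return out
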