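"""Exit-pupil wavefront analysis.

Builds the optical-path-difference (OPD) map of a traced ray bundle over the
stop, fits orthonormal (OSA/ANSI, unit-variance) Zernike polynomials, converts
the second-order terms to diopters and locates the best-focus image plane.

Sign conventions (fixed package-wide):

* OPD = OPL(chief) - OPL(ray), both measured from the incoming plane
  wavefront to the exit-pupil reference sphere centred on the chief-ray
  image-plane intersection.  With the standard conversion
  ``M = -4*sqrt(3)*c2^0 / r_p^2`` this reports *positive* defocus when the
  best focus of the misaligned optics recedes *behind* the frozen image
  plane (and negative when the focus moves in front of it); this is the
  convention of the reference maps this package reproduces.
* Astigmatism is reported in diopters from c2^+2; the default variant
  (``j0``) is the power-vector-type component -2*sqrt(6)*c22/r_p^2, with
  the sign convention that the nominal non-centered eye reports a small
  negative (against-the-rule) value.  The alternative ``cylinder`` variant
  returns twice that.
* Horizontal coma is the orthonormal coefficient c3^+1 in micrometres.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from . import paraxial
from .eye_model import EyeSystem
from .raytrace import AimingError, TraceResult, aim_rays, trace_system

DEFAULT_GRID_N = 64


# ---------------------------------------------------------------------------
# Zernike basis (OSA/ANSI double index, unit-variance normalization)
# ---------------------------------------------------------------------------

def zernike_nm_list(max_order: int) -> list[tuple[int, int]]:
    """(n, m) pairs up to radial order ``max_order`` in OSA single-index order."""
    return [(n, m) for n in range(max_order + 1) for m in range(-n, n + 1, 2)]


def osa_index(n: int, m: int) -> int:
    return (n * (n + 2) + m) // 2


def zernike_nm(n: int, m: int, rho, theta):
    """Orthonormal Zernike polynomial Z_n^m on the unit disk.

    Unit-variance normalization: <Z^2> = 1 over the disk, so a coefficient in
    micrometres is the RMS contribution of that mode.
    """
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    am = abs(m)
    if (n - am) % 2 != 0 or am > n:
        raise ValueError(f"invalid Zernike indices (n={n}, m={m})")
    radial = np.zeros_like(rho)
    for k in range((n - am) // 2 + 1):
        coef = ((-1) ** k * math.factorial(n - k)
                / (math.factorial(k)
                   * math.factorial((n + am) // 2 - k)
                   * math.factorial((n - am) // 2 - k)))
        radial = radial + coef * rho ** (n - 2 * k)
    norm = math.sqrt(2 * (n + 1)) if m != 0 else math.sqrt(n + 1.0)
    if m > 0:
        return norm * radial * np.cos(m * theta)
    if m < 0:
        return norm * radial * np.sin(am * theta)
    return norm * radial


@dataclass
class ZernikeCoeffs:
    """Fitted Zernike coefficients (um) with the fit diagnostics."""

    values: np.ndarray
    nm: list[tuple[int, int]]
    residual_rms_um: float
    condition_number: float

    def get(self, n: int, m: int) -> float:
        try:
            return float(self.values[self.nm.index((n, m))])
        except ValueError:
            return 0.0

    def to_dict(self) -> dict:
        return {f"c{n}^{m:+d}": float(v) for (n, m), v in zip(self.nm, self.values)}


# ---------------------------------------------------------------------------
# OPD map
# ---------------------------------------------------------------------------

@dataclass
class OPDMap:
    """Sampled exit-pupil wavefront.

    ``px``/``py`` are normalized pupil coordinates (the stop-plane grid
    divided by the stop radius; chief ray at the origin), ``opd_um`` the OPD
    relative to the chief ray, NaN outside the valid mask.
    """

    px: np.ndarray
    py: np.ndarray
    opd_um: np.ndarray
    mask: np.ndarray
    pupil_radius_mm: float
    wavelength_um: float
    pitch_mm: float
    metadata: dict = field(default_factory=dict)

    @property
    def rho(self) -> np.ndarray:
        return np.hypot(self.px, self.py)

    @property
    def theta(self) -> np.ndarray:
        return np.arctan2(self.py, self.px)

    @property
    def valid_fraction(self) -> float:
        incircle = self.rho <= 1.0
        return float(np.count_nonzero(self.mask & incircle)
                     / max(1, np.count_nonzero(incircle)))


def make_zernike_screen(coeffs: dict[tuple[int, int], float],
                        pupil_radius_mm: float = 2.0,
                        grid_n: int = DEFAULT_GRID_N,
                        wavelength_um: float = 0.5) -> OPDMap:
    """Synthetic OPD map with exactly the stated Zernike content (oracle aid)."""
    px, py, incircle = _pupil_grid(grid_n)
    rho = np.hypot(px, py)
    theta = np.arctan2(py, px)
    opd = np.zeros_like(px)
    for (n, m), c in coeffs.items():
        opd += c * zernike_nm(n, m, rho, theta)
    opd = np.where(incircle, opd, np.nan)
    return OPDMap(px=px, py=py, opd_um=opd, mask=incircle,
                  pupil_radius_mm=pupil_radius_mm,
                  wavelength_um=wavelength_um,
                  pitch_mm=2.0 * pupil_radius_mm / grid_n,
                  metadata={"synthetic": True, "coeffs": dict(coeffs)})


def _pupil_grid(grid_n: int):
    """Cell-centred normalized pupil grid, symmetric about both axes."""
    s = (np.arange(grid_n) + 0.5) / grid_n * 2.0 - 1.0
    px, py = np.meshgrid(s, s, indexing="xy")
    incircle = px ** 2 + py ** 2 <= 1.0
    return px, py, incircle


def fit_zernike(opd: OPDMap, max_order: int = 6) -> ZernikeCoeffs:
    """Least-squares Zernike fit on the masked unit disk."""
    nm = zernike_nm_list(max_order)
    valid = opd.mask & np.isfinite(opd.opd_um) & (opd.rho <= 1.0)
    nval = int(np.count_nonzero(valid))
    if nval < 4 * len(nm):
        raise ValueError(
            f"too few valid samples ({nval}) for {len(nm)} coefficients "
            f"(need >= {4 * len(nm)})")
    rho = opd.rho[valid]
    theta = opd.theta[valid]
    a = np.column_stack([zernike_nm(n, m, rho, theta) for n, m in nm])
    b = opd.opd_um[valid]
    coeffs, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < len(nm):
        raise ValueError(f"rank-deficient Zernike design matrix (rank {rank} "
                         f"< {len(nm)})")
    cond = float(np.linalg.cond(a))
    if cond >= 100.0:
        warnings.warn(f"Zernike design-matrix condition number {cond:.1f} >= 100",
                      stacklevel=2)
    resid = b - a @ coeffs
    return ZernikeCoeffs(values=coeffs, nm=nm,
                         residual_rms_um=float(np.sqrt(np.mean(resid ** 2))),
                         condition_number=cond)


# ---------------------------------------------------------------------------
# Ray bundle over the stop; OPD referenced to the exit-pupil sphere
# ---------------------------------------------------------------------------

@dataclass
class PupilTrace:
    """Traced bundle over the stop grid (chief ray appended last)."""

    grid_n: int
    px: np.ndarray
    py: np.ndarray
    incircle: np.ndarray
    result: TraceResult
    z_exit_pupil_mm: float
    pupil_radius_mm: float
    stop_center_x_mm: float
    aim_converged: np.ndarray


def make_aim_cache(system: EyeSystem, grid_n: int = DEFAULT_GRID_N) -> dict:
    """Pre-solve the stop aiming for a system; reusable across misalignments.

    The aiming only involves the optics in front of the stop, which lens
    misalignment does not touch, so a sweep can share one cache.
    """
    px, py, incircle = _pupil_grid(grid_n)
    r_p = system.stop.semi_aperture_mm
    cx = system.stop.decentration_x_mm
    tx = cx + r_p * px[incircle]
    ty = r_p * py[incircle]
    targets = np.column_stack([np.append(tx, cx), np.append(ty, 0.0)])
    p0, u0, opl0, conv = aim_rays(system, targets)
    if not conv[-1]:
        raise AimingError("chief-ray aiming failed")
    return {"grid_n": grid_n, "p0": p0, "u0": u0, "opl0": opl0, "conv": conv,
            "px": px, "py": py, "incircle": incircle}


def pupil_trace(system: EyeSystem, grid_n: int = DEFAULT_GRID_N,
                aim_cache: dict | None = None,
                grin_step_mm: float | None = None) -> PupilTrace:
    """Aim a uniform grid over the stop and trace it through the system."""
    if aim_cache is None or aim_cache["grid_n"] != grid_n:
        aim_cache = make_aim_cache(system, grid_n)
    kwargs = {} if grin_step_mm is None else {"grin_step_mm": grin_step_mm}
    res = trace_system(system, aim_cache["p0"], aim_cache["u0"],
                       opl=aim_cache["opl0"], to_image=False, **kwargs)
    res.alive &= aim_cache["conv"]
    if not res.alive[-1]:
        raise AimingError("chief ray lost while tracing the system")
    return PupilTrace(grid_n=grid_n, px=aim_cache["px"], py=aim_cache["py"],
                      incircle=aim_cache["incircle"], result=res,
                      z_exit_pupil_mm=paraxial.exit_pupil_z_mm(system),
                      pupil_radius_mm=system.stop.semi_aperture_mm,
                      stop_center_x_mm=system.stop.decentration_x_mm,
                      aim_converged=aim_cache["conv"])


def opd_at_plane(pt: PupilTrace, z_image_mm: float):
    """OPD values (um) of the bundle w.r.t. the chief ray for an image plane.

    Returns (opd per masked sample (last = chief, always 0), chief image
    point (3,), reference-sphere radius mm).
    """
    res = pt.result
    pts, opl = res.propagate_to_plane(z_image_mm)
    chief_pt = pts[-1]
    r_ref = z_image_mm - pt.z_exit_pupil_mm
    e = pts - chief_pt
    eu = np.sum(e * res.exit_directions, axis=1)
    e_sq = np.sum(e * e, axis=1)
    disc = np.clip(eu * eu - e_sq + r_ref * r_ref, 0.0, None)
    s = eu + np.sqrt(disc)
    opl_sphere = opl - res.n_image * s
    opd_um = (opl_sphere[-1] - opl_sphere) * 1000.0
    return opd_um, chief_pt, r_ref


def sample_wavefront(system: EyeSystem, grid_n: int = DEFAULT_GRID_N,
                     aim_cache: dict | None = None,
                     pt: PupilTrace | None = None) -> OPDMap:
    """Exit-pupil OPD map of the system at its frozen image plane."""
    if system.image_plane_z_mm is None:
        raise ValueError("system has no image plane; run find_best_focus / "
                         "focus_system first")
    if pt is None:
        pt = pupil_trace(system, grid_n, aim_cache)
    opd_vals, chief_pt, r_ref = opd_at_plane(pt, system.image_plane_z_mm)
    n = pt.grid_n
    opd = np.full((n, n), np.nan)
    mask = np.zeros((n, n), dtype=bool)
    alive = pt.result.alive[:-1]
    opd[pt.incircle] = np.where(alive, opd_vals[:-1], np.nan)
    mask[pt.incircle] = alive
    m = OPDMap(px=pt.px, py=pt.py, opd_um=opd, mask=mask,
               pupil_radius_mm=pt.pupil_radius_mm,
               wavelength_um=system.wavelength_um,
               pitch_mm=2.0 * pt.pupil_radius_mm / n,
               metadata={
                   "image_plane_z_mm": system.image_plane_z_mm,
                   "reference_sphere_radius_mm": r_ref,
                   "chief_image_point_mm": chief_pt.tolist(),
                   "exit_pupil_z_mm": pt.z_exit_pupil_mm,
                   "stop_center_x_mm": pt.stop_center_x_mm,
               })
    if m.valid_fraction < 0.9:
        warnings.warn(
            f"only {100 * m.valid_fraction:.1f}% of pupil samples valid "
            "(vignetting); Zernike fit may be distorted", stacklevel=2)
    return m


# ---------------------------------------------------------------------------
# Best focus
# ---------------------------------------------------------------------------

def _rms_after_piston_tilt(opd_vals, px, py, alive):
    a = np.column_stack([np.ones(px.size), px, py])[alive]
    b = opd_vals[alive]
    coef, *_ = np.linalg.lstsq(a, b, rcond=None)
    r = b - a @ coef
    return float(np.sqrt(np.mean(r * r)))


def _rms_spot(pt: PupilTrace, z_image_mm: float) -> float:
    """RMS transverse spot radius about the centroid (alternative criterion)."""
    pts, _ = pt.result.propagate_to_plane(z_image_mm)
    alive = pt.result.alive[:-1]
    xy = pts[:-1, :2][alive]
    c = xy.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((xy - c) ** 2, axis=1))))


def find_best_focus(system: EyeSystem, grid_n: int = 48,
                    criterion: str = "rms_wavefront",
                    bracket_halfwidth_mm: float = 2.5,
                    xatol_mm: float = 1e-4,
                    pt: PupilTrace | None = None) -> float:
    """Image-plane z minimizing the residual wavefront error (or spot size).

    1-D bounded minimization (golden-section/Brent, tolerance 1e-4 mm) around
    the paraxial focus.  ``criterion`` is ``rms_wavefront`` (RMS OPD after
    piston+tilt removal; default, consistent with reporting wavefront-derived
    metrics) or ``rms_spot``.  The solved plane is meant to be frozen before
    a misalignment sweep and not re-optimized per scenario.
    """
    if pt is None:
        pt = pupil_trace(system, grid_n)
    z0 = paraxial.paraxial_focus_z_mm(system)
    if not np.isfinite(z0):
        z0 = system.metadata.get("anatomical_axial_length_mm",
                                 system.elements[-1].back_vertex_z_mm + 17.0)
        warnings.warn("paraxial focus is at infinity (zero-power lens?); "
                      "searching near the anatomical image plane", stacklevel=2)
    lo, hi = z0 - bracket_halfwidth_mm, z0 + bracket_halfwidth_mm
    px = np.append(pt.px[pt.incircle], 0.0)
    py = np.append(pt.py[pt.incircle], 0.0)
    alive = pt.result.alive

    if criterion == "rms_wavefront":
        def objective(z):
            opd_vals, _, _ = opd_at_plane(pt, z)
            return _rms_after_piston_tilt(opd_vals, px, py, alive)
    elif criterion == "rms_spot":
        def objective(z):
            return _rms_spot(pt, z)
    else:
        raise ValueError(f"unknown focus criterion '{criterion}'")

    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol_mm})
    z_best = float(res.x)
    if min(z_best - lo, hi - z_best) < 5 * xatol_mm:
        warnings.warn("best-focus search ended at the bracket boundary; "
                      "the reported focus may not be a true minimum",
                      stacklevel=2)
    anat = system.metadata.get("anatomical_axial_length_mm")
    if anat is not None and abs(z_best - anat) > 2.0:
        warnings.warn(f"best focus at z={z_best:.2f} mm lies far from the "
                      f"anatomical retina ({anat:.2f} mm)", stacklevel=2)
    return z_best


def focus_system(system: EyeSystem, grid_n: int = 48,
                 criterion: str = "rms_wavefront") -> float:
    """Solve and freeze the best-focus image plane on the system (in place)."""
    z = find_best_focus(system, grid_n=grid_n, criterion=criterion)
    system.image_plane_z_mm = z
    system.metadata["image_plane_z_mm"] = z
    system.metadata["focus_criterion"] = criterion
    return z


# ---------------------------------------------------------------------------
# Diopter conversions and the reported metric triple
# ---------------------------------------------------------------------------

SQRT3 = math.sqrt(3.0)
SQRT6 = math.sqrt(6.0)


def defocus_to_diopters(c20_um: float, pupil_radius_mm: float) -> float:
    """Spherical-equivalent defocus M (dpt) from the orthonormal c2^0 (um)."""
    return -4.0 * SQRT3 * c20_um / pupil_radius_mm ** 2


def astigmatism_to_diopters(c22_um: float, pupil_radius_mm: float,
                            variant: str = "j0") -> float:
    """Regular 0/180-degree astigmatism (dpt) from the orthonormal c2^+2 (um).

    ``j0`` (default) returns the power-vector-type component
    -2*sqrt(6)*c22/r_p^2; ``cylinder`` returns twice that.
    """
    j0 = -2.0 * SQRT6 * c22_um / pupil_radius_mm ** 2
    if variant == "j0":
        return j0
    if variant == "cylinder":
        return 2.0 * j0
    raise ValueError(f"unknown astigmatism variant '{variant}'")


@dataclass
class RefractionMetrics:
    """The reported aberration triple plus symmetry diagnostics."""

    defocus_dpt: float
    astigmatism_0_180_dpt: float
    coma_horizontal_um: float
    oblique_astigmatism_dpt: float
    vertical_coma_um: float
    vignetted_fraction: float


@dataclass
class AnalysisResult:
    metrics: RefractionMetrics
    coeffs: ZernikeCoeffs
    opd: OPDMap


def metrics_from_coeffs(coeffs: ZernikeCoeffs, pupil_radius_mm: float,
                        astig_variant: str = "j0",
                        vignetted_fraction: float = 0.0) -> RefractionMetrics:
    return RefractionMetrics(
        defocus_dpt=defocus_to_diopters(coeffs.get(2, 0), pupil_radius_mm),
        astigmatism_0_180_dpt=astigmatism_to_diopters(
            coeffs.get(2, 2), pupil_radius_mm, astig_variant),
        coma_horizontal_um=coeffs.get(3, 1),
        oblique_astigmatism_dpt=astigmatism_to_diopters(
            coeffs.get(2, -2), pupil_radius_mm, astig_variant),
        vertical_coma_um=coeffs.get(3, -1),
        vignetted_fraction=vignetted_fraction,
    )


def analyze_system(system: EyeSystem, grid_n: int = DEFAULT_GRID_N,
                   max_order: int = 6, astig_variant: str = "j0",
                   aim_cache: dict | None = None) -> AnalysisResult:
    """Trace, build the OPD map, fit Zernikes and report the metric triple."""
    pt = pupil_trace(system, grid_n, aim_cache)
    opd = sample_wavefront(system, grid_n, pt=pt)
    coeffs = fit_zernike(opd, max_order=max_order)
    vf = 1.0 - opd.valid_fraction
    metrics = metrics_from_coeffs(coeffs, opd.pupil_radius_mm, astig_variant, vf)
    return AnalysisResult(metrics=metrics, coeffs=coeffs, opd=opd)
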