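"""YAML serialization of eye-model and IOL prescriptions.

Schema (eye): surfaces[] with radius_mm / conic / semi_aperture_mm /
vertex_z_mm and either index or grin{...} for the following medium, plus
stop{diameter_mm, decentration_x_mm}, field_angle_deg, wavelength_um.
"""

from __future__ import annotations

import math
from dataclasses import asdict

import yaml

from .eye_model import (ConicSurface, EyeSystem, GrinMedium, IOLDesign,
                        Medium, MisalignmentState, OpticalElement, Stop)


def _medium_to_dict(m: Medium) -> dict:
    if m.is_grin:
        g = m.grin
        return {"grin": {"n00": g.n00, "a1": g.a1, "a2": g.a2, "b1": g.b1,
                         "valid_thickness_mm": g.valid_thickness_mm,
                         "origin_z_mm": g.origin_z_mm}}
    return {"index": m.index}


def _medium_from_dict(d: dict) -> Medium:
    if "grin" in d:
        return Medium(grin=GrinMedium(**d["grin"]))
    return Medium(index=float(d["index"]))


def _surface_to_dict(s: ConicSurface) -> dict:
    d = {"radius_mm": None if math.isinf(s.radius_mm) else s.radius_mm,
         "conic": s.conic, "semi_aperture_mm": s.semi_aperture_mm,
         "vertex_z_mm": s.vertex_z_mm}
    if s.a4 or s.a6:
        d["a4"] = s.a4
        d["a6"] = s.a6
    return d


def _surface_from_dict(d: dict) -> ConicSurface:
    radius = d.get("radius_mm")
    return ConicSurface(radius_mm=math.inf if radius is None else float(radius),
                        conic=float(d.get("conic", 0.0)),
                        semi_aperture_mm=float(d.get("semi_aperture_mm", 5.0)),
                        vertex_z_mm=float(d.get("vertex_z_mm", 0.0)),
                        a4=float(d.get("a4", 0.0)), a6=float(d.get("a6", 0.0)))


def system_to_dict(system: EyeSystem) -> dict:
    elements = []
    for i, el in enumerate(system.elements):
        elements.append({
            "label": el.label,
            "is_lens": el.is_lens,
            "surfaces": [_surface_to_dict(s) for s in el.surfaces],
            "internal_media": [_medium_to_dict(m) for m in el.media],
            "medium_after": _medium_to_dict(system.media_after[i]),
            "misalignment": asdict(el.misalignment),
        })
    return {
        "elements": elements,
        "ambient": _medium_to_dict(system.ambient),
        "stop": {"z_mm": system.stop.z_mm,
                 "diameter_mm": 2.0 * system.stop.semi_aperture_mm,
                 "decentration_x_mm": system.stop.decentration_x_mm},
        "field_angle_deg": system.field_angle_deg,
        "wavelength_um": system.wavelength_um,
        "image_plane_z_mm": system.image_plane_z_mm,
        "metadata": dict(system.metadata),
    }


def system_from_dict(d: dict) -> EyeSystem:
    elements, media_after = [], []
    for e in d["elements"]:
        mis = e.get("misalignment", {})
        elements.append(OpticalElement(
            label=e.get("label", "element"),
            surfaces=tuple(_surface_from_dict(s) for s in e["surfaces"]),
            media=tuple(_medium_from_dict(m) for m in e.get("internal_media", [])),
            misalignment=MisalignmentState(
                decentration_x_mm=float(mis.get("decentration_x_mm", 0.0)),
                tilt_y_deg=float(mis.get("tilt_y_deg", 0.0)),
                pivot_z_mm=float(mis.get("pivot_z_mm", 0.0))),
            is_lens=bool(e.get("is_lens", False))))
        media_after.append(_medium_from_dict(e["medium_after"]))
    stop = d["stop"]
    return EyeSystem(
        elements=tuple(elements),
        media_after=tuple(media_after),
        stop=Stop(z_mm=float(stop["z_mm"]),
                  semi_aperture_mm=0.5 * float(stop["diameter_mm"]),
                  decentration_x_mm=float(stop.get("decentration_x_mm", 0.0))),
        ambient=_medium_from_dict(d.get("ambient", {"index": 1.0})),
        field_angle_deg=float(d.get("field_angle_deg", 0.0)),
        wavelength_um=float(d.get("wavelength_um", 0.555)),
        image_plane_z_mm=d.get("image_plane_z_mm"),
        metadata=dict(d.get("metadata", {})),
    )


def save_system(system: EyeSystem, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(system_to_dict(system), fh, sort_keys=False)


def load_system(path) -> EyeSystem:
    with open(path) as fh:
        return system_from_dict(yaml.safe_load(fh))


def save_iol(iol: IOLDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(iol), fh, sort_keys=False)


def load_iol(path) -> IOLDesign:
    with open(path) as fh:
        return IOLDesign(**yaml.safe_load(fh))


def opd_to_csv(opd, path) -> None:
    """Export an OPD map as CSV rows (rho, theta, OPD_um) over valid samples."""
    import numpy as np
    valid = opd.mask & np.isfinite(opd.opd_um)
    rows = np.column_stack([opd.rho[valid], opd.theta[valid],
                            opd.opd_um[valid]])
    header = "rho,theta_rad,opd_um"
    np.savetxt(path, rows, delimiter=",", header=header, comments="")


def opd_to_png(opd, path, cmap: str = "RdBu_r") -> None:
    """False-color PNG of an OPD map over the pupil."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    img = np.where(opd.mask, opd.opd_um, np.nan)
    lim = float(np.nanmax(np.abs(img))) or 1e-9
    fig, ax = plt.subplots(figsize=(4.4, 3.8))
    im = ax.imshow(img, origin="lower", cmap=cmap, vmin=-lim, vmax=lim,
                   extent=(-1, 1, -1, 1))
    ax.set_xlabel("pupil x / r_p")
    ax.set_ylabel("pupil y / r_p")
    fig.colorbar(im, ax=ax, label="OPD [um]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def surface_points_to_csv(trace_result, path) -> None:
    """Debug dump: per-surface intersection points of a recorded trace.

    Requires a trace run with ``record_surfaces=True``; rows are
    (surface_index, ray_index, x_mm, y_mm, z_mm).
    """
    import numpy as np
    rows = []
    for si, pts in enumerate(trace_result.surface_points):
        for ri, p in enumerate(pts):
            rows.append((si, ri, p[0], p[1], p[2]))
    np.savetxt(path, np.asarray(rows), delimiter=",",
               header="surface_index,ray_index,x_mm,y_mm,z_mm", comments="")
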