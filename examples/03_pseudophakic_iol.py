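"""Replace the crystalline lens by an intraocular lens and compare designs.

The IOL's haptic plane is aligned to the natural lens equator, the image
plane is re-focused, and the nominal aberration triple is compared between
(a) a generic aberration-correcting conic asphere (spherical aberration
nulled over its 6-mm optic) and (b) an equiconvex spherical lens of the same
power and material.
"""

from ocusim import (analyze_system, build_phakic_eye, build_pseudophakic_eye,
                    focus_system)
from ocusim.eye_model import (design_aberration_correcting_iol,
                              make_equiconvex_iol)

phakic = build_phakic_eye()
focus_system(phakic, grid_n=48)

aspheric = design_aberration_correcting_iol()
spherical = make_equiconvex_iol()
print(f"aspheric IOL : R = +-{aspheric.front_radius_mm:.3f} mm, front conic "
      f"Q = {aspheric.front_conic:.2f}, {aspheric.labelled_power_dpt:.0f} dpt")
print(f"spherical IOL: R = +-{spherical.front_radius_mm:.3f} mm, "
      f"{spherical.labelled_power_dpt:.0f} dpt, same silicone "
      f"(n = {spherical.material_index})\n")

for iol in (aspheric, spherical):
    pseudo = build_pseudophakic_eye(phakic, iol, focus_grid_n=48)
    res = analyze_system(pseudo, grid_n=64)
    m = res.metrics
    c40 = res.coeffs.get(4, 0)
    print(f"{iol.label:22s}: focus z {pseudo.image_plane_z_mm:.3f} mm | "
          f"defocus {m.defocus_dpt:+.4f} dpt | astig "
          f"{m.astigmatism_0_180_dpt:+.4f} dpt | coma "
          f"{m.coma_horizontal_um:+.4f} um | SA c4^0 {c40:+.4f} um")

print()
print("The aberration-correcting design nulls the eye's spherical")
print("aberration over its full 6-mm optic (a small residual remains at the")
print("4-mm, 5-degree-field analysis above); the spherical lens leaves a")
print("large c4^0 that blurs the retinal point image even when centred.")
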