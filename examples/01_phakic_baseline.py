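"""Build the non-centered schematic phakic eye and report its nominal optics.

The model eye has aspheric corneal surfaces, a two-half gradient-index
crystalline lens, a pupil decentred 0.5 mm nasally and an incoming beam
tilted 5 degrees (angle alpha).  The image plane is placed at the best focus
and the residual second/third-order aberrations are reported.
"""

from ocusim import analyze_system, build_phakic_eye, focus_system, paraxial_oracle

eye = build_phakic_eye(pupil_diameter_mm=4.0, wavelength_um=0.5)
power, bfd = paraxial_oracle(eye)
print(f"equivalent power : {power:.2f} dpt (paraxial matrix oracle)")
print(f"back focal dist. : {bfd:.3f} mm behind the posterior lens vertex")

z_focus = focus_system(eye, grid_n=48)
print(f"best-focus plane : z = {z_focus:.4f} mm "
      f"(anatomical axial length 23.95 mm)")

result = analyze_system(eye, grid_n=64)
m = result.metrics
print(f"nominal defocus     : {m.defocus_dpt:+.4f} dpt")
print(f"nominal astigmatism : {m.astigmatism_0_180_dpt:+.4f} dpt "
      "(negative = against-the-rule)")
print(f"nominal coma        : {m.coma_horizontal_um:+.4f} um (horizontal)")
print(f"oblique astig / vertical coma: {m.oblique_astigmatism_dpt:.2e} dpt / "
      f"{m.vertical_coma_um:.2e} um (zero by plane symmetry)")
print()
print("Even perfectly positioned, the non-centered eye carries a small")
print("against-the-rule astigmatism and a small horizontal coma from the")
print("5-degree obliquity of the visual axis; defocus is near zero because")
print("the retina was placed at the best focus.")
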