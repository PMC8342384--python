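"""Point-spread functions across misalignment scenarios.

Renders the 3x3 gallery (decentration -0.6/0/+0.6 mm x tilt -6/0/+6 deg)
of diffraction PSFs for the phakic eye, and prints the encircled-energy spot
summary of the spherical comparison IOL at nominal alignment.
"""

import warnings

from ocusim import (build_phakic_eye, build_pseudophakic_eye,
                    central_spot_diameter, compute_psf, encircled_energy,
                    focus_system, sample_wavefront, set_misalignment)
from ocusim.eye_model import make_equiconvex_iol
from ocusim.psf_metrics import psf_montage
from ocusim.wavefront import make_aim_cache

warnings.filterwarnings("ignore")
eye = build_phakic_eye()
focus_system(eye, grid_n=48)

cache = make_aim_cache(eye, 64)
grids = {}
for t in (6.0, 0.0, -6.0):
    for d in (-0.6, 0.0, 0.6):
        scen = set_misalignment(eye, d, t)
        opd = sample_wavefront(scen, 64, aim_cache=cache)
        grids[f"d={d:+.1f} mm, t={t:+.0f} deg"] = compute_psf(opd)
path = psf_montage(grids, "ocusim_out/psf_phakic_gallery.png",
                   title="phakic eye: PSF vs lens misalignment")
print(f"wrote {path} (shared linear intensity scale; coma's comet tail")
print("dominates every misaligned panel)\n")

spherical = build_pseudophakic_eye(build_phakic_eye(), make_equiconvex_iol(),
                                   focus_grid_n=48)
opd = sample_wavefront(spherical, 64)
psf = compute_psf(opd)
d80 = central_spot_diameter(psf, 0.8)
ee16 = encircled_energy(psf, 8.0)
print(f"spherical IOL at nominal alignment:")
print(f"  80%-energy spot diameter: {d80:.1f} um")
print(f"  energy inside a 16-um spot: {100 * ee16:.1f} %")
print("The uncorrected spherical aberration spreads the central spot far")
print("beyond the aberration-corrected designs.")
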