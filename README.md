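# ocusim

Optical simulation of combined **horizontal decentration** and
**vertical-axis tilt** of the lens in a non-centered schematic model eye —
for the natural crystalline lens (phakic eye) and for an implanted
intraocular lens (pseudophakic eye).

After cataract surgery the IOL's haptic plane aligns only approximately with
the natural lens equator; the resulting decentration/tilt induces refractive
errors that keratometry cannot explain. `ocusim` quantifies them: for each
misalignment scenario it reports the induced **defocus** (spherical
equivalent, dpt), **regular 0/180° astigmatism** (dpt) and **horizontal
coma** (µm), plus diffraction point-spread functions. It is a library for
ophthalmic-optics researchers and IOL designers; the `examples/` scripts and
a thin `ocusim` CLI sit on top of the importable API.

## Model and method

* **Schematic eye** — the anatomically based finite model eye: aspheric
  cornea (7.77 mm/−0.18, 6.40 mm/−0.60), aqueous 1.336, a two-half
  gradient-index crystalline lens
  `n(w,z) = 1.368 + 0.049057 z − 0.015427 z² − 0.001978 w²` (anterior) /
  `1.407 − 0.006605 z² − 0.001978 w²` (posterior), pupil decentred 0.5 mm
  nasally at the anterior lens vertex, incoming beam tilted 5° in the
  horizontal plane (angle α). Stop diameter 4 mm, λ = 500 nm, collimated
  source.
* **Raytracing** — exact sequential 3-D tracing: Newton intersection with
  conic aspheres, vector Snell refraction, and fixed-step RK4 integration of
  the gradient-index ray equation `d/ds(n dr/ds) = ∇n` (step 10 µm) with
  bisected exit-surface crossing. Rays are aimed at a uniform grid on the
  stop by a 2-D Newton solver.
* **Wavefront** — optical path differences w.r.t. the chief ray on the
  exit-pupil reference sphere; least-squares fit of orthonormal (OSA/ANSI)
  Zernike polynomials to radial order 6; conversions
  `M = −4√3·c₂⁰/r_p²` and `J = −2√6·c₂⁺²/r_p²` with r_p = 2 mm; coma is
  c₃⁺¹ in µm. The fovea is placed at the best focus (minimum RMS wavefront)
  of the nominal eye and **frozen** before any misalignment.
* **Sweep** — decentration −1.0…+1.0 mm (step 0.2) × tilt −10…+10° (step
  2°): 11 × 11 = 121 scenarios per eye. By plane symmetry the oblique
  astigmatism and vertical coma vanish identically.
* **PSF** — Fourier optics on the sampled pupil function; Strehl ratio,
  encircled energy and the 80%-energy central-spot diameter.

## Worked example

```python
from ocusim import (analyze_system, build_phakic_eye, focus_system,
                    run_sweep, summarize_extrema)

eye = build_phakic_eye(pupil_diameter_mm=4.0, wavelength_um=0.5)
focus_system(eye, grid_n=48)          # freeze the retina at best focus
m = analyze_system(eye, grid_n=64).metrics
print(f"defocus {m.defocus_dpt:+.4f} dpt | astig {m.astigmatism_0_180_dpt:+.4f} dpt"
      f" | coma {m.coma_horizontal_um:+.4f} um")
sweep = run_sweep(eye, grid_n=64)     # the 121-scenario grid
for kind, e in summarize_extrema(sweep)["coma_horizontal_um"].items():
    print(f"coma {kind}: {e.value:+.4f} um at ({e.decentration_mm:+.1f} mm, "
          f"{e.tilt_deg:+.0f} deg)")
```

prints:

```
defocus -0.0017 dpt | astig -0.0502 dpt | coma -0.0213 um
coma max: +0.4234 um at (+1.0 mm, +10 deg)
coma min: -0.4901 um at (-1.0 mm, -10 deg)
```

At perfect alignment the non-centered eye keeps a small against-the-rule
astigmatism (−0.05 dpt) and coma (−0.02 µm) from the 5° obliquity of the
visual axis, and essentially zero defocus (retina at best focus). Combined
positive decentration and tilt drive all three aberrations to their positive
extremes — up to ~0.42 µm of coma, which spectacles cannot correct — while
the opposite corner mirrors the coma to −0.49 µm.

The same workflow applies to the pseudophakic eye
(`build_pseudophakic_eye(eye, design_aberration_correcting_iol())`), with
the IOL's haptic plane aligned to the natural lens equator. Or from a shell:

```bash
ocusim sweep --eye both --grid 11x11 --out results/
ocusim psf --eye phakic
ocusim validate
```

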