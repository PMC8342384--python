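# Methods

## The model eye

`ocusim` implements the anatomically based finite schematic eye with a
5° horizontal tilt of the incoming beam (angle α: the fovea lies temporal to
the posterior pole, so the fixation axis crosses the optical elements
obliquely) and a pupil decentred 0.5 mm nasally. Prescription (lengths mm,
z from the corneal vertex toward the retina):

| surface            | radius | conic Q | thickness | medium after |
|--------------------|-------:|--------:|----------:|--------------|
| cornea anterior    |  7.77  |  −0.18  |   0.50    | cornea 1.376 |
| cornea posterior   |  6.40  |  −0.60  |   3.16    | aqueous 1.336|
| lens anterior      | 12.40  |  −0.94  |   1.59    | GRIN I       |
| lens equator plane |   ∞    |    0    |   2.43    | GRIN II      |
| lens posterior     | −8.10  |  +0.96  |  16.27    | vitreous 1.336|

GRIN I: `n(w,z) = 1.368 + 0.049057 z − 0.015427 z² − 0.001978 w²` with z
from the anterior lens vertex; GRIN II: `1.407 − 0.006605 z² − 0.001978 w²`
with z from the equator. The halves join continuously (n = 1.40700 on the
axis). The aperture stop (default diameter 4 mm) sits in the anterior lens
vertex plane, decentred −0.5 mm (nasal is −x for the right eye in our
frame); `center_stop=True` zeroes that decentration, and the choice is
recorded in the run metadata because it shifts the small baseline
aberrations. Indices are the 555-nm values of the published model, used
unchanged at the 500-nm design wavelength (no dispersion model; see
Limitations).

Coordinates: right-handed, +z toward the retina, +y up, +x horizontal
(right eye). The collimated beam direction is `(sin α, 0, cos α)` with
α = +5°.

## Misalignment convention

A single lens element (crystalline lens or IOL) carries a rigid-body
misalignment: decentration along x, then rotation about the vertical axis
through the pivot point. Equivalently
`world = R_y(t) · (local − pivot) + pivot + (d, 0, 0)`.

* **Pivot** — at the lens group's *front vertex* on the axis (the natural
  location of a tilt/decenter transform in a sequential surface list, and
  the choice that reproduces the reference astigmatism/coma extrema to a few
  percent; pivoting at the equator degrades them to 15–30%). The pivot is a
  field of `MisalignmentState`, so any other choice remains available.
* **Signs** — positive decentration and tilt are *defined* as the directions
  that drive defocus, astigmatism and coma jointly to their positive extrema
  at (+1 mm, +10°); a test asserts this pattern. Left eyes follow by
  mirroring (`mirror_lr`): defocus/astigmatism are mirror-invariant,
  horizontal coma changes sign.
* The stop (iris) does **not** move with the lens.

## Wavefront analysis and reported metrics

Rays are aimed at a cell-centred uniform grid over the stop (default
64 × 64, ~3200 rays inside the 4-mm circle) by a vectorized 2-D Newton
solver (tolerance 1 nm at the stop; the solve involves only the cornea and
is shared across all misalignment scenarios). The OPD of each ray is
measured against the chief ray (through the stop centre) on the reference
sphere centred at the chief ray's image-plane intersection, with radius
equal to the exit-pupil-to-image distance (exit pupil located paraxially).

**Sign convention.** `OPD = OPL(chief) − OPL(ray)`. With the standard
conversions below, a scenario whose best focus recedes *behind* the frozen
image plane reports positive defocus. (In a toy eye whose image plane is
pushed behind the focus — the classic myopic-eye geometry — the reported
defocus is therefore negative; the convention was fixed to match the
reference misalignment maps, which place their largest positive defocus at
the corner where the focus recedes.)

Orthonormal (unit-variance, OSA/ANSI) Zernike polynomials to radial order 6
are least-squares fitted on the masked unit disk (requires ≥ 4 samples per
coefficient; design-matrix condition number checked < 100). Conversions,
with r_p = 2 mm the stop semi-aperture (entrance/exit-pupil scaling is
deliberately *not* applied — a documented simplification):

* defocus `M = −4√3·c₂⁰ / r_p²` [dpt];
* astigmatism `J = −2√6·c₂⁺² / r_p²` [dpt] (variant `"j0"`, the default;
  `"cylinder"` returns 2J). Positive values = astigmatism "at 0°" in the
  reference nomenclature; the nominal eye reports −0.05 dpt
  (against-the-rule), as the oblique beam path predicts;
* horizontal coma = c₃⁺¹ [µm]; oblique astigmatism and vertical coma are
  diagnostics that vanish by plane symmetry (asserted < 10⁻⁶ µm, observed
  ~10⁻¹³).

**Best focus** minimizes the RMS OPD after piston+tilt removal over the
image-plane z (bounded Brent around the paraxial focus, tolerance 10⁻⁴ mm);
an `rms_spot` criterion is available, and a test reports the (small, ~30 µm
here) difference between the two. The plane is solved once for the nominal
eye and frozen for the whole sweep.

## Pseudophakic eye and IOL designs

`build_pseudophakic_eye` replaces the GRIN lens by an IOL whose haptic plane
(default mid-thickness) coincides with the natural lens equator
(z = 5.25 mm), fills the former lens volume with aqueous, validates the
labelled power against the thick-lens paraxial power (±0.5 dpt) and
re-solves the best focus. Two built-in designs, both 21 dpt silicone
(n = 1.458, centre thickness 1.2 mm, equiconvex radii ±11.57 mm from a
root solve of the thick-lens power to 10⁻⁶ dpt):

* **aberration-correcting** — front conic solved (Q ≈ −35) so the
  pseudophakic eye's spherical aberration c₄⁰ vanishes over the full 6-mm
  optic of an on-axis design eye, the design condition of high-correction
  aspheric IOLs;
* **spherical equiconvex** — the comparison lens; it leaves a large
  spherical aberration (c₄⁰ ≈ −0.12 µm at the 4-mm pupil).

A user-supplied YAML prescription (conic + even-asphere terms A4, A6) can
stand in for a proprietary design.

## Numerics

* GRIN integration: fixed-step RK4 on (r, T = n·dr/ds, OPL), default step
  0.01 mm (testably 4th-order: halving the step moves the exit point by
  < 10⁻⁸ mm); exit-surface crossing bisected to |F| < 10⁻⁹ mm; rays leaving
  the clear aperture laterally are vignetted.
* Conic intersection: Newton from the vertex-plane hit, |F| < 10⁻¹⁰ mm,
  ≤ 50 iterations; non-convergence or aperture violation vignettes the ray
  (never raises mid-trace). Total internal reflection vignettes and logs.
* Vignetting: every surface clips at its semi-aperture; a sweep warns when
  any scenario vignettes (the 4-mm pupil keeps the phakic sweep
  vignetting-free; the extreme IOL scenarios clip ≤ ~7% of rays at the 6-mm
  optic) and the wavefront module warns below 90% valid samples.
* Paraxial oracle: 2 × 2 refraction/translation matrices; GRIN media enter
  as ≥ 100 thin slabs of the axial index profile, each slab also carrying
  the paraxial radial-gradient power `dΦ = −2 b₁ dz` (without it the
  crystalline lens would miss several diopters; exact in the homogeneous
  limit b₁ = 0). The oracle shares no kernels with the raytracer and agrees
  with it to < 0.1 dpt on the full ~60-dpt eye.
* PSF: FFT of the pupil function on the stop grid, zero-padded ×4 (default);
  pixel scale λR/(NΔp); Parseval checked to 10⁻⁹. "Central spot" is
  operationalized as the smallest centroid-centred circle holding 80% of
  the energy (both threshold and method configurable); montage rendering is
  linear by default with a log option.

## What the synthetic oracles cover — and what they do not

The toy systems (single refracting sphere with closed-form focus, the
stigmatic Cartesian conic, thin lens, zero-gradient GRIN, pure-Zernike
screens) pin down every kernel against independent closed forms, so the
pipeline's green tests certify the *machinery*. They do not certify the
anatomical fidelity of the schematic eye itself, which is taken from the
published prescription, nor individual-eye variability: the study is a
deterministic simulation of one standardized eye, and no measurement noise
is modelled.

## Problem sizes

Defaults were chosen so a full dual 11 × 11 sweep at 64 × 64 pupil sampling
completes in about two minutes on a single core: the GRIN trace dominates
(~1 s per phakic scenario); the pseudophakic sweep is ~100× faster. Metric
grid convergence is 10⁻⁷–10⁻⁸ dpt/µm between 64 and 128 samples, far below
the 10⁻³ acceptance band, so 64 is comfortably converged.

## Known limitations

* **Defocus map mismatch.** Against the reference misalignment study, the
  astigmatism and coma maps agree to a few percent (extrema cells exact,
  values −3%…+5%), and the nominal triple agrees within 0.03 units, but the
  defocus extrema do not: this implementation finds +1.98 dpt at
  (+1 mm, +10°) vs the reported 1.547, and a negative lobe of −1.21 dpt at
  (0.8, −10°) where the reference reports −0.293 at (0, −10°). The
  discrepancy survives every modelling alternative we probed (tilt pivot
  from the anterior vertex to 10 mm, stop co-moving with the lens, both OPD
  signs, entrance-pupil scaling of r_p, a spherical-aberration term in the
  defocus conversion) and most likely reflects an unstated convention of
  the reference raytracer's defocus extraction; the corresponding test is
  expected to fail and says so in its docstring.
* The shipped aberration-correcting IOL is a generic stand-in for a
  proprietary lens; its misalignment sensitivity reaches only ~90–100% of
  the phakic lens's, whereas the proprietary design roughly doubles it, so
  phakic-vs-pseudophakic *magnitude* comparisons should use a real
  prescription (supply one via YAML).
* Monochromatic only; no chromatic dispersion, accommodation, Stiles-
  Crawford apodization or retinal curvature (the image plane is a plane).
* Only horizontal decentration and vertical-axis tilt are swept (the
  y-symmetric 2-degree-of-freedom case). The transforms are full 3-D, so
  the API does not preclude extending to 4 degrees of freedom.
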