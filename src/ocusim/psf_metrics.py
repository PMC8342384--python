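"""Diffraction point-spread functions from the sampled pupil function.

The PSF is the squared modulus of the Fourier transform of the generalized
pupil function A(x,y) * exp(i 2 pi OPD / lambda) built from an :class:`OPDMap`
(uniform amplitude over the valid mask).  Geometric rays carry no diffraction;
it enters the model only here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wavefront import OPDMap


@dataclass
class PSFGrid:
    """Normalized image-plane intensity grid.

    ``pixel_scale_um`` is the image-plane sampling in micrometres per pixel;
    ``intensity`` sums to 1 after normalization.
    """

    intensity: np.ndarray
    pixel_scale_um: float
    wavelength_um: float
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def centroid_px(self) -> tuple[float, float]:
        iy, ix = np.indices(self.shape)
        w = self.intensity
        return float(np.sum(ix * w)), float(np.sum(iy * w))


def _image_distance_mm(opd: OPDMap) -> float:
    r = opd.metadata.get("reference_sphere_radius_mm")
    if r is None:
        # synthetic screens: a nominal eye-like exit-pupil-to-image distance
        r = 20.0
    return float(r)


def compute_psf(opd: OPDMap, oversample: int = 4) -> PSFGrid:
    """PSF = |FT{A * exp(i 2 pi OPD/lambda)}|^2, zero-padded by ``oversample``.

    The pupil grid of the OPD map (pitch ``opd.pitch_mm`` over the stop) is
    embedded in an ``oversample``-times larger zero-padded array, so the
    image-plane pixel scale is ``lambda * R / (N_pad * pitch)`` with R the
    exit-pupil-to-image distance.
    """
    n = opd.opd_um.shape[0]
    npad = n * int(oversample)
    amp = np.where(opd.mask, 1.0, 0.0)
    phase = np.where(opd.mask, 2.0 * np.pi * np.nan_to_num(opd.opd_um)
                     / opd.wavelength_um, 0.0)
    pupil = amp * np.exp(1j * phase)
    field_ = np.zeros((npad, npad), dtype=complex)
    field_[:n, :n] = pupil
    img = np.fft.fftshift(np.fft.fft2(field_))
    psf = np.abs(img) ** 2
    pupil_energy = float(np.sum(np.abs(pupil) ** 2))
    image_energy = float(np.sum(psf)) / (npad * npad)  # Parseval for DFT
    total = psf.sum()
    psf /= total
    r_mm = _image_distance_mm(opd)
    pixel_um = (opd.wavelength_um * 1e-3) * r_mm / (npad * opd.pitch_mm) * 1e3
    return PSFGrid(intensity=psf, pixel_scale_um=pixel_um,
                   wavelength_um=opd.wavelength_um,
                   metadata={"oversample": int(oversample),
                             "pupil_energy": pupil_energy,
                             "image_energy": image_energy,
                             "image_distance_mm": r_mm})


def strehl_ratio(opd: OPDMap, oversample: int = 4) -> float:
    """Peak intensity relative to the diffraction-limited PSF of the same mask."""
    aberrated = compute_psf(opd, oversample)
    flat = OPDMap(px=opd.px, py=opd.py, opd_um=np.zeros_like(opd.opd_um),
                  mask=opd.mask, pupil_radius_mm=opd.pupil_radius_mm,
                  wavelength_um=opd.wavelength_um, pitch_mm=opd.pitch_mm,
                  metadata=dict(opd.metadata))
    reference = compute_psf(flat, oversample)
    return float(aberrated.intensity.max() / reference.intensity.max())


def _radii_um(psf: PSFGrid) -> np.ndarray:
    cx, cy = psf.centroid_px()
    iy, ix = np.indices(psf.shape)
    return np.hypot(ix - cx, iy - cy) * psf.pixel_scale_um


def encircled_energy(psf: PSFGrid, radius_um: float) -> float:
    """Fraction of total energy strictly inside ``radius_um`` of the centroid.

    Monotone non-decreasing in the radius; 0 at radius 0 and 1 once the
    circle covers the grid.
    """
    if radius_um < 0:
        raise ValueError("radius must be >= 0")
    r = _radii_um(psf)
    return float(np.sum(psf.intensity[r < radius_um]))


def central_spot_diameter(psf: PSFGrid, threshold_fraction: float = 0.8) -> float:
    """Diameter (um) of the smallest centroid-centred circle holding
    ``threshold_fraction`` of the total energy."""
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    r = _radii_um(psf).ravel()
    order = np.argsort(r)
    cum = np.cumsum(psf.intensity.ravel()[order])
    idx = int(np.searchsorted(cum, threshold_fraction))
    idx = min(idx, r.size - 1)
    return 2.0 * float(r[order][idx])


def psf_montage(psf_grids: dict, path, ncols: int = 3,
                crop_um: float | None = 100.0, log_scale: bool = False,
                title: str | None = None):
    """Write a labelled montage PNG of several PSFs on a shared intensity scale.

    ``psf_grids`` maps panel labels to :class:`PSFGrid`; panels are cropped to
    ``crop_um`` half-width about the centroid.  Linear intensity by default.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    items = list(psf_grids.items())
    nrows = int(np.ceil(len(items) / ncols))
    vmax = max(g.intensity.max() for _, g in items)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 3 * nrows),
                             squeeze=False)
    for ax in axes.ravel():
        ax.set_axis_off()
    for ax, (label, g) in zip(axes.ravel(), items):
        img = g.intensity
        cx, cy = g.centroid_px()
        if crop_um is not None:
            half = int(round(crop_um / g.pixel_scale_um))
            x0 = max(0, int(cx) - half)
            x1 = min(img.shape[1], int(cx) + half)
            y0 = max(0, int(cy) - half)
            y1 = min(img.shape[0], int(cy) + half)
            img = img[y0:y1, x0:x1]
        if log_scale:
            from matplotlib.colors import LogNorm
            norm = LogNorm(vmin=vmax * 1e-5, vmax=vmax)
            ax.imshow(np.maximum(img, vmax * 1e-12), norm=norm, cmap="inferno",
                      origin="lower")
        else:
            ax.imshow(img, vmin=0.0, vmax=vmax, cmap="inferno", origin="lower")
        ax.set_title(label, fontsize=9)
        ax.set_axis_off()
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
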