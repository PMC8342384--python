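"""The misalignment-grid experiment driver.

Runs the decentration x tilt grid (default +-1.0 mm step 0.2, +-10 deg step 2:
11 x 11 = 121 scenarios) on a focused eye, collects the reported metric triple
plus symmetry diagnostics per scenario, locates extrema and renders heatmaps.
The image plane is frozen at the nominal best focus and never re-optimized
per scenario.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import wavefront
from .eye_model import EyeSystem, set_misalignment
from .raytrace import AimingError

DEFAULT_DECENTRATIONS = tuple(np.round(np.arange(-1.0, 1.01, 0.2), 10))
DEFAULT_TILTS = tuple(np.round(np.arange(-10.0, 10.01, 2.0), 10))

SWEEP_COLUMNS = [
    "eye_kind", "decentration_mm", "tilt_deg",
    "defocus_dpt", "astigmatism_0_180_dpt", "coma_horizontal_um",
    "oblique_astigmatism_dpt", "vertical_coma_um",
    "vignetted_fraction", "ok",
]


def default_grid() -> tuple[tuple[float, ...], tuple[float, ...]]:
    """The reference misalignment grid: 11 decentrations x 11 tilts."""
    return DEFAULT_DECENTRATIONS, DEFAULT_TILTS


def run_sweep(system: EyeSystem,
              decentrations_mm=None, tilts_deg=None,
              grid_n: int = wavefront.DEFAULT_GRID_N,
              astig_variant: str = "j0",
              eye_kind: str | None = None) -> pd.DataFrame:
    """Run the misalignment grid on a focused system.

    Rows are ordered decentration-outer / tilt-inner.  The stop-plane ray
    aiming is solved once and shared by all scenarios (lens misalignment does
    not affect the optics in front of the stop).  A scenario whose chief-ray
    aiming or tracing fails is flagged ``ok = False`` (metrics NaN) and the
    run continues.
    """
    if system.image_plane_z_mm is None:
        raise ValueError("solve and freeze the best focus before sweeping "
                         "(wavefront.focus_system)")
    decentrations_mm = DEFAULT_DECENTRATIONS if decentrations_mm is None \
        else tuple(decentrations_mm)
    tilts_deg = DEFAULT_TILTS if tilts_deg is None else tuple(tilts_deg)
    if eye_kind is None:
        eye_kind = system.metadata.get("eye_kind", "custom")

    aim_cache = wavefront.make_aim_cache(system, grid_n)
    rows = []
    any_vignetting = 0.0
    for d in decentrations_mm:
        for t in tilts_deg:
            scenario = set_misalignment(system, d, t)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = wavefront.analyze_system(
                        scenario, grid_n=grid_n, astig_variant=astig_variant,
                        aim_cache=aim_cache)
                m = res.metrics
                rows.append((eye_kind, d, t, m.defocus_dpt,
                             m.astigmatism_0_180_dpt, m.coma_horizontal_um,
                             m.oblique_astigmatism_dpt, m.vertical_coma_um,
                             m.vignetted_fraction, True))
                any_vignetting = max(any_vignetting, m.vignetted_fraction)
            except (AimingError, ValueError) as exc:
                warnings.warn(f"scenario (d={d}, t={t}) failed: {exc}",
                              stacklevel=2)
                rows.append((eye_kind, d, t) + (np.nan,) * 6 + (False,))
    if any_vignetting > 0:
        warnings.warn(
            f"up to {100 * any_vignetting:.1f}% of pupil rays vignetted in "
            "some scenarios; Zernike fits there use the surviving rays",
            stacklevel=2)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


@dataclass(frozen=True)
class Extremum:
    value: float
    decentration_mm: float
    tilt_deg: float


def summarize_extrema(result: pd.DataFrame,
                      metrics=("defocus_dpt", "astigmatism_0_180_dpt",
                               "coma_horizontal_um")) -> dict:
    """Per-metric global max/min with their grid cells.

    Ties are broken toward the smallest (|decentration|, |tilt|), then
    lexicographically by (decentration, tilt).
    """
    out = {}
    ok = result[result["ok"]].copy()
    for metric in metrics:
        entry = {}
        for kind, sign in (("max", -1.0), ("min", 1.0)):
            sub = ok.assign(_v=sign * ok[metric],
                           _ad=ok["decentration_mm"].abs(),
                           _at=ok["tilt_deg"].abs())
            sub = sub.sort_values(
                ["_v", "_ad", "_at", "decentration_mm", "tilt_deg"],
                kind="mergesort")
            row = sub.iloc[0]
            entry[kind] = Extremum(value=float(row[metric]),
                                   decentration_mm=float(row["decentration_mm"]),
                                   tilt_deg=float(row["tilt_deg"]))
        out[metric] = entry
    return out


def render_heatmap(result: pd.DataFrame, metric: str, path,
                   eye_kind: str | None = None, cmap: str = "turbo"):
    """Heatmap of one metric: decentration on x, tilt on y, value in color.

    Color limits span the data min/max of the rendered panel.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result if eye_kind is None else result[result["eye_kind"] == eye_kind]
    pivot = df.pivot_table(index="tilt_deg", columns="decentration_mm",
                           values=metric)
    fig, ax = plt.subplots(figsize=(5.2, 4.2))
    ds, ts = pivot.columns.to_numpy(), pivot.index.to_numpy()
    im = ax.imshow(pivot.to_numpy(), origin="lower", aspect="auto", cmap=cmap,
                   extent=(ds.min(), ds.max(), ts.min(), ts.max()),
                   vmin=np.nanmin(pivot.values), vmax=np.nanmax(pivot.values))
    ax.set_xlabel("decentration [mm]")
    ax.set_ylabel("tilt [deg]")
    label = {"defocus_dpt": "defocus [dpt]",
             "astigmatism_0_180_dpt": "astigmatism 0/180 [dpt]",
             "coma_horizontal_um": "horizontal coma [um]"}.get(metric, metric)
    ax.set_title(f"{df['eye_kind'].iloc[0] if len(df) else ''}: {label}")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def render_all_heatmaps(result: pd.DataFrame, out_dir) -> list:
    """One PNG per metric per eye kind (6 files for a dual sweep)."""
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for kind in result["eye_kind"].unique():
        for metric in ("defocus_dpt", "astigmatism_0_180_dpt",
                       "coma_horizontal_um"):
            path = out_dir / f"heatmap_{kind}_{metric}.png"
            files.append(render_heatmap(result, metric, path, eye_kind=kind))
    return files


def write_outputs(result: pd.DataFrame, out_dir, run_config: dict | None = None):
    """Write the sweep CSV plus a JSON metadata record.

    The CSV uses '.' decimal separator, UTF-8, 4-decimal metric precision and
    a fixed header; the metadata JSON records the resolved conventions and a
    checksum of the numeric table.
    """
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "sweep.csv"
    formatted = result.copy()
    for col in SWEEP_COLUMNS[3:9]:
        formatted[col] = formatted[col].map(
            lambda v: f"{v:.4f}" if np.isfinite(v) else "nan")
    formatted.to_csv(csv_path, index=False, encoding="utf-8")
    checksum = hashlib.sha256(csv_path.read_bytes()).hexdigest()
    meta = {
        "conventions": {
            "opd_sign": "chief_minus_ray",
            "astigmatism_variant": "j0",
            "tilt_pivot": "lens_front_vertex",
            "pupil_radius_for_conversions_mm": "stop_semi_aperture",
        },
        "csv_sha256": checksum,
        "n_rows": int(len(result)),
        "run_config": run_config or {},
    }
    meta_path = out_dir / "sweep_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    return csv_path, meta_path
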