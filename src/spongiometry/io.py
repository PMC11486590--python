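"""Reading and writing of series, maps, boundaries and measurement tables.

Image volumes travel as NIfTI with the prep-time stack along the last
axis, accompanied by a JSON sidecar::

    {"prep_times_ms": [...], "pixel_spacing_mm": 0.52, "contrast_label": "T2"}

Boundaries are CSV files with ``x_mm,y_mm`` columns; measurements are
one-row-per-femoral-head CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .morphometry import GrowthPlateBoundary, LineProfileSet, MorphometryResult
from .relaxometry import MapSeries, RelaxationMap

__all__ = [
    "load_series",
    "save_series",
    "load_map",
    "save_map",
    "read_boundary_csv",
    "write_boundary_csv",
    "write_profiles_csv",
    "result_to_row",
]


def _affine(spacing: float) -> np.ndarray:
    return np.diag([spacing, spacing, 1.0, 1.0])


def load_series(series_path: str | Path, sidecar_path: str | Path) -> MapSeries:
    """Load a prepared image series (H, W, n_prep NIfTI) plus its sidecar."""
    meta = json.loads(Path(sidecar_path).read_text())
    data = np.asanyarray(nib.load(str(series_path)).dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D series volume, got shape {data.shape}")
    return MapSeries(
        images=np.moveaxis(data, -1, 0),
        prep_times=np.asarray(meta["prep_times_ms"], dtype=float),
        pixel_spacing=float(meta["pixel_spacing_mm"]),
        contrast_label=meta["contrast_label"],
    )


def save_series(series: MapSeries, series_path: str | Path, sidecar_path: str | Path) -> None:
    data = np.moveaxis(series.images, 0, -1)
    nib.save(nib.Nifti1Image(data, _affine(series.pixel_spacing)), str(series_path))
    Path(sidecar_path).write_text(
        json.dumps(
            {
                "prep_times_ms": series.prep_times.tolist(),
                "pixel_spacing_mm": series.pixel_spacing,
                "contrast_label": series.contrast_label,
            },
            indent=2,
        )
    )


def save_map(rmap: RelaxationMap, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write values/s0/rsq NIfTI maps plus a JSON provenance sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("values", "s0", "rsq"):
        p = out_dir / f"{stem}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(getattr(rmap, name), _affine(rmap.pixel_spacing)), str(p))
        paths[name] = p
    sidecar = out_dir / f"{stem}_map.json"
    sidecar.write_text(
        json.dumps(
            {
                "pixel_spacing_mm": rmap.pixel_spacing,
                "contrast_label": rmap.contrast_label,
                "shape": list(rmap.shape),
                "n_failed_pixels": int((~rmap.finite_mask).sum()),
            },
            indent=2,
        )
    )
    paths["sidecar"] = sidecar
    return paths


def load_map(values_path: str | Path, sidecar_path: str | Path) -> RelaxationMap:
    """Load a values map; companion ``*_s0``/``*_rsq`` volumes are optional."""
    meta = json.loads(Path(sidecar_path).read_text())
    values = np.asanyarray(nib.load(str(values_path)).dataobj, dtype=float)
    values_path = Path(values_path)

    def _companion(tag: str) -> np.ndarray:
        name = values_path.name.replace("_values", f"_{tag}")
        p = values_path.with_name(name)
        if name != values_path.name and p.exists():
            return np.asanyarray(nib.load(str(p)).dataobj, dtype=float)
        return np.full_like(values, np.nan) if tag == "s0" else np.where(np.isfinite(values), 1.0, np.nan)

    return RelaxationMap(
        values=values,
        s0=_companion("s0"),
        rsq=_companion("rsq"),
        pixel_spacing=float(meta["pixel_spacing_mm"]),
        contrast_label=meta["contrast_label"],
    )


def read_boundary_csv(path: str | Path, distal_hint) -> GrowthPlateBoundary:
    df = pd.read_csv(path)
    if not {"x_mm", "y_mm"} <= set(df.columns):
        raise ValueError("boundary CSV needs x_mm and y_mm columns")
    return GrowthPlateBoundary(
        points=df[["x_mm", "y_mm"]].to_numpy(float),
        distal_hint=np.asarray(distal_hint, dtype=float),
    )


def write_boundary_csv(boundary: GrowthPlateBoundary, path: str | Path) -> None:
    pd.DataFrame(boundary.points, columns=["x_mm", "y_mm"]).to_csv(path, index=False)


def write_profiles_csv(profile_set: LineProfileSet, path: str | Path) -> None:
    """Long-format per-profile table: line_id, depth_mm, value_ms."""
    n_lines, n_depths = profile_set.profiles.shape
    df = pd.DataFrame(
        {
            "line_id": np.repeat(np.arange(n_lines), n_depths),
            "depth_mm": np.tile(profile_set.depths, n_lines),
            "value_ms": profile_set.profiles.ravel(),
        }
    )
    df.to_csv(path, index=False)


def result_to_row(result: MorphometryResult, **extra) -> dict:
    row = {**extra, **result.to_dict()}
    if result.provenance:
        row["n_lines"] = result.provenance.get("n_lines")
        row["config_hash"] = result.provenance.get("config_hash")
    return row
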