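"""File I/O for the pipeline's standard formats.

Volumes travel as NIfTI (via nibabel) with voxel spacing in the affine;
surfaces as STL (via trimesh, ASCII or binary); waveforms as two-column CSV
(``time_s,velocity_mm_s``); profiles/summaries as CSV/JSON; and flow-field /
wall-metric snapshots as legacy-ASCII VTK files readable by ParaView.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthgen import ImageVolume, VelocityWaveform, VesselGeometry

__all__ = [
    "save_volume", "load_volume",
    "save_mask", "load_mask",
    "save_surface_stl",
    "save_waveform_csv", "load_waveform_csv",
    "save_ground_truth_json",
    "save_profile_csv",
    "write_vtk_structured", "write_vtk_wall_polyline",
    "load_config",
]


def save_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write an image volume as NIfTI with spacing/origin in the affine."""
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.intensities.astype(np.float32), affine),
             str(path))


def load_volume(path: str | Path) -> ImageVolume:
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    spacing = tuple(np.abs(np.diag(affine)[:3]))
    origin = tuple(affine[:3, 3])
    return ImageVolume(intensities=np.asanyarray(img.dataobj, dtype=float),
                       spacing=spacing, origin=origin)


def save_mask(mask, path: str | Path) -> None:
    """Write a segmentation mask in the same NIfTI container (uint8)."""
    import nibabel as nib

    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), str(path))


def load_mask(path: str | Path):
    from .segmentation import SegmentationMask
    vol = load_volume(path)
    return SegmentationMask(mask=vol.intensities > 0.5, spacing=vol.spacing,
                            origin=vol.origin)


def save_surface_stl(mesh, path: str | Path, ascii: bool = False) -> None:
    """Export a trimesh surface as STL (binary by default, ASCII on request)."""
    path = Path(path)
    if ascii:
        path.write_text(mesh.export(file_type="stl_ascii"))
    else:
        mesh.export(str(path), file_type="stl")


def save_waveform_csv(waveform: VelocityWaveform, path: str | Path) -> None:
    pd.DataFrame({"time_s": waveform.times,
                  "velocity_mm_s": waveform.velocities}).to_csv(path, index=False)


def load_waveform_csv(path: str | Path, heart_rate: float | None = None) -> VelocityWaveform:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    period = float(t[-1] - t[0])
    return VelocityWaveform(times=t, velocities=df["velocity_mm_s"].to_numpy(),
                            period=period,
                            heart_rate=heart_rate if heart_rate else 60.0 / period)


def save_ground_truth_json(geometry: VesselGeometry, path: str | Path,
                           n_samples: int = 120) -> None:
    """Sidecar with shape parameters, centerline polylines and D(s) samples."""
    from dataclasses import asdict

    out: dict = {"params": asdict(geometry.params), "branches": {}}
    for name in geometry.branches:
        pts, s, dia = geometry.centerline_points(name, n=n_samples)
        out["branches"][name] = {
            "points_mm": np.round(pts, 5).tolist(),
            "arclength_mm": np.round(np.asarray(s), 5).tolist(),
            "diameter_mm": np.round(np.asarray(dia), 5).tolist(),
        }
    Path(path).write_text(json.dumps(out))


def save_profile_csv(profile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Legacy-ASCII VTK writers (structured grid + wall polyline with point data)
# ---------------------------------------------------------------------------

def write_vtk_structured(flow, path: str | Path, sample: int = 0) -> None:
    """One time sample of a FlowField as a VTK structured grid (mm, mm/s, Pa)."""
    m = flow.mesh
    ni1, nj1 = m.X_mm.shape
    lines = ["# vtk DataFile Version 3.0", "avf_hemoflow flow field", "ASCII",
             "DATASET STRUCTURED_GRID", f"DIMENSIONS {ni1} {nj1} 1",
             f"POINTS {ni1 * nj1} float"]
    for j in range(nj1):
        for i in range(ni1):
            lines.append(f"{m.X_mm[i, j]:.6g} {m.Y_mm[i, j]:.6g} 0")
    u, v, p = flow.u[sample], flow.v[sample], flow.p[sample]
    lines.append(f"CELL_DATA {m.ni * m.nj}")
    lines.append("VECTORS velocity_mm_s float")
    for j in range(m.nj):
        for i in range(m.ni):
            lines.append(f"{u[i, j]:.6g} {v[i, j]:.6g} 0")
    lines.append("SCALARS pressure_pa float 1")
    lines.append("LOOKUP_TABLE default")
    for j in range(m.nj):
        for i in range(m.ni):
            lines.append(f"{p[i, j]:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk_wall_polyline(arclength: np.ndarray, point_data: dict[str, np.ndarray],
                            path: str | Path) -> None:
    """Wall metrics (TAWSS, OSI, ...) along the wall as a VTK polyline."""
    order = np.argsort(arclength)
    s = np.asarray(arclength)[order]
    n = len(s)
    lines = ["# vtk DataFile Version 3.0", "avf_hemoflow wall metrics", "ASCII",
             "DATASET POLYDATA", f"POINTS {n} float"]
    lines += [f"{si:.6g} 0 0" for si in s]
    lines.append(f"LINES 1 {n + 1}")
    lines.append(" ".join([str(n)] + [str(k) for k in range(n)]))
    lines.append(f"POINT_DATA {n}")
    for name, vals in point_data.items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.6g}" for v in np.asarray(vals)[order]]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> dict:
    """Pipeline run configuration (YAML with segmentation:/solver:/... blocks)."""
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}
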