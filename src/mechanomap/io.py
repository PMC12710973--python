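"""Readers and writers for the pipeline's on-disk formats.

Volumes travel as multi-page TIFF or NIfTI (voxel size in the header);
tables as CSV; point clouds as ASCII PLY (STL meshes import read-only via
trimesh); calibration models as JSON; configurations as YAML.  Stress is
always kPa and length always mm at every interface.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import PLYParseError, ValidationError
from .mrsignal import Detection, MRVolume
from .registration import PointCloud

__all__ = [
    "write_volume_tiff",
    "read_volume_tiff",
    "write_volume_nifti",
    "read_volume_nifti",
    "detections_to_frame",
    "write_detections_csv",
    "read_detections_csv",
    "write_point_cloud_ply",
    "read_point_cloud_ply",
    "read_mesh_as_cloud",
    "scene_to_frame",
    "load_yaml",
    "dump_yaml",
]


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def write_volume_tiff(volume: MRVolume, path) -> None:
    """Multi-page TIFF, one page per axial slice; voxel size in ImageJ tags."""
    dz, dy, dx = volume.voxel_size
    tifffile.imwrite(
        path,
        volume.intensities.astype(np.float32),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "mm", "axes": "ZYX"},
    )


def read_volume_tiff(path, voxel_size=None) -> MRVolume:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if voxel_size is None:
            try:
                tags = tf.pages[0].tags
                dx = tags["XResolution"].value
                dx = dx[1] / dx[0]
                dy = tags["YResolution"].value
                dy = dy[1] / dy[0]
                dz = float(tf.imagej_metadata.get("spacing", dx))
                voxel_size = (dz, dy, dx)
            except (KeyError, TypeError, AttributeError) as exc:
                raise ValidationError(
                    f"{path}: no voxel size metadata; pass voxel_size explicitly"
                ) from exc
    return MRVolume(intensities=np.asarray(data, dtype=float), voxel_size=voxel_size)


def write_volume_nifti(volume: MRVolume, path) -> None:
    """NIfTI-1 with the voxel size carried in the affine (mm units)."""
    dz, dy, dx = volume.voxel_size
    data = np.transpose(volume.intensities, (2, 1, 0))  # (z,y,x) -> (x,y,z)
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_volume_nifti(path) -> MRVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    return MRVolume(
        intensities=np.asarray(data),
        voxel_size=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
    )


# ---------------------------------------------------------------------------
# detection tables
# ---------------------------------------------------------------------------

DETECTION_COLUMNS = [
    "id", "session_time_days",
    "centroid_z_vox", "centroid_y_vox", "centroid_x_vox",
    "x_mm", "y_mm", "z_mm",
    "roi_mean", "background_mean", "sbr", "dark_area_px",
    "is_aggregate", "noise_sd", "normalized_signal",
    "stress_kPa", "stress_in_range",
]


def detections_to_frame(detections, session_time=None) -> pd.DataFrame:
    rows = []
    for det in detections:
        rows.append({
            "id": det.id,
            "session_time_days": session_time,
            "centroid_z_vox": det.centroid[0],
            "centroid_y_vox": det.centroid[1],
            "centroid_x_vox": det.centroid[2],
            "x_mm": det.position_mm[0],
            "y_mm": det.position_mm[1],
            "z_mm": det.position_mm[2],
            "roi_mean": det.roi_mean,
            "background_mean": det.background_mean,
            "sbr": det.sbr,
            "dark_area_px": det.dark_area_px,
            "is_aggregate": det.is_aggregate,
            "noise_sd": det.noise_sd,
            "normalized_signal": det.normalized_signal,
            "stress_kPa": det.stress_kPa,
            "stress_in_range": det.stress_in_range,
        })
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def write_detections_csv(detections, path, session_time=None) -> None:
    detections_to_frame(detections, session_time).to_csv(path, index=False)


def read_detections_csv(path) -> list[Detection]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(
            Detection(
                centroid=np.array(
                    [r.centroid_z_vox, r.centroid_y_vox, r.centroid_x_vox]
                ),
                position_mm=np.array([r.x_mm, r.y_mm, r.z_mm]),
                roi_mean=r.roi_mean,
                background_mean=r.background_mean,
                sbr=r.sbr,
                dark_area_px=int(r.dark_area_px),
                is_aggregate=bool(r.is_aggregate),
                noise_sd=r.noise_sd,
                normalized_signal=None if pd.isna(r.normalized_signal)
                else float(r.normalized_signal),
                stress_kPa=None if pd.isna(r.stress_kPa) else float(r.stress_kPa),
                stress_in_range=bool(r.stress_in_range),
                id=None if pd.isna(r.id) else int(r.id),
            )
        )
    return out


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------

def write_point_cloud_ply(cloud: PointCloud, path) -> None:
    """ASCII PLY with x/y/z vertex properties (mm)."""
    pts = cloud.points
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment frame {cloud.frame_label}\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("end_header\n")
        for p in pts:
            fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")


def read_point_cloud_ply(path) -> PointCloud:
    """Read an ASCII PLY point cloud; parse errors report the line number."""
    path = Path(path)
    frame = ""
    n_vertex = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise PLYParseError(f"{path}:1: not a PLY file (missing 'ply' magic)")
    header_end = None
    for i, line in enumerate(lines[1:], start=2):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format" and tok[1] != "ascii":
            raise PLYParseError(f"{path}:{i}: only ascii PLY is supported")
        if tok[0] == "comment" and len(tok) >= 3 and tok[1] == "frame":
            frame = tok[2]
        if tok[0] == "element" and tok[1] == "vertex":
            try:
                n_vertex = int(tok[2])
            except (IndexError, ValueError):
                raise PLYParseError(f"{path}:{i}: bad vertex count") from None
        if tok[0] == "end_header":
            header_end = i
            break
    if header_end is None or n_vertex is None:
        raise PLYParseError(f"{path}: header missing end_header or vertex element")
    pts = []
    for i, line in enumerate(lines[header_end:header_end + n_vertex],
                             start=header_end + 1):
        tok = line.split()
        try:
            pts.append([float(tok[0]), float(tok[1]), float(tok[2])])
        except (IndexError, ValueError):
            raise PLYParseError(f"{path}:{i}: malformed vertex line {line!r}") from None
    if len(pts) != n_vertex:
        raise PLYParseError(
            f"{path}: expected {n_vertex} vertices, file ends after {len(pts)}"
        )
    return PointCloud(points=np.array(pts), frame_label=frame)


def read_mesh_as_cloud(path, max_points: int = 2000) -> PointCloud:
    """Load a surface mesh (STL/PLY via trimesh) as a subsampled point cloud."""
    import trimesh

    mesh = trimesh.load(str(path))
    verts = np.asarray(mesh.vertices)
    if len(verts) > max_points:
        step = int(np.ceil(len(verts) / max_points))
        verts = verts[::step]
    return PointCloud(points=verts, frame_label=Path(path).stem)


# ---------------------------------------------------------------------------
# scenes, configs
# ---------------------------------------------------------------------------

def scene_to_frame(scene) -> pd.DataFrame:
    """Ground-truth table: one row per (particle, session)."""
    rows = []
    for p in scene.particles:
        for s, t in enumerate(scene.session_times):
            rows.append({
                "particle_id": p.id,
                "session_time_days": float(t),
                "x_mm": p.positions[s, 0],
                "y_mm": p.positions[s, 1],
                "z_mm": p.positions[s, 2],
                "true_stress_kPa": p.true_stress[s],
                "is_aggregate_cluster": p.is_aggregate_cluster,
            })
    return pd.DataFrame(rows)


def load_yaml(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out if out is not None else {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
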