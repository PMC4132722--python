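"""File formats: MRC volumes (via gemmi), STAR-like TSV pose tables, YAML configs.

All lengths are nm in memory; MRC headers store the cell in angstroms
(1 nm = 10 A), the native unit of the format.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

__all__ = [
    "write_mrc", "read_mrc",
    "write_reference", "read_reference",
    "write_pose_table", "read_pose_table",
    "write_config", "read_config",
    "write_fsc",
    "POSE_TABLE_COLUMNS",
]

POSE_TABLE_COLUMNS = [
    "tomogram_id", "particle_id", "polysome_id",
    "x_nm", "y_nm", "z_nm",
    "quat_w", "quat_x", "quat_y", "quat_z",
    "order_index", "closed", "topology_label",
]


def write_mrc(path, array: np.ndarray, voxel_size_nm: float) -> None:
    """Write a 3D volume as MRC/CCP4 mode-2 with voxel size in the header."""
    arr = np.ascontiguousarray(np.asarray(array), dtype=np.float32)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(arr)
    a = 10.0 * voxel_size_nm  # nm -> angstrom
    m.grid.unit_cell = gemmi.UnitCell(arr.shape[0] * a, arr.shape[1] * a,
                                      arr.shape[2] * a, 90, 90, 90)
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC volume; returns (array, voxel_size_nm)."""
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True)
    voxel_nm = m.grid.spacing[0] / 10.0
    return arr, float(voxel_nm)


def write_reference(directory, ref) -> None:
    """Reference map as MRC plus a JSON sidecar of body-frame landmarks (nm)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_mrc(directory / "reference.mrc", ref.density, ref.voxel_size)
    meta = {
        "landmarks_nm": {k: list(map(float, v)) for k, v in ref.landmarks.items()},
        "diameter_nm": ref.diameter,
        "mrna_direction": list(map(float, ref.mrna_direction)),
    }
    (directory / "reference_landmarks.json").write_text(json.dumps(meta, indent=2))


def read_reference(directory):
    from .ribosome import RibosomeReference

    directory = Path(directory)
    density, voxel = read_mrc(directory / "reference.mrc")
    meta = json.loads((directory / "reference_landmarks.json").read_text())
    return RibosomeReference(
        density=density,
        voxel_size=voxel,
        landmarks={k: np.asarray(v, dtype=float) for k, v in meta["landmarks_nm"].items()},
        diameter=float(meta["diameter_nm"]),
        mrna_direction=np.asarray(meta["mrna_direction"], dtype=float),
    )


def pose_table(poses, membership=None, mrna_order=None, closed=None,
               labels=None) -> pd.DataFrame:
    """Assemble the STAR-like particle table from poses and optional ground truth."""
    membership = membership or {}
    order_lookup: dict[str, int] = {}
    if mrna_order:
        for _, seq in mrna_order.items():
            for k, pid in enumerate(seq):
                order_lookup[pid] = k
    rows = []
    for p in poses:
        q = p.rotation.as_quat()  # scipy order: x, y, z, w
        poly = membership.get(p.particle_id, "")
        rows.append({
            "tomogram_id": p.tomogram_id or "",
            "particle_id": p.particle_id,
            "polysome_id": poly,
            "x_nm": p.position[0], "y_nm": p.position[1], "z_nm": p.position[2],
            "quat_w": q[3], "quat_x": q[0], "quat_y": q[1], "quat_z": q[2],
            "order_index": order_lookup.get(p.particle_id, -1),
            "closed": bool(closed[poly]) if closed and poly in closed else False,
            "topology_label": labels.get(poly, "") if labels else "",
        })
    return pd.DataFrame(rows, columns=POSE_TABLE_COLUMNS)


def write_pose_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_pose_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"tomogram_id": str, "particle_id": str,
                                              "polysome_id": str})


def poses_from_table(table: pd.DataFrame):
    """Rebuild Pose objects from a pose table."""
    from .ribosome import Pose

    poses = []
    for _, row in table.iterrows():
        rot = Rotation.from_quat([row.quat_x, row.quat_y, row.quat_z, row.quat_w])
        poses.append(Pose(
            particle_id=str(row.particle_id),
            position=np.array([row.x_nm, row.y_nm, row.z_nm], dtype=float),
            rotation=rot,
            tomogram_id=str(row.tomogram_id),
        ))
    return poses


def write_config(path, cfg) -> None:
    data = dataclasses.asdict(cfg)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_config(path, cls):
    data = yaml.safe_load(Path(path).read_text())
    for key in ("size_distribution",):
        if key in data and isinstance(data[key], dict):
            data[key] = {int(k): float(v) for k, v in data[key].items()}
    if "occupancy_nt" in data and isinstance(data["occupancy_nt"], list):
        data["occupancy_nt"] = tuple(data["occupancy_nt"])
    return cls(**data)


def write_fsc(path, freq_per_nm: np.ndarray, fsc: np.ndarray) -> None:
    pd.DataFrame({"freq_1_per_nm": freq_per_nm, "fsc": fsc}).to_csv(
        path, sep="\t", index=False)
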