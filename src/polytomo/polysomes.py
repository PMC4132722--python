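"""Grouping aligned particles into polyribosomes and placing the average back.

Polysome membership is defined by single-linkage proximity: particles whose
centres lie within a cutoff (default 1.5 x ribosome diameter = 40.5 nm) of
each other belong to the same polyribosome.  Neighbouring polysomal ribosomes
are not in contact — the mRNA alone holds them together — so the cutoff is
deliberately looser than touching distance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .simulate import Tomogram
from .volume import embed_volume

__all__ = ["PolysomeGroup", "group_particles", "place_back", "DEFAULT_CUTOFF_NM"]

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_NM = 40.5   # 1.5 x 27 nm ribosome diameter


@dataclass
class PolysomeGroup:
    polysome_id: str
    particle_ids: list
    poses: list
    tomogram_id: str | None = None

    def __len__(self):
        return len(self.poses)

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.poses])


def group_particles(poses, cutoff_nm: float = DEFAULT_CUTOFF_NM) -> list[PolysomeGroup]:
    """Single-linkage connected components of the centre-distance graph.

    Every particle lands in exactly one group; group ids are assigned in order
    of first appearance, so the output is deterministic for a given pose list.
    """
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")
    poses = list(poses)
    if not poses:
        return []
    positions = np.array([p.position for p in poses])
    # particles in different tomograms can never be neighbours: offset each
    # tomogram far apart before the spatial query
    tomo_ids = [p.tomogram_id or "" for p in poses]
    uniq = {t: i for i, t in enumerate(dict.fromkeys(tomo_ids))}
    span = max(np.ptp(positions), cutoff_nm)
    shifted = positions + np.array(
        [[uniq[t] * (span + 10 * cutoff_nm), 0.0, 0.0] for t in tomo_ids])

    tree = cKDTree(shifted)
    pairs = np.array(sorted(tree.query_pairs(cutoff_nm)), dtype=int)
    n = len(poses)
    if len(pairs):
        adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                         shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    _, labels = connected_components(adj, directed=False)

    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(order[lab], []).append(i)
    out = []
    for gid in sorted(groups):
        members = groups[gid]
        out.append(PolysomeGroup(
            polysome_id=f"poly{gid:04d}",
            particle_ids=[poses[i].particle_id for i in members],
            poses=[poses[i] for i in members],
            tomogram_id=poses[members[0]].tomogram_id,
        ))
    return out


def place_back(avg: np.ndarray, poses, canvas_shape, voxel_size: float,
               tomogram_id: str = "reconstruction") -> Tomogram:
    """Re-place the averaged map at each recovered pose (the reconstruction
    step that turns per-particle alignments back into a clean tomogram)."""
    canvas = np.zeros(tuple(canvas_shape), dtype=np.float64)
    size_nm = np.asarray(canvas_shape, dtype=float) * voxel_size
    halfbox = np.linalg.norm(avg.shape) / 2.0 * voxel_size
    for p in poses:
        if np.any(p.position < -halfbox) or np.any(p.position > size_nm + halfbox):
            logger.warning("pose %s outside canvas: skipped", p.particle_id)
            continue
        embed_volume(canvas, np.asarray(avg, dtype=np.float64), voxel_size,
                     p.matrix, p.position)
    return Tomogram(canvas.astype(np.float32), voxel_size, tomogram_id)
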