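"""Rotation utilities: near-uniform SO(3) grids, perturbation sets, gauge fixing.

Rotations are handled as :class:`scipy.spatial.transform.Rotation` objects
(unit quaternions internally); matrices are materialised only at the point of
volume resampling.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "fibonacci_directions",
    "rotation_grid",
    "perturbation_set",
    "mean_rotation",
    "angular_distance_deg",
    "gauge_fix",
]

_GOLDEN = (1.0 + 5.0**0.5) / 2.0


def fibonacci_directions(n: int) -> np.ndarray:
    """n near-uniformly distributed unit vectors (Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = 2.0 * np.pi * i / _GOLDEN
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def rotation_grid(spacing_deg: float) -> Rotation:
    """Near-uniform grid over SO(3) with the given angular spacing.

    View directions are Fibonacci-distributed at ``spacing_deg`` separation and
    combined with in-plane spins at the same step, the standard construction
    for exhaustive orientation searches.
    """
    if not 0.0 < spacing_deg <= 60.0:
        raise ValueError("angular spacing must be in (0, 60] degrees")
    spacing = np.radians(spacing_deg)
    n_dir = max(1, int(round(4.0 * np.pi / spacing**2)))
    dirs = fibonacci_directions(n_dir)
    n_psi = max(1, int(round(2.0 * np.pi / spacing)))
    psis = np.arange(n_psi) * 2.0 * np.pi / n_psi

    # rotation taking +z to each direction, with minimal twist
    z = np.array([0.0, 0.0, 1.0])
    quats = []
    for d in dirs:
        axis = np.cross(z, d)
        s = np.linalg.norm(axis)
        c = float(np.dot(z, d))
        if s < 1e-12:
            r_align = Rotation.identity() if c > 0 else Rotation.from_rotvec([np.pi, 0, 0])
        else:
            r_align = Rotation.from_rotvec(axis / s * np.arctan2(s, c))
        spins = Rotation.from_euler("z", psis[:, None])
        quats.append((r_align * spins).as_quat())
    # include the identity so already-aligned particles are representable
    quats.insert(0, np.array([[0.0, 0.0, 0.0, 1.0]]))
    return Rotation.from_quat(np.concatenate(quats))


def perturbation_set(delta_deg: float) -> Rotation:
    """Small rotations covering a ball of radius ~sqrt(3)*delta around identity.

    Rotation vectors on the 3x3x3 lattice with components in {-delta, 0, +delta}.
    """
    d = np.radians(delta_deg)
    g = np.array([-d, 0.0, d])
    vecs = np.array(np.meshgrid(g, g, g, indexing="ij")).reshape(3, -1).T
    return Rotation.from_rotvec(vecs)


def mean_rotation(rotations: Rotation) -> Rotation:
    """Chordal (quaternion eigenvector) mean of a set of rotations."""
    q = rotations.as_quat()
    if q.ndim == 1:
        return rotations
    m = q.T @ q
    w, v = np.linalg.eigh(m)
    return Rotation.from_quat(v[:, -1])


def angular_distance_deg(a: Rotation, b: Rotation) -> np.ndarray:
    """Geodesic angle(s) in degrees between rotations a and b (broadcast pairwise)."""
    return np.degrees((a.inv() * b).magnitude())


def gauge_fix(true: Rotation, est: Rotation) -> tuple[Rotation, np.ndarray]:
    """Remove the global-rotation gauge freedom of reference-free alignment.

    A reference-free average is determined only up to one rotation ``h`` of
    the average's body frame, which multiplies every estimate on the right:
    ``est_i ~ true_i * h``.  Estimates ``h`` (chordal mean) and returns it with
    the residual per-particle angular errors (deg).
    """
    h = mean_rotation(true.inv() * est)
    residual = angular_distance_deg(true * h, est)
    return h, residual
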