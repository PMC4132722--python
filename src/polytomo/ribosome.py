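"""Procedural ribosome reference map and rigid-body poses.

The 80S ribosome is modelled as a union of smooth ellipsoidal lobes: a large
60S body, a smaller 40S lobe, the 40S head with its beak, and the protruding
P1/P2 stalk of the 60S subunit.  The construction is deliberately asymmetric —
no rotation of 30 degrees or more maps the density onto itself — which is what
makes per-particle orientation recovery during subtomogram averaging
well-posed.

Body-frame convention (declared once, used everywhere):

* centre of mass at the origin;
* 40S lobe on the -y side;
* P1/P2 stalk protruding along +x;
* the mRNA channel spans the 40S lobe along a configurable axis (default x),
  entry on the + side, exit on the - side, default span 8 nm, so the mRNA
  travels through the ribosome in the -x direction.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation
from scipy.special import expit

__all__ = [
    "ShapeConfig",
    "RibosomeReference",
    "Pose",
    "SizingError",
    "ValidationError",
    "build_reference",
    "body_landmarks",
    "landmarks_world",
    "transform_pose",
]

LANDMARK_NAMES = ("mrna_entry", "mrna_exit", "stalk_tip", "head_apex", "center")


class SizingError(ValueError):
    """Requested box cannot contain the reference with the required margin."""


class ValidationError(ValueError):
    """A pose or reference violates its geometric contract."""


@dataclass(frozen=True)
class ShapeConfig:
    """Parameters of the procedural ribosome (all lengths in nm, body frame)."""

    diameter: float = 27.0
    channel_span: float = 8.0
    channel_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    channel_center: tuple[float, float, float] = (0.0, -8.5, 0.0)
    edge_softness: float = 0.08
    # (center, semi-axes, amplitude) of each smooth ellipsoidal lobe;
    # x/z anisotropy of the bodies plus the offset head and stalk remove all
    # approximate rotational self-symmetry
    lobes: tuple = (
        ((0.0, 3.5, -1.0), (11.0, 9.0, 7.5), 1.0),    # 60S body
        ((-1.0, -7.5, 0.0), (9.5, 5.5, 6.5), 0.9),    # 40S body
        ((4.0, -9.0, 7.0), (5.0, 4.5, 5.0), 1.0),     # 40S head + beak
        ((12.0, 2.5, 2.0), (5.0, 3.0, 3.0), 1.0),     # P1/P2 stalk
        # intra-subunit domains (rRNA helices / protein clusters): fixed small
        # bumps that give the map realistic spectral content at 3-6 nm scales,
        # without which resolution estimates in the few-nm regime would be
        # meaningless for a smooth blob
        ((2.7, 7.1, 0.9), (2.0, 2.0, 2.0), 0.5),
        ((1.7, 1.3, 2.2), (2.0, 2.0, 2.0), 0.5),
        ((-2.7, 3.3, 3.8), (2.0, 2.0, 2.0), 0.5),
        ((0.6, -1.4, -3.0), (2.0, 2.0, 2.0), 0.5),
        ((2.7, 5.6, -1.9), (2.0, 2.0, 2.0), 0.5),
        ((-0.4, 3.1, -2.5), (2.0, 2.0, 2.0), 0.5),
        ((2.2, 5.5, 3.5), (2.0, 2.0, 2.0), 0.5),
        ((-2.0, 2.3, 1.0), (2.0, 2.0, 2.0), 0.5),
        ((-1.3, 6.2, -1.8), (2.0, 2.0, 2.0), 0.5),
        ((2.3, -5.1, 1.5), (2.0, 2.0, 2.0), 0.5),
        ((0.7, -8.3, 3.9), (2.0, 2.0, 2.0), 0.5),
        ((2.5, -7.0, -1.1), (2.0, 2.0, 2.0), 0.5),
        ((-6.7, -7.8, -2.2), (2.0, 2.0, 2.0), 0.5),
        ((-5.0, -6.6, 1.0), (2.0, 2.0, 2.0), 0.5),
        ((-5.1, -5.3, -0.1), (2.0, 2.0, 2.0), 0.5),
    )
    stalk_tip: tuple[float, float, float] = (15.0, 2.5, 2.0)
    head_apex: tuple[float, float, float] = (4.0, -9.0, 10.0)


def body_landmarks(shape: ShapeConfig | None = None) -> dict[str, np.ndarray]:
    """Analytic body-frame landmark coordinates (before centre-of-mass shift)."""
    shape = shape or ShapeConfig()
    axis = np.asarray(shape.channel_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    mid = np.asarray(shape.channel_center, dtype=float)
    half = 0.5 * shape.channel_span
    return {
        "mrna_entry": mid + half * axis,
        "mrna_exit": mid - half * axis,
        "stalk_tip": np.asarray(shape.stalk_tip, dtype=float),
        "head_apex": np.asarray(shape.head_apex, dtype=float),
        "center": np.zeros(3),
    }


@dataclass
class RibosomeReference:
    """Procedural reference density plus body-frame landmarks."""

    density: np.ndarray            # [ix, iy, iz], arbitrary density units
    voxel_size: float              # nm / voxel
    landmarks: dict[str, np.ndarray]   # nm, body frame
    diameter: float                # nm
    mrna_direction: np.ndarray     # unit vector, direction of mRNA travel (entry -> exit)
    shape_config: ShapeConfig = field(default_factory=ShapeConfig)

    @property
    def origin_nm(self) -> np.ndarray:
        """Body-frame coordinate of voxel (0,0,0) (centred grid)."""
        return -(np.asarray(self.density.shape, dtype=float) - 1.0) / 2.0 * self.voxel_size

    def density_at(self, points_nm: np.ndarray) -> np.ndarray:
        """Trilinear density values at body-frame points (nm)."""
        pts = np.atleast_2d(points_nm)
        idx = (pts - self.origin_nm) / self.voxel_size
        return ndimage.map_coordinates(self.density, idx.T, order=1, mode="constant")


def _evaluate_density(coords: list[np.ndarray], shape: ShapeConfig,
                      lobe_shift: np.ndarray) -> np.ndarray:
    x, y, z = coords
    density = np.zeros_like(x)
    for center, semi, amp in shape.lobes:
        c = np.asarray(center, dtype=float) + lobe_shift
        a = np.asarray(semi, dtype=float)
        q = np.sqrt(((x - c[0]) / a[0]) ** 2
                    + ((y - c[1]) / a[1]) ** 2
                    + ((z - c[2]) / a[2]) ** 2)
        density += amp * expit((1.0 - q) / shape.edge_softness)
    return density


def build_reference(voxel_size: float, box_edge: int,
                    shape_config: ShapeConfig | None = None) -> RibosomeReference:
    """Build the procedural reference map on a centred grid.

    Deterministic for fixed inputs.  The lobe union is built twice: the second
    pass shifts all lobes by minus the first pass's centre of mass so the body
    frame origin coincides with the centre of mass.
    """
    shape = shape_config or ShapeConfig()
    if box_edge * voxel_size < 1.5 * shape.diameter:
        raise SizingError(
            f"box of {box_edge} voxels at {voxel_size} nm/voxel is smaller than "
            f"1.5 x diameter ({1.5 * shape.diameter:.1f} nm)"
        )
    grid_1d = (np.arange(box_edge) - (box_edge - 1) / 2.0) * voxel_size
    coords = list(np.meshgrid(grid_1d, grid_1d, grid_1d, indexing="ij"))

    rho = _evaluate_density(coords, shape, np.zeros(3))
    total = rho.sum()
    com = np.array([(rho * c).sum() / total for c in coords])
    rho = _evaluate_density(coords, shape, -com)

    landmarks = body_landmarks(shape)
    landmarks = {k: v - com for k, v in landmarks.items()}
    landmarks["center"] = np.zeros(3)

    axis = np.asarray(shape.channel_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    ref = RibosomeReference(
        density=rho.astype(np.float32),
        voxel_size=float(voxel_size),
        landmarks=landmarks,
        diameter=shape.diameter,
        mrna_direction=-axis,
        shape_config=shape,
    )
    _validate_reference(ref)
    return ref


def _validate_reference(ref: RibosomeReference) -> None:
    rho = ref.density
    if not np.all(np.isfinite(rho)) or rho.min() < 0:
        raise ValidationError("density must be non-negative and finite")
    threshold = 0.1 * float(rho.max())
    for name in LANDMARK_NAMES:
        if name not in ref.landmarks:
            raise ValidationError(f"missing landmark {name!r}")
        if ref.density_at(ref.landmarks[name])[0] <= threshold:
            raise ValidationError(f"landmark {name!r} lies outside the density support")
    entry, exit_ = ref.landmarks["mrna_entry"], ref.landmarks["mrna_exit"]
    if np.allclose(entry, exit_):
        raise ValidationError("mRNA entry and exit sites coincide")
    if entry[1] >= 0 or exit_[1] >= 0:
        raise ValidationError("mRNA entry/exit must lie on the 40S-lobe (-y) side")


@dataclass
class Pose:
    """Rigid placement (body -> world) of one ribosome in a tomogram.

    ``rotation`` is a proper rotation (orthonormal, det +1); stored as a unit
    quaternion via scipy's Rotation.
    """

    particle_id: str
    position: np.ndarray          # nm, tomogram frame
    rotation: Rotation
    tomogram_id: str | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValidationError("position must be a 3-vector")
        _check_rotation(self.rotation.as_matrix())

    @classmethod
    def from_matrix(cls, particle_id: str, position, matrix, tomogram_id=None) -> "Pose":
        matrix = np.asarray(matrix, dtype=float)
        _check_rotation(matrix)
        return cls(particle_id, np.asarray(position, dtype=float),
                   Rotation.from_matrix(matrix), tomogram_id)

    @property
    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()


def _check_rotation(matrix: np.ndarray) -> None:
    if matrix.shape != (3, 3):
        raise ValidationError("rotation must be a 3x3 matrix")
    if not np.allclose(matrix @ matrix.T, np.eye(3), atol=1e-6):
        raise ValidationError("rotation matrix is not orthonormal")
    if not np.isclose(np.linalg.det(matrix), 1.0, atol=1e-6):
        raise ValidationError("rotation matrix must have determinant +1")


def landmarks_world(pose: Pose, ref: RibosomeReference) -> dict[str, np.ndarray]:
    """World-frame image of every body-frame landmark: R @ x_body + t."""
    r = pose.matrix
    return {name: r @ coord + pose.position for name, coord in ref.landmarks.items()}


def transform_pose(pose: Pose, rotation: Rotation, translation) -> Pose:
    """Compose an extra world-frame rigid transform with a pose."""
    translation = np.asarray(translation, dtype=float)
    return Pose(
        particle_id=pose.particle_id,
        position=rotation.apply(pose.position) + translation,
        rotation=rotation * pose.rotation,
        tomogram_id=pose.tomogram_id,
    )
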