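"""Synthetic polyribosome fields with known ground truth.

Stands in for flash-frozen translation samples: polyribosomes of 2-10
ribosomes are laid out with one of five mRNA topologies, each ribosome
oriented so that its mRNA exit site faces the entry site of the next ribosome
along the message.  Every consecutive exit->entry spacer respects the
occupancy budget: a ribosome footprint of ~30 nt on an mRNA carrying
100-140 nt per ribosome leaves at most (occupancy - footprint) * 0.34 nm of
single-stranded spacer between neighbours.

Tomograms are rendered by trilinear placement of the reference density at
each pose, optionally filtered by the missing wedge of a limited tilt series
(default +-66 degrees) and degraded with additive white Gaussian noise at a
configured SNR.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .ribosome import (Pose, RibosomeReference, ShapeConfig, body_landmarks,
                       build_reference, transform_pose)
from .volume import embed_volume

__all__ = [
    "GeneratorConfig", "Tomogram", "GroundTruth", "GenerationError",
    "TOPOLOGIES", "CIRCULAR_TOPOLOGIES", "max_spacer_nm",
    "sample_polysome", "render_tomogram", "apply_missing_wedge",
    "simulate_condition",
]

TOPOLOGIES = ("circular_ring", "circular_double_row", "linear_double_row",
              "linear_single_row", "helical")
CIRCULAR_TOPOLOGIES = frozenset({"circular_ring", "circular_double_row"})

# Layout constants (nm).  The source data report no inter-ribosome centre
# distances; these are declared conventions chosen so that all generated links
# satisfy the occupancy spacer cap and the 120-degree bend cap with margin.
RING_SPACING = 27.0        # centre-to-centre chord on the ring
ROW_SPACING = 23.0         # within-row spacing of double rows
ROW_SEPARATION = 20.0      # distance between the two rows
ZIGZAG_STEP = 16.0         # axial half-step of the zigzag double row
ZIGZAG_SEPARATION = 16.0   # lateral offset of the zigzag rows
CHAIN_SPACING = 26.0       # single-row spacing
HELIX_RADIUS = 15.0
HELIX_TWIST_DEG = 60.0
HELIX_SPACING = 27.0       # centre distance between consecutive helix members
MIN_CENTER_DISTANCE_FACTOR = 0.8   # of the ribosome diameter


class GenerationError(ValueError):
    """Requested polysome geometry is infeasible under the current config."""


@dataclass
class GeneratorConfig:
    """Study conditions of one simulated translation experiment."""

    n_polysomes: int = 150
    size_distribution: dict = field(default_factory=lambda: {
        2: 0.05, 3: 0.08, 4: 0.14, 5: 0.20, 6: 0.20, 7: 0.18, 8: 0.10,
        9: 0.03, 10: 0.02})
    topology_mixture: dict = field(default_factory=lambda: {
        "circular_ring": 0.25, "circular_double_row": 0.25,
        "linear_double_row": 0.18, "linear_single_row": 0.18, "helical": 0.14})
    occupancy_nt: tuple = (100.0, 140.0)   # nt of mRNA per ribosome (sampling range)
    footprint_nt: float = 30.0             # nt covered by one ribosome
    nm_per_nt: float = 0.34                # ssRNA contour length
    coding_length_nt: float | None = None  # if set, occupancy = coding length / n
    snr: float = 0.5                       # signal variance / noise variance
    missing_wedge: bool = False
    tilt_half_angle_deg: float = 66.0
    orientation_jitter_deg: float = 5.0
    voxel_size: float = 2.0                # nm / voxel
    box_edge: int = 64                     # voxels per field tile (enlarged if needed)
    stratified_mixture: bool = True        # balanced topology allocation
    seed: int = 0

    def __post_init__(self):
        for name, dist in (("size_distribution", self.size_distribution),
                           ("topology_mixture", self.topology_mixture)):
            total = sum(dist.values())
            if not np.isclose(total, 1.0, atol=1e-8):
                raise ValueError(f"{name} weights must sum to 1 (got {total})")
        if any(k not in TOPOLOGIES for k in self.topology_mixture):
            raise ValueError("unknown topology in mixture")
        occ = self.occupancy_nt if np.iterable(self.occupancy_nt) else (
            self.occupancy_nt, self.occupancy_nt)
        self.occupancy_nt = (float(occ[0]), float(occ[-1]))
        if self.occupancy_nt[0] < self.footprint_nt:
            raise ValueError("occupancy must be at least the ribosome footprint")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not 0.0 < self.tilt_half_angle_deg <= 90.0:
            raise ValueError("tilt half-angle must be in (0, 90] degrees")


@dataclass
class Tomogram:
    density: np.ndarray | None
    voxel_size: float
    tomogram_id: str
    tilt_half_angle_deg: float | None = None  # None: no missing wedge

    def __post_init__(self):
        if self.density is not None and not np.all(np.isfinite(self.density)):
            raise ValueError("tomogram density must be finite")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows: poses, membership, mRNA order, labels."""

    poses: list
    membership: dict            # particle_id -> polysome_id
    mrna_order: dict            # polysome_id -> particle sequence (5' -> 3')
    closed: dict                # polysome_id -> bool
    topology_label: dict        # polysome_id -> label
    occupancy: dict = field(default_factory=dict)  # polysome_id -> nt/ribosome

    def validate(self) -> None:
        seen = set()
        for pid, poly in self.membership.items():
            if pid in seen:
                raise ValueError(f"particle {pid} in more than one polysome")
            seen.add(pid)
        for poly, seq in self.mrna_order.items():
            if len(set(seq)) != len(seq):
                raise ValueError(f"duplicate particle in mrna_order of {poly}")
            if {self.membership[p] for p in seq} != {poly}:
                raise ValueError(f"mrna_order of {poly} crosses polysomes")

    def n_links(self, polysome_id: str) -> int:
        n = len(self.mrna_order[polysome_id])
        if n <= 1:
            return 0
        return n if self.closed[polysome_id] else n - 1

    def to_table(self):
        from .io import pose_table
        return pose_table(self.poses, self.membership, self.mrna_order,
                          self.closed, self.topology_label)


def max_spacer_nm(occupancy_nt: float, footprint_nt: float = 30.0,
                  nm_per_nt: float = 0.34) -> float:
    """Longest admissible exit->entry spacer for a given occupancy budget."""
    return (occupancy_nt - footprint_nt) * nm_per_nt


def _occupancy_for(n: int, cfg: GeneratorConfig, rng: np.random.Generator) -> float:
    if cfg.coding_length_nt is not None:
        return cfg.coding_length_nt / n
    lo, hi = cfg.occupancy_nt
    return float(rng.uniform(lo, hi))


# ---------------------------------------------------------------------------
# Topology layouts: centres, 40S-side hints, closure flag (local frame)
# ---------------------------------------------------------------------------

def _layout_ring(n: int):
    radius = RING_SPACING / (2.0 * np.sin(np.pi / n))
    theta = 2.0 * np.pi * np.arange(n) / n
    centers = np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                               np.zeros(n)])
    inward = -centers / np.linalg.norm(centers, axis=1, keepdims=True)
    # stalks point along the circle: exits face the local tangent, so the
    # mRNA turns smoothly even on small rings where the chord direction
    # would put a sharp kink at every entry site
    tangent = np.column_stack([-np.sin(theta), np.cos(theta), np.zeros(n)])
    return centers, inward, True, tangent


def _layout_chain(n: int) -> tuple[np.ndarray, np.ndarray, bool]:
    centers = np.column_stack([CHAIN_SPACING * np.arange(n), np.zeros(n), np.zeros(n)])
    hints = np.tile([0.0, -1.0, 0.0], (n, 1))
    return centers, hints, False


def _layout_zigzag(n: int) -> tuple[np.ndarray, np.ndarray, bool]:
    x = ZIGZAG_STEP * np.arange(n)
    y = np.where(np.arange(n) % 2 == 0, -0.5, 0.5) * ZIGZAG_SEPARATION
    centers = np.column_stack([x, y, np.zeros(n)])
    hints = np.tile([0.0, 0.0, -1.0], (n, 1))
    return centers, hints, False


def _layout_double_row(n: int) -> tuple[np.ndarray, np.ndarray, bool]:
    # flattened ring: down row A (+x), U-turn, back row B (-x); the path ends
    # meet at the left flank where the closing link crosses the rows
    m_a = n // 2
    m_b = n - m_a
    row_a = np.column_stack([ROW_SPACING * np.arange(m_a),
                             np.full(m_a, ROW_SEPARATION / 2), np.zeros(m_a)])
    xb = ROW_SPACING * np.arange(m_b)[::-1]
    row_b = np.column_stack([xb, np.full(m_b, -ROW_SEPARATION / 2), np.zeros(m_b)])
    centers = np.vstack([row_a, row_b])
    hints = np.tile([0.0, 0.0, -1.0], (n, 1))
    return centers, hints, True


def _layout_helix(n: int) -> tuple[np.ndarray, np.ndarray, bool]:
    twist = np.radians(HELIX_TWIST_DEG)
    chord = 2.0 * HELIX_RADIUS * np.sin(twist / 2.0)
    rise = np.sqrt(max(HELIX_SPACING**2 - chord**2, 1.0))
    theta = twist * np.arange(n)
    centers = np.column_stack([HELIX_RADIUS * np.cos(theta),
                               HELIX_RADIUS * np.sin(theta),
                               rise * np.arange(n)])
    hints = np.column_stack([-np.cos(theta), -np.sin(theta), np.zeros(n)])
    return centers, hints, False


_LAYOUTS = {
    "circular_ring": _layout_ring,
    "circular_double_row": _layout_double_row,
    "linear_double_row": _layout_zigzag,
    "linear_single_row": _layout_chain,
    "helical": _layout_helix,
}


def _effective_topology(topology: str, n: int) -> str:
    """Geometry actually generated for a requested topology at size n.

    Small and odd-sized circular double rows are rendered as rings: a 2x2
    double row is a rectangle, whose corners are always concyclic (the square
    tetrasome is the canonical circular form), and a flattened ring with
    unequal rows needs an apex ribosome whose closing geometry would violate
    the bend cap.  Both forms are circular, so the topology-class mixture that
    matters for circularity statistics is unchanged.  Sizes below 3 cannot
    close at all and below 4 a helix is indistinguishable from a chain.
    """
    if n <= 2:
        return "linear_single_row"
    if topology == "circular_double_row" and (n <= 5 or n % 2 == 1):
        return "circular_ring"
    if topology == "circular_ring" and n < 3:
        return "linear_single_row"
    if topology == "helical" and n < 6:
        # below six members a 60-degree-twist helix spans less than one turn
        # and its centres are indistinguishable from a planar zigzag
        return "linear_single_row"
    return topology


def _orientations(centers: np.ndarray, closed: bool, hints: np.ndarray,
                  u_override: np.ndarray | None = None) -> list[Rotation]:
    """Rotation per ribosome: body -x (exit side) faces the next centre (or a
    layout-supplied direction), body -y (40S side) follows the hint as
    closely as orthogonality allows."""
    n = len(centers)
    rots = []
    for i in range(n):
        if u_override is not None:
            u = u_override[i]
        elif closed:
            u = centers[(i + 1) % n] - centers[i]
        elif i < n - 1:
            u = centers[i + 1] - centers[i]
        else:
            u = centers[i] - centers[i - 1]
        u = u / np.linalg.norm(u)
        v = hints[i] - np.dot(hints[i], u) * u
        nv = np.linalg.norm(v)
        if nv < 1e-9:  # hint parallel to chain: pick any perpendicular
            v = np.cross(u, [0.0, 0.0, 1.0])
            if np.linalg.norm(v) < 1e-9:
                v = np.cross(u, [0.0, 1.0, 0.0])
            nv = np.linalg.norm(v)
        v = v / nv
        col_x = -u              # R @ (+x) ; exit (-x) maps to +u
        col_y = -v              # R @ (+y) ; 40S side (-y) maps to +v
        col_z = np.cross(col_x, col_y)
        rots.append(Rotation.from_matrix(np.column_stack([col_x, col_y, col_z])))
    return rots


def _link_spacers(centers: np.ndarray, rots: list[Rotation], closed: bool,
                  landmarks: dict) -> np.ndarray:
    """Euclidean exit->entry distances of consecutive links (incl. closing)."""
    n = len(centers)
    if n <= 1:
        return np.zeros(0)
    exit_b, entry_b = landmarks["mrna_exit"], landmarks["mrna_entry"]
    exits = np.array([rots[i].apply(exit_b) + centers[i] for i in range(n)])
    entries = np.array([rots[i].apply(entry_b) + centers[i] for i in range(n)])
    pairs = [(i, i + 1) for i in range(n - 1)]
    if closed:
        pairs.append((n - 1, 0))
    return np.array([np.linalg.norm(entries[j] - exits[i]) for i, j in pairs])


def sample_polysome(topology: str, n_ribosomes: int, cfg: GeneratorConfig,
                    rng: np.random.Generator,
                    ref: RibosomeReference | None = None,
                    occupancy_nt: float | None = None):
    """One polyribosome in its local frame.

    Returns ``(poses, mrna_order, closed)`` with mrna_order the 5'->3' particle
    index sequence.  Raises :class:`GenerationError` when the occupancy budget
    cannot accommodate the geometry even after shrinking it to the closest
    allowed packing (0.8 x diameter between centres).
    """
    if not 1 <= n_ribosomes <= 12:
        raise GenerationError(f"n_ribosomes={n_ribosomes} outside supported range 1..12")
    if topology not in TOPOLOGIES:
        raise GenerationError(f"unknown topology {topology!r}")

    landmarks = ref.landmarks if ref is not None else body_landmarks()
    diameter = ref.diameter if ref is not None else ShapeConfig().diameter
    occupancy = occupancy_nt if occupancy_nt is not None else _occupancy_for(
        n_ribosomes, cfg, rng)
    cap = max_spacer_nm(occupancy, cfg.footprint_nt, cfg.nm_per_nt)

    if n_ribosomes == 1:
        pose = Pose("p0", np.zeros(3), Rotation.random(rng=rng))
        return [pose], [0], False

    effective = _effective_topology(topology, n_ribosomes)
    layout = _LAYOUTS[effective](n_ribosomes)
    centers0, hints, closed = layout[0], layout[1], layout[2]
    u_override = layout[3] if len(layout) > 3 else None
    shift = centers0.mean(axis=0)
    centers0 = centers0 - shift

    def spacers_at(scale: float):
        centers = centers0 * scale
        rots = _orientations(centers, closed, hints, u_override)
        return centers, rots, _link_spacers(centers, rots, closed, landmarks)

    # fit to 93% of the cap so orientation jitter cannot push a link over it
    fit_cap = 0.93 * cap
    centers, rots, spacers = spacers_at(1.0)
    if spacers.max() > fit_cap:
        # shrink uniformly, but never pack centres tighter than 0.8 x diameter
        dists = np.linalg.norm(centers0[:, None] - centers0[None, :], axis=-1)
        min_dist = dists[dists > 0].min()
        s_min = MIN_CENTER_DISTANCE_FACTOR * diameter / min_dist
        if s_min >= 1.0 or spacers_at(s_min)[2].max() > fit_cap:
            raise GenerationError(
                f"{topology} of {n_ribosomes} ribosomes infeasible: occupancy "
                f"{occupancy:.0f} nt allows spacers up to {cap:.1f} nm")
        lo, hi = s_min, 1.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if spacers_at(mid)[2].max() > fit_cap:
                hi = mid
            else:
                lo = mid
        centers, rots, spacers = spacers_at(lo)

    # orientation jitter: small random world-frame rotation about each centre
    sigma = np.radians(cfg.orientation_jitter_deg) / np.sqrt(3.0)
    for _ in range(20):
        if sigma > 0:
            jitter = [Rotation.from_rotvec(rng.normal(0.0, sigma, 3)) for _ in rots]
            rots_j = [j * r for j, r in zip(jitter, rots)]
        else:
            rots_j = rots
        if _link_spacers(centers, rots_j, closed, landmarks).max() <= cap:
            break
    else:
        raise GenerationError("orientation jitter keeps violating the spacer cap")

    poses = [Pose(f"p{i}", centers[i], rots_j[i]) for i in range(n_ribosomes)]
    return poses, list(range(n_ribosomes)), closed


def apply_missing_wedge(volume: np.ndarray, tilt_half_angle_deg: float,
                        beam_axis: int = 2, tilt_axis: int = 1) -> np.ndarray:
    """Zero the Fourier wedge left unsampled by a limited tilt series.

    A projection at tilt theta (about ``tilt_axis``, beam along ``beam_axis``)
    samples the central plane normal to the beam; tilting through
    +-tilt_half_angle sweeps every direction whose angle from the in-plane
    axis is at most the half-angle.  Directions closer to the beam axis are
    never sampled and are set exactly to zero.  The mask is symmetric under
    k -> -k, so the output stays real.
    """
    if not 0.0 < tilt_half_angle_deg <= 90.0:
        raise ValueError("tilt half-angle must be in (0, 90] degrees")
    in_plane_axis = ({0, 1, 2} - {beam_axis, tilt_axis}).pop()
    freqs = [np.fft.fftfreq(n) for n in volume.shape]
    grids = np.meshgrid(*freqs, indexing="ij")
    k_beam, k_plane = np.abs(grids[beam_axis]), np.abs(grids[in_plane_axis])
    missing = np.arctan2(k_beam, k_plane) > np.radians(tilt_half_angle_deg)
    spectrum = np.fft.fftn(volume)
    spectrum[missing] = 0.0
    return np.fft.ifftn(spectrum).real


def render_tomogram(poses, ref: RibosomeReference, cfg: GeneratorConfig,
                    rng: np.random.Generator, box_edge: int | None = None,
                    tomogram_id: str = "tomo") -> Tomogram:
    """Forward model: sum of posed reference copies + wedge filter + noise."""
    box = box_edge or cfg.box_edge
    margin = ref.diameter / 2.0
    size_nm = box * cfg.voxel_size
    canvas = np.zeros((box, box, box), dtype=np.float64)
    positions = np.array([p.position for p in poses]).reshape(-1, 3)
    if len(poses):
        if positions.min() < margin or positions.max() > size_nm - margin:
            raise GenerationError("pose outside the volume with the required margin")
        d = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
        crowding = d[np.triu_indices(len(poses), 1)]
        if crowding.size and crowding.min() < MIN_CENTER_DISTANCE_FACTOR * ref.diameter:
            warnings.warn("particles closer than 0.8 x diameter: crowded but physical",
                          stacklevel=2)
    for p in poses:
        embed_volume(canvas, ref.density.astype(np.float64), cfg.voxel_size,
                     p.matrix, p.position)
    wedge = cfg.tilt_half_angle_deg if cfg.missing_wedge else None
    if wedge is not None:
        canvas = apply_missing_wedge(canvas, wedge)
    signal_var = float(canvas.var())
    noise_sigma = np.sqrt(signal_var / cfg.snr) if signal_var > 0 else 1.0
    if np.isfinite(cfg.snr):
        canvas = canvas + rng.normal(0.0, noise_sigma, canvas.shape)
    return Tomogram(canvas.astype(np.float32), cfg.voxel_size, tomogram_id, wedge)


def _allocate_topologies(cfg: GeneratorConfig, rng: np.random.Generator) -> list[str]:
    """Topology per polysome: balanced largest-remainder allocation (default)
    or iid draws; both converge to the configured mixture."""
    labels = list(cfg.topology_mixture)
    weights = np.array([cfg.topology_mixture[t] for t in labels], dtype=float)
    if not cfg.stratified_mixture:
        return list(rng.choice(labels, size=cfg.n_polysomes, p=weights / weights.sum()))
    ideal = weights / weights.sum() * cfg.n_polysomes
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    for i in np.argsort(-remainder)[: cfg.n_polysomes - counts.sum()]:
        counts[i] += 1
    out = [lab for lab, c in zip(labels, counts) for _ in range(c)]
    rng.shuffle(out)
    return out


def simulate_condition(cfg: GeneratorConfig, ref: RibosomeReference | None = None,
                       render: bool = True):
    """Generate one experimental condition: tomogram tiles + ground truth.

    Each polyribosome is placed, under a random world rotation, at the centre
    of its own field tile (tiles grow beyond ``cfg.box_edge`` when a large
    polysome needs the margin).  Returns ``(tomograms, ground_truth)``;
    ``tomograms`` is None when ``render`` is False.
    """
    rng = np.random.default_rng(cfg.seed)
    if ref is None and render:
        ref_box = int(np.ceil(1.5 * ShapeConfig().diameter / cfg.voxel_size)) + 2
        ref = build_reference(cfg.voxel_size, ref_box + ref_box % 2)
    diameter = ref.diameter if ref is not None else ShapeConfig().diameter

    sizes = list(cfg.size_distribution)
    size_w = np.array([cfg.size_distribution[s] for s in sizes], dtype=float)
    size_w /= size_w.sum()
    topologies = _allocate_topologies(cfg, rng)

    poses_all, membership, mrna_order, closed_map, labels, occupancies = (
        [], {}, {}, {}, {}, {})
    tomograms = [] if render else None

    for k, requested in enumerate(topologies):
        n = int(rng.choice(sizes, p=size_w))
        occupancy = _occupancy_for(n, cfg, rng)
        local_poses, order, closed = sample_polysome(
            requested, n, cfg, rng, ref=ref, occupancy_nt=occupancy)
        poly_id = f"poly{k:04d}"
        tomo_id = f"tomo{k:04d}"

        extent = max((np.linalg.norm(p.position) for p in local_poses), default=0.0)
        need_vox = int(np.ceil(2.0 * (extent + diameter / 2.0 + 2.0) / cfg.voxel_size))
        tile_edge = max(cfg.box_edge, need_vox + need_vox % 2)
        center = np.full(3, tile_edge * cfg.voxel_size / 2.0)

        world_rot = Rotation.random(rng=rng)
        placed = []
        for i, p in enumerate(local_poses):
            q = transform_pose(p, world_rot, center)
            q.particle_id = f"{poly_id}_r{i}"
            q.tomogram_id = tomo_id
            placed.append(q)
        poses_all.extend(placed)
        membership.update({p.particle_id: poly_id for p in placed})
        mrna_order[poly_id] = [placed[i].particle_id for i in order]
        closed_map[poly_id] = closed
        labels[poly_id] = _effective_topology(requested, n)
        occupancies[poly_id] = occupancy

        if render:
            tomograms.append(render_tomogram(
                placed, ref, cfg, rng, box_edge=tile_edge, tomogram_id=tomo_id))

    gt = GroundTruth(poses_all, membership, mrna_order, closed_map, labels,
                     occupancies)
    gt.validate()
    return tomograms, gt
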