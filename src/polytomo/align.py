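"""Reference-free maximum-likelihood subtomogram averaging.

Each extracted subvolume X_i is modelled as a rotated copy of an unknown
average A plus white Gaussian noise of standard deviation sigma.  Orientation
is treated as a latent variable on a discrete near-uniform SO(3) grid and the
model is fitted by expectation-maximization:

    E-step   gamma(i,R)  proportional to  exp(-||X_i - T_R A||^2 / (2 sigma^2))
    M-step   A     <-  sum_i,R gamma(i,R) T_R^{-1}(X_i)  /  sum gamma
             sigma^2 <- mean responsibility-weighted residual

The initial average is the mean of the unaligned particles — no external
reference enters at any point.  Because rotations preserve the norm,
T_R^{-1} can be pulled out of the per-rotation weighted particle sums, so one
iteration costs one volume rotation per grid element plus a single matrix
product, independent of the particle count.

A second pass refines the grid around each particle's best orientation
(coarse-to-fine).  Resolution of the result is estimated by Fourier shell
correlation between averages of the even- and odd-indexed particle halves.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.spatial.transform import Rotation

from .simulate import Tomogram
from .so3 import perturbation_set, rotation_grid
from .volume import rotate_volume

__all__ = [
    "ParticleSet", "AlignmentConfig", "AlignmentResult",
    "ExtractionError", "extract_subtomograms", "ml_align", "fsc_resolution",
    "soft_spherical_mask",
]


class ExtractionError(ValueError):
    """A requested subtomogram crop falls outside the tomogram."""


@dataclass
class ParticleSet:
    subvolumes: np.ndarray            # (N, b, b, b), one box, one voxel size
    voxel_size: float
    positions: np.ndarray | None = None   # picked positions, nm
    particle_ids: list | None = None
    tomogram_id: str | None = None

    def __post_init__(self):
        if self.subvolumes.ndim != 4:
            raise ValueError("subvolumes must be a (N, b, b, b) stack")
        b = self.subvolumes.shape[1]
        if self.subvolumes.shape[2] != b or self.subvolumes.shape[3] != b:
            raise ValueError("subvolume boxes must be cubic and identical")

    def __len__(self):
        return self.subvolumes.shape[0]


@dataclass
class AlignmentConfig:
    """Knobs of the EM alignment; all defaults are plain method choices."""

    rotation_grid_deg: float = 15.0     # angular spacing of the global grid
    # coarse-to-fine local refinement levels (None: single pass)
    refine_grid_deg: float | tuple | None = (7.5, 3.75)
    n_iterations: int = 8                # EM iterations on the global grid
    refine_iterations: int = 4           # EM iterations per refinement level
    sigma: float | None = None           # noise sd; None: estimated from the data
    convergence_tol: float = 1e-4        # relative change of the average
    max_shift_voxels: int = 3            # translational search around the pick
    rotations: Rotation | None = None    # custom rotation set (overrides the grid)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.rotation_grid_deg <= 60.0:
            raise ValueError("angular spacing must be in (0, 60] degrees")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")


@dataclass
class AlignmentResult:
    average: np.ndarray
    voxel_size: float
    rotations: Rotation                  # per-particle estimate (responsibility mode)
    responsibilities: np.ndarray         # (N, n_rotations), rows sum to 1
    rotation_set: Rotation
    log_likelihood: list                 # one trace per pass
    half_averages: tuple                 # (even, odd)
    shifts: np.ndarray                   # (N, 3) integer voxel shifts applied
    sigma: float
    converged: bool

    def to_table(self, particle_ids=None) -> pd.DataFrame:
        n = len(self.responsibilities)
        ids = particle_ids or [f"p{i}" for i in range(n)]
        q = self.rotations.as_quat().reshape(n, 4)
        return pd.DataFrame({
            "particle_id": ids,
            "quat_w": q[:, 3], "quat_x": q[:, 0], "quat_y": q[:, 1], "quat_z": q[:, 2],
            "max_responsibility": self.responsibilities.max(axis=1),
            "shift_x": self.shifts[:, 0], "shift_y": self.shifts[:, 1],
            "shift_z": self.shifts[:, 2],
        })


def extract_subtomograms(tomogram: Tomogram, positions, box_edge: int,
                         particle_ids=None) -> ParticleSet:
    """Axis-aligned crops centred on the voxel nearest each position (nm)."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    ids = list(particle_ids) if particle_ids is not None else [
        f"p{i}" for i in range(len(positions))]
    vol = tomogram.density
    subs = np.empty((len(positions), box_edge, box_edge, box_edge),
                    dtype=vol.dtype)
    half = box_edge // 2
    for k, pos in enumerate(positions):
        c = np.rint(pos / tomogram.voxel_size).astype(int)
        lo = c - half
        hi = lo + box_edge
        if np.any(lo < 0) or np.any(hi > vol.shape):
            raise ExtractionError(
                f"particle {ids[k]} at {pos} nm: crop [{lo}..{hi}) outside "
                f"tomogram of shape {vol.shape}")
        subs[k] = vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return ParticleSet(subs, tomogram.voxel_size, positions, ids,
                       tomogram.tomogram_id)


def _rotate_stack(vol3: np.ndarray, matrices: np.ndarray,
                  inverse: bool = False) -> np.ndarray:
    out = np.empty((len(matrices), vol3.size), dtype=np.float32)
    for k, m in enumerate(matrices):
        out[k] = rotate_volume(vol3, m.T if inverse else m).ravel()
    return out


def _best_shifts(x_work, best_rot_avg, box, max_shift):
    """Integer-voxel shift per particle maximizing cross-correlation with its
    best-matching rotated average, restricted to +-max_shift."""
    n = len(x_work)
    shifts = np.zeros((n, 3), dtype=int)
    fa = np.fft.fftn(best_rot_avg.reshape(n, box, box, box), axes=(1, 2, 3))
    fx = np.fft.fftn(x_work.reshape(n, box, box, box), axes=(1, 2, 3))
    cc = np.fft.ifftn(fx * np.conj(fa), axes=(1, 2, 3)).real
    rng_ok = np.r_[0:max_shift + 1, box - max_shift:box] if max_shift < box else np.r_[0:box]
    for i in range(n):
        sub = cc[i][np.ix_(rng_ok, rng_ok, rng_ok)]
        a, b, c = np.unravel_index(np.argmax(sub), sub.shape)
        ijk = np.array([rng_ok[a], rng_ok[b], rng_ok[c]])
        shifts[i] = np.where(ijk > box // 2, ijk - box, ijk)
    return shifts


def ml_align(particles: ParticleSet, cfg: AlignmentConfig | None = None) -> AlignmentResult:
    """Reference-free EM alignment and averaging over a discrete rotation grid."""
    cfg = cfg or AlignmentConfig()
    n = len(particles)
    if n < 2:
        raise ValueError("need at least two particles to align")
    box = particles.subvolumes.shape[1]
    v = box**3

    x = particles.subvolumes.reshape(n, v).astype(np.float32)
    x_work = x.copy()
    shifts = np.zeros((n, 3), dtype=int)

    # reference-free start: the mean of a small random subset of the raw
    # particles.  A full mean is nearly rotationally symmetric, which is a
    # fixed point of EM (uniform responsibilities); a subset mean keeps the
    # asymmetry needed to break that symmetry while using no external model.
    rng = np.random.default_rng(cfg.seed)
    subset = rng.choice(n, size=max(2, n // 8), replace=False)
    avg = x_work[subset].mean(axis=0)
    sigma_floor = 1e-12 * float(np.mean(x**2)) + 1e-30
    sigma2 = cfg.sigma**2 if cfg.sigma is not None else max(
        float(np.mean((x_work - x_work.mean(axis=0)) ** 2)), sigma_floor)

    if cfg.rotations is not None:
        schedule: list = [None]
    else:
        refine = cfg.refine_grid_deg
        if refine is None:
            levels: tuple = ()
        elif np.isscalar(refine):
            levels = (float(refine),)
        else:
            levels = tuple(refine)
        schedule = [None] + list(levels)

    ll_traces: list[list[float]] = []
    gamma = None
    best_idx = np.zeros(n, dtype=int)
    rot_set = cfg.rotations if cfg.rotations is not None else rotation_grid(
        cfg.rotation_grid_deg)
    converged = False

    for level in schedule:
        if level is not None:
            # local refinement: union of neighbourhoods of per-particle modes
            base = rot_set[np.unique(best_idx)]
            pert = perturbation_set(level)
            quats = [(b * pert).as_quat() for b in base]
            q = np.concatenate(quats)
            q = q * np.sign(q[:, 3:4] + 1e-300)          # canonical hemisphere
            q = np.unique(np.round(q, 4), axis=0)
            rot_set = Rotation.from_quat(q)
            n_iter = cfg.refine_iterations
        else:
            n_iter = cfg.n_iterations

        mats = rot_set.as_matrix()
        m = len(mats)
        trace: list[float] = []
        gamma = None
        avg3 = avg.reshape(box, box, box)

        for it in range(n_iter):
            rot_avg = _rotate_stack(avg3, mats)               # (M, V)
            cross = x_work @ rot_avg.T                        # (N, M)
            norm_x = np.einsum("ij,ij->i", x_work, x_work)
            norm_a = np.einsum("ij,ij->i", rot_avg, rot_avg)
            d2 = norm_x[:, None] - 2.0 * cross + norm_a[None, :]
            np.maximum(d2, 0.0, out=d2)

            if gamma is not None and cfg.sigma is None:
                sigma2 = max(float((gamma * d2).sum() / (n * v)), sigma_floor)

            logits = -d2 / (2.0 * sigma2)
            ll = float(logsumexp(logits, axis=1).sum() - n * np.log(m)
                       - n * v / 2.0 * np.log(2.0 * np.pi * sigma2))
            trace.append(ll)
            gamma = np.exp(logits - logits.max(axis=1, keepdims=True))
            gamma /= gamma.sum(axis=1, keepdims=True)
            best_idx = np.argmax(gamma, axis=1)

            if cfg.max_shift_voxels > 0:
                new_shifts = _best_shifts(x_work, rot_avg[best_idx], box,
                                          cfg.max_shift_voxels)
                moved = np.any(new_shifts != 0, axis=1)
                for i in np.where(moved)[0]:
                    total = shifts[i] + new_shifts[i]
                    if np.all(np.abs(total) <= cfg.max_shift_voxels):
                        x_work[i] = np.roll(
                            x[i].reshape(box, box, box),
                            tuple(total), axis=(0, 1, 2)).ravel()
                        shifts[i] = total

            weights = gamma.sum(axis=0)                       # (M,)
            keep = weights > weights.max() * 1e-10
            s = gamma.T[keep] @ x_work                        # (M', V)
            new_avg3 = np.zeros((box, box, box), dtype=np.float64)
            for srow, mat in zip(s, mats[keep]):
                new_avg3 += rotate_volume(
                    srow.reshape(box, box, box).astype(np.float64), mat.T)
            new_avg3 /= n
            delta = np.linalg.norm(new_avg3.ravel() - avg) / max(
                np.linalg.norm(avg), 1e-30)
            avg = new_avg3.ravel().astype(np.float32)
            avg3 = new_avg3.astype(np.float32)
            if delta < cfg.convergence_tol and it >= 2:
                converged = True
                break
        ll_traces.append(trace)

    # half-set averages from the final responsibilities (even/odd split)
    halves = []
    mats = rot_set.as_matrix()
    for parity in (0, 1):
        sel = np.arange(n) % 2 == parity
        g = gamma[sel]
        weights = g.sum(axis=0)
        keep = weights > weights.max() * 1e-10
        s = g.T[keep] @ x_work[sel]
        h = np.zeros((box, box, box), dtype=np.float64)
        for srow, mat in zip(s, mats[keep]):
            h += rotate_volume(srow.reshape(box, box, box).astype(np.float64),
                               mat.T)
        halves.append((h / max(sel.sum(), 1)).astype(np.float32))

    return AlignmentResult(
        average=avg.reshape(box, box, box),
        voxel_size=particles.voxel_size,
        rotations=rot_set[best_idx],
        responsibilities=gamma,
        rotation_set=rot_set,
        log_likelihood=ll_traces,
        half_averages=(halves[0], halves[1]),
        shifts=shifts,
        sigma=float(np.sqrt(sigma2)),
        converged=converged,
    )


def soft_spherical_mask(shape, voxel_size: float, radius_nm: float,
                        edge_nm: float = 3.0) -> np.ndarray:
    """Soft (raised-cosine edge) spherical solvent mask on a centred grid.

    Standard practice before Fourier shell correlation: the solvent region of
    a subtomogram average carries only noise, and leaving it in depresses the
    measured correlation of genuinely identical structure.
    """
    grids = [(np.arange(s) - (s - 1) / 2.0) * voxel_size for s in shape]
    r = np.sqrt(sum(g**2 for g in np.meshgrid(*grids, indexing="ij")))
    t = np.clip((radius_nm + edge_nm - r) / edge_nm, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * t)


def fsc_resolution(half_a: np.ndarray, half_b: np.ndarray, voxel_size: float,
                   threshold: float = 0.5):
    """Fourier shell correlation of two half-maps and the threshold crossing.

    Returns ``(curve, resolution_nm)`` where curve is a DataFrame with shell
    centre frequencies (1/nm) and FSC values.  Resolution is reported at the
    first downward crossing of ``threshold``; if the curve never drops below
    it the resolution is the Nyquist limit (2 x voxel size); if it starts
    below it (uncorrelated maps) the resolution is undefined (NaN).
    """
    if half_a.shape != half_b.shape:
        raise ValueError("half-maps must share one grid")
    if not half_a.any() or not half_b.any():
        raise ValueError("FSC of an all-zero map is undefined")
    n = half_a.shape[0]
    fa = np.fft.fftn(half_a)
    fb = np.fft.fftn(half_b)
    freqs = [np.fft.fftfreq(s, d=voxel_size) for s in half_a.shape]
    kk = np.sqrt(sum(g**2 for g in np.meshgrid(*freqs, indexing="ij")))
    shell_width = 1.0 / (n * voxel_size)
    shell = np.rint(kk / shell_width).astype(int)
    n_shell = n // 2 + 1
    mask = shell < n_shell
    num = np.bincount(shell[mask], (fa * np.conj(fb)).real[mask], n_shell)
    pa = np.bincount(shell[mask], np.abs(fa[mask])**2, n_shell)
    pb = np.bincount(shell[mask], np.abs(fb[mask])**2, n_shell)
    denom = np.sqrt(pa * pb)
    fsc = np.divide(num, denom, out=np.ones_like(num), where=denom > 0)
    freq = np.arange(n_shell) * shell_width
    curve = pd.DataFrame({"freq_1_per_nm": freq, "fsc": fsc})

    if n_shell > 1 and fsc[1] < threshold:
        # uncorrelated already at the lowest resolved frequency
        return curve, float("nan")
    res = 2.0 * voxel_size  # Nyquist unless the curve crosses earlier
    for s in range(2, n_shell):
        if fsc[s] < threshold <= fsc[s - 1]:
            f_cross = freq[s - 1] + (fsc[s - 1] - threshold) / (
                fsc[s - 1] - fsc[s]) * shell_width
            res = 1.0 / f_cross
            break
    return curve, res
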