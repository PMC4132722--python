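"""mRNA path inference and topology classification of polyribosomes.

The mRNA leaves each ribosome at its exit site and threads into the entry
site of the next ribosome along the message, so the 5'->3' route through a
polyribosome can be recovered from pure exit->entry geometry.  A candidate
link between two ribosomes is *feasible* when

* the exit->entry distance does not exceed the spacer budget
  ``(occupancy - footprint) * 0.34 nm/nt`` — the mRNA simply is not long
  enough for anything farther — and
* the bend between the two ribosomes' mRNA directions stays below a cap
  (default 120 degrees), the operational reading of "no kinks".

The best route is the minimum-total-spacer feasible Hamiltonian path (open)
or tour (closed); "no knots" is enforced by rejecting routes in which two
non-adjacent spacer segments pass closer than a quarter of the ribosome
diameter.  A polysome is called closed (circular mRNA topology) when a fully
feasible tour exists, and the geometry of the ordered centres then decides
between ring-shaped and double-row circular forms; open paths are classified
as zigzag double rows, single rows, helices, or left as other linear forms.
Dimers and trimers are never assigned: two or three points cannot support an
unambiguous circular/linear call.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .ribosome import RibosomeReference, body_landmarks, ShapeConfig
from .polysomes import PolysomeGroup

__all__ = [
    "TraceConfig", "LinkCandidate", "PathSolution", "TOPOLOGY_LABELS",
    "candidate_links", "solve_path", "classify_topology", "trace_polysome",
    "trace_all",
]

TOPOLOGY_LABELS = ("circular_ring", "circular_double_row", "linear_double_row",
                   "linear_single_row", "helical", "linear_other", "unassigned")

CIRCULAR_LABELS = frozenset({"circular_ring", "circular_double_row"})

_ENUMERATION_MAX = 9     # exact enumeration up to this size, Held-Karp beyond
_SOLVE_MAX = 12


@dataclass
class TraceConfig:
    """Thresholds of link feasibility, path search and shape classification."""

    occupancy_nt: float = 140.0        # spacer budget: nt of mRNA per ribosome
    footprint_nt: float = 30.0
    nm_per_nt: float = 0.34
    coding_length_nt: float | None = None  # if set, occupancy = coding length / n
    max_bend_deg: float = 120.0        # "no kinks"
    knot_clearance_frac: float = 0.25  # x diameter: "no knots"
    uniqueness_margin: float = 0.05    # runner-up must cost >= 5% more
    circle_rms_frac: float = 0.25      # circle fit: radial RMS / mean radius
    line_rms_frac: float = 0.25        # line fit: RMS / mean spacing
    row_separation_frac: float = 0.30  # two-row split: gap / mean spacing
    helix_min_turn_deg: float = 90.0   # total azimuthal advance of a helix

    def max_spacer_nm(self, n_ribosomes: int) -> float:
        occ = (self.coding_length_nt / n_ribosomes
               if self.coding_length_nt is not None else self.occupancy_nt)
        return (occ - self.footprint_nt) * self.nm_per_nt


@dataclass
class LinkCandidate:
    from_particle: str
    to_particle: str
    spacer_nm: float
    bend_deg: float
    feasible: bool


@dataclass
class PathSolution:
    order: list | None            # particle ids, 5'->3' along the mRNA
    link_costs: list = field(default_factory=list)
    total_cost: float = float("inf")
    closed: bool = False
    unique: bool = False
    feasible: bool = False
    closing_spacer_nm: float = float("nan")


def _site_geometry(group: PolysomeGroup, ref: RibosomeReference | None):
    landmarks = ref.landmarks if ref is not None else body_landmarks()
    direction = (ref.mrna_direction if ref is not None
                 else -np.asarray(ShapeConfig().channel_axis, dtype=float))
    exits, entries, dirs = [], [], []
    for p in group.poses:
        r = p.matrix
        exits.append(r @ landmarks["mrna_exit"] + p.position)
        entries.append(r @ landmarks["mrna_entry"] + p.position)
        dirs.append(r @ direction)
    return np.array(exits), np.array(entries), np.array(dirs)


def candidate_links(group: PolysomeGroup, ref: RibosomeReference | None,
                    cfg: TraceConfig) -> list[LinkCandidate]:
    """Score every ordered pair of group members as a potential mRNA link."""
    for p in group.poses:
        if p.rotation is None:
            raise ValueError(f"particle {p.particle_id} has no recovered pose")
    exits, entries, dirs = _site_geometry(group, ref)
    cap = cfg.max_spacer_nm(len(group))
    links = []
    ids = group.particle_ids

    def angle(u, v):
        return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))

    for i in range(len(group)):
        for j in range(len(group)):
            if i == j:
                continue
            seg = entries[j] - exits[i]
            spacer = float(np.linalg.norm(seg))
            bend = angle(dirs[i], dirs[j])
            kink = bend
            if spacer > 1e-9:
                # the spacer must leave the exit and arrive at the entry
                # without doubling back: its direction is held to the same
                # bend cap against both ribosomes' mRNA directions
                seg = seg / spacer
                kink = max(kink, angle(dirs[i], seg), angle(seg, dirs[j]))
            links.append(LinkCandidate(
                ids[i], ids[j], spacer, bend,
                feasible=spacer <= cap and kink <= cfg.max_bend_deg))
    return links


def _cost_matrix(group: PolysomeGroup, links) -> np.ndarray:
    ids = {pid: k for k, pid in enumerate(group.particle_ids)}
    n = len(group)
    cost = np.full((n, n), np.inf)
    for link in links:
        if link.feasible:
            cost[ids[link.from_particle], ids[link.to_particle]] = link.spacer_nm
    return cost


def _segment_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between 3D segments p1-p2 and q1-q2."""
    u, v, w = p2 - p1, q2 - q1, p1 - q1
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    s = np.clip((b * t - d) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    return float(np.linalg.norm(p1 + s * u - (q1 + t * v)))


def _is_knotted(order, closed, exits, entries, clearance: float) -> bool:
    """Two non-adjacent straight spacer segments closer than ``clearance``."""
    n = len(order)
    segs = [(exits[order[k]], entries[order[k + 1]]) for k in range(n - 1)]
    if closed:
        segs.append((exits[order[-1]], entries[order[0]]))
    m = len(segs)
    for a in range(m):
        for b in range(a + 1, m):
            if b == a + 1 or (closed and a == 0 and b == m - 1):
                continue  # consecutive segments share a ribosome
            if _segment_distance(*segs[a], *segs[b]) < clearance:
                return True
    return False


@lru_cache(maxsize=8)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def _enumerate_best(cost, closed, knot_fn):
    """Exact search by full enumeration; returns (order, cost, runner_up_cost)."""
    n = cost.shape[0]
    if closed:
        sub = _all_permutations(n - 1) + 1
        perms = np.concatenate([np.zeros((len(sub), 1), dtype=np.int8), sub], axis=1)
        totals = cost[perms[:, :-1], perms[:, 1:]].sum(axis=1)
        totals = totals + cost[perms[:, -1], perms[:, 0]]
    else:
        perms = _all_permutations(n)
        totals = cost[perms[:, :-1], perms[:, 1:]].sum(axis=1)
    ranked = np.argsort(totals, kind="stable")
    best = None
    best_cost = np.inf
    runner = np.inf
    for k in ranked[:500]:
        c = float(totals[k])
        if not np.isfinite(c):
            break
        order = perms[k].tolist()
        if knot_fn(order):
            continue
        if best is None:
            best, best_cost = order, c
        else:
            runner = c   # next knot-free candidate, ties included
            break
    return best, best_cost, runner


def _held_karp(cost, closed):
    """Exact minimum Hamiltonian path/tour by subset dynamic programming."""
    n = cost.shape[0]
    full = 1 << n
    starts = [0] if closed else range(n)
    best_order, best_cost = None, np.inf
    for s in starts:
        dp = np.full((full, n), np.inf)
        parent = np.full((full, n), -1, dtype=int)
        dp[1 << s, s] = 0.0
        for mask in range(full):
            if not mask & (1 << s):
                continue
            for last in range(n):
                if not mask & (1 << last) or not np.isfinite(dp[mask, last]):
                    continue
                base = dp[mask, last]
                for nxt in range(n):
                    if mask & (1 << nxt) or not np.isfinite(cost[last, nxt]):
                        continue
                    nm = mask | (1 << nxt)
                    cand = base + cost[last, nxt]
                    if cand < dp[nm, nxt]:
                        dp[nm, nxt] = cand
                        parent[nm, nxt] = last
        ends = dp[full - 1] + (cost[:, s] if closed else 0.0)
        e = int(np.argmin(ends))
        if ends[e] < best_cost:
            best_cost = float(ends[e])
            order = [e]
            mask = full - 1
            while parent[mask, order[-1]] >= 0:
                prev = parent[mask, order[-1]]
                mask ^= 1 << order[-1]
                order.append(int(prev))
            best_order = order[::-1]
    return best_order, best_cost


def _dp_best(cost, closed, knot_fn):
    order, c = _held_karp(cost, closed)
    if order is None or not np.isfinite(c) or knot_fn(order):
        return None, np.inf, np.inf
    # runner-up: best solution avoiding at least one edge of the optimum
    edges = list(zip(order[:-1], order[1:]))
    if closed:
        edges.append((order[-1], order[0]))
    runner = np.inf
    for a, b in edges:
        c2 = cost.copy()
        c2[a, b] = np.inf
        o2, v2 = _held_karp(c2, closed)
        if o2 is not None and np.isfinite(v2) and not knot_fn(o2):
            runner = min(runner, v2)
    return order, c, runner


def solve_path(group: PolysomeGroup, links, cfg: TraceConfig,
               ref: RibosomeReference | None = None) -> PathSolution:
    """Minimum-spacer feasible route through a polyribosome (exact search).

    Both the best open path and the best closed tour are computed; a fully
    feasible tour (closing link within the spacer budget) is reported as
    closed.  ``unique`` records whether the returned route undercuts the
    runner-up by at least the configured margin.
    """
    n = len(group)
    if n > _SOLVE_MAX:
        raise ValueError(f"exact search supports up to {_SOLVE_MAX} ribosomes, got {n}")
    ids = group.particle_ids
    if n == 1:
        return PathSolution(order=list(ids), total_cost=0.0, closed=False,
                            unique=True, feasible=True)
    exits, entries, _ = _site_geometry(group, ref)
    diameter = ref.diameter if ref is not None else ShapeConfig().diameter
    clearance = cfg.knot_clearance_frac * diameter
    cost = _cost_matrix(group, links)

    def knot(order, closed):
        return _is_knotted(order, closed, exits, entries, clearance)

    search = _enumerate_best if n <= _ENUMERATION_MAX else _dp_best
    closed_order, closed_cost, closed_runner = search(
        cost, True, lambda o: knot(o, True)) if n >= 3 else (None, np.inf, np.inf)
    open_order, open_cost, open_runner = search(
        cost, False, lambda o: knot(o, False))

    if closed_order is not None and np.isfinite(closed_cost):
        order, total, runner, closed = closed_order, closed_cost, closed_runner, True
    elif open_order is not None and np.isfinite(open_cost):
        order, total, runner, closed = open_order, open_cost, open_runner, False
    else:
        return PathSolution(order=None)

    link_costs = [float(cost[a, b]) for a, b in zip(order[:-1], order[1:])]
    closing = float(cost[order[-1], order[0]]) if closed else float("nan")
    if closed:
        link_costs.append(closing)
    unique = (not np.isfinite(runner)) or runner >= total * (1.0 + cfg.uniqueness_margin)
    return PathSolution(
        order=[ids[k] for k in order],
        link_costs=link_costs,
        total_cost=float(total),
        closed=closed,
        unique=bool(unique),
        feasible=True,
        closing_spacer_nm=closing,
    )


# ---------------------------------------------------------------------------
# Shape classification of the ordered centres
# ---------------------------------------------------------------------------

def _principal_frame(centers: np.ndarray):
    mean = centers.mean(axis=0)
    centred = centers - mean
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    return centred @ vt.T, vt   # coordinates in the principal frame


def _circle_residual(xy: np.ndarray) -> tuple[float, float]:
    """Kasa algebraic circle fit; returns (radial RMS, mean radius)."""
    a = np.column_stack([2 * xy, np.ones(len(xy))])
    b = (xy**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:2]
    radii = np.linalg.norm(xy - center, axis=1)
    return float(np.sqrt(np.mean((radii - radii.mean())**2))), float(radii.mean())


def _two_rows(coords, mean_spacing, cfg):
    """Two-line clustering of the second principal coordinate: every split of
    its sorted values into two rows of >= 2 members is scored, and the best
    must separate the rows clearly against both the within-row spread and the
    link scale."""
    s = coords[:, 1]
    order = np.argsort(s)
    n = len(s)
    best = None
    best_score = -np.inf
    for k in range(1, n - 2):
        row_low, row_high = order[:k + 1], order[k + 1:]
        sep = float(s[row_high].mean() - s[row_low].mean())
        spread = max(float(s[row_low].std()), float(s[row_high].std()), 1e-9)
        if sep < cfg.row_separation_frac * mean_spacing or sep < 2.0 * spread:
            continue
        score = sep / spread
        if score > best_score:
            best_score = score
            best = (row_low, row_high)
    if best is None:
        return None
    rows = np.zeros(n, dtype=int)
    rows[best[1]] = 1
    return rows


def _row_directions_antiparallel(coords, rows, order_idx, closed) -> tuple[bool, int]:
    """Travel direction of the path within each row (along the first principal
    axis) and the number of cross-row links."""
    t = coords[:, 0]
    drift = [0.0, 0.0]
    cross = 0
    n = len(order_idx)
    n_links = n if closed else n - 1
    for k in range(n_links):
        a, b = order_idx[k], order_idx[(k + 1) % n]
        if rows[a] == rows[b]:
            drift[rows[a]] += t[b] - t[a]
        else:
            cross += 1
    antiparallel = drift[0] * drift[1] < 0
    return antiparallel, cross


def classify_topology(group: PolysomeGroup, path: PathSolution,
                      cfg: TraceConfig, ref: RibosomeReference | None = None) -> str:
    """Label the mRNA topology of one polyribosome from its solved path."""
    n = len(group)
    if n <= 3 or path.order is None or not path.feasible:
        return "unassigned"

    idx = {pid: k for k, pid in enumerate(group.particle_ids)}
    order_idx = [idx[pid] for pid in path.order]
    centers = group.positions
    coords, _ = _principal_frame(centers)
    ordered = centers[order_idx]
    mean_spacing = float(np.mean(np.linalg.norm(np.diff(ordered, axis=0), axis=1)))

    # double rows are planar; out-of-plane spread rules them out (e.g. a helix
    # whose lateral scatter would otherwise look like two rows)
    planar = float(np.sqrt(np.mean(coords[:, 2]**2))) < 0.15 * mean_spacing

    if path.closed:
        rms, mean_r = _circle_residual(coords[order_idx][:, :2])
        if rms < cfg.circle_rms_frac * mean_r:
            return "circular_ring"
        rows = _two_rows(coords, mean_spacing, cfg)
        if rows is not None and planar:
            antiparallel, cross = _row_directions_antiparallel(
                coords, rows, order_idx, closed=True)
            if antiparallel and cross == 2:
                return "circular_double_row"
        return "linear_other"

    # open paths
    rows = _two_rows(coords, mean_spacing, cfg)
    if rows is not None and planar:
        _, cross = _row_directions_antiparallel(coords, rows, order_idx,
                                                closed=False)
        t = coords[:, 0]
        span = float(t.max() - t.min())
        termini_apart = span > 0 and abs(
            t[order_idx[-1]] - t[order_idx[0]]) > 0.5 * span
        # a zigzag threads back and forth: most links change row
        if termini_apart and cross >= 0.5 * (n - 1):
            return "linear_double_row"
    # collinear: residual distance from the best-fit 3D line
    line_res = float(np.sqrt(np.mean(coords[:, 1]**2 + coords[:, 2]**2)))
    if line_res < cfg.line_rms_frac * mean_spacing:
        return "linear_single_row"
    # helix: monotone rise along the principal axis plus consistent rotation
    t = coords[order_idx, 0]
    dt = np.diff(t)
    lateral = coords[order_idx, 1:]
    radius = np.linalg.norm(lateral, axis=1)
    if np.all(dt > 0) or np.all(dt < 0):
        if np.median(radius) > 0.2 * mean_spacing:
            ang = np.arctan2(lateral[:, 1], lateral[:, 0])
            dang = np.angle(np.exp(1j * np.diff(ang)))
            # consistent, genuinely rotating steps; near-180-degree flips are
            # a planar zigzag, not a helix
            if (np.all(dang > 0) or np.all(dang < 0)) and np.all(
                    np.degrees(np.abs(dang)) <= 150.0):
                if np.degrees(abs(dang).sum()) >= cfg.helix_min_turn_deg:
                    return "helical"
    return "linear_other"


def trace_polysome(group: PolysomeGroup, ref: RibosomeReference | None,
                   cfg: TraceConfig) -> dict:
    """Full per-polysome pipeline: links -> path -> label -> report row."""
    links = candidate_links(group, ref, cfg)
    path = solve_path(group, links, cfg, ref)
    label = classify_topology(group, path, cfg, ref)
    return {
        "polysome_id": group.polysome_id,
        "n_ribosomes": len(group),
        "order": ";".join(path.order) if path.order else "",
        "closed": path.closed,
        "unique": path.unique,
        "label": label,
        "total_cost_nm": path.total_cost if path.feasible else float("nan"),
        "closing_spacer_nm": path.closing_spacer_nm,
    }


def trace_all(groups, ref: RibosomeReference | None, cfg: TraceConfig) -> pd.DataFrame:
    return pd.DataFrame([trace_polysome(g, ref, cfg) for g in groups])
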