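"""End-to-end convenience: simulate a condition, trace it, report it.

This is the one-call version of the analysis used throughout the examples:
generate a polyribosome field with a known circular proportion, group the
particles, infer every mRNA path, classify topologies and aggregate the
circular-fraction statistics against the generator's ground truth.
"""
from __future__ import annotations

from .polysomes import group_particles
from .report import TopologyReport, condition_report
from .simulate import GeneratorConfig, simulate_condition
from .trace import TraceConfig, trace_all

__all__ = ["condition_config", "run_condition"]


def condition_config(p_circular: float, n_polysomes: int = 150, seed: int = 0,
                     coding_length_nt: float | None = None,
                     orientation_jitter_deg: float = 5.0,
                     sizes=range(4, 9)) -> GeneratorConfig:
    """Generator config for a condition with a given true circular proportion.

    The circular mass is split evenly between ring-shaped and double-row
    forms, the linear mass evenly between zigzag double rows, single rows and
    helices; polysome sizes are uniform over ``sizes``.
    """
    mixture = {
        "circular_ring": p_circular / 2.0,
        "circular_double_row": p_circular / 2.0,
        "linear_double_row": (1.0 - p_circular) / 3.0,
        "linear_single_row": (1.0 - p_circular) / 3.0,
        "helical": (1.0 - p_circular) / 3.0,
    }
    sizes = list(sizes)
    return GeneratorConfig(
        n_polysomes=n_polysomes,
        topology_mixture=mixture,
        size_distribution={n: 1.0 / len(sizes) for n in sizes},
        orientation_jitter_deg=orientation_jitter_deg,
        coding_length_nt=coding_length_nt,
        seed=seed,
    )


def run_condition(cfg: GeneratorConfig, condition: str = "condition",
                  ref=None) -> TopologyReport:
    """Simulate -> group -> trace -> classify -> report, on ground-truth poses."""
    _, gt = simulate_condition(cfg, ref=ref, render=False)
    groups = group_particles(gt.poses)
    tcfg = TraceConfig(coding_length_nt=cfg.coding_length_nt,
                       occupancy_nt=cfg.occupancy_nt[1],
                       footprint_nt=cfg.footprint_nt,
                       nm_per_nt=cfg.nm_per_nt)
    table = trace_all(groups, ref, tcfg)
    id_map = {g.polysome_id: gt.membership[g.particle_ids[0]] for g in groups}
    table = table.assign(polysome_id=table["polysome_id"].map(id_map))
    return condition_report(table, ground_truth=gt, condition=condition,
                            coding_length_nt=cfg.coding_length_nt)
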