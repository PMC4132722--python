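"""Condition-level statistics: circular fractions, occupancy, topology reports.

Circular fractions are reported under two weightings, because both appear in
the literature's phrasing: *per polysome* (circular polysomes / assigned
polysomes) and *per ribosome* (ribosomes sitting in circular polysomes /
ribosomes in assigned polysomes).  Dimers and trimers are tallied but
excluded from the denominators — dimerisation happens without mRNA, and three
ribosomes cannot support an unambiguous circular/linear call.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .trace import TOPOLOGY_LABELS, CIRCULAR_LABELS

__all__ = ["TopologyReport", "circular_fraction", "occupancy",
           "condition_report", "write_report"]

logger = logging.getLogger(__name__)


def circular_fraction(labels, sizes, weighting: str = "per_polysome") -> float:
    """Fraction of circular polysomes among assigned ones.

    ``labels``/``sizes`` are parallel sequences of topology labels and
    ribosome counts.  ``weighting`` is ``per_polysome`` (count polysomes) or
    ``per_ribosome`` (count the ribosomes they contain).
    """
    if weighting not in ("per_polysome", "per_ribosome"):
        raise ValueError("weighting must be per_polysome or per_ribosome")
    labels = list(labels)
    sizes = list(sizes)
    if len(labels) != len(sizes):
        raise ValueError("labels and sizes must be parallel")
    num = den = 0.0
    for lab, n in zip(labels, sizes):
        if lab == "unassigned":
            continue
        w = n if weighting == "per_ribosome" else 1
        den += w
        if lab in CIRCULAR_LABELS:
            num += w
    if den == 0:
        raise ValueError("no assigned polysomes: circular fraction undefined")
    return num / den


def occupancy(coding_length_nt: float, n_ribosomes: int) -> float:
    """Nucleotides of coding sequence per bound ribosome."""
    if n_ribosomes < 1:
        raise ValueError("need at least one ribosome")
    return coding_length_nt / n_ribosomes


@dataclass
class TopologyReport:
    condition: str
    n_polysomes: int
    n_ribosomes: int
    counts: dict                       # label -> polysome count
    circular_fraction_per_polysome: float
    circular_fraction_per_ribosome: float
    per_tomogram: dict = field(default_factory=dict)   # tomogram -> label counts
    occupancy_summary: dict = field(default_factory=dict)
    confusion: pd.DataFrame | None = None   # true labels x inferred labels
    true_circular_fraction_per_polysome: float | None = None
    true_circular_fraction_per_ribosome: float | None = None


def _label_counts(labels) -> dict:
    out = {lab: 0 for lab in TOPOLOGY_LABELS}
    for lab in labels:
        out[lab] += 1
    return {k: v for k, v in out.items() if v or k in ("circular_ring", "unassigned")}


def condition_report(trace_table: pd.DataFrame, ground_truth=None,
                     condition: str = "condition",
                     coding_length_nt: float | None = None,
                     tomogram_of: dict | None = None) -> TopologyReport:
    """Aggregate a per-polysome trace table into the condition statistics.

    ``trace_table`` is the output of :func:`polytomo.trace.trace_all`.  With
    ground truth attached, the report additionally carries the confusion
    matrix (true vs inferred label) and the true circular fractions.
    """
    labels = trace_table["label"].tolist()
    sizes = trace_table["n_ribosomes"].tolist()
    report = TopologyReport(
        condition=condition,
        n_polysomes=len(labels),
        n_ribosomes=int(sum(sizes)),
        counts=_label_counts(labels),
        circular_fraction_per_polysome=circular_fraction(labels, sizes, "per_polysome"),
        circular_fraction_per_ribosome=circular_fraction(labels, sizes, "per_ribosome"),
    )
    if tomogram_of:
        per_tomo: dict = {}
        for pid, lab in zip(trace_table["polysome_id"], labels):
            per_tomo.setdefault(tomogram_of.get(pid, ""), []).append(lab)
        report.per_tomogram = {t: _label_counts(v) for t, v in per_tomo.items()}
    if coding_length_nt is not None:
        occ = [occupancy(coding_length_nt, n) for n in sizes]
        report.occupancy_summary = {
            "coding_length_nt": coding_length_nt,
            "min_nt_per_ribosome": float(np.min(occ)),
            "mean_nt_per_ribosome": float(np.mean(occ)),
            "max_nt_per_ribosome": float(np.max(occ)),
        }
    if ground_truth is not None:
        true_of = {}
        size_of = {}
        for poly, seq in ground_truth.mrna_order.items():
            true_of[poly] = ground_truth.topology_label[poly]
            size_of[poly] = len(seq)
        rows = sorted({*true_of.values()})
        cols = list(TOPOLOGY_LABELS)
        confusion = pd.DataFrame(0, index=rows, columns=cols)
        true_labels, true_sizes = [], []
        for pid, inferred in zip(trace_table["polysome_id"], labels):
            if pid not in true_of:
                continue
            confusion.loc[true_of[pid], inferred] += 1
            true_labels.append(true_of[pid])
            true_sizes.append(size_of[pid])
        report.confusion = confusion
        report.true_circular_fraction_per_polysome = circular_fraction(
            true_labels, true_sizes, "per_polysome")
        report.true_circular_fraction_per_ribosome = circular_fraction(
            true_labels, true_sizes, "per_ribosome")
    return report


def write_report(report: TopologyReport, directory) -> None:
    """JSON summary + TSV tables (counts, confusion matrix if present)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = asdict(report)
    if report.confusion is not None:
        payload["confusion"] = {str(k): v for k, v in
                                report.confusion.to_dict(orient="index").items()}
    (directory / f"{report.condition}_report.json").write_text(
        json.dumps(payload, indent=2, default=float))
    pd.Series(report.counts).rename("n_polysomes").to_csv(
        directory / f"{report.condition}_counts.tsv", sep="\t")
    if report.confusion is not None:
        report.confusion.to_csv(directory / f"{report.condition}_confusion.tsv",
                                sep="\t")
    logger.info("report for %s written to %s", report.condition, directory)
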