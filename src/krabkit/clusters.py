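"""Genomic cluster detection for KRAB-ZFP gene loci.

A cluster is a run of at least two family members lying within 200 kb of each
other on one chromosome. Detection is single-linkage chaining of genes sorted
by start coordinate, using the edge-to-edge gap between neighbouring genes
(overlapping genes have gap 0); strand is ignored. Cluster ids are assigned
in ascending order by natural chromosome order (1, 2, ..., 10, ..., X, Y)
then leftmost coordinate; genes in no cluster carry id 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "GeneLocus",
    "ClusterAssignment",
    "find_clusters",
    "cluster_id_map",
    "natural_chrom_key",
]

DEFAULT_MAX_GAP = 200_000


@dataclass(frozen=True)
class GeneLocus:
    """A gene's genomic footprint; 0-based half-open bp coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"{self.gene_id}: empty chromosome name")
        if not self.start < self.end:
            raise ValueError(
                f"{self.gene_id}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class ClusterAssignment:
    """One cluster (id > 0, ≥2 members) or one singleton (id 0, 1 member)."""

    cluster_id: int
    gene_ids: tuple[str, ...]


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key giving the natural chromosome order 1, 2, ..., 10, ..., X, Y."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    parts = re.split(r"(\d+)", name)
    return tuple((0, int(p)) if p.isdigit() else (1, p) for p in parts if p)


def _gap(left: GeneLocus, right: GeneLocus) -> int:
    """Edge-to-edge gap between two loci sorted by start; 0 if overlapping."""
    return max(0, right.start - left.end)


def find_clusters(
    loci: Iterable[GeneLocus], max_gap: int = DEFAULT_MAX_GAP
) -> list[ClusterAssignment]:
    """Partition gene loci into genomic clusters and singletons.

    Parameters
    ----------
    loci
        Gene loci; gene_ids must be unique.
    max_gap
        Maximum edge-to-edge distance (bp) between neighbouring genes of one
        cluster. Default 200 kb.

    Returns
    -------
    Assignments covering every gene exactly once. Clusters (≥2 members) are
    numbered 1, 2, ... by chromosome order then leftmost start; each
    singleton is returned as its own assignment with cluster_id 0.
    """
    loci = list(loci)
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    seen: set[str] = set()
    for l in loci:
        if l.gene_id in seen:
            raise ValueError(f"duplicate gene_id {l.gene_id!r}")
        seen.add(l.gene_id)

    by_chrom: dict[str, list[GeneLocus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chrom, []).append(l)

    assignments: list[ClusterAssignment] = []
    next_id = 1
    for chrom in sorted(by_chrom, key=natural_chrom_key):
        genes = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.gene_id))
        run: list[GeneLocus] = []
        # track the rightmost end seen in the run: a gene overlapping a prior
        # long gene must not break the chain
        run_end = 0
        for g in genes:
            if run and max(0, g.start - run_end) <= max_gap:
                run.append(g)
                run_end = max(run_end, g.end)
            else:
                assignments.extend(_flush(run, next_id))
                if run and len(run) >= 2:
                    next_id += 1
                run = [g]
                run_end = g.end
        assignments.extend(_flush(run, next_id))
        if len(run) >= 2:
            next_id += 1
    return assignments


def _flush(run: Sequence[GeneLocus], next_id: int) -> list[ClusterAssignment]:
    if not run:
        return []
    if len(run) == 1:
        return [ClusterAssignment(0, (run[0].gene_id,))]
    return [ClusterAssignment(next_id, tuple(g.gene_id for g in run))]


def cluster_id_map(assignments: Iterable[ClusterAssignment]) -> dict[str, int]:
    """Flatten assignments to a gene_id → cluster_id mapping."""
    out: dict[str, int] = {}
    for a in assignments:
        for g in a.gene_ids:
            out[g] = a.cluster_id
    return out
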