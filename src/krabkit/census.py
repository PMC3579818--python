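"""Protein-domain census of KRAB-containing genes.

KRAB-containing proteins fall into two classes: canonical KRAB zinc-finger
proteins (KRAB-ZFPs), which pair an N-terminal Krüppel-associated box with an
array of C2H2 zinc fingers, and KRAB-only (KRAB-O) proteins, which lack zinc
fingers entirely. This module extracts C2H2 fingers from protein sequences by
pattern scanning, evaluates the D5/V6 dipeptide of annotated KRAB domains
(required for KAP1 recruitment by canonical KRAB modules), and classifies each
gene from its longest protein isoform.

KRAB-domain presence is taken from an input annotation table; the census
starts downstream of domain identification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AMINO_ACIDS",
    "ZF_PATTERN",
    "ProteinRecord",
    "ZincFinger",
    "KrabDomain",
    "CensusEntry",
    "select_longest_protein",
    "extract_zinc_fingers",
    "check_dv_motif",
    "classify_protein",
    "build_census",
]

#: The 20 standard residues plus the ambiguity code X.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_AA = "[ACDEFGHIKLMNPQRSTVWYX]"

#: C2H2 zinc-finger motif C-X(2-4)-C-X(12)-H-X(3-5)-H. Lazy quantifiers give
#: leftmost, shortest-match scanning; X may occupy any spacer position but the
#: four coordinating residues must literally be C or H.
ZF_PATTERN = re.compile(
    f"C{_AA}{{2,4}}?C{_AA}{{12}}H{_AA}{{3,5}}?H"
)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein isoform with its transcript/gene linkage."""

    protein_id: str
    transcript_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not (self.protein_id and self.transcript_id and self.gene_id):
            raise ValueError("protein/transcript/gene ids must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"{self.protein_id}: invalid residues {sorted(bad)} "
                "(expected the 20 standard amino acids or X, uppercase)"
            )


@dataclass(frozen=True)
class ZincFinger:
    """A matched C2H2 finger; coordinates are 0-based half-open in the protein."""

    ordinal: int
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("finger coordinates inconsistent with sequence")
        if not 21 <= len(self.sequence) <= 25:
            raise ValueError("C2H2 finger length must be in [21, 25]")
        if ZF_PATTERN.fullmatch(self.sequence) is None:
            raise ValueError(f"not a C2H2 finger: {self.sequence!r}")


@dataclass(frozen=True)
class KrabDomain:
    """An annotated KRAB domain with its repression-competence dipeptide flags.

    ``has_d5``/``has_v6`` report whether residues 5 and 6 (1-based within the
    domain) are aspartate and valine; both are needed for canonical
    KRAB-mediated KAP1 recruitment.
    """

    start: int
    end: int
    sequence: str
    has_d5: bool = field(default=False)
    has_v6: bool = field(default=False)


@dataclass(frozen=True)
class CensusEntry:
    """Classification of one gene from its chosen (longest) isoform."""

    gene_id: str
    klass: str  # "KRAB-ZFP" or "KRAB-O"
    n_zf: int
    protein_id: str
    transcript_id: str
    cluster_id: int = 0

    def __post_init__(self) -> None:
        if self.klass not in ("KRAB-ZFP", "KRAB-O"):
            raise ValueError(f"unknown class {self.klass!r}")
        if (self.klass == "KRAB-O") != (self.n_zf == 0):
            raise ValueError("KRAB-O iff zero zinc fingers")


def select_longest_protein(records: Iterable[ProteinRecord]) -> ProteinRecord:
    """Pick the longest isoform of a gene.

    Ties are broken by lexicographically smallest transcript_id so the choice
    is deterministic regardless of input order.
    """
    records = list(records)
    if not records:
        raise ValueError("no protein records supplied for gene")
    genes = {r.gene_id for r in records}
    if len(genes) > 1:
        raise ValueError(f"records span multiple genes: {sorted(genes)}")
    return min(records, key=lambda r: (-len(r.sequence), r.transcript_id))


def extract_zinc_fingers(sequence: str) -> list[ZincFinger]:
    """Scan a protein for C2H2 fingers matching C-X(2-4)-C-X(12)-H-X(3-5)-H.

    Scanning is leftmost, shortest-match and non-overlapping: after a finger
    is accepted the scan resumes at its end. Returned fingers are ordered by
    start and numbered from 1.
    """
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid residues in sequence: {sorted(bad)}")
    fingers = []
    for i, m in enumerate(ZF_PATTERN.finditer(sequence), start=1):
        fingers.append(
            ZincFinger(ordinal=i, start=m.start(), end=m.end(), sequence=m.group())
        )
    return fingers


def check_dv_motif(domain: KrabDomain) -> tuple[bool, bool]:
    """Check for aspartate at KRAB position 5 and valine at position 6.

    Positions are 1-based from the first residue of the annotated domain.
    """
    if len(domain.sequence) < 6:
        raise ValueError("KRAB domain shorter than 6 residues; cannot assess D5/V6")
    return domain.sequence[4] == "D", domain.sequence[5] == "V"


def classify_protein(record: ProteinRecord, krab: KrabDomain) -> CensusEntry:
    """Classify a gene as KRAB-ZFP (≥1 finger) or KRAB-O (no fingers)."""
    fingers = extract_zinc_fingers(record.sequence)
    n = len(fingers)
    return CensusEntry(
        gene_id=record.gene_id,
        klass="KRAB-ZFP" if n >= 1 else "KRAB-O",
        n_zf=n,
        protein_id=record.protein_id,
        transcript_id=record.transcript_id,
    )


def build_census(
    records: Sequence[ProteinRecord],
    krab_annotations: Mapping[str, KrabDomain],
) -> list[CensusEntry]:
    """Build the per-gene census over all annotated KRAB-containing genes.

    Parameters
    ----------
    records
        Protein isoforms; a gene may contribute several.
    krab_annotations
        gene_id → annotated KRAB domain. Every annotated gene must have at
        least one record.

    Returns
    -------
    One entry per annotated gene, sorted by gene_id.
    """
    by_gene: dict[str, list[ProteinRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    missing = sorted(set(krab_annotations) - set(by_gene))
    if missing:
        raise KeyError(
            f"KRAB annotation references genes without protein records: {missing}"
        )
    entries = []
    for gene_id in sorted(krab_annotations):
        chosen = select_longest_protein(by_gene[gene_id])
        entries.append(classify_protein(chosen, krab_annotations[gene_id]))
    return entries
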