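"""Cross-species ortholog calling from zinc-finger-array homology.

Putative mouse–human ortholog pairs are defined by the percent homology of
the proteins' concatenated C2H2 zinc-finger arrays (spacer sequences between
fingers excluded): a global pairwise alignment is computed and percent
homology is 100 × identical columns / total alignment columns (gaps count in
the denominator, so length-mismatched arrays are penalized). Pairs above a
threshold — 70% by default — are retained, including one-to-many matches.

The aligner is an affine-gap Needleman–Wunsch (Gotoh) with match +1,
mismatch −1, gap open −5, gap extend −1, and a deterministic traceback
(diagonal preferred over vertical over horizontal on ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .census import ZincFinger

__all__ = [
    "AlignmentScoring",
    "ZfArray",
    "HomologyScore",
    "OrthologPair",
    "build_zf_array",
    "global_align",
    "percent_homology",
    "call_orthologs",
]

NEG_INF = float(-1e18)


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0  # score of the first residue of a gap
    gap_extend: float = -1.0  # score of each further gap residue


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class ZfArray:
    """Concatenated zinc-finger sequences of one protein, in finger order."""

    protein_id: str
    gene_id: str
    species: str  # "mouse" | "human"
    array: str

    @property
    def alignable(self) -> bool:
        return len(self.array) > 0


@dataclass(frozen=True)
class HomologyScore:
    protein_a: str
    protein_b: str
    percent_homology: float
    n_identical: int
    alignment_length: int


@dataclass(frozen=True)
class OrthologPair:
    mouse_gene: str
    human_gene: str
    mouse_protein: str
    human_protein: str
    percent_homology: float


def build_zf_array(fingers: Sequence[ZincFinger], *, protein_id: str,
                   gene_id: str, species: str) -> ZfArray:
    """Concatenate a protein's fingers (ordered, spacers excluded) into an array."""
    for prev, cur in zip(fingers, fingers[1:]):
        if cur.start < prev.end:
            raise ValueError("fingers must be ordered and non-overlapping")
    return ZfArray(
        protein_id=protein_id,
        gene_id=gene_id,
        species=species,
        array="".join(f.sequence for f in fingers),
    )


def global_align(
    a: str, b: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> tuple[str, str, float]:
    """Global affine-gap alignment (Gotoh); returns (aligned_a, aligned_b, score).

    Three-state dynamic programme: M (a[i-1] aligned to b[j-1]), X (gap in b,
    i.e. a residue of `a` against '-'), Y (gap in a). Ties in the traceback
    resolve M > X > Y, so the alignment is deterministic.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    n, m = len(a), len(b)
    go, ge = scoring.gap_open, scoring.gap_extend

    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + ge * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = go + ge * (j - 1)

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = scoring.match if ai == b[j - 1] else scoring.mismatch
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            Y[i, j] = max(M[i, j - 1] + go, Y[i, j - 1] + ge, X[i, j - 1] + go)

    # traceback
    i, j = n, m
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))  # 0=M, 1=X, 2=Y
    score = float([M[i, j], X[i, j], Y[i, j]][state])
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            cand = [M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go]
            i -= 1
            state = int(np.argmax(cand))
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            cand = [M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge]
            j -= 1
            state = int(np.argmax(cand))
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score


def percent_homology(
    a: ZfArray, b: ZfArray, scoring: AlignmentScoring = DEFAULT_SCORING
) -> HomologyScore:
    """Percent identity of two finger arrays over the full global alignment.

    Denominator is the total number of alignment columns including gap
    columns; identical residue pairs count in the numerator. Symmetric in its
    arguments.
    """
    if not a.alignable or not b.alignable:
        raise ValueError("empty zinc-finger array is not alignable")
    # align in a canonical order so the result is exactly symmetric
    first, second = (a, b) if a.array <= b.array else (b, a)
    al1, al2, _ = global_align(first.array, second.array, scoring)
    n_id = sum(x == y and x != "-" for x, y in zip(al1, al2))
    cols = len(al1)
    return HomologyScore(
        protein_a=a.protein_id,
        protein_b=b.protein_id,
        percent_homology=100.0 * n_id / cols,
        n_identical=n_id,
        alignment_length=cols,
    )


def call_orthologs(
    mouse: Iterable[ZfArray],
    human: Iterable[ZfArray],
    threshold: float = 70.0,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> list[OrthologPair]:
    """Call putative ortholog pairs exceeding a percent-homology threshold.

    All cross-species pairs with percent homology strictly above ``threshold``
    are retained — one-to-many matches included, since sequence alone cannot
    single out the true ortholog. Proteins with empty arrays (KRAB-O) are
    excluded. Output is sorted by mouse gene, then descending homology.
    """
    if not 0 < threshold < 100:
        raise ValueError("threshold must lie in (0, 100)")
    mouse = [z for z in mouse if z.alignable]
    human = [z for z in human if z.alignable]
    pairs = []
    for zm in mouse:
        for zh in human:
            h = percent_homology(zm, zh, scoring)
            if h.percent_homology > threshold:
                pairs.append(
                    OrthologPair(
                        mouse_gene=zm.gene_id,
                        human_gene=zh.gene_id,
                        mouse_protein=zm.protein_id,
                        human_protein=zh.protein_id,
                        percent_homology=h.percent_homology,
                    )
                )
    pairs.sort(key=lambda p: (p.mouse_gene, -p.percent_homology, p.human_gene))
    return pairs
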