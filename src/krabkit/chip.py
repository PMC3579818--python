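"""Meta-gene interval analysis: promoter windows, bin profiles, ERV distances.

Consumes ChIP enriched-region intervals (BED-style, 0-based half-open) and
gene loci, and computes:

* strand-aware promoter windows (TSS −3.5 kb / +500 bp) and extended windows
  (gene body ±3.5 kb), clamped at the chromosome origin;
* per-gene × per-mark any-overlap boolean tables over either window;
* meta-gene bin profiles: the extended window divided into 8 near-equal bins
  (5′→3′ in gene orientation), each bin flagged when any enriched region
  overlaps it by ≥1 bp, summarized as the fraction of genes hit per bin;
* nearest-ERV distances (edge-to-edge, 0 when overlapping, ERVs <500 bp
  excluded) and a two-sided Wilcoxon rank-sum comparison between gene groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import GeneLocus

__all__ = [
    "GenomicInterval",
    "GeneWindows",
    "BinProfile",
    "ErvDistanceResult",
    "make_windows",
    "split_bins",
    "metagene_profile",
    "mark_table",
    "nearest_erv_distance",
    "wilcoxon_rank_sum",
    "fold_upregulated",
]

PROMOTER_UP = 3_500
PROMOTER_DOWN = 500
FLANK = 3_500
N_BINS = 8
ERV_MIN_LEN = 500


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"interval start must be < end: {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneWindows:
    """Promoter and extended (body ± flank) windows of one gene."""

    gene_id: str
    chrom: str
    strand: str
    promoter: tuple[int, int]
    extended: tuple[int, int]


def make_windows(
    locus: GeneLocus,
    promoter_up: int = PROMOTER_UP,
    promoter_down: int = PROMOTER_DOWN,
    flank: int = FLANK,
) -> GeneWindows:
    """Strand-aware promoter and extended windows, clamped at position 0.

    On the plus strand the TSS is the gene start and the promoter is
    [TSS − promoter_up, TSS + promoter_down); on the minus strand the TSS is
    the gene end and the window is reflected.
    """
    if locus.strand == "+":
        tss = locus.start
        prom = (max(0, tss - promoter_up), tss + promoter_down)
    else:
        tss = locus.end
        prom = (max(0, tss - promoter_down), tss + promoter_up)
    ext = (max(0, locus.start - flank), locus.end + flank)
    return GeneWindows(
        gene_id=locus.gene_id,
        chrom=locus.chrom,
        strand=locus.strand,
        promoter=prom,
        extended=ext,
    )


def split_bins(start: int, end: int, n_bins: int = N_BINS) -> list[tuple[int, int]]:
    """Tile [start, end) into n near-equal bins; remainder spread left-to-right."""
    if n_bins < 1:
        raise ValueError("n_bins must be ≥1")
    width, rem = divmod(end - start, n_bins)
    if width == 0:
        raise ValueError(f"window [{start},{end}) too short for {n_bins} bins")
    edges = [start]
    for i in range(n_bins):
        edges.append(edges[-1] + width + (1 if i < rem else 0))
    return [(edges[i], edges[i + 1]) for i in range(n_bins)]


def _interval_index(
    intervals: Iterable[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) sorted by start, for overlap queries."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        s = np.array([p[0] for p in pairs])
        e = np.array([p[1] for p in pairs])
        # running max of ends supports overlap queries on nested intervals
        out[chrom] = (s, np.maximum.accumulate(e))
    return out


def _any_overlap(
    index: Mapping[str, tuple[np.ndarray, np.ndarray]],
    chrom: str,
    start: int,
    end: int,
) -> bool:
    if chrom not in index:
        return False
    starts, cummax_ends = index[chrom]
    # candidates with interval.start < end
    k = int(np.searchsorted(starts, end, side="left"))
    if k == 0:
        return False
    return bool(cummax_ends[k - 1] > start)


@dataclass
class BinProfile:
    """Per-gene bin hits and per-bin hit fractions for one mark."""

    mark: str
    hits: pd.DataFrame  # genes × bins, boolean; columns bin_1..bin_n, 5'→3'
    fractions: pd.Series  # per-bin fraction of genes hit


def metagene_profile(
    loci: Sequence[GeneLocus],
    intervals: Iterable[GenomicInterval],
    n_bins: int = N_BINS,
    mark: str = "mark",
    flank: int = FLANK,
    body_only: bool = False,
) -> BinProfile:
    """Meta-gene profile: fraction of genes whose k-th bin carries the mark.

    The extended window (gene body ± flank, or the body alone when
    ``body_only``) is split into ``n_bins`` near-equal bins; bin 1 is 5′-most
    in gene orientation (bin order is reversed for minus-strand genes). A bin
    is hit when any interval overlaps it by at least 1 bp.
    """
    index = _interval_index(intervals)
    cols = [f"bin_{i}" for i in range(1, n_bins + 1)]
    rows = {}
    for locus in loci:
        if body_only:
            w = (locus.start, locus.end)
        else:
            w = make_windows(locus, flank=flank).extended
        bins = split_bins(w[0], w[1], n_bins)
        flags = [_any_overlap(index, locus.chrom, s, e) for s, e in bins]
        if locus.strand == "-":
            flags = flags[::-1]
        rows[locus.gene_id] = flags
    hits = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return BinProfile(mark=mark, hits=hits, fractions=hits.mean(axis=0))


def mark_table(
    loci: Sequence[GeneLocus],
    marks: Mapping[str, Iterable[GenomicInterval]],
    window: str = "promoter",
    **window_kwargs,
) -> pd.DataFrame:
    """Gene × mark boolean table of any-overlap with the chosen window.

    ``window`` selects "promoter" (TSS −3.5 kb/+0.5 kb) or "extended"
    (body ±3.5 kb). Mark chromosomes absent from the loci are ignored with a
    warning.
    """
    if window not in ("promoter", "extended"):
        raise ValueError("window must be 'promoter' or 'extended'")
    locus_chroms = {l.chrom for l in loci}
    table = {}
    for name, intervals in marks.items():
        intervals = list(intervals)
        stray = {iv.chrom for iv in intervals} - locus_chroms
        if stray:
            warnings.warn(
                f"mark {name!r}: chromosomes {sorted(stray)} absent from loci; ignored"
            )
        index = _interval_index(iv for iv in intervals if iv.chrom in locus_chroms)
        col = {}
        for locus in loci:
            w = make_windows(locus, **window_kwargs)
            s, e = w.promoter if window == "promoter" else w.extended
            col[locus.gene_id] = _any_overlap(index, locus.chrom, s, e)
        table[name] = col
    return pd.DataFrame(table).loc[[l.gene_id for l in loci]]


def nearest_erv_distance(
    loci: Sequence[GeneLocus],
    ervs: Iterable[GenomicInterval],
    min_len: int = ERV_MIN_LEN,
) -> pd.Series:
    """Per-gene distance (bp) to the nearest ERV of length ≥ min_len.

    Distance is edge-to-edge from the gene body; 0 when gene and ERV overlap.
    Genes on chromosomes without any retained ERV get NaN and are excluded
    from downstream testing.
    """
    retained = [iv for iv in ervs if len(iv) >= min_len]
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in retained:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = {}
    for locus in loci:
        if locus.chrom not in by_chrom:
            out[locus.gene_id] = np.nan
            continue
        best = None
        for iv in by_chrom[locus.chrom]:
            if iv.end <= locus.start:
                d = locus.start - iv.end
            elif iv.start >= locus.end:
                d = iv.start - locus.end
            else:
                d = 0
            best = d if best is None else min(best, d)
        out[locus.gene_id] = float(best)
    return pd.Series(out, name="nearest_erv_bp")


@dataclass(frozen=True)
class ErvDistanceResult:
    statistic: float
    p_value: float
    n_x: int
    n_y: int
    median_x: float
    median_y: float


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> ErvDistanceResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact null enumeration when the combined sample size is ≤12 and there
    are no ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return ErvDistanceResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_x=int(x.size),
        n_y=int(y.size),
        median_x=float(np.median(x)),
        median_y=float(np.median(y)),
    )


def fold_upregulated(
    rpkm: pd.DataFrame, ko_col: str, wt_col: str, min_fold: float = 2.0
) -> pd.Series:
    """Boolean per-gene flag: knockout/wild-type RPKM ratio ≥ min_fold.

    Genes undetected (≤0) in either condition yield False.
    """
    valid = (rpkm[ko_col] > 0) & (rpkm[wt_col] > 0)
    ratio = rpkm[ko_col] / rpkm[wt_col].where(rpkm[wt_col] > 0)
    return (valid & (ratio >= min_fold)).rename("upregulated")
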