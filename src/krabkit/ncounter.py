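"""NanoString nCounter normalization and stage-specific expression calling.

The pipeline follows the standard digital-count workflow for a custom
probe panel profiled across cell types with replicate assays:

1. background correction — subtract, per assay, the geometric mean of the
   negative-control probe counts; values ≤ 0 are floored at 0.1;
2. reference-gene selection by geNorm — for each housekeeping gene j the
   stability value M_j is the mean over partner genes k≠j of the standard
   deviation across assays of log2(x_j/x_k); genes with M < 0.5 are selected;
3. normalization — each assay is divided by its normalization factor, the
   geometric mean of the selected reference genes' corrected counts rescaled
   to geometric mean 1 over assays;
4. summarization — replicate assays are averaged per cell type; a gene is
   called expressed when its mean exceeds a count threshold (99 by default)
   in at least one cell type; relative log2 values r_gc = log2(mean_gc /
   geomean_c' mean_gc') feed correlation and clustering;
5. differential calling — per gene, a two-sided Mann–Whitney U test of the
   pluripotent groups (G1 ∪ G2) against the rest on replicate-level
   normalized counts, Benjamini–Hochberg adjusted across target genes, plus
   a ≥2-fold change filter on group means, yields pluripotency-associated /
   non-pluripotent-associated / housekeeping-like categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PROBE_CLASSES",
    "GROUPS",
    "CountMatrix",
    "AssayDesign",
    "GeNormResult",
    "ExpressionTable",
    "DifferentialCall",
    "background_correct",
    "genorm_stability",
    "genorm_iterative_ranking",
    "normalize_counts",
    "summarize_expression",
    "sample_correlation",
    "differential_groups",
    "compare_platform_ratios",
]

PROBE_CLASSES = ("target", "negative", "housekeeping", "control")
#: G1/G2: pluripotent (2i+LIF and BMP4/FCS+LIF); G3: EpiSC/EB; G4: committed.
GROUPS = ("G1", "G2", "G3", "G4")
PLURIPOTENT_GROUPS = ("G1", "G2")

BACKGROUND_FLOOR = 0.1


@dataclass
class CountMatrix:
    """Probes × assays count matrix with per-probe class and gene annotation.

    ``counts`` is indexed by probe_id; ``probe_info`` carries columns
    ``gene_id`` and ``probe_class`` on the same index.
    """

    counts: pd.DataFrame
    probe_info: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.probe_info.index):
            raise ValueError("counts and probe_info must share the probe index")
        unknown = set(self.probe_info["probe_class"]) - set(PROBE_CLASSES)
        if unknown:
            raise ValueError(f"unknown probe classes: {sorted(unknown)}")
        if not np.isfinite(self.counts.to_numpy(dtype=float)).all():
            raise ValueError("counts must be finite")
        if (self.counts.to_numpy(dtype=float) < 0).any():
            raise ValueError("counts must be non-negative")

    def of_class(self, probe_class: str) -> pd.DataFrame:
        mask = self.probe_info["probe_class"] == probe_class
        return self.counts.loc[mask]

    @property
    def assays(self) -> list[str]:
        return list(self.counts.columns)

    def subset_probes(self, probe_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[list(probe_ids)], self.probe_info.loc[list(probe_ids)]
        )


@dataclass
class AssayDesign:
    """Assay → cell type / replicate / group mapping.

    ``table`` is indexed by assay_id with columns cell_type, replicate, group.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"cell_type", "replicate", "group"}
        if not need <= set(self.table.columns):
            raise ValueError(f"design table needs columns {sorted(need)}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups: {sorted(bad)}")
        reps = self.table.groupby("cell_type").size()
        low = reps[reps < 2]
        if not low.empty:
            raise ValueError(
                f"every cell type needs ≥2 replicate assays; got {low.to_dict()}"
            )

    @property
    def cell_types(self) -> list[str]:
        # stable: order of first appearance
        return list(dict.fromkeys(self.table["cell_type"]))

    def assays_of(self, cell_type: str) -> list[str]:
        return list(self.table.index[self.table["cell_type"] == cell_type])

    def group_of(self, assay_id: str) -> str:
        return str(self.table.loc[assay_id, "group"])


@dataclass
class GeNormResult:
    """geNorm stability values and per-assay normalization factors."""

    m_values: pd.Series  # gene → M
    selected: list[str]
    normalization_factors: pd.Series  # assay → NF, geometric mean 1
    m_cutoff: float


@dataclass
class ExpressionTable:
    """Per-cell-type averaged counts, relative log2 values and expressed flags."""

    means: pd.DataFrame  # gene × cell_type averaged normalized counts
    relative_log2: pd.DataFrame  # r_gc, rows sum to 0
    expressed: pd.Series  # gene → bool, mean > threshold in ≥1 cell type
    threshold: float
    gene_info: pd.DataFrame = field(default=None)  # gene_id/probe_class lookup


@dataclass(frozen=True)
class DifferentialCall:
    gene_id: str
    category: str  # pluripotency-associated | non-pluripotent-associated |
    #                housekeeping-like | none
    p_adjusted: float
    max_fold_change: float


def _geomean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def background_correct(m: CountMatrix) -> CountMatrix:
    """Subtract per-assay geometric-mean negative-control background.

    Corrected values ≤ 0 are set to 0.1 so downstream log/ratio operations
    stay defined. Zero counts among the negatives are replaced by 1 before
    the geometric mean. Negative probes are dropped from the output.
    """
    negatives = m.of_class("negative")
    if negatives.empty:
        raise ValueError("count matrix has no negative-control probes")
    neg = negatives.to_numpy(dtype=float)
    neg[neg == 0] = 1.0
    background = np.exp(np.log(neg).mean(axis=0))  # per assay
    keep = m.probe_info["probe_class"] != "negative"
    corrected = m.counts.loc[keep].astype(float).sub(background, axis=1)
    corrected = corrected.where(corrected > 0, BACKGROUND_FLOOR)
    return CountMatrix(corrected, m.probe_info.loc[keep].copy())


def _pairwise_m(log2x: pd.DataFrame) -> pd.Series:
    """M_j = mean over k≠j of sd across assays of log2(x_j / x_k)."""
    genes = list(log2x.index)
    m = {}
    for j in genes:
        sds = [
            float(np.std((log2x.loc[j] - log2x.loc[k]).to_numpy(), ddof=1))
            for k in genes
            if k != j
        ]
        m[j] = float(np.mean(sds))
    return pd.Series(m, name="M")


def genorm_stability(
    hk: CountMatrix | pd.DataFrame, m_cutoff: float = 0.5
) -> GeNormResult:
    """Rank housekeeping genes by geNorm stability and derive NFs.

    One-pass variant: every gene with M < ``m_cutoff`` is selected as a
    reference gene. If fewer than two genes pass, the two lowest-M genes are
    used with a warning. The per-assay normalization factor is the geometric
    mean of the selected genes' counts, rescaled so NFs have geometric mean 1
    across assays.
    """
    counts = hk.of_class("housekeeping") if isinstance(hk, CountMatrix) else hk
    if len(counts) < 3:
        raise ValueError("geNorm needs ≥3 housekeeping genes")
    if counts.shape[1] < 2:
        raise ValueError("geNorm needs ≥2 assays")
    x = counts.to_numpy(dtype=float)
    if (x <= 0).any():
        raise ValueError("geNorm requires strictly positive counts")
    log2x = pd.DataFrame(np.log2(x), index=counts.index, columns=counts.columns)
    m = _pairwise_m(log2x)
    selected = sorted(m.index[m < m_cutoff], key=lambda g: m[g])
    if len(selected) < 2:
        warnings.warn(
            f"only {len(selected)} genes below M cutoff {m_cutoff}; "
            "falling back to the 2 most stable genes",
            stacklevel=2,
        )
        selected = list(m.sort_values().index[:2])
    nf_raw = counts.loc[selected].apply(lambda col: _geomean(col.to_numpy()), axis=0)
    nf = nf_raw / _geomean(nf_raw.to_numpy())
    return GeNormResult(
        m_values=m, selected=selected, normalization_factors=nf, m_cutoff=m_cutoff
    )


def genorm_iterative_ranking(hk: CountMatrix | pd.DataFrame) -> list[str]:
    """Classical geNorm ranking by iterative exclusion of the least stable gene.

    Returned least-stable-first; the final two genes (ranked last, tied) are
    the most stable pair. Exposed for QC alongside the one-pass selection.
    """
    counts = hk.of_class("housekeeping") if isinstance(hk, CountMatrix) else hk
    log2x = pd.DataFrame(
        np.log2(counts.to_numpy(dtype=float)),
        index=counts.index,
        columns=counts.columns,
    )
    excluded: list[str] = []
    remaining = list(log2x.index)
    while len(remaining) > 2:
        m = _pairwise_m(log2x.loc[remaining])
        worst = m.sort_values(ascending=False).index[0]
        excluded.append(str(worst))
        remaining.remove(worst)
    return excluded + sorted(remaining)


def normalize_counts(m: CountMatrix, g: GeNormResult) -> CountMatrix:
    """Divide every assay by its normalization factor.

    Housekeeping probes are retained for QC; the selected reference genes'
    per-assay geometric mean becomes constant across assays afterwards.
    """
    nf = g.normalization_factors
    missing = set(m.assays) - set(nf.index)
    if missing:
        raise ValueError(f"normalization factors missing for assays {sorted(missing)}")
    if (nf <= 0).any():
        raise ValueError("normalization factors must be positive")
    normalized = m.counts.astype(float).div(nf[m.assays], axis=1)
    return CountMatrix(normalized, m.probe_info.copy())


def summarize_expression(
    m: CountMatrix, design: AssayDesign, threshold: float = 99.0
) -> ExpressionTable:
    """Average replicates per cell type and derive relative log2 values.

    A gene is flagged expressed when its averaged count strictly exceeds
    ``threshold`` in at least one cell type. Relative log2 values are
    centred per gene (they sum to zero across cell types by construction).
    """
    missing = set(design.table.index) - set(m.assays)
    if missing:
        raise ValueError(f"design references assays absent from counts: {sorted(missing)}")
    means = pd.DataFrame(
        {ct: m.counts[design.assays_of(ct)].mean(axis=1) for ct in design.cell_types}
    )
    logm = np.log2(means.where(means > 0, BACKGROUND_FLOOR))
    relative = logm.sub(logm.mean(axis=1), axis=0)
    expressed = (means > threshold).any(axis=1)
    return ExpressionTable(
        means=means,
        relative_log2=relative,
        expressed=expressed,
        threshold=threshold,
        gene_info=m.probe_info.copy(),
    )


def sample_correlation(
    t: ExpressionTable, probe_class: str = "target"
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between cell types plus a dendrogram leaf order.

    Correlation is computed on relative log2 values of the requested probe
    class; clustering is agglomerative with average linkage on Euclidean
    distances between cell-type profiles.
    """
    rel = t.relative_log2
    if t.gene_info is not None and probe_class is not None:
        rel = rel.loc[t.gene_info["probe_class"] == probe_class]
    if rel.shape[1] < 2:
        raise ValueError("need ≥2 samples for correlation")
    sds = rel.std(axis=0, ddof=0)
    flat = sds.index[sds == 0]
    if len(flat) > 0:
        raise ValueError(
            f"zero-variance sample(s): {list(map(str, flat))}; correlation undefined"
        )
    corr = rel.corr(method="pearson")
    link = hierarchy.linkage(pdist(rel.T.to_numpy()), method="average")
    order = hierarchy.leaves_list(link)
    leaf_order = [str(rel.columns[i]) for i in order]
    return corr, leaf_order


def _bh(p: Sequence[float]) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def differential_groups(
    m: CountMatrix,
    design: AssayDesign,
    alpha: float = 0.05,
    min_fold: float = 2.0,
    probe_class: str = "target",
) -> list[DifferentialCall]:
    """Call stage-specific genes from replicate-level normalized counts.

    Per gene, a two-sided Mann–Whitney U test compares the pluripotent
    groups (G1 ∪ G2) against all other assays; p-values are BH-adjusted
    across the tested genes. A gene is pluripotency-associated when
    adj-p ≤ alpha, the between-group fold change is ≥ min_fold and the
    pluripotent mean is the higher one; non-pluripotent-associated when the
    direction is reversed. Housekeeping-like requires all pairwise group
    comparisons (BH-adjusted per comparison) non-significant and a maximum
    between-group fold change < min_fold. Everything else is "none".
    """
    counts = m.of_class(probe_class)
    genes = [str(g) for g in counts.index]
    groups = {g: [a for a in m.assays if design.group_of(a) == g] for g in GROUPS}
    pluri_assays = groups["G1"] + groups["G2"]
    rest_assays = groups["G3"] + groups["G4"]
    if len(pluri_assays) < 2 or len(rest_assays) < 2:
        raise ValueError("each side of the comparison needs ≥2 assays")

    x = counts[pluri_assays].to_numpy(dtype=float)
    y = counts[rest_assays].to_numpy(dtype=float)

    p_main = np.ones(len(genes))
    for i in range(len(genes)):
        if np.all(x[i] == x[i][0]) and np.all(y[i] == y[i][0]) and x[i][0] == y[i][0]:
            p_main[i] = 1.0
        else:
            p_main[i] = stats.mannwhitneyu(x[i], y[i], alternative="two-sided").pvalue
    p_adj = _bh(p_main)

    # group means (floored) for fold changes, and pairwise group tests for the
    # housekeeping-like category
    group_means = {}
    for g in GROUPS:
        arr = counts[groups[g]].to_numpy(dtype=float) if groups[g] else None
        group_means[g] = arr.mean(axis=1) if arr is not None else None
    present = [g for g in GROUPS if group_means[g] is not None]
    gm = np.vstack([np.maximum(group_means[g], BACKGROUND_FLOOR) for g in present])
    max_fold = (gm.max(axis=0) / gm.min(axis=0))

    pair_sig = np.zeros(len(genes), dtype=bool)
    for ga, gb in combinations(present, 2):
        a, b = counts[groups[ga]].to_numpy(float), counts[groups[gb]].to_numpy(float)
        if a.shape[1] < 2 or b.shape[1] < 2:
            warnings.warn(f"group {ga} vs {gb}: <2 assays, comparison skipped")
            continue
        p = np.array(
            [
                1.0
                if np.all(a[i] == b[i][0]) and np.all(b[i] == b[i][0])
                else stats.mannwhitneyu(a[i], b[i], alternative="two-sided").pvalue
                for i in range(len(genes))
            ]
        )
        pair_sig |= _bh(p) <= alpha

    pluri_mean = np.maximum(x.mean(axis=1), BACKGROUND_FLOOR)
    rest_mean = np.maximum(y.mean(axis=1), BACKGROUND_FLOOR)

    calls = []
    for i, gene in enumerate(genes):
        if p_adj[i] <= alpha and max_fold[i] >= min_fold:
            if pluri_mean[i] > rest_mean[i]:
                cat = "pluripotency-associated"
            else:
                cat = "non-pluripotent-associated"
        elif not pair_sig[i] and max_fold[i] < min_fold:
            cat = "housekeeping-like"
        else:
            cat = "none"
        calls.append(
            DifferentialCall(
                gene_id=gene,
                category=cat,
                p_adjusted=float(p_adj[i]),
                max_fold_change=float(max_fold[i]),
            )
        )
    return calls


def compare_platform_ratios(
    table: pd.DataFrame,
    a_cols: tuple[str, str] = ("ncounter_esc", "ncounter_mef"),
    b_cols: tuple[str, str] = ("rpkm_esc", "rpkm_mef"),
) -> tuple[float, float, pd.DataFrame]:
    """Cross-platform check: Pearson r of per-gene log2 ESC/MEF ratios.

    Consumes a precomputed table with nCounter counts and RNA-seq RPKM for
    genes detectable on both platforms; returns (r, r²) and the ratio table.
    """
    t = table.copy()
    for c in (*a_cols, *b_cols):
        t = t[t[c] > 0]
    la = np.log2(t[a_cols[0]] / t[a_cols[1]])
    lb = np.log2(t[b_cols[0]] / t[b_cols[1]])
    r = float(np.corrcoef(la, lb)[0, 1])
    out = pd.DataFrame({"log2_ratio_ncounter": la, "log2_ratio_rnaseq": lb})
    return r, r * r, out
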