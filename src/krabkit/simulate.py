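"""Seeded synthetic data with planted ground truth for every pipeline stage.

Each generator emulates one class of study input — proteomes with planted
KRAB and zinc-finger domains, chromosome layouts with planted gene clusters,
nCounter count matrices with negative-control background / housekeeping
stability ranking / replicate structure / planted group effects, ChIP
interval sets with planted bin preferences and ERV-distance shifts, and CT
tables with planted fold changes — and returns the planted parameters as a
serializable ground-truth record so downstream recovery can be scored
without reading generator internals.

Determinism: every generator draws from its own RNG stream derived from the
master seed and a stable per-generator label, so identical (seed, config)
always yields identical output and adding a generator never perturbs the
others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .census import KrabDomain, ProteinRecord
from .chip import GenomicInterval
from .clusters import GeneLocus

__all__ = [
    "rng_for",
    "GroundTruth",
    "gen_proteome",
    "gen_loci",
    "gen_counts",
    "gen_chip",
    "gen_qpcr",
]

# residues that can never seed or extend a C2H2 match (no C, no H)
_SAFE = "ADEFGIKLMNPQRSTVWY"

#: 62-residue KRAB consensus used for planting; D5/V6 present, no C/H anywhere
#: so the domain can never collide with zinc-finger pattern scanning.
KRAB_CONSENSUS = (
    "MDVRDVAVDFSPEEWALLDSAQRNLYRDVMLENYRNLVSLG"
    "LAVSKPDLITLLEQGKEPW"
)
assert KRAB_CONSENSUS[4] == "D" and KRAB_CONSENSUS[5] == "V"


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Independent RNG stream for (master seed, generator label)."""
    h = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, h])


@dataclass
class GroundTruth:
    """Planted parameters of one generator call; JSON-serializable."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)
    per_item: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "generator": self.generator,
            "seed": self.seed,
            "params": self.params,
            "per_item": self.per_item,
        }


def _random_finger(rng: np.random.Generator) -> str:
    """A random sequence matching C-X(2-4)-C-X(12)-H-X(3-5)-H exactly once."""
    def spacer(n: int) -> str:
        return "".join(rng.choice(list(_SAFE), size=n))

    g1 = int(rng.integers(2, 5))
    g2 = int(rng.integers(3, 6))
    return f"C{spacer(g1)}C{spacer(12)}H{spacer(g2)}H"


def _linker(rng: np.random.Generator, lo: int = 4, hi: int = 12) -> str:
    return "".join(rng.choice(list(_SAFE), size=int(rng.integers(lo, hi + 1))))


def gen_proteome(
    n_genes: int,
    zf_count_range: tuple[int, int] = (1, 15),
    krab_o_fraction: float = 0.1,
    seed: int = 0,
    mutate_dv_fraction: float = 0.0,
) -> tuple[list[ProteinRecord], dict[str, KrabDomain], GroundTruth]:
    """Synthetic proteome of KRAB-containing proteins with planted fingers.

    Each protein is a short N-terminal linker, the planted KRAB consensus
    (optionally with its D5/V6 dipeptide mutated), and — for the KRAB-ZFP
    share — k zinc fingers separated by pattern-free linkers. Linkers and
    spacers avoid C and H entirely, so pattern scanning recovers exactly the
    planted fingers at the planted coordinates.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be ≥1")
    if not 0 <= krab_o_fraction <= 1:
        raise ValueError("krab_o_fraction must lie in [0,1]")
    lo, hi = zf_count_range
    if lo < 1 or hi < lo:
        raise ValueError("zf_count_range must satisfy 1 ≤ lo ≤ hi")
    rng = rng_for(seed, "proteome")
    n_krab_o = int(round(n_genes * krab_o_fraction))
    is_krab_o = np.zeros(n_genes, dtype=bool)
    is_krab_o[rng.choice(n_genes, size=n_krab_o, replace=False)] = True

    records: list[ProteinRecord] = []
    annotations: dict[str, KrabDomain] = {}
    truth_items: dict[str, dict] = {}
    for i in range(n_genes):
        gene = f"SYNG{i:04d}"
        head = _linker(rng, 2, 6)
        krab = KRAB_CONSENSUS
        if mutate_dv_fraction and rng.random() < mutate_dv_fraction:
            krab = krab[:5] + "A" + krab[6:]  # knock out V6, Ssx-style
        seq = head + krab
        krab_start, krab_end = len(head), len(head) + len(krab)
        fingers: list[tuple[int, int]] = []
        if not is_krab_o[i]:
            k = int(rng.integers(lo, hi + 1))
            for _ in range(k):
                seq += _linker(rng)
                f = _random_finger(rng)
                fingers.append((len(seq), len(seq) + len(f)))
                seq += f
            seq += _linker(rng)
        records.append(
            ProteinRecord(
                protein_id=f"SYNP{i:04d}",
                transcript_id=f"SYNT{i:04d}",
                gene_id=gene,
                sequence=seq,
            )
        )
        annotations[gene] = KrabDomain(
            start=krab_start,
            end=krab_end,
            sequence=seq[krab_start:krab_end],
            has_d5=seq[krab_start + 4] == "D",
            has_v6=seq[krab_start + 5] == "V",
        )
        truth_items[gene] = {
            "krab_o": bool(is_krab_o[i]),
            "n_zf": len(fingers),
            "zf_coords": fingers,
            "krab": [krab_start, krab_end],
        }
    truth = GroundTruth(
        generator="proteome",
        seed=seed,
        params={
            "n_genes": n_genes,
            "zf_count_range": list(zf_count_range),
            "krab_o_fraction": krab_o_fraction,
            "mutate_dv_fraction": mutate_dv_fraction,
        },
        per_item=truth_items,
    )
    return records, annotations, truth


def gen_loci(
    cluster_sizes: Sequence[int] = (2, 5, 41),
    n_singletons: int = 10,
    chrom_lengths: Mapping[str, int] | None = None,
    max_gap: int = 200_000,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (5_000, 30_000),
) -> tuple[list[GeneLocus], GroundTruth]:
    """Chromosome gene layout with planted clusters and singletons.

    Within a planted cluster every consecutive edge-to-edge gap is ≤ max_gap;
    planted blocks (clusters or singletons) are separated by gaps strictly
    greater than max_gap, so cluster detection recovers exactly the planted
    partition.
    """
    if any(s < 2 for s in cluster_sizes):
        raise ValueError("planted clusters need ≥2 genes")
    if chrom_lengths is None:
        chrom_lengths = {"1": 150_000_000, "2": 120_000_000, "X": 100_000_000}
    rng = rng_for(seed, "loci")
    blocks: list[int] = list(cluster_sizes) + [1] * n_singletons
    order = rng.permutation(len(blocks))
    chroms = list(chrom_lengths)

    loci: list[GeneLocus] = []
    membership: dict[str, int] = {}
    cursor = {c: 0 for c in chroms}
    gene_i = 0
    cluster_label = 0
    for bi in order:
        size = blocks[bi]
        is_cluster = size >= 2
        if is_cluster:
            cluster_label += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = cursor[chrom] + max_gap + 1 + int(rng.integers(0, 100_000))
        for j in range(size):
            glen = int(rng.integers(*gene_length_range))
            if j > 0:
                pos += int(rng.integers(1, max_gap + 1))  # gap ≤ max_gap
            gid = f"SYNG{gene_i:04d}"
            if pos + glen > chrom_lengths[chrom]:
                raise ValueError(f"chromosome {chrom} overflow at {gid}")
            loci.append(
                GeneLocus(
                    gene_id=gid,
                    chrom=chrom,
                    start=pos,
                    end=pos + glen,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
            membership[gid] = cluster_label if is_cluster else 0
            pos += glen
            gene_i += 1
        cursor[chrom] = pos
    truth = GroundTruth(
        generator="loci",
        seed=seed,
        params={
            "cluster_sizes": list(cluster_sizes),
            "n_singletons": n_singletons,
            "max_gap": max_gap,
        },
        per_item={"membership": membership},
    )
    return loci, truth


#: Study-like assay design: cell types with their subgroup and replicate count
#: (pluripotent ground-state G1, pluripotent serum/BMP4 G2, post-implantation
#: G3, committed G4; duplicates only for MEFs).
DEFAULT_DESIGN: tuple[tuple[str, str, int], ...] = (
    ("ESC_2iLIF", "G1", 3),
    ("EGC_2iLIF", "G1", 3),
    ("ESC_FCSLIF", "G2", 3),
    ("ESC_BMP4LIF", "G2", 3),
    ("EpiSC", "G3", 3),
    ("EB_D6", "G3", 3),
    ("XEN", "G4", 3),
    ("TSC", "G4", 3),
    ("NPC", "G4", 3),
    ("MEF", "G4", 2),
)


def _design_frame(design: Sequence[tuple[str, str, int]]) -> pd.DataFrame:
    rows = []
    for cell_type, group, n_rep in design:
        for r in range(1, n_rep + 1):
            rows.append(
                {
                    "assay_id": f"{cell_type}_r{r}",
                    "cell_type": cell_type,
                    "replicate": r,
                    "group": group,
                }
            )
    return pd.DataFrame(rows).set_index("assay_id")


def gen_counts(
    n_targets: int = 100,
    n_housekeeping: int = 8,
    n_negative: int = 6,
    effects: Mapping[str, float] | None = None,
    n_effect_genes: int = 10,
    effect_fold: float = 4.0,
    cv: float = 0.10,
    background_lambda: float = 4.0,
    design: Sequence[tuple[str, str, int]] = DEFAULT_DESIGN,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Synthetic nCounter run: counts, probe info, design, ground truth.

    Counts are round(lognormal) biological signal plus Poisson background;
    negative probes carry background only. Housekeeping genes get ascending
    per-gene noise (planted stability order = probe order). ``effects`` maps
    target gene ids to fold changes applied in the pluripotent groups
    (G1∪G2); fold < 1 plants a non-pluripotent-associated gene. When
    ``effects`` is None, the first ``n_effect_genes`` targets get
    ``effect_fold``.
    """
    if n_housekeeping < 3 or n_negative < 1:
        raise ValueError("need ≥3 housekeeping and ≥1 negative probes")
    rng = rng_for(seed, "counts")
    design_df = _design_frame(design)
    assays = list(design_df.index)
    pluripotent = design_df["group"].isin(("G1", "G2")).to_numpy()

    target_ids = [f"SYNG{i:04d}" for i in range(n_targets)]
    if effects is None:
        effects = {g: effect_fold for g in target_ids[:n_effect_genes]}
    unknown = set(effects) - set(target_ids)
    if unknown:
        raise ValueError(f"effects reference unknown genes: {sorted(unknown)}")

    sigma_ln = float(np.sqrt(np.log1p(cv**2)))  # lognormal sigma giving CV
    hk_sigmas = np.linspace(0.05, 0.40, n_housekeeping)

    rows, info = [], []
    for gi, gene in enumerate(target_ids):
        mu = float(rng.uniform(150, 1500))
        fold = float(effects.get(gene, 1.0))
        level = np.where(pluripotent, mu * fold, mu)
        signal = level * np.exp(rng.normal(0.0, sigma_ln, size=len(assays)))
        counts = np.round(signal) + rng.poisson(background_lambda, size=len(assays))
        rows.append(counts)
        info.append((f"probe_t{gi:04d}", gene, "target"))
    for hi in range(n_housekeeping):
        mu = float(rng.uniform(300, 3000))
        signal = mu * np.exp(rng.normal(0.0, hk_sigmas[hi], size=len(assays)))
        counts = np.round(signal) + rng.poisson(background_lambda, size=len(assays))
        rows.append(counts)
        info.append((f"probe_h{hi:02d}", f"HK{hi:02d}", "housekeeping"))
    for ni in range(n_negative):
        counts = rng.poisson(background_lambda, size=len(assays)).astype(float)
        rows.append(counts)
        info.append((f"probe_n{ni:02d}", f"NEG{ni:02d}", "negative"))

    probe_info = pd.DataFrame(
        info, columns=["probe_id", "gene_id", "probe_class"]
    ).set_index("probe_id")
    counts_df = pd.DataFrame(
        np.vstack(rows), index=probe_info.index, columns=assays
    )
    truth = GroundTruth(
        generator="counts",
        seed=seed,
        params={
            "n_targets": n_targets,
            "cv": cv,
            "background_lambda": background_lambda,
            "effect_fold": effect_fold,
        },
        per_item={
            "effects": dict(effects),
            "hk_stability_order": [f"HK{h:02d}" for h in range(n_housekeeping)],
            "hk_sigmas": hk_sigmas.tolist(),
        },
    )
    return counts_df, probe_info, design_df, truth


def gen_chip(
    loci: Sequence[GeneLocus],
    bin_probs: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    near_gene_ids: Sequence[str] = (),
    erv_near_distance: float = 1_000.0,
    erv_far_distance: float = 6_000.0,
    erv_distance_sd: float = 300.0,
    short_erv_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[GenomicInterval], list[GenomicInterval], GroundTruth]:
    """Synthetic ChIP mark intervals and ERVs for a given gene layout.

    Marks: for each gene, each of the 8 bins of its extended window is hit
    with the per-bin probability (in 5′→3′ gene orientation) by planting a
    small interval inside the bin. ERVs: one per gene, placed downstream of
    the gene end at a distance drawn around ``erv_near_distance`` for genes
    in ``near_gene_ids`` and ``erv_far_distance`` otherwise; a stated
    fraction of additional decoy ERVs is shorter than 500 bp (those sit
    closer than either group but must be excluded by the length filter).
    """
    from .chip import make_windows, split_bins  # local import avoids cycle

    rng = rng_for(seed, "chip")
    near = set(near_gene_ids)
    marks: list[GenomicInterval] = []
    ervs: list[GenomicInterval] = []
    planted_bins: dict[str, list[int]] = {}
    planted_dist: dict[str, float] = {}
    for locus in loci:
        w = make_windows(locus).extended
        bins = split_bins(w[0], w[1], len(bin_probs))
        if locus.strand == "-":
            bins = bins[::-1]  # bin 1 is 5'-most in gene orientation
        hit_bins = []
        for b, (s, e) in enumerate(bins, start=1):
            if rng.random() < bin_probs[b - 1]:
                mid = (s + e) // 2
                half = max(1, (e - s) // 8)
                marks.append(
                    GenomicInterval(locus.chrom, mid - half, mid + half, name="mark")
                )
                hit_bins.append(b)
        planted_bins[locus.gene_id] = hit_bins

        d_mean = erv_near_distance if locus.gene_id in near else erv_far_distance
        d = max(1.0, float(rng.normal(d_mean, erv_distance_sd)))
        length = int(rng.integers(600, 4_000))
        start = locus.end + int(d)
        ervs.append(GenomicInterval(locus.chrom, start, start + length, name="ERV"))
        planted_dist[locus.gene_id] = float(int(d))
        if rng.random() < short_erv_fraction:
            # decoy: shorter than the filter, parked right at the gene edge
            ervs.append(
                GenomicInterval(
                    locus.chrom, locus.end + 10, locus.end + 10 + 300, name="ERV_short"
                )
            )
    truth = GroundTruth(
        generator="chip",
        seed=seed,
        params={
            "bin_probs": list(bin_probs),
            "erv_near_distance": erv_near_distance,
            "erv_far_distance": erv_far_distance,
        },
        per_item={
            "bins": planted_bins,
            "erv_distance": planted_dist,
            "near_genes": sorted(near),
        },
    )
    return marks, ervs, truth


def gen_qpcr(
    folds: Mapping[str, Mapping[str, float]] | None = None,
    normalizers: Sequence[str] = ("Actb", "Tubb2c"),
    reference_sample: str = "ESC_FCSLIF",
    n_replicates: int = 3,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """CT table with planted per-sample fold changes for each target gene.

    ``folds`` maps target gene → {sample → fold relative to the reference
    sample}; the reference sample itself is fold 1. CT values are constructed
    so 2^(−ΔΔCT) recovers the planted fold exactly when ``ct_noise_sd`` is 0.
    """
    rng = rng_for(seed, "qpcr")
    if folds is None:
        folds = {
            "Zfp459": {"ESC_2iLIF": 8.0, "EpiSC": 0.25, "EB_D6": 0.125},
            "Zfp809": {"ESC_2iLIF": 1.0, "EpiSC": 1.0, "EB_D6": 1.0},
        }
    samples: list[str] = [reference_sample]
    for per_sample in folds.values():
        for s in per_sample:
            if s not in samples:
                samples.append(s)
    rows = []
    base_norm_ct = {g: float(rng.uniform(18, 22)) for g in normalizers}
    base_target_ct = {g: float(rng.uniform(24, 30)) for g in folds}
    for s in samples:
        shift = float(rng.uniform(-1, 1))  # per-sample loading offset
        for g in normalizers:
            for r in range(n_replicates):
                rows.append(
                    {
                        "sample": s,
                        "gene": g,
                        "ct": base_norm_ct[g] + shift
                        + float(rng.normal(0, ct_noise_sd)),
                    }
                )
        for g, per_sample in folds.items():
            fold = per_sample.get(s, 1.0) if s != reference_sample else 1.0
            for r in range(n_replicates):
                rows.append(
                    {
                        "sample": s,
                        "gene": g,
                        "ct": base_target_ct[g] + shift - float(np.log2(fold))
                        + float(rng.normal(0, ct_noise_sd)),
                    }
                )
    truth = GroundTruth(
        generator="qpcr",
        seed=seed,
        params={"reference_sample": reference_sample, "ct_noise_sd": ct_noise_sd},
        per_item={"folds": {g: dict(v) for g, v in folds.items()}},
    )
    return pd.DataFrame(rows), truth
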