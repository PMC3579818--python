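"""Readers/writers for the pipeline's file formats and input validation.

All internal coordinates are 0-based half-open (BED convention); 1-based
inclusive inputs must be converted at this boundary. Analysis outputs are
TSVs with a header comment recording version, seed and config hash.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .census import CensusEntry, KrabDomain, ProteinRecord
from .chip import GenomicInterval
from .clusters import GeneLocus
from .config import PipelineConfig
from .ncounter import AssayDesign, CountMatrix
from .orthology import OrthologPair

__all__ = [
    "read_protein_fasta",
    "write_protein_fasta",
    "read_krab_annotations",
    "read_gene_bed",
    "read_interval_bed",
    "write_bed",
    "read_count_matrix",
    "write_count_matrix",
    "read_assay_design",
    "write_census",
    "read_census",
    "write_orthologs",
    "write_table",
    "ValidationReport",
    "validate_inputs",
    "convert_xlsx_to_tsv",
]


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read proteins from FASTA with headers ``protein_id|transcript_id|gene_id``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"{path}: header {rec.id!r} is not 'protein|transcript|gene'"
            )
        records.append(
            ProteinRecord(
                protein_id=parts[0],
                transcript_id=parts[1],
                gene_id=parts[2],
                sequence=str(rec.seq).upper(),
            )
        )
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.protein_id}|{r.transcript_id}|{r.gene_id}",
            description="",
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_krab_annotations(
    path: str | Path, records: Sequence[ProteinRecord]
) -> dict[str, KrabDomain]:
    """Read the KRAB domain-annotation TSV (gene_id, protein_id, krab_start,
    krab_end; coordinates 0-based half-open in the protein)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"gene_id", "protein_id", "krab_start", "krab_end"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(need)}")
    by_protein = {r.protein_id: r for r in records}
    out: dict[str, KrabDomain] = {}
    for row in df.itertuples(index=False):
        rec = by_protein.get(row.protein_id)
        if rec is None:
            raise KeyError(f"{path}: unknown protein_id {row.protein_id!r}")
        s, e = int(row.krab_start), int(row.krab_end)
        sub = rec.sequence[s:e]
        out[str(row.gene_id)] = KrabDomain(
            start=s,
            end=e,
            sequence=sub,
            has_d5=len(sub) >= 5 and sub[4] == "D",
            has_v6=len(sub) >= 6 and sub[5] == "V",
        )
    return out


def read_gene_bed(path: str | Path) -> list[GeneLocus]:
    """Read gene loci from BED6 (chrom, start, end, gene_id, score, strand)."""
    loci = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 6:
            raise ValueError(f"{path}:{ln}: BED6 line needs 6 fields")
        try:
            loci.append(
                GeneLocus(
                    gene_id=f[3], chrom=f[0], start=int(f[1]), end=int(f[2]),
                    strand=f[5],
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: {exc}") from exc
    return loci


def read_interval_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals (RepeatMasker-style exports acceptable)."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 3:
            raise ValueError(f"{path}:{ln}: BED line needs ≥3 fields")
        try:
            out.append(
                GenomicInterval(
                    chrom=f[0], start=int(f[1]), end=int(f[2]),
                    name=f[3] if len(f) > 3 else ".",
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: {exc}") from exc
    return out


def write_bed(items: Iterable[GeneLocus | GenomicInterval], path: str | Path) -> None:
    lines = []
    for it in items:
        if isinstance(it, GeneLocus):
            lines.append(
                f"{it.chrom}\t{it.start}\t{it.end}\t{it.gene_id}\t0\t{it.strand}"
            )
        else:
            lines.append(f"{it.chrom}\t{it.start}\t{it.end}\t{it.name}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read the raw counts TSV: probe_id, gene_id, class, then one column per assay."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"probe_id", "gene_id", "class"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(need)}")
    df = df.set_index("probe_id")
    info = df[["gene_id", "class"]].rename(columns={"class": "probe_class"})
    counts = df.drop(columns=["gene_id", "class"]).astype(float)
    return CountMatrix(counts, info)


def write_count_matrix(m: CountMatrix, path: str | Path, **meta) -> None:
    df = m.probe_info.rename(columns={"probe_class": "class"}).join(m.counts)
    write_table(df.reset_index(), path, **meta)


def read_assay_design(path: str | Path) -> AssayDesign:
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"assay_id", "cell_type", "replicate", "group"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(need)}")
    return AssayDesign(df.set_index("assay_id"))


def write_census(entries: Iterable[CensusEntry], path: str | Path, **meta) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "transcript_id": e.transcript_id,
                "protein_id": e.protein_id,
                "n_zf": e.n_zf,
                "klass": e.klass,
                "cluster_id": e.cluster_id,
            }
            for e in entries
        ]
    )
    write_table(df, path, **meta)


def read_census(path: str | Path) -> list[CensusEntry]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        CensusEntry(
            gene_id=str(r.gene_id),
            klass=str(r.klass),
            n_zf=int(r.n_zf),
            protein_id=str(r.protein_id),
            transcript_id=str(r.transcript_id),
            cluster_id=int(r.cluster_id),
        )
        for r in df.itertuples(index=False)
    ]


def write_orthologs(pairs: Iterable[OrthologPair], path: str | Path, **meta) -> None:
    df = pd.DataFrame(
        [
            {
                "mouse_gene": p.mouse_gene,
                "human_gene": p.human_gene,
                "mouse_protein": p.mouse_protein,
                "human_protein": p.human_protein,
                "percent_homology": p.percent_homology,
            }
            for p in pairs
        ]
    )
    write_table(df, path, **meta)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config: PipelineConfig | None = None,
    seed: int | None = None,
    index: bool = False,
) -> None:
    """Write a TSV with a provenance header comment; floats at 6 sig. digits."""
    header = f"# krabkit {__version__}"
    if seed is not None:
        header += f" seed={seed}"
    if config is not None:
        header += f" config={config.digest()}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    paths: Mapping[str, str | Path], config: PipelineConfig | None = None
) -> ValidationReport:
    """Check format conformance of a set of pipeline inputs.

    ``paths`` maps kinds to files; recognized kinds: ``fasta``, ``bed``
    (gene loci), ``intervals``, ``counts``, ``design``. Problems are
    collected rather than raised; errors make ``report.ok`` false.
    """
    report = ValidationReport()
    readers = {
        "fasta": read_protein_fasta,
        "bed": read_gene_bed,
        "intervals": read_interval_bed,
        "counts": read_count_matrix,
        "design": read_assay_design,
    }
    loaded: dict[str, object] = {}
    for kind, path in paths.items():
        if kind not in readers:
            report.warnings.append(f"unrecognized input kind {kind!r}; skipped")
            continue
        if not Path(path).exists():
            report.errors.append(f"{kind}: file not found: {path}")
            continue
        try:
            loaded[kind] = readers[kind](path)
        except Exception as exc:  # collect, don't raise
            report.errors.append(f"{kind}: {exc}")
    if "bed" in loaded:
        loci: list[GeneLocus] = loaded["bed"]  # type: ignore[assignment]
        by_chrom: dict[str, int] = {}
        for l in loci:
            prev = by_chrom.get(l.chrom)
            if prev is not None and l.start < prev:
                report.warnings.append(f"bed: {l.chrom} not sorted by start")
                break
            by_chrom[l.chrom] = l.start
    if "counts" in loaded and "design" in loaded:
        m: CountMatrix = loaded["counts"]  # type: ignore[assignment]
        d: AssayDesign = loaded["design"]  # type: ignore[assignment]
        missing = set(d.table.index) - set(m.assays)
        for a in sorted(missing):
            report.errors.append(f"design: assay {a!r} absent from counts")
        classes = set(m.probe_info["probe_class"])
        if "negative" not in classes:
            report.errors.append("counts: no negative-control probes")
        if (m.probe_info["probe_class"] == "housekeeping").sum() < 2:
            report.errors.append("counts: fewer than 2 housekeeping probes")
    return report


def convert_xlsx_to_tsv(
    xlsx_path: str | Path, tsv_path: str | Path, sheet: int | str = 0
) -> pd.DataFrame:
    """Thin converter for supplementary XLSX tables → module TSVs."""
    df = pd.read_excel(xlsx_path, sheet_name=sheet)
    df.to_csv(tsv_path, sep="\t", index=False)
    return df
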