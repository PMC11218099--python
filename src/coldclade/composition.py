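"""Per-genome cold-adaptation composition proxies.

Psychrophilic proteomes are depleted in arginine relative to lysine, so
the genome-wide Arg/Lys residue ratio serves as a genetic proxy of cold
adaptation.  GC content is computed genome-wide and partitioned into the
intergenic complement of all annotated genes and the union of annotated
rRNA loci.

Coordinates: GFF3 input is 1-based inclusive; internally every feature
is 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Feature",
    "AnnotatedGenome",
    "CompositionProfile",
    "ProteomeExtraction",
    "extract_proteome",
    "arg_lys_ratio",
    "gc_content",
    "gc_partitioned",
    "composition_profile",
    "read_gff3",
    "write_profiles",
]

# non-feature GFF3 types that describe whole sequences, not genes
_NON_GENE_TYPES = {"region", "source", "chromosome", "contig", "scaffold"}


@dataclass(frozen=True)
class Feature:
    """Annotated interval, 0-based half-open on its contig."""

    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    kind: str  # 'CDS', 'rRNA' or 'other'

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class AnnotatedGenome:
    genome_id: str
    contigs: dict[str, str]
    features: list[Feature]

    def __post_init__(self) -> None:
        self.contigs = {c: s.upper() for c, s in self.contigs.items()}
        for f in self.features:
            if f.contig_id not in self.contigs:
                raise ValueError(f"feature on unknown contig {f.contig_id!r}")
            if f.end > len(self.contigs[f.contig_id]):
                raise ValueError(
                    f"feature [{f.start}, {f.end}) overruns contig "
                    f"{f.contig_id!r} of length {len(self.contigs[f.contig_id])}"
                )

    @classmethod
    def from_files(cls, fasta_path, gff_path, genome_id: str | None = None) -> "AnnotatedGenome":
        fasta_path = Path(fasta_path)
        contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
        if not contigs:
            raise ValueError(f"no sequences in {fasta_path}")
        return cls(
            genome_id=genome_id or fasta_path.stem,
            contigs=contigs,
            features=read_gff3(gff_path),
        )


def read_gff3(path) -> list[Feature]:
    """Read GFF3 features; only seqid, type, start, end, strand are consumed.

    Types other than CDS/rRNA map to 'other'; whole-sequence records
    (region/source/...) are skipped.  GFF3 1-based inclusive coordinates
    are converted to 0-based half-open.
    """
    features: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(f"malformed GFF3 line: {line[:80]!r}")
            seqid, _, ftype, start, end, _, strand = cols[:7]
            if ftype in _NON_GENE_TYPES:
                continue
            if ftype == "CDS":
                kind = "CDS"
            elif ftype.endswith("rRNA") or ftype == "rRNA":
                kind = "rRNA"
            else:
                kind = "other"
            features.append(
                Feature(
                    contig_id=seqid,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand if strand in {"+", "-"} else "+",
                    kind=kind,
                )
            )
    return features


@dataclass
class CompositionProfile:
    """Genome-level composition summary.

    ``gc_rrna`` / ``gc_intergenic`` are NaN when the genome has no
    annotated rRNA / no intergenic sequence; the ratio is pooled over all
    residues of the proteome, not averaged per gene.
    """

    genome_id: str
    arg_count: int
    lys_count: int
    arg_lys_ratio: float
    gc_genome: float
    gc_intergenic: float
    gc_rrna: float


@dataclass
class ProteomeExtraction:
    proteins: list[str]
    n_skipped_not_multiple_of_3: int
    n_internal_stop: int


_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_proteome(genome: AnnotatedGenome, translation_table: int = 11) -> ProteomeExtraction:
    """Translate every annotated CDS with the bacterial code.

    Minus-strand CDS are reverse-complemented first.  A single trailing
    stop is trimmed; internal stops are retained in the protein and
    counted.  CDS whose length is not a multiple of 3 (edge genes on
    draft contigs) are skipped and counted, never silently dropped.
    """
    proteins: list[str] = []
    skipped = 0
    internal = 0
    for f in genome.features:
        if f.kind != "CDS":
            continue
        nt = genome.contigs[f.contig_id][f.start : f.end]
        if f.strand == "-":
            nt = _revcomp(nt)
        if len(nt) % 3 != 0:
            skipped += 1
            continue
        aa = str(Seq(nt).translate(table=translation_table))
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            internal += 1
        proteins.append(aa)
    return ProteomeExtraction(proteins, skipped, internal)


def arg_lys_ratio(proteome: list[str]) -> tuple[int, int, float]:
    """Pooled (arg_count, lys_count, ratio) over all proteins of a genome."""
    if not proteome:
        raise ValueError("empty proteome")
    arg = sum(p.count("R") for p in proteome)
    lys = sum(p.count("K") for p in proteome)
    if lys == 0:
        raise ValueError("undefined ratio: no lysine residues")
    return arg, lys, arg / lys


def _gc_counts(seq: str) -> tuple[int, int]:
    """(gc, total unambiguous) over one sequence; everything but ACGT is ignored."""
    gc = seq.count("G") + seq.count("C")
    total = gc + seq.count("A") + seq.count("T")
    return gc, total


def gc_content(sequence: str) -> float:
    """Percent G+C among unambiguous bases; N (and other ambiguity codes) excluded."""
    gc, total = _gc_counts(sequence.upper())
    if total == 0:
        raise ValueError("no unambiguous bases (denominator 0)")
    return 100.0 * gc / total


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def gc_partitioned(genome: AnnotatedGenome) -> tuple[float, float, float]:
    """(gc_genome, gc_intergenic, gc_rrna) percents.

    Intergenic is the per-contig complement of the union of ALL annotated
    features regardless of strand or kind; rRNA GC is computed over the
    union of rRNA intervals.  Empty partitions come back as NaN.
    """
    gc_all = tot_all = 0
    gc_inter = tot_inter = 0
    gc_rrna = tot_rrna = 0
    by_contig: dict[str, list[Feature]] = {c: [] for c in genome.contigs}
    for f in genome.features:
        by_contig[f.contig_id].append(f)
    for contig_id, seq in genome.contigs.items():
        g, t = _gc_counts(seq)
        gc_all += g
        tot_all += t
        gene_union = _merge_intervals([(f.start, f.end) for f in by_contig[contig_id]])
        pos = 0
        for s, e in gene_union:
            g, t = _gc_counts(seq[pos:s])
            gc_inter += g
            tot_inter += t
            pos = max(pos, e)
        g, t = _gc_counts(seq[pos:])
        gc_inter += g
        tot_inter += t
        for s, e in _merge_intervals(
            [(f.start, f.end) for f in by_contig[contig_id] if f.kind == "rRNA"]
        ):
            g, t = _gc_counts(seq[s:e])
            gc_rrna += g
            tot_rrna += t
    if tot_all == 0:
        raise ValueError("genome has no unambiguous bases")
    return (
        100.0 * gc_all / tot_all,
        100.0 * gc_inter / tot_inter if tot_inter else math.nan,
        100.0 * gc_rrna / tot_rrna if tot_rrna else math.nan,
    )


def composition_profile(genome: AnnotatedGenome, translation_table: int = 11) -> CompositionProfile:
    """Full per-genome profile: pooled Arg/Lys plus partitioned GC."""
    extraction = extract_proteome(genome, translation_table)
    arg, lys, ratio = arg_lys_ratio(extraction.proteins)
    gc_genome, gc_inter, gc_rrna = gc_partitioned(genome)
    return CompositionProfile(
        genome_id=genome.genome_id,
        arg_count=arg,
        lys_count=lys,
        arg_lys_ratio=ratio,
        gc_genome=gc_genome,
        gc_intergenic=gc_inter,
        gc_rrna=gc_rrna,
    )


def write_profiles(profiles: list[CompositionProfile], path) -> None:
    pd.DataFrame(
        [
            {
                "genome_id": p.genome_id,
                "arg_count": p.arg_count,
                "lys_count": p.lys_count,
                "arg_lys_ratio": p.arg_lys_ratio,
                "gc_genome": p.gc_genome,
                "gc_intergenic": p.gc_intergenic,
                "gc_rrna": p.gc_rrna,
            }
            for p in profiles
        ]
    ).to_csv(path, sep="\t", index=False)
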