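"""Genome inclusion filters and AAI-based dereplication.

Assemblies enter the study only if they pass draft-quality thresholds
(contig count, N50, completeness, contamination as estimated by an
external QC tool), and near-identical genomes are collapsed to a single
representative using a pairwise average amino-acid identity (AAI) matrix
produced upstream. Both the metadata and the AAI matrix are *inputs*;
this module never computes completeness or AAI itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GenomeMetadata",
    "AAIMatrix",
    "QCThresholds",
    "compute_n50",
    "filter_genomes",
    "dereplicate_by_aai",
    "read_metadata",
    "write_metadata",
]

#: Removal thresholds: a genome is removed iff it has MORE than
#: ``max_contigs`` contigs, an N50 strictly BELOW ``min_n50``,
#: completeness strictly below ``min_completeness`` or contamination
#: strictly above ``max_contamination``.  Values exactly at a threshold
#: are kept (strict inequalities).
@dataclass(frozen=True)
class QCThresholds:
    max_contigs: int = 300
    min_n50: int = 20_000
    min_completeness: float = 95.0
    max_contamination: float = 5.0


@dataclass
class GenomeMetadata:
    """Per-genome record consumed by the QC filter.

    ``completeness`` and ``contamination`` are percentages (0-100) as
    reported by marker-gene QC tools; ``group_label`` assigns the genome
    to a study group (``polar1``/``polar2``/``polar3``/``nonpolar``/
    ``outgroup``).
    """

    genome_id: str
    n_contigs: int | None = None
    n50: int | None = None
    completeness: float | None = None
    contamination: float | None = None
    isolation_source: str = ""
    group_label: str = "nonpolar"
    contig_lengths: list[int] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.contig_lengths is not None:
            if any(L <= 0 for L in self.contig_lengths):
                raise ValueError(f"{self.genome_id}: contig lengths must be positive")
            if self.n_contigs is None:
                self.n_contigs = len(self.contig_lengths)
            elif self.n_contigs != len(self.contig_lengths):
                raise ValueError(
                    f"{self.genome_id}: n_contigs={self.n_contigs} does not match "
                    f"{len(self.contig_lengths)} contig lengths"
                )
            if self.n50 is None:
                self.n50 = compute_n50(self.contig_lengths)
            elif self.n50 > max(self.contig_lengths):
                raise ValueError(f"{self.genome_id}: n50 exceeds longest contig")
        for name in ("completeness", "contamination"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{self.genome_id}: {name}={v} outside [0, 100]")


def compute_n50(contig_lengths: list[int]) -> int:
    """Contig length at which contigs that long or longer reach half the assembly.

    Scans from the largest contig; the N50 is the length of the contig at
    which the cumulative sum first covers >= 50% of the total assembly.
    """
    if not contig_lengths:
        raise ValueError("no contigs")
    if any(L <= 0 for L in contig_lengths):
        raise ValueError("contig lengths must be positive")
    lengths = sorted(contig_lengths, reverse=True)
    half = sum(lengths) / 2.0
    acc = 0
    for L in lengths:
        acc += L
        if acc >= half:
            return L
    raise AssertionError("unreachable")  # pragma: no cover


_QC_FIELDS = ("n_contigs", "n50", "completeness", "contamination")


def filter_genomes(
    metadata: list[GenomeMetadata],
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[list[GenomeMetadata], list[tuple[GenomeMetadata, list[str]]]]:
    """Partition genomes into (kept, removed-with-reasons).

    A genome is removed iff any strict-inequality criterion fires:
    ``n_contigs > max_contigs``, ``n50 < min_n50``,
    ``completeness < min_completeness`` or
    ``contamination > max_contamination``.  Every failed criterion is
    listed in the reasons.  Boundary values are kept.
    """
    kept: list[GenomeMetadata] = []
    removed: list[tuple[GenomeMetadata, list[str]]] = []
    for m in metadata:
        for f in _QC_FIELDS:
            if getattr(m, f) is None:
                raise ValueError(f"genome {m.genome_id!r}: missing QC field {f!r}")
        reasons = []
        if m.n_contigs > thresholds.max_contigs:
            reasons.append("contigs")
        if m.n50 < thresholds.min_n50:
            reasons.append("n50")
        if m.completeness < thresholds.min_completeness:
            reasons.append("completeness")
        if m.contamination > thresholds.max_contamination:
            reasons.append("contamination")
        if reasons:
            removed.append((m, reasons))
        else:
            kept.append(m)
    return kept, removed


@dataclass
class AAIMatrix:
    """Symmetric pairwise AAI matrix (percent identities, 0-100)."""

    genome_ids: list[str]
    values: np.ndarray

    SYMMETRY_TOL = 1e-6

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genome_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"AAI matrix shape {self.values.shape} does not match "
                f"{n} genome ids"
            )
        if not np.allclose(self.values, self.values.T, atol=self.SYMMETRY_TOL, rtol=0):
            raise ValueError("AAI matrix asymmetric beyond tolerance")
        # absent diagonal treated as self-identity 100
        np.fill_diagonal(self.values, 100.0)

    @classmethod
    def from_tsv(cls, path) -> "AAIMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if list(df.index) != list(df.columns):
            raise ValueError("AAI matrix row and column ids differ")
        return cls(genome_ids=[str(g) for g in df.index], values=df.to_numpy(float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.genome_ids, columns=self.genome_ids).to_csv(
            path, sep="\t"
        )

    def subset(self, ids: list[str]) -> "AAIMatrix":
        idx = [self.genome_ids.index(g) for g in ids]
        return AAIMatrix(list(ids), self.values[np.ix_(idx, idx)])


def dereplicate_by_aai(
    matrix: AAIMatrix,
    metadata: list[GenomeMetadata],
    threshold: float = 99.5,
) -> list[str]:
    """Collapse genomes linked at AAI >= ``threshold`` to one representative each.

    Single-linkage: connected components of the graph whose edges are
    pairs with AAI >= threshold.  The representative of a component is the
    genome with the highest completeness; ties break to the lowest
    contamination, then the lexicographically smallest genome id.
    Idempotent: re-running on the representatives changes nothing.
    """
    meta = {m.genome_id: m for m in metadata}
    missing = [g for g in (m.genome_id for m in metadata) if g not in matrix.genome_ids]
    if missing:
        raise ValueError(f"AAI matrix does not cover genomes: {missing}")
    sub = matrix.subset([m.genome_id for m in metadata])
    adj = sub.values >= threshold
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)

    reps: list[str] = []
    for comp in np.unique(labels):
        members = [sub.genome_ids[i] for i in np.flatnonzero(labels == comp)]
        reps.append(
            min(
                members,
                key=lambda g: (
                    -(meta[g].completeness if meta[g].completeness is not None else 0.0),
                    meta[g].contamination if meta[g].contamination is not None else 100.0,
                    g,
                ),
            )
        )
    return sorted(reps)


def read_metadata(path) -> list[GenomeMetadata]:
    """Read the tab-delimited per-genome metadata table."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str}, comment="#")
    if "genome_id" not in df.columns:
        raise ValueError("metadata TSV must have a genome_id column")
    out = []
    for row in df.to_dict("records"):
        out.append(
            GenomeMetadata(
                genome_id=row["genome_id"],
                n_contigs=int(row["n_contigs"]) if pd.notna(row.get("n_contigs")) else None,
                n50=int(row["n50"]) if pd.notna(row.get("n50")) else None,
                completeness=float(row["completeness"]) if pd.notna(row.get("completeness")) else None,
                contamination=float(row["contamination"]) if pd.notna(row.get("contamination")) else None,
                isolation_source=str(row.get("isolation_source", "") or ""),
                group_label=str(row.get("group_label", "nonpolar") or "nonpolar"),
            )
        )
    return out


def write_metadata(metadata: list[GenomeMetadata], path) -> None:
    pd.DataFrame(
        [
            {
                "genome_id": m.genome_id,
                "n_contigs": m.n_contigs,
                "n50": m.n50,
                "completeness": m.completeness,
                "contamination": m.contamination,
                "isolation_source": m.isolation_source,
                "group_label": m.group_label,
            }
            for m in metadata
        ]
    ).to_csv(path, sep="\t", index=False)
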