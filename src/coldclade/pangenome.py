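"""Pan/core-genome rarefaction, gene categories, and Heaps-law openness.

The pan-genome of a genus is *open* when adding genomes keeps revealing
new gene families.  Openness is diagnosed by fitting a power-law decay

    n_new(N) = kappa * N**(-alpha)

to the median number of genes newly observed (pan) or newly lost from
the running core (core) at the N-th genome over many random genome
orderings; alpha < 1 marks an open pan-genome.  Occupancy bands follow
the usual cloud (< 15% of genomes) / shell (15-95%) / soft core
(95-100%, exclusive of 100) / strict core (100%) convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "PresenceAbsenceMatrix",
    "RarefactionCurve",
    "RarefactionResult",
    "HeapsFit",
    "GeneCategoryBreakdown",
    "categorize_genes",
    "rarefy_pan",
    "rarefy_core",
    "fit_heaps",
    "predict_per_genome_change",
]


@dataclass
class PresenceAbsenceMatrix:
    """Binary genes x genomes occupancy matrix."""

    gene_ids: list[str]
    genome_ids: list[str]
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != (len(self.gene_ids), len(self.genome_ids)):
            raise ValueError("occupancy shape does not match gene/genome ids")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValueError("genome ids not unique")
        if self.occupancy.size and not self.occupancy.any(axis=1).all():
            raise ValueError("matrix contains all-zero gene rows")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PresenceAbsenceMatrix":
        occ = df.to_numpy()
        keep = occ.astype(bool).any(axis=1)
        return cls(
            gene_ids=[str(g) for g, k in zip(df.index, keep) if k],
            genome_ids=[str(c) for c in df.columns],
            occupancy=occ[keep].astype(bool),
        )

    @classmethod
    def from_tsv(cls, path) -> "PresenceAbsenceMatrix":
        """Read either a wide 0/1 matrix or a clustering-tool table.

        Dialect is sniffed: if every cell parses as 0/1 the table is a
        binary matrix; otherwise any non-empty cell marks presence
        (Roary/PEPPAN ``gene_presence_absence`` style, non-genome
        annotation columns such as Annotation/No. isolates dropped).
        """
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False, comment="#")
        as_num = df.apply(pd.to_numeric, errors="coerce")
        if as_num.notna().to_numpy().all() and as_num.isin([0, 1]).to_numpy().all():
            return cls.from_dataframe(as_num.astype(int))
        drop = [c for c in df.columns if c.lower() in {
            "annotation", "gene", "non-unique gene name", "no. isolates", "no. sequences",
        }]
        return cls.from_dataframe((df.drop(columns=drop) != "").astype(int))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.occupancy.astype(int), index=self.gene_ids, columns=self.genome_ids
        ).rename_axis("gene_id").to_csv(path, sep="\t")


@dataclass
class GeneCategoryBreakdown:
    counts: dict[str, int]
    fractions: dict[str, float]
    total: int


def categorize_genes(matrix: PresenceAbsenceMatrix) -> GeneCategoryBreakdown:
    """Cloud / shell / soft-core / strict-core occupancy bands.

    f = fraction of genomes carrying the gene: cloud f < 0.15; shell
    0.15 <= f < 0.95; soft core 0.95 <= f < 1; strict core f == 1.
    """
    f = matrix.occupancy.sum(axis=1) / matrix.n_genomes
    counts = {
        "cloud": int((f < 0.15).sum()),
        "shell": int(((f >= 0.15) & (f < 0.95)).sum()),
        "soft_core": int(((f >= 0.95) & (f < 1.0)).sum()),
        "strict_core": int((f == 1.0).sum()),
    }
    total = matrix.n_genes
    assert sum(counts.values()) == total
    fractions = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return GeneCategoryBreakdown(counts, fractions, total)


@dataclass
class RarefactionCurve:
    n_genomes: np.ndarray  # 1..G
    median_values: np.ndarray
    permutation_count: int
    seed: int | None


@dataclass
class RarefactionResult:
    curve: RarefactionCurve
    step_change_medians: np.ndarray  # new (pan) or lost (core) genes at step N
    per_permutation: np.ndarray  # permutations x G curve values


def _rarefy(
    matrix: PresenceAbsenceMatrix, n_permutations: int, seed, accumulate, exhaustive: bool
) -> RarefactionResult:
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if matrix.n_genomes < 2:
        raise ValueError("need at least 2 genomes")
    G = matrix.n_genomes
    occ = matrix.occupancy
    if exhaustive:
        if G > 8:
            raise ValueError("exhaustive enumeration limited to 8 genomes")
        orders = list(permutations(range(G)))
        n_permutations = len(orders)
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(G) for _ in range(n_permutations)]
    curves = np.empty((n_permutations, G), dtype=np.int64)
    for i, order in enumerate(orders):
        curves[i] = accumulate(occ[:, list(order)], axis=1).sum(axis=0)
    medians = np.median(curves, axis=0)
    steps = np.abs(np.diff(curves, axis=1, prepend=0))
    return RarefactionResult(
        curve=RarefactionCurve(np.arange(1, G + 1), medians, n_permutations, seed),
        step_change_medians=np.median(steps, axis=0),
        per_permutation=curves,
    )


def rarefy_pan(
    matrix: PresenceAbsenceMatrix, n_permutations: int = 1000, seed=None, exhaustive: bool = False
) -> RarefactionResult:
    """Median cumulative pan-genome size and per-step new-gene counts.

    For each seeded random genome order the pan curve is the running
    union of gene sets; medians are taken across permutations (even
    counts average the two central order statistics, per ``np.median``).
    ``exhaustive`` enumerates every order of a small (<= 8) genome set
    instead of sampling.
    """
    return _rarefy(matrix, n_permutations, seed, np.logical_or.accumulate, exhaustive)


def rarefy_core(
    matrix: PresenceAbsenceMatrix, n_permutations: int = 1000, seed=None, exhaustive: bool = False
) -> RarefactionResult:
    """Median running-core size and per-step lost-gene counts (intersection)."""
    return _rarefy(matrix, n_permutations, seed, np.logical_and.accumulate, exhaustive)


@dataclass
class HeapsFit:
    kappa: float
    alpha: float
    alpha_se: float

    @property
    def open(self) -> bool:
        return self.alpha < 1.0


def _power_law(n, kappa, alpha):
    return kappa * np.power(n, -alpha)


def fit_heaps(step_medians, n_values=None) -> HeapsFit:
    """Fit n_new(N) = kappa * N**(-alpha) to per-step median gene changes.

    ``step_medians`` are medians of genes newly gained (pan) or lost
    (core) at genome N; by default they are taken to start at N = 2 (the
    step at N = 1 is the first genome itself, not an accretion).  The fit
    is nonlinear least squares initialised from an ordinary log-log
    regression; points from the first zero median onward are truncated.
    """
    y = np.asarray(step_medians, dtype=float)
    n = (
        np.arange(2, 2 + y.size, dtype=float)
        if n_values is None
        else np.asarray(n_values, dtype=float)
    )
    if n.size != y.size:
        raise ValueError("n_values and step_medians differ in length")
    zero = np.flatnonzero(y <= 0)
    if zero.size:
        n, y = n[: zero[0]], y[: zero[0]]
    if y.size < 3:
        raise ValueError("insufficient signal: fewer than 3 positive points")
    slope, intercept = np.polyfit(np.log(n), np.log(y), 1)
    p0 = (float(np.exp(intercept)), float(-slope))
    # constant relative error: gene counts span decades and their noise is
    # multiplicative, so weight residuals by 1/y
    popt, pcov = curve_fit(_power_law, n, y, p0=p0, sigma=y, maxfev=10_000)
    kappa, alpha = popt
    alpha_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
    return HeapsFit(float(kappa), float(alpha), alpha_se)


def predict_per_genome_change(fit: HeapsFit, n: int) -> float:
    """Expected genes gained (pan) or lost (core) when genome N is added."""
    if n < 1:
        raise ValueError("N must be >= 1")
    return float(fit.kappa * n ** (-fit.alpha))
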