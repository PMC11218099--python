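"""Synthetic study generator with known ground truth.

Every pipeline input can be generated here: annotated genomes whose
codon usage hits a target Arg/Lys ratio and GC content, gene
presence/absence matrices whose accumulation curve behaves like an open
pan-genome, bifurcating species trees with designated monophyletic
clades and neighbour sets, and group-shifted growth-temperature
phenotypes.  All generators are pure functions of their parameters and
seed: the same seed yields byte-identical files.

The default :class:`StudyScenario` mirrors the structure of the real
study set: 1 + 4 + 3 polar genomes in three groups, 75 non-polar
genomes, a two-leaf outgroup, a genetically cold-adapted clade (lower
Arg/Lys and temperatures), and a plastic-only clade (temperatures only,
its clade neighbours sharing its Arg/Lys level).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.optimize import brentq

from .composition import AnnotatedGenome, Feature, _revcomp
from .genome_qc import AAIMatrix, GenomeMetadata, write_metadata
from .pangenome import PresenceAbsenceMatrix
from .phylo import GroupedPhylogeny, read_newick

__all__ = [
    "StudyScenario",
    "SyntheticStudy",
    "codon_distribution",
    "gen_genome",
    "gen_pangenome",
    "gen_phenotypes",
    "gen_tree",
    "simulate_study",
    "write_fasta",
    "write_gff3",
]

_BASES = np.array(list("ACGT"))
_TABLE = CodonTable.unambiguous_dna_by_id[11]
_SENSE = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _TABLE.stop_codons
)
_AA_OF = {c: _TABLE.forward_table[c] for c in _SENSE}


def _gc_frac(codon: str) -> float:
    return (codon.count("G") + codon.count("C")) / 3.0


def _aa_codon_extremes() -> dict[str, tuple[list[str], list[str]]]:
    """Per amino acid, its minimum-GC and maximum-GC synonymous codons."""
    by_aa: dict[str, list[str]] = {}
    for c, aa in _AA_OF.items():
        by_aa.setdefault(aa, []).append(c)
    out = {}
    for aa, codons in by_aa.items():
        gcs = [_gc_frac(c) for c in codons]
        lo, hi = min(gcs), max(gcs)
        out[aa] = (
            [c for c, g in zip(codons, gcs) if g == lo],
            [c for c, g in zip(codons, gcs) if g == hi],
        )
    return out


_EXTREMES = _aa_codon_extremes()
_RK_MASS = 0.10  # combined Arg+Lys residue fraction of the proteome

# high-GC proteomes are Ala/Gly/Pro/Val/Leu-rich; the amino-acid profile
# interpolates from uniform toward these weights as the GC target rises
_GC_RICH_WEIGHTS = {"A": 0.20, "G": 0.18, "P": 0.12, "V": 0.12, "L": 0.10}


def _distribution_at(lam: float, aa_mass: dict[str, float]) -> tuple[list[str], np.ndarray]:
    codons: list[str] = []
    probs: list[float] = []
    for aa, mass in aa_mass.items():
        lo, hi = _EXTREMES[aa]
        for c in lo:
            probs.append(mass * (1 - lam) / len(lo))
            codons.append(c)
        for c in hi:
            w = mass * lam / len(hi)
            if c in lo:  # single-codon amino acids
                probs[codons.index(c)] += w
            else:
                probs.append(w)
                codons.append(c)
    return codons, np.asarray(probs)


def codon_distribution(
    target_arg_lys: float, target_gc_codon_fraction: float, rk_mass: float = _RK_MASS
) -> tuple[list[str], np.ndarray]:
    """Codon sampling distribution hitting an Arg:Lys mass ratio and expected GC.

    Arg and Lys split ``rk_mass`` in the target ratio; one mixing
    parameter simultaneously (a) tilts the remaining amino-acid profile
    from uniform toward a GC-rich Ala/Gly/Pro-heavy composition and (b)
    moves every amino acid from its lowest- toward its highest-GC
    synonymous codons.  Expected GC is monotone in the mixing parameter,
    so the target is solved by bracketed root finding; an unreachable
    target raises with the feasible range.
    """
    if target_arg_lys <= 0:
        raise ValueError("target Arg/Lys ratio must be positive")
    other = sorted(set(_AA_OF.values()) - {"R", "K"})
    p_r = rk_mass * target_arg_lys / (1.0 + target_arg_lys)
    p_k = rk_mass / (1.0 + target_arg_lys)
    other_mass = 1.0 - rk_mass
    uniform = {aa: other_mass / len(other) for aa in other}
    rest = [aa for aa in other if aa not in _GC_RICH_WEIGHTS]
    rich_left = other_mass * (1.0 - sum(_GC_RICH_WEIGHTS.values()))
    rich = {aa: other_mass * _GC_RICH_WEIGHTS.get(aa, 0.0) + (rich_left / len(rest) if aa in rest else 0.0)
            for aa in other}

    def masses_at(lam: float) -> dict[str, float]:
        aa_mass = {aa: (1 - lam) * uniform[aa] + lam * rich[aa] for aa in other}
        aa_mass["R"] = p_r
        aa_mass["K"] = p_k
        return aa_mass

    def expected_gc(lam: float) -> float:
        codons, probs = _distribution_at(lam, masses_at(lam))
        return float(sum(p * _gc_frac(c) for c, p in zip(codons, probs)))

    g_lo, g_hi = expected_gc(0.0), expected_gc(1.0)
    if not g_lo <= target_gc_codon_fraction <= g_hi:
        raise ValueError(
            f"target codon GC {100 * target_gc_codon_fraction:.1f}% infeasible under the "
            f"Arg/Lys constraint; feasible range [{100 * g_lo:.1f}%, {100 * g_hi:.1f}%]"
        )
    if g_hi == g_lo:
        lam = 0.0
    elif expected_gc(0.0) == target_gc_codon_fraction:
        lam = 0.0
    else:
        lam = float(brentq(lambda x: expected_gc(x) - target_gc_codon_fraction, 0.0, 1.0))
    return _distribution_at(lam, masses_at(lam))


def _random_seq(rng: np.random.Generator, length: int, gc_percent: float) -> str:
    g = gc_percent / 200.0
    return "".join(rng.choice(_BASES, size=length, p=[0.5 - g, g, g, 0.5 - g]))


def gen_genome(
    genome_id: str,
    target_arg_lys: float,
    target_gc: float,
    n_genes: int = 100,
    gene_length_codons: int = 150,
    seed: int | None = None,
    intergenic_length: int = 100,
    intergenic_gc: float | None = None,
    n_rrna: int = 1,
    rrna_length: int = 1500,
    rrna_gc: float = 57.0,
) -> AnnotatedGenome:
    """One single-contig genome whose composition hits the given targets.

    ``target_gc`` is the expected genome-wide GC percent: the codon
    distribution is solved so that coding GC compensates exactly for the
    fixed start/stop codons, the intergenic spacers (GC =
    ``intergenic_gc``, defaulting to the target) and the rRNA loci.
    Genes alternate strands; one locus is annotated as rRNA per
    ``n_rrna``.
    """
    if not 0 < target_gc < 100:
        raise ValueError("target_gc must lie in (0, 100)")
    rng = np.random.default_rng(seed)
    if intergenic_gc is None:
        intergenic_gc = target_gc
    n_codons = n_genes * gene_length_codons
    n_spacers = n_genes + n_rrna + 1
    total_len = (
        n_genes * (3 * gene_length_codons + 6)
        + n_rrna * rrna_length
        + n_spacers * intergenic_length
    )
    # expected GC bases from everything that is not a sampled codon
    fixed_gc = (
        n_genes * 1.0  # ATG + TAA contribute one G/C base per gene
        + n_rrna * rrna_length * rrna_gc / 100.0
        + n_spacers * intergenic_length * intergenic_gc / 100.0
    )
    g_codon = (target_gc / 100.0 * total_len - fixed_gc) / (3.0 * n_codons)
    codons, probs = codon_distribution(target_arg_lys, g_codon)
    probs = probs / probs.sum()

    parts: list[str] = []
    features: list[Feature] = []
    pos = 0

    def spacer() -> None:
        nonlocal pos
        s = _random_seq(rng, intergenic_length, intergenic_gc)
        parts.append(s)
        pos += len(s)

    spacer()
    for i in range(n_genes):
        body = "ATG" + "".join(rng.choice(codons, size=gene_length_codons, p=probs)) + "TAA"
        strand = "+" if i % 2 == 0 else "-"
        genomic = body if strand == "+" else _revcomp(body)
        features.append(Feature("contig_1", pos, pos + len(genomic), strand, "CDS"))
        parts.append(genomic)
        pos += len(genomic)
        spacer()
    for _ in range(n_rrna):
        s = _random_seq(rng, rrna_length, rrna_gc)
        features.append(Feature("contig_1", pos, pos + len(s), "+", "rRNA"))
        parts.append(s)
        pos += len(s)
        spacer()
    return AnnotatedGenome(genome_id, {"contig_1": "".join(parts)}, features)


def gen_pangenome(
    n_genomes: int = 50,
    core_size: int = 500,
    n_accessory: int = 5000,
    occupancy_alpha: float = 0.3,
    occupancy_beta: float = 20.0,
    seed: int | None = None,
    genome_ids: list[str] | None = None,
    n_soft_accessory: int = 0,
    soft_alpha: float = 20.0,
    soft_beta: float = 0.5,
) -> PresenceAbsenceMatrix:
    """Presence/absence matrix with a core plus Beta-occupancy accessory pool.

    Each accessory gene's per-genome presence probability is drawn from
    Beta(``occupancy_alpha``, ``occupancy_beta``); the default
    Beta(0.3, 20) concentrates occupancy near zero, which yields the
    heavy cloud fraction and, over study-scale genome counts, the
    power-law new-gene decay with exponent < 1 of an open pan-genome
    (iid occupancy decays as (N + beta)**-(1 + alpha), so the second
    shape parameter sets how long the curve stays in the open regime).  Accessory genes never
    observed are dropped.
    """
    if min(n_genomes, core_size) < 1 or n_accessory < 0:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    if genome_ids is None:
        genome_ids = [f"genome_{i + 1:03d}" for i in range(n_genomes)]
    elif len(genome_ids) != n_genomes:
        raise ValueError("genome_ids length mismatch")
    core = np.ones((core_size, n_genomes), dtype=bool)
    p = rng.beta(occupancy_alpha, occupancy_beta, size=n_accessory)
    acc = rng.random((n_accessory, n_genomes)) < p[:, None]
    blocks = [core, acc[acc.any(axis=1)]]
    if n_soft_accessory:
        q = rng.beta(soft_alpha, soft_beta, size=n_soft_accessory)
        soft = rng.random((n_soft_accessory, n_genomes)) < q[:, None]
        blocks.append(soft[soft.any(axis=1)])
    occ = np.vstack(blocks)
    return PresenceAbsenceMatrix(
        gene_ids=[f"gene_{i + 1:05d}" for i in range(occ.shape[0])],
        genome_ids=list(genome_ids),
        occupancy=occ,
    )


def gen_phenotypes(
    assignment: dict[str, str],
    group_means: dict[str, tuple[float, float, float]],
    sd: float = 2.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Growth-temperature table (t_min/t_opt/t_max, degC) per genome.

    Draws three independent normals around the genome's group means and
    sorts each row so t_min <= t_opt <= t_max always holds.
    """
    for g, (tmin, topt, tmax) in group_means.items():
        if not tmin <= topt <= tmax:
            raise ValueError(f"group {g!r}: means must satisfy t_min <= t_opt <= t_max")
    rng = np.random.default_rng(seed)
    rows = {}
    for genome_id, group in assignment.items():
        draws = np.sort(rng.normal(group_means[group], sd))
        rows[genome_id] = draws
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["t_min", "t_opt", "t_max"])
    df.index.name = "genome_id"
    return df


def _random_join(units: list[str], rng: np.random.Generator) -> str:
    units = list(units)
    while len(units) > 1:
        i, j = rng.choice(len(units), size=2, replace=False)
        a, b = units[i], units[j]
        bl_a, bl_b = rng.uniform(0.02, 0.2, size=2)
        joined = f"({a}:{bl_a:.4f},{b}:{bl_b:.4f})"
        units = [u for k, u in enumerate(units) if k not in (i, j)] + [joined]
    return units[0]


def gen_tree(
    group_leaves: dict[str, list[str]],
    monophyletic_groups: list[str],
    outgroup_ids: list[str],
    seed: int | None = None,
    neighbour_sets: dict[str, list[str]] | None = None,
) -> GroupedPhylogeny:
    """Random bifurcating tree with designated monophyletic clades.

    Each group in ``monophyletic_groups`` becomes a clade; if it has an
    entry in ``neighbour_sets`` those leaves form its sister clade, so
    the group's parent clade contains exactly those neighbours.  The
    outgroup pair attaches at the root.  Leaves in neighbour sets must
    also appear in some group (normally 'nonpolar').
    """
    rng = np.random.default_rng(seed)
    neighbour_sets = neighbour_sets or {}
    placed: set[str] = set()
    units: list[str] = []
    for g in monophyletic_groups:
        leaves = group_leaves[g]
        clade = _random_join(list(leaves), rng)
        placed.update(leaves)
        nbs = neighbour_sets.get(g, [])
        if nbs:
            clade = f"({clade}:0.05,{_random_join(list(nbs), rng)}:0.05)"
            placed.update(nbs)
        units.append(clade)
    free = [
        leaf
        for g, leaves in group_leaves.items()
        for leaf in leaves
        if leaf not in placed and g != "outgroup"
    ]
    ingroup = _random_join(units + free, rng)
    og = _random_join(list(outgroup_ids), rng)
    newick = f"({ingroup}:0.1,{og}:0.3);"
    tree = read_newick(newick, from_string=True)
    tree.is_rooted = True
    groups = {
        leaf: g for g, leaves in group_leaves.items() for leaf in leaves
    }
    for o in outgroup_ids:
        groups[o] = "outgroup"
    return GroupedPhylogeny(tree=tree, groups=groups, outgroup_ids=list(outgroup_ids))


@dataclass
class StudyScenario:
    """Ground-truth parameters of a synthetic study (paper-like defaults).

    Defaults state the world the pipeline is meant to recover: polar2 is
    the genetically cold-adapted clade (Arg/Lys 1.5 vs 2.4 non-polar,
    temperatures shifted -10 degC); polar3 is plastic-only (temperatures
    shifted, Arg/Lys 1.9 shared with its designated clade neighbours so
    the neighbour contrast cancels); polar1 is a lone unshifted isolate.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"polar1": 1, "polar2": 4, "polar3": 3, "nonpolar": 77}
    )
    neighbour_counts: dict[str, int] = field(
        default_factory=lambda: {"polar2": 6, "polar3": 4}
    )
    arg_lys_means: dict[str, float] = field(
        default_factory=lambda: {"polar1": 2.4, "polar2": 1.5, "polar3": 1.9, "nonpolar": 2.4}
    )
    arg_lys_neighbour_means: dict[str, float] = field(default_factory=lambda: {"polar3": 1.9})
    arg_lys_sd: float = 0.25
    gc_means: dict[str, float] = field(
        default_factory=lambda: {"polar1": 67.0, "polar2": 62.0, "polar3": 64.0, "nonpolar": 67.0}
    )
    gc_neighbour_means: dict[str, float] = field(default_factory=lambda: {"polar3": 64.0})
    gc_sd: float = 2.0
    temp_means: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "polar1": (10.0, 30.0, 37.0),
            "polar2": (0.0, 20.0, 27.0),
            "polar3": (0.0, 20.0, 27.0),
            "nonpolar": (10.0, 30.0, 37.0),
        }
    )
    temp_sd: float = 2.0
    core_size: int = 500
    n_accessory: int = 5000
    occupancy_alpha: float = 0.3
    occupancy_beta: float = 20.0
    n_soft_accessory: int = 500
    soft_alpha: float = 20.0
    soft_beta: float = 0.5
    n_genes: int = 60
    gene_length_codons: int = 120
    seed: int = 0

    @classmethod
    def paperlike(cls, seed: int = 0) -> "StudyScenario":
        return cls(seed=seed)


# reaction -> (cycle, prevalence probability); polar2 is forced positive
# for nitrite ammonification, its nitrogen-cycle signature
_TRAIT_SPECS: dict[str, tuple[str, float]] = {
    "organic_carbon_oxidation": ("carbon", 0.95),
    "acetate_oxidation": ("carbon", 0.80),
    "ethanol_fermentation": ("carbon", 0.70),
    "methane_oxidation": ("carbon", 0.08),
    "nitrite_ammonification": ("nitrogen", 0.60),
    "nitrogen_fixation": ("nitrogen", 0.03),
    "sulfite_oxidation": ("sulphur", 0.80),
    "sulfate_reduction": ("sulphur", 0.70),
    "sulfur_oxidation": ("sulphur", 0.10),
    "arsenate_reduction": ("arsenate", 0.80),
    "arsenite_oxidation": ("arsenate", 0.40),
}


@dataclass
class SyntheticStudy:
    scenario: StudyScenario
    metadata: list[GenomeMetadata]
    aai: AAIMatrix
    metrics: pd.DataFrame
    phylogeny: GroupedPhylogeny
    matrix: PresenceAbsenceMatrix
    traits: pd.DataFrame
    trait_cycles: dict[str, str]
    neighbour_ids: dict[str, list[str]]
    genome_targets: dict[str, tuple[float, float]]  # per-genome (arg_lys, gc) means


def simulate_study(scenario: StudyScenario | None = None, seed: int | None = None) -> SyntheticStudy:
    """Draw one full synthetic study from a scenario.

    ``seed`` overrides the scenario seed.  Everything downstream of the
    study — QC, contrasts, rarefaction, classification — can run on the
    returned bundle exactly as on real files.
    """
    sc = scenario or StudyScenario()
    if seed is not None:
        sc = StudyScenario(**{**asdict(sc), "seed": int(seed)})
    rng = np.random.default_rng(sc.seed)

    ids: dict[str, list[str]] = {
        g: [f"{g}_{i + 1:03d}" for i in range(n)] for g, n in sc.group_sizes.items()
    }
    outgroup = ["outgroup_001", "outgroup_002"]
    ingroup = [g for leaves in ids.values() for g in leaves]

    # designate clade neighbours among the non-polar genomes
    pool = list(ids["nonpolar"])
    neighbour_ids: dict[str, list[str]] = {}
    offset = 0
    for g, k in sc.neighbour_counts.items():
        neighbour_ids[g] = pool[offset : offset + k]
        offset += k

    # per-genome composition means (neighbours may share the focal group's)
    targets: dict[str, tuple[float, float]] = {}
    for g, leaves in ids.items():
        for leaf in leaves:
            targets[leaf] = (sc.arg_lys_means[g], sc.gc_means[g])
    for g, nbs in neighbour_ids.items():
        for leaf in nbs:
            targets[leaf] = (
                sc.arg_lys_neighbour_means.get(g, sc.arg_lys_means["nonpolar"]),
                sc.gc_neighbour_means.get(g, sc.gc_means["nonpolar"]),
            )

    assignment = {leaf: g for g, leaves in ids.items() for leaf in leaves}
    metrics = gen_phenotypes(
        assignment, sc.temp_means, sd=sc.temp_sd, seed=int(rng.integers(2**31))
    )
    comp_rng = np.random.default_rng(int(rng.integers(2**31)))
    metrics["arg_lys_ratio"] = [
        comp_rng.normal(targets[g][0], sc.arg_lys_sd) for g in metrics.index
    ]
    metrics["gc_genome"] = [comp_rng.normal(targets[g][1], sc.gc_sd) for g in metrics.index]

    phylogeny = gen_tree(
        ids,
        monophyletic_groups=[g for g in ("polar2", "polar3") if g in ids],
        outgroup_ids=outgroup,
        seed=int(rng.integers(2**31)),
        neighbour_sets=neighbour_ids,
    )

    matrix = gen_pangenome(
        n_genomes=len(ingroup),
        core_size=sc.core_size,
        n_accessory=sc.n_accessory,
        occupancy_alpha=sc.occupancy_alpha,
        occupancy_beta=sc.occupancy_beta,
        seed=int(rng.integers(2**31)),
        genome_ids=ingroup,
        n_soft_accessory=sc.n_soft_accessory,
        soft_alpha=sc.soft_alpha,
        soft_beta=sc.soft_beta,
    )

    meta_rng = np.random.default_rng(int(rng.integers(2**31)))
    metadata = [
        GenomeMetadata(
            genome_id=g,
            n_contigs=int(meta_rng.integers(5, 200)),
            n50=int(meta_rng.integers(50_000, 500_000)),
            completeness=float(np.round(meta_rng.uniform(96.0, 100.0), 2)),
            contamination=float(np.round(meta_rng.uniform(0.0, 2.0), 2)),
            isolation_source="polar" if assignment[g].startswith("polar") else "temperate",
            group_label=assignment[g],
        )
        for g in ingroup
    ]
    n = len(ingroup)
    tri = meta_rng.uniform(56.0, 99.2, size=(n, n))
    aai_vals = np.triu(tri, 1)
    aai_vals = aai_vals + aai_vals.T
    np.fill_diagonal(aai_vals, 100.0)
    aai = AAIMatrix(list(ingroup), aai_vals)

    trait_rng = np.random.default_rng(int(rng.integers(2**31)))
    trait_rows = {}
    for reaction, (_, p) in _TRAIT_SPECS.items():
        row = trait_rng.random(n) < p
        if reaction == "nitrite_ammonification":
            row[[ingroup.index(g) for g in ids["polar2"]]] = True
        trait_rows[reaction] = row
    traits = pd.DataFrame.from_dict(trait_rows, orient="index", columns=ingroup)
    traits.index.name = "reaction"

    return SyntheticStudy(
        scenario=sc,
        metadata=metadata,
        aai=aai,
        metrics=metrics,
        phylogeny=phylogeny,
        matrix=matrix,
        traits=traits,
        trait_cycles={r: c for r, (c, _) in _TRAIT_SPECS.items()},
        neighbour_ids=neighbour_ids,
        genome_targets=targets,
    )


def write_fasta(genome: AnnotatedGenome, path, seed: int | None = None, width: int = 80) -> None:
    with open(path, "w") as fh:
        for contig_id, seq in genome.contigs.items():
            tag = f" seed={seed}" if seed is not None else ""
            fh.write(f">{contig_id} genome={genome.genome_id}{tag}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genome: AnnotatedGenome, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for i, f in enumerate(genome.features):
            ftype = f.kind if f.kind in {"CDS", "rRNA"} else "misc_feature"
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "coldclade_sim",
                        ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if f.kind == "CDS" else ".",
                        f"ID={genome.genome_id}_{i + 1:05d}",
                    ]
                )
                + "\n"
            )


def write_study(study: SyntheticStudy, out_dir, write_sequences: bool = False) -> None:
    """Emit every study file; TSVs carry a '# seed=' header comment."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = study.scenario.seed

    def _tsv(df: pd.DataFrame, name: str, **kwargs) -> None:
        with open(out / name, "w") as fh:
            fh.write(f"# seed={seed}\n")
            df.to_csv(fh, sep="\t", **kwargs)

    write_metadata(study.metadata, out / "metadata.tsv")
    study.aai.to_tsv(out / "aai.tsv")
    _tsv(study.metrics, "metrics.tsv")
    _tsv(
        pd.DataFrame(
            sorted(study.phylogeny.groups.items()), columns=["genome_id", "group_label"]
        ),
        "groups.tsv",
        index=False,
    )
    study.phylogeny.tree.write(path=str(out / "tree.nwk"), schema="newick", unquoted_underscores=True)
    study.matrix.to_tsv(out / "matrix.tsv")
    _tsv(study.traits.astype(int), "traits.tsv")
    (out / "scenario.json").write_text(
        json.dumps(
            {
                "seed": seed,
                "scenario": asdict(study.scenario),
                "neighbour_ids": study.neighbour_ids,
                "trait_cycles": study.trait_cycles,
            },
            indent=2,
        )
    )
    if write_sequences:
        seq_dir = out / "genomes"
        seq_dir.mkdir(exist_ok=True)
        sc = study.scenario
        for i, (genome_id, (ratio, gc)) in enumerate(sorted(study.genome_targets.items())):
            genome = gen_genome(
                genome_id,
                target_arg_lys=ratio,
                target_gc=gc,
                n_genes=sc.n_genes,
                gene_length_codons=sc.gene_length_codons,
                seed=(seed * 100_003 + i) % (2**31),
            )
            write_fasta(genome, seq_dir / f"{genome_id}.fasta", seed=seed)
            write_gff3(genome, seq_dir / f"{genome_id}.gff3", seed=seed)
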