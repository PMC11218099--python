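# Methods

`coldclade` implements a reverse-ecology workflow for deciding whether a
clade of bacterial isolates from cold environments is *genetically*
cold-adapted, merely *plastic* (phenotype shifted without genetic
change), or neither. The design mirrors a genus-scale comparative
survey: a quality-screened, dereplicated set of genomes, a rooted
species tree, growth-temperature phenotypes, a gene presence/absence
matrix from pan-genome clustering, and boolean metabolic trait calls.

## Genome inclusion and dereplication

Draft assemblies are admitted when none of four removal criteria fires:
more than 300 contigs, N50 below 20 kb, completeness below 95%, or
contamination above 5%. All four are strict inequalities — values
exactly at a threshold are kept. N50 is the length of the contig at
which, scanning from the largest, the cumulative length first reaches
half the assembly.

Near-identical genomes are collapsed using a pairwise average
amino-acid identity (AAI) matrix computed upstream: pairs at AAI ≥
99.5% are linked, connected components of that graph (single linkage)
form clusters, and one representative per cluster is retained — highest
completeness, ties broken by lowest contamination, then lexicographic
genome id. The rule is deterministic and idempotent. Completeness,
contamination and AAI are consumed as inputs; computing them is out of
scope.

## Composition proxies

Cold-active proteomes are systematically depleted in arginine relative
to lysine, so the **genome-wide Arg/Lys ratio** — total R residues over
total K residues pooled across every translated CDS — is the genetic
cold-adaptation proxy. Pooling (rather than averaging per-gene ratios)
makes the statistic independent of how the proteome is split into
genes. CDS are extracted from GFF3 annotations (1-based inclusive on
disk, 0-based half-open internally; conversions are tested exactly),
reverse-complemented on the minus strand, and translated with the
bacterial code (table 11). A single trailing stop is trimmed; internal
stops are kept and counted; CDS whose length is not a multiple of 3
(edge genes of draft contigs) are skipped with accounting. A proteome
without lysine makes the ratio undefined and is an error, not a zero.

GC content is reported genome-wide, over the union of annotated rRNA
loci, and over the **intergenic** complement of the union of all
annotated features (any kind, either strand). Ambiguity codes are
excluded from both numerator and denominator; an empty partition is
reported as missing (NaN), never as 0. GC contrasts are computed and
reported but deliberately excluded from the adaptation call: a GC
decrease is an unvalidated cold proxy.

## Tree handling and the dual-baseline contrast design

The species tree is rooted on the branch separating a designated
outgroup (which must form a split of the unrooted tree), the split
branch length being halved across the new root, and then sorted by
*increasing node order*: at every node, children are ordered by
subtree leaf count, ties broken toward the clade containing the
lexicographically smallest label, so the sorted form is unique.

Each focal group is contrasted against two baselines:

1. **all non-polar genomes**, and
2. its **clade neighbours** — starting at the focal group's MRCA, walk
   rootward until the clade holds at least `min_neighbours` (default 1)
   non-focal ingroup leaves; those leaves are the baseline.

The second contrast is the phylogeny-aware control: a composition shift
shared by the whole clade (mere divergence) cancels there. An explicit
neighbour list can override the walk to pin hand-enumerated baselines.
MRCA queries use a side-effect-free postorder scan (the tree library's
own MRCA reroots unrooted trees as a side effect).

## Rank-sum testing

Group comparisons use the Wilcoxon rank-sum (Mann–Whitney U) test with
midranks for ties. For tie-free pooled samples of at most 12
observations the p-value is exact, by enumeration of all C(n1+n2, n1)
rank assignments; otherwise a normal approximation is used with tie
correction, a continuity correction of ½ toward the null mean, and an
Edgeworth kurtosis term (the U null is symmetric but platykurtic, with
excess kurtosis −(6/5)(n1²+n2²+n1n2+n1+n2)/(n1n2(n+1)) in the tie-free
case). Two-sided p is twice the smaller tail, capped at 1. The method
used is recorded in every result. With both sides ≥ 3 the corrected
approximation tracks the exact p within 0.01 at the 12-observation
boundary; more extreme splits are always handled exactly, and no
normal-family tail can track their near-uniform null to that tolerance.
Tests are two-sided; the direction (sign of the median difference) is
reported separately, and "significant" additionally requires the tested
direction (a decrease, for cold adaptation). No multiple-testing
correction is applied by default; a Holm adjustment is available.

## Pan-genome openness

Rarefaction draws seeded uniformly random genome orders (default 1000;
exhaustive enumeration is available for ≤ 8 genomes) and accumulates
the running union (pan) or intersection (core) of gene sets. Medians
across orders are reported per step; an even number of orders averages
the two central order statistics. Openness is diagnosed by fitting

    n_new(N) = κ · N^(−α)

to the median number of genes newly observed (pan) or newly lost from
the running core (core) at the N-th genome, for N ≥ 2. The fit is
nonlinear least squares initialised from an ordinary log–log
regression, with residuals weighted by 1/value (gene counts span
decades and their noise is multiplicative; unweighted least squares
underestimates the exponent's uncertainty). α's standard error comes
from the scaled fit covariance; the pan-genome is called **open** iff
α < 1. Points from the first zero median onward are truncated; fewer
than three positive points is an error ("insufficient signal"). The
fitted law also predicts the expected genes gained/lost when genome N
is added, κ·N^(−α).

Occupancy bands: cloud f < 0.15, shell 0.15 ≤ f < 0.95, soft core
0.95 ≤ f < 1, strict core f = 1, where f is the fraction of genomes
carrying the gene. The conventional printed bands leave [99%, 100%)
unassigned; it is folded into the soft core here so the four fractions
always sum to 1.

## Ecotype classification

Three boolean signals feed a fixed truth table:

- `genotype_vs_all`: significant Arg/Lys *decrease* vs all non-polar;
- `genotype_vs_neighbours`: the same vs clade neighbours;
- `phenotype_vs_all`: growth temperatures shifted down vs non-polar —
  by default a significant t_opt decrease plus at least one of
  t_min/t_max (`topt-plus-one`), a slight relaxation so one noisy
  temperature cannot flip a call; a strict `all` rule is available.

Both genotype signals are required for a genetic call — the neighbour
contrast is exactly what separates adaptation from shared divergence:

| genotype (both) | phenotype | call                 |
|-----------------|-----------|----------------------|
| yes             | yes       | GENETIC_COLD_ADAPTED |
| no              | yes       | PLASTIC_ONLY         |
| —               | no        | NO_COLD_ADAPTATION   |

Any required contrast unavailable (e.g. no clade neighbours found)
yields INSUFFICIENT_DATA. Note that with a focal group of 3 and a
neighbour baseline of 4, the smallest attainable two-sided exact p is
2/35 ≈ 0.057 > 0.05 — such a group can never show a significant
neighbour contrast and is therefore structurally capped at
PLASTIC_ONLY; this is a property of the design, not a bug. In some
published accounts of this kind of analysis the group names attached to
the proposed cold-adapted clade are internally inconsistent between the
summary and the tree figure; this package takes group membership from
the tree/group-table inputs only.

Trait prevalence summarises a boolean reaction × genome table as the
fraction of genomes positive per reaction plus per-group
all/some/none flags, ordered by biogeochemical cycle.

## Synthetic data: the stated world

The generator produces every pipeline input with known ground truth;
all generators are pure functions of their parameters and seed.

**Genomes.** Codons are sampled i.i.d. from a distribution with two
constraints: the Arg:Lys codon mass equals the target ratio (R and K
jointly hold 10% of residue mass, a typical bacterial value), and the
expected genome-wide GC equals the target. A single mixing parameter
simultaneously tilts the remaining amino-acid profile from uniform
toward a GC-rich Ala/Gly/Pro/Val/Leu-heavy composition (as in real
high-GC bacteria) and moves each amino acid from its lowest- toward its
highest-GC synonymous codons; the parameter is solved by bracketed root
finding after compensating for the fixed start/stop codons, the
intergenic spacers and the rRNA loci, so the *genome-wide* expectation
hits the target. Feasible GC spans roughly 31–79%; outside it the
generator raises with the feasible range (e.g. GC 100% is impossible
because lysine forces AT-rich codons). Genes alternate strands; one
rRNA locus (1500 bp, GC 57%) is included by default.

**Presence/absence.** Core genes are present everywhere. Each
accessory gene's per-genome presence probability is drawn from
Beta(0.3, 20) and presence is sampled independently per genome. Under
i.i.d. occupancy the expected new-gene curve is
n_acc·B(a+1, b+N−1)/B(a,b) ∝ (N+b)^−(1+a), so the *asymptotic* decay
exponent is 1+a > 1 regardless of parameters — a finite i.i.d. pool is
always ultimately closed. The second shape parameter b sets how long
the curve stays in the pre-asymptotic, effectively open regime
(effective exponent ≈ (1+a)·N/(N+b)); b = 20 puts the fitted α near
0.45 over a 50-genome study, the regime typical of environmental
genera. A small Beta(0.3, 2) would instead yield α ≈ 1.05–1.08 and a
"closed" verdict — the reason this default was chosen analytically. A
second, high-occupancy component (Beta(20, 0.5), the soft-core shoulder
of real U-shaped occupancy spectra) gives the running core a slow decay
instead of collapsing after a few genomes.

**Phenotypes.** t_min/t_opt/t_max are independent normals around group
means, row-sorted to restore ordering.

**Trees.** Random bifurcating topologies by sequential joining;
requested groups are built as clades, with designated neighbour leaves
as their sister clade; a two-leaf outgroup attaches at the root.

**The paper-like scenario** states the world the pipeline must recover:
85 ingroup genomes in groups polar1 (n=1), polar2 (n=4), polar3 (n=3)
and non-polar (n=77), plus two outgroup leaves. Arg/Lys means 2.4
(non-polar, polar1), 1.5 (polar2 — the genetic cold clade), 1.9
(polar3 *and its four designated clade neighbours*, so the neighbour
contrast cancels); sd 0.25. GC 67/62/64%, sd 2. Growth temperatures
(10, 30, 37) °C for non-polar/polar1 and shifted −10 °C for
polar2/polar3, sd 2 °C. Polar2's six designated neighbours keep
non-polar composition. Nitrite ammonification is forced positive in
all polar2 genomes over a 60% background, with ten further reactions
across the carbon/nitrogen/sulphur/arsenate cycles at fixed
prevalences.

**What the generator does not emulate** — and hence what a green test
does not establish: gene content is independent of the tree (no
phylogenetic autocorrelation of occupancy), composition values are
drawn per genome rather than evolved along branches, phenotypes are
independent across genomes, and sequences have no synteny, operon
structure or codon autocorrelation. The recovery properties certify the
statistical machinery, not robustness to phylogenetic confounding —
which is exactly why the clade-neighbour baseline exists.

## Numerical conventions

- Medians use the mean-of-central-pair convention for even counts.
- Dereplication representative rule and ladderize tie-breaks are total
  orders, so every output is deterministic.
- Random order generation uses a seeded PCG64 generator; seeds are
  recorded in rarefaction results and in every emitted study file.
- AAI matrices must be symmetric within 1e-6; a missing diagonal is
  treated as 100.
- Exact rank-sum enumeration is capped at 12 pooled observations
  (C(12,6) = 924 arrangements); the threshold is recorded per result.

## Known limitations

- The walk-up neighbour rule is one reproducible formalisation of
  "closely related genomes in the same clade"; hand-curated baselines
  should use the override.
- Heaps-law α from a median curve is a summary statistic; its standard
  error reflects fit uncertainty around the median curve, not
  permutation resampling variance.
- No phylogenetically independent contrasts or phylogenetic regression:
  divergence confounding is addressed only through the neighbour
  baseline.
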