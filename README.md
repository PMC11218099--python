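# coldclade

Reverse-ecology detection of genetically cold-adapted clades in
bacterial genera.

Isolates recovered from polar and high-alpine environments are not
necessarily cold-adapted: low temperature also *preserves* cells, and
some lineages survive through phenotypic plasticity — downshifted
growth temperatures without genetic change. `coldclade` is for
microbial comparative genomicists who need to tell these cases apart
across a genus-scale genome collection. It combines:

- **Genome QC and dereplication** — contig count / N50 / completeness /
  contamination filters (removal iff > 300 contigs, N50 < 20 kb,
  completeness < 95% or contamination > 5%) and single-linkage
  collapsing of genomes at AAI ≥ 99.5%.
- **Composition proxies** — the genome-wide Arg/Lys residue ratio
  (cold-active proteomes are Arg-depleted) and GC content partitioned
  into genome-wide / intergenic / rRNA fractions, from FASTA + GFF3.
- **Phylogeny-aware dual-baseline contrasts** — each polar group is
  compared (Wilcoxon rank-sum; exact for small tie-free samples,
  Edgeworth-corrected normal approximation otherwise) against *all*
  non-polar genomes **and** against its clade neighbours in the rooted,
  node-sorted species tree. Only a signal that survives the second,
  phylogeny-aware baseline counts as adaptation rather than divergence.
- **Pan-genome openness** — permutation rarefaction of pan and core
  gene sets and a Heaps-law fit n_new(N) = κ·N^(−α) to the median
  new-gene counts; α < 1 diagnoses an open pan-genome. Occupancy bands
  (cloud < 15%, shell 15–95%, soft core ≥ 95%, strict core = 100%) and
  per-genome gain/loss predictions come with it.
- **Ecotype classification** — genotype (Arg/Lys decrease vs both
  baselines) × phenotype (t_min/t_opt/t_max decrease) truth table:
  GENETIC_COLD_ADAPTED / PLASTIC_ONLY / NO_COLD_ADAPTATION /
  INSUFFICIENT_DATA, plus biogeochemical trait prevalence.
- **A synthetic-data generator** — codon-controlled genomes, Beta-
  occupancy presence/absence matrices, constrained random trees and
  group-shifted phenotypes, all pure functions of a seed, so the whole
  pipeline can be validated against planted ground truth.

See `docs/methods.md` for the model details and design choices.

## Worked example

Generate a paper-like synthetic study (85 ingroup genomes: polar groups
of 1, 4 and 3 isolates, 77 non-polar, two outgroup leaves; a planted
genetic cold clade `polar2` and a plastic-only clade `polar3`) and run
the pipeline:

```bash
coldclade simulate --preset paperlike --seed 5 --out study/ --sequences
coldclade qc --metadata study/metadata.tsv --aai study/aai.tsv --out kept.tsv
coldclade compose --fasta-dir study/genomes --gff-dir study/genomes --out profiles.tsv
coldclade pangenome --matrix study/matrix.tsv --permutations 1000 --seed 17
coldclade classify --metrics study/metrics.tsv --tree study/tree.nwk --groups study/groups.tsv
```

The same flow through the library (seed 1) prints:

```
QC: kept 85 of 85 genomes, 85 after AAI dereplication
composition: sequence-level Arg/Lys polar2 median 1.404 vs non-polar 2.397
pan-genome: 2989 genes over 85 genomes; alpha = 0.667 +/- 0.016 (open); core alpha = 0.872 +/- 0.026
predicted new genes at genome 86: 9.7; core losses: 1.0
polar1: NO_COLD_ADAPTATION (Arg/Lys vs all p=0.8498, vs neighbours p=0.6)
polar2: GENETIC_COLD_ADAPTED (Arg/Lys vs all p=0, vs neighbours p=0.009524)
polar3: PLASTIC_ONLY (Arg/Lys vs all p=0.004692, vs neighbours p=0.6286)
nitrite ammonification: 0.6000 of genomes positive, polar2 flag all
```

Reading this: the planted cold clade (`polar2`, Arg/Lys ≈ 1.4 from its
generated sequences vs ≈ 2.4 in non-polar genomes) is significant
against *both* baselines and is called genetically cold-adapted.
`polar3` is lower than the non-polar background (p ≈ 0.005) but not
lower than its own clade neighbours (p ≈ 0.63) — its background signal
is shared divergence, so with downshifted growth temperatures it is
plastic-only. The accessory-genome spectrum yields an open pan-genome
(α < 1), still revealing ~10 new genes per added genome at N = 86.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on the seeded paper-like
scenario — QC + dereplication, sequence-level composition profiling of
every generated genome, 1000-permutation rarefaction with Heaps-law
fits, dual-baseline contrasts, ecotype calls and trait prevalence —
printing a summary and writing the results JSON.
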