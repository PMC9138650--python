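# phyloepi

Phylo-epigenetic analysis of CpG conservation in multiple sequence
alignments: classify CpG dinucleotide sites by how well they are preserved
across taxa, recode them into binary epigenetic characters, and compare the
rooted UPGMA tree built from all nucleotide differences (**SNP mode**) with
the one built from CpG retention patterns alone (**CpG mode**).

## Why

Methylated CpG dinucleotides decay to TpG by spontaneous deamination of
5-methylcytosine at a transition rate roughly 10–50× above other
transitions, while CpG islands — unmethylated, functionally relevant
promoter CpGs — are protected from this erosion. Which CpGs of a homologous
region each species has kept is therefore an evolutionary signal of its own,
distinct from bulk nucleotide divergence, and potentially sharper between
closely related species. `phyloepi` is aimed at comparative genomicists who
have an alignment of homologous (typically promoter) regions from a handful
of species — for example the tandem KIR gene promoters of the great apes —
and want both tracks of that comparison plus the supporting statistics.

## The method

Given an alignment of N taxa, a dinucleotide site is a pair of adjacent
columns `[i, i+2)`. A CpG site is *preserved* when a strict majority of taxa
show `CG` there (the rule is configurable: `majority`, `any`, or
`reference_taxon:<label>`). Each preserved, gap-free site is recoded per
taxon:

```
character(taxon, site) = 'A'  if the taxon's dinucleotide is exactly CG
                         'T'  otherwise (mutated in ≥1 of the 2 positions)
```

Pairwise dissimilarity is the p-distance, `d(x, y) = #mismatches /
#compared positions`, over all columns (SNP mode) or over the A/T characters
(CpG mode). Trees are built with classical UPGMA: merge the closest clusters
at height d/2, with the merged cluster's distance to others the size-weighted
arithmetic mean — a rooted, ultrametric tree under the molecular-clock
assumption. Divergence statistics accompany the trees: the fraction of
polymorphic columns, and for each dinucleotide type the number of preserved
sites, the altered share of preserved sites, and altered sites as a fraction
of all columns.

A context-dependent simulator (Gillespie event sampling along a known tree,
with the C→T / G→A rates at unprotected CpGs multiplied by a configurable
factor and CpG-rich island layout under control) provides ground-truth data
for validation. See `docs/methods.md` for the full model description and
design rationale.

## Worked example

Simulate a 10 kb five-species great-ape-like dataset with CpG multiplier 25,
then run both tracks:

```bash
phyloepi simulate --length 10000 --seed 42 --out sim
phyloepi stats --input sim/alignment.fasta --out stats
phyloepi tree  --input sim/alignment.fasta --mode snp --out tree_snp
phyloepi tree  --input sim/alignment.fasta --mode cpg --out tree_cpg
```

`stats/stats.json` from this exact run:

```
polymorphic_column_fraction: 0.0668
CG  n_preserved=213  n_variable=129  preserved_variable_fraction=0.606  genome_fraction=0.0129
AG  n_preserved=620  n_variable=53   preserved_variable_fraction=0.085  genome_fraction=0.0053
TG  n_preserved=642  n_variable=79   preserved_variable_fraction=0.123  genome_fraction=0.0079
GG  n_preserved=463  n_variable=47   preserved_variable_fraction=0.102  genome_fraction=0.0047
```

Read: 6.7% of columns are polymorphic in at least one species; 61% of the
213 majority-preserved CpG sites carry at least one change in at least one
species, and those altered CpGs span 1.3% of the alignment — two to three
times the corresponding AG/TG/GG fractions, the CpG-hypermutability
footprint the method keys on. The two trees (`tree_snp/tree.nwk`,
`tree_cpg/tree.nwk`):

```
((((chimp:0.0023,bonobo:0.0023):0.0060,human:0.0082):0.0041,gorilla:0.0123):0.0105,orangutan:0.0229);
((((chimp:0.0258,bonobo:0.0258):0.0786,human:0.1045):0.0387,gorilla:0.1432):0.0522,orangutan:0.1954);
```

Both recover the true simulated topology; branch lengths are in p-distance
units, so the CpG tree is "longer" — its characters mutate much faster. Each
output directory contains a `manifest.json` (tool version, parameters,
SHA-256 of inputs) sufficient to reproduce the run.

The same operations are available as a library
(`read_alignment`, `scan_dinuc_sites`, `dinuc_divergence_stats`,
`recode_cpg_matrix`, `p_distance_matrix`, `upgma`, `evolve_along_tree`, …).

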