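# Methods

## The problem and the approach

Vertebrate DNA methylation happens at CpG dinucleotides, and methylated CpGs
are hypermutable: spontaneous hydrolytic deamination of 5-methylcytosine turns
CpG into TpG at a transition rate one to two orders of magnitude (roughly
10–50×) above other transitions. CpG islands — CpG-rich promoter regions that
stay unmethylated — are exempt from this erosion. Functionally relevant,
protected CpGs therefore evolve on their own clock, and comparing *which*
CpGs of a homologous region remain intact across closely related species
("phylo-epigenetics") is a source of phylogenetic signal distinct from bulk
nucleotide divergence.

`phyloepi` implements that comparison as a two-track pipeline on an input
multiple sequence alignment:

1. **SNP mode** — p-distances over all alignment columns, then UPGMA.
2. **CpG mode** — scan for CpG sites preserved across taxa, recode each
   (taxon, site) to a binary character (`A` = CpG intact, `T` = mutated in at
   least one of the two positions), p-distances over those characters, then
   UPGMA.

plus the divergence statistics that motivate the contrast (share of
polymorphic columns; per dinucleotide type, the altered share of preserved
sites and the altered sites as a fraction of all columns), and a simulator of
CpG-hypermutable sequence evolution that supplies ground truth for testing.

## Site scanning and classification

A dinucleotide site is an ordered pair of adjacent columns `[i, i+2)`
(0-based, half-open). A site *belongs to* a type (CG, AG, TG, GG, or any of
the 16) under a configurable preservation rule:

- `majority` (default): a strict majority of taxa show the dinucleotide.
  "Largely preserved across taxa" has no unique formalisation; majority is
  symmetric in the taxa and robust to a single divergent lineage, which is
  why it is the default rather than `any` or a designated reference taxon.
- `reference_taxon:<label>`: that taxon shows it.
- `any`: at least one taxon shows it.

Classification of a reported site: `gapped` if any taxon has `-` or `N` in
either column; `conserved_all` if every taxon shows the type;
`preserved_variable` otherwise (≥1 taxon deviates in ≥1 of the two
positions — counted once per site regardless of how many taxa or positions
deviate). The enum also carries `not_preserved` for sites that fail the
preservation rule; the scanner never reports such sites, so the value only
appears when classifying arbitrary column pairs directly.

Denominators, stated explicitly because published percentages are sensitive
to them:

- `polymorphic_column_fraction` = columns with ≥2 distinct non-gap states,
  over **all** columns ( `-` and `N` are not states).
- `genome_fraction` = preserved-variable **sites** (column pairs) over **all
  columns**. One could also argue for 2×sites/columns; sites/columns is the
  conservative choice and is used throughout.
- Sites containing a gap or `N` in any taxon are excluded from every
  numerator and from the preserved-site count, but columns stay in the
  denominators.
- Only the written (plus) strand is scanned. CpG is strand-symmetric, but
  promoter sequence is analysed as written.

## Binary recoding

Each admitted CpG site contributes one character per taxon: `A` iff the
taxon's dinucleotide is exactly `CG`, else `T`. The assignment is per taxon,
not per site: a per-site global A/T would give every taxon the identical
string and an uninformative star tree, so only the per-taxon reading yields a
CpG tree that can differ from the SNP tree. Constant all-`A` columns are kept
by default (`include_constant=True`): they dilute every pairwise p-distance
by the same factor and cannot change an average-linkage topology, only the
height scale; `include_constant=False` is available for a variable-sites-only
matrix. Because all sites live in one shared alignment coordinate frame, the
recoded characters are positionally homologous by construction and no
realignment step is needed (realigning identical-coordinate strings is a
no-op).

## Distances and trees

The dissimilarity is the p-distance (proportion of mismatching positions);
no multiple-hit correction is applied, since the tree method assumes a clock
and the intended regime is closely related taxa at small divergence. With
`ignore_gaps` (default), positions where either sequence has `-`/`N` are
excluded from numerator and denominator of that pair; a pair left with zero
comparable positions is an error rather than a silent 0.

UPGMA is the classical size-weighted form: merge the closest pair at height
d/2; the merged cluster's distance to any other is the arithmetic mean of
member distances weighted by cluster sizes (equivalently, the unweighted mean
over all leaf pairs — the test suite exploits this equivalence as an
independent oracle). Ties in the closest-pair search are broken by the
smallest pair of cluster positions in label order, so runs are exactly
reproducible; UPGMA (average linkage) is monotone, so merge heights never
invert. Output trees are rooted (the clock assumption places the root at the
last merge), ultrametric to 1e-9, and serialised as rooted Newick with branch
lengths (`parent height − child height`). Heights are in p-distance units; no
claim is made that they match any published figure's scale.

## The simulator

Purpose: generate gap-free leaf alignments with full ground truth (true tree,
root sequence, per-substitution log) under exactly the mechanism the tool is
meant to detect.

**Per-site process.** K80-style: each base leaves at total rate `base_rate`
per unit branch length, split between one transition (weight `ti_tv_ratio`,
default 2) and two transversions (weight 1 each). Branch lengths are thus in
expected-substitutions-per-site units at non-CpG sites, and `base_rate`
defaults to 1.

**CpG hypermutability.** Wherever the *current* sequence has a CpG outside a
protected island, the C→T rate at the C and the G→A rate at the paired G are
multiplied by `cpg_multiplier` (default 25, the midpoint of the reported
10–50 range, which the simulator treats as a free parameter). Deamination is
applied strand-symmetrically (C→T on the written strand, G→A at the paired
G); protection of a pair is read at the position of its C. "Methylated" is
operationalised as "CpG outside a protected island"; per-site methylation
states are not modelled further.

**Event sampling.** Because substitutions create and destroy CpG context at
their neighbours, rates change mid-branch; a site-independent
matrix-exponential scheme cannot express this. Each branch is therefore
simulated by Gillespie event sampling: exponential waiting times at the
current total rate, site chosen proportionally to its rate via a Fenwick
(binary indexed) tree (O(log L) sample and update), and the three affected
sites (the substituted one and both neighbours) re-rated after every event.
All randomness flows from the single `SimConfig.seed` through one generator
in a deterministic preorder traversal, so identical configs give
byte-identical bundles.

**Root sequences.** CpG density is controlled by planting: scanning left to
right, a `CG` is planted with probability d/(1−d) (d = local target density,
inside vs outside the island intervals), which makes the expected CpG-start
frequency per column equal d; other positions are filled uniformly, excluding
`G` directly after a `C` so no accidental CpGs arise. Densities above 0.5 are
geometrically infeasible (a CpG occupies two columns) and are rejected. The
fill exclusion biases base composition slightly around planted CpGs, so for
null experiments that compare CG against other dinucleotide types on equal
footing, `SimConfig.root_sequence` accepts an explicit i.i.d. uniform root —
under a uniform root and multiplier 1 all 16 dinucleotide types are
exchangeable and the null holds exactly by symmetry.

**Islands.** `make_island_spec` lays out evenly spaced, non-overlapping
intervals and marks the first `round(protected_fraction × n)` protected;
`SubstitutionModel.protected_fraction` feeds that builder, while the per-site
process reads protection off the explicit intervals.

**Presets.** `five_taxon_primate_tree(scale=1)` is a clock tree over human,
chimp, bonobo, gorilla and orangutan with merge heights 0.0015 / 0.006 /
0.008 / 0.016 in p-distance units — the implied human–chimp leaf-to-leaf
distance of ~1.2% matches whole-genome divergence estimates for that pair.
`three_taxon_caterpillar(h1, h2)` gives ((A,B),C) with chosen heights.

## What the simulations do and do not show

Simulated alignments are gap-free, homogeneous outside the CpG effect, and
born aligned — there is no aligner error, no indels, no selection, no rate
heterogeneity beyond CpG context, and no recombination. Passing the
end-to-end tests therefore demonstrates that the pipeline correctly extracts
the signal its model generates; it does not validate robustness to alignment
artefacts or non-clock evolution in real data. The tool consumes pre-aligned
input and deliberately does not implement alignment, homology search, or
sequence retrieval.

## Experiment sizes and calibration checks

Chosen once as realistic desk-scale study conditions; all are exercised by
the test suite and the acceptance script:

- Null calibration: multiplier 1, i.i.d. uniform 10 kb roots, 10 replicates
  on the great-ape tree; pooled CG vs AG/TG/GG preserved-variable counts
  compared by two-proportion z-tests at α = 0.01.
- Signal: multiplier 25, 10 kb, 10 islands × 200 bp (density 0.10 in / 0.01
  out, unprotected — modelling methylated promoter islands), 50 replicates;
  CG's altered share of preserved sites must exceed AG/TG/GG's in ≥95% of
  replicates.
- Rate calibration: on a two-taxon tree at 100 kb, C→T events per ancestral
  CpG-C opportunity vs per non-CpG C must sit within ±30% of the configured
  multiplier.
- Topology recovery: `five_taxon_primate_tree(scale=3)` (merge-height gaps
  well above p-distance sampling noise at 10 kb), 100 replicates; the
  SNP-mode pipeline must return the true rooted topology in ≥95.
- UPGMA: equivalence with a brute-force all-leaf-pairs agglomerator on 200
  tie-free random matrices (n ≤ 8), exact recovery on ultrametric inputs, and
  cophenetic-distance identity with scipy's average linkage.

## Numerical choices and degenerate inputs

- Tie-break in UPGMA: smallest (i, j) cluster-position pair; an all-zero
  matrix yields a deterministic left-to-right caterpillar at height 0.
- Ultrametricity asserted to 1e-9; Newick branch lengths printed with a
  configurable number of decimals (default 6).
- Empty recoded matrices (no preserved CpG sites) are flagged
  (`EpiMatrix.is_degenerate`) and refused by the tree pipeline with a clear
  error instead of producing a meaningless star tree.
- Ambiguity codes other than `N`, and the gap character `.`, are rejected at
  read time; silent coercion could fabricate or destroy CpG calls.
- Fractions over empty preserved-site sets are defined as 0.

## Known limitations

- The preservation rule and both denominator conventions are parameters, not
  discoveries; published percentages computed under different conventions
  can differ by up to a factor of 2 on the genome fraction.
- p-distance with no correction saturates for deep divergences; the method
  targets closely related taxa.
- UPGMA inherits the molecular-clock assumption; rate variation across
  lineages will distort topologies in either mode.
- CpG-mode trees rest on far fewer characters than SNP-mode trees (hundreds
  of sites rather than the whole alignment), so their topologies are noisier
  at equal sequence length.
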