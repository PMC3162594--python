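# Methods

This note records the statistical conventions, algorithmic choices and
synthetic-data design behind `gclandscape`, including the places where
the design was genuinely open and what the package chose.

## Coordinates and region classes

All internal coordinates are 0-based half-open; conversion to/from
1-based inclusive GenBank locations happens only in `io`. Features that
cross the origin of a circular genome are split into two sub-intervals
on ingest and rejoined for sequence extraction.

Every genome position is assigned to exactly one of five classes.
Overlapping annotations are resolved by the precedence
`protein_coding > structural_rna > intron > unclassified_orf >
intergenic`; coding assignment must win for the coding/intergenic GC
split to be well defined. A CDS whose gene name matches `^orf` (or
whose product is "hypothetical" with no gene name), and any CDS nested
entirely within an annotated intron, is treated as an *unclassified
ORF*: it claims no coding territory beyond what the intron precedence
allows, never enters the gene inventory, and contributes no codon
sites. The noncoding fraction is `1 − (protein_coding +
structural_rna)/L`, so introns and unclassified ORFs count as
noncoding. Introns are their own class and are excluded from
"intergenic"; a report option exists to pool them if a different
convention is needed.

## GC statistics

GC content is `(#G+#C)/(#A+#C+#G+#T)`; N and other ambiguity codes are
excluded from numerator and denominator (the treatment of ambiguous
bases in published tables is rarely stated; excluding them keeps the
weighted-mean identity `GC_total = Σ len_c · GC_c / Σ len_c` exact when
no ambiguity codes are present). An empty effective denominator yields
an undefined marker (`None`), never zero. GC skew is `(G−C)/(G+C)` on
the deposited strand; its sign depends on the arbitrary strand choice,
so cross-study comparisons should use `|skew|`.

Codon-position GC pools all protein-coding genes into one concatenate
(single GC1/GC2/GC3 values per genome, making site counts well
defined) rather than averaging per-gene values. Phase is counted in
translation order across exon junctions, along the reverse complement
for minus-strand genes. Terminal stop codons are excluded by default
(`include_stop` flips this; published tables rarely state the
convention, and the difference is ≤0.1 percentage points at organelle
scale). A CDS whose length is not a multiple of 3 contributes up to its
last complete codon, with a warning. Since GC is strand-symmetric,
residues are read off the forward strand.

"Coding" GC pools protein_coding + structural_rna; "structural RNA"
pools rRNA + tRNA (one number per genome). A protein-only variant is
available by reading the partition directly.

Amino-acid composition translates every complete codon of every
protein-coding feature with the standard genetic code; stops are
excluded and an internal stop is warned about and skipped.

## Repeat discovery

A maximal pair is two identical substrings (forward) or exact
reverse-complements (inverted) that cannot be extended one position
left or right. Discovery is seed-and-extend over a k-mer index with
k = `min_len`: any maximal pair of length ≥ k contains a shared k-mer
at an aligned offset, so extending every shared seed and deduplicating
the extended coordinates enumerates the maximal pair set exactly.
Correctness is defined by — and tested against — an independent
brute-force oracle that scans every diagonal of the comparison matrix.
`min_len ≥ 8` is enforced to guard against quadratic blowup on trivial
seeds; the default `min_len = 20` matches the shortest repeats of
interest in organelle genomes, and the cross-genome default of 30
suppresses chance matches between ~65-kb and ~176-kb genomes (expected
chance count ≪ 1).

Conventions worth noting:

* A perfect hairpin (a segment equal to its own reverse complement) is
  a single interval, not two copies, and is not reported as an inverted
  pair. Chance 20-nt hairpins arise at ~4⁻¹⁰ per center and would
  otherwise contaminate exact-recovery comparisons.
* Circular genomes are analysed as the linearized sequence plus a
  300-nt wrap extension (comfortably above the longest repeats seen in
  these genomes); hits are mapped back modulo L, a copy matching its
  own wrap image is discarded, and a hit truncated by the extension
  boundary is dropped in favour of the longer image of the same pair.
  Repeats longer than the wrap extension would be reported truncated.
* Distinct maximal inverted pairs can share start coordinates with
  different lengths (palindromic centers differ); hits are therefore
  keyed by coordinates *and* length.
* Pairs lying wholly inside homopolymer/dinucleotide runs longer than
  50 nt are flagged `low_complexity`, not removed.

Repeat coverage is the union of all copy intervals divided by genome
length. Shared-segment summaries count merged match intervals per
genome (`n_sites`), honouring circular adjacency, and the union length
in genome A (`total_shared_nt`).

## Supermatrix assembly and column filtering

Gene selection keeps an alignment when it has sequence for ≥ 70% (the
default threshold) of the reference taxa. Concatenation joins each
taxon's per-gene rows in order with all-gap blocks for missing genes.

The column filter follows the stringent conserved-block settings: no
gapped columns; conserved and flank thresholds both default to
`floor(T/2)+1` sequences ("50% of the number of taxa plus one", read as
strict majority); at most 10 contiguous non-conserved positions within
a block; minimum block length 8. Blocks are found by a single greedy
left-to-right scan — gapped columns and over-long non-conserved runs
break blocks, block ends are trimmed to flank-qualified columns, and
short blocks are dropped. This is the simplest reading consistent with
the four quoted settings; replicating any particular published
program's multi-pass heuristics is explicitly not attempted. Ties for
the most frequent residue resolve to the larger count, and gaps never
count toward conservation. With the default thresholds the filter is
idempotent.

## Rooting and fast-taxon removal

`root_on_clade` first canonicalizes the tree to its unrooted shape
(collapsing a basal bifurcation, whose two half-edges represent one
edge), finds the edge whose leaf-split isolates the requested clade,
and places the root at its midpoint (the split fraction is a
parameter). The offset shifts every root-to-tip distance uniformly, so
the distance *ranking* — the procedure's actual product — is
offset-invariant, and the canonicalization is what makes re-rooting on
the same clade idempotent. Rooting never changes leaf-pair path
lengths.

Root-to-tip distances are branch-length sums from the root; ties break
alphabetically for determinism. Removal takes either an explicit name
list or the top-k of the ranking with an optional exemption list (the
"all but the slowest representative" pattern). Pruning suppresses the
resulting degree-2 nodes with branch lengths summed, so survivor
pairwise path lengths are unchanged.

## Synthetic data

The generator plans the entire genome — gene layout, spacer sizes,
repeat placements — before drawing a single residue, then synthesizes
each region class by **exact-count sampling**: a class of n sites with
GC target g receives exactly `round(g·n)` G/C residues (G/C split by
the skew target), shuffled by the seeded stream. Realized class GC
therefore equals the design to rounding rather than to binomial noise,
which is what makes tight recovery tolerances meaningful. Codon pools
are built per strand the same way (strand-aware skew), with stop
codons repaired by third-position swaps that preserve pool counts, and
pool budgets offset for the fixed ATG starts so the *measured*
GC1/GC2/GC3 land on target. The intergenic background budget is reduced
by the GC the planted repeats carry, and its skew boosted to cover the
skew-neutral planted copies, so whole-class and whole-genome targets
hold with repeats included.

Planted repeat copies receive deliberately mismatched flanking bases
(distinct per copy, in the source-sense upstream/downstream
directions), pinning every maximal pair to exactly the planted
coordinates — never a chance-extended version. This caps a shared
element at 4 total copies across a genome pair. Shared elements can be
planted at several sites per genome to reproduce controlled site
geometries (e.g. 5 sites in one genome, 11 in the other).

The default "study condition" specs (`organelle_study_specs`) encode a
GC-rich organelle genome pair: 65.4-kb mitochondrial genome (53.2% GC
total, GC1/GC2/GC3 = 51.4/40.8/59.8, intergenic 55.7, structural RNA
52.5, skew 0.015, 52% noncoding, 59 genes, five introns) and a
175.7-kb plastid genome (50.7% GC, 56.1/43.6/50.1, intergenic 51, skew
0.008, 56% noncoding, 115 genes, one intron), each with ~7% of its
length in 65%-GC direct/inverted repeats of 20–250 nt and with 500 nt
of repeat sequence shared across the pair at 5 + 11 sites. Where a
component value is not independently published (gene-kind splits, ORF
and intron sizes, the plastid structural-RNA/ORF/intron GC), it was set
once so that the class-weighted mean reproduces the published
aggregate values, and not revisited.

Trees come from a seeded birth–death sampler; pendant edges are floored
at 1% of tree depth (the sampler can emit zero-length pendants at the
stopping event, on which a rate multiplier could not act) and then
scaled by per-taxon rate multipliers. Gene alignments are
presence/absence scaffolds with uniform random residues: sufficient for
occupancy, concatenation and selection logic, but carrying **no
evolutionary signal** — so passing tests demonstrate the bookkeeping
and procedure rules, not phylogenetic accuracy, and the column filter
applied to these scaffolds retains nothing (as it should).

What the generator does not emulate: substitution processes along the
tree, codon-usage bias beyond positional GC, intron splice structure,
gene-order conservation, and sequencing error. Conclusions about real
genomes should rest on the statistics' definitions, which are exact,
not on the generator's realism.

## Problem sizes and numerical notes

Tests run the full pipeline on the 65.4-kb + 175.7-kb study pair, 20
seeded 30-kb recovery genomes, 200 random sequences (two alphabet
sizes) against the brute-force repeat oracle, and 50-taxon random trees
against a path-sum distance oracle (agreement to 1e−9); the whole
suite completes in well under a minute. Percentages are reported to
three decimals in TSV output; undefined statistics (empty site or
class sets) propagate as empty fields rather than zeros. All generator
randomness flows from a single integer seed per call; identical seeds
give byte-identical GenBank/Newick/TSV outputs.
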