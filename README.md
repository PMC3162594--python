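# gclandscape

Nucleotide-landscape and phylogenomic analysis for organelle genomes,
built around the unusual case of GC-rich mitochondrial and plastid DNA
in trebouxiophyte green algae. Most organelle genomes are strongly
AT-biased; a genome pair in which *both* compartments exceed 50% GC
invites a set of questions this package answers quantitatively:

* how GC is distributed across region classes — protein-coding,
  structural RNA (rRNA + tRNA), introns, unclassified ORFs, intergenic —
  and across codon positions (GC1/GC2/GC3, with GC3 and intergenic GC
  the least functionally constrained);
* whether the strands are compositionally symmetric
  (GC skew = (G−C)/(G+C));
* how much of each genome consists of repeated sequence — maximal exact
  direct and inverted (palindromic) repeat pairs — and whether repeat
  elements are shared between the mitochondrial and plastid genomes;
* how to assemble concatenated phylogenomic supermatrices (gene
  selection at a taxon-occupancy threshold, all-gap padding,
  Gblocks-style conserved-block column filtering) and prune
  fast-evolving taxa by root-to-tip distance to guard against
  long-branch attraction.

It is aimed at researchers doing comparative organelle genomics who
want these statistics reproducibly from annotated GenBank records, plus
a seeded synthetic-genome generator so every stage is testable without
downloads.

## Core definitions

For a sequence with unambiguous base counts `#A, #C, #G, #T`:

```
GC   = (#G + #C) / (#A + #C + #G + #T)        (ambiguity codes excluded)
skew = (#G − #C) / (#G + #C)                  (sign is strand-dependent)
```

GC1/GC2/GC3 pool all protein-coding genes into one concatenate and
evaluate GC at each within-codon phase, counted along the reverse
complement for minus-strand genes; terminal stop codons are excluded by
default. Overlapping annotations are resolved with precedence
protein_coding > structural_rna > intron > unclassified_orf >
intergenic, and the noncoding fraction counts introns and unclassified
ORFs as noncoding. A *maximal repeat pair* is two identical (forward)
or reverse-complementary (inverted) substrings that cannot be extended
in either direction; discovery is seed-and-extend over a k-mer index,
with circular genomes analysed through a wrap extension. Root-to-tip
distance is the branch-length sum from a root — placed at the midpoint
of the edge subtending a designated outgroup clade — to a leaf.

## Worked example

Generate the default synthetic organelle genome pair and characterize
its landscape:

```
$ gclandscape simulate --seed 3 --out-dir sim
$ gclandscape landscape sim/SYNMT.gb --out-dir mt_out
$ gclandscape repeats sim/SYNMT.gb --shared-with sim/SYNPT.gb --out mt.tsv
20 repeat pairs -> mt.tsv
shared: 5 sites in A, 11 in B, 500 nt -> mt.shared.tsv
```

`mt_out/landscape.tsv` contains one row per genome; for the
mitochondrial genome above (values in percent except length and skew):

```
genome_id  length_kb  gc_total_pct  gc1_pct  gc2_pct  gc3_pct  gc_coding_pct  gc_intergenic_pct  gc_structural_rna_pct  gc_skew  noncoding_pct  n_genes  repeat_pct
SYNMT      65.4       53.188        51.402   40.798   59.801   51.027         55.701             52.507                 0.015    52.002         59       6.804
```

Read: a 65.4-kb genome at 53.2% GC overall, with intergenic regions
(55.7%) and third codon positions (59.8%) more GC-rich than the
constrained first/second codon positions and structural-RNA genes —
the signature of a genome-wide force pushing composition toward GC —
near-zero strand asymmetry (skew 0.015), 59 genes, and ~7% of the
genome in GC-rich repeats, ~500 nt of which recur in the companion
plastid genome at 5 mitochondrial / 11 plastid sites.

Supermatrix assembly and fast-taxon pruning:

```
$ gclandscape supermatrix sim/g*.faa --taxa T01,...,T15 --out sm.phy
$ gclandscape prune sim/tree.nwk --outgroup T01,T02 --drop-k 3 --out pruned.nwk
```

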