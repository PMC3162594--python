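"""Nucleotide-landscape statistics: GC by region class and codon position,
GC skew, noncoding fraction, and amino-acid composition.

Conventions
-----------
* GC content = (#G + #C) / (#A + #C + #G + #T). N and other ambiguity
  codes are excluded from numerator and denominator; an empty effective
  denominator yields ``None`` (undefined), never 0.
* GC skew = (G − C) / (G + C) on the given strand. The sign depends on
  the arbitrary strand choice of the deposited sequence, so comparisons
  against published values should use the absolute value.
* "Coding" pools the protein_coding and structural_rna classes;
  "noncoding" is everything else (introns and unclassified ORFs count as
  noncoding). Codon-position GC pools all genes into one concatenate
  rather than averaging per-gene values.
"""

from __future__ import annotations

import warnings
from collections import Counter

from Bio.Data.CodonTable import standard_dna_table

from .model import (CodonSiteSets, GenomeRecord, LandscapeReport,
                    RegionPartition, ValidationError)
from .regions import _intron_spans, effective_kind, gene_inventory


def gc_fraction(seq: str) -> float | None:
    g = seq.count("G")
    c = seq.count("C")
    denom = g + c + seq.count("A") + seq.count("T")
    return (g + c) / denom if denom else None


def gc_skew(seq: str) -> float | None:
    g = seq.count("G")
    c = seq.count("C")
    return (g - c) / (g + c) if g + c else None


def codon_position_gc(record: GenomeRecord, sites: CodonSiteSets
                      ) -> tuple[float | None, float | None, float | None]:
    """GC at first/second/third codon positions. GC is strand-symmetric,
    so residues are read off the forward strand regardless of gene strand.
    """
    seq = record.sequence
    out = []
    for site_set in (sites.pos1, sites.pos2, sites.pos3):
        out.append(gc_fraction("".join(seq[p] for p in site_set)))
    return tuple(out)


def _pct(x: float | None) -> float | None:
    return None if x is None else 100.0 * x


def landscape_report(record: GenomeRecord, partition: RegionPartition,
                     sites: CodonSiteSets | None,
                     repeat_pct: float | None = None) -> LandscapeReport:
    """Fill one landscape row (the per-genome length/GC/skew/noncoding
    summary) from a record, its partition and its codon site sets."""
    if partition.genome_id != record.id or partition.length != record.length:
        raise ValidationError("partition does not belong to this record")
    gc1 = gc2 = gc3 = None
    if sites is not None:
        gc1, gc2, gc3 = codon_position_gc(record, sites)
    coding_seq = (partition.class_sequence(record, "protein_coding")
                  + partition.class_sequence(record, "structural_rna"))
    coding_len = (partition.class_length("protein_coding")
                  + partition.class_length("structural_rna"))
    noncoding_pct = (100.0 * (1.0 - coding_len / record.length)
                     if record.length else 100.0)
    inv = gene_inventory(record)
    return LandscapeReport(
        genome_id=record.id,
        length_kb=record.length / 1000.0,
        gc_total_pct=_pct(gc_fraction(record.sequence)),
        gc1_pct=_pct(gc1), gc2_pct=_pct(gc2), gc3_pct=_pct(gc3),
        gc_coding_pct=_pct(gc_fraction(coding_seq)),
        gc_intergenic_pct=_pct(gc_fraction(
            partition.class_sequence(record, "intergenic"))),
        gc_structural_rna_pct=_pct(gc_fraction(
            partition.class_sequence(record, "structural_rna"))),
        gc_skew=gc_skew(record.sequence),
        noncoding_pct=noncoding_pct,
        n_genes=inv.n_total,
        repeat_pct=repeat_pct,
    )


def amino_acid_composition(record: GenomeRecord) -> dict[str, float]:
    """Amino-acid frequencies over every complete codon of every
    protein-coding gene, translated with the standard genetic code.
    Stop codons are excluded; an internal stop is warned about and
    skipped. Frequencies sum to 1.
    """
    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    introns = _intron_spans(record)
    counts: Counter[str] = Counter()
    n_cds = 0
    for f in record.features:
        if effective_kind(f, introns) != "protein_coding":
            continue
        n_cds += 1
        cds = record.feature_sequence(f)
        codons = [cds[i:i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
        for i, codon in enumerate(codons):
            if codon in stops:
                if i < len(codons) - 1:
                    warnings.warn(
                        f"{record.id}:{f.gene_name or '?'}: internal stop "
                        f"codon at codon {i + 1}", stacklevel=2)
                continue
            aa = table.get(codon)
            if aa is not None:  # skip codons containing ambiguity codes
                counts[aa] += 1
    if n_cds == 0:
        raise ValidationError(f"{record.id}: no protein-coding features")
    total = sum(counts.values())
    return {aa: n / total for aa, n in sorted(counts.items())}
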