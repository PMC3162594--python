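"""Region partitioning, codon-position site sets, and gene inventories.

Every genome position is assigned to exactly one of five classes —
protein_coding, structural_rna, intron, unclassified_orf, intergenic —
with overlap precedence protein_coding > structural_rna > intron >
unclassified_orf > intergenic, so the coding/intergenic split underlying
all per-class GC statistics is well defined. An ORF nested entirely
within an annotated intron is treated as an unclassified (hence
noncoding) ORF regardless of how it was annotated.
"""

from __future__ import annotations

import warnings

import numpy as np

from .model import (CodonSiteSets, Feature, GeneInventory, GenomeRecord,
                    RegionPartition, ValidationError)

# paint order: later paint wins, so list ascends in precedence
_PAINT_ORDER = ("unclassified_orf", "intron", "structural_rna",
                "protein_coding")
_CLASS_CODE = {"intergenic": 0, "unclassified_orf": 1, "intron": 2,
               "structural_rna": 3, "protein_coding": 4}
_CODE_CLASS = {v: k for k, v in _CLASS_CODE.items()}

STOP_CODONS = {"TAA", "TAG", "TGA"}


def effective_kind(feature: Feature, intron_spans: list[tuple[int, int]]
                   ) -> str:
    """Feature kind after the intronic-ORF reclassification rule."""
    kind = feature.kind
    if kind == "protein_coding":
        lo = min(s for s, _ in feature.exons)
        hi = max(e for _, e in feature.exons)
        for s, e in intron_spans:
            if s <= lo and hi <= e:
                return "unclassified_orf"
    return kind


def _intron_spans(record: GenomeRecord) -> list[tuple[int, int]]:
    return [iv for f in record.features if f.kind == "intron"
            for iv in f.exons]


def _region_class_of(feature_kind: str) -> str | None:
    if feature_kind == "protein_coding":
        return "protein_coding"
    if feature_kind in ("rRNA", "tRNA"):
        return "structural_rna"
    if feature_kind == "intron":
        return "intron"
    if feature_kind == "unclassified_orf":
        return "unclassified_orf"
    return None  # 'other' features do not claim territory


def partition_genome(record: GenomeRecord) -> RegionPartition:
    record.validate()
    codes = np.zeros(record.length, dtype=np.int8)  # 0 = intergenic
    introns = _intron_spans(record)
    by_class: dict[str, list[tuple[int, int]]] = {c: [] for c in _PAINT_ORDER}
    for f in record.features:
        cls = _region_class_of(effective_kind(f, introns))
        if cls is None:
            continue
        for s, e in f.exons:
            if not (0 <= s < e <= record.length):
                raise ValidationError(
                    f"{record.id}: exon [{s},{e}) outside genome")
            by_class[cls].append((s, e))
    for cls in _PAINT_ORDER:  # ascending precedence; later paint wins
        for s, e in by_class[cls]:
            codes[s:e] = _CLASS_CODE[cls]
    intervals: dict[str, list[tuple[int, int]]] = {}
    if record.length:
        breaks = np.flatnonzero(np.diff(codes)) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [record.length]))
        for s, e in zip(starts, ends):
            intervals.setdefault(_CODE_CLASS[int(codes[s])], []).append(
                (int(s), int(e)))
    part = RegionPartition(genome_id=record.id, length=record.length,
                           intervals=intervals)
    part.validate()
    return part


def codon_position_sites(record: GenomeRecord,
                         include_stop: bool = False) -> CodonSiteSets:
    """Assign each coding position its within-codon phase, pooled over all
    protein-coding genes; phase is counted along the reverse complement for
    minus-strand genes. The terminal stop codon is excluded by default; a
    CDS whose length is not a multiple of 3 contributes up to its last
    complete codon (with a warning).
    """
    introns = _intron_spans(record)
    sets: tuple[set[int], set[int], set[int]] = (set(), set(), set())
    n_genes = 0
    for f in record.features:
        if effective_kind(f, introns) != "protein_coding":
            continue
        positions = f.genomic_positions()
        if len(positions) % 3 != 0:
            warnings.warn(
                f"{record.id}:{f.gene_name or '?'}: CDS length "
                f"{len(positions)} not divisible by 3; truncating",
                stacklevel=2)
            positions = positions[: len(positions) - len(positions) % 3]
        if not positions:
            continue
        if not include_stop and len(positions) >= 3:
            # positions are in translation order; minus-strand bases are
            # read as their complements
            codon = "".join(record.sequence[p] if f.strand == "+" else
                            _COMP.get(record.sequence[p], "N")
                            for p in positions[-3:])
            if codon in STOP_CODONS:
                positions = positions[:-3]
        n_genes += 1
        for i, p in enumerate(positions):
            sets[i % 3].add(p)
    if n_genes == 0:
        raise ValidationError(f"{record.id}: no protein-coding features")
    return CodonSiteSets(pos1=sets[0], pos2=sets[1], pos3=sets[2],
                         source_gene_count=n_genes)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def gene_inventory(record: GenomeRecord, dedupe: bool = False
                   ) -> GeneInventory:
    """Count protein-, rRNA- and tRNA-coding genes. Unclassified ORFs and
    introns never count. By default every feature instance counts
    (duplicate tRNA isoacceptors count once per copy); dedupe collapses
    identical (kind, name) pairs.
    """
    introns = _intron_spans(record)
    counted: dict[str, int] = {"protein_coding": 0, "rRNA": 0, "tRNA": 0}
    names: list[str] = []
    seen: set[tuple[str, str]] = set()
    for f in record.features:
        kind = effective_kind(f, introns)
        if kind not in counted:
            continue
        if dedupe:
            key = (kind, f.gene_name)
            if key in seen:
                continue
            seen.add(key)
        counted[kind] += 1
        names.append(f.gene_name or f"unnamed_{kind}")
    return GeneInventory(n_protein=counted["protein_coding"],
                         n_rrna=counted["rRNA"], n_trna=counted["tRNA"],
                         names=names)
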