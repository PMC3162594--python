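"""Readers and writers for the formats the pipeline touches.

GenBank and FASTA parsing is delegated to Biopython; Newick to dendropy.
This module owns only the mapping into the package's data model:
1-based inclusive source coordinates become 0-based half-open,
``complement`` becomes strand '-', ``join`` becomes multi-exon features,
and features crossing the origin of a circular record are split.
"""

from __future__ import annotations

import re

from Bio import SeqIO

from .model import (Feature, GenomeRecord, RegionPartition, ValidationError,
                    merge_intervals)
from .tree import PhyloTree

# GenBank feature keys we ingest, and the model kind they map to.
_KIND_MAP = {
    "CDS": "protein_coding",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "intron": "intron",
}

_ORF_RE = re.compile(r"^orf", re.IGNORECASE)


class ParseError(ValueError):
    pass


def _classify_cds(gene: str, product: str) -> str:
    """Unnamed ORFs and hypothetical products count as unclassified ORFs."""
    if gene and not _ORF_RE.match(gene):
        return "protein_coding"
    if _ORF_RE.match(gene) or _ORF_RE.match(product) \
            or "hypothetical" in product.lower():
        return "unclassified_orf"
    return "protein_coding"


def _feature_from_seqfeature(sf, length: int, circular: bool) -> Feature | None:
    kind = _KIND_MAP.get(sf.type)
    if kind is None:
        return None
    quals = {k: v[0] for k, v in sf.qualifiers.items() if v}
    gene = quals.get("gene", "") or quals.get("locus_tag", "")
    if sf.type == "CDS":
        kind = _classify_cds(quals.get("gene", ""), quals.get("product", ""))
    strand = "-" if sf.location.strand == -1 else "+"
    parts = sf.location.parts
    if strand == "-":
        # Biopython lists minus-strand parts in translation order;
        # normalize to genomic order (translation handled by Feature).
        parts = sorted(parts, key=lambda p: int(p.start))
    exons: list[tuple[int, int]] = []
    wraps = False
    for part in parts:
        s, e = int(part.start), int(part.end)
        if e > length:
            if not circular:
                raise ValidationError(
                    f"feature {gene or sf.type} exceeds linear record end")
            # origin-crossing span: split into tail + head pieces
            exons.append((s, length))
            exons.append((0, e - length))
            wraps = True
        else:
            exons.append((s, e))
    if not wraps and circular and len(exons) >= 2:
        # join(tail..L, 1..head) encodes an origin-crossing gene
        starts = [s for s, _ in exons]
        if strand == "+" and starts != sorted(starts) \
                and exons[-1][1] <= exons[0][0]:
            wraps = True
    return Feature(kind=kind, gene_name=gene, strand=strand, exons=exons,
                   qualifiers=quals, wraps_origin=wraps)


def read_genome_record(path, fmt: str = "genbank") -> GenomeRecord:
    """Read one GenBank or FASTA record into a validated GenomeRecord."""
    if fmt not in ("genbank", "fasta"):
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        seqrec = next(SeqIO.parse(str(path), fmt))
    except StopIteration:
        raise ParseError(f"{path}: no records found") from None
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    seq = str(seqrec.seq).upper()
    circular = seqrec.annotations.get("topology", "") == "circular"
    features: list[Feature] = []
    if fmt == "genbank":
        for sf in seqrec.features:
            feat = _feature_from_seqfeature(sf, len(seq), circular)
            if feat is not None:
                features.append(feat)
    record = GenomeRecord(id=seqrec.id, sequence=seq, circular=circular,
                          features=features)
    record.validate()
    return record


def read_newick(path) -> PhyloTree:
    """Read a Newick tree; every non-root edge must carry a branch length."""
    return PhyloTree.from_newick_file(str(path))


def write_region_table(partition: RegionPartition, path) -> None:
    """Write a partition as BED (0-based half-open), one line per maximal
    same-class run, sorted by start."""
    partition.validate()
    lines = []
    for cls, ivs in partition.intervals.items():
        for s, e in merge_intervals(ivs):
            lines.append((s, e, cls))
    lines.sort()
    with open(path, "w") as fh:
        for s, e, cls in lines:
            fh.write(f"{partition.genome_id}\t{s}\t{e}\t{cls}\n")


def read_region_table(path) -> RegionPartition:
    """Inverse of write_region_table."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    genome_id, length = "", 0
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                gid, s, e, cls = line.split("\t")
                s, e = int(s), int(e)
            except ValueError:
                raise ParseError(f"{path}:{i}: malformed BED line") from None
            genome_id = gid
            intervals.setdefault(cls, []).append((s, e))
            length = max(length, e)
    part = RegionPartition(genome_id=genome_id, length=length,
                           intervals={c: merge_intervals(v)
                                      for c, v in intervals.items()})
    part.validate()
    return part


def to_genbank_location(feature: Feature, length: int) -> str:
    """Render a feature back to a 1-based inclusive GenBank location string
    (the inverse of ingest, used for round-trip checks and GenBank output)."""
    if feature.wraps_origin and len(feature.exons) == 2 \
            and feature.exons[0][1] == length and feature.exons[1][0] == 0:
        (s1, _), (_, e2) = feature.exons
        inner = f"join({s1 + 1}..{length},1..{e2})"
    else:
        pieces = [f"{s + 1}..{e}" for s, e in feature.exons]
        inner = pieces[0] if len(pieces) == 1 else f"join({','.join(pieces)})"
    return f"complement({inner})" if feature.strand == "-" else inner
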