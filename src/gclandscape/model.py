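"""Shared data model for organelle-genome landscape analysis.

Coordinates are 0-based half-open everywhere inside the package;
conversion to/from 1-based inclusive GenBank coordinates happens only at
the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

# IUPAC nucleotide alphabet (uppercase). Statistics only ever count
# unambiguous A/C/G/T; other codes are kept verbatim in the sequence.
IUPAC_NT = set("ACGTNRYSWKMBDHV")
UNAMBIGUOUS = set("ACGT")

FEATURE_KINDS = (
    "protein_coding",
    "rRNA",
    "tRNA",
    "intron",
    "unclassified_orf",
    "other",
)

REGION_CLASSES = (
    "protein_coding",
    "structural_rna",
    "intron",
    "unclassified_orf",
    "intergenic",
)

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """An object violates a data-model invariant."""


@dataclass
class Feature:
    """One annotated genome feature.

    ``exons`` is an ordered list of half-open ``(start, end)`` intervals in
    translation order for the feature's own strand reading; a feature that
    crosses the origin of a circular genome is stored as two sub-intervals.
    """

    kind: str
    gene_name: str = ""
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    qualifiers: dict[str, str] = field(default_factory=dict)
    wraps_origin: bool = False

    def validate(self, genome_length: int) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValidationError("feature has no exons")
        for s, e in self.exons:
            if not (0 <= s < e <= genome_length):
                raise ValidationError(
                    f"exon [{s},{e}) outside [0,{genome_length})")

    @property
    def span(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genomic_positions(self) -> list[int]:
        """Genomic indices of every exon base, in translation order."""
        if self.strand == "+":
            return [p for s, e in self.exons for p in range(s, e)]
        # minus strand: read exons and bases in reverse
        return [p for s, e in reversed(self.exons)
                for p in range(e - 1, s - 1, -1)]


@dataclass
class GenomeRecord:
    """One annotated nucleotide sequence (the unit of every computation)."""

    id: str
    sequence: str
    circular: bool = False
    features: list[Feature] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        bad = set(self.sequence) - IUPAC_NT
        if bad:
            raise ValidationError(
                f"{self.id}: residues outside IUPAC alphabet: {sorted(bad)}")
        for f in self.features:
            f.validate(self.length)
            if f.kind == "protein_coding" and f.span % 3 != 0:
                warnings.warn(
                    f"{self.id}:{f.gene_name or '?'}: CDS length {f.span} "
                    "not divisible by 3", stacklevel=2)

    def feature_sequence(self, feature: Feature) -> str:
        """Spliced feature sequence on the feature's own strand."""
        joined = "".join(self.sequence[s:e] for s, e in feature.exons)
        return revcomp(joined) if feature.strand == "-" else joined


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class RegionPartition:
    """Mutually exclusive, exhaustive assignment of positions to classes.

    ``intervals`` maps each region class to a sorted list of disjoint
    half-open intervals; their union covers [0, length) exactly.
    """

    genome_id: str
    length: int
    intervals: dict[str, list[tuple[int, int]]]

    def validate(self) -> None:
        covered = 0
        all_iv = []
        for cls, ivs in self.intervals.items():
            if cls not in REGION_CLASSES:
                raise ValidationError(f"unknown region class {cls!r}")
            covered += sum(e - s for s, e in ivs)
            all_iv.extend(ivs)
        if covered != self.length:
            raise ValidationError(
                f"partition covers {covered} of {self.length} positions")
        merged = merge_intervals(all_iv)
        if merged != [(0, self.length)] and self.length > 0:
            raise ValidationError("partition classes overlap or leave gaps")

    def class_length(self, cls: str) -> int:
        return sum(e - s for s, e in self.intervals.get(cls, []))

    def class_sequence(self, record: GenomeRecord, cls: str) -> str:
        return "".join(record.sequence[s:e]
                       for s, e in self.intervals.get(cls, []))


@dataclass
class CodonSiteSets:
    """Genomic site indices at codon phases 1/2/3, pooled over all CDSs."""

    pos1: set[int]
    pos2: set[int]
    pos3: set[int]
    source_gene_count: int = 0


@dataclass
class GeneInventory:
    n_protein: int
    n_rrna: int
    n_trna: int
    names: list[str] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return self.n_protein + self.n_rrna + self.n_trna


@dataclass
class LandscapeReport:
    """Computed per-genome landscape row (lengths in kb, GC in percent)."""

    genome_id: str
    length_kb: float
    gc_total_pct: float | None
    gc1_pct: float | None
    gc2_pct: float | None
    gc3_pct: float | None
    gc_coding_pct: float | None
    gc_intergenic_pct: float | None
    gc_structural_rna_pct: float | None
    gc_skew: float | None
    noncoding_pct: float
    n_genes: int
    repeat_pct: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class RepeatHit:
    """One maximal repeated pair within a genome."""

    orientation: str          # "forward" | "inverted"
    pos_a: int
    pos_b: int
    length: int
    gc_pct: float | None = None
    low_complexity: bool = False


@dataclass(frozen=True)
class SharedSegment:
    """One maximal exact segment present in two genomes."""

    pos_in_a: int
    pos_in_b: int
    length: int
    orientation: str


@dataclass
class SharedSummary:
    n_sites_a: int
    n_sites_b: int
    total_shared_nt: int


@dataclass
class GeneAlignment:
    """One per-gene amino-acid alignment (gap character '-')."""

    gene_name: str
    taxa: list[str]
    rows: list[str]

    def validate(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError(f"{self.gene_name}: duplicate taxa")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise ValidationError(f"{self.gene_name}: ragged rows")
        if len(self.taxa) != len(self.rows):
            raise ValidationError(f"{self.gene_name}: taxa/rows mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row_for(self, taxon: str) -> str | None:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            return None


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: list[str]
    gene_boundaries: list[tuple[str, int, int]]  # (gene, start_col, end_col)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def occupancy(self) -> dict[str, float]:
        n = self.n_columns
        return {t: (1.0 - r.count("-") / n) if n else 0.0
                for t, r in zip(self.taxa, self.rows)}

    def validate(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValidationError("ragged supermatrix rows")
        total = sum(e - s for _, s, e in self.gene_boundaries)
        if self.rows and total != self.n_columns:
            raise ValidationError("gene boundaries do not tile the matrix")
        prev = 0
        for _, s, e in self.gene_boundaries:
            if s != prev or e < s:
                raise ValidationError("gene boundaries unordered or gapped")
            prev = e
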