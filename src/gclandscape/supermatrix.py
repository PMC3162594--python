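"""Phylogenomic supermatrix assembly.

Three steps: gene selection by taxon occupancy (a gene is kept when it
has sequence for at least a threshold fraction — default 70% — of the
reference taxa), concatenation with all-gap padding for missing taxa,
and a conserved-block column filter in the style of Gblocks with the
stated stringent settings: no gapped columns, conserved/flank majority
thresholds of floor(T/2)+1 sequences, at most 10 contiguous
non-conserved positions inside a block, and a minimum block length
of 8 columns.
"""

from __future__ import annotations

from collections import Counter

from .model import GeneAlignment, Supermatrix, ValidationError

GAP = "-"


def default_majority(n_taxa: int) -> int:
    """'50% of the number of taxa plus one', read as floor(T/2)+1."""
    return n_taxa // 2 + 1


def select_genes(alignments: list[GeneAlignment], taxa: list[str],
                 threshold: float = 0.7) -> list[GeneAlignment]:
    """Keep genes present in at least ``threshold`` of the reference taxa."""
    if not taxa:
        raise ValueError("reference taxon list is empty")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    selected = []
    for aln in alignments:
        aln.validate()
        present = sum(1 for t in taxa if aln.row_for(t) is not None)
        if present / len(taxa) >= threshold:
            selected.append(aln)
    return selected


def concatenate(selected: list[GeneAlignment], taxa: list[str]
                ) -> Supermatrix:
    """Join each taxon's per-gene rows in order, padding missing genes
    with all-gap blocks."""
    if not selected:
        raise ValueError("no gene alignments to concatenate")
    for aln in selected:
        aln.validate()
        if len(set(aln.taxa)) != len(aln.taxa):
            raise ValidationError(
                f"{aln.gene_name}: duplicate sequences for one taxon")
    rows = {t: [] for t in taxa}
    boundaries = []
    col = 0
    for aln in selected:
        w = aln.n_columns
        for t in taxa:
            row = aln.row_for(t)
            rows[t].append(row if row is not None else GAP * w)
        boundaries.append((aln.gene_name, col, col + w))
        col += w
    sm = Supermatrix(taxa=list(taxa),
                     rows=["".join(rows[t]) for t in taxa],
                     gene_boundaries=boundaries)
    sm.validate()
    return sm


def _column_stats(matrix: Supermatrix, c: int) -> tuple[bool, int]:
    """(has_gap, count of the most frequent non-gap residue) for column c.
    Ties for the most frequent residue resolve to the larger count, and
    gaps never count toward conservation."""
    col = [r[c] for r in matrix.rows]
    counts = Counter(ch for ch in col if ch != GAP)
    return (GAP in col, max(counts.values()) if counts else 0)


def filter_columns(matrix: Supermatrix, min_conserved: int | None = None,
                   min_flank: int | None = None, max_noncon: int = 10,
                   min_block: int = 8, allow_gaps: bool = False
                   ) -> Supermatrix:
    """Retain columns forming conserved blocks.

    Blocks are scanned greedily left to right: gapped columns (when gaps
    are disallowed) and runs of more than ``max_noncon`` consecutive
    non-conserved columns break blocks; each block is trimmed at both
    ends to columns meeting the flank threshold; blocks shorter than
    ``min_block`` are dropped. Column order is preserved and gene
    boundaries are remapped onto the retained columns.
    """
    n_taxa = len(matrix.taxa)
    if min_conserved is None:
        min_conserved = default_majority(n_taxa)
    if min_flank is None:
        min_flank = default_majority(n_taxa)
    if min_conserved > n_taxa or min_flank > n_taxa:
        raise ValueError("majority thresholds exceed the taxon count")
    ncol = matrix.n_columns
    stats = [_column_stats(matrix, c) for c in range(ncol)]
    usable = [not (has_gap and not allow_gaps) for has_gap, _ in stats]
    conserved = [top >= min_conserved for _, top in stats]
    flank_ok = [top >= min_flank for _, top in stats]

    kept: list[int] = []
    # segments of consecutive usable columns
    c = 0
    while c < ncol:
        if not usable[c]:
            c += 1
            continue
        seg_start = c
        while c < ncol and usable[c]:
            c += 1
        segment = list(range(seg_start, c))
        # break the segment at runs of > max_noncon non-conserved columns
        blocks: list[list[int]] = []
        cur: list[int] = []
        run = 0
        for idx in segment:
            if conserved[idx]:
                run = 0
                cur.append(idx)
            else:
                run += 1
                cur.append(idx)
                if run > max_noncon:
                    # the whole offending run is discarded
                    blocks.append(cur[:-run])
                    cur, run = [], 0
                    # consume the rest of this non-conserved run
                    continue
        blocks.append(cur)
        for block in blocks:
            # trim both ends to flank-qualified columns
            while block and not flank_ok[block[0]]:
                block.pop(0)
            while block and not flank_ok[block[-1]]:
                block.pop()
            if len(block) >= min_block:
                kept.extend(block)

    kept.sort()
    new_rows = ["".join(r[c] for c in kept) for r in matrix.rows]
    # remap gene boundaries onto retained columns
    new_bounds = []
    pos = 0
    for gene, s, e in matrix.gene_boundaries:
        width = sum(1 for c in kept if s <= c < e)
        new_bounds.append((gene, pos, pos + width))
        pos += width
    out = Supermatrix(taxa=list(matrix.taxa), rows=new_rows,
                      gene_boundaries=new_bounds)
    out.validate()
    return out


def write_phylip(matrix: Supermatrix, path) -> None:
    """Relaxed PHYLIP output."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.taxa)} {matrix.n_columns}\n")
        for t, r in zip(matrix.taxa, matrix.rows):
            fh.write(f"{t}  {r}\n")


def write_fasta_alignment(aln: GeneAlignment, path) -> None:
    with open(path, "w") as fh:
        for t, r in zip(aln.taxa, aln.rows):
            fh.write(f">{t}\n{r}\n")


def read_fasta_alignment(path, gene_name: str | None = None) -> GeneAlignment:
    taxa, rows = [], []
    cur = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                taxa.append(line[1:].split()[0])
                rows.append([])
                cur = rows[-1]
            elif line:
                if cur is None:
                    raise ValidationError(f"{path}: sequence before header")
                cur.append(line)
    import os
    name = gene_name or os.path.splitext(os.path.basename(str(path)))[0]
    aln = GeneAlignment(gene_name=name, taxa=taxa,
                        rows=["".join(r) for r in rows])
    aln.validate()
    return aln
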