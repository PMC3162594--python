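"""Seeded synthetic-genome and synthetic-phylogeny generators.

The generators emit inputs with the statistical structure the analysis
stages assume — circular annotated genomes with genes on both strands,
introns, unclassified ORFs, designed per-region-class GC and codon-position
GC, planted direct/inverted repeats (optionally shared between a genome
pair), and trees with controlled root-to-tip heterogeneity plus
gene-alignment sets with controlled taxon occupancy — together with
machine-readable truth tables.

Design notes
------------
* Everything is planned before any residue is drawn: gene layout, spacer
  sizes and repeat placements are fixed first, and each region class is
  then synthesized by exact-count sampling (a class of n sites with GC
  target g receives exactly round(g*n) G/C residues, shuffled), so the
  realized class GC equals the design to rounding rather than to binomial
  noise. Codon-position pools are built the same way, with stop codons
  repaired by third-position swaps that preserve the pool counts.
* Planted repeat copies get deliberately mismatched flanking bases so the
  maximal repeated pair is exactly the planted segment — never a
  chance-extended version of it.
* One pseudo-random stream per generator call, fully determined by the
  seed; no global state.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .model import (Feature, GeneAlignment, GenomeRecord, RepeatHit,
                    SharedSegment, revcomp)
from .tree import PhyloTree

STOPS = ("TAA", "TAG", "TGA")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# specs and truth tables

@dataclass
class RepeatSpec:
    length: int
    orientation: str = "forward"   # "forward" | "inverted"
    gc: float = 0.65


@dataclass
class SharedSpec:
    """One repeat element shared between a genome pair; it is planted at
    ``copies_a`` sites in genome A and ``copies_b`` sites in genome B
    (total copies <= 4 so flank mismatching can keep every pair maximal
    at exactly the planted coordinates)."""
    length: int
    orientation: str = "forward"   # orientation of the B copies vs A
    gc: float = 0.65
    copies_a: int = 1
    copies_b: int = 1


@dataclass
class GenomeSpec:
    genome_id: str
    length: int
    seed: int
    circular: bool = True
    n_protein: int = 20
    n_rrna: int = 2
    n_trna: int = 15
    n_orfs: int = 4
    n_introns: int = 2
    noncoding_fraction: float = 0.5
    gc1: float = 0.50
    gc2: float = 0.42
    gc3: float = 0.55
    gc_structural_rna: float = 0.52
    gc_intron: float = 0.48
    gc_orf: float = 0.50
    gc_intergenic: float = 0.54    # target for the whole intergenic class,
                                   # planted repeats included
    gc_skew: float = 0.0
    repeats: list[RepeatSpec] = field(default_factory=list)

    def validate(self) -> None:
        for g in (self.gc1, self.gc2, self.gc3, self.gc_structural_rna,
                  self.gc_intron, self.gc_orf, self.gc_intergenic):
            if not (0.0 < g < 1.0):
                raise ValueError("GC targets must be in (0,1)")
        for r in self.repeats:
            if r.length > self.length // 4:
                raise ValueError("planted repeat longer than length/4")


@dataclass
class GenomeTruth:
    genome_id: str
    length: int
    gc_total: float
    gc_by_class: dict[str, float | None]
    gc1: float
    gc2: float
    gc3: float
    gc_skew: float
    noncoding_fraction: float
    n_protein: int
    n_rrna: int
    n_trna: int
    repeats: list[RepeatHit]
    repeat_coverage: float


@dataclass
class PairTruth:
    a: GenomeTruth
    b: GenomeTruth
    shared: list[SharedSegment]
    n_sites_a: int
    n_sites_b: int
    total_shared_nt: int


@dataclass
class TreeTruth:
    root_to_tip: dict[str, float]
    presence: dict[str, set[str]]   # gene -> taxa with a sequence


# ---------------------------------------------------------------------------
# exact-count residue sampling

def _exact_counts_string(n: int, n_gc: int, rng, skew: float = 0.0) -> str:
    if not (0 <= n_gc <= n):
        raise ValueError("GC budget outside [0, n]")
    n_g = int(round(n_gc * (1.0 + skew) / 2.0))
    n_c = n_gc - n_g
    n_at = n - n_gc
    n_a = n_at // 2
    arr = np.array(list("G" * n_g + "C" * n_c + "A" * n_a
                        + "T" * (n_at - n_a)))
    rng.shuffle(arr)
    return "".join(arr)


def _exact_gc_string(n: int, gc: float, rng, skew: float = 0.0) -> str:
    return _exact_counts_string(n, int(round(gc * n)), rng, skew)


def _codon_pool(n_codons: int, gc1: float, gc2: float, gc3: float,
                rng, skew: float = 0.0, n_genes: int = 0) -> list[str]:
    """n interior codons whose pooled per-position GC hits the targets
    exactly (to rounding), with no stop codons.

    Measured codon-position GC pools the fixed ATG start codons too
    (A/T/G at positions 1/2/3), so with ``n_genes`` > 0 the pool budgets
    are offset to land the measured values, not the raw pool, on target.
    """
    n_meas = n_codons + n_genes
    budgets = [int(round(gc1 * n_meas)),
               int(round(gc2 * n_meas)),
               int(round(gc3 * n_meas)) - n_genes]
    cols = [_exact_counts_string(n_codons, min(max(b, 0), n_codons), rng,
                                 skew)
            for b in budgets]
    codons = [x + y + z for x, y, z in zip(*cols)]
    for i, cd in enumerate(codons):
        if cd not in STOPS:
            continue
        for j in range(len(codons)):   # third-position swap keeps counts
            cj = codons[j]
            if j == i or cj in STOPS or cj[0] == "T":
                continue
            ni, nj = cd[:2] + cj[2], cj[:2] + cd[2]
            if ni not in STOPS and nj not in STOPS:
                codons[i], codons[j] = ni, nj
                break
        else:
            raise RuntimeError("could not repair a stop codon")
    return codons


# ---------------------------------------------------------------------------
# layout planning

@dataclass
class _Seg:
    cls: str          # protein | rna | orf
    start: int = -1
    length: int = 0
    strand: str = "+"
    name: str = ""
    kind: str = ""    # feature kind for rna segs: rRNA | tRNA
    intron_at: int = -1     # offset of intron start within the segment
    intron_len: int = 0
    interior_codons: int = 0


@dataclass
class _Placement:
    start: int
    length: int
    content: str      # genomic-forward residues
    left_flank: str
    right_flank: str


def _plan_segments(spec: GenomeSpec, rng) -> tuple[list[_Seg], list[tuple[int, int]]]:
    trna = rng.integers(70, 91, spec.n_trna)
    rrna = rng.integers(1200, 2600, spec.n_rrna)
    coding_target = int(round(spec.length * (1.0 - spec.noncoding_fraction)))
    budget = coding_target - int(trna.sum()) - int(rrna.sum())
    budget -= budget % 3
    if budget < 153 * spec.n_protein:
        raise ValueError("infeasible spec: coding budget too small")
    w = rng.random(spec.n_protein) + 0.5
    lens = np.maximum(153, (budget * w / w.sum() / 3).astype(int) * 3)
    diff = budget - int(lens.sum())
    i = 0
    while diff != 0:            # settle to the exact codon budget
        step = 3 if diff > 0 else -3
        if lens[i % len(lens)] + step >= 153:
            lens[i % len(lens)] += step
            diff -= step
        i += 1

    orf_lens = 3 * rng.integers(50, 134, spec.n_orfs)
    intron_lens = rng.integers(200, 801, spec.n_introns)
    segs: list[_Seg] = []
    for gi, ln in enumerate(lens):
        segs.append(_Seg(cls="protein", length=int(ln),
                         name=f"gene{gi + 1:03d}",
                         interior_codons=int(ln) // 3 - 2))
    for ri, ln in enumerate(rrna):
        segs.append(_Seg(cls="rna", length=int(ln), kind="rRNA",
                         name=f"rrn{ri + 1}"))
    for ti, ln in enumerate(trna):
        segs.append(_Seg(cls="rna", length=int(ln), kind="tRNA",
                         name=f"trn{chr(65 + ti % 26)}{ti + 1}"))
    for oi, ln in enumerate(orf_lens):
        segs.append(_Seg(cls="orf", length=int(ln),
                         name=f"orf{int(ln) // 3 - 1}_{oi + 1}"))
    rng.shuffle(segs)
    for s in segs:
        s.strand = "+" if rng.random() < 0.5 else "-"
    # drop introns into the first n_introns protein genes encountered
    protein_segs = [s for s in segs if s.cls == "protein"]
    if spec.n_introns > len(protein_segs):
        raise ValueError("more introns than protein genes")
    for s, iln in zip(protein_segs, intron_lens):
        s.intron_at = int(rng.integers(30, s.length - 30))
        s.intron_len = int(iln)

    total_feature = sum(s.length + s.intron_len for s in segs)
    n_gaps = len(segs)
    spacer_total = spec.length - total_feature
    if spacer_total < 10 * n_gaps:
        raise ValueError("infeasible spec: class budgets exceed length")
    extra = rng.multinomial(spacer_total - 10 * n_gaps,
                            np.full(n_gaps, 1.0 / n_gaps))
    gaps = 10 + extra
    pos = 0
    spacers: list[tuple[int, int]] = []
    for s, gap in zip(segs, gaps):
        spacers.append((pos, pos + int(gap)))
        pos += int(gap)
        s.start = pos
        pos += s.length + s.intron_len
    assert pos == spec.length
    return segs, spacers


class _FreeList:
    """Free intergenic space for repeat planting; placements reserve a
    1-nt flank margin on each side."""

    def __init__(self, spacers: list[tuple[int, int]]):
        self.free = [(s, e) for s, e in spacers if e - s >= 4]

    def place(self, length: int, rng) -> int:
        cands = [i for i, (s, e) in enumerate(self.free)
                 if e - s >= length + 2]
        if not cands:
            raise ValueError("infeasible spec: no intergenic room "
                             "for a planted repeat")
        idx = cands[int(rng.integers(0, len(cands)))]
        s, e = self.free[idx]
        start = int(rng.integers(s + 1, e - length))
        self.free[idx:idx + 1] = [iv for iv in
                                  [(s, start - 1), (start + length + 1, e)]
                                  if iv[1] - iv[0] >= 4]
        return start


_FLANK_BASES = "ACGT"


def _copy_placement(start: int, source: str, inverted: bool,
                    copy_idx: int) -> _Placement:
    """Plant one copy with source-sense flanks chosen per copy index so
    that no two copies of the same element share an upstream or a
    downstream flank — which pins maximal pairs to the planted bounds."""
    up = _FLANK_BASES[copy_idx]
    down = _FLANK_BASES[copy_idx]
    if not inverted:
        return _Placement(start, len(source), source, up, down)
    return _Placement(start, len(source), revcomp(source),
                      _COMP[down], _COMP[up])


# ---------------------------------------------------------------------------
# synthesis

def _synthesize(spec: GenomeSpec, segs: list[_Seg],
                spacers: list[tuple[int, int]],
                placements: list[_Placement], rng
                ) -> tuple[GenomeRecord, dict]:
    L = spec.length
    chars: list[str | None] = [None] * L
    features: list[Feature] = []

    # --- protein genes: one pooled codon machine per strand (skew is a
    #     genomic-forward property, so minus-strand content gets -skew)
    pools = {}
    pool_pos = {}
    for strand, sk in (("+", spec.gc_skew), ("-", -spec.gc_skew)):
        mine = [s for s in segs if s.cls == "protein"
                and s.strand == strand]
        pools[strand] = _codon_pool(sum(s.interior_codons for s in mine),
                                    spec.gc1, spec.gc2, spec.gc3, rng, sk,
                                    n_genes=len(mine))
        pool_pos[strand] = 0
    codon_truth: list[list[int]] = [[], [], []]   # genomic sites by phase
    for s in segs:
        if s.cls != "protein":
            continue
        m = s.interior_codons
        pp = pool_pos[s.strand]
        cds = "ATG" + "".join(pools[s.strand][pp:pp + m]) \
            + STOPS[int(rng.integers(0, 3))]
        pool_pos[s.strand] = pp + m
        strand_skew = spec.gc_skew if s.strand == "+" else -spec.gc_skew
        if s.intron_len:
            transcript = (cds[:s.intron_at]
                          + _exact_gc_string(s.intron_len, spec.gc_intron,
                                             rng, strand_skew)
                          + cds[s.intron_at:])
        else:
            transcript = cds
        genomic = transcript if s.strand == "+" else revcomp(transcript)
        for k, ch in enumerate(genomic):
            chars[s.start + k] = ch
        total = s.length + s.intron_len
        if s.intron_len:
            if s.strand == "+":
                exons = [(s.start, s.start + s.intron_at),
                         (s.start + s.intron_at + s.intron_len,
                          s.start + total)]
                iv_intron = (s.start + s.intron_at,
                             s.start + s.intron_at + s.intron_len)
            else:
                tail = s.length - s.intron_at   # transcript tail length
                exons = [(s.start, s.start + tail),
                         (s.start + tail + s.intron_len, s.start + total)]
                iv_intron = (s.start + tail, s.start + tail + s.intron_len)
            features.append(Feature(kind="intron", gene_name=s.name,
                                    strand=s.strand, exons=[iv_intron]))
        else:
            exons = [(s.start, s.start + s.length)]
        feat = Feature(kind="protein_coding", gene_name=s.name,
                       strand=s.strand, exons=exons)
        features.append(feat)
        # codon-site truth (translation order, final stop excluded)
        positions = feat.genomic_positions()[:-3]
        for k, p in enumerate(positions):
            codon_truth[k % 3].append(p)

    # --- structural RNAs (pooled) and unclassified ORFs (pooled),
    #     one blob per strand for the same skew reason
    for cls, gc in (("rna", spec.gc_structural_rna), ("orf", spec.gc_orf)):
        for strand, sk in (("+", spec.gc_skew), ("-", -spec.gc_skew)):
            group = [s for s in segs if s.cls == cls and s.strand == strand]
            total = sum(s.length for s in group)
            blob = _exact_gc_string(total, gc, rng, sk)
            off = 0
            for s in group:
                piece = blob[off:off + s.length]
                off += s.length
                genomic = piece if s.strand == "+" else revcomp(piece)
                for k, ch in enumerate(genomic):
                    chars[s.start + k] = ch
                kind = s.kind if cls == "rna" else "unclassified_orf"
                features.append(Feature(
                    kind=kind, gene_name=s.name, strand=s.strand,
                    exons=[(s.start, s.start + s.length)]))

    # --- planted repeat copies and their forced flanks
    planted_gc = 0
    planted_nt = 0
    flank_positions: list[tuple[int, str]] = []
    for p in placements:
        for k, ch in enumerate(p.content):
            chars[p.start + k] = ch
        planted_nt += p.length
        planted_gc += p.content.count("G") + p.content.count("C")
        flank_positions.append((p.start - 1, p.left_flank))
        flank_positions.append((p.start + p.length, p.right_flank))
    for pos, base in flank_positions:
        chars[pos % L] = base
        planted_nt += 1
        planted_gc += base in "GC"

    # --- intergenic background with the GC budget that lands the whole
    #     intergenic class (planted repeats included) on target
    ig_total = sum(e - s for s, e in spacers)
    n_bg = ig_total - planted_nt
    budget = int(round(spec.gc_intergenic * ig_total)) - planted_gc
    budget = min(max(budget, 0), n_bg)
    # planted copies carry no skew; boost the background so the
    # whole-genome skew still lands on target
    sk_bg = (spec.gc_skew * (budget + planted_gc) / budget if budget
             else spec.gc_skew)
    bg = _exact_counts_string(n_bg, budget, rng, min(sk_bg, 1.0))
    bi = 0
    for s, e in spacers:
        for pos in range(s, e):
            if chars[pos] is None:
                chars[pos] = bg[bi]
                bi += 1
    assert bi == n_bg

    record = GenomeRecord(id=spec.genome_id, sequence="".join(chars),
                          circular=spec.circular, features=features)
    record.validate()
    meta = {"spacers": spacers, "codon_truth": codon_truth, "segs": segs}
    return record, meta


def _measure_truth(record: GenomeRecord, spec: GenomeSpec, meta: dict,
                   repeat_hits: list[RepeatHit]) -> GenomeTruth:
    """Realized statistics, computed from the generator's own layout
    bookkeeping (not through the analysis modules)."""
    seq = record.sequence
    segs: list[_Seg] = meta["segs"]

    def gc_of(ivs):
        sub = "".join(seq[s:e] for s, e in ivs)
        n = len(sub)
        return (sub.count("G") + sub.count("C")) / n if n else None

    class_iv: dict[str, list[tuple[int, int]]] = {
        "protein_coding": [], "structural_rna": [], "intron": [],
        "unclassified_orf": [], "intergenic": list(meta["spacers"])}
    for s in segs:
        total = s.length + s.intron_len
        if s.cls == "protein":
            if s.intron_len:
                intron_off = (s.intron_at if s.strand == "+"
                              else s.length - s.intron_at)
                class_iv["protein_coding"] += [
                    (s.start, s.start + intron_off),
                    (s.start + intron_off + s.intron_len, s.start + total)]
                class_iv["intron"].append(
                    (s.start + intron_off, s.start + intron_off
                     + s.intron_len))
            else:
                class_iv["protein_coding"].append((s.start, s.start + total))
        elif s.cls == "rna":
            class_iv["structural_rna"].append((s.start, s.start + s.length))
        else:
            class_iv["unclassified_orf"].append((s.start,
                                                 s.start + s.length))
    gc_by_class = {c: gc_of(iv) for c, iv in class_iv.items()}
    g = seq.count("G")
    c = seq.count("C")
    codon_gc = []
    for phase_sites in meta["codon_truth"]:
        sub = [seq[p] for p in phase_sites]
        codon_gc.append(sum(ch in "GC" for ch in sub) / len(sub))
    coding_nt = (sum(e - s for s, e in class_iv["protein_coding"])
                 + sum(e - s for s, e in class_iv["structural_rna"]))
    cover = np.zeros(record.length, dtype=bool)
    for h in repeat_hits:
        for start in (h.pos_a, h.pos_b):
            cover[np.arange(start, start + h.length) % record.length] = True
    return GenomeTruth(
        genome_id=record.id, length=record.length,
        gc_total=(g + c) / record.length,
        gc_by_class=gc_by_class,
        gc1=codon_gc[0], gc2=codon_gc[1], gc3=codon_gc[2],
        gc_skew=(g - c) / (g + c),
        noncoding_fraction=1.0 - coding_nt / record.length,
        n_protein=sum(1 for s in segs if s.cls == "protein"),
        n_rrna=sum(1 for s in segs if s.cls == "rna" and s.kind == "rRNA"),
        n_trna=sum(1 for s in segs if s.cls == "rna" and s.kind == "tRNA"),
        repeats=repeat_hits,
        repeat_coverage=float(cover.sum()) / record.length,
    )


def _gc_pct(s: str) -> float:
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def generate_genome(spec: GenomeSpec) -> tuple[GenomeRecord, GenomeTruth]:
    """One synthetic annotated circular genome plus its truth table."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    segs, spacers = _plan_segments(spec, rng)
    freelist = _FreeList(spacers)
    placements: list[_Placement] = []
    hits: list[RepeatHit] = []
    for rs in sorted(spec.repeats, key=lambda r: -r.length):
        source = _exact_gc_string(rs.length, rs.gc, rng)
        p1 = freelist.place(rs.length, rng)
        p2 = freelist.place(rs.length, rng)
        inverted = rs.orientation == "inverted"
        placements.append(_copy_placement(p1, source, False, 0))
        placements.append(_copy_placement(p2, source, inverted, 1))
        a, b = min(p1, p2), max(p1, p2)
        hits.append(RepeatHit(orientation=rs.orientation, pos_a=a, pos_b=b,
                              length=rs.length, gc_pct=_gc_pct(source)))
    record, meta = _synthesize(spec, segs, spacers, placements, rng)
    hits.sort(key=lambda h: (h.pos_a, h.pos_b))
    truth = _measure_truth(record, spec, meta, hits)
    return record, truth


def generate_genome_pair(spec_a: GenomeSpec, spec_b: GenomeSpec,
                         shared: list[SharedSpec]
                         ) -> tuple[GenomeRecord, GenomeRecord, PairTruth]:
    """Two genomes with within-genome repeats plus cross-genome shared
    repeat elements planted at controlled numbers of sites."""
    spec_a.validate()
    spec_b.validate()
    rng_a = np.random.default_rng(spec_a.seed)
    rng_b = np.random.default_rng(spec_b.seed)
    rng_s = np.random.default_rng([spec_a.seed, spec_b.seed, 97])

    plan = {}
    for label, spec, rng in (("a", spec_a, rng_a), ("b", spec_b, rng_b)):
        segs, spacers = _plan_segments(spec, rng)
        plan[label] = dict(segs=segs, spacers=spacers,
                           freelist=_FreeList(spacers), placements=[],
                           hits=[])
        for rs in sorted(spec.repeats, key=lambda r: -r.length):
            source = _exact_gc_string(rs.length, rs.gc, rng)
            p1 = plan[label]["freelist"].place(rs.length, rng)
            p2 = plan[label]["freelist"].place(rs.length, rng)
            inverted = rs.orientation == "inverted"
            plan[label]["placements"] += [
                _copy_placement(p1, source, False, 0),
                _copy_placement(p2, source, inverted, 1)]
            plan[label]["hits"].append(RepeatHit(
                orientation=rs.orientation, pos_a=min(p1, p2),
                pos_b=max(p1, p2), length=rs.length, gc_pct=_gc_pct(source)))

    shared_truth: list[SharedSegment] = []
    for ss in shared:
        if ss.copies_a + ss.copies_b > len(_FLANK_BASES):
            raise ValueError("at most 4 total copies per shared element")
        source = _exact_gc_string(ss.length, ss.gc, rng_s)
        inverted = ss.orientation == "inverted"
        idx = 0
        pos_a_list, pos_b_list = [], []
        for _ in range(ss.copies_a):
            p = plan["a"]["freelist"].place(ss.length, rng_s)
            plan["a"]["placements"].append(
                _copy_placement(p, source, False, idx))
            pos_a_list.append(p)
            idx += 1
        for _ in range(ss.copies_b):
            p = plan["b"]["freelist"].place(ss.length, rng_s)
            plan["b"]["placements"].append(
                _copy_placement(p, source, inverted, idx))
            pos_b_list.append(p)
            idx += 1
        for pa in pos_a_list:
            for pb in pos_b_list:
                shared_truth.append(SharedSegment(
                    pos_in_a=pa, pos_in_b=pb, length=ss.length,
                    orientation=ss.orientation))
        # extra copies within one genome are within-genome repeats too
        for label, positions, inv in (("a", pos_a_list, False),
                                      ("b", pos_b_list, inverted)):
            for i in range(len(positions)):
                for j in range(i + 1, len(positions)):
                    p, q = sorted((positions[i], positions[j]))
                    plan[label]["hits"].append(RepeatHit(
                        orientation="forward", pos_a=p, pos_b=q,
                        length=ss.length, gc_pct=_gc_pct(source)))

    rec_a, meta_a = _synthesize(spec_a, plan["a"]["segs"],
                                plan["a"]["spacers"],
                                plan["a"]["placements"], rng_a)
    rec_b, meta_b = _synthesize(spec_b, plan["b"]["segs"],
                                plan["b"]["spacers"],
                                plan["b"]["placements"], rng_b)
    for label in ("a", "b"):
        plan[label]["hits"].sort(key=lambda h: (h.pos_a, h.pos_b))
    truth_a = _measure_truth(rec_a, spec_a, meta_a, plan["a"]["hits"])
    truth_b = _measure_truth(rec_b, spec_b, meta_b, plan["b"]["hits"])
    shared_truth.sort(key=lambda s: (s.pos_in_a, s.pos_in_b))

    mask_a = np.zeros(rec_a.length, dtype=bool)
    mask_b = np.zeros(rec_b.length, dtype=bool)
    for s in shared_truth:
        mask_a[s.pos_in_a:s.pos_in_a + s.length] = True
        mask_b[s.pos_in_b:s.pos_in_b + s.length] = True
    n_sites_a = int(np.sum(mask_a & ~np.roll(mask_a, 1)))
    n_sites_b = int(np.sum(mask_b & ~np.roll(mask_b, 1)))
    truth = PairTruth(a=truth_a, b=truth_b, shared=shared_truth,
                      n_sites_a=n_sites_a, n_sites_b=n_sites_b,
                      total_shared_nt=int(mask_a.sum()))
    return rec_a, rec_b, truth


# ---------------------------------------------------------------------------
# trees and gene-alignment sets

def generate_tree_and_alignments(n_taxa: int, n_genes: int,
                                 occupancy: float = 0.8,
                                 fast_taxa: dict[str, float] | None = None,
                                 seed: int = 0,
                                 aa_len_range: tuple[int, int] = (120, 300)
                                 ) -> tuple[PhyloTree, list[GeneAlignment],
                                            TreeTruth]:
    """A birth-death-shaped rooted tree with optional pendant-edge rate
    multipliers, plus gene alignments with controlled taxon occupancy.

    Alignments are presence/absence scaffolds with random residues — they
    carry no evolutionary signal, which is sufficient for occupancy and
    concatenation logic.
    """
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4")
    if not (0.0 < occupancy <= 1.0):
        raise ValueError("occupancy must be in (0, 1]")
    fast_taxa = fast_taxa or {}
    if any(m < 1.0 for m in fast_taxa.values()):
        raise ValueError("rate multipliers must be >= 1")
    pyrng = _pyrandom.Random(int(seed))
    dtree = treesim.birth_death_tree(birth_rate=1.0, death_rate=0.2,
                                     num_extant_tips=n_taxa, rng=pyrng,
                                     repeat_until_success=True)
    leaves = sorted(dtree.leaf_node_iter(),
                    key=lambda lf: lf.taxon.label)
    for i, leaf in enumerate(leaves):
        leaf.taxon.label = f"T{i + 1:02d}"
    unknown = set(fast_taxa) - {lf.taxon.label for lf in leaves}
    if unknown:
        raise ValueError(f"unknown fast taxa: {sorted(unknown)}")
    depth = max(sum(nd.edge.length or 0.0 for nd in lf.ancestor_iter())
                + (lf.edge.length or 0.0)
                for lf in leaves)
    floor = 0.01 * (depth or 1.0)
    for leaf in dtree.leaf_node_iter():
        # the sampler can emit zero-length pendants (tips born at the
        # stopping event); floor them so rate multipliers always bite
        leaf.edge.length = max(leaf.edge.length or 0.0, floor)
        mult = fast_taxa.get(leaf.taxon.label)
        if mult:
            leaf.edge.length *= mult
    dtree.seed_node.edge.length = None
    tree = PhyloTree(dtree, rooted=True)

    # truth root-to-tip via direct parent-path sums
    dist: dict[str, float] = {}
    for leaf in dtree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        dist[leaf.taxon.label] = d

    taxa = sorted(dist)
    arng = np.random.default_rng([int(seed), 211])
    alignments: list[GeneAlignment] = []
    presence: dict[str, set[str]] = {}
    for gi in range(n_genes):
        width = int(arng.integers(aa_len_range[0], aa_len_range[1] + 1))
        name = f"g{gi + 1:03d}"
        here = [t for t in taxa if arng.random() < occupancy]
        rows = ["".join(arng.choice(list(AA20), size=width))
                for _ in here]
        alignments.append(GeneAlignment(gene_name=name, taxa=here,
                                        rows=rows))
        presence[name] = set(here)
    return tree, alignments, TreeTruth(root_to_tip=dist, presence=presence)


# ---------------------------------------------------------------------------
# GenBank output

def write_genbank(record: GenomeRecord, path) -> None:
    """Write a generated record as a GenBank flat file (fixed date header,
    so identical inputs give byte-identical files)."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    type_map = {"protein_coding": "CDS", "rRNA": "rRNA", "tRNA": "tRNA",
                "intron": "intron", "unclassified_orf": "CDS",
                "other": "misc_feature"}
    sr = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                   description="synthetic organelle genome")
    sr.annotations["molecule_type"] = "DNA"
    sr.annotations["topology"] = "circular" if record.circular else "linear"
    sr.annotations["date"] = "01-JAN-2000"
    sr.annotations["data_file_division"] = "PLN"
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        parts = [SimpleLocation(s, e, strand) for s, e in f.exons]
        if strand == -1:
            parts = parts[::-1]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        quals = {"gene": [f.gene_name]} if f.gene_name else {}
        sr.features.append(SeqFeature(loc, type=type_map[f.kind],
                                      qualifiers=quals))
    SeqIO.write(sr, str(path), "genbank")


# ---------------------------------------------------------------------------
# the study-condition genome specs

def organelle_study_specs(seed: int = 0
                          ) -> tuple[GenomeSpec, GenomeSpec,
                                     list[SharedSpec]]:
    """Default specs emulating a GC-rich trebouxiophyte organelle genome
    pair: a 65.4-kb mitochondrial genome (53.2% GC, 52% noncoding, 59
    genes, five introns) and a 175.7-kb plastid genome (50.7% GC, 56%
    noncoding, 115 genes, one intron), each with ~7% of its length in
    GC-rich (65%) direct/inverted repeats of 20-250 nt, and ~500 nt of
    repeat sequence shared between the two at 5 mitochondrial and 11
    plastid sites.
    """
    def repeat_plan(target_nt: int) -> list[RepeatSpec]:
        # pair copies cover 2*length nt each; 20-250 nt, mean ~100
        lengths = [250, 220, 200, 180, 160, 150, 140, 130, 120, 110,
                   100, 90, 80, 70, 60, 50, 40, 30, 25, 20]
        plan: list[int] = []
        total = 0
        i = 0
        while total + 2 * lengths[i % len(lengths)] <= target_nt:
            ln = lengths[i % len(lengths)]
            plan.append(ln)
            total += 2 * ln
            i += 1
        return [RepeatSpec(length=ln,
                           orientation="forward" if k % 2 == 0
                           else "inverted",
                           gc=0.65)
                for k, ln in enumerate(plan)]

    mt = GenomeSpec(
        genome_id="SYNMT", length=65400, seed=seed * 1000 + 11,
        circular=True, n_protein=32, n_rrna=3, n_trna=24,
        n_orfs=6, n_introns=5, noncoding_fraction=0.52,
        gc1=0.514, gc2=0.408, gc3=0.598,
        gc_structural_rna=0.525, gc_intron=0.50, gc_orf=0.52,
        gc_intergenic=0.557, gc_skew=0.015,
        repeats=repeat_plan(int(0.07 * 65400)),
    )
    pt = GenomeSpec(
        genome_id="SYNPT", length=175700, seed=seed * 1000 + 13,
        circular=True, n_protein=74, n_rrna=3, n_trna=38,
        n_orfs=8, n_introns=1, noncoding_fraction=0.56,
        # structural-RNA / ORF / intron GC are not independently pinned;
        # they are set so the class-weighted mean reproduces the genome's
        # published 50.7% total alongside the published codon-position and
        # intergenic values
        gc1=0.561, gc2=0.436, gc3=0.501,
        gc_structural_rna=0.52, gc_intron=0.52, gc_orf=0.555,
        gc_intergenic=0.51, gc_skew=0.008,
        # multi-copy shared elements already cover ~1.1 kb of the plastid
        # genome as within-genome repeats; budget the rest here
        repeats=repeat_plan(int(0.07 * 175700) - 1070),
    )
    shared = [SharedSpec(length=120, copies_a=1, copies_b=3),
              SharedSpec(length=110, copies_a=1, copies_b=3),
              SharedSpec(length=100, orientation="inverted",
                         copies_a=1, copies_b=2),
              SharedSpec(length=90, copies_a=1, copies_b=2),
              SharedSpec(length=80, copies_a=1, copies_b=1)]
    return mt, pt, shared
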