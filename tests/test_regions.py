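"""Region partitioning, codon phase assignment, gene inventories."""

import random

import pytest

from gclandscape.model import Feature, GenomeRecord
from gclandscape.regions import (codon_position_sites, gene_inventory,
                                 partition_genome)


def rec_with(features, length=100, seq=None):
    seq = seq or ("ACGT" * (length // 4 + 1))[:length]
    return GenomeRecord(id="R1", sequence=seq, circular=False,
                        features=features)


def cds(s, e, strand="+", name="g", exons=None):
    return Feature(kind="protein_coding", gene_name=name, strand=strand,
                   exons=exons or [(s, e)])


class TestPartition:
    def test_single_cds(self):
        part = partition_genome(rec_with([cds(0, 30)]))
        assert part.class_length("protein_coding") == 30
        assert part.class_length("intergenic") == 70

    def test_overlap_precedence_coding_wins(self):
        trna = Feature(kind="tRNA", gene_name="t", exons=[(25, 40)])
        part = partition_genome(rec_with([cds(0, 30), trna]))
        assert part.class_length("protein_coding") == 30
        assert part.class_length("structural_rna") == 10
        assert part.class_length("intergenic") == 60

    def test_intron_between_exons(self):
        feat = cds(0, 90, exons=[(0, 30), (60, 90)])
        intr = Feature(kind="intron", exons=[(30, 60)])
        part = partition_genome(rec_with([feat, intr]))
        assert part.class_length("protein_coding") == 60
        assert part.class_length("intron") == 30

    def test_cds_inside_intron_reclassified(self):
        # an ORF nested in an intron is noncoding: it claims no
        # protein_coding territory, is absent from the gene inventory,
        # and contributes no codon sites
        host = cds(0, 90, exons=[(0, 21), (69, 90)], name="host")
        intr = Feature(kind="intron", exons=[(21, 69)])
        orf = cds(30, 60, name="maturase")
        rec = rec_with([host, intr, orf])
        part = partition_genome(rec)
        assert part.class_length("protein_coding") == 42
        assert part.class_length("intron") == 48
        assert gene_inventory(rec).n_protein == 1
        sites = codon_position_sites(rec, include_stop=True)
        assert len(sites.pos1 | sites.pos2 | sites.pos3) == 42

    def test_completeness_on_randomized_genomes(self):
        rnd = random.Random(42)
        kinds = ["protein_coding", "rRNA", "tRNA", "intron",
                 "unclassified_orf"]
        for _ in range(200):
            length = rnd.randint(50, 400)
            feats = []
            for _ in range(rnd.randint(0, 8)):
                s = rnd.randrange(0, length - 1)
                e = rnd.randrange(s + 1, length + 1)
                feats.append(Feature(kind=rnd.choice(kinds),
                                     strand=rnd.choice("+-"),
                                     exons=[(s, e)]))
            part = partition_genome(rec_with(feats, length=length))
            assert sum(part.class_length(c)
                       for c in part.intervals) == length

    def test_feature_order_independent(self):
        feats = [cds(0, 30), Feature(kind="tRNA", exons=[(25, 40)]),
                 Feature(kind="intron", exons=[(50, 70)])]
        p1 = partition_genome(rec_with(feats))
        p2 = partition_genome(rec_with(feats[::-1]))
        assert p1.intervals == p2.intervals


class TestCodonSites:
    def test_plus_strand_phases(self):
        sites = codon_position_sites(rec_with([cds(0, 9)],
                                              seq="ATGGCCAAA" + "T" * 91))
        assert sites.pos1 == {0, 3, 6}
        assert sites.pos2 == {1, 4, 7}
        assert sites.pos3 == {2, 5, 8}

    def test_minus_strand_phases(self):
        # reverse-complement reading: translation starts at position 8
        seq = "TTTGGCCAT" + "A" * 91   # revcomp of leading 9 = ATGGCCAAA
        sites = codon_position_sites(rec_with([cds(0, 9, strand="-")],
                                              seq=seq))
        assert sites.pos1 == {8, 5, 2}
        assert sites.pos2 == {7, 4, 1}
        assert sites.pos3 == {6, 3, 0}

    def test_terminal_stop_excluded_by_default(self):
        seq = "ATGGCCAAATAA" + "C" * 88
        rec = rec_with([cds(0, 12)], seq=seq)
        sites = codon_position_sites(rec)
        assert len(sites.pos1 | sites.pos2 | sites.pos3) == 9
        sites = codon_position_sites(rec, include_stop=True)
        assert len(sites.pos1 | sites.pos2 | sites.pos3) == 12

    def test_incomplete_codon_truncated_with_warning(self):
        rec = rec_with([cds(0, 10)])
        with pytest.warns(UserWarning, match="not divisible"):
            sites = codon_position_sites(rec)
        assert len(sites.pos1 | sites.pos2 | sites.pos3) == 9

    def test_sites_within_coding_class(self):
        rec = rec_with([cds(0, 30), cds(40, 70, strand="-")])
        part = partition_genome(rec)
        coding = {p for s, e in part.intervals["protein_coding"]
                  for p in range(s, e)}
        sites = codon_position_sites(rec, include_stop=True)
        assert (sites.pos1 | sites.pos2 | sites.pos3) <= coding

    def test_phase_sets_disjoint_across_junction(self):
        feat = cds(0, 90, exons=[(0, 10), (50, 58)])  # 18 nt spliced
        sites = codon_position_sites(rec_with([feat], seq="A" * 100))
        assert not (sites.pos1 & sites.pos2)
        assert not (sites.pos2 & sites.pos3)
        assert len(sites.pos1) == len(sites.pos2) == len(sites.pos3) == 6


class TestInventory:
    def test_counts_by_kind(self):
        feats = [cds(0, 9, name="a"), cds(10, 19, name="b"),
                 Feature(kind="rRNA", gene_name="rrnS", exons=[(20, 30)]),
                 Feature(kind="tRNA", gene_name="trnA", exons=[(30, 35)]),
                 Feature(kind="tRNA", gene_name="trnB", exons=[(36, 41)]),
                 Feature(kind="tRNA", gene_name="trnC", exons=[(42, 47)])]
        inv = gene_inventory(rec_with(feats))
        assert (inv.n_protein, inv.n_rrna, inv.n_trna) == (2, 1, 3)
        assert inv.n_total == 6

    def test_orfs_and_introns_never_counted(self):
        feats = [cds(0, 9, name="a"),
                 Feature(kind="unclassified_orf", exons=[(20, 29)]),
                 Feature(kind="intron", exons=[(40, 60)])]
        assert gene_inventory(rec_with(feats)).n_total == 1

    def test_duplicate_copies_count_per_copy(self):
        feats = [Feature(kind="tRNA", gene_name="trnM", exons=[(0, 5)]),
                 Feature(kind="tRNA", gene_name="trnM", exons=[(10, 15)])]
        assert gene_inventory(rec_with(feats)).n_trna == 2
        assert gene_inventory(rec_with(feats), dedupe=True).n_trna == 1
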