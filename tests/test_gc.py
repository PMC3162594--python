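"""GC statistics, skew, landscape assembly, amino-acid composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gclandscape.gc import (amino_acid_composition, codon_position_gc,
                            gc_fraction, gc_skew, landscape_report)
from gclandscape.model import Feature, GenomeRecord, revcomp
from gclandscape.regions import codon_position_sites, partition_genome

dna = st.text(alphabet="ACGT", min_size=0, max_size=300)


class TestScalarStats:
    @pytest.mark.parametrize("seq,expected", [
        ("GGCC", 1.0),
        ("ATATN", 0.0),          # N excluded from the denominator
        ("ATGC", 0.5),
        ("NNNN", None),          # empty effective denominator: undefined
        ("", None),
    ])
    def test_gc_fraction(self, seq, expected):
        assert gc_fraction(seq) == expected

    @pytest.mark.parametrize("seq,expected", [
        ("GGGC", 0.5),
        ("GC", 0.0),
        ("ATAT", None),
    ])
    def test_gc_skew(self, seq, expected):
        assert gc_skew(seq) == expected

    @settings(max_examples=100, derandomize=True)
    @given(dna)
    def test_gc_revcomp_invariant_skew_antisymmetric(self, seq):
        assert gc_fraction(seq) == gc_fraction(revcomp(seq))
        sk = gc_skew(seq)
        if sk is not None:
            assert gc_skew(revcomp(seq)) == pytest.approx(-sk)


class TestCodonGC:
    def test_single_codon_pairs(self):
        seq = "ATGGCC" + "A" * 94
        rec = GenomeRecord(id="R", sequence=seq, features=[
            Feature(kind="protein_coding", exons=[(0, 6)])])
        sites = codon_position_sites(rec, include_stop=True)
        gc1, gc2, gc3 = codon_position_gc(rec, sites)
        assert (gc1, gc2, gc3) == (0.5, 0.5, 1.0)

    def test_mean_of_positions_equals_overall_coding_gc(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        rec = GenomeRecord(id="R", sequence=seq, features=[
            Feature(kind="protein_coding", exons=[(0, 150)]),
            Feature(kind="protein_coding", strand="-", exons=[(150, 300)])])
        sites = codon_position_sites(rec, include_stop=True)
        gc1, gc2, gc3 = codon_position_gc(rec, sites)
        pooled = gc_fraction(seq)
        assert (gc1 + gc2 + gc3) / 3 == pytest.approx(pooled, abs=1e-12)


class TestLandscapeReport:
    def test_featureless_genome(self):
        rec = GenomeRecord(id="R", sequence="ACGT" * 25)
        rpt = landscape_report(rec, partition_genome(rec), None)
        assert rpt.noncoding_pct == 100.0
        assert rpt.gc_coding_pct is None
        assert rpt.gc1_pct is None

    def test_weighted_mean_identity(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        rec = GenomeRecord(id="R", sequence=seq, features=[
            Feature(kind="protein_coding", exons=[(0, 150)]),
            Feature(kind="rRNA", exons=[(200, 350)]),
            Feature(kind="intron", exons=[(400, 500)])])
        part = partition_genome(rec)
        rpt = landscape_report(rec, part, None)
        weighted = sum(
            part.class_length(c) * (gc_fraction(part.class_sequence(rec, c))
                                    or 0.0)
            for c in part.intervals) / rec.length
        assert rpt.gc_total_pct == pytest.approx(100 * weighted, abs=1e-9)

    def test_noncoding_counts_introns_and_orfs(self):
        seq = "ACGT" * 50
        rec = GenomeRecord(id="R", sequence=seq, features=[
            Feature(kind="protein_coding", exons=[(0, 60)]),
            Feature(kind="tRNA", exons=[(60, 80)]),
            Feature(kind="intron", exons=[(100, 140)]),
            Feature(kind="unclassified_orf", exons=[(140, 170)])])
        rpt = landscape_report(rec, partition_genome(rec), None)
        # coding = 60 + 20 of 200; introns and unclassified ORFs noncoding
        assert rpt.noncoding_pct == pytest.approx(60.0)

    def test_mismatched_partition_rejected(self):
        rec = GenomeRecord(id="R", sequence="ACGT" * 25)
        other = GenomeRecord(id="Q", sequence="ACGT" * 30)
        with pytest.raises(Exception):
            landscape_report(rec, partition_genome(other), None)


# independent codon table for the translation oracle
_ORACLE_TABLE = {}
_BASES = "TCAG"
_AAS = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG")
for _i, (_b1, _b2, _b3) in enumerate(
        (a, b, c) for a in _BASES for b in _BASES for c in _BASES):
    _ORACLE_TABLE[_b1 + _b2 + _b3] = _AAS[_i]


class TestAminoAcidComposition:
    def test_three_codon_cds(self):
        seq = "ATGGCTGGA" + "C" * 91
        rec = GenomeRecord(id="R", sequence=seq, features=[
            Feature(kind="protein_coding", exons=[(0, 9)])])
        comp = amino_acid_composition(rec)
        assert comp == {"A": pytest.approx(1 / 3),
                        "G": pytest.approx(1 / 3),
                        "M": pytest.approx(1 / 3)}

    def test_frequencies_sum_to_one_and_match_oracle(self):
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list("ACGT"), size=902))
        feats = [Feature(kind="protein_coding", exons=[(0, 450)]),
                 Feature(kind="protein_coding", strand="-",
                         exons=[(450, 900)])]
        rec = GenomeRecord(id="R", sequence=seq[:900], features=feats)
        with pytest.warns(UserWarning, match="internal stop"):
            comp = amino_acid_composition(rec)
        assert sum(comp.values()) == pytest.approx(1.0)
        # oracle: independent table lookup over both annotated frames
        counts = {}
        for f in feats:
            cds = rec.feature_sequence(f)
            for i in range(0, len(cds) - 2, 3):
                aa = _ORACLE_TABLE[cds[i:i + 3]]
                if aa != "*":
                    counts[aa] = counts.get(aa, 0) + 1
        total = sum(counts.values())
        for aa, freq in comp.items():
            assert freq == pytest.approx(counts[aa] / total)
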