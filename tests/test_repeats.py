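"""Maximal repeat discovery vs the brute-force diagonal oracle."""

import numpy as np
import pytest

from gclandscape.model import GenomeRecord, revcomp
from gclandscape.repeats import (find_maximal_repeats, repeat_coverage,
                                 shared_repeats)
from conftest import (oracle_cross_pairs, oracle_forward_pairs,
                      oracle_inverted_pairs, random_seq)


def lin(seq, rec_id="R1", circular=False):
    return GenomeRecord(id=rec_id, sequence=seq, circular=circular)


def as_sets(hits):
    fwd = {(h.pos_a, h.pos_b, h.length) for h in hits
           if h.orientation == "forward"}
    inv = {(h.pos_a, h.pos_b, h.length) for h in hits
           if h.orientation == "inverted"}
    return fwd, inv


class TestFinderBasics:
    def test_planted_forward_pair(self):
        seq = "AAACGTACGTTTTTACGTACGTAAA"
        hits = find_maximal_repeats(lin(seq), min_len=8, orientations=("forward",))
        fwd, _ = as_sets(hits)
        assert fwd == oracle_forward_pairs(seq, 8)
        assert any(seq[a:a + ln] == seq[b:b + ln] and ln >= 8
                   for a, b, ln in fwd)

    def test_planted_inverted_pair(self):
        rng = np.random.default_rng(0)
        core = random_seq(rng, 30)
        seq = random_seq(rng, 40) + core + random_seq(rng, 40) \
            + revcomp(core) + random_seq(rng, 40)
        hits = find_maximal_repeats(lin(seq), min_len=30,
                                    orientations=("inverted",))
        assert len(hits) == 1
        h = hits[0]
        assert (h.pos_a, h.pos_b, h.length) == (40, 110, 30)
        assert seq[h.pos_a:h.pos_a + 30] == revcomp(
            seq[h.pos_b:h.pos_b + 30])

    def test_random_sequence_usually_empty(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 2000)
        hits = find_maximal_repeats(lin(seq), min_len=20)
        fwd, inv = as_sets(hits)
        assert fwd == oracle_forward_pairs(seq, 20)
        assert inv == oracle_inverted_pairs(seq, 20)

    def test_min_len_guard(self):
        with pytest.raises(ValueError):
            find_maximal_repeats(lin("ACGTACGTACGT"), min_len=4)

    def test_circular_wrap_repeat_found_once(self):
        rng = np.random.default_rng(2)
        core = random_seq(rng, 40)
        # one copy crosses the origin: tail at the end, head at the start
        seq = core[25:] + random_seq(rng, 200) + core \
            + random_seq(rng, 200) + core[:25]
        rec = lin(seq, circular=True)
        hits = [h for h in find_maximal_repeats(rec, min_len=20)
                if h.length >= 40]
        assert len(hits) == 1
        assert hits[0].length == 40

    def test_gc_of_hit_reported(self):
        core = "G" * 10 + "ACGTACGTAC"
        seq = "TT" + core + "AATTAATTAA" + core + "CC"
        hits = find_maximal_repeats(lin(seq), min_len=20,
                                    orientations=("forward",))
        assert hits and hits[0].gc_pct == pytest.approx(75.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("alphabet,n_seqs,max_len,min_len", [
        ("ACGT", 30, 600, 8),
        ("AC", 20, 300, 8),
    ])
    def test_agreement_on_random_sequences(self, alphabet, n_seqs,
                                           max_len, min_len):
        rng = np.random.default_rng(7)
        for _ in range(n_seqs):
            n = int(rng.integers(50, max_len))
            seq = random_seq(rng, n, alphabet)
            fwd, inv = as_sets(find_maximal_repeats(lin(seq), min_len))
            assert fwd == oracle_forward_pairs(seq, min_len)
            assert inv == oracle_inverted_pairs(seq, min_len)

    def test_monotonicity_in_min_len(self):
        rng = np.random.default_rng(8)
        seq = random_seq(rng, 400, "AC")
        loose = find_maximal_repeats(lin(seq), min_len=8)
        strict = find_maximal_repeats(lin(seq), min_len=12)
        keys = {(h.orientation, h.pos_a, h.pos_b, h.length) for h in loose}
        # every strict hit is present at the looser threshold
        assert all((h.orientation, h.pos_a, h.pos_b, h.length) in keys
                   for h in strict)
        assert len(strict) <= len(loose)


class TestCoverage:
    def test_disjoint_copies(self):
        from gclandscape.model import RepeatHit
        hits = [RepeatHit("forward", 0, 200, 100)]
        assert repeat_coverage(hits, 1000) == pytest.approx(0.2)

    def test_overlapping_copies_counted_once(self):
        from gclandscape.model import RepeatHit
        hits = [RepeatHit("forward", 0, 50, 100)]
        assert repeat_coverage(hits, 1000) == pytest.approx(0.15)


class TestSharedRepeats:
    def _pair(self, seed=3, block=None, invert=False):
        rng = np.random.default_rng(seed)
        block = block or random_seq(rng, 100)
        a = random_seq(rng, 2000) + block + random_seq(rng, 2900)
        bseg = revcomp(block) if invert else block
        b = random_seq(rng, 1000) + bseg + random_seq(rng, 3900)
        return lin(a, "GA"), lin(b, "GB"), block

    def test_identical_block_found(self):
        a, b, _ = self._pair()
        segs, summary = shared_repeats(a, b, min_len=30)
        assert len(segs) == 1
        s = segs[0]
        assert (s.pos_in_a, s.pos_in_b, s.length,
                s.orientation) == (2000, 1000, 100, "forward")
        assert summary.total_shared_nt == 100
        assert (summary.n_sites_a, summary.n_sites_b) == (1, 1)

    def test_inverted_block_found(self):
        a, b, _ = self._pair(seed=4, invert=True)
        segs, _ = shared_repeats(a, b, min_len=30)
        assert len(segs) == 1 and segs[0].orientation == "inverted"

    def test_matches_cross_oracle(self):
        rng = np.random.default_rng(5)
        block = random_seq(rng, 60)
        a = random_seq(rng, 500) + block + random_seq(rng, 440)
        b = random_seq(rng, 200) + revcomp(block) + random_seq(rng, 300) \
            + block + random_seq(rng, 240)
        segs, _ = shared_repeats(lin(a, "GA"), lin(b, "GB"), min_len=30)
        got_f = {(s.pos_in_a, s.pos_in_b, s.length) for s in segs
                 if s.orientation == "forward"}
        got_i = {(s.pos_in_a, s.pos_in_b, s.length) for s in segs
                 if s.orientation == "inverted"}
        assert got_f == oracle_cross_pairs(a, b, 30, inverted=False)
        assert got_i == oracle_cross_pairs(a, b, 30, inverted=True)

    def test_symmetry(self):
        a, b, _ = self._pair(seed=6)
        segs_ab, sum_ab = shared_repeats(a, b, min_len=30)
        segs_ba, sum_ba = shared_repeats(b, a, min_len=30)
        assert {(s.pos_in_a, s.pos_in_b, s.length) for s in segs_ab} == \
            {(s.pos_in_b, s.pos_in_a, s.length) for s in segs_ba}
        assert sum_ab.n_sites_a == sum_ba.n_sites_b

    def test_merged_site_counting(self):
        rng = np.random.default_rng(9)
        b1 = random_seq(rng, 60)
        b2 = random_seq(rng, 60)
        # two blocks adjacent in A (one merged site), separate in B
        a = random_seq(rng, 800) + b1 + b2 + random_seq(rng, 1080)
        b = random_seq(rng, 300) + b1 + random_seq(rng, 500) + b2 \
            + random_seq(rng, 1040)
        _, summary = shared_repeats(lin(a, "GA"), lin(b, "GB"), min_len=30)
        assert summary.n_sites_a == 1
        assert summary.n_sites_b == 2
        assert summary.total_shared_nt == 120
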