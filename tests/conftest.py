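"""Shared fixtures and independent brute-force oracles.

The repeat oracles enumerate maximal matched runs along every diagonal
of the (self- or cross-) comparison matrix with numpy — a different
algorithm family from the package's k-mer seed-and-extend finder, so
agreement between the two is a meaningful check.
"""

from __future__ import annotations

import numpy as np
import pytest

from gclandscape.model import GenomeRecord, revcomp


def _runs(match: np.ndarray):
    """(start, length) of every maximal True-run in a boolean vector."""
    padded = np.concatenate(([0], match.view(np.int8), [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return zip(starts, ends - starts)


def oracle_forward_pairs(s: str, min_len: int) -> set[tuple[int, int, int]]:
    """All maximal forward pairs (a, b, len), a < b, by diagonal scan."""
    a = np.frombuffer(s.encode(), dtype=np.uint8)
    n = len(s)
    out = set()
    for d in range(1, n):
        for st, ln in _runs(a[: n - d] == a[d:]):
            if ln >= min_len:
                out.add((int(st), int(st + d), int(ln)))
    return out


def oracle_inverted_pairs(s: str, min_len: int) -> set[tuple[int, int, int]]:
    """All maximal inverted pairs (a, b, len), canonical a <= b, where
    s[a:a+len] == revcomp(s[b:b+len]); via forward matches of s against
    revcomp(s)."""
    n = len(s)
    a = np.frombuffer(s.encode(), dtype=np.uint8)
    r = np.frombuffer(revcomp(s).encode(), dtype=np.uint8)
    out = set()
    for off in range(-(n - 1), n):
        lo = max(0, -off)
        hi = min(n, n - off)
        if hi - lo < min_len:
            continue
        for st, ln in _runs(a[lo:hi] == r[lo + off:hi + off]):
            if ln < min_len:
                continue
            i = int(lo + st)
            p = i + off          # start in revcomp coordinates
            j = n - p - int(ln)  # start of the partner in s coordinates
            if i != j:           # a perfect hairpin is not a copy pair
                out.add((min(i, j), max(i, j), int(ln)))
    return out


def oracle_cross_pairs(s: str, t: str, min_len: int, inverted: bool
                       ) -> set[tuple[int, int, int]]:
    """All maximal cross-string matches (i in s, j in t, len)."""
    a = np.frombuffer(s.encode(), dtype=np.uint8)
    other = revcomp(t) if inverted else t
    b = np.frombuffer(other.encode(), dtype=np.uint8)
    ns, nt = len(s), len(t)
    out = set()
    for off in range(-(ns - 1), nt):
        lo = max(0, -off)
        hi = min(ns, nt - off)
        if hi - lo < min_len:
            continue
        for st, ln in _runs(a[lo:hi] == b[lo + off:hi + off]):
            if ln < min_len:
                continue
            i = int(lo + st)
            p = i + off
            j = nt - p - int(ln) if inverted else p
            out.add((i, int(j), int(ln)))
    return out


def random_seq(rng, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture
def linear_record():
    def make(seq: str, rec_id: str = "LIN1") -> GenomeRecord:
        return GenomeRecord(id=rec_id, sequence=seq, circular=False)
    return make


# a small hand-written GenBank flat file exercising the coordinate
# conventions: plain CDS, join, complement, origin-crossing join
HAND_GENBANK = """\
LOCUS       TEST0001                 100 bp    DNA     circular PLN 01-JAN-2000
DEFINITION  synthetic test record.
ACCESSION   TEST0001
VERSION     TEST0001
KEYWORDS    .
SOURCE      synthetic
  ORGANISM  synthetic
FEATURES             Location/Qualifiers
     source          1..100
     CDS             1..30
                     /gene="abcA"
     CDS             join(10..20,30..40)
                     /gene="ijkB"
     CDS             complement(41..70)
                     /gene="revC"
     CDS             join(91..100,1..10)
                     /gene="wrpD"
     tRNA            71..90
                     /gene="trnX"
     CDS             45..59
                     /gene="orf4"
ORIGIN
        1 atgaaacccg ggtttacgta cgtaacgtag catgcatgca tgcatgcatg catgcatgca
       61 tgcatgcatg acgtacgtac gtacgtacgt atgcatgcat
//
"""


@pytest.fixture
def hand_genbank_path(tmp_path):
    p = tmp_path / "hand.gb"
    p.write_text(HAND_GENBANK)
    return p
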