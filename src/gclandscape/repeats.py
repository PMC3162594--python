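"""Maximal exact repeat discovery, within and between genomes.

A *maximal pair* is two identical substrings (forward) or exact
reverse-complement substrings (inverted) that cannot be extended one
position left or right without breaking the match. Discovery is by
seed-and-extend over a k-mer index with k = ``min_len``: every maximal
pair of length >= min_len contains a shared k-mer at an aligned offset,
so extending from every shared seed and deduplicating the extended
coordinates enumerates exactly the maximal pair set. Correctness is
pinned by a brute-force all-pairs oracle in the test suite.

Circular genomes are analysed as the linearized sequence plus a wrap
extension (default 300 nt, comfortably above the longest repeats seen
in organelle genomes); hits are mapped back modulo the genome length
and deduplicated.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .model import (GenomeRecord, RepeatHit, SharedSegment, SharedSummary,
                    revcomp)
from .gc import gc_fraction

WRAP_NT = 300
_MIN_ALLOWED = 8  # guards quadratic blowup on trivial seeds

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _work_string(seq: str, circular: bool, wrap: int = WRAP_NT) -> str:
    return seq + seq[: min(wrap, len(seq) - 1)] if circular else seq


def _kmer_index(t: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(t) - k + 1):
        index[t[i:i + k]].append(i)
    return index


def _covered(intervals: list[tuple[int, int]], s: int, e: int) -> bool:
    return any(a <= s and e <= b for a, b in intervals)


def _forward_pairs(t: str, k: int) -> set[tuple[int, int, int]]:
    """All maximal forward pairs (start_a, start_b, length) with a < b."""
    n = len(t)
    found: set[tuple[int, int, int]] = set()
    seen_diag: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for positions in _kmer_index(t, k).values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                d = j - i
                if _covered(seen_diag[d], i, i + k):
                    continue  # seed inside an already-extended pair
                left = 0
                while i - left - 1 >= 0 and t[i - left - 1] == t[j - left - 1]:
                    left += 1
                right = 0
                while j + k + right < n and t[i + k + right] == t[j + k + right]:
                    right += 1
                a, b, ln = i - left, j - left, k + left + right
                found.add((a, b, ln))
                seen_diag[d].append((a, a + ln))
    return found


def _inverted_pairs(t: str, k: int) -> set[tuple[int, int, int]]:
    """All maximal inverted pairs (a, b, length), canonical a <= b, where
    t[a:a+len] == revcomp(t[b:b+len])."""
    n = len(t)
    index = _kmer_index(t, k)
    found: set[tuple[int, int, int]] = set()
    done_seeds: set[tuple[int, int]] = set()
    for j in range(n - k + 1):
        rc = revcomp(t[j:j + k])
        for i in index.get(rc, ()):
            # t[i:i+k] == revcomp(t[j:j+k]); relation is symmetric in (i,j)
            lo, hi = min(i, j), max(i, j)
            if (lo, hi) in done_seeds:
                continue
            done_seeds.add((lo, hi))
            left = 0   # extend left of copy A, right of copy B
            while (i - left - 1 >= 0 and j + k + left < n
                   and t[i - left - 1] == _COMP.get(t[j + k + left], "?")):
                left += 1
            right = 0  # extend right of copy A, left of copy B
            while (i + k + right < n and j - right - 1 >= 0
                   and t[i + k + right] == _COMP.get(t[j - right - 1], "?")):
                right += 1
            a, b, ln = i - left, j - right, k + left + right
            found.add((min(a, b), max(a, b), ln))
    return found


def _low_complexity_runs(seq: str, min_run: int = 50) -> list[tuple[int, int]]:
    """Maximal intervals where the sequence has period <= 2 (homopolymer or
    dinucleotide runs) longer than ``min_run``."""
    runs = []
    n = len(seq)
    start = 0
    i = 2
    while i <= n:
        if i == n or seq[i] != seq[i - 2]:
            if i - start > min_run:
                runs.append((start, i))
            start = i - 1
        i += 1
    return runs


def _map_circular(pairs, length: int, orientation: str,
                  t_len: int) -> set[tuple[str, int, int, int]]:
    """Map linearized hit coordinates back modulo the genome length.

    Distinct maximal pairs may share canonical starts with different
    lengths (palindromes with different centers), so hits are keyed by
    start pair *and* length; only hits truncated by the end of the wrap
    extension are dropped in favour of a longer image of the same pair.
    """
    groups: dict[tuple[str, int, int], list[tuple[int, bool]]] = {}
    for a0, b0, ln in pairs:
        truncated = max(a0, b0) + ln == t_len
        ln = min(ln, length)
        a, b = a0 % length, b0 % length
        if a == b:
            # forward: a copy matching its own wrap image; inverted: a
            # self-reverse-complementary hairpin — one interval, not a
            # pair of repeat copies
            continue
        if b < a:
            a, b = b, a
        groups.setdefault((orientation, a, b), []).append((ln, truncated))
    out: set[tuple[str, int, int, int]] = set()
    for (orient, a, b), entries in groups.items():
        longest = max(ln for ln, _ in entries)
        for ln, truncated in entries:
            if truncated and ln < longest:
                continue
            out.add((orient, a, b, ln))
    return out


def _copy_seq(seq: str, start: int, ln: int) -> str:
    """Extract a copy that may wrap the origin of a circular genome."""
    end = start + ln
    if end <= len(seq):
        return seq[start:end]
    return seq[start:] + seq[: end - len(seq)]


def find_maximal_repeats(record: GenomeRecord, min_len: int = 20,
                         orientations: tuple[str, ...] = ("forward",
                                                          "inverted")
                         ) -> list[RepeatHit]:
    """Exactly the maximal repeated pairs of length >= min_len within one
    genome, in the requested orientations."""
    if min_len < _MIN_ALLOWED:
        raise ValueError(f"min_len must be >= {_MIN_ALLOWED}")
    seq = record.sequence
    if len(seq) < min_len:
        raise ValueError("sequence shorter than min_len")
    t = _work_string(seq, record.circular)
    lc_runs = _low_complexity_runs(seq)
    hits: list[RepeatHit] = []
    combined: set[tuple[str, int, int, int]] = set()
    if "forward" in orientations:
        combined |= _map_circular(_forward_pairs(t, min_len),
                                  len(seq), "forward", len(t))
    if "inverted" in orientations:
        combined |= _map_circular(_inverted_pairs(t, min_len),
                                  len(seq), "inverted", len(t))
    for orient, a, b, ln in sorted(combined,
                                   key=lambda k: (k[1], k[2], k[3])):
        copy_a = _copy_seq(seq, a, ln)
        low = (_covered(lc_runs, a, min(a + ln, len(seq)))
               and _covered(lc_runs, b, min(b + ln, len(seq))))
        hits.append(RepeatHit(orientation=orient, pos_a=a, pos_b=b,
                              length=ln, gc_pct=_pct(gc_fraction(copy_a)),
                              low_complexity=low))
    return hits


def _pct(x):
    return None if x is None else 100.0 * x


def repeat_coverage(hits: list[RepeatHit], length: int) -> float:
    """Fraction of the genome covered by the union of all repeat copies."""
    mask = np.zeros(length, dtype=bool)
    for h in hits:
        for start in (h.pos_a, h.pos_b):
            idx = np.arange(start, start + h.length) % length
            mask[idx] = True
    return float(mask.sum()) / length if length else 0.0


def _cross_pairs(ta: str, tb: str, k: int, inverted: bool
                 ) -> set[tuple[int, int, int]]:
    """Maximal cross-string matches (i in a, j in b, length)."""
    na, nb = len(ta), len(tb)
    index = _kmer_index(ta, k)
    found: set[tuple[int, int, int]] = set()
    for j in range(nb - k + 1):
        key = revcomp(tb[j:j + k]) if inverted else tb[j:j + k]
        for i in index.get(key, ()):
            if not inverted:
                left = 0
                while (i - left - 1 >= 0 and j - left - 1 >= 0
                       and ta[i - left - 1] == tb[j - left - 1]):
                    left += 1
                right = 0
                while (i + k + right < na and j + k + right < nb
                       and ta[i + k + right] == tb[j + k + right]):
                    right += 1
                found.add((i - left, j - left, k + left + right))
            else:
                left = 0
                while (i - left - 1 >= 0 and j + k + left < nb
                       and ta[i - left - 1] == _COMP.get(tb[j + k + left], "?")):
                    left += 1
                right = 0
                while (i + k + right < na and j - right - 1 >= 0
                       and ta[i + k + right] == _COMP.get(tb[j - right - 1], "?")):
                    right += 1
                found.add((i - left, j - right, k + left + right))
    return found


def _circular_site_count(mask: np.ndarray, circular: bool) -> int:
    """Number of distinct marked runs, honouring circular adjacency."""
    if not mask.any():
        return 0
    if mask.all():
        return 1
    if circular:
        return int(np.sum(mask & ~np.roll(mask, 1)))
    padded = np.concatenate(([0], mask.view(np.int8)))
    return int(np.sum(np.diff(padded) == 1))


def shared_repeats(record_a: GenomeRecord, record_b: GenomeRecord,
                   min_len: int = 30
                   ) -> tuple[list[SharedSegment], SharedSummary]:
    """All maximal exact segments (both orientations) shared between two
    genomes, with a site summary: ``n_sites_a``/``n_sites_b`` count merged
    match intervals in each genome, ``total_shared_nt`` is the union
    length in genome A."""
    if min_len < _MIN_ALLOWED:
        raise ValueError(f"min_len must be >= {_MIN_ALLOWED}")
    if record_a.id == record_b.id and record_a.sequence == record_b.sequence:
        raise ValueError("shared_repeats requires two distinct records")
    ta = _work_string(record_a.sequence, record_a.circular)
    tb = _work_string(record_b.sequence, record_b.circular)
    la, lb = record_a.length, record_b.length
    groups: dict[tuple[str, int, int], list[tuple[int, bool]]] = {}
    for orient, inv in (("forward", False), ("inverted", True)):
        for a0, b0, ln in _cross_pairs(ta, tb, min_len, inv):
            truncated = (a0 + ln == len(ta)) or (b0 + ln == len(tb))
            groups.setdefault((orient, a0 % la, b0 % lb), []).append(
                (min(ln, la, lb), truncated))
    keep: set[tuple[str, int, int, int]] = set()
    for (orient, a, b), entries in groups.items():
        longest = max(ln for ln, _ in entries)
        for ln, truncated in entries:
            if not (truncated and ln < longest):
                keep.add((orient, a, b, ln))
    segments = [SharedSegment(pos_in_a=a, pos_in_b=b, length=ln,
                              orientation=orient)
                for orient, a, b, ln in sorted(
                    keep, key=lambda k: (k[1], k[2], k[3]))]
    mask_a = np.zeros(la, dtype=bool)
    mask_b = np.zeros(lb, dtype=bool)
    for s in segments:
        mask_a[np.arange(s.pos_in_a, s.pos_in_a + s.length) % la] = True
        mask_b[np.arange(s.pos_in_b, s.pos_in_b + s.length) % lb] = True
    summary = SharedSummary(
        n_sites_a=_circular_site_count(mask_a, record_a.circular),
        n_sites_b=_circular_site_count(mask_b, record_b.circular),
        total_shared_nt=int(mask_a.sum()),
    )
    return segments, summary
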