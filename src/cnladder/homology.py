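"""Exact-substring homology screening.

Ladder elements must share no exact substring longer than a small bound
(25 nt by default) with the natural sequences they could be confused with.
The screen here answers longest-common-substring queries with hashed
fixed-length word sets: a word length ``L`` is shared between candidate and
reference iff their packed ``L``-mer sets intersect, and the property is
monotone in ``L``, so the longest shared length is found by binary search
over ``L`` in [1, 32]. Matches that might exceed 32 nt (for example a
candidate screened against itself) are located explicitly and extended
base by base.

This replaces a database BLAST search with a stricter, fully local and
deterministic screen: an exact match is the limiting case of a BLAST hit,
so any sequence passing this screen has no exact BLAST hit longer than the
bound either.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._codec import INVALID, encode, forward_codes, revcomp

_EXTENSION_PAIR_CAP = 200_000  # safety valve for pathological repeat structures


@dataclass(frozen=True)
class ScreenReport:
    """Outcome of screening one candidate against a reference collection."""

    passed: bool
    longest: int
    reference_id: str | None
    max_match: int


def _unique_word_codes(arr: np.ndarray, L: int) -> np.ndarray:
    return np.unique(forward_codes(arr, L))


def _extend_match(a: np.ndarray, b: np.ndarray, i: int, j: int, seed_len: int) -> int:
    """Length of the maximal common run through seeds a[i:i+seed_len] == b[j:j+seed_len]."""
    # extend right
    ra, rb = a[i + seed_len :], b[j + seed_len :]
    n = min(ra.size, rb.size)
    if n:
        neq = ra[:n] != rb[:n]
        right = int(np.argmax(neq)) if neq.any() else n
    else:
        right = 0
    # extend left
    la, lb = a[:i][::-1], b[:j][::-1]
    n = min(la.size, lb.size)
    if n:
        neq = la[:n] != lb[:n]
        left = int(np.argmax(neq)) if neq.any() else n
    else:
        left = 0
    return seed_len + left + right


def _longest_one_strand(a_arr: np.ndarray, b_arr: np.ndarray) -> int:
    """Longest exact common substring of two encoded sequences (one strand)."""
    la, lb = a_arr.size, b_arr.size
    if la == 0 or lb == 0:
        return 0
    cap = min(la, lb, 32)
    lo, hi = 0, cap
    while lo < hi:
        mid = (lo + hi + 1) // 2
        sa = _unique_word_codes(a_arr, mid)
        sb = _unique_word_codes(b_arr, mid)
        if sa.size and sb.size and np.intersect1d(sa, sb, assume_unique=True).size:
            lo = mid
        else:
            hi = mid - 1
    if lo < cap or cap == min(la, lb):
        return lo
    # shared at the 32-mer cap: locate seeds and extend explicitly
    fa = forward_codes(a_arr, 32)
    fb = forward_codes(b_arr, 32)
    shared = np.intersect1d(np.unique(fa), np.unique(fb), assume_unique=True)
    best = 32
    pairs = 0
    for code in shared:
        pa = np.flatnonzero(fa == code)
        pb = np.flatnonzero(fb == code)
        for i in pa:
            for j in pb:
                best = max(best, _extend_match(a_arr, b_arr, int(i), int(j), 32))
                pairs += 1
                if pairs > _EXTENSION_PAIR_CAP:
                    return best
    return best


def longest_shared_substring(candidate: str, reference: str, *, both_strands: bool = True) -> int:
    """Length of the longest exact substring shared by candidate and reference.

    With ``both_strands`` (the default) the reference is screened in forward
    and reverse-complement orientation, so a match to either strand counts.
    """
    a = encode(candidate)
    b = encode(reference)
    best = _longest_one_strand(a, b)
    if both_strands:
        best = max(best, _longest_one_strand(a, encode(revcomp(reference))))
    return best


class HomologyScreen:
    """Reusable screen over a fixed reference collection.

    Word-code sets per (reference, strand, L) are cached, so screening many
    candidates against the same megabase-scale template is cheap.
    """

    def __init__(self, references: Mapping[str, str] | Sequence[tuple[str, str]],
                 *, both_strands: bool = True):
        if isinstance(references, Mapping):
            items = list(references.items())
        else:
            items = list(references)
        if not items:
            raise ValueError("reference collection must be non-empty")
        self.both_strands = both_strands
        self._refs: list[tuple[str, np.ndarray]] = []
        for ref_id, seq in items:
            self._refs.append((ref_id, encode(seq)))
            if both_strands:
                self._refs.append((ref_id, encode(revcomp(seq))))
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    def _ref_codes(self, idx: int, L: int) -> np.ndarray:
        key = (idx, L)
        if key not in self._cache:
            self._cache[key] = _unique_word_codes(self._refs[idx][1], L)
        return self._cache[key]

    def shares_word(self, cand_arr: np.ndarray, L: int) -> str | None:
        """Id of a reference sharing an exact L-mer with the candidate, if any."""
        sa = _unique_word_codes(cand_arr, L)
        if not sa.size:
            return None
        for idx, (ref_id, _) in enumerate(self._refs):
            sb = self._ref_codes(idx, L)
            if sb.size and np.intersect1d(sa, sb, assume_unique=True).size:
                return ref_id
        return None

    def longest_match(self, candidate: str) -> tuple[int, str | None]:
        """Longest shared substring vs any reference, with the offending id."""
        cand = encode(candidate)
        if cand.size == 0:
            raise ValueError("candidate must be non-empty")
        best, best_ref = 0, None
        for idx, (ref_id, ref_arr) in enumerate(self._refs):
            cap = min(cand.size, ref_arr.size, 32)
            lo, hi = 0, cap
            while lo < hi:
                mid = (lo + hi + 1) // 2
                sa = _unique_word_codes(cand, mid)
                sb = self._ref_codes(idx, mid)
                if sa.size and sb.size and np.intersect1d(sa, sb, assume_unique=True).size:
                    lo = mid
                else:
                    hi = mid - 1
            if lo == cap == 32 and min(cand.size, ref_arr.size) > 32:
                lo = _longest_one_strand(cand, ref_arr)
            if lo > best:
                best, best_ref = lo, ref_id
        return best, best_ref


def screen_homology(candidate: str,
                    references: Mapping[str, str] | Sequence[tuple[str, str]] | Iterable[str],
                    max_match: int = 25) -> ScreenReport:
    """Screen a candidate sequence against references on both strands.

    The candidate passes iff its longest exact shared substring with every
    reference (either strand) is at most ``max_match`` nucleotides.
    """
    if not candidate:
        raise ValueError("candidate must be non-empty")
    if np.any(encode(candidate) == INVALID):
        raise ValueError("candidate must contain only A/C/G/T")
    if not isinstance(references, Mapping):
        refs = list(references)
        if refs and isinstance(refs[0], str):
            refs = [(f"ref{i}", s) for i, s in enumerate(refs)]
        references = dict(refs)
    screen = HomologyScreen(references)
    longest, ref_id = screen.longest_match(candidate)
    return ScreenReport(passed=longest <= max_match, longest=longest,
                        reference_id=ref_id, max_match=max_match)
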