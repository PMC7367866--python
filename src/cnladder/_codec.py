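"""Two-bit DNA encoding and vectorised canonical k-mer extraction.

A k-mer of length ``k <= 32`` is packed into a ``uint64``, two bits per base
(A=0, C=1, G=2, T=3), most-significant bits first, so that integer ordering
of packed codes equals lexicographic ordering of the k-mer strings. The
*canonical* form of a k-mer is the smaller of the forward code and the code
of its reverse complement; counting canonical forms makes quantification
strand-agnostic.

All routines operate on numpy arrays so that whole reads (or whole batches
of concatenated reads) are processed without Python-level loops over bases.
Non-ACGT characters encode to :data:`INVALID`; any window containing an
invalid base is dropped, which also lets callers concatenate many sequences
with a single invalid separator byte and extract k-mers in one pass without
creating artificial junction k-mers.
"""

from __future__ import annotations

import numpy as np

MAX_K = 32
INVALID = np.uint8(255)

_ENC = np.full(256, INVALID, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENC[_b] = _i
_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Map a nucleotide string to uint8 base codes (non-ACGT -> INVALID)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENC[np.frombuffer(seq, dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    """Inverse of :func:`encode`; raises on invalid base codes."""
    if arr.size and arr.max(initial=0) > 3:
        raise ValueError("cannot decode invalid base codes")
    return _DEC[arr].tobytes().decode("ascii")


def complement_array(arr: np.ndarray) -> np.ndarray:
    """Complement base codes; invalid bases stay invalid."""
    out = (3 - arr).astype(np.uint8)
    out[arr == INVALID] = INVALID
    return out


def revcomp(seq: str) -> str:
    arr = encode(seq)
    if np.any(arr == INVALID):
        raise ValueError("reverse complement requires an ACGT-only sequence")
    return decode((3 - arr)[::-1])


def _window_valid(arr: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask over the ``len(arr)-k+1`` windows free of invalid bases."""
    bad = (arr == INVALID).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    return (cs[k:] - cs[:-k]) == 0


def forward_codes(arr: np.ndarray, k: int, *, validate: bool = True) -> np.ndarray:
    """Packed uint64 codes of all length-``k`` windows free of invalid bases.

    Returns codes in sequence order (invalid windows removed). Set
    ``validate=False`` when the caller guarantees a clean ACGT array.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    m = arr.size - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    a = arr
    if validate and np.any(arr == INVALID):
        a = np.where(arr == INVALID, 0, arr)
    a64 = a.astype(np.uint64)
    out = np.zeros(m, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        out = (out << two) | a64[j : j + m]
    if validate:
        ok = _window_valid(arr, k)
        if not ok.all():
            out = out[ok]
    return out


def canonical_codes(arr: np.ndarray, k: int, *, validate: bool = True,
                    return_positions: bool = False):
    """Canonical packed codes of all valid length-``k`` windows of ``arr``.

    With ``return_positions`` also returns the start position of each
    retained window, which lets callers map windows back to the reads of a
    separator-joined batch.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    m = arr.size - k + 1
    if m <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return (empty, np.empty(0, dtype=np.int64)) if return_positions else empty
    a = arr
    if validate and np.any(arr == INVALID):
        a = np.where(arr == INVALID, 0, arr)
    a64 = a.astype(np.uint64)
    c64 = (np.uint64(3) - a64)
    fwd = np.zeros(m, dtype=np.uint64)
    rc = np.zeros(m, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        fwd = (fwd << two) | a64[j : j + m]
        # reverse complement read back-to-front: position k-1-j of the window
        rc = (rc << two) | c64[k - 1 - j : k - 1 - j + m]
    out = np.minimum(fwd, rc)
    pos = None
    if validate:
        ok = _window_valid(arr, k)
        if not ok.all():
            out = out[ok]
            if return_positions:
                pos = np.flatnonzero(ok)
    if return_positions:
        if pos is None:
            pos = np.arange(m, dtype=np.int64)
        return out, pos
    return out


def canonicalize_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical form of already-packed forward codes."""
    rc = revcomp_codes(codes, k)
    return np.minimum(codes, rc)


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed code of the reverse complement of each packed code."""
    codes = np.asarray(codes, dtype=np.uint64)
    out = np.zeros_like(codes)
    two = np.uint64(2)
    three = np.uint64(3)
    tmp = codes.copy()
    for _ in range(k):
        out = (out << two) | (three - (tmp & three))
        tmp = tmp >> two
    return out


def codes_to_kmers(codes: np.ndarray, k: int) -> list[str]:
    """Unpack uint64 codes back to k-mer strings (for text output)."""
    codes = np.asarray(codes, dtype=np.uint64)
    mat = np.empty((codes.size, k), dtype=np.uint8)
    for j in range(k):
        shift = np.uint64(2 * (k - 1 - j))
        mat[:, j] = ((codes >> shift) & np.uint64(3)).astype(np.uint8)
    flat = _DEC[mat]
    return [row.tobytes().decode("ascii") for row in flat]


def kmers_to_codes(kmers: "list[str] | np.ndarray", k: int) -> np.ndarray:
    """Pack k-mer strings into forward uint64 codes."""
    joined = "".join(kmers)
    arr = encode(joined)
    if np.any(arr == INVALID):
        raise ValueError("k-mer strings must be ACGT only")
    if arr.size != k * len(kmers):
        raise ValueError("all k-mers must have length k")
    a64 = arr.astype(np.uint64).reshape(len(kmers), k)
    out = np.zeros(len(kmers), dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        out = (out << two) | a64[:, j]
    return out
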