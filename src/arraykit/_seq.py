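"""Low-level DNA string helpers shared across modules.

Sequences are plain upper-case Python strings over the alphabet ACGTN.
Coordinates are 0-based, half-open everywhere inside the package.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: 2-bit base codes; N and anything else maps to 255 (invalid for k-mers).
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMP)[::-1]


def validate_dna(seq: str, name: str = "sequence") -> None:
    """Raise ``ValueError`` naming the first offending position if *seq*
    contains characters outside ACGTN (case-insensitive)."""
    arr = np.frombuffer(seq.upper().encode("ascii", "replace"), dtype=np.uint8)
    bad = (_ENC[arr] == 255) & (arr != ord("N"))
    if bad.any():
        pos = int(np.argmax(bad))
        raise ValueError(
            f"{name} contains non-ACGTN character {seq[pos]!r} at position {pos}"
        )


def seq_to_u8(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0 C=1 G=2 T=3, other=255)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer codes of *seq* packed 2 bits/base into uint64.

    Returns ``(codes, valid)`` where ``codes[i]`` encodes ``seq[i:i+k]`` and
    ``valid[i]`` is False when the window contains a non-ACGT base. Requires
    ``k <= 32``.
    """
    if k > 32:
        raise ValueError("k must be <= 32 for 64-bit packing")
    u = seq_to_u8(seq)
    n = len(u)
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    u64 = (u & np.uint8(3)).astype(np.uint64)
    codes = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        codes |= u64[j : j + m] << np.uint64(2 * (k - 1 - j))
    invalid = (u == 255).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(invalid)])
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


_CODE1 = {c: v for v, c in enumerate("ACGT")}


def kmer_code_at(seq: str, start: int, k: int):
    """Pack ``seq[start:start+k]`` into a uint64 code, or None if the window
    is short or contains a non-ACGT base. Scalar counterpart of
    :func:`kmer_codes` for per-read probing."""
    if start < 0 or start + k > len(seq):
        return None
    code = 0
    for ch in seq[start : start + k]:
        v = _CODE1.get(ch)
        if v is None:
            return None
        code = (code << 2) | v
    return np.uint64(code)


def match_left_extension(a: str, ai: int, b: str, bi: int) -> int:
    """Length of the maximal common suffix of ``a[:ai]`` and ``b[:bi]``.

    Compared in chunks so multi-kb extensions cost O(length) with few
    Python-level iterations.
    """
    ext = 0
    chunk = 256
    while True:
        step = min(chunk, ai - ext, bi - ext)
        if step <= 0:
            return ext
        if a[ai - ext - step : ai - ext] == b[bi - ext - step : bi - ext]:
            ext += step
            chunk = min(chunk * 4, 1 << 20)
            continue
        # mismatch inside this chunk: finish base by base
        while ext < ai and ext < bi and a[ai - ext - 1] == b[bi - ext - 1]:
            ext += 1
        return ext


def match_right_extension(a: str, ai: int, b: str, bi: int) -> int:
    """Length of the maximal common prefix of ``a[ai:]`` and ``b[bi:]``."""
    ext = 0
    la, lb = len(a), len(b)
    chunk = 256
    while True:
        step = min(chunk, la - ai - ext, lb - bi - ext)
        if step <= 0:
            return ext
        if a[ai + ext : ai + ext + step] == b[bi + ext : bi + ext + step]:
            ext += step
            chunk = min(chunk * 4, 1 << 20)
            continue
        while ai + ext < la and bi + ext < lb and a[ai + ext] == b[bi + ext]:
            ext += 1
        return ext


_BASES_U8 = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA string of *length* bases."""
    return _BASES_U8[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
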