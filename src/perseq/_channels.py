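"""Canonical base/trinucleotide/channel encodings shared across the package.

Bases are encoded A=0, C=1, G=2, T=3, N=4.  A trinucleotide is encoded as
``16*left + 4*center + right`` (0..63, lexicographic).  The strand-specific
error space has 192 channels: 64 template trinucleotides x 3 possible
misincorporated (alt) bases, ordered by trinucleotide code then alt base.
The strand-collapsed space has 96 pyrimidine-centric channels in COSMIC SBS
row order (C>A, C>G, C>T, T>A, T>C, T>G blocks, flanks lexicographic).
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

# ASCII -> code lookup (everything unexpected maps to N)
ASCII_TO_CODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    ASCII_TO_CODE[ord(_b)] = _i
    ASCII_TO_CODE[ord(_b.lower())] = _i

CODE_TO_ASCII = np.frombuffer(b"ACGTN", dtype=np.uint8).copy()

# complement in code space (N stays N)
COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

TRINUCS = [a + b + c for a in BASES for b in BASES for c in BASES]
TRINUC_INDEX = {t: i for i, t in enumerate(TRINUCS)}

# alt ranks: for a center base, its three possible alts sorted alphabetically
ALTS_FOR = {b: [x for x in BASES if x != b] for b in BASES}
# ALT_RANK[center_code, alt_code] -> 0..2 (or -1 if alt == center)
ALT_RANK = np.full((4, 4), -1, dtype=np.int8)
for _c in range(4):
    for _r, _a in enumerate(ALTS_FOR[BASES[_c]]):
        ALT_RANK[_c, BASES.index(_a)] = _r

#: 192 strand-specific channels as (template trinucleotide, alt base)
CHANNELS_192 = [(t, a) for t in TRINUCS for a in ALTS_FOR[t[1]]]
CHANNEL_192_INDEX = {c: i for i, c in enumerate(CHANNELS_192)}

SUB_TYPES = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]

#: 96 strand-collapsed channels in COSMIC SBS order, as (trinuc, alt)
CHANNELS_96 = [
    (five + ref + three, alt)
    for ref, alt in SUB_TYPES
    for five in BASES
    for three in BASES
]
CHANNEL_96_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 code array."""
    return ASCII_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return CODE_TO_ASCII[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return decode(COMP[encode(seq)][::-1])


def trinuc_codes(codes: np.ndarray) -> np.ndarray:
    """Per-position trinucleotide codes; -1 at the two ends and where any
    of the three bases is N."""
    n = len(codes)
    out = np.full(n, -1, dtype=np.int32)
    if n < 3:
        return out
    left = codes[:-2].astype(np.int32)
    mid = codes[1:-1].astype(np.int32)
    right = codes[2:].astype(np.int32)
    tc = 16 * left + 4 * mid + right
    tc[(left > 3) | (mid > 3) | (right > 3)] = -1
    out[1:-1] = tc
    return out


def channel_192(trinuc: str, alt: str) -> int:
    """Index of a (template trinucleotide, alt) channel in the 192 ordering."""
    return CHANNEL_192_INDEX[(trinuc, alt)]


def revcomp_trinuc(t: str) -> str:
    return revcomp(t)


def _comp_base(b: str) -> str:
    return BASES[3 - BASES.index(b)]


#: for each 96 channel, the (pyrimidine 192 index, purine partner 192 index)
COLLAPSE_PAIRS = np.empty((96, 2), dtype=np.int64)
for _i, (_t, _a) in enumerate(CHANNELS_96):
    COLLAPSE_PAIRS[_i, 0] = CHANNEL_192_INDEX[(_t, _a)]
    COLLAPSE_PAIRS[_i, 1] = CHANNEL_192_INDEX[(revcomp(_t), _comp_base(_a))]

#: vectorized (trinuc_code, alt_code) -> 192 channel index; -1 where invalid
CHANNEL_LOOKUP = np.full((64, 4), -1, dtype=np.int32)
for _tc, _t in enumerate(TRINUCS):
    _center = BASES.index(_t[1])
    for _ac in range(4):
        _r = int(ALT_RANK[_center, _ac])
        if _r >= 0:
            CHANNEL_LOOKUP[_tc, _ac] = 3 * _tc + _r
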