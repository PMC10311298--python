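"""64-bit mixing and byte-string hashing primitives.

Every source of pseudo-randomness in the package (the minimizer ordering,
the MPHF level hashes, the fallback hashes) is derived from the two
functions below, so any structure is reproducible from (input, seed) alone:

* ``splitmix64`` -- a statistically strong 64-bit finalizer (Steele et al.'s
  SplitMix generator step), used to mix packed 2-bit codes with a seed;
* ``fnv1a64`` -- FNV-1a over arbitrary byte strings, used to reduce MPHF
  keys to 64-bit fingerprints before mixing.

Each scalar function has a numpy companion that computes bit-identical
values over uint64 arrays; the scalar/vector agreement is what makes the
streaming (vectorized) and single-k-mer code paths interchangeable.
"""

from __future__ import annotations

import numpy as np

MASK64 = 0xFFFFFFFFFFFFFFFF

_GAMMA = 0x9E3779B97F4A7C15
_MIX1 = 0xBF58476D1CE4E5B9
_MIX2 = 0x94D049BB133111EB

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3


def splitmix64(x: int) -> int:
    """Mix a 64-bit integer through the SplitMix64 finalizer."""
    z = (x + _GAMMA) & MASK64
    z = ((z ^ (z >> 30)) * _MIX1) & MASK64
    z = ((z ^ (z >> 27)) * _MIX2) & MASK64
    return (z ^ (z >> 31)) & MASK64


def splitmix64_np(x: np.ndarray) -> np.ndarray:
    """Vectorized :func:`splitmix64` over a uint64 array (bit-identical)."""
    z = (x + np.uint64(_GAMMA)).astype(np.uint64, copy=False)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(_MIX1)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(_MIX2)
    return z ^ (z >> np.uint64(31))


def fnv1a64(data: bytes) -> int:
    """FNV-1a 64-bit hash of a byte string."""
    h = _FNV_OFFSET
    for b in data:
        h = ((h ^ b) * _FNV_PRIME) & MASK64
    return h


def fnv1a64_u64le_np(x: np.ndarray) -> np.ndarray:
    """FNV-1a of each uint64 in *x* serialized as 8 little-endian bytes.

    Bit-identical to ``fnv1a64(int(v).to_bytes(8, "little"))``.
    """
    h = np.full(x.shape, _FNV_OFFSET, dtype=np.uint64)
    prime = np.uint64(_FNV_PRIME)
    for i in range(8):
        byte = (x >> np.uint64(8 * i)) & np.uint64(0xFF)
        h = (h ^ byte) * prime
    return h


def hash_bytes(key: bytes, seed: int) -> int:
    """Seeded 64-bit hash of an arbitrary byte-string key."""
    return splitmix64(fnv1a64(key) ^ splitmix64(seed & MASK64))


def hash_u64_np(codes: np.ndarray, seed: int) -> np.ndarray:
    """Seeded hash of uint64 codes; equals :func:`hash_bytes` on the
    8-byte little-endian serialization of each code."""
    s = np.uint64(splitmix64(seed & MASK64))
    return splitmix64_np(fnv1a64_u64le_np(codes) ^ s)


def mix_u64(x: int, seed: int) -> int:
    """Seeded mix of a 64-bit value (scalar)."""
    return splitmix64(x ^ splitmix64(seed & MASK64))


def mix_u64_np(x: np.ndarray, seed: int) -> np.ndarray:
    """Seeded mix of uint64 values (vectorized, bit-identical to scalar)."""
    s = np.uint64(splitmix64(seed & MASK64))
    return splitmix64_np(x ^ s)
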