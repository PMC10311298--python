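"""Generic minimal perfect hashing over distinct byte-string keys.

The construction is the classic multi-level collision-cascading scheme
(BBHash-style): level l allocates a bitmap of gamma * (keys still active)
bits; every active key hashes to one bit, keys that land alone keep that
bit and leave, colliding keys cascade to level l+1 with a fresh level
seed. A key's final value is the rank of its bit among all set bits, in
level order, which is a bijection onto [0..n-1]. The few keys still
active after the last level go into an explicit remainder table, which
guarantees termination.

Keys are first reduced to 64-bit fingerprints ("bases"); if two distinct
keys ever share a base (probability ~ n^2 / 2^64), the whole construction
deterministically re-derives a new base seed and retries, so evaluation
on the construction set is always a true bijection. Evaluating a key
outside the set returns an arbitrary value in [0..n-1], as the MPHF
contract allows.

Expected space with the default gamma = 2 is ~4 bits/key — deliberately
plain; the index treats the inner MPHF as a pluggable component whose
only obligations are the bijection and a reported bits/key cost.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from . import _hashing
from ._serial import ByteReader, ByteWriter
from .errors import FormatError, InputError
from .succinct import RankBitVector

__all__ = ["Mphf", "mphf_build", "mphf_eval"]

_DEFAULT_GAMMA = 2.0
_MAX_LEVELS = 32
_MAX_BASE_ATTEMPTS = 64


def _base_seed(seed: int, attempt: int) -> int:
    return _hashing.splitmix64((seed & _hashing.MASK64) ^ (0xB0A5 + attempt))


def _level_seed(seed: int, level: int) -> int:
    return _hashing.splitmix64((seed & _hashing.MASK64) ^ (0x1E7E1 * (level + 1)))


class Mphf:
    """A built minimal perfect hash function (see module docstring)."""

    def __init__(
        self,
        n_keys: int,
        seed: int,
        attempt: int,
        gamma: float,
        levels: list[RankBitVector],
        remainder: dict[int, int],
    ):
        self.n_keys = n_keys
        self.seed = seed
        self._attempt = attempt
        self.gamma = gamma
        self.levels = levels
        self.level_offsets = np.concatenate(
            ([0], np.cumsum([lv.n_ones for lv in levels]))
        ).astype(np.int64)
        self.remainder = remainder

    # -- evaluation ---------------------------------------------------------

    def eval_bytes(self, key: bytes) -> int:
        base = _hashing.hash_bytes(key, _base_seed(self.seed, self._attempt))
        return self._eval_base(base)

    def _eval_base(self, base: int) -> int:
        for l, bv in enumerate(self.levels):
            pos = _hashing.mix_u64(base, _level_seed(self.seed, l)) % bv.n_bits
            if bv.get_bit(pos):
                return int(self.level_offsets[l]) + bv.rank1(pos)
        if base in self.remainder:
            return self.remainder[base]
        return _hashing.splitmix64(base) % self.n_keys

    def eval_u64(self, code: int) -> int:
        """Evaluate on a key given as its 8-byte little-endian uint64 form."""
        base = _hashing.hash_u64_np(
            np.asarray([code], dtype=np.uint64), _base_seed(self.seed, self._attempt)
        )
        return self._eval_base(int(base[0]))

    def eval_u64_many(self, codes: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`eval_u64` over a uint64 array."""
        codes = np.asarray(codes, dtype=np.uint64)
        bases = _hashing.hash_u64_np(codes, _base_seed(self.seed, self._attempt))
        out = np.empty(codes.size, dtype=np.int64)
        pending = np.arange(codes.size, dtype=np.int64)
        for l, bv in enumerate(self.levels):
            if pending.size == 0:
                break
            pos = (
                _hashing.mix_u64_np(bases[pending], _level_seed(self.seed, l))
                % np.uint64(bv.n_bits)
            ).astype(np.int64)
            hit = (bv._padded[pos >> 6] >> (pos & 63).astype(np.uint64)) & np.uint64(1)
            hit = hit.astype(bool)
            found = pending[hit]
            out[found] = self.level_offsets[l] + bv.rank1_many(pos[hit])
            pending = pending[~hit]
        for i in pending:
            b = int(bases[i])
            out[i] = self.remainder.get(b, _hashing.splitmix64(b) % self.n_keys)
        return out

    # -- reporting ----------------------------------------------------------

    def total_bits(self) -> int:
        level_bits = sum(bv.bits() for bv in self.levels)
        # remainder entries: 64-bit fingerprint + a value in [0..n)
        value_bits = max(1, (self.n_keys - 1).bit_length()) if self.n_keys else 1
        return level_bits + len(self.remainder) * (64 + value_bits)

    @property
    def bits_per_key(self) -> float:
        return self.total_bits() / self.n_keys

    # -- serialization ------------------------------------------------------

    def write(self, w: ByteWriter) -> None:
        w.u64(self.n_keys)
        w.u64(self.seed & _hashing.MASK64)
        w.u32(self._attempt)
        w.u32(int(self.gamma * 1000))
        w.u32(len(self.levels))
        for bv in self.levels:
            bv.write(w)
        w.u64(len(self.remainder))
        items = sorted(self.remainder.items())
        w.u64_array(np.asarray([k for k, _ in items], dtype=np.uint64))
        w.u64_array(np.asarray([v for _, v in items], dtype=np.uint64))

    @classmethod
    def read(cls, r: ByteReader) -> "Mphf":
        n_keys = r.u64("mphf n_keys")
        seed = r.u64("mphf seed")
        attempt = r.u32("mphf attempt")
        gamma = r.u32("mphf gamma") / 1000.0
        n_levels = r.u32("mphf level count")
        if n_levels > _MAX_LEVELS:
            raise FormatError(f"implausible level count {n_levels} at offset {r.pos}")
        levels = [RankBitVector.read(r) for _ in range(n_levels)]
        n_rem = r.u64("mphf remainder count")
        rem_keys = r.u64_array("mphf remainder keys")
        rem_vals = r.u64_array("mphf remainder values")
        if rem_keys.size != n_rem or rem_vals.size != n_rem:
            raise FormatError(f"remainder table size mismatch at offset {r.pos}")
        remainder = {int(k): int(v) for k, v in zip(rem_keys, rem_vals)}
        return cls(n_keys, seed, attempt, gamma, levels, remainder)

    def to_bytes(self) -> bytes:
        w = ByteWriter()
        self.write(w)
        return w.getvalue()

    @classmethod
    def from_bytes(cls, data: bytes) -> "Mphf":
        r = ByteReader(data)
        out = cls.read(r)
        r.expect_end()
        return out


def _bases_for_keys(keys: Sequence[bytes], seed: int, attempt: int) -> np.ndarray:
    bs = _base_seed(seed, attempt)
    return np.fromiter(
        (_hashing.hash_bytes(k, bs) for k in keys), dtype=np.uint64, count=len(keys)
    )


def mphf_build(
    keys: Iterable[bytes],
    seed: int = 0,
    gamma: float = _DEFAULT_GAMMA,
    *,
    _precomputed_u64: np.ndarray | None = None,
) -> Mphf:
    """Build an MPHF over distinct byte-string keys.

    Deterministic for fixed (keys, seed). Duplicate keys raise
    :class:`InputError` naming one duplicate. ``_precomputed_u64`` is an
    internal fast path taking keys as a uint64 array (their 8-byte
    little-endian forms), bit-compatible with the bytes path.
    """
    if _precomputed_u64 is not None:
        codes = np.asarray(_precomputed_u64, dtype=np.uint64)
        n = codes.size
        if n == 0:
            raise InputError("cannot build an MPHF over an empty key set")
        uniq = np.unique(codes)
        if uniq.size != n:
            cnt = np.unique(codes, return_counts=True)
            dup = int(cnt[0][cnt[1] > 1][0])
            raise InputError(f"duplicate key {dup.to_bytes(8, 'little')!r}")
        base_fn = lambda attempt: _hashing.hash_u64_np(codes, _base_seed(seed, attempt))
    else:
        keys = list(keys)
        n = len(keys)
        if n == 0:
            raise InputError("cannot build an MPHF over an empty key set")
        seen: set[bytes] = set()
        for k in keys:
            if k in seen:
                raise InputError(f"duplicate key {k!r}")
            seen.add(k)
        base_fn = lambda attempt: _bases_for_keys(keys, seed, attempt)

    if gamma <= 1.0:
        raise InputError(f"gamma must exceed 1, got {gamma}")

    for attempt in range(_MAX_BASE_ATTEMPTS):
        bases = base_fn(attempt)
        if np.unique(bases).size == n:
            break
    else:  # pragma: no cover - probability ~ (n^2/2^64)^64
        raise InputError("could not find collision-free 64-bit fingerprints")

    levels: list[RankBitVector] = []
    active = bases
    for level in range(_MAX_LEVELS):
        if active.size == 0:
            break
        size = max(64, int(np.ceil(gamma * active.size / 64.0)) * 64)
        pos = (
            _hashing.mix_u64_np(active, _level_seed(seed, level)) % np.uint64(size)
        ).astype(np.int64)
        counts = np.bincount(pos, minlength=size)
        alone = counts[pos] == 1
        bits = np.zeros(size, dtype=np.uint8)
        bits[pos[alone]] = 1
        levels.append(RankBitVector(bits))
        active = active[~alone]

    placed = sum(lv.n_ones for lv in levels)
    remainder = {
        int(b): placed + i for i, b in enumerate(np.sort(active))
    }
    return Mphf(n, seed, attempt, gamma, levels, remainder)


def mphf_eval(f: Mphf, key: bytes) -> int:
    """Evaluate *f* on a byte-string key; in [0..n-1], bijective on the
    construction set, arbitrary (but in-range) elsewhere."""
    return f.eval_bytes(key)
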