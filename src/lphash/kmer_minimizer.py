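"""Random minimizers and super-k-mer decomposition.

A *random minimizer scheme* is a triple (k, m, h): the minimizer of a k-mer
is its m-mer with the smallest value under a seeded random hash h, ties
broken by taking the leftmost occurrence. A *super-k-mer* of a string is a
maximal run of consecutive k-mers that share one occurrence of the same
minimizer. Within a super-k-mer g, if the minimizer starts at (1-based)
position p1 inside the first k-mer, it starts at position p1 - i + 1 inside
the i-th k-mer, so the pair (p1, p) implicitly ranks the k-mers of g
without any string comparison. This implicit ranking is the primitive the
locality-preserving index is built on.

Super-k-mers are classified by the FL (first/last) rule into four types
according to whether the minimizer position is maximal (= w, with
w = k - m + 1) in the first k-mer and/or minimal (= 1) in the last one:
left-right-max, left-max, right-max, non-max.

All heavy operations are vectorized over numpy arrays; the public
per-k-mer functions are thin wrappers over the same code path, which keeps
the streaming and scalar results identical by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from . import _hashing
from .errors import InputError

__all__ = [
    "FlType",
    "MinimizerScheme",
    "MinimizerHit",
    "SuperKmer",
    "DensityRegimeWarning",
    "minimizer_of_kmer",
    "streaming_minimizers",
    "superkmer_decompose",
    "rank_in_superkmer",
    "classify_superkmer",
    "encode_dna",
    "decode_dna",
]

# 2-bit DNA encoding; 255 marks an invalid symbol.
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


class DensityRegimeWarning(UserWarning):
    """The minimizer length is too small for the 2/(w+1) density regime."""


class FlType(IntEnum):
    """FL-rule type of a super-k-mer.

    The integer codes (0..3) are also the symbol values stored in the
    partitioned index's type sequence, in partition order.
    """

    LEFT_RIGHT_MAX = 0
    LEFT_MAX = 1
    RIGHT_MAX = 2
    NON_MAX = 3


def encode_dna(sequence: str) -> np.ndarray:
    """Encode an A/C/G/T string (case-insensitive) to 2-bit codes.

    Raises :class:`InputError` naming the first offending position.
    """
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _ENCODE[raw]
    bad = np.flatnonzero(codes == 255)
    if bad.size:
        pos = int(bad[0])
        raise InputError(
            f"invalid symbol {sequence[pos]!r} at position {pos}: expected A, C, G or T"
        )
    return codes


def decode_dna(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_dna`."""
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class MinimizerScheme:
    """Parameters (k, m, seed) of a random minimizer scheme.

    ``w = k - m + 1`` is the number of m-mers per k-mer. The same
    (k, m, seed) always selects identical minimizers on identical input.
    A warning (never an error) is emitted when m <= (3+eps)*log4(w+1),
    the regime below which the expected density 2/(w+1) need not hold.
    """

    k: int
    m: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.m <= self.k):
            raise InputError(f"require 1 <= m <= k, got k={self.k}, m={self.m}")
        if self.m > 32:
            raise InputError(
                f"minimizer length m={self.m} > 32 not supported "
                "(m-mers are packed into one 64-bit word)"
            )
        threshold = (3 + 0.001) * math.log(self.w + 1, 4)
        if self.m <= threshold:
            warnings.warn(
                f"m={self.m} <= (3+eps)*log4(w+1) = {threshold:.3f}: the "
                "expected super-k-mer density 2/(w+1) may not hold",
                DensityRegimeWarning,
                stacklevel=2,
            )

    @property
    def w(self) -> int:
        """Number of m-mer windows per k-mer, k - m + 1."""
        return self.k - self.m + 1

    def mmer_hash(self, mmer: str) -> int:
        """Hash h(mmer) used for minimizer selection."""
        codes = encode_dna(mmer)
        if codes.size != self.m:
            raise InputError(f"expected an m-mer of length {self.m}, got {codes.size}")
        packed = _pack_codes(codes, self.m)
        return int(_hashing.mix_u64(int(packed[0]), self.seed))


@dataclass(frozen=True)
class MinimizerHit:
    """Minimizer of one k-mer: the m-mer, its 1-based start position in the
    k-mer (in [1..w]) and its hash value."""

    mmer: str
    pos: int
    hash: int


@dataclass(frozen=True)
class SuperKmer:
    """One super-k-mer of an SPSS string.

    ``start`` is the 0-based offset of the super-k-mer's first symbol in
    the string, ``length`` its symbol length, ``size = length - k + 1`` its
    number of k-mers. ``p_first``/``p_last`` are the 1-based minimizer
    start positions inside the first/last k-mer; the identity
    ``p_last = p_first - size + 1`` always holds, as does
    ``size <= p_first <= w``.
    """

    string_id: int
    start: int
    length: int
    size: int
    minimizer: str
    p_first: int
    p_last: int
    fl_type: FlType = field(compare=False)


def _pack_codes(codes: np.ndarray, m: int) -> np.ndarray:
    """Pack every length-m window of 2-bit codes into a uint64.

    Big-endian within the word: the first symbol occupies the highest
    2*m-bit slot. Doubling construction: O(log m) vectorized passes,
    no len*m intermediate.
    """
    if codes.size < m:
        return np.empty(0, dtype=np.uint64)
    c = codes.astype(np.uint64)
    span = 1
    while span < m:
        take = min(span, m - span)
        n_out = c.size - take
        mask = np.uint64((1 << (2 * take)) - 1)
        # append the `take` trailing symbols of the window `take` later
        c = (c[:n_out] << np.uint64(2 * take)) | (c[take : take + n_out] & mask)
        span += take
    return c


def _minimizer_arrays(
    codes: np.ndarray, scheme: MinimizerScheme
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-k-mer minimizer data for an encoded sequence.

    Returns ``(mcodes, mhash, abs_start)`` where ``mcodes``/``mhash`` are
    the packed codes and hashes of all m-mers (length L-m+1) and
    ``abs_start[i]`` is the 0-based start of the chosen minimizer of the
    i-th k-mer within the sequence (length L-k+1).

    ``argmin`` over each length-w window returns the first minimum, which
    realizes the leftmost tie-breaking rule.
    """
    w = scheme.w
    mcodes = _pack_codes(codes, scheme.m)
    mhash = _hashing.mix_u64_np(mcodes, scheme.seed)
    if mhash.size < w:
        raise InputError(
            f"sequence of length {codes.size} shorter than k={scheme.k}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(mhash, w)
    rel = windows.argmin(axis=1)
    abs_start = np.arange(rel.size, dtype=np.int64) + rel
    return mcodes, mhash, abs_start


def minimizer_of_kmer(kmer: str, scheme: MinimizerScheme) -> MinimizerHit:
    """Minimizer of a single k-mer: minimum-hash m-mer, leftmost on ties."""
    codes = encode_dna(kmer)
    if codes.size != scheme.k:
        raise InputError(
            f"expected a k-mer of length {scheme.k}, got length {codes.size}"
        )
    _, mhash, abs_start = _minimizer_arrays(codes, scheme)
    pos = int(abs_start[0]) + 1
    return MinimizerHit(
        mmer=kmer[pos - 1 : pos - 1 + scheme.m].upper(),
        pos=pos,
        hash=int(mhash[pos - 1]),
    )


def streaming_minimizers(sequence: str, scheme: MinimizerScheme) -> list[MinimizerHit]:
    """Minimizer of every k-mer of *sequence*, in order.

    Element i equals ``minimizer_of_kmer`` on the i-th k-mer; the whole
    sequence is processed in a few vectorized passes (amortized constant
    work per position).
    """
    codes = encode_dna(sequence)
    _, mhash, abs_start = _minimizer_arrays(codes, scheme)
    seq = sequence.upper()
    m = scheme.m
    return [
        MinimizerHit(mmer=seq[s : s + m], pos=int(s - i + 1), hash=int(mhash[s]))
        for i, s in enumerate(abs_start)
    ]


def _decompose_arrays(
    codes: np.ndarray, scheme: MinimizerScheme
) -> dict[str, np.ndarray]:
    """Array form of the super-k-mer decomposition of one encoded string.

    A new super-k-mer starts exactly when the *absolute* start position of
    the selected minimizer changes: this covers both a change of minimizer
    value and a recurrence of the same value at a different position (the
    minimizer must occur only once inside a super-k-mer).

    Returns arrays indexed by super-k-mer: ``first`` (k-mer index of the
    first k-mer), ``size``, ``p_first``, ``p_last``, ``mcode`` (packed
    minimizer), ``fl_type``.
    """
    mcodes, _, abs_start = _minimizer_arrays(codes, scheme)
    n_kmers = abs_start.size
    boundaries = np.flatnonzero(np.diff(abs_start) != 0) + 1
    first = np.concatenate(([0], boundaries)).astype(np.int64)
    size = np.diff(np.concatenate((first, [n_kmers]))).astype(np.int64)
    p_first = abs_start[first] - first + 1
    p_last = p_first - size + 1
    w = scheme.w
    fl = np.full(first.size, int(FlType.NON_MAX), dtype=np.uint8)
    left = p_last == 1
    right = p_first == w
    fl[left & right] = int(FlType.LEFT_RIGHT_MAX)
    fl[left & ~right] = int(FlType.LEFT_MAX)
    fl[~left & right] = int(FlType.RIGHT_MAX)
    return {
        "first": first,
        "size": size,
        "p_first": p_first.astype(np.int64),
        "p_last": p_last.astype(np.int64),
        "mcode": mcodes[abs_start[first]],
        "fl_type": fl,
    }


def superkmer_decompose(
    sequence: str, string_id: int, scheme: MinimizerScheme
) -> list[SuperKmer]:
    """Decompose *sequence* into its ordered super-k-mers.

    The k-mer sets of the returned super-k-mers partition the sequence's
    k-mers in order: sizes sum to ``len(sequence) - k + 1``.
    """
    codes = encode_dna(sequence)
    arrays = _decompose_arrays(codes, scheme)
    seq = sequence.upper()
    k, m = scheme.k, scheme.m
    out = []
    for first, size, p_first, p_last, fl in zip(
        arrays["first"],
        arrays["size"],
        arrays["p_first"],
        arrays["p_last"],
        arrays["fl_type"],
    ):
        first = int(first)
        size = int(size)
        p_first = int(p_first)
        mstart = first + p_first - 1
        out.append(
            SuperKmer(
                string_id=string_id,
                start=first,
                length=size + k - 1,
                size=size,
                minimizer=seq[mstart : mstart + m],
                p_first=p_first,
                p_last=int(p_last),
                fl_type=FlType(int(fl)),
            )
        )
    return out


def rank_in_superkmer(p: int, p_first: int, size: int) -> int | None:
    """Implicit rank of a k-mer inside a super-k-mer, or None.

    *p* is the 1-based minimizer start position in the query k-mer,
    *p_first* the position in the super-k-mer's first k-mer. Returns
    ``p_first - p + 1`` when that value lies in [1..size]; otherwise
    ``None`` (the k-mer cannot belong to this super-k-mer).
    """
    if p < 1 or size < 1 or p_first < size:
        raise InputError(
            f"require 1 <= size <= p_first and p >= 1, got p={p}, "
            f"p_first={p_first}, size={size}"
        )
    rank = p_first - p + 1
    if 1 <= rank <= size:
        return rank
    return None


def classify_superkmer(p_first: int, p_last: int, w: int) -> FlType:
    """FL-rule type from the first/last minimizer positions.

    left-right-max iff p_first = w and p_last = 1; left-max iff
    p_first < w and p_last = 1; right-max iff p_first = w and p_last > 1;
    non-max otherwise.
    """
    if not (1 <= p_last <= p_first <= w):
        raise InputError(
            f"require 1 <= p_last <= p_first <= w, got "
            f"p_first={p_first}, p_last={p_last}, w={w}"
        )
    if p_first == w:
        return FlType.LEFT_RIGHT_MAX if p_last == 1 else FlType.RIGHT_MAX
    return FlType.LEFT_MAX if p_last == 1 else FlType.NON_MAX
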