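"""The locality-preserving MPHF over an SPSS: build, query, persist.

Both layouts share the same skeleton. All super-k-mers of the input are
computed in one pass; an MPHF ``fm`` over the distinct minimizers assigns
each minimizer a slot; per-slot metadata then turns the implicit
in-super-k-mer rank (minimizer position arithmetic) into a global k-mer
code:

* **Unpartitioned**: a prefix-sum array ``L`` of super-k-mer sizes in
  slot order (Elias-Fano) plus the first-k-mer minimizer position ``P``
  per slot (bit-packed). A k-mer with minimizer slot i and minimizer
  position p gets code ``L[i] + P[i] - p``.
* **Partitioned**: slots carry an FL type in a wavelet tree ``R``; the
  codomain is split into four consecutive partitions (left-right-max,
  left-max, right-max, non-max). Left-right-max slots store nothing
  (size and position both equal w); left/right-max slots store only a
  size prefix-sum; non-max slots store size and position. Addressing
  within a partition uses ``j = Rank_t(i)`` on ``R``.

A minimizer shared by more than one super-k-mer is *ambiguous*: its slot
records size 0 (a size no real super-k-mer can have) and all its k-mers
are delegated to a fallback MPHF occupying the tail of the codomain
``[n_unamb..n)``. In the partitioned layout ambiguous slots are typed
right-max, whose lookup path already reads a size.

Restricted to the indexed spectrum, both layouts are bijections onto
``[0..n-1]`` and map consecutive k-mers of a super-k-mer to consecutive
codes. K-mers outside the spectrum return arbitrary in-range values (an
MPHF is not a membership structure); results are reduced modulo n so the
contractual range holds even then.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _hashing
from ._serial import ByteReader, ByteWriter
from .errors import FormatError, InputError
from .io_spss import Spss
from .kmer_minimizer import (
    FlType,
    MinimizerScheme,
    _decompose_arrays,
    _minimizer_arrays,
    encode_dna,
)
from .mphf_core import Mphf, mphf_build
from .succinct import EliasFanoSeq, PackedIntVector, WaveletTree4

__all__ = [
    "UnpartitionedIndex",
    "PartitionedIndex",
    "build_unpartitioned",
    "build_partitioned",
    "lookup_unpartitioned",
    "lookup_partitioned",
    "lookup_streaming",
    "serialize",
    "deserialize",
]

MAGIC = b"LPMH"
VERSION = 1
LAYOUT_UNPARTITIONED = 0
LAYOUT_PARTITIONED = 1

_FM_SEED_SALT = 0x5EED_F00D
_FALLBACK_SEED_SALT = 0xFA11_BACC


@dataclass
class _BuildTables:
    """Intermediate per-slot tables shared by the two layouts."""

    fm: Mphf
    size_slot: np.ndarray  # super-k-mer size per slot; 0 marks ambiguous
    p_slot: np.ndarray  # p_first per slot; filler w on ambiguous slots
    type_slot: np.ndarray  # FL type per slot; ambiguous typed RIGHT_MAX
    fallback: Mphf | None
    n: int
    n_unamb: int


def _collect_superkmers(spss: Spss, scheme: MinimizerScheme) -> dict[str, np.ndarray]:
    """Decompose every SPSS string; concatenated super-k-mer arrays."""
    parts: dict[str, list[np.ndarray]] = {
        key: [] for key in ("mcode", "size", "p_first", "fl_type", "string_id", "first")
    }
    for sid, s in enumerate(spss.strings):
        arr = _decompose_arrays(encode_dna(s), scheme)
        parts["mcode"].append(arr["mcode"])
        parts["size"].append(arr["size"])
        parts["p_first"].append(arr["p_first"])
        parts["fl_type"].append(arr["fl_type"])
        parts["first"].append(arr["first"])
        parts["string_id"].append(np.full(arr["size"].size, sid, dtype=np.int64))
    return {key: np.concatenate(v) for key, v in parts.items()}


def _build_tables(spss: Spss, scheme: MinimizerScheme) -> _BuildTables:
    if scheme.k != spss.k:
        raise InputError(f"scheme k={scheme.k} does not match SPSS k={spss.k}")
    n = spss.n
    if n < 1:
        raise InputError("empty SPSS")
    sk = _collect_superkmers(spss, scheme)
    codes = sk["mcode"]
    uniq, inverse, counts = np.unique(codes, return_inverse=True, return_counts=True)
    order = np.argsort(inverse, kind="stable")
    first_sk = order[np.cumsum(counts) - counts]  # one super-k-mer per minimizer
    ambiguous = counts > 1

    fm = mphf_build(
        None,
        seed=_hashing.mix_u64(scheme.seed, _FM_SEED_SALT),
        _precomputed_u64=uniq,
    )
    slot_of_uniq = fm.eval_u64_many(uniq)

    w = scheme.w
    n_slots = uniq.size
    size_slot = np.zeros(n_slots, dtype=np.int64)
    p_slot = np.full(n_slots, w, dtype=np.int64)
    type_slot = np.full(n_slots, int(FlType.RIGHT_MAX), dtype=np.uint8)
    un = ~ambiguous
    su, si = slot_of_uniq[un], first_sk[un]
    size_slot[su] = sk["size"][si]
    p_slot[su] = sk["p_first"][si]
    type_slot[su] = sk["fl_type"][si]
    n_unamb = int(size_slot.sum())

    fallback = None
    if n_unamb < n:
        amb_sk = np.flatnonzero(ambiguous[inverse])
        keys: list[bytes] = []
        k = scheme.k
        for j in amb_sk:
            s = spss.strings[int(sk["string_id"][j])]
            start = int(sk["first"][j])
            for i in range(int(sk["size"][j])):
                keys.append(s[start + i : start + i + k].encode("ascii"))
        fallback = mphf_build(
            keys, seed=_hashing.mix_u64(scheme.seed, _FALLBACK_SEED_SALT)
        )
    return _BuildTables(fm, size_slot, p_slot, type_slot, fallback, n, n_unamb)


class _IndexBase:
    """Query plumbing shared by both layouts."""

    scheme: MinimizerScheme
    fm: Mphf
    fallback: Mphf | None
    n: int
    n_unamb: int

    def _slot_info(self, slots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-slot (C, size): ``C = prefix + offset + p1`` so that a k-mer
        with in-k-mer minimizer position p gets code C - p. size 0 flags
        the fallback path."""
        raise NotImplementedError

    def lookup_sequence(self, sequence: str) -> np.ndarray:
        """Code of every k-mer of *sequence*, in order (streaming path).

        Consecutive k-mers sharing a minimizer occurrence form a run; fm
        and the slot arrays are consulted once per run, and codes within
        the run follow by the +1 locality rule.
        """
        seq = sequence.upper()
        codes = encode_dna(seq)
        if codes.size < self.scheme.k:
            raise InputError(
                f"query of length {codes.size} shorter than k={self.scheme.k}"
            )
        mcodes, _, abs_start = _minimizer_arrays(codes, self.scheme)
        n_kmers = abs_start.size
        boundaries = np.flatnonzero(np.diff(abs_start) != 0) + 1
        run_first = np.concatenate(([0], boundaries)).astype(np.int64)
        run_of = np.zeros(n_kmers, dtype=np.int64)
        run_of[boundaries] = 1
        run_of = np.cumsum(run_of)

        slots = self.fm.eval_u64_many(mcodes[abs_start[run_first]])
        C, size = self._slot_info(slots)

        idx = np.arange(n_kmers, dtype=np.int64)
        vals = C[run_of] - (abs_start - idx + 1)

        fb_runs = size == 0
        if np.any(fb_runs):
            k = self.scheme.k
            for i in np.flatnonzero(fb_runs[run_of]):
                key = seq[int(i) : int(i) + k].encode("ascii")
                if self.fallback is not None:
                    vals[i] = self.n_unamb + self.fallback.eval_bytes(key)
                else:
                    vals[i] = _hashing.hash_bytes(key, 0) % self.n
        return vals % self.n

    def lookup(self, kmer: str) -> int:
        """Code of a single k-mer (random-access path)."""
        if len(kmer) != self.scheme.k:
            raise InputError(
                f"expected a k-mer of length {self.scheme.k}, got {len(kmer)}"
            )
        return int(self.lookup_sequence(kmer)[0])

    # -- space accounting ---------------------------------------------------

    def _component_bits(self) -> dict[str, int]:
        raise NotImplementedError

    def space_bits(self) -> dict[str, float]:
        comp = self._component_bits()
        comp["fm"] = self.fm.total_bits()
        comp["fallback"] = self.fallback.total_bits() if self.fallback else 0
        total = sum(comp.values())
        report: dict[str, float] = dict(comp)
        report["total"] = total
        report["bits_per_kmer"] = total / self.n
        return report


@dataclass
class UnpartitionedIndex(_IndexBase):
    """Basic layout: fm + size prefix sums L + positions P + fallback."""

    scheme: MinimizerScheme
    fm: Mphf
    L: EliasFanoSeq
    P: PackedIntVector
    fallback: Mphf | None
    n: int
    n_unamb: int

    def _slot_info(self, slots):
        Lv = self.L.access_many(slots)
        Ln = self.L.access_many(slots + 1)
        return Lv + self.P.get_many(slots), Ln - Lv

    def _component_bits(self):
        return {"L": self.L.bits(), "P": self.P.bits()}

    def serialize(self, sink) -> bytes | None:
        return serialize(self, sink)


@dataclass
class PartitionedIndex(_IndexBase):
    """FL-partitioned layout: fm + type sequence R + per-type arrays."""

    scheme: MinimizerScheme
    fm: Mphf
    R: WaveletTree4
    Ll: EliasFanoSeq
    Lr: EliasFanoSeq
    Ln: EliasFanoSeq
    Pn: PackedIntVector
    kmer_totals: tuple[int, int, int, int]  # (Nlr, Nl, Nr, Nn)
    fallback: Mphf | None
    n: int
    n_unamb: int

    def _slot_info(self, slots):
        w = self.scheme.w
        Nlr, Nl, Nr, _ = self.kmer_totals
        t = self.R.access_many(slots).astype(np.int64)
        j = self.R.rank_many(t, slots + 1)  # 1-based rank including the slot
        C = np.empty(slots.size, dtype=np.int64)
        size = np.empty(slots.size, dtype=np.int64)

        m = t == int(FlType.LEFT_RIGHT_MAX)
        C[m] = j[m] * w  # prefix 0, offset (j-1)w, p1 = w
        size[m] = w

        m = t == int(FlType.LEFT_MAX)
        lo, hi = self.Ll.access_many(j[m] - 1), self.Ll.access_many(j[m])
        C[m] = Nlr + hi  # offset Ll[j-1], p1 = Ll[j]-Ll[j-1]
        size[m] = hi - lo

        m = t == int(FlType.RIGHT_MAX)
        lo, hi = self.Lr.access_many(j[m] - 1), self.Lr.access_many(j[m])
        C[m] = Nlr + Nl + lo + w  # offset Lr[j-1], p1 = w
        size[m] = hi - lo  # 0 flags an ambiguous minimizer

        m = t == int(FlType.NON_MAX)
        lo, hi = self.Ln.access_many(j[m] - 1), self.Ln.access_many(j[m])
        C[m] = Nlr + Nl + Nr + lo + self.Pn.get_many(j[m] - 1)
        size[m] = hi - lo
        return C, size

    def _component_bits(self):
        return {
            "R": self.R.bits(),
            "Ll": self.Ll.bits(),
            "Lr": self.Lr.bits(),
            "Ln": self.Ln.bits(),
            "Pn": self.Pn.bits(),
        }

    def serialize(self, sink) -> bytes | None:
        return serialize(self, sink)


def _prefix_ef(sizes: np.ndarray) -> EliasFanoSeq:
    return EliasFanoSeq(np.concatenate(([0], np.cumsum(sizes))).astype(np.int64))


def build_unpartitioned(spss: Spss, scheme: MinimizerScheme) -> UnpartitionedIndex:
    """Build the basic-layout index over a validated SPSS in one pass."""
    t = _build_tables(spss, scheme)
    width = max(1, scheme.w.bit_length())
    return UnpartitionedIndex(
        scheme=scheme,
        fm=t.fm,
        L=_prefix_ef(t.size_slot),
        P=PackedIntVector(t.p_slot, width),
        fallback=t.fallback,
        n=t.n,
        n_unamb=t.n_unamb,
    )


def build_partitioned(spss: Spss, scheme: MinimizerScheme) -> PartitionedIndex:
    """Build the FL-partitioned index over a validated SPSS in one pass."""
    t = _build_tables(spss, scheme)
    w = scheme.w
    types = t.type_slot
    is_l = types == int(FlType.LEFT_MAX)
    is_r = types == int(FlType.RIGHT_MAX)
    is_n = types == int(FlType.NON_MAX)
    n_lr = int((types == int(FlType.LEFT_RIGHT_MAX)).sum())
    Ll = _prefix_ef(t.size_slot[is_l])
    Lr = _prefix_ef(t.size_slot[is_r])
    Ln = _prefix_ef(t.size_slot[is_n])
    width = max(1, w.bit_length())
    totals = (w * n_lr, Ll.access(Ll.count - 1), Lr.access(Lr.count - 1),
              Ln.access(Ln.count - 1))
    if sum(totals) != t.n_unamb:  # pragma: no cover - internal consistency
        raise AssertionError("partition totals do not cover the unambiguous k-mers")
    return PartitionedIndex(
        scheme=scheme,
        fm=t.fm,
        R=WaveletTree4(types),
        Ll=Ll,
        Lr=Lr,
        Ln=Ln,
        Pn=PackedIntVector(t.p_slot[is_n], width),
        kmer_totals=totals,
        fallback=t.fallback,
        n=t.n,
        n_unamb=t.n_unamb,
    )


def lookup_unpartitioned(index: UnpartitionedIndex, kmer: str) -> int:
    """Code of *kmer* under the basic layout (in [0..n-1])."""
    return index.lookup(kmer)


def lookup_partitioned(index: PartitionedIndex, kmer: str) -> int:
    """Code of *kmer* under the partitioned layout (in [0..n-1])."""
    return index.lookup(kmer)


def lookup_streaming(index: _IndexBase, sequence: str) -> np.ndarray:
    """Codes of all k-mers of *sequence*, elementwise equal to per-k-mer
    lookups but with one slot resolution per minimizer run."""
    return index.lookup_sequence(sequence)


# -- persistence -------------------------------------------------------------


def serialize(index: _IndexBase, sink=None) -> bytes | None:
    """Serialize an index to *sink* (path or binary file-like); with no
    sink, return the bytes."""
    w = ByteWriter()
    w.raw(MAGIC)
    w.u16(VERSION)
    is_part = isinstance(index, PartitionedIndex)
    w.u16(LAYOUT_PARTITIONED if is_part else LAYOUT_UNPARTITIONED)
    w.u32(index.scheme.k)
    w.u32(index.scheme.m)
    w.u64(index.scheme.seed & _hashing.MASK64)
    w.u64(index.n)
    w.u64(index.n_unamb)
    index.fm.write(w)
    if is_part:
        index.R.write(w)
        index.Ll.write(w)
        index.Lr.write(w)
        index.Ln.write(w)
        index.Pn.write(w)
        for v in index.kmer_totals:
            w.u64(v)
    else:
        index.L.write(w)
        index.P.write(w)
    w.u8(1 if index.fallback is not None else 0)
    if index.fallback is not None:
        index.fallback.write(w)
    data = w.getvalue()
    if sink is None:
        return data
    if isinstance(sink, (str, Path)):
        Path(sink).write_bytes(data)
    else:
        sink.write(data)
    return None


def deserialize(source) -> UnpartitionedIndex | PartitionedIndex:
    """Load an index from a path, binary file-like or bytes."""
    if isinstance(source, (str, Path)):
        data = Path(source).read_bytes()
    elif isinstance(source, (bytes, bytearray)):
        data = bytes(source)
    else:
        data = source.read()
    r = ByteReader(data)
    magic = r.take(4, "magic")
    if magic != MAGIC:
        raise FormatError(f"bad magic {magic!r} at offset 0: not an index file")
    version = r.u16("version")
    if version != VERSION:
        raise FormatError(f"unsupported format version {version} at offset 4")
    layout = r.u16("layout")
    if layout not in (LAYOUT_UNPARTITIONED, LAYOUT_PARTITIONED):
        raise FormatError(f"unknown layout code {layout} at offset 6")
    k = r.u32("k")
    m = r.u32("m")
    seed = r.u64("seed")
    n = r.u64("n")
    n_unamb = r.u64("n_unamb")
    scheme = MinimizerScheme(k, m, seed)
    fm = Mphf.read(r)
    if layout == LAYOUT_PARTITIONED:
        R = WaveletTree4.read(r)
        Ll = EliasFanoSeq.read(r)
        Lr = EliasFanoSeq.read(r)
        Ln = EliasFanoSeq.read(r)
        Pn = PackedIntVector.read(r)
        totals = tuple(r.u64("kmer totals") for _ in range(4))
    else:
        L = EliasFanoSeq.read(r)
        P = PackedIntVector.read(r)
    has_fb = r.u8("fallback flag")
    fallback = Mphf.read(r) if has_fb else None
    r.expect_end()
    if layout == LAYOUT_PARTITIONED:
        return PartitionedIndex(scheme, fm, R, Ll, Lr, Ln, Pn, totals, fallback,
                                n, n_unamb)
    return UnpartitionedIndex(scheme, fm, L, P, fallback, n, n_unamb)
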