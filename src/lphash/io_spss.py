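"""Reading, validating, writing and synthesizing spectrum-preserving
string sets (SPSS).

An SPSS here is an ordered set of A/C/G/T strings, each of length >= k,
in which every k-mer occurs exactly once across all strings. Such sets
are produced upstream by compacted de Bruijn graph tools (e.g. unitigs or
their stitched variants); this module only consumes, checks and emulates
them. The model-level assumption that no string-end k-mer overlaps another
string's start by k-1 symbols affects only the optimality of the SPSS,
not the correctness of any index built here, and is deliberately not
validated.

The synthetic generator draws uniform random DNA and enforces k-mer
distinctness with a seen-set, which makes its output statistically match
the model under which the density and FL-type formulas are derived:
i.i.d. symbols, no repeats. Real genomes add repeats (more ambiguous
minimizers) and base composition bias, which this generator deliberately
does not emulate.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError, ValidationError
from .kmer_minimizer import _DECODE, encode_dna

__all__ = ["Spss", "read_spss", "write_spss", "synthetic_spss"]


@dataclass
class Spss:
    """A validated spectrum-preserving string set.

    ``n`` is the total number of (distinct) k-mers,
    ``sum(len(s) - k + 1 for s in strings)``.
    """

    strings: list[str]
    k: int
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ids:
            self.ids = [f"s{i + 1}" for i in range(len(self.strings))]

    @property
    def n(self) -> int:
        return sum(len(s) - self.k + 1 for s in self.strings)

    def kmers(self):
        """Yield all k-mers in SPSS order."""
        k = self.k
        for s in self.strings:
            for i in range(len(s) - k + 1):
                yield s[i : i + k]


def _kmer_codes_iter(string: str, k: int):
    """Yield (position, packed k-mer code) pairs; arbitrary k (Python ints)."""
    codes = encode_dna(string)
    mask = (1 << (2 * k)) - 1
    cur = 0
    for i, c in enumerate(codes.tolist()):
        cur = ((cur << 2) | c) & mask
        if i >= k - 1:
            yield i - k + 1, cur


def validate_spss(strings: list[str], k: int, ids: list[str] | None = None) -> None:
    """Enforce the SPSS invariants; raise :class:`ValidationError` on the
    first violation, naming the offending record and k-mer."""
    if k < 1:
        raise InputError(f"k must be positive, got {k}")
    if not strings:
        raise InputError("empty SPSS: no strings")
    ids = ids or [f"s{i + 1}" for i in range(len(strings))]
    seen: dict[int, tuple[int, int]] = {}
    for si, s in enumerate(strings):
        if len(s) < k:
            raise ValidationError(
                f"record {ids[si]!r} has length {len(s)} < k = {k}"
            )
        try:
            for pos, code in _kmer_codes_iter(s, k):
                if code in seen:
                    osi, opos = seen[code]
                    raise ValidationError(
                        f"duplicate k-mer {s[pos:pos + k]!r}: record "
                        f"{ids[osi]!r} position {opos} and record "
                        f"{ids[si]!r} position {pos}"
                    )
                seen[code] = (si, pos)
        except InputError as e:
            if isinstance(e, ValidationError):
                raise
            raise ValidationError(f"record {ids[si]!r}: {e}") from e


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def read_spss(path: str | Path, k: int, *, split_on_invalid: bool = False) -> Spss:
    """Read and validate an SPSS from a (possibly gzipped) FASTA file.

    With ``split_on_invalid`` set, each record is split at runs of
    non-A/C/G/T symbols and pieces shorter than k are dropped; otherwise
    any non-A/C/G/T symbol is a validation error.
    """
    strings: list[str] = []
    ids: list[str] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if split_on_invalid:
                piece = []
                pieces: list[str] = []
                for ch in seq:
                    if ch in "ACGT":
                        piece.append(ch)
                    elif piece:
                        pieces.append("".join(piece))
                        piece = []
                if piece:
                    pieces.append("".join(piece))
                for j, p in enumerate(pc for pc in pieces if len(pc) >= k):
                    strings.append(p)
                    ids.append(f"{rec.id}.{j + 1}")
            else:
                strings.append(seq)
                ids.append(rec.id)
    if not strings:
        raise InputError(f"no usable FASTA records in {path}")
    validate_spss(strings, k, ids)
    return Spss(strings=strings, k=k, ids=ids)


def write_spss(spss: Spss, path: str | Path) -> Path:
    """Write an SPSS to FASTA (80-column wrapped; gzip if path ends .gz)."""
    if not spss.strings:
        raise InputError("refusing to write an empty SPSS")
    path = Path(path)
    records = [
        SeqRecord(Seq(s), id=rid, description="")
        for s, rid in zip(spss.strings, spss.ids)
    ]
    try:
        if path.suffix == ".gz":
            with gzip.open(path, "wt") as fh:
                SeqIO.write(records, fh, "fasta")
        else:
            with open(path, "w") as fh:
                SeqIO.write(records, fh, "fasta")
    except OSError as e:
        raise InputError(f"cannot write SPSS to {path}: {e}") from e
    return path


def synthetic_spss(
    n_target: int, k: int, n_strings: int = 1, seed: int = 0
) -> Spss:
    """Generate a random SPSS with exactly *n_target* distinct k-mers.

    The k-mers are split as evenly as possible into *n_strings* strings,
    so the fragmentation factor is (n_strings - 1) / n_target. Symbols are
    i.i.d. uniform over {A,C,G,T}; distinctness is enforced by scanning
    with a seen-set and re-drawing any string that collides (rare while
    4^k >> n_target). Deterministic for a fixed seed.
    """
    if n_strings < 1 or n_target < n_strings:
        raise InputError(
            f"require n_target >= n_strings >= 1, got {n_target}, {n_strings}"
        )
    if 4**k < n_target:
        raise InputError(
            f"4^{k} < {n_target}: not enough distinct k-mers exist"
        )
    if 4**k < 64 * n_target:
        warnings.warn(
            f"4^k is only {4**k / n_target:.0f}x n_target: generation may be "
            "slow and heavily constrained",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    counts = np.full(n_strings, n_target // n_strings, dtype=np.int64)
    counts[: n_target % n_strings] += 1

    seen: set[int] = set()
    mask = (1 << (2 * k)) - 1
    strings: list[str] = []
    for c in counts:
        length = int(c) + k - 1
        for _ in range(1000):  # re-draw attempts per string
            bases = rng.integers(0, 4, length, dtype=np.uint8)
            codes = _string_kmer_codes(bases, k)
            if len(set(codes)) == len(codes) and seen.isdisjoint(codes):
                seen.update(codes)
                strings.append(_DECODE[bases].tobytes().decode("ascii"))
                break
            new = _sequential_string(rng, length, k, mask, seen)
            if new is not None:
                strings.append(new)
                break
        else:  # pragma: no cover - spectrum saturated
            raise InputError(
                "could not generate a collision-free string; spectrum too dense"
            )
    return Spss(strings=strings, k=k)


def _string_kmer_codes(bases: np.ndarray, k: int) -> list[int]:
    codes = []
    mask = (1 << (2 * k)) - 1
    cur = 0
    for i, b in enumerate(bases.tolist()):
        cur = ((cur << 2) | b) & mask
        if i >= k - 1:
            codes.append(cur)
    return codes


def _sequential_string(rng, length: int, k: int, mask: int, seen: set[int]) -> str | None:
    """Build one string base-by-base, avoiding any k-mer in *seen*.

    Returns None if a position admits no valid base (caller re-draws).
    Successful generation commits its k-mers to *seen*.
    """
    out = list(rng.integers(0, 4, k - 1, dtype=np.uint8).tolist())
    cur = 0
    for b in out:
        cur = ((cur << 2) | b) & mask
    local: list[int] = []
    local_set: set[int] = set()
    for _ in range(length - k + 1):
        order = rng.permutation(4)
        for b in order:
            cand = ((cur << 2) | int(b)) & mask
            if cand not in seen and cand not in local_set:
                out.append(int(b))
                cur = cand
                local.append(cand)
                local_set.add(cand)
                break
        else:
            return None
    seen.update(local)
    return _DECODE[np.asarray(out, dtype=np.uint8)].tobytes().decode("ascii")
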