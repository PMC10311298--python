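"""Closed-form predictions and empirical measurement for minimizer schemes.

The closed forms implemented here, all parametric in w = k - m + 1:

* expected super-k-mer density of a random minimizer scheme,
  ``d = 2/(w+1)`` (lower-order terms dropped), valid once the minimizer
  length clears the (3+eps)*log4(w+1) threshold;
* FL-type probabilities from the Markov-chain model of the minimizer
  position: with ``W = (1 - 1/w)/2``,

  ====================  =================
  left-right-max        W^2 + 1/w
  left-max = right-max  W(1 - W)
  non-max               W^2
  ====================  =================

  These sum to 1 exactly and satisfy p_lr - p_n = 1/w. The model treats
  the first-k-mer and last-k-mer minimizer positions of a super-k-mer as
  independent; on random sequences that approximation carries a small
  systematic bias (about +0.01 on the left-right-max fraction at w = 11)
  even though the marginal relations above hold tightly — see the
  methods note;
* the unpartitioned index space bound
  ``n * 2/(w+1) * (log2(4 (w+1)^2) + b + overhead)`` bits, where b is the
  bits/key cost of the inner MPHF (must exceed log2(e)) and ``overhead``
  stands in for all little-o terms (default 0.5, the empirical estimate
  for Rank9-style redundancy).

The measurement half quantifies how well a concrete SPSS matches the
model: the fragmentation factor alpha = (|S|-1)/n, the ambiguous-k-mer
fraction xi, the realized super-k-mer density, the FL-type census and
the locality-preservation defect epsilon = 1 - |A|/n of a built index,
where A is the set of consecutive-k-mer pairs mapped to consecutive
codes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .io_spss import Spss
from .kmer_minimizer import FlType, MinimizerScheme, _decompose_arrays, encode_dna
from .lphash_index import _IndexBase, lookup_streaming

__all__ = [
    "SchemeStats",
    "MeasuredStats",
    "expected_density",
    "fl_type_probabilities",
    "space_bound_unpartitioned",
    "fragmentation",
    "measure_epsilon",
    "measure_scheme",
    "scheme_stats",
]

_LOG2_E = math.log2(math.e)


@dataclass(frozen=True)
class SchemeStats:
    """Closed-form quantities of a random minimizer scheme with window
    count w."""

    w: int
    density: float
    eps_expected: float
    p_lr: float
    p_l: float
    p_r: float
    p_n: float
    W: float


@dataclass(frozen=True)
class MeasuredStats:
    """Empirical quantities of an SPSS under a scheme (see module doc)."""

    n: int
    n_superkmers: int
    alpha: float
    xi: float
    density: float
    type_fractions: tuple[float, float, float, float]
    eps_measured: float | None = None
    bits_total: int | None = None
    bits_per_kmer: float | None = None


def expected_density(w: int) -> float:
    """Expected super-k-mers per k-mer, 2/(w+1)."""
    if w < 1:
        raise InputError(f"w must be >= 1, got {w}")
    return 2.0 / (w + 1)


def fl_type_probabilities(w: int) -> tuple[float, float, float, float]:
    """FL-type probabilities (p_lr, p_l, p_r, p_n) for window count w.

    With W = (1 - 1/w)/2: p_lr = W^2 + 1/w, p_l = p_r = W(1-W),
    p_n = W^2. At w = 1 every super-k-mer is left-right-max.
    """
    if w < 1:
        raise InputError(f"w must be >= 1, got {w}")
    if w == 1:
        return (1.0, 0.0, 0.0, 0.0)
    W = 0.5 * (1.0 - 1.0 / w)
    p_lr = W * W + 1.0 / w
    p_side = W * (1.0 - W)
    p_n = W * W
    return (p_lr, p_side, p_side, p_n)


def space_bound_unpartitioned(
    n: int, w: int, b: float, overhead: float = 0.5
) -> float:
    """Space bound (bits) of the unpartitioned layout:
    n * 2/(w+1) * (log2(4 (w+1)^2) + b + overhead).

    *b* is the bits/key of the inner MPHF and must exceed log2(e);
    *overhead* absorbs the little-o redundancy terms (default 0.5).
    """
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    if w < 1:
        raise InputError(f"w must be >= 1, got {w}")
    if b <= _LOG2_E:
        raise InputError(f"b must exceed log2(e) = {_LOG2_E:.4f}, got {b}")
    return n * (2.0 / (w + 1)) * (math.log2(4.0 * (w + 1) ** 2) + b + overhead)


def scheme_stats(w: int) -> SchemeStats:
    """Bundle the closed forms for window count w."""
    d = expected_density(w)
    p = fl_type_probabilities(w)
    return SchemeStats(
        w=w,
        density=d,
        eps_expected=d,
        p_lr=p[0],
        p_l=p[1],
        p_r=p[2],
        p_n=p[3],
        W=0.5 * (1.0 - 1.0 / w) if w > 1 else 0.0,
    )


def fragmentation(spss: Spss) -> float:
    """Fragmentation factor alpha = (|S| - 1) / n."""
    if not spss.strings:
        raise InputError("empty SPSS")
    return (len(spss.strings) - 1) / spss.n


def measure_epsilon(index: _IndexBase, spss: Spss) -> float:
    """Measured locality defect 1 - |A|/n of *index* on *spss*.

    A is the set of consecutive k-mer pairs (within a string) whose codes
    are consecutive integers.
    """
    if index.n != spss.n:
        raise InputError(
            f"index carries n={index.n} k-mers but the SPSS has n={spss.n}"
        )
    a = 0
    for s in spss.strings:
        codes = lookup_streaming(index, s)
        a += int(np.count_nonzero(np.diff(codes) == 1))
    return 1.0 - a / spss.n


def measure_scheme(
    spss: Spss, scheme: MinimizerScheme, index: _IndexBase | None = None
) -> MeasuredStats:
    """Decompose *spss* under *scheme* and report empirical statistics.

    With an *index* built from the same SPSS and scheme, additionally
    reports measured epsilon and the index space.
    """
    codes_all = []
    sizes_all = []
    types_all = []
    for s in spss.strings:
        arr = _decompose_arrays(encode_dna(s), scheme)
        codes_all.append(arr["mcode"])
        sizes_all.append(arr["size"])
        types_all.append(arr["fl_type"])
    mcode = np.concatenate(codes_all)
    size = np.concatenate(sizes_all)
    fl = np.concatenate(types_all)
    n = spss.n
    n_sk = mcode.size

    _, inverse, counts = np.unique(mcode, return_inverse=True, return_counts=True)
    amb_sk = counts[inverse] > 1
    xi = float(size[amb_sk].sum()) / n
    unamb = ~amb_sk
    n_unamb_sk = int(unamb.sum())
    if n_unamb_sk:
        fr = tuple(
            float((fl[unamb] == int(t)).sum()) / n_unamb_sk for t in FlType
        )
    else:
        fr = (0.0, 0.0, 0.0, 0.0)

    eps = bits_total = bpk = None
    if index is not None:
        eps = measure_epsilon(index, spss)
        space = index.space_bits()
        bits_total = int(space["total"])
        bpk = float(space["bits_per_kmer"])
    return MeasuredStats(
        n=n,
        n_superkmers=n_sk,
        alpha=fragmentation(spss),
        xi=xi,
        density=n_sk / n,
        type_fractions=fr,
        eps_measured=eps,
        bits_total=bits_total,
        bits_per_kmer=bpk,
    )
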