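"""Minimizer selection, super-k-mer decomposition, implicit ranking."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lphash.errors import InputError
from lphash.kmer_minimizer import (
    DensityRegimeWarning,
    FlType,
    MinimizerScheme,
    classify_superkmer,
    decode_dna,
    minimizer_of_kmer,
    rank_in_superkmer,
    streaming_minimizers,
    superkmer_decompose,
)

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")

dna = st.text(alphabet="ACGT", min_size=31, max_size=400)


class TestScheme:
    def test_w_derivation(self):
        assert MinimizerScheme(31, 21).w == 11
        assert MinimizerScheme(13, 7).w == 7

    @pytest.mark.parametrize("k,m", [(5, 0), (5, 6), (10, 33)])
    def test_invalid_parameters_rejected(self, k, m):
        with pytest.raises(InputError):
            MinimizerScheme(k, m)

    def test_small_m_warns_not_errors(self):
        with pytest.warns(DensityRegimeWarning):
            scheme = MinimizerScheme(31, 4)
        assert scheme.w == 28

    def test_determinism_across_instances(self, random_dna):
        seq = random_dna(120)
        a = streaming_minimizers(seq, MinimizerScheme(31, 15, seed=5))
        b = streaming_minimizers(seq, MinimizerScheme(31, 15, seed=5))
        assert a == b
        c = streaming_minimizers(seq, MinimizerScheme(31, 15, seed=6))
        assert a != c  # a different seed reorders the m-mers


class TestMinimizerOfKmer:
    def test_single_window_returns_whole_kmer(self):
        hit = minimizer_of_kmer("ACGTACGT", MinimizerScheme(8, 8))
        assert (hit.mmer, hit.pos) == ("ACGTACGT", 1)

    def test_all_equal_mmers_take_leftmost(self):
        hit = minimizer_of_kmer("AAAAAAAA", MinimizerScheme(8, 4))
        assert (hit.mmer, hit.pos) == ("AAAA", 1)

    def test_matches_bruteforce_enumeration(self, rng):
        """Against explicit argmin over all w m-mer hashes, leftmost ties."""
        scheme = MinimizerScheme(31, 21, seed=99)
        for _ in range(100):
            kmer = decode_dna(rng.integers(0, 4, 31).astype(np.uint8))
            hit = minimizer_of_kmer(kmer, scheme)
            best = min(
                (scheme.mmer_hash(kmer[i : i + 21]), i + 1) for i in range(11)
            )
            assert (hit.hash, hit.pos) == best
            assert hit.mmer == kmer[hit.pos - 1 : hit.pos + 20]

    def test_invalid_input_names_position(self):
        scheme = MinimizerScheme(8, 4)
        with pytest.raises(InputError, match="position 3"):
            minimizer_of_kmer("ACGNACGT", scheme)
        with pytest.raises(InputError, match="length"):
            minimizer_of_kmer("ACGT", scheme)


class TestStreaming:
    def test_sequence_of_length_k_is_single_hit(self, random_dna):
        scheme = MinimizerScheme(31, 15, seed=1)
        seq = random_dna(31)
        assert streaming_minimizers(seq, scheme) == [minimizer_of_kmer(seq, scheme)]

    def test_elementwise_equals_per_kmer_recompute(self, random_dna):
        scheme = MinimizerScheme(31, 15, seed=3)
        seq = random_dna(200)
        hits = streaming_minimizers(seq, scheme)
        assert len(hits) == 170
        for i, hit in enumerate(hits):
            assert hit == minimizer_of_kmer(seq[i : i + 31], scheme)

    def test_constant_sequence(self):
        scheme = MinimizerScheme(31, 15, seed=0)
        for hit in streaming_minimizers("A" * 200, scheme):
            assert hit.mmer == "A" * 15
            assert hit.pos == 1

    def test_too_short_rejected(self):
        with pytest.raises(InputError, match="shorter"):
            streaming_minimizers("ACGT", MinimizerScheme(31, 15))


class TestDecomposition:
    def test_single_kmer_sequence(self, random_dna):
        scheme = MinimizerScheme(31, 15, seed=2)
        (sk,) = superkmer_decompose(random_dna(31), 7, scheme)
        assert (sk.size, sk.string_id) == (1, 7)
        assert sk.p_first == sk.p_last

    def test_length16_superkmer_with_k13_has_4_kmers(self):
        scheme = MinimizerScheme(13, 7, seed=0)
        sks = superkmer_decompose("ACGT" * 4, 0, scheme)
        total = sum(g.size for g in sks)
        assert total == 4
        for g in sks:
            assert g.length == g.size + 12

    @given(seq=dna, seed=st.integers(0, 2**32 - 1))
    def test_partition_and_position_invariants(self, seq, seed):
        """Sizes partition the k-mers; p-arithmetic and FL types hold."""
        scheme = MinimizerScheme(31, 15, seed=seed)
        sks = superkmer_decompose(seq, 0, scheme)
        assert sum(g.size for g in sks) == len(seq) - 30
        pos = 0
        for g in sks:
            assert g.start == pos
            pos += g.size
            assert 1 <= g.size <= g.p_first <= scheme.w
            assert g.p_last == g.p_first - g.size + 1
            assert g.length == g.size + 30
            assert g.fl_type == classify_superkmer(g.p_first, g.p_last, scheme.w)
            mstart = g.start + g.p_first - 1
            assert seq[mstart : mstart + 15] == g.minimizer

    def test_matches_naive_grouping_of_per_kmer_minimizers(self, random_dna):
        """Concatenated k-mer runs equal groups of identical minimizer
        occurrences from the naive per-k-mer scan."""
        scheme = MinimizerScheme(31, 15, seed=8)
        seq = random_dna(300)
        hits = streaming_minimizers(seq, scheme)
        naive_groups = []
        prev = None
        for i, hit in enumerate(hits):
            occurrence = i + hit.pos  # absolute minimizer start (1-based)
            if occurrence != prev:
                naive_groups.append([])
                prev = occurrence
            naive_groups[-1].append(i)
        sks = superkmer_decompose(seq, 0, scheme)
        assert len(sks) == len(naive_groups)
        for g, group in zip(sks, naive_groups):
            assert list(range(g.start, g.start + g.size)) == group
            # in-super-k-mer minimizer positions decrease by one per k-mer
            for j, i in enumerate(group):
                assert hits[i].pos == g.p_first - j

    def test_superkmer_density_near_2_over_w_plus_1(self):
        """On long random DNA the super-k-mer count per k-mer sits within
        4 binomial sigma of 2/(w+1)."""
        scheme = MinimizerScheme(31, 21, seed=5)
        rng = np.random.default_rng(5)
        n = 10**5
        seq = decode_dna(rng.integers(0, 4, n + 30).astype(np.uint8))
        n_sk = len(superkmer_decompose(seq, 0, scheme))
        d = 2 / (scheme.w + 1)
        sigma = math.sqrt(d * (1 - d) / n)
        assert abs(n_sk / n - d) < 4 * sigma


class TestRankInSuperkmer:
    def test_first_and_last_kmer(self):
        assert rank_in_superkmer(5, 5, 3) == 1
        assert rank_in_superkmer(3, 5, 3) == 3

    def test_exhaustive_window(self):
        expected = {5: 1, 4: 2, 3: 3}
        for p in range(1, 8):
            assert rank_in_superkmer(p, 5, 3) == expected.get(p)

    def test_precondition_violation(self):
        with pytest.raises(InputError):
            rank_in_superkmer(0, 5, 3)
        with pytest.raises(InputError):
            rank_in_superkmer(1, 2, 3)  # p_first < size


class TestClassify:
    @pytest.mark.parametrize(
        "p_first,p_last,w,expected",
        [
            (7, 1, 7, FlType.LEFT_RIGHT_MAX),
            (5, 1, 7, FlType.LEFT_MAX),
            (7, 3, 7, FlType.RIGHT_MAX),
            (4, 2, 7, FlType.NON_MAX),
            (1, 1, 1, FlType.LEFT_RIGHT_MAX),
        ],
    )
    def test_reference_cases(self, p_first, p_last, w, expected):
        assert classify_superkmer(p_first, p_last, w) == expected

    def test_every_pair_gets_exactly_one_type(self):
        w = 7
        for p_first in range(1, w + 1):
            for p_last in range(1, p_first + 1):
                t = classify_superkmer(p_first, p_last, w)
                assert isinstance(t, FlType)

    def test_rejects_inconsistent_positions(self):
        with pytest.raises(InputError):
            classify_superkmer(3, 5, 7)
        with pytest.raises(InputError):
            classify_superkmer(8, 1, 7)
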