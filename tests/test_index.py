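"""Both index layouts: bijectivity, locality, fallback, persistence."""

import numpy as np
import pytest

from lphash.errors import FormatError, InputError
from lphash.io_spss import Spss, synthetic_spss
from lphash.kmer_minimizer import FlType, MinimizerScheme, superkmer_decompose
from lphash.lphash_index import (
    build_partitioned,
    build_unpartitioned,
    deserialize,
    lookup_partitioned,
    lookup_streaming,
    lookup_unpartitioned,
    serialize,
)

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


def _all_codes(index, spss):
    return np.concatenate([lookup_streaming(index, s) for s in spss.strings])


@pytest.fixture(scope="module")
def built():
    """One SPSS with both layouts, minimizers short enough to force some
    ambiguity."""
    spss = synthetic_spss(20_000, 31, n_strings=3, seed=11)
    scheme = MinimizerScheme(31, 9, seed=7)
    return (
        spss,
        scheme,
        build_unpartitioned(spss, scheme),
        build_partitioned(spss, scheme),
    )


class TestBuildUnpartitioned:
    def test_single_kmer_spss(self):
        spss = Spss(strings=["ACGTACGTACG"], k=11)
        index = build_unpartitioned(spss, MinimizerScheme(11, 5, seed=0))
        assert index.n == 1
        assert index.fm.n_keys == 1
        assert [index.L.access(i) for i in range(2)] == [0, 1]
        assert lookup_unpartitioned(index, "ACGTACGTACG") == 0

    def test_kmer_conservation(self):
        spss = synthetic_spss(470, 31, 1, seed=23)
        index = build_unpartitioned(spss, MinimizerScheme(31, 15, seed=1))
        fallback_keys = index.fallback.n_keys if index.fallback else 0
        assert index.L.access(index.L.count - 1) + fallback_keys == 470

    def test_ambiguous_minimizer_slot_is_zero_and_feeds_fallback(self, built):
        spss, scheme, ui, _ = built
        assert ui.n_unamb < ui.n  # the fixture does contain ambiguity
        assert ui.fallback.n_keys == ui.n - ui.n_unamb
        sizes = np.diff([ui.L.access(i) for i in range(ui.L.count)])
        n_zero_slots = int((sizes == 0).sum())
        # every ambiguous minimizer (>=2 super-k-mers) has a zero slot
        sks = [g for s in spss.strings for g in superkmer_decompose(s, 0, scheme)]
        from collections import Counter

        by_min = Counter(g.minimizer for g in sks)
        assert n_zero_slots == sum(1 for c in by_min.values() if c > 1)

    def test_mismatched_k_rejected(self):
        spss = synthetic_spss(100, 31, 1, seed=0)
        with pytest.raises(InputError, match="does not match"):
            build_unpartitioned(spss, MinimizerScheme(21, 9, seed=0))


class TestBuildPartitioned:
    def test_single_kmer_spss_type_matches_classification(self):
        spss = Spss(strings=["ACGTACGTACG"], k=11)
        scheme = MinimizerScheme(11, 5, seed=0)
        index = build_partitioned(spss, scheme)
        (g,) = superkmer_decompose(spss.strings[0], 0, scheme)
        assert index.R.access(0) == int(g.fl_type)
        assert lookup_partitioned(index, "ACGTACGTACG") == 0

    def test_partition_totals_conserve_kmers(self, built):
        _, _, _, pi = built
        fallback_keys = pi.fallback.n_keys if pi.fallback else 0
        assert sum(pi.kmer_totals) + fallback_keys == pi.n

    def test_types_in_R_match_superkmer_classification(self, built):
        spss, scheme, _, pi = built
        sks = [g for s in spss.strings for g in superkmer_decompose(s, 0, scheme)]
        from collections import Counter

        by_min = Counter(g.minimizer for g in sks)
        for g in sks:
            slot = pi.fm.eval_bytes(_pack_mmer(g.minimizer))
            expected = (
                FlType.RIGHT_MAX if by_min[g.minimizer] > 1 else g.fl_type
            )
            assert pi.R.access(slot) == int(expected)

    def test_lr_partition_width_is_w_per_slot(self, built):
        _, scheme, _, pi = built
        n_lr = int(pi.R.counts()[int(FlType.LEFT_RIGHT_MAX)])
        assert pi.kmer_totals[0] == scheme.w * n_lr


def _pack_mmer(mmer: str) -> bytes:
    code = 0
    for c in mmer:
        code = (code << 2) | "ACGT".index(c)
    return code.to_bytes(8, "little")


class TestLookup:
    def test_minimal_perfection_both_layouts(self, built):
        spss, _, ui, pi = built
        for index in (ui, pi):
            codes = _all_codes(index, spss)
            assert sorted(codes.tolist()) == list(range(index.n))

    def test_locality_within_unambiguous_superkmers(self, built):
        spss, scheme, ui, pi = built
        from collections import Counter

        sks = [
            (sid, g)
            for sid, s in enumerate(spss.strings)
            for g in superkmer_decompose(s, sid, scheme)
        ]
        by_min = Counter(g.minimizer for _, g in sks)
        for index in (ui, pi):
            per_string = [lookup_streaming(index, s) for s in spss.strings]
            for sid, g in sks:
                if by_min[g.minimizer] > 1:
                    continue
                run = per_string[sid][g.start : g.start + g.size]
                assert np.array_equal(np.diff(run), np.ones(g.size - 1)), (
                    "codes inside a super-k-mer must be consecutive"
                )

    def test_streaming_equals_per_kmer_lookup(self, built):
        spss, _, ui, pi = built
        s = spss.strings[0][:300]
        k = 31
        for index in (ui, pi):
            st = lookup_streaming(index, s)
            rd = [index.lookup(s[i : i + k]) for i in range(len(s) - k + 1)]
            assert st.tolist() == rd

    def test_alien_kmers_in_range_and_consistent(self, built, random_dna):
        _, _, ui, pi = built
        alien = random_dna(200)
        for index in (ui, pi):
            st = lookup_streaming(index, alien)
            rd = [index.lookup(alien[i : i + 31]) for i in range(170)]
            assert st.tolist() == rd
            assert 0 <= st.min() and st.max() < index.n

    def test_fallback_codes_occupy_tail(self, built):
        spss, _, ui, pi = built
        for index in (ui, pi):
            codes = _all_codes(index, spss)
            # recompute which k-mers are ambiguous via slot sizes
            tail = codes[codes >= index.n_unamb]
            assert len(tail) == index.n - index.n_unamb

    def test_layouts_agree_on_fallback_key_count(self, built):
        _, _, ui, pi = built
        assert ui.n_unamb == pi.n_unamb
        assert (ui.fallback is None) == (pi.fallback is None)
        if ui.fallback is not None:
            assert ui.fallback.n_keys == pi.fallback.n_keys

    def test_malformed_kmer_rejected(self, built):
        _, _, ui, _ = built
        with pytest.raises(InputError):
            ui.lookup("ACGT")
        with pytest.raises(InputError):
            ui.lookup("N" * 31)


class TestDegenerate:
    def test_fully_ambiguous_input_degrades_to_fallback(self):
        spss = synthetic_spss(500, 15, 2, seed=5)
        scheme = MinimizerScheme(15, 2, seed=1)
        for build in (build_unpartitioned, build_partitioned):
            index = build(spss, scheme)
            codes = _all_codes(index, spss)
            assert sorted(codes.tolist()) == list(range(500))

    def test_w_equals_one(self):
        spss = synthetic_spss(300, 15, 1, seed=8)
        scheme = MinimizerScheme(15, 15, seed=0)  # every k-mer its own window
        index = build_partitioned(spss, scheme)
        codes = _all_codes(index, spss)
        assert sorted(codes.tolist()) == list(range(300))
        # all types left-right-max in the degenerate w = 1 case
        assert pytest.approx(1.0) == pi_fraction(index, FlType.LEFT_RIGHT_MAX)


def pi_fraction(index, t):
    counts = index.R.counts()
    return counts[int(t)] / counts.sum()


class TestPersistence:
    def test_round_trip_identical_lookups(self, built):
        spss, _, ui, pi = built
        for index in (ui, pi):
            clone = deserialize(serialize(index))
            for s in spss.strings[:2]:
                assert np.array_equal(
                    lookup_streaming(clone, s), lookup_streaming(index, s)
                )

    def test_build_is_byte_deterministic(self, built):
        spss, scheme, _, pi = built
        assert serialize(build_partitioned(spss, scheme)) == serialize(pi)

    def test_truncated_file_reports_offset(self, built, tmp_path):
        _, _, ui, _ = built
        blob = serialize(ui)
        with pytest.raises(FormatError, match="offset"):
            deserialize(blob[: len(blob) // 2])

    def test_bad_magic_and_version(self, built):
        _, _, ui, _ = built
        blob = bytearray(serialize(ui))
        tampered = b"XXXX" + bytes(blob[4:])
        with pytest.raises(FormatError, match="magic"):
            deserialize(tampered)
        versioned = bytes(blob[:4]) + (99).to_bytes(2, "little") + bytes(blob[6:])
        with pytest.raises(FormatError, match="version"):
            deserialize(versioned)

    def test_file_round_trip(self, built, tmp_path):
        _, _, _, pi = built
        path = tmp_path / "index.lph"
        serialize(pi, path)
        clone = deserialize(path)
        assert clone.n == pi.n


class TestSpace:
    def test_partitioned_smaller_than_unpartitioned(self, built):
        _, _, ui, pi = built
        assert pi.space_bits()["total"] < ui.space_bits()["total"]

    def test_report_components_sum_to_total(self, built):
        _, _, ui, pi = built
        for index in (ui, pi):
            rep = index.space_bits()
            parts = [v for key, v in rep.items()
                     if key not in ("total", "bits_per_kmer")]
            assert sum(parts) == rep["total"]
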