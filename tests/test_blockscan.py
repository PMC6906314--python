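"""Triplet block detection, IUPAC difference conventions, p-values, dating."""
import numpy as np
import pytest

from introscan import blockscan
from introscan.blockscan import Block, TripletScanParams
from introscan.io_core import IntroscanError, Region
from introscan.simgenomes import SpeciesTree


class TestPairDifferences:
    @pytest.mark.parametrize("a,b,expected", [
        (b"A", b"A", 0.0),
        (b"A", b"T", 1.0),
        (b"R", b"A", 0.5),   # ambiguity vs contained base
        (b"R", b"R", 0.0),   # identical codes
        (b"R", b"Y", 1.0),   # disjoint allele sets
        (b"R", b"S", 0.5),   # overlapping sets
    ])
    def test_conventions(self, a, b, expected):
        d = blockscan.pair_differences(
            np.frombuffer(a, dtype="S1"), np.frombuffer(b, dtype="S1")
        )
        assert d[0] == expected

    def test_masked_is_nan(self):
        d = blockscan.pair_differences(
            np.frombuffer(b"N", dtype="S1"), np.frombuffer(b"A", dtype="S1")
        )
        assert np.isnan(d[0])

    def test_length_mismatch(self):
        with pytest.raises(IntroscanError):
            blockscan.pair_differences(
                np.frombuffer(b"AA", dtype="S1"), np.frombuffer(b"A", dtype="S1")
            )


class TestBlockPValue:
    def test_closed_form_zero_diffs(self):
        # P(X = 0) for Binomial(100, 0.05) = 0.95^100
        assert blockscan.block_p_value(0, 100, 0.05) == pytest.approx(0.95 ** 100)

    def test_expected_value_is_central(self):
        assert blockscan.block_p_value(50, 1_000, 0.05) >= 0.5

    def test_full_support(self):
        assert blockscan.block_p_value(100, 100, 0.05) == pytest.approx(1.0)

    def test_degenerate_background(self):
        with pytest.raises(IntroscanError):
            blockscan.block_p_value(0, 10, 0.0)


class TestDateBlock:
    def test_clock_arithmetic(self):
        assert blockscan.date_block(8, 1_000, 0.2e-8) == pytest.approx(2_000_000)

    def test_zero_diffs(self):
        assert blockscan.date_block(0, 1_000) == 0.0

    def test_scale_invariance(self):
        a = blockscan.date_block(13, 4_000)
        b = blockscan.date_block(26, 8_000)
        assert a == pytest.approx(b)


def _block(pair, n_snps=50, p=1e-9, triplet=("major", "crossleyi", "medius")):
    return Block(
        triplet=triplet, pair=pair, region=Region("s1", 0, 1_000),
        n_snps_in_block=n_snps, pair_diffs=5, block_len=1_000,
        divergence=0.005, p_value=p, age_years=1.25e6,
    )


class TestFilterBlocks:
    @pytest.fixture()
    def tree(self):
        return SpeciesTree(
            ((("major", "crossleyi", 1.5e6), "medius", 2.5e6), "sibreei", 4.5e6)
        )

    def test_snp_count_filter(self, tree):
        kept = blockscan.filter_blocks(
            [_block(("major", "medius"), n_snps=9)], TripletScanParams(), tree
        )
        assert kept == []

    def test_p_value_filter(self, tree):
        kept = blockscan.filter_blocks(
            [_block(("major", "medius"), p=1e-5)], TripletScanParams(), tree
        )
        assert kept == []

    def test_sister_pair_removed(self, tree):
        kept = blockscan.filter_blocks(
            [_block(("major", "crossleyi")), _block(("major", "medius"))],
            TripletScanParams(), tree,
        )
        assert [b.pair for b in kept] == [("major", "medius")]

    def test_unresolvable_triplet_errors(self, tree):
        bad = _block(("major", "medius"), triplet=("major", "nope", "medius"))
        with pytest.raises(IntroscanError):
            blockscan.filter_blocks([bad], TripletScanParams(), tree)


class TestScanTriplet:
    def test_identical_sequences_no_blocks(self):
        seq = np.full(5_000, b"A", dtype="S1")
        out = blockscan.scan_triplet({"a": seq, "b": seq.copy(), "c": seq.copy()})
        assert out == []

    def test_mutually_equidistant_no_blocks(self):
        # every position differs for every pair -> permanent three-way tie
        n = 50_000
        a = np.full(n, b"A", dtype="S1")
        b = np.full(n, b"C", dtype="S1")
        c = np.full(n, b"G", dtype="S1")
        assert blockscan.scan_triplet({"a": a, "b": b, "c": c}) == []

    @staticmethod
    def _triplet_with_tract(seed, lo, hi):
        """Sisters a,b (closer to each other) and c; a c-segment copied into b."""
        rng = np.random.default_rng(seed)
        n = 60_000
        bases = np.frombuffer(b"ACGT", dtype="S1")
        anc = bases[rng.integers(0, 4, n)]

        def mutate(seq, rate):
            s = seq.copy()
            hit = rng.random(n) < rate
            s[hit] = bases[rng.integers(0, 4, hit.sum())]
            return s

        ab_anc = mutate(anc, 0.03)
        a = mutate(ab_anc, 0.03)
        b = mutate(ab_anc, 0.03)
        c = mutate(anc, 0.06)
        b[lo:hi] = c[lo:hi]  # planted donor copy into b
        return a, b, c

    def test_planted_copy_detected(self):
        a, b, c = self._triplet_with_tract(10, 20_000, 28_000)
        out = blockscan.scan_triplet({"a": a, "b": b, "c": c})
        bc = [blk for blk in out if set(blk.pair) == {"b", "c"}]
        assert bc, "planted tract not detected"
        top = max(bc, key=lambda blk: blk.region.length)
        assert top.region.start < 21_000 and top.region.end > 27_000
        assert top.p_value < 1e-6
        assert top.divergence < 0.01

    def test_explicit_background_pair_matches_inferred(self):
        a, b, c = self._triplet_with_tract(11, 20_000, 28_000)
        auto = blockscan.scan_triplet({"a": a, "b": b, "c": c})
        explicit = blockscan.scan_triplet({"a": a, "b": b, "c": c},
                                          background_pair=("a", "b"))
        assert [blk.region for blk in auto] == [blk.region for blk in explicit]

    def test_retained_block_divergence_below_background(self):
        a, b, c = self._triplet_with_tract(12, 10_000, 16_000)
        out = blockscan.scan_triplet({"a": a, "b": b, "c": c})
        bg = np.nanmean(blockscan.pair_differences(b, c))
        assert any(set(blk.pair) == {"b", "c"} for blk in out)
        for blk in out:
            if set(blk.pair) == {"b", "c"}:
                assert blk.divergence < bg


class TestSummarize:
    def test_empty(self):
        s = blockscan.summarize_blocks([])
        assert s["n_blocks"] == 0 and s["pairs"] == {}

    def test_blocks_equal_candidates(self):
        from introscan.io_core import merge_regions

        blocks = [_block(("a", "b"))]
        blocks[0].region = Region("s1", 100, 200)
        cand = merge_regions([Region("s1", 100, 200)])
        s = blockscan.summarize_blocks(blocks, cand)
        assert s["n_fd_regions_hit"] == 1
        assert s["n_sections"] == 1
        assert s["pairs"]["a/b"]["mean_length_bp"] == 100
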