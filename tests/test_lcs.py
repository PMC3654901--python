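import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcsclust.align import align_affine
from lcsclust.lcs import compute_pm, lcs_filter, llcs_bitparallel, llcs_dp
from lcsclust.seqio import SequenceRecord
from lcsclust.synth import mutate
from oracles import llcs_brute, random_dna

dna = st.text(alphabet="ACGTN", max_size=8)


def _bits(blocks, w):
    out = 0
    for i, b in enumerate(blocks):
        out |= b << (i * w)
    return out


class TestComputePM:
    def test_position_masks_by_definition(self, rec):
        pm = compute_pm(rec("ACCA"))
        w = pm.w
        assert _bits(pm.masks[0], w) == 0b1001  # A at 0 and 3
        assert _bits(pm.masks[1], w) == 0b0110  # C at 1 and 2
        assert _bits(pm.masks[2], w) == 0
        assert _bits(pm.masks[3], w) == 0

    def test_homopolymer(self, rec):
        pm = compute_pm(rec("AAAA"))
        assert _bits(pm.masks[0], pm.w) == 0b1111

    def test_n_set_in_no_mask(self, rec):
        pm = compute_pm(rec("ANG"))
        union = 0
        for c in range(4):
            for c2 in range(c + 1, 4):
                assert _bits(pm.masks[c], pm.w) & _bits(pm.masks[c2], pm.w) == 0
            union |= _bits(pm.masks[c], pm.w)
        assert union == 0b101

    def test_masks_partition_non_n_positions(self, rng, rec):
        seq = random_dna(rng, 200, "ACGTN")
        pm = compute_pm(rec(seq), w=64)
        union = 0
        for c in range(4):
            v = _bits(pm.masks[c], pm.w)
            assert union & v == 0
            union |= v
        expected = sum(1 << i for i, ch in enumerate(seq) if ch != "N")
        assert union == expected


class TestLLCS:
    def test_worked_example(self, rec):
        assert llcs_dp("ATCAGTC", "CTAGAC") == 4  # "TAGC"
        pm = compute_pm(rec("ATCAGTC"))
        assert llcs_bitparallel(pm, "CTAGAC") == 4

    def test_empty_and_identical(self, rec):
        assert llcs_dp("ACGT", "") == 0
        assert llcs_dp("", "ACGT") == 0
        assert llcs_dp("ACGT", "ACGT") == 4

    @given(x=dna, y=dna)
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_dp_equals_subsequence_enumeration(self, x, y):
        assert llcs_dp(x, y) == llcs_brute(x, y)

    @given(x=dna, y=dna, w=st.sampled_from([1, 3, 8, 64]))
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_bitparallel_equals_dp_short(self, x, y, w):
        pm = compute_pm(SequenceRecord("x", x), w=w)
        assert llcs_bitparallel(pm, y) == llcs_dp(x, y)

    @pytest.mark.parametrize("w", [64, 17])
    def test_bitparallel_equals_dp_across_blocks(self, rng, rec, w):
        for _ in range(300):
            x = random_dna(rng, int(rng.integers(1, 321)), "ACGTN")
            y = random_dna(rng, int(rng.integers(1, 321)), "ACGTN")
            pm = compute_pm(rec(x), w=w)
            assert llcs_bitparallel(pm, y) == llcs_dp(x, y)

    def test_self_lcs_is_length(self, rng, rec):
        for _ in range(100):
            x = random_dna(rng, int(rng.integers(1, 321)))
            assert llcs_bitparallel(compute_pm(rec(x)), x) == len(x)

    def test_symmetry_and_length_bound(self, rng):
        for _ in range(100):
            x = random_dna(rng, int(rng.integers(1, 100)), "ACGTN")
            y = random_dna(rng, int(rng.integers(1, 100)), "ACGTN")
            v = llcs_dp(x, y)
            assert v == llcs_dp(y, x)
            assert v <= min(len(x), len(y))


class TestLCSFilter:
    def test_worked_example_fails_high_threshold(self, rec):
        # LLCS = 4, shorter length 6: 0.667 < 0.9
        assert not lcs_filter(rec("ATCAGTC"), rec("CTAGAC"), 0.9)

    def test_identical_pass_any_threshold(self, rec):
        for s in (0.5, 0.9, 1.0):
            assert lcs_filter(rec("ACGTACGT"), rec("ACGTACGT"), s)

    def test_identity_upper_bound_no_false_negatives(self, rng, rec):
        # every pair whose alignment identity reaches s must pass the filter
        for _ in range(300):
            seed = random_dna(rng, 120)
            q = rec(mutate(seed, rng.uniform(0, 0.15), rng.uniform(0, 0.02), rng))
            r = rec(seed)
            ident = align_affine(q, r).identity
            for s in (0.8, 0.9, 0.95):
                if ident >= s:
                    assert lcs_filter(q, r, s)

    def test_degenerate_empty_fails(self, rec):
        assert not lcs_filter(rec(""), rec("ACGT"), 0.9)
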