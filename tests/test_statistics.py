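import numpy as np
import pytest

import oracles
from coevocontact.errors import NoColumnsRemainError
from coevocontact.msa_io import N_STATES, make_alignment
from coevocontact.statistics import (
    build_covariance,
    frequency_tables,
    gap_frequencies,
    gap_mask,
    pair_frequencies,
    single_frequencies,
)
from coevocontact.weighting import compute_weights
from conftest import random_alignment

A = 0  # code of 'A'
C = 1  # code of 'C'


def tables_for(rng, M=12, L=6, pseudocnt=1.0, pw=0.0, clustpc=80.0, gap_p=0.15):
    aln = random_alignment(rng, M, L, gap_p=gap_p)
    ws = compute_weights(aln, clustpc)
    return aln, ws, frequency_tables(aln, ws, pseudocnt, pw)


class TestSingleFrequencies:
    def test_single_sequence_no_pseudocount(self):
        aln = make_alignment(["AAAA"])
        ws = compute_weights(aln, 62.0)
        f1 = single_frequencies(aln, ws, 0.0, 0.0)
        assert f1[0, A] == 1.0
        assert f1[0, 1:].sum() == 0.0

    def test_large_pseudocount_limit(self):
        aln = make_alignment(["ACDE"])
        ws = compute_weights(aln, 62.0)
        f1 = single_frequencies(aln, ws, 1e12, 0.0)
        np.testing.assert_allclose(f1, 1.0 / N_STATES, atol=1e-9)

    def test_two_sequence_formula(self):
        # equal weights 1/2, lambda' = 1: f1[A] = (1/21 + 1/2) / 2
        aln = make_alignment(["A", "C"])
        ws = compute_weights(aln, 0.0)  # same cluster -> w = (1/2, 1/2), Meff = 1
        f1 = single_frequencies(aln, ws, 1.0, 0.0)
        assert f1[0, A] == pytest.approx((1 / 21 + 1 / 2) / 2, abs=1e-15)

    def test_pscount_weight_scales_by_meff(self):
        aln = make_alignment(["AAAA", "CCCC", "DDDD"])  # Meff = 3
        ws = compute_weights(aln, 90.0)
        f1_fixed = single_frequencies(aln, ws, 1.0, 0.0)     # lambda' = 1
        f1_meff = single_frequencies(aln, ws, 1.0, 1.0)      # lambda' = 3
        exp_fixed = (1 / 21 + 1) / (1 + 3)
        exp_meff = (3 / 21 + 1) / (3 + 3)
        assert f1_fixed[0, A] == pytest.approx(exp_fixed, abs=1e-15)
        assert f1_meff[0, A] == pytest.approx(exp_meff, abs=1e-15)

    def test_oracle(self, rng):
        aln, ws, t = tables_for(rng)
        f1o = oracles.single_freq(aln.encoded, ws.w, 1.0, 0.0)
        np.testing.assert_allclose(t.f1, f1o, atol=1e-12)


class TestPairFrequencies:
    def test_single_sequence(self):
        aln = make_alignment(["AC"])
        ws = compute_weights(aln, 62.0)
        f2 = pair_frequencies(aln, ws, 0.0, 0.0)
        assert f2[0, 1, A, C] == 1.0
        assert f2[0, 1].sum() == 1.0

    def test_oracle(self, rng):
        aln, ws, t = tables_for(rng)
        f2o = oracles.pair_freq(aln.encoded, ws.w, 1.0, 0.0)
        np.testing.assert_allclose(t.f2, f2o, atol=1e-12)

    @pytest.mark.parametrize("pseudocnt,pw", [(0.0, 0.0), (1.0, 0.0), (0.7, 1.0), (2.0, 0.3)])
    def test_invariants(self, rng, pseudocnt, pw):
        aln, ws, t = tables_for(rng, pseudocnt=pseudocnt, pw=pw)
        L = aln.L
        # rows of f1 sum to 1
        np.testing.assert_allclose(t.f1.sum(axis=1), 1.0, atol=1e-9)
        # marginalization to f1
        np.testing.assert_allclose(t.f2.sum(axis=3), np.broadcast_to(t.f1[:, None, :], (L, L, N_STATES)), atol=1e-9)
        # diagonal blocks
        for i in range(L):
            np.testing.assert_allclose(t.f2[i, i], np.diag(t.f1[i]), atol=0)
        # block transpose symmetry
        np.testing.assert_allclose(t.f2, t.f2.transpose(1, 0, 3, 2), atol=1e-12)


class TestGapMask:
    def test_gapth_one_masks_nothing(self):
        gapfreq = np.array([0.0, 0.5, 1.0])
        assert not gap_mask(gapfreq, 1.0, True).any()

    def test_all_gap_column_masked(self):
        aln = make_alignment(["-A", "-C", "-D"])
        ws = compute_weights(aln, 90.0)
        gf = gap_frequencies(aln, ws)
        mask = gap_mask(gf, 0.5, True)
        assert mask[0] and not mask[1]

    def test_apply_false_is_identity(self):
        gapfreq = np.array([1.0, 1.0])
        assert not gap_mask(gapfreq, 0.5, False).any()

    def test_all_masked_raises(self):
        with pytest.raises(NoColumnsRemainError):
            gap_mask(np.array([1.0, 1.0]), 0.5, True)

    def test_gap_frequency_has_no_pseudocount(self):
        aln = make_alignment(["--", "A-"])
        ws = compute_weights(aln, 0.0)
        gf = gap_frequencies(aln, ws)
        assert gf[1] == 1.0  # pseudocount would pull this below 1

    def test_bad_gapth(self):
        with pytest.raises(ValueError):
            gap_mask(np.array([0.5]), 0.0, True)


class TestBuildCovariance:
    def test_sides(self, rng):
        aln, ws, t = tables_for(rng, L=10)
        assert build_covariance(t.f1, t.f2, cov20=True).C.shape == (200, 200)
        assert build_covariance(t.f1, t.f2, cov20=False).C.shape == (210, 210)

    def test_single_sequence_diagonal_is_bernoulli_variance(self):
        aln = make_alignment(["AC"])
        ws = compute_weights(aln, 62.0)
        t = frequency_tables(aln, ws, 0.5, 0.0)
        cov = build_covariance(t.f1, t.f2, cov20=False)
        for i in range(2):
            for a in range(N_STATES):
                f = t.f1[i, a]
                assert cov.C[i * 21 + a, i * 21 + a] == pytest.approx(f * (1 - f), abs=1e-12)

    def test_independent_columns_have_small_covariance(self):
        rng = np.random.default_rng(7)
        aln = random_alignment(rng, 2000, 2, gap_p=0.0)
        ws = compute_weights(aln, 100.0, "gt")  # all weights 1
        t = frequency_tables(aln, ws, 0.0, 0.0)
        cov = build_covariance(t.f1, t.f2, cov20=False)
        off_block = cov.C[:21, 21:]
        assert np.abs(off_block).max() < 0.05

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("cov20", [True, False])
    def test_oracle(self, seed, cov20):
        rng = np.random.default_rng(seed)
        M, L = int(rng.integers(2, 30)), int(rng.integers(2, 8))
        aln = random_alignment(rng, M, L, gap_p=0.2)
        ws = compute_weights(aln, 70.0)
        t = frequency_tables(aln, ws, 1.0, 0.5)
        mask = np.zeros(L, dtype=bool)
        if L > 2:
            mask[int(rng.integers(0, L))] = True
        cov = build_covariance(t.f1, t.f2, mask, cov20)
        kept = np.where(~mask)[0]
        q = 20 if cov20 else 21
        Co = oracles.covariance(t.f1, t.f2, kept, q)
        np.testing.assert_allclose(cov.C, Co, atol=1e-10)
        np.testing.assert_array_equal(cov.column_index, kept)

    def test_symmetry_and_block_sums(self, rng):
        aln, ws, t = tables_for(rng, pseudocnt=0.0)
        cov = build_covariance(t.f1, t.f2, cov20=False)
        np.testing.assert_allclose(cov.C, cov.C.T, atol=0)
        # off-diagonal q x q blocks have vanishing row/col sums at lambda=0
        L = aln.L
        Cb = cov.C.reshape(L, 21, L, 21)
        for i in range(L):
            for j in range(L):
                if i != j:
                    np.testing.assert_allclose(Cb[i, :, j, :].sum(axis=1), 0.0, atol=1e-9)
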