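import numpy as np
import pytest

from sodnet import coupling, msa_io
from sodnet.msa_io import ALPHABET, GAP_STATE, Q

import oracles


def model_from_exact(joint: np.ndarray, lam_ratio: float = 1.0) -> coupling.FrequencyModel:
    """Embed an exact 2-site q0-state joint distribution into the full
    21-state frequency model, applying the same pseudocount convention as
    :func:`coupling.frequencies` with lambda = lam_ratio * M_eff (M_eff=1)."""
    q0 = joint.shape[0]
    lam, m_eff = lam_ratio, 1.0
    norm = lam + m_eff
    f1 = np.full((2, Q), lam / Q / norm)
    f1[0, :q0] += joint.sum(axis=1) / norm
    f1[1, :q0] += joint.sum(axis=0) / norm
    f2 = np.full((2, 2, Q, Q), lam / Q**2 / norm)
    f2[0, 1, :q0, :q0] += joint / norm
    f2[1, 0] = f2[0, 1].T
    eye = np.eye(Q)
    for i in range(2):
        f2[i, i] = eye * f1[i]
    return coupling.FrequencyModel(f1=f1, f2=f2, lam=lam)


class TestComputeWeights:
    def test_identical_sequences_share_unit_weight(self):
        aln = msa_io.from_sequences(["ACDE"] * 3)
        ws = coupling.compute_weights(aln, 0.8)
        assert np.allclose(ws.weights, 1 / 3)
        assert ws.m_eff == pytest.approx(1.0)

    def test_dissimilar_sequences_keep_weight_one(self):
        aln = msa_io.from_sequences(["ACDEF", "GHIKL", "MNPQR", "STVWY"])
        ws = coupling.compute_weights(aln, 0.8)
        assert np.allclose(ws.weights, 1.0)
        assert ws.m_eff == pytest.approx(4.0)

    def test_matches_pairwise_identity_oracle(self, rng):
        rows = [
            "ACDEFGHIKL",
            "ACDEFGHIKM",  # 90% identical to row 0
            "ACDEFGHIKL",  # duplicate of row 0
            "MNPQRSTVWY",
            "MNPQRSTVWA",
            "YWVTSRQPNM",
        ]
        aln = msa_io.from_sequences(rows)
        for t in (0.7, 0.8, 0.95, 1.0):
            ws = coupling.compute_weights(aln, t)
            assert np.allclose(ws.weights, oracles.pairwise_identity_weights(rows, t))

    def test_threshold_out_of_range(self):
        aln = msa_io.from_sequences(["AC"])
        with pytest.raises(ValueError):
            coupling.compute_weights(aln, 0.0)


class TestFrequencies:
    def test_single_sequence_no_pseudocount_is_indicator(self):
        aln = msa_io.from_sequences(["ACD"])
        ws = coupling.compute_weights(aln)
        fm = coupling.frequencies(aln, ws, lam=0.0)
        for i, aa in enumerate("ACD"):
            assert fm.f1[i, ALPHABET.index(aa)] == pytest.approx(1.0)
            assert fm.f1[i].sum() == pytest.approx(1.0)

    def test_huge_pseudocount_approaches_uniform(self):
        aln = msa_io.from_sequences(["ACDE", "ACDF"])
        ws = coupling.compute_weights(aln)
        fm = coupling.frequencies(aln, ws, lam=1e6 * ws.m_eff)
        assert np.abs(fm.f1 - 1 / Q).max() < 1e-4

    def test_matches_weighted_counting_oracle(self):
        rows = ["ACDE", "ACDE", "AGHE", "TGHE"]
        aln = msa_io.from_sequences(rows)
        ws = coupling.compute_weights(aln, 0.8)
        lam = ws.m_eff
        fm = coupling.frequencies(aln, ws, lam)
        w = oracles.pairwise_identity_weights(rows, 0.8)
        m_eff = sum(w)
        # brute-force weighted counting for a few site/pair entries
        for i in range(4):
            for a_sym in "ACDEGHT":
                count = sum(wa for wa, r in zip(w, rows) if r[i] == a_sym)
                expected = (lam / Q + count) / (lam + m_eff)
                assert fm.f1[i, ALPHABET.index(a_sym)] == pytest.approx(expected)
        i, j = 0, 3
        for a_sym, b_sym in [("A", "E"), ("T", "E"), ("A", "A")]:
            count = sum(
                wa for wa, r in zip(w, rows) if r[i] == a_sym and r[j] == b_sym
            )
            expected = (lam / Q**2 + count) / (lam + m_eff)
            assert fm.f2[i, j, ALPHABET.index(a_sym), ALPHABET.index(b_sym)] == pytest.approx(expected)

    def test_distribution_invariants(self, rng):
        rows = ["".join(rng.choice(list("ACDE-"), 6)) for _ in range(8)]
        aln = msa_io.from_sequences(rows)
        ws = coupling.compute_weights(aln)
        fm = coupling.frequencies(aln, ws, lam=ws.m_eff)
        L = fm.length
        assert np.allclose(fm.f1.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(fm.f2.sum(axis=(2, 3)), 1.0, atol=1e-10)
        # marginal consistency and diagonal delta structure
        assert np.allclose(fm.f2.sum(axis=3), np.broadcast_to(fm.f1[:, None, :], (L, L, Q)), atol=1e-10)
        for i in range(L):
            assert np.allclose(fm.f2[i, i], np.diag(fm.f1[i]), atol=1e-12)

    def test_pseudocount_monotonically_flattens_sites(self):
        aln = msa_io.from_sequences(["ACDE", "ACDE", "ACDF"])
        ws = coupling.compute_weights(aln)
        devs = []
        for lam in [0.0, 0.5, 1.0, 5.0, 50.0]:
            fm = coupling.frequencies(aln, ws, lam)
            devs.append(np.abs(fm.f1 - 1 / Q).max())
        assert all(a >= b - 1e-15 for a, b in zip(devs, devs[1:]))


class TestMutualInformation:
    def test_independent_columns_zero_mi(self):
        # exact product counts: all four combinations equally represented
        rows = ["AD", "AE", "CD", "CE"]
        aln = msa_io.from_sequences(rows)
        ws = coupling.WeightSet(np.ones(4), 1.0)
        fm = coupling.frequencies(aln, ws, lam=0.0)
        mi = coupling.mutual_information(fm)
        assert abs(mi[0, 1]) < 1e-12

    def test_perfect_covariation_gives_ln2(self):
        rows = ["AD", "AD", "CE", "CE"]
        aln = msa_io.from_sequences(rows)
        ws = coupling.WeightSet(np.ones(4), 1.0)
        fm = coupling.frequencies(aln, ws, lam=0.0)
        mi = coupling.mutual_information(fm)
        assert mi[0, 1] == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_plugin_counting_oracle(self, rng):
        rows = ["".join(rng.choice(list("ACDE"), 4)) for _ in range(6)]
        aln = msa_io.from_sequences(rows)
        ws = coupling.WeightSet(np.ones(6), 1.0)
        fm = coupling.frequencies(aln, ws, lam=0.0)
        mi = coupling.mutual_information(fm)
        for i in range(4):
            for j in range(i + 1, 4):
                cols = ["".join(r[k] for r in rows) for k in (i, j)]
                assert mi[i, j] == pytest.approx(oracles.plugin_mi(*cols), abs=1e-12)
        assert np.allclose(mi, mi.T)


class TestMeanFieldCouplings:
    def test_independent_columns_give_small_couplings(self, rng):
        M = 4000
        rows = ["".join(rng.choice(list("ACDE"), 2)) for _ in range(M)]
        aln = msa_io.from_sequences(rows)
        ws = coupling.compute_weights(aln, 0.8)
        fm = coupling.frequencies(aln, ws, lam=1.0)
        e = coupling.mean_field_couplings(fm)
        # couplings are gauge-defined up to row/column offsets; compare in
        # the zero-sum gauge over the observed states
        block = e[0, 1, :4, :4]
        block = (
            block
            - block.mean(axis=0, keepdims=True)
            - block.mean(axis=1, keepdims=True)
            + block.mean()
        )
        assert np.abs(block).max() < 0.15  # sampling noise only

    def test_recovers_planted_two_site_couplings(self, rng):
        # sample M=1e4 sequences exactly from the enumerated joint
        J = np.array([[1.2, 0.0, -0.4], [0.0, 0.8, 0.2], [-0.3, 0.1, 0.6]])
        joint, _ = oracles.enumerate_two_site_potts(J)
        M = 10000
        flat = rng.choice(9, p=joint.ravel(), size=M)
        letters = "ACD"
        rows = [letters[k // 3] + letters[k % 3] for k in flat]
        aln = msa_io.from_sequences(rows)
        ws = coupling.WeightSet(np.ones(M), 1.0)
        fm = coupling.frequencies(aln, ws, lam=float(M))
        e_hat = coupling.mean_field_couplings(fm)

        # oracle: -C^{-1} assembled by explicit loops from the exact joint
        fm_exact = model_from_exact(joint, lam_ratio=1.0)
        keep = [s for s in range(Q) if s != GAP_STATE]
        r = len(keep)
        C = np.zeros((2 * r, 2 * r))
        for ii in range(2):
            for jj in range(2):
                for ai, a_s in enumerate(keep):
                    for bi, b_s in enumerate(keep):
                        C[ii * r + ai, jj * r + bi] = (
                            fm_exact.f2[ii, jj, a_s, b_s]
                            - fm_exact.f1[ii, a_s] * fm_exact.f1[jj, b_s]
                        )
        e_exact = -np.linalg.inv(C)
        block_hat = e_hat[0, 1, :3, :3]
        block_exact = e_exact[:r, r:][:3, :3]
        denom = np.linalg.norm(block_exact)
        assert np.linalg.norm(block_hat - block_exact) / denom < 0.10

    def test_coupling_tensor_exchange_symmetry(self, rng):
        rows = ["".join(rng.choice(list("ACDEF"), 5)) for _ in range(50)]
        aln = msa_io.from_sequences(rows)
        ws = coupling.compute_weights(aln)
        fm = coupling.frequencies(aln, ws, ws.m_eff)
        e = coupling.mean_field_couplings(fm)
        asym = np.abs(e - e.transpose(1, 0, 3, 2)).max()
        assert asym < 1e-8

    def test_requires_pseudocount(self):
        aln = msa_io.from_sequences(["AC", "CA"])
        ws = coupling.compute_weights(aln)
        fm = coupling.frequencies(aln, ws, lam=0.0)
        with pytest.raises(ValueError):
            coupling.mean_field_couplings(fm)


class TestDirectInformation:
    def test_zero_couplings_give_zero_di(self, rng):
        rows = ["".join(rng.choice(list("ACDE"), 3)) for _ in range(20)]
        aln = msa_io.from_sequences(rows)
        ws = coupling.compute_weights(aln)
        fm = coupling.frequencies(aln, ws, ws.m_eff)
        e = np.zeros((3, 3, Q, Q))
        di = coupling.direct_information(fm, e)
        assert np.abs(di).max() < 1e-10

    def test_two_site_di_equals_enumerated_mi(self):
        # with the true couplings and exact marginals, the fitted direct
        # distribution is the true joint, so DI = enumerated MI
        J = np.array([[1.5, -0.2, 0.0], [0.3, 0.9, -0.5], [0.0, 0.4, 1.1]])
        joint, mi_exact = oracles.enumerate_two_site_potts(J)
        fm = model_from_exact(joint, lam_ratio=0.0)
        fm.lam = 0.0
        e = np.zeros((2, 2, Q, Q))
        e[0, 1, :3, :3] = J
        e[1, 0, :3, :3] = J.T
        di = coupling.direct_information(fm, e)
        assert di[0, 1] == pytest.approx(mi_exact, abs=1e-6)

    def test_row_order_invariance(self, rng):
        rows = ["".join(rng.choice(list("ACDE"), 4)) for _ in range(30)]
        aln1 = msa_io.from_sequences(rows)
        perm = rng.permutation(len(rows))
        aln2 = msa_io.from_sequences([rows[k] for k in perm])
        s1 = coupling.compute_couplings(aln1)
        s2 = coupling.compute_couplings(aln2)
        assert np.allclose(s1.mi, s2.mi, atol=1e-10)
        assert np.allclose(s1.di, s2.di, atol=1e-10)


def test_single_sequence_alignment_rejected():
    aln = msa_io.from_sequences(["ACDE"])
    with pytest.raises(ValueError, match="2 effective sequences"):
        coupling.compute_couplings(aln)
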