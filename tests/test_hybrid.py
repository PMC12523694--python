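"""Tuning options, blending modes, and assembly of the hybrid H inverse."""

import numpy as np
import pytest

from ssgblup import (
    HybridParams,
    RelationshipMatrix,
    SingularMatrixError,
    TuningError,
    assemble_H_inverse,
    blend_G,
    build_A,
    build_A_inverse,
    extract_A22,
    read_and_renumber,
    tune_G,
)

from conftest import random_pedigree_frame
import pandas as pd


def rel(values, role, index=None):
    values = np.asarray(values, dtype=float)
    index = np.arange(1, len(values) + 1) if index is None else index
    return RelationshipMatrix(values, index, role)


def simulated_G(n=200, m=1000, seed=0):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=m)
    d = rng.binomial(2, p, size=(n, m)).astype(float)
    Z = d - 2 * p
    return rel(Z @ Z.T / (2 * np.sum(p * (1 - p))), "G")


class TestHybridParams:
    def test_defaults_are_standard(self):
        p = HybridParams()
        assert (p.beta, p.tuning, p.tau, p.omega) == (0.05, "TG2", 1.0, 1.0)
        assert p.blend_mode == "matrix"

    @pytest.mark.parametrize(
        "kw", [dict(beta=-0.1), dict(beta=1.1), dict(tuning="TG9"),
               dict(tau=0.0), dict(omega=-1.0), dict(blend_mode="x")]
    )
    def test_validation(self, kw):
        with pytest.raises(ValueError):
            HybridParams(**kw)


class TestTuning:
    def test_tg0_identity(self):
        G = simulated_G(50, 300, seed=1)
        out = tune_G(G, None, "TG0")
        np.testing.assert_array_equal(out.dense(), G.dense())

    def test_tg1_means(self):
        G = simulated_G(200, 1000, seed=2)
        out = tune_G(G, None, "TG1").dense()
        assert np.mean(np.diag(out)) == pytest.approx(1.0, abs=1e-10)
        off = (out.sum() - np.trace(out)) / (200 * 199)
        assert off == pytest.approx(0.0, abs=1e-10)

    def test_tg2_toy_linear_system(self):
        G = rel([[1.2, 0.1], [0.1, 1.1]], "G")
        A22 = rel([[1.0, 0.25], [0.25, 1.05]], "A22")
        out = tune_G(G, A22, "TG2").dense()
        assert np.mean(np.diag(out)) == pytest.approx(1.025, abs=1e-12)
        assert out[0, 1] == pytest.approx(0.25, abs=1e-12)

    def test_tg2_matches_a22_means(self):
        G = simulated_G(120, 800, seed=3)
        rng = np.random.default_rng(4)
        ped = read_and_renumber(random_pedigree_frame(300, rng))
        A = build_A(ped)
        codes = np.sort(rng.choice(np.arange(1, 301), 120, replace=False))
        A22, _ = extract_A22(A, codes)
        out = tune_G(G, A22, "TG2").dense()
        Am = A22.dense()
        assert np.mean(np.diag(out)) == pytest.approx(
            np.mean(np.diag(Am)), abs=1e-10
        )
        n = 120
        off = lambda M: (M.sum() - np.trace(M)) / (n * (n - 1))
        assert off(out) == pytest.approx(off(Am), abs=1e-10)

    def test_tg3_overall_mean(self):
        G = simulated_G(80, 500, seed=5)
        A22 = rel(np.eye(80) + 0.02, "A22")
        out = tune_G(G, A22, "TG3").dense()
        assert np.mean(out) == pytest.approx(np.mean(A22.dense()), abs=1e-10)

    def test_tg4_fst_rescale_form(self):
        G = simulated_G(60, 400, seed=6)
        A22 = rel(np.eye(60) + 0.05, "A22")
        s = float(np.mean(A22.dense()) - np.mean(G.dense()))
        out = tune_G(G, A22, "TG4").dense()
        np.testing.assert_allclose(out, (1 - s / 2) * G.dense() + s, atol=1e-12)

    def test_degenerate_constant_matrix(self):
        G = rel(np.full((4, 4), 0.7), "G")
        with pytest.raises(TuningError):
            tune_G(G, None, "TG1")


class TestBlending:
    def test_beta_one_returns_a22(self):
        G = simulated_G(30, 200, seed=7)
        A22 = rel(np.eye(30) + 0.01, "A22")
        out = blend_G(G, A22, beta=1.0)
        np.testing.assert_allclose(out.dense(), A22.dense(), atol=1e-12)

    def test_beta_zero_returns_g(self):
        G = simulated_G(30, 200, seed=8)
        A22 = rel(np.eye(30), "A22")
        out = blend_G(G, A22, beta=0.0)
        np.testing.assert_allclose(out.dense(), G.dense(), atol=1e-12)

    def test_convex_combination_toy(self):
        G = rel([[1.2, 0.3], [0.3, 1.1]], "G")
        out = blend_G(G, rel(np.eye(2), "A22"), beta=0.5)
        np.testing.assert_allclose(out.dense(), [[1.1, 0.15], [0.15, 1.05]])

    def test_beta_zero_singular_g_errors(self):
        # 3 individuals, 2 effective loci: rank-deficient G
        d = np.array([[0.0, 2.0], [2.0, 0.0], [0.0, 2.0]])
        p = d.mean(axis=0) / 2
        Z = d - 2 * p
        G = rel(Z @ Z.T / (2 * np.sum(p * (1 - p))), "G")
        with pytest.raises(SingularMatrixError, match="eigenvalue"):
            blend_G(G, rel(np.eye(3), "A22"), beta=0.0)

    def test_modes_agree_when_g_equals_a22(self):
        A22 = rel(np.array([[1.1, 0.2], [0.2, 1.3]]), "A22")
        G = rel(A22.dense().copy(), "G")
        m1 = blend_G(G, A22, 0.3, "matrix").dense()
        m2 = blend_G(G, A22, 0.3, "literal_inverse").dense()
        np.testing.assert_allclose(m1, m2, atol=1e-12)

    def test_modes_differ_otherwise(self):
        G = simulated_G(10, 100, seed=9)
        A22 = rel(np.eye(10), "A22")
        m1 = blend_G(G, A22, 0.3, "matrix").dense()
        m2 = blend_G(G, A22, 0.3, "literal_inverse").dense()
        assert np.max(np.abs(m1 - m2)) > 1e-6


def toy_system(seed=0, n=20, n_geno=6):
    rng = np.random.default_rng(seed)
    ped = read_and_renumber(random_pedigree_frame(n, rng))
    A = build_A(ped)
    Ainv = build_A_inverse(ped)
    codes = np.sort(rng.choice(np.arange(1, n + 1), n_geno, replace=False))
    A22, A22i = extract_A22(A, codes)
    Gb = A22.dense() + 0.1 * np.eye(n_geno) + 0.03
    Gb = 0.5 * (Gb + Gb.T)
    return ped, A, Ainv, A22, A22i, Gb, codes


class TestAssembleHInverse:
    def test_no_genotyped_animals(self):
        ped, A, Ainv, *_ = toy_system()
        H = assemble_H_inverse(
            Ainv, RelationshipMatrix(np.empty((0, 0)), [], "A22_inverse"),
            np.empty((0, 0)), genotyped_codes=[],
        )
        np.testing.assert_array_equal(H.dense(), Ainv.dense())

    def test_cancellation_when_gb_is_a22(self):
        ped, A, Ainv, A22, A22i, _, codes = toy_system(seed=1)
        Gb_inv = np.linalg.inv(A22.dense())
        H = assemble_H_inverse(Ainv, A22i, Gb_inv, 1.0, 1.0, codes)
        np.testing.assert_array_equal(H.dense(), Ainv.dense())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_bordered_oracle(self, seed):
        ped, A, Ainv, A22, A22i, Gb, codes = toy_system(seed=seed, n=40, n_geno=12)
        H = np.linalg.inv(
            assemble_H_inverse(
                Ainv, A22i, np.linalg.inv(Gb), 1.0, 1.0, codes
            ).dense()
        )
        # joint-distribution H: A plus the bordered correction through A12
        Ad = A.dense()
        idx = codes - 1
        A_1g = Ad[:, idx]
        K = A22i.dense()
        corr = A_1g @ K @ (Gb - A22.dense()) @ K @ A_1g.T
        np.testing.assert_allclose(H, Ad + corr, atol=1e-8)

    def test_symmetric_and_pd_at_defaults(self):
        ped, A, Ainv, A22, A22i, Gb, codes = toy_system(seed=2)
        Gb_blend = 0.95 * Gb + 0.05 * A22.dense()
        H = assemble_H_inverse(Ainv, A22i, np.linalg.inv(Gb_blend), 1.0, 1.0, codes)
        H.check_symmetric(1e-10)
        assert np.linalg.eigvalsh(H.dense()).min() > 0

    @pytest.mark.parametrize("beta", [0.5, 0.9, 1.0])
    def test_blending_toward_pedigree(self, beta):
        # as beta -> 1 the implied H approaches A
        ped, A, Ainv, A22, A22i, Gb, codes = toy_system(seed=3)
        from ssgblup.hybrid import blend_G as bg

        Gt = RelationshipMatrix(Gb, codes, "G")
        Gb_b = bg(Gt, A22, beta).dense()
        H = np.linalg.inv(
            assemble_H_inverse(Ainv, A22i, np.linalg.inv(Gb_b), 1.0, 1.0, codes).dense()
        )
        dist = np.max(np.abs(H - A.dense()))
        if beta == 1.0:
            assert dist < 1e-8
        else:
            Gb_b_lo = bg(Gt, A22, beta - 0.4).dense()
            H_lo = np.linalg.inv(
                assemble_H_inverse(
                    Ainv, A22i, np.linalg.inv(Gb_b_lo), 1.0, 1.0, codes
                ).dense()
            )
            assert dist < np.max(np.abs(H_lo - A.dense()))

    def test_tau_omega_scale_the_block(self):
        ped, A, Ainv, A22, A22i, Gb, codes = toy_system(seed=4)
        Gb_inv = np.linalg.inv(Gb)
        H = assemble_H_inverse(Ainv, A22i, Gb_inv, 0.6, 0.8, codes).dense()
        delta = H - Ainv.dense()
        idx = codes - 1
        np.testing.assert_allclose(
            delta[np.ix_(idx, idx)], 0.6 * Gb_inv - 0.8 * A22i.dense(), atol=1e-12
        )
        mask = np.ones(len(A.index), bool)
        mask[idx] = False
        assert np.abs(delta[np.ix_(mask, mask)]).max() == 0.0

    def test_out_of_range_code_errors(self):
        ped, A, Ainv, A22, A22i, Gb, codes = toy_system(seed=5)
        with pytest.raises(ValueError, match="outside"):
            assemble_H_inverse(Ainv, A22i, np.linalg.inv(Gb), 1.0, 1.0,
                               np.array([9999]))
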