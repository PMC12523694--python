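"""Repeatability-model design matrices, MME solver, and PEV accuracies."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from ssgblup import (
    DesignError,
    ModelSpec,
    RelationshipMatrix,
    SolverError,
    build_A,
    build_A_inverse,
    build_design,
    individual_accuracy,
    inbreeding,
    read_and_renumber,
    solve_mme,
)
from ssgblup.model import DesignSet

from conftest import random_pedigree_frame


def toy_records(ped, rng, n_cg=3, trait_sd=1.0):
    """Records for every female-ish animal; CG labels cycle."""
    rows = []
    labels = list(ped.labels)
    for k, a in enumerate(labels):
        for par in range(1, 1 + (k % 2) + 1):
            rows.append(
                dict(cow=a, herd=f"h{k % n_cg}", parity=par,
                     cg_id=f"cg{k % n_cg}",
                     age_months=25.0 + 12 * (par - 1) + rng.uniform(-2, 2),
                     milk_kg=float(rng.normal(0, trait_sd)))
            )
    return pd.DataFrame(rows)


def dense_gls_ebv(design, Kinv_dense, spec):
    """Independent oracle: dense normal equations of the same mixed model."""
    X = design.X.toarray()
    Z = design.Z.toarray()
    W = design.W.toarray()
    y = design.y
    lam_a = spec.sigma2_e / spec.sigma2_a
    lam_pe = spec.sigma2_e / spec.sigma2_pe
    p, na, npe = X.shape[1], Z.shape[1], W.shape[1]
    C = np.block([
        [X.T @ X, X.T @ Z, X.T @ W],
        [Z.T @ X, Z.T @ Z + lam_a * Kinv_dense, Z.T @ W],
        [W.T @ X, W.T @ Z, W.T @ W + lam_pe * np.eye(npe)],
    ])
    rhs = np.concatenate([X.T @ y, Z.T @ y, W.T @ y])
    sol = np.linalg.solve(C, rhs)
    return sol[:p], sol[p:p + na], sol[p + na:]


@pytest.fixture
def toy_setup():
    rng = np.random.default_rng(0)
    ped = read_and_renumber(random_pedigree_frame(12, rng))
    records = toy_records(ped, rng)
    spec = ModelSpec(trait="milk", sigma2_a=0.3, sigma2_pe=0.2, sigma2_e=0.5)
    return ped, records, spec


class TestBuildDesign:
    def test_repeated_records_share_rows(self, toy_setup):
        ped, records, spec = toy_setup
        design = build_design(records, ped, spec)
        cow = records["cow"].iloc[0]
        rows = np.flatnonzero((records["cow"] == cow).to_numpy())
        Z = design.Z.toarray()
        W = design.W.toarray()
        for r in rows[1:]:
            np.testing.assert_array_equal(Z[rows[0]], Z[r])
            np.testing.assert_array_equal(W[rows[0]], W[r])

    def test_reference_level_dropped(self, toy_setup):
        ped, records, spec = toy_setup
        design = build_design(records, ped, spec)
        n_cg = records["cg_id"].nunique()
        n_par = records["parity"].nunique()
        assert design.X.shape[1] == (n_cg - 1) + n_par + n_par

    def test_xtx_matches_cross_tabulation(self, toy_setup):
        ped, records, spec = toy_setup
        design = build_design(records, ped, spec)
        XtX = (design.X.T @ design.X).toarray()
        # CG-by-CG block counts records per contemporary group
        cg_levels = sorted(records["cg_id"].unique())[1:]
        for i, cg in enumerate(cg_levels):
            assert XtX[i, i] == (records["cg_id"] == cg).sum()

    def test_single_cg_errors(self, toy_setup):
        ped, records, spec = toy_setup
        records = records.assign(cg_id="only")
        with pytest.raises(DesignError, match="confounded"):
            build_design(records, ped, spec)


class TestSolveMME:
    def test_mean_only_limit(self):
        # X = intercept, Z/W carry no information: b recovers mean(y)
        rng = np.random.default_rng(1)
        y = rng.normal(5.0, 1.0, size=20)
        design = DesignSet(
            X=sparse.csr_matrix(np.ones((20, 1))),
            Z=sparse.csr_matrix((20, 3)),
            W=sparse.csr_matrix((20, 2)),
            y=y,
            fixed_labels=["mu"],
            animal_labels=np.array(["a", "b", "c"]),
            cow_labels=np.array(["a", "b"]),
        )
        Kinv = RelationshipMatrix(np.eye(3), [1, 2, 3], "A_inverse")
        spec = ModelSpec(sigma2_a=1.0, sigma2_pe=1.0, sigma2_e=1.0)
        fit = solve_mme(design, Kinv, spec)
        assert fit.fixed["mu"] == pytest.approx(y.mean(), abs=1e-10)
        assert np.allclose(fit.ebv.to_numpy(), 0.0)

    def test_matches_dense_gls_oracle(self, toy_setup):
        ped, records, spec = toy_setup
        design = build_design(records, ped, spec)
        Kinv = build_A_inverse(ped)
        fit = solve_mme(design, Kinv, spec)
        b, a, pe = dense_gls_ebv(design, Kinv.dense(), spec)
        np.testing.assert_allclose(fit.ebv.to_numpy(), a, atol=1e-8)
        np.testing.assert_allclose(fit.fixed.to_numpy(), b, atol=1e-8)

    def test_phenotype_shift_leaves_ebv(self, toy_setup):
        ped, records, spec = toy_setup
        design = build_design(records, ped, spec)
        Kinv = build_A_inverse(ped)
        fit1 = solve_mme(design, Kinv, spec)
        shifted = records.assign(milk_kg=records["milk_kg"] + 100.0)
        fit2 = solve_mme(build_design(shifted, ped, spec), Kinv, spec)
        np.testing.assert_allclose(
            fit1.ebv.to_numpy(), fit2.ebv.to_numpy(), atol=1e-8
        )

    def test_pcg_agrees_with_direct(self, toy_setup):
        ped, records, spec = toy_setup
        design = build_design(records, ped, spec)
        Kinv = build_A_inverse(ped)
        direct = solve_mme(design, Kinv, spec, method="direct")
        pcg = solve_mme(design, Kinv, spec, method="pcg", tol=1e-12)
        np.testing.assert_allclose(
            direct.ebv.to_numpy(), pcg.ebv.to_numpy(), atol=1e-6
        )

    def test_pcg_nonconvergence_raises(self, toy_setup):
        ped, records, spec = toy_setup
        design = build_design(records, ped, spec)
        Kinv = build_A_inverse(ped)
        with pytest.raises(SolverError, match="residual"):
            solve_mme(design, Kinv, spec, method="pcg", tol=1e-14, max_iter=2)

    def test_founder_ebv_centered(self):
        # founder population, mean-only fixed structure: EBVs average ~0
        rng = np.random.default_rng(3)
        n = 30
        ped = read_and_renumber(
            pd.DataFrame({"animal": [f"f{k}" for k in range(n)],
                          "sire": ["0"] * n, "dam": ["0"] * n})
        )
        y = rng.normal(10.0, 1.0, size=n)
        design = DesignSet(
            X=sparse.csr_matrix(np.ones((n, 1))),
            Z=sparse.identity(n, format="csr"),
            W=sparse.identity(n, format="csr"),
            y=y,
            fixed_labels=["mu"],
            animal_labels=ped.labels,
            cow_labels=ped.labels,
        )
        Kinv = build_A_inverse(ped)
        spec = ModelSpec(sigma2_a=0.3, sigma2_pe=0.2, sigma2_e=0.5)
        fit = solve_mme(design, Kinv, spec)
        assert abs(fit.ebv.mean()) < 1e-8

    def test_pev_and_accuracy(self, toy_setup):
        ped, records, spec = toy_setup
        design = build_design(records, ped, spec)
        Kinv = build_A_inverse(ped)
        F = inbreeding(ped)
        fit = solve_mme(design, Kinv, spec, compute_pev=True, inbreeding=F)
        assert fit.pev is not None and (fit.pev >= 0).all()
        # PEV never exceeds the prior additive variance (1+F) sigma2_a
        cap = (1 + F) * spec.sigma2_a
        assert (fit.pev.to_numpy() <= cap + 1e-8).all()
        assert fit.accuracy.between(0, 1).all()


class TestIndividualAccuracy:
    def test_arithmetic(self):
        assert individual_accuracy([0.0], [0.0], 1.0)[0] == pytest.approx(1.0)
        assert individual_accuracy([1.0], [0.0], 1.0)[0] == pytest.approx(0.0)
        assert individual_accuracy([0.36], [0.0], 1.0)[0] == pytest.approx(0.8)
        # inbreeding raises the denominator
        assert individual_accuracy([0.25], [0.25], 1.0)[0] == pytest.approx(
            np.sqrt(1 - 0.25 / 1.25)
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            individual_accuracy([0.1], [0.0], 0.0)
        with pytest.raises(ValueError):
            individual_accuracy([-0.1], [0.0], 1.0)


class TestModelSpec:
    def test_from_h2_components(self):
        spec = ModelSpec.from_h2("milk", phenotypic_var=100.0, h2=0.28,
                                 repeatability=0.45)
        assert spec.sigma2_a == pytest.approx(28.0)
        assert spec.sigma2_pe == pytest.approx(17.0)
        assert spec.sigma2_e == pytest.approx(55.0)
        assert spec.h2 == pytest.approx(0.28)

    def test_invalid_variances(self):
        with pytest.raises(ValueError):
            ModelSpec(sigma2_a=0.0)
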