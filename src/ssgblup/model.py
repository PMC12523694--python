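"""Single-trait repeatability animal model and its mixed-model equations.

The model is y = Xb + Za + W pe + e with fixed effects b (contemporary
group, parity, and a linear age-at-calving covariate nested within parity),
additive genetic effects a ~ N(0, K sigma2_a) over the full pedigree (K is
A for the pedigree model or H for single-step), permanent-environment
effects pe ~ N(0, I sigma2_pe) per cow, and residuals e ~ N(0, I sigma2_e).

Henderson's equations are assembled sparse with variance ratios
lambda_a = sigma2_e / sigma2_a and lambda_pe = sigma2_e / sigma2_pe and
solved either by sparse LU (default; enables prediction-error variances on
request) or by Jacobi-preconditioned conjugate gradients for large systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import linalg as spla

from .pedigree import PedigreeTable, RelationshipMatrix

TRAIT_COLUMNS = {"milk": "milk_kg", "protein": "protein_kg", "fat": "fat_kg"}

#: illustrative default heritabilities for the three yield traits and the
#: assumed repeatability used to split the non-genetic animal variance
DEFAULT_H2 = {"milk": 0.28, "protein": 0.21, "fat": 0.25}
DEFAULT_REPEATABILITY = 0.45


class DesignError(ValueError):
    """Confounded or unbuildable design (e.g. a single contemporary group)."""


class SolverError(RuntimeError):
    """Iterative solver failed to converge."""


@dataclass
class ModelSpec:
    """Trait and variance components for one evaluation."""

    trait: str = "milk"
    sigma2_a: float = 1.0
    sigma2_pe: float = 1.0
    sigma2_e: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sigma2_a, self.sigma2_pe, self.sigma2_e) <= 0:
            raise ValueError("variance components must be positive")

    @property
    def h2(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_pe + self.sigma2_e)

    @classmethod
    def from_h2(
        cls,
        trait: str,
        phenotypic_var: float,
        h2: float | None = None,
        repeatability: float = DEFAULT_REPEATABILITY,
    ) -> "ModelSpec":
        """Build components from heritability and repeatability.

        sigma2_a = h2 * Vp, sigma2_pe = (r - h2) * Vp, sigma2_e = (1 - r) * Vp.
        """
        h2 = DEFAULT_H2[trait] if h2 is None else h2
        if not 0 < h2 < repeatability < 1:
            raise ValueError("need 0 < h2 < repeatability < 1")
        return cls(
            trait=trait,
            sigma2_a=h2 * phenotypic_var,
            sigma2_pe=(repeatability - h2) * phenotypic_var,
            sigma2_e=(1.0 - repeatability) * phenotypic_var,
        )


@dataclass
class DesignSet:
    """Incidence structures and response for one dataset/trait."""

    X: sparse.csr_matrix
    Z: sparse.csr_matrix
    W: sparse.csr_matrix
    y: np.ndarray
    fixed_labels: list[str]
    animal_labels: np.ndarray  # pedigree external labels, code order
    cow_labels: np.ndarray     # unique cows with records (W column order)


@dataclass
class ModelFit:
    """Solutions of one mixed-model run."""

    fixed: pd.Series
    ebv: pd.Series
    pe: pd.Series
    pev: pd.Series | None = None
    accuracy: pd.Series | None = None
    solver_log: dict = field(default_factory=dict)

    def solutions_frame(self) -> pd.DataFrame:
        rows = []
        for lvl, v in self.fixed.items():
            rows.append(("fixed", lvl, v, np.nan, np.nan))
        for a, v in self.ebv.items():
            pev = self.pev.get(a, np.nan) if self.pev is not None else np.nan
            acc = self.accuracy.get(a, np.nan) if self.accuracy is not None else np.nan
            rows.append(("animal", a, v, pev, acc))
        for c, v in self.pe.items():
            rows.append(("pe", c, v, np.nan, np.nan))
        return pd.DataFrame(
            rows, columns=["effect_type", "level", "solution", "pev", "accuracy"]
        )


def build_design(
    edited: pd.DataFrame, ped: PedigreeTable, spec: ModelSpec
) -> DesignSet:
    """Sparse incidence matrices for the repeatability model.

    X holds contemporary-group dummies (first level dropped for
    identifiability), parity dummies (all levels; they span the intercept),
    and the age covariate nested within parity (centered).  Z maps records
    to pedigree internal codes over all animals; W maps records to cows.
    """
    if "cg_id" not in edited.columns:
        raise DesignError("records lack cg_id; run form_contemporary_groups first")
    ycol = TRAIT_COLUMNS.get(spec.trait, spec.trait)
    if ycol not in edited.columns:
        raise DesignError(f"no column {ycol!r} for trait {spec.trait!r}")
    nrec = len(edited)
    if nrec == 0:
        raise DesignError("no records")

    cg_levels = np.array(sorted(edited["cg_id"].unique()))
    if len(cg_levels) < 2:
        raise DesignError(
            "contemporary groups are confounded: a single level remains"
        )
    cg_pos = {c: k for k, c in enumerate(cg_levels)}
    parities = np.array(sorted(edited["parity"].unique()))
    par_pos = {p: k for k, p in enumerate(parities)}

    rows, cols, vals = [], [], []
    ncg = len(cg_levels) - 1  # reference level dropped
    npar = len(parities)
    age = edited["age_months"].to_numpy(dtype=float)
    age_c = age - age.mean()
    for r, (cg, par) in enumerate(zip(edited["cg_id"], edited["parity"])):
        k = cg_pos[cg]
        if k > 0:
            rows.append(r); cols.append(k - 1); vals.append(1.0)
        rows.append(r); cols.append(ncg + par_pos[par]); vals.append(1.0)
        rows.append(r); cols.append(ncg + npar + par_pos[par]); vals.append(age_c[r])
    p = ncg + 2 * npar
    X = sparse.coo_matrix((vals, (rows, cols)), shape=(nrec, p)).tocsr()
    fixed_labels = (
        [f"cg:{c}" for c in cg_levels[1:]]
        + [f"parity:{p_}" for p_ in parities]
        + [f"age_within_parity:{p_}" for p_ in parities]
    )

    codes = ped.code_of(edited["cow"].astype(str))
    Z = sparse.coo_matrix(
        (np.ones(nrec), (np.arange(nrec), codes - 1)), shape=(nrec, ped.n)
    ).tocsr()

    cow_labels = np.array(sorted(edited["cow"].astype(str).unique()))
    cow_pos = {c: k for k, c in enumerate(cow_labels)}
    wcols = edited["cow"].astype(str).map(cow_pos).to_numpy()
    W = sparse.coo_matrix(
        (np.ones(nrec), (np.arange(nrec), wcols)), shape=(nrec, len(cow_labels))
    ).tocsr()

    return DesignSet(
        X=X,
        Z=Z,
        W=W,
        y=edited[ycol].to_numpy(dtype=float),
        fixed_labels=fixed_labels,
        animal_labels=ped.labels,
        cow_labels=cow_labels,
    )


def _coefficient_matrix(
    design: DesignSet, K_inv: RelationshipMatrix, spec: ModelSpec
) -> tuple[sparse.csc_matrix, np.ndarray]:
    lam_a = spec.sigma2_e / spec.sigma2_a
    lam_pe = spec.sigma2_e / spec.sigma2_pe
    X, Z, W, y = design.X, design.Z, design.W, design.y
    Ki = K_inv.values if sparse.issparse(K_inv.values) else sparse.csr_matrix(K_inv.values)
    if Ki.shape[0] != Z.shape[1]:
        raise ValueError("K inverse order does not match the pedigree")
    C = sparse.bmat(
        [
            [X.T @ X, X.T @ Z, X.T @ W],
            [Z.T @ X, Z.T @ Z + lam_a * Ki, Z.T @ W],
            [W.T @ X, W.T @ Z, W.T @ W + lam_pe * sparse.eye(W.shape[1])],
        ],
        format="csc",
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y, W.T @ y])
    return C, rhs


def solve_mme(
    design: DesignSet,
    K_inv: RelationshipMatrix,
    spec: ModelSpec,
    method: str = "direct",
    tol: float = 1e-10,
    max_iter: int = 5000,
    compute_pev: bool = False,
    inbreeding: np.ndarray | None = None,
) -> ModelFit:
    """Solve Henderson's equations and return solutions (and PEV on request).

    ``compute_pev`` requires the direct method and inverts the coefficient
    matrix densely, so it is intended for modest problem sizes; PEV_i is the
    i-th diagonal of the animal block of C^-1 times sigma2_e.  When
    ``inbreeding`` is supplied, per-animal accuracies
    sqrt(1 - PEV / ((1 + F) sigma2_a)) are attached.
    """
    C, rhs = _coefficient_matrix(design, K_inv, spec)
    p = design.X.shape[1]
    na = design.Z.shape[1]
    npe = design.W.shape[1]
    log: dict = {"method": method, "n_equations": C.shape[0]}

    pev = None
    if method == "direct":
        if compute_pev:
            Cd = np.linalg.inv(C.toarray())
            sol = Cd @ rhs
            pev_vals = np.diag(Cd)[p : p + na] * spec.sigma2_e
            pev = pd.Series(pev_vals, index=design.animal_labels)
        else:
            # MME are symmetric positive definite: symmetric-mode LU with an
            # AT+A minimum-degree ordering keeps fill-in manageable
            lu = spla.splu(
                C, permc_spec="MMD_AT_PLUS_A", options=dict(SymmetricMode=True)
            )
            sol = lu.solve(rhs)
    elif method == "pcg":
        diag = C.diagonal()
        diag[diag == 0] = 1.0
        M = sparse.diags(1.0 / diag)
        sol, info = spla.cg(C, rhs, rtol=tol, maxiter=max_iter, M=M)
        if info != 0:
            resid = float(np.linalg.norm(C @ sol - rhs) / np.linalg.norm(rhs))
            raise SolverError(
                f"PCG did not converge in {max_iter} iterations "
                f"(relative residual {resid:.3e})"
            )
        log["pcg_info"] = info
    else:
        raise ValueError(f"unknown method {method!r}")

    resid = float(np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
    log["relative_residual"] = resid

    fit = ModelFit(
        fixed=pd.Series(sol[:p], index=design.fixed_labels),
        ebv=pd.Series(sol[p : p + na], index=design.animal_labels),
        pe=pd.Series(sol[p + na : p + na + npe], index=design.cow_labels),
        pev=pev,
        solver_log=log,
    )
    if pev is not None and inbreeding is not None:
        fit.accuracy = pd.Series(
            individual_accuracy(pev.to_numpy(), inbreeding, spec.sigma2_a),
            index=design.animal_labels,
        )
    return fit


def individual_accuracy(pev, F, sigma2_a: float):
    """Per-animal accuracy sqrt(1 - PEV / ((1 + F) sigma2_a)), clipped to [0, 1].

    PEV is the prediction-error variance of the animal's breeding value; F
    its pedigree inbreeding coefficient.
    """
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    pev = np.asarray(pev, dtype=float)
    if np.any(pev < 0):
        raise ValueError("PEV must be non-negative")
    F = np.asarray(F, dtype=float)
    r2 = 1.0 - pev / ((1.0 + F) * sigma2_a)
    return np.sqrt(np.clip(r2, 0.0, 1.0))
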