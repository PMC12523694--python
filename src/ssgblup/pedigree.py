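"""Pedigree handling and pedigree-based relationship matrices.

Reads animal/sire/dam pedigrees, renumbers them parents-before-offspring,
and builds the numerator relationship matrix A (tabular method), its sparse
inverse via the Meuwissen-Luo algorithm with inbreeding, and the genotyped
block A22 with its dense inverse.

Unknown parents are treated as unrelated base-population animals (no
unknown-parent groups).  Animals that appear only in a parent column are
appended to the pedigree as founders.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from collections import deque
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

#: labels interpreted as "parent unknown" in pedigree files
UNKNOWN_CODES = frozenset({"0", "", "NA", "na", "nan", "None"})

#: roles a RelationshipMatrix may carry
MATRIX_ROLES = (
    "A",
    "A_inverse",
    "A22",
    "A22_inverse",
    "G",
    "G_blended",
    "H_inverse",
)


class PedigreeError(ValueError):
    """Invalid pedigree structure (cycle, duplicate, missing animal)."""


class SingularMatrixError(np.linalg.LinAlgError):
    """A relationship (sub)matrix required to be invertible is singular."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class PedigreeTable:
    """Renumbered pedigree ordered parents-before-offspring.

    ``table`` has one row per animal with columns ``animal_id``, ``sire_id``,
    ``dam_id`` (external labels, unknown parents as None), ``code``,
    ``sire_code``, ``dam_code`` (1-based internal codes, 0 = unknown) and,
    when available, ``birth_date``.  Rows are sorted by internal code, so
    every known parent's row precedes its offspring's.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        codes = self.table["code"].to_numpy()
        n = len(codes)
        if not np.array_equal(np.sort(codes), np.arange(1, n + 1)):
            raise PedigreeError("internal codes must be a permutation of 1..n")
        sc = self.table["sire_code"].to_numpy()
        dc = self.table["dam_code"].to_numpy()
        if np.any((sc >= codes) & (sc != 0)) or np.any((dc >= codes) & (dc != 0)):
            raise PedigreeError("parent codes must precede offspring codes")

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> np.ndarray:
        """External labels ordered by internal code."""
        return self.table["animal_id"].to_numpy()

    @property
    def sire_codes(self) -> np.ndarray:
        return self.table["sire_code"].to_numpy()

    @property
    def dam_codes(self) -> np.ndarray:
        return self.table["dam_code"].to_numpy()

    def code_of(self, labels: Iterable) -> np.ndarray:
        """Map external labels to internal 1-based codes."""
        lookup = dict(zip(self.table["animal_id"], self.table["code"]))
        try:
            return np.array([lookup[str(x)] for x in labels], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree") from None


@dataclass
class RelationshipMatrix:
    """A symmetric relationship matrix tagged with its role and index.

    ``values`` is dense ``ndarray`` or ``scipy.sparse`` (for the sparse
    Meuwissen-Luo A inverse and H inverse); ``index`` holds the animal
    identifiers (internal codes or external labels) the rows refer to.
    """

    values: np.ndarray | sparse.spmatrix
    index: np.ndarray
    role: str

    def __post_init__(self) -> None:
        if self.role not in MATRIX_ROLES:
            raise ValueError(f"unknown matrix role {self.role!r}")
        self.index = np.asarray(self.index)
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("relationship matrix must be square")
        if self.values.shape[0] != len(self.index):
            raise ValueError("index length does not match matrix order")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return self.values.toarray()
        return np.asarray(self.values)

    def check_symmetric(self, tol: float = 1e-10) -> None:
        v = self.values
        if sparse.issparse(v):
            d = abs(v - v.T)
            err = d.max() if d.nnz else 0.0
        else:
            err = float(np.max(np.abs(v - v.T))) if self.n else 0.0
        if err > tol:
            raise ValueError(f"matrix role={self.role} asymmetric by {err:.2e}")


# ---------------------------------------------------------------------------
# reading and renumbering
# ---------------------------------------------------------------------------

def read_and_renumber(
    pedigree: str | io.IOBase | pd.DataFrame,
    unknown_codes: Iterable[str] = UNKNOWN_CODES,
) -> PedigreeTable:
    """Read a pedigree CSV and renumber it parents-before-offspring.

    The file needs columns ``animal``, ``sire``, ``dam`` and optionally
    ``birth_date`` (ISO-8601).  Parents that never appear as animals are
    appended as founders; unknown parents map to internal code 0.  A cycle
    (an animal among its own ancestors) raises :class:`PedigreeError`
    naming one animal on the cycle.
    """
    if isinstance(pedigree, pd.DataFrame):
        df = pedigree.copy()
    else:
        df = pd.read_csv(pedigree, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    rename = {"animal_id": "animal", "sire_id": "sire", "dam_id": "dam"}
    df = df.rename(columns=rename)
    for col in ("animal", "sire", "dam"):
        if col not in df.columns:
            raise PedigreeError(f"pedigree is missing column {col!r}")

    unknown = {str(u) for u in unknown_codes}

    def clean(x) -> str | None:
        s = "" if x is None or (isinstance(x, float) and np.isnan(x)) else str(x).strip()
        return None if s in unknown else s

    animals = [clean(a) for a in df["animal"]]
    if any(a is None for a in animals):
        raise PedigreeError("animal label missing or coded unknown")
    if len(set(animals)) != len(animals):
        dup = pd.Series(animals)
        dup = dup[dup.duplicated()].iloc[0]
        raise PedigreeError(f"duplicate animal label {dup!r}")

    sires = [clean(s) for s in df["sire"]]
    dams = [clean(d) for d in df["dam"]]
    births = {}
    if "birth_date" in df.columns:
        parsed = pd.to_datetime(df["birth_date"], errors="coerce")
        births = dict(zip(animals, parsed))

    parent_of = dict(zip(animals, zip(sires, dams)))
    # implicit founders: labels seen only in parent columns
    for p in [*sires, *dams]:
        if p is not None and p not in parent_of:
            parent_of[p] = (None, None)

    order = _topological_order(parent_of)

    code = {a: i + 1 for i, a in enumerate(order)}
    rows = {
        "animal_id": order,
        "sire_id": [parent_of[a][0] for a in order],
        "dam_id": [parent_of[a][1] for a in order],
        "code": [code[a] for a in order],
        "sire_code": [code.get(parent_of[a][0], 0) if parent_of[a][0] else 0 for a in order],
        "dam_code": [code.get(parent_of[a][1], 0) if parent_of[a][1] else 0 for a in order],
    }
    out = pd.DataFrame(rows)
    if births:
        out["birth_date"] = [births.get(a, pd.NaT) for a in order]
    # carry any extra metadata columns (sex, generation, ...) through
    extra = [c for c in df.columns if c not in {"animal", "sire", "dam", "birth_date"}]
    if extra:
        meta = df[extra].copy()
        meta.index = animals
        for c in extra:
            out[c] = [meta[c].get(a, None) for a in order]
    return PedigreeTable(out)


def _topological_order(parent_of: dict[str, tuple[str | None, str | None]]) -> list[str]:
    """Kahn's algorithm over the parent->offspring DAG; stable by insertion."""
    indeg = {a: sum(p is not None for p in ps) for a, ps in parent_of.items()}
    children: dict[str, list[str]] = {a: [] for a in parent_of}
    for a, (s, d) in parent_of.items():
        for p in (s, d):
            if p is not None:
                children[p].append(a)
    queue = deque(a for a in parent_of if indeg[a] == 0)
    order: list[str] = []
    while queue:
        a = queue.popleft()
        order.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != len(parent_of):
        on_cycle = next(a for a in parent_of if indeg[a] > 0)
        raise PedigreeError(f"pedigree cycle detected involving animal {on_cycle!r}")
    return order


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------

def build_A(ped: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular (recursive) method.

    a_ij = 0.5 (a_{s(i),j} + a_{d(i),j}) for j < i and
    a_ii = 1 + 0.5 a_{s(i),d(i)}; unknown parents contribute 0.
    """
    n = ped.n
    s = ped.sire_codes
    d = ped.dam_codes
    # row/col 0 kept as zeros so unknown parents (code 0) drop out
    A = np.zeros((n + 1, n + 1))
    for i in range(1, n + 1):
        si, di = s[i - 1], d[i - 1]
        if i > 1:
            row = 0.5 * (A[si, 1:i] + A[di, 1:i])
            A[i, 1:i] = row
            A[1:i, i] = row
        A[i, i] = 1.0 + 0.5 * A[si, di]
    return RelationshipMatrix(A[1:, 1:], np.arange(1, n + 1), "A")


def inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen-Luo ancestor trace."""
    F, _ = _meuwissen_luo(ped)
    return F


def _meuwissen_luo(ped: PedigreeTable) -> tuple[np.ndarray, np.ndarray]:
    """Return (F, D): inbreeding coefficients and Mendelian-sampling
    variance ratios d_i, computed jointly in one pass.

    For animal i with both parents known, a_ii is accumulated as
    sum_j L_ij^2 d_j over its ancestors (Meuwissen & Luo); F_i = a_ii - 1.
    d_i = 0.5 - 0.25 (F_s + F_d) with both parents known,
    0.75 - 0.25 F_p with one, 1 with none.
    """
    n = ped.n
    s = ped.sire_codes
    d = ped.dam_codes
    F = np.zeros(n + 1)  # F[0] unused (unknown parent)
    D = np.zeros(n + 1)
    for i in range(1, n + 1):
        si, di = s[i - 1], d[i - 1]
        if si and di:
            D[i] = 0.5 - 0.25 * (F[si] + F[di])
        elif si or di:
            D[i] = 0.75 - 0.25 * F[si or di]
        else:
            D[i] = 1.0
        if si == 0 or di == 0:
            F[i] = 0.0
            continue
        # trace ancestors of i, accumulating L coefficients highest-code first
        coef: dict[int, float] = {int(i): 1.0}
        a_ii = 0.0
        while coef:
            k = max(coef)
            v = coef.pop(k)
            a_ii += v * v * D[k]
            sk, dk = s[k - 1], d[k - 1]
            if sk:
                coef[sk] = coef.get(sk, 0.0) + 0.5 * v
            if dk:
                coef[dk] = coef.get(dk, 0.0) + 0.5 * v
        F[i] = a_ii - 1.0
    return F[1:], D[1:]


def build_A_inverse(ped: PedigreeTable) -> RelationshipMatrix:
    """Sparse A inverse by the Meuwissen-Luo construction with inbreeding.

    Mendelian-sampling variances use parental inbreeding, so the result
    equals the dense inverse of :func:`build_A` to numerical precision.
    """
    n = ped.n
    s = ped.sire_codes
    d = ped.dam_codes
    _, D = _meuwissen_luo(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i - 1)
        cols.append(j - 1)
        vals.append(v)
        if i != j:
            rows.append(j - 1)
            cols.append(i - 1)
            vals.append(v)

    for i in range(1, n + 1):
        alpha = 1.0 / D[i - 1]
        si, di = s[i - 1], d[i - 1]
        add(i, i, alpha)
        for p in (si, di):
            if p:
                add(p, i, -0.5 * alpha)
                # 0.25*alpha lands on every parent-by-parent cell, so each
                # known parent contributes to its own diagonal here ...
                rows.append(p - 1)
                cols.append(p - 1)
                vals.append(0.25 * alpha)
        # ... and the sire-dam cross cells are added once, symmetrically
        if si and di:
            if si != di:
                add(si, di, 0.25 * alpha)
            else:  # selfing: both cross cells coincide on the diagonal
                add(si, si, 0.5 * alpha)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(Ainv, np.arange(1, n + 1), "A_inverse")


def extract_A22(
    A: RelationshipMatrix, genotyped_codes: Sequence[int]
) -> tuple[RelationshipMatrix, RelationshipMatrix]:
    """Principal submatrix of A for the genotyped animals and its inverse.

    ``genotyped_codes`` gives internal codes in the ordering used by G.
    Raises :class:`SingularMatrixError` when A22 is singular (e.g. an
    animal duplicated in the genotyped list).
    """
    if A.role != "A":
        raise ValueError("extract_A22 expects a matrix with role 'A'")
    codes = np.asarray(genotyped_codes, dtype=np.int64)
    if codes.size and (codes.min() < 1 or codes.max() > A.n):
        raise PedigreeError("genotyped code outside pedigree range")
    idx = codes - 1
    A22 = A.dense()[np.ix_(idx, idx)]
    try:
        A22_inv = np.linalg.inv(A22)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError(f"A22 is singular: {exc}") from None
    if A22.size:
        resid = np.max(np.abs(A22 @ A22_inv - np.eye(len(idx))))
        if not np.isfinite(resid) or resid > 1e-6:
            raise SingularMatrixError(
                f"A22 is numerically singular (inverse residual {resid:.2e})"
            )
    return (
        RelationshipMatrix(A22, codes, "A22"),
        RelationshipMatrix(A22_inv, codes, "A22_inverse"),
    )


def A22_from_A_inverse(
    A_inv: RelationshipMatrix, genotyped_codes: Sequence[int]
) -> RelationshipMatrix:
    """A22 by exact indirect products: solve A^-1 X = E for the genotyped
    indicator columns E and read off the genotyped rows.

    Equivalent to extracting the principal submatrix of A but never forms
    the dense n x n matrix, so it scales to large pedigrees.
    """
    if A_inv.role != "A_inverse":
        raise ValueError("A22_from_A_inverse expects a matrix with role 'A_inverse'")
    codes = np.asarray(genotyped_codes, dtype=np.int64)
    n = A_inv.n
    if codes.size and (codes.min() < 1 or codes.max() > n):
        raise PedigreeError("genotyped code outside pedigree range")
    from scipy.sparse import linalg as spla  # local: keeps import cost off hot paths

    lu = spla.splu(
        A_inv.values.tocsc(),
        permc_spec="MMD_AT_PLUS_A",
        options=dict(SymmetricMode=True),
    )
    E = np.zeros((n, codes.size))
    E[codes - 1, np.arange(codes.size)] = 1.0
    cols = lu.solve(E)
    A22 = cols[codes - 1]
    A22 = 0.5 * (A22 + A22.T)
    return RelationshipMatrix(A22, codes, "A22")


def write_symmetric_coo(mat: RelationshipMatrix, path: str) -> None:
    """Export the upper triangle as 1-based ``i j value`` coordinate text."""
    M = mat.dense()
    with open(path, "w") as fh:
        fh.write(f"# role={mat.role} n={mat.n}\n")
        for i in range(mat.n):
            for j in range(i, mat.n):
                if M[i, j] != 0.0:
                    fh.write(f"{i + 1} {j + 1} {M[i, j]:.12g}\n")
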