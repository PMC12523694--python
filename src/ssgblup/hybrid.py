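"""Blending, tuning, tau/omega scaling, and assembly of the single-step
hybrid relationship matrix inverse

    H^-1 = A^-1 + [0 0; 0  tau * Gb^-1 - omega * A22^-1]

where the non-zero block is scattered into the genotyped animals' rows and
columns of the full-pedigree matrix.

Tuning rescales G so its base and scale are compatible with A22; blending
mixes a fraction ``beta`` of pedigree relationships back into G so the
combined matrix is positive definite and carries the residual polygenic
variance G does not capture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .pedigree import RelationshipMatrix, SingularMatrixError

TUNING_OPTIONS = ("TG0", "TG1", "TG2", "TG3", "TG4")
BLEND_MODES = ("matrix", "literal_inverse")


class TuningError(ValueError):
    """Degenerate G for the requested tuning option."""


@dataclass
class HybridParams:
    """One ssGBLUP variant: blending fraction, tuning option, scaling weights.

    Defaults are the standard configuration: beta = 0.05, TG2 tuning
    (match diagonal and off-diagonal means of G to A22), tau = omega = 1.
    ``blend_mode`` selects whether blending combines the matrices
    (``matrix``, the default software behaviour) or their inverses
    (``literal_inverse``).
    """

    beta: float = 0.05
    tuning: str = "TG2"
    tau: float = 1.0
    omega: float = 1.0
    blend_mode: str = "matrix"

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if self.tuning not in TUNING_OPTIONS:
            raise ValueError(f"tuning must be one of {TUNING_OPTIONS}")
        if self.tau <= 0 or self.omega <= 0:
            raise ValueError("tau and omega must be positive")
        if self.blend_mode not in BLEND_MODES:
            raise ValueError(f"blend_mode must be one of {BLEND_MODES}")

    def label(self) -> str:
        """Model label in the conventional naming scheme."""
        if self.tuning != "TG2":
            return f"ssGBLUP_{self.tuning}"
        if self.tau != 1.0:
            return f"ssGBLUP_τ{self.tau:.2f}"
        if self.omega != 1.0:
            return f"ssGBLUP_ω{self.omega:.2f}"
        return f"ssGBLUP_G{1.0 - self.beta:.2f}"


def _mean_diag(M: np.ndarray) -> float:
    return float(np.mean(np.diag(M)))


def _mean_offdiag(M: np.ndarray) -> float:
    n = M.shape[0]
    if n < 2:
        raise TuningError("off-diagonal mean undefined for a 1x1 matrix")
    return float((M.sum() - np.trace(M)) / (n * (n - 1)))


def tune_G(
    G: RelationshipMatrix,
    A22: RelationshipMatrix | None,
    option: str = "TG2",
) -> RelationshipMatrix:
    """Rescale G for compatibility with A22.

    TG0  no adjustment.
    TG1  affine a + bG with mean(diag) = 1 and mean(offdiag) = 0.
    TG2  affine a + bG with diagonal and off-diagonal means equal to A22's.
    TG3  additive shift a*J with overall mean equal to A22's.
    TG4  Fst-style rescale: s = mean(A22) - mean(G), G* = (1 - s/2) G + s J.

    TG1/TG2 are degenerate when mean(diag(G)) equals mean(offdiag(G)).
    """
    if option not in TUNING_OPTIONS:
        raise ValueError(f"unknown tuning option {option!r}")
    Gm = G.dense()
    if option == "TG0":
        return RelationshipMatrix(Gm.copy(), G.index, "G")
    if option in ("TG2", "TG3", "TG4"):
        if A22 is None:
            raise ValueError(f"tuning {option} requires A22")
        if A22.n != G.n:
            raise ValueError("G and A22 must share the same index order")
        Am = A22.dense()

    if option in ("TG1", "TG2"):
        gd, go = _mean_diag(Gm), _mean_offdiag(Gm)
        if abs(gd - go) < 1e-12:
            raise TuningError(
                f"{option} degenerate: mean(diag(G)) == mean(offdiag(G)) == {gd:.6g}"
            )
        td, to = (1.0, 0.0) if option == "TG1" else (_mean_diag(Am), _mean_offdiag(Am))
        # solve a + b*gd = td, a + b*go = to
        b = (td - to) / (gd - go)
        a = td - b * gd
        out = a + b * Gm
    elif option == "TG3":
        a = float(np.mean(Am) - np.mean(Gm))
        out = Gm + a
    else:  # TG4
        s = float(np.mean(Am) - np.mean(Gm))
        out = (1.0 - s / 2.0) * Gm + s
    return RelationshipMatrix(out, G.index, "G")


def blend_G(
    G_tuned: RelationshipMatrix,
    A22: RelationshipMatrix,
    beta: float = 0.05,
    blend_mode: str = "matrix",
) -> RelationshipMatrix:
    """Blend a fraction ``beta`` of pedigree relationships into G.

    ``matrix`` mode returns Gb = (1 - beta) G + beta A22 (the standard
    software behaviour).  ``literal_inverse`` mode blends the inverses,
    Gb^-1 = (1 - beta) G^-1 + beta A22^-1, and returns the matrix whose
    inverse that is, so downstream code can invert either result uniformly.
    The two agree exactly when G = A22 and differ otherwise.
    """
    if blend_mode not in BLEND_MODES:
        raise ValueError(f"blend_mode must be one of {BLEND_MODES}")
    Gm = G_tuned.dense()
    Am = A22.dense()
    if Gm.shape != Am.shape:
        raise ValueError("G and A22 are not conformable")
    if beta == 0.0:
        w = np.linalg.eigvalsh(Gm)
        if w.min() < 1e-10:
            raise SingularMatrixError(
                f"beta=0 with (near-)singular G: smallest eigenvalue {w.min():.3e}"
            )
    if blend_mode == "matrix":
        Gb = (1.0 - beta) * Gm + beta * Am
    else:
        Gb_inv = (1.0 - beta) * np.linalg.inv(Gm) + beta * np.linalg.inv(Am)
        Gb = np.linalg.inv(Gb_inv)
    Gb = 0.5 * (Gb + Gb.T)
    return RelationshipMatrix(Gb, G_tuned.index, "G_blended")


def assemble_H_inverse(
    A_inv: RelationshipMatrix,
    A22_inv: RelationshipMatrix,
    Gb_inv: np.ndarray | RelationshipMatrix,
    tau: float = 1.0,
    omega: float = 1.0,
    genotyped_codes=None,
) -> RelationshipMatrix:
    """Scatter ``tau * Gb^-1 - omega * A22^-1`` into the genotyped block of
    the sparse pedigree inverse.

    ``genotyped_codes`` are 1-based pedigree internal codes in the row order
    of Gb/A22 (defaults to ``A22_inv.index``).  With no genotyped animals
    the result is A^-1 unchanged.
    """
    if genotyped_codes is None:
        genotyped_codes = A22_inv.index
    codes = np.asarray(genotyped_codes, dtype=np.int64)
    n = A_inv.n
    if codes.size and (codes.min() < 1 or codes.max() > n):
        raise ValueError("genotyped internal code outside pedigree range")
    Ainv = A_inv.values.tocsr() if sparse.issparse(A_inv.values) else sparse.csr_matrix(A_inv.values)
    if codes.size == 0:
        return RelationshipMatrix(Ainv.copy(), A_inv.index, "H_inverse")
    Gi = Gb_inv.dense() if isinstance(Gb_inv, RelationshipMatrix) else np.asarray(Gb_inv)
    delta = tau * Gi - omega * A22_inv.dense()
    if delta.shape != (codes.size, codes.size):
        raise ValueError("Gb inverse / A22 inverse order mismatch with codes")
    rows = np.repeat(codes - 1, codes.size)
    cols = np.tile(codes - 1, codes.size)
    scatter = sparse.coo_matrix((delta.ravel(), (rows, cols)), shape=(n, n))
    H_inv = (Ainv + scatter.tocsr()).tocsr()
    return RelationshipMatrix(H_inv, A_inv.index, "H_inverse")


def build_H_inverse(
    A_inv: RelationshipMatrix,
    A22: RelationshipMatrix,
    A22_inv: RelationshipMatrix,
    G: RelationshipMatrix,
    params: HybridParams,
    genotyped_codes=None,
) -> RelationshipMatrix:
    """Tune, blend, invert, and assemble in one call."""
    Gt = tune_G(G, A22, params.tuning)
    Gb = blend_G(Gt, A22, params.beta, params.blend_mode)
    Gb_inv = np.linalg.inv(Gb.dense())
    return assemble_H_inverse(
        A_inv, A22_inv, Gb_inv, params.tau, params.omega, genotyped_codes
    )
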