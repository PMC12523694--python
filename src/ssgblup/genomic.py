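"""Genotype I/O, marker/animal quality control, and the VanRaden genomic
relationship matrix.

Dosages count the minor (or declared) allele per biallelic locus; missing
calls are NaN.  QC mirrors common PLINK practice and is applied in a fixed,
reported order: individual call rate, SNP call rate, minor allele frequency,
Hardy-Weinberg equilibrium.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import RelationshipMatrix


class GenotypeError(ValueError):
    """Malformed genotype input (triallelic locus, ragged rows, ...)."""


class QCError(ValueError):
    """Quality control removed everything or thresholds are inconsistent."""


@dataclass
class GenotypePanel:
    """Individuals x loci dosage matrix with missing mask and metadata.

    ``dosages`` is float with entries {0, 1, 2, NaN}; rows follow
    ``individual_ids``, columns ``locus_ids``.  ``alleles`` optionally maps
    each locus to its (counted, other) allele letters.
    """

    dosages: np.ndarray
    individual_ids: np.ndarray
    locus_ids: np.ndarray
    alleles: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        n, m = self.dosages.shape
        if n != len(self.individual_ids) or m != len(self.locus_ids):
            raise GenotypeError("dosage matrix shape does not match id lists")
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(self.dosages) & ~np.isin(self.dosages, (0.0, 1.0, 2.0))
        if bad.any():
            raise GenotypeError("dosages must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-locus frequency of the counted allele over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset(self, ind_mask=None, locus_mask=None) -> "GenotypePanel":
        ind_mask = slice(None) if ind_mask is None else ind_mask
        locus_mask = slice(None) if locus_mask is None else locus_mask
        alle = None
        if self.alleles is not None:
            keep = np.arange(self.n_loci)[locus_mask]
            alle = [self.alleles[j] for j in keep]
        return GenotypePanel(
            self.dosages[ind_mask][:, locus_mask],
            self.individual_ids[ind_mask],
            self.locus_ids[locus_mask],
            alle,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotypes(path: str, format: str = "ped_map") -> GenotypePanel:
    """Read genotypes from PLINK text PED/MAP or a headered dosage CSV.

    For ``ped_map``, ``path`` is the file-set prefix (``prefix.ped`` /
    ``prefix.map``).  The counted allele is the minor allele observed in the
    data (lexicographic tie-break); a locus with more than two alleles
    raises :class:`GenotypeError`.  ``0`` is the missing-allele code.
    """
    if format == "ped_map":
        return _read_ped_map(path)
    if format == "dosage_matrix":
        return _read_dosage_csv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_ped_map(prefix: str) -> GenotypePanel:
    map_df = pd.read_csv(
        prefix + ".map", sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "bp"], dtype=str,
    )
    locus_ids = map_df["snp"].to_numpy(dtype=object)
    m = len(locus_ids)

    ids: list[str] = []
    pairs: list[list[tuple[str, str]]] = []
    with open(prefix + ".ped") as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise GenotypeError(
                    f"PED row for {fields[1] if len(fields) > 1 else '?'} has "
                    f"{len(fields) - 6} allele fields, expected {2 * m}"
                )
            ids.append(fields[1])
            al = fields[6:]
            pairs.append([(al[2 * j], al[2 * j + 1]) for j in range(m)])

    n = len(ids)
    dos = np.full((n, m), np.nan)
    alleles: list[tuple[str, str]] = []
    for j in range(m):
        counts: dict[str, int] = {}
        for i in range(n):
            for a in pairs[i][j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise GenotypeError(
                f"locus {locus_ids[j]} has {len(counts)} alleles: {sorted(counts)}"
            )
        if not counts:
            alleles.append(("0", "0"))
            continue
        # counted allele = minor, ties broken lexicographically
        ordered = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))
        counted = ordered[0][0]
        other = ordered[1][0] if len(ordered) > 1 else counted
        alleles.append((counted, other))
        for i in range(n):
            a1, a2 = pairs[i][j]
            if a1 == "0" or a2 == "0":
                continue
            dos[i, j] = (a1 == counted) + (a2 == counted)
    return GenotypePanel(dos, np.array(ids, dtype=object), locus_ids, alleles)


def _read_dosage_csv(path: str) -> GenotypePanel:
    df = pd.read_csv(path, index_col=0)
    return GenotypePanel(
        df.to_numpy(dtype=float),
        df.index.astype(str).to_numpy(dtype=object),
        df.columns.astype(str).to_numpy(dtype=object),
    )


def write_dosage_csv(panel: GenotypePanel, path: str) -> None:
    pd.DataFrame(
        panel.dosages, index=panel.individual_ids, columns=panel.locus_ids
    ).to_csv(path, index_label="id")


def write_ped_map(panel: GenotypePanel, prefix: str) -> None:
    """Write PLINK text PED/MAP.  Dosages map to allele letters: the counted
    allele is written as ``B`` and the alternative as ``A`` unless the panel
    carries real allele letters; missing becomes ``0 0``."""
    alleles = panel.alleles or [("B", "A")] * panel.n_loci
    with open(prefix + ".map", "w") as fh:
        for j, snp in enumerate(panel.locus_ids):
            fh.write(f"1 {snp} 0 {j + 1}\n")
    geno_for = {
        0.0: lambda c, o: f"{o} {o}",
        1.0: lambda c, o: f"{c} {o}",
        2.0: lambda c, o: f"{c} {c}",
    }
    with open(prefix + ".ped", "w") as fh:
        for i, ind in enumerate(panel.individual_ids):
            cells = []
            for j in range(panel.n_loci):
                d = panel.dosages[i, j]
                c, o = alleles[j]
                cells.append("0 0" if np.isnan(d) else geno_for[d](c, o))
            fh.write(f"FAM {ind} 0 0 0 -9 " + " ".join(cells) + "\n")


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def hwe_test(aa: int, ab: int, bb: int) -> float:
    """One-df chi-square p-value for Hardy-Weinberg equilibrium.

    Genotype counts are for (0, 1, 2) copies of the counted allele.
    A monomorphic locus returns p = 1 by convention.
    """
    if min(aa, ab, bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = aa + ab + bb
    if n == 0:
        raise ValueError("no genotype calls")
    p = (2 * bb + ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    q = 1.0 - p
    expected = np.array([n * q * q, 2 * n * p * q, n * p * p])
    observed = np.array([aa, ab, bb], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


@dataclass
class QCReport:
    """Counts removed per QC step, in application order."""

    individuals_low_call: int = 0
    snps_low_call: int = 0
    snps_low_maf: int = 0
    snps_hwe: int = 0
    individuals_in: int = 0
    snps_in: int = 0
    individuals_out: int = 0
    snps_out: int = 0
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("individual_call_rate", self.individuals_low_call),
            ("snp_call_rate", self.snps_low_call),
            ("maf", self.snps_low_maf),
            ("hwe", self.snps_hwe),
        ]
        return pd.DataFrame(rows, columns=["rule", "n_removed"])

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def qc_filter(
    panel: GenotypePanel,
    maf_min: float = 0.05,
    snp_call_min: float = 0.90,
    ind_call_min: float = 0.90,
    hwe_alpha: float = 1e-4,
) -> tuple[GenotypePanel, QCReport]:
    """Apply the QC rules in order: individual call rate >= ``ind_call_min``,
    SNP call rate >= ``snp_call_min``, MAF >= ``maf_min``, HWE p >=
    ``hwe_alpha``.  Statistics for each rule are recomputed on the survivors
    of the previous one, and the ordered pass is repeated until no further
    removals occur (dropping a locus can push an individual's call rate
    below threshold), so the filter is idempotent.  Per-rule counts
    accumulate over passes.  Raises :class:`QCError` if no locus survives.
    """
    if panel.n_individuals == 0 or panel.n_loci == 0:
        raise QCError("empty genotype panel")
    report = QCReport(
        individuals_in=panel.n_individuals,
        snps_in=panel.n_loci,
        thresholds=dict(
            maf_min=maf_min, snp_call_min=snp_call_min,
            ind_call_min=ind_call_min, hwe_alpha=hwe_alpha,
        ),
    )

    changed = True
    while changed:
        n_ind, n_loc = panel.n_individuals, panel.n_loci

        called = ~np.isnan(panel.dosages)
        keep_ind = called.mean(axis=1) >= ind_call_min
        report.individuals_low_call += int((~keep_ind).sum())
        panel = panel.subset(ind_mask=keep_ind)

        called = ~np.isnan(panel.dosages)
        snp_rate = (
            called.mean(axis=0) if panel.n_individuals else np.zeros(panel.n_loci)
        )
        keep_snp = snp_rate >= snp_call_min
        report.snps_low_call += int((~keep_snp).sum())
        panel = panel.subset(locus_mask=keep_snp)

        freq = panel.allele_freq
        with np.errstate(invalid="ignore"):
            maf = np.minimum(freq, 1.0 - freq)
            keep_snp = maf >= maf_min
        report.snps_low_maf += int((~keep_snp).sum())
        panel = panel.subset(locus_mask=keep_snp)

        keep_hwe = np.ones(panel.n_loci, dtype=bool)
        for j in range(panel.n_loci):
            col = panel.dosages[:, j]
            col = col[~np.isnan(col)]
            counts = [int((col == k).sum()) for k in (0, 1, 2)]
            if sum(counts) == 0:
                continue
            keep_hwe[j] = hwe_test(*counts) >= hwe_alpha
        report.snps_hwe += int((~keep_hwe).sum())
        panel = panel.subset(locus_mask=keep_hwe)

        if panel.n_loci == 0:
            raise QCError(
                "all loci removed by QC; relax maf_min/snp_call_min/hwe_alpha"
            )
        changed = (panel.n_individuals, panel.n_loci) != (n_ind, n_loc)

    report.individuals_out = panel.n_individuals
    report.snps_out = panel.n_loci
    return panel, report


# ---------------------------------------------------------------------------
# genomic relationship matrix
# ---------------------------------------------------------------------------

def build_G(panel: GenotypePanel) -> RelationshipMatrix:
    """VanRaden (method 1) genomic relationship matrix.

    G = Z Z' / (2 sum_j p_j (1 - p_j)) where Z is the dosage matrix with
    column j centered by 2 p_j; p_j is the counted-allele frequency observed
    in the genotyped set.  Missing dosages are imputed to the locus mean
    (equivalently 2 p_j) before centering, so they contribute zero to Z.
    """
    M = panel.dosages.copy()
    p = panel.allele_freq
    if np.isnan(p).any():
        raise GenotypeError("locus with no calls; run qc_filter first")
    nan = np.isnan(M)
    if nan.any():
        M[nan] = np.broadcast_to(2.0 * p, M.shape)[nan]
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise GenotypeError("all loci monomorphic; G denominator is zero")
    Z = M - 2.0 * p
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(G, panel.individual_ids, "G")
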