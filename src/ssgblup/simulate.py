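"""Synthetic dairy population generator.

Emulates the data structure of a national dairy evaluation: a
multi-generation random-mating pedigree with few sires and many dams, a
small genotyped subset biased toward recent generations nested in a large
phenotyped population, unlinked SNP genotypes gene-dropped from founder
haplotypes, an additive architecture split between marker (QTL) effects
and a residual polygenic term, and 1-3 repeated 305-day lactation records
per cow with herd-year-season, parity, and age-at-calving fixed structure
plus a permanent-environment component.

All randomness flows from ``SimConfig.seed``; two runs with equal configs
are bit-identical.  Founder-level genetic variances are calibrated exactly
(components standardised within the founder cohort), so realised
heritabilities track their targets up to pedigree sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import PedigreeTable, read_and_renumber
from .genomic import GenotypePanel


@dataclass(frozen=True)
class TraitSpec:
    """Phenotypic scale and heritability target for one yield trait (kg)."""

    mean: float
    sd: float
    h2: float


#: trait scales typical of 305-day Holstein lactation yields
DEFAULT_TRAITS: dict[str, TraitSpec] = {
    "milk": TraitSpec(mean=7940.1, sd=2615.1, h2=0.28),
    "protein": TraitSpec(mean=290.23, sd=100.25, h2=0.21),
    "fat": TraitSpec(mean=252.54, sd=82.98, h2=0.25),
}


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic population.

    Defaults describe a pedigree of 300 founders plus four generations of
    2,400 offspring (~9,900 animals) yielding roughly 3,000 recorded cows
    once milk-recording enrollment and the forward-in-time cutoff are
    applied; 300 genotyped animals (recent cows plus the proven AI sire
    battery), 4,000 unlinked SNPs of which 400 are QTL, a 0.7/0.3
    marker/polygenic split of the additive variance, repeatability 0.45,
    and 25 herds.
    """

    n_founders: int = 300
    n_generations: int = 4
    n_offspring_per_gen: int = 2400
    n_sires_per_gen: int = 40
    # the last two cohorts are sired by wide batteries of young bulls (the
    # genomic-preselection era), so recent cows' sires are weakly proven
    n_sires_recent: int = 200

    n_snps: int = 4000
    maf_range: tuple = (0.05, 0.5)
    n_qtl: int = 400
    marker_fraction: float = 0.7

    traits: dict = field(default_factory=lambda: dict(DEFAULT_TRAITS))
    genetic_corr: float = 0.8
    env_corr: float = 0.8
    repeatability: float = 0.45

    n_herds: int = 25
    first_year: int = 2005
    cg_sd_fraction: float = 0.5
    parity_effects: tuple = (0.0, 0.45, 0.65)  # in phenotypic SD units
    age_slope_sd_per_month: float = 0.01
    records_per_cow_probs: tuple = (0.5, 0.3, 0.2)

    genotyped_fraction: float = 300 / 9900
    recency_bias: float = 2.0  # per-generation multiplicative weight on cows
    # share of the genotyping budget spent on AI sires, sampled with
    # probability proportional to progeny count (proven bulls first)
    genotyped_sire_fraction: float = 0.2

    # pedigree recording is incomplete in national data: a non-genotyped
    # animal's sire/dam is present in the recorded pedigree with these
    # probabilities (genotyped animals keep near-complete parentage, as in
    # routinely genotyped herds); true parents always drive inheritance
    sire_recording_rate: float = 0.6
    dam_recording_rate: float = 0.8

    # milk-recording enrollment: only this fraction of females ever enters
    # the recording scheme (national pedigrees carry many more females
    # than recorded cows); genotyped cows are sampled from recorded herds
    # and always have records
    cow_recording_rate: float = 0.65
    # forward-in-time recording: the youngest cohort is still milking, so
    # only this fraction of its non-genotyped recorded cows has records yet
    young_cow_recording_fraction: float = 0.3

    seed: int = 20250930

    def __post_init__(self) -> None:
        if not 0 < self.genotyped_fraction <= 1:
            raise ValueError("genotyped_fraction must be in (0, 1]")
        if not 0 <= self.marker_fraction <= 1:
            raise ValueError("marker_fraction must be in [0, 1]")
        for t, ts in self.traits.items():
            if not 0 < ts.h2 < self.repeatability < 1:
                raise ValueError(f"trait {t}: need 0 < h2 < repeatability < 1")

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits)

    def phenotypic_var(self, trait: str) -> float:
        return self.traits[trait].sd ** 2


def _trait_corr(names: list[str], rho: float) -> np.ndarray:
    k = len(names)
    C = np.full((k, k), rho)
    np.fill_diagonal(C, 1.0)
    return C


def _standardise(X: np.ndarray, rows: np.ndarray, target_sd: np.ndarray) -> np.ndarray:
    """Center and rescale columns of X so that over ``rows`` each column has
    mean 0 and standard deviation ``target_sd`` exactly."""
    sub = X[rows]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd * target_sd


def simulate_population(
    cfg: SimConfig,
) -> tuple[PedigreeTable, GenotypePanel, pd.DataFrame]:
    """Simulate pedigree, genotypes, and true breeding values.

    Returns the renumbered pedigree (with ``sex`` and ``generation``
    metadata columns), the genotype panel of the genotyped subset, and a
    DataFrame of true breeding values (rows = animals, columns = traits,
    kg units).  Founder haplotypes are drawn at Uniform(maf_range) allele
    frequencies; each offspring receives one gamete per parent with
    independent Mendelian sampling per locus (unlinked loci).
    """
    rng = np.random.default_rng(cfg.seed)
    nf = cfg.n_founders
    total = nf + cfg.n_generations * cfg.n_offspring_per_gen

    sex = np.empty(total, dtype="U1")
    gen = np.zeros(total, dtype=int)
    sire = np.zeros(total, dtype=int)  # 0 = unknown, else 1-based position
    dam = np.zeros(total, dtype=int)
    sex[:nf] = rng.permutation(["M"] * (nf // 2) + ["F"] * (nf - nf // 2))

    # haplotypes: total x 2 x n_snps, int8
    p0 = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    hap = np.zeros((total, 2, cfg.n_snps), dtype=np.int8)
    hap[:nf] = (rng.random((nf, 2, cfg.n_snps)) < p0).astype(np.int8)

    start = nf
    gen_lo = 0
    for g in range(1, cfg.n_generations + 1):
        k = cfg.n_offspring_per_gen
        # discrete generations: parents come from the preceding cohort, as
        # in a population turning over through young AI sires
        prev = np.arange(gen_lo, start)
        males = prev[sex[prev] == "M"]
        females = prev[sex[prev] == "F"]
        # few sires, many dams: a sampled sire team serves the generation;
        # recent cohorts use the wider young-bull battery
        n_team = (
            cfg.n_sires_recent
            if g > cfg.n_generations - 2
            else cfg.n_sires_per_gen
        )
        team = rng.choice(males, size=min(n_team, males.size), replace=False)
        s_idx = rng.choice(team, size=k, replace=True)
        d_idx = rng.choice(females, size=k, replace=True)
        idx = np.arange(start, start + k)
        sire[idx] = s_idx + 1
        dam[idx] = d_idx + 1
        gen[idx] = g
        sex[idx] = np.where(rng.random(k) < 0.5, "F", "M")
        pick_s = rng.integers(0, 2, size=(k, cfg.n_snps))
        pick_d = rng.integers(0, 2, size=(k, cfg.n_snps))
        cols = np.arange(cfg.n_snps)
        hap[idx, 0, :] = hap[s_idx[:, None], pick_s, cols]
        hap[idx, 1, :] = hap[d_idx[:, None], pick_d, cols]
        gen_lo = start
        start += k

    labels = np.array([f"AN{i + 1:06d}" for i in range(total)], dtype=object)
    birth_year = np.where(
        gen == 0,
        cfg.first_year - 3 + rng.integers(0, 3, size=total),
        cfg.first_year - 2 + 2 * gen,
    )
    birth_month = rng.integers(1, 13, size=total)
    birth_date = pd.to_datetime(
        {"year": birth_year, "month": birth_month, "day": 15}
    )

    # ---- genotyped subset: recent cows plus the AI sire battery ----
    # a fixed share of the genotyping budget goes to sires, drawn with
    # probability proportional to progeny count (proven AI bulls are
    # genotyped first); the rest goes to cows with a recency bias; bull
    # calves that never sired are not genotyped
    n_geno = max(1, round(cfg.genotyped_fraction * total))
    progeny = np.bincount(sire[sire > 0] - 1, minlength=total).astype(float)
    sire_pos = np.flatnonzero(progeny > 0)
    n_sire_geno = min(round(cfg.genotyped_sire_fraction * n_geno), sire_pos.size)
    ws = progeny[sire_pos] / progeny[sire_pos].sum()
    geno_sires = rng.choice(sire_pos, size=n_sire_geno, replace=False, p=ws)
    cow_pos = np.flatnonzero(sex == "F")
    if n_geno - n_sire_geno > cow_pos.size:
        raise ValueError(
            "genotyped_fraction too large for the available female pool"
        )
    wc = cfg.recency_bias ** gen[cow_pos].astype(float)
    wc /= wc.sum()
    geno_cows = rng.choice(
        cow_pos, size=n_geno - n_sire_geno, replace=False, p=wc
    )
    geno_idx = np.sort(np.concatenate([geno_sires, geno_cows]))
    is_geno = np.zeros(total, dtype=bool)
    is_geno[geno_idx] = True

    # recorded pedigree: parentage of non-genotyped animals is incompletely
    # recorded; inheritance above always used the true parents
    rec_sire = sire.copy()
    rec_dam = dam.copy()
    drop_s = (~is_geno) & (rng.random(total) > cfg.sire_recording_rate)
    drop_d = (~is_geno) & (rng.random(total) > cfg.dam_recording_rate)
    rec_sire[drop_s] = 0
    rec_dam[drop_d] = 0

    ped_df = pd.DataFrame(
        {
            "animal": labels,
            "sire": np.where(rec_sire > 0, labels[rec_sire - 1], "0"),
            "dam": np.where(rec_dam > 0, labels[rec_dam - 1], "0"),
            "birth_date": birth_date.astype(str),
            "sex": sex,
            "generation": gen,
        }
    )
    ped = read_and_renumber(ped_df)

    # ---- true breeding values: marker + residual polygenic, per trait ----
    names = cfg.trait_names
    k_tr = len(names)
    sd_a = np.array([cfg.traits[t].sd * np.sqrt(cfg.traits[t].h2) for t in names])
    corr = _trait_corr(names, cfg.genetic_corr)
    chol = np.linalg.cholesky(corr)
    founders = np.arange(nf)

    # only the QTL columns (all animals) and the genotyped rows of the
    # dosage matrix are ever needed; the full matrix is never materialised
    bv = np.zeros((total, k_tr))
    marker = None
    if cfg.n_qtl > 0 and cfg.marker_fraction > 0:
        qtl = rng.choice(cfg.n_snps, size=min(cfg.n_qtl, cfg.n_snps), replace=False)
        effects = rng.standard_normal((qtl.size, k_tr)) @ chol.T
        qtl_dosage = hap[:, :, qtl].sum(axis=1, dtype=np.int8).astype(np.float64)
        marker_raw = qtl_dosage @ effects
        marker = _standardise(
            marker_raw, founders, sd_a * np.sqrt(cfg.marker_fraction)
        )
        bv += marker
    if cfg.marker_fraction < 1:
        sd_poly = sd_a * np.sqrt(1.0 - cfg.marker_fraction)
        poly = np.zeros((total, k_tr))
        poly[:nf] = rng.standard_normal((nf, k_tr)) @ chol.T
        if marker is not None:
            # make the founder polygenic deviations orthogonal to the marker
            # component so the founder additive variance calibrates exactly
            for t in range(k_tr):
                m = marker[founders, t] - marker[founders, t].mean()
                denom = float(m @ m)
                if denom > 0:
                    b = float(poly[founders, t] @ m) / denom
                    poly[:nf, t] -= b * m
        poly[:nf] = _standardise(poly[:nf], founders, np.ones(k_tr))
        ms = rng.standard_normal((total, k_tr)) @ chol.T * np.sqrt(0.5)
        for i in range(nf, total):
            si, di = sire[i] - 1, dam[i] - 1
            poly[i] = 0.5 * (poly[si] + poly[di]) + ms[i]
        poly *= sd_poly
        bv += poly

    true_bv = pd.DataFrame(bv, index=labels, columns=names)
    # reindex rows into pedigree (renumbered) order
    true_bv = true_bv.loc[ped.labels]

    panel = GenotypePanel(
        hap[geno_idx].sum(axis=1, dtype=np.int8).astype(np.float64),
        labels[geno_idx],
        np.array([f"SNP{j + 1:05d}" for j in range(cfg.n_snps)], dtype=object),
    )
    return ped, panel, true_bv


def simulate_phenotypes(
    ped: PedigreeTable,
    true_bv: pd.DataFrame,
    cfg: SimConfig,
    genotyped_ids=None,
    return_effects: bool = False,
):
    """Repeated 305-day lactation records for non-founder females.

    The youngest cohort is only partially recorded (it is still milking
    when the evaluation is run): a non-genotyped final-generation cow has
    records with probability ``cfg.young_cow_recording_fraction``, while
    genotyped cows (``genotyped_ids``) always do.

    y = HYS effect + parity effect + age-within-parity covariate + BV + pe
    + e, with the permanent-environment term constant across a cow's
    parities.  Ages at calving are drawn uniformly inside the legal editing
    windows and yields/percentages are truncated to the legal recording
    ranges, so the generated table passes record-level editing unchanged.

    Returns the lactation table; with ``return_effects=True`` also a frame
    holding the per-record sum of simulated fixed effects per trait (useful
    for estimating genetic parameters net of the fixed structure).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    names = cfg.trait_names
    k_tr = len(names)
    tab = ped.table
    gen_col = tab["generation"].astype(int)
    is_cow = (tab["sex"] == "F") & (gen_col > 0)
    last_gen = int(gen_col.max())
    geno = {str(g) for g in genotyped_ids} if genotyped_ids is not None else set()
    is_geno = tab["animal_id"].isin(geno).to_numpy()
    # enrollment in milk recording (genotyped cows are always enrolled)
    enrolled = (rng.random(len(tab)) < cfg.cow_recording_rate) | is_geno
    # the youngest cohort is only partially recorded yet
    young = (gen_col == last_gen).to_numpy() & ~is_geno
    started = rng.random(len(tab)) < cfg.young_cow_recording_fraction
    is_cow &= enrolled & (~young | started)
    cows = tab[is_cow]
    nc = len(cows)
    if nc == 0:
        raise ValueError("no non-founder females to record")

    sd_p = np.array([cfg.traits[t].sd for t in names])
    mean_p = np.array([cfg.traits[t].mean for t in names])
    sd_pe = np.array(
        [
            cfg.traits[t].sd * np.sqrt(cfg.repeatability - cfg.traits[t].h2)
            for t in names
        ]
    )
    sd_e = sd_p * np.sqrt(1.0 - cfg.repeatability)
    env_chol = np.linalg.cholesky(_trait_corr(names, cfg.env_corr))

    herds = rng.integers(1, cfg.n_herds + 1, size=nc)
    n_rec = rng.choice([1, 2, 3], size=nc, p=cfg.records_per_cow_probs)
    # forward-in-time cap: a cow born close to the evaluation cutoff has
    # not had time to complete later lactations (the youngest cohort has
    # first lactations only, the one before it at most two)
    cow_gen = cows["generation"].astype(int).to_numpy()
    cap = np.where(cow_gen >= last_gen, 1, np.where(cow_gen == last_gen - 1, 2, 3))
    n_rec = np.minimum(n_rec, cap)
    pe = (rng.standard_normal((nc, k_tr)) @ env_chol.T) * sd_pe

    cg_effect: dict[str, float] = {}  # shared standardised HYS deviation

    windows = {1: (20, 42), 2: (30, 54), 3: (40, 67)}
    recs: list[dict] = []
    y_parts: list[np.ndarray] = []
    fixed_parts: list[np.ndarray] = []
    bv_cows = true_bv.loc[cows["animal_id"]].to_numpy()
    birth = pd.to_datetime(cows["birth_date"]).to_numpy()

    for ci in range(nc):
        age = rng.uniform(22.0, 40.0)
        for par in range(1, n_rec[ci] + 1):
            lo, hi = windows[par]
            if par > 1:
                age = age + rng.uniform(11.0, 14.0)
            age = float(np.clip(age, lo + 0.5, hi - 0.5))
            calving = pd.Timestamp(birth[ci]) + pd.Timedelta(
                days=age * 30.4375
            )
            season = "summer" if calving.month in {10, 11, 12, 1, 2, 3} else "winter"
            key = f"{herds[ci]}_{calving.year}_{season}"
            if key not in cg_effect:
                cg_effect[key] = float(rng.standard_normal())
            fixed = (
                cfg.cg_sd_fraction * cg_effect[key] * sd_p
                + np.array(cfg.parity_effects)[par - 1] * sd_p
                + cfg.age_slope_sd_per_month * (age - 31.0) * sd_p
            )
            e = (rng.standard_normal(k_tr) @ env_chol.T) * sd_e
            y = mean_p + fixed + bv_cows[ci] + pe[ci] + e
            recs.append(
                {
                    "cow": cows["animal_id"].iloc[ci],
                    "herd": int(herds[ci]),
                    "parity": par,
                    "birth_date": pd.Timestamp(birth[ci]),
                    "calving_date": calving.normalize(),
                    "age_months": age,
                }
            )
            y_parts.append(y)
            fixed_parts.append(fixed)

    df = pd.DataFrame(recs)
    Y = np.vstack(y_parts)
    ymap = dict(zip(names, Y.T))
    milk = np.clip(ymap["milk"], 1000.0 + 1e-6, 30000.0 - 1e-6)
    df["milk_kg"] = milk
    for comp in ("fat", "protein"):
        kg = np.clip(ymap[comp], 0.0201 * milk, 0.0899 * milk)
        df[f"{comp}_kg"] = kg
        df[f"{comp}_pct"] = 100.0 * kg / milk
    if return_effects:
        eff = pd.DataFrame(fixed_parts, columns=[f"fixed_{t}" for t in names])
        return df, eff
    return df


def true_accuracy(estimated, truth, ids) -> float:
    """Pearson correlation of predictions with simulated breeding values."""
    est = pd.Series(estimated).loc[list(ids)].to_numpy(dtype=float)
    tru = pd.Series(truth).loc[list(ids)].to_numpy(dtype=float)
    if len(est) < 3:
        raise ValueError("need at least 3 animals")
    if np.std(est) == 0 or np.std(tru) == 0:
        raise ValueError("zero variance in predictions or truth")
    return float(np.corrcoef(est, tru)[0, 1])


# ---------------------------------------------------------------------------
# file output matching the reader formats
# ---------------------------------------------------------------------------

def write_pedigree_csv(ped: PedigreeTable, path: str) -> None:
    out = ped.table[["animal_id", "sire_id", "dam_id"]].copy()
    out.columns = ["animal", "sire", "dam"]
    out = out.fillna("0")
    if "birth_date" in ped.table.columns:
        out["birth_date"] = pd.to_datetime(ped.table["birth_date"]).dt.date
    out.to_csv(path, index=False)


def write_phenotypes_csv(table: pd.DataFrame, path: str) -> None:
    out = table.copy()
    for c in ("birth_date", "calving_date"):
        out[c] = pd.to_datetime(out[c]).dt.date
    out.to_csv(path, index=False)
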