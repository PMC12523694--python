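"""Forward validation, realized accuracy, and the blending/tuning/scaling
experiment sweeps.

Forward validation masks the phenotypes of the most recently born genotyped
cows and predicts them from older data.  Realized accuracy is the Pearson
correlation, over the validation cows, between the full-data pedigree-BLUP
EBVs and the reduced-data (G)EBVs of the model under test — the full-data
reference is always the pedigree model, so every variant is scored against
the same yardstick.  A config switch allows a same-model full reference for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import (
    PedigreeTable,
    RelationshipMatrix,
    A22_from_A_inverse,
    build_A,
    build_A_inverse,
    extract_A22,
)
from .genomic import GenotypePanel, build_G, qc_filter
from .hybrid import HybridParams, blend_G, tune_G, assemble_H_inverse
from .model import ModelSpec, build_design, solve_mme
from .editing import form_contemporary_groups
from .simulate import SimConfig, simulate_population, simulate_phenotypes, true_accuracy

#: the standard one-factor experiment grids
BLENDING_GRID = (0.40, 0.30, 0.20, 0.10, 0.05)
TUNING_GRID = ("TG0", "TG1", "TG2", "TG3", "TG4")
SCALING_GRID = (0.60, 0.70, 0.80, 0.90, 1.0)

#: default fraction of eligible genotyped cows masked for validation
DEFAULT_VALIDATION_FRACTION = 0.32


class ValidationError(ValueError):
    """Invalid validation design (too few animals, zero variance, ...)."""


@dataclass
class ValidationPlan:
    """Masked-cow design: which cows, and the full/reduced record pair."""

    validation_ids: list
    full_data: pd.DataFrame
    reduced_data: pd.DataFrame


def select_validation_cows(
    genotyped_ids,
    phenotypes: pd.DataFrame,
    ped: PedigreeTable,
    n: int | None = None,
    fraction: float = DEFAULT_VALIDATION_FRACTION,
) -> ValidationPlan:
    """Mask the ``n`` most recently born genotyped cows with records.

    Eligible cows are genotyped animals with at least one lactation record;
    they are ranked by birth date descending with ties broken by label, and
    the top ``n`` (default ``round(fraction * eligible)``) have all their
    records removed from the reduced dataset.
    """
    geno = {str(g) for g in genotyped_ids}
    recorded = set(phenotypes["cow"].astype(str))
    eligible = sorted(geno & recorded)
    if not eligible and (n or 0) > 0:
        raise ValidationError("no genotyped cows with lactation records")
    birth = dict(zip(ped.table["animal_id"], pd.to_datetime(ped.table["birth_date"])))
    # most recent birth first; ties broken ascending by label for determinism
    order = sorted(
        eligible, key=lambda c: (-birth.get(c, pd.Timestamp.min).value, c)
    )
    if n is None:
        n = int(round(fraction * len(eligible)))
    if n > len(eligible):
        raise ValidationError(
            f"requested {n} validation cows but only {len(eligible)} eligible"
        )
    chosen = order[:n]
    mask = phenotypes["cow"].astype(str).isin(set(chosen))
    return ValidationPlan(
        validation_ids=chosen,
        full_data=phenotypes.reset_index(drop=True),
        reduced_data=phenotypes[~mask].reset_index(drop=True),
    )


def realized_accuracy(ebv_full, ebv_reduced, ids) -> float:
    """Pearson correlation of full-data vs reduced-data EBVs on the
    validation animals."""
    ids = list(ids)
    if len(ids) < 3:
        raise ValidationError("need at least 3 validation animals")
    full = pd.Series(ebv_full).loc[ids].to_numpy(dtype=float)
    red = pd.Series(ebv_reduced).loc[ids].to_numpy(dtype=float)
    if np.std(full) == 0 or np.std(red) == 0:
        raise ValidationError("zero variance among validation animals")
    return float(np.corrcoef(full, red)[0, 1])


# ---------------------------------------------------------------------------
# data bundle and sweep machinery
# ---------------------------------------------------------------------------

@dataclass
class EvaluationData:
    """Everything one sweep needs, with relationship matrices cached."""

    ped: PedigreeTable
    records: pd.DataFrame          # edited + contemporary-grouped, full data
    panel: GenotypePanel           # post-QC genotypes
    plan: ValidationPlan
    specs: dict                    # trait -> ModelSpec
    A: RelationshipMatrix = None
    A_inv: RelationshipMatrix = None
    A22: RelationshipMatrix = None
    A22_inv: RelationshipMatrix = None
    G: RelationshipMatrix = None
    genotyped_codes: np.ndarray = None

    def __post_init__(self) -> None:
        if self.A_inv is None:
            self.A_inv = build_A_inverse(self.ped)
        if self.genotyped_codes is None:
            self.genotyped_codes = self.ped.code_of(self.panel.individual_ids)
        if self.A22 is None or self.A22_inv is None:
            if self.A is not None:
                self.A22, self.A22_inv = extract_A22(self.A, self.genotyped_codes)
            else:
                # indirect products keep large pedigrees out of dense memory
                self.A22 = A22_from_A_inverse(self.A_inv, self.genotyped_codes)
                self.A22_inv = RelationshipMatrix(
                    np.linalg.inv(self.A22.dense()),
                    self.genotyped_codes,
                    "A22_inverse",
                )
        if self.G is None:
            self.G = build_G(self.panel)


def _fit(records: pd.DataFrame, data: EvaluationData, spec: ModelSpec, K_inv):
    design = build_design(records, data.ped, spec)
    return solve_mme(design, K_inv, spec)


def fit_ablup(records: pd.DataFrame, data: EvaluationData, spec: ModelSpec):
    """Pedigree-only evaluation."""
    return _fit(records, data, spec, data.A_inv)


def fit_ssgblup(
    records: pd.DataFrame,
    data: EvaluationData,
    spec: ModelSpec,
    params: HybridParams,
):
    """Single-step evaluation under one blending/tuning/scaling variant."""
    Gt = tune_G(data.G, data.A22, params.tuning)
    Gb = blend_G(Gt, data.A22, params.beta, params.blend_mode)
    Gb_inv = np.linalg.inv(Gb.dense())
    H_inv = assemble_H_inverse(
        data.A_inv, data.A22_inv, Gb_inv, params.tau, params.omega,
        data.genotyped_codes,
    )
    return _fit(records, data, spec, H_inv)


def sweep_grid(mode: str) -> list[tuple[str, HybridParams]]:
    """(label, params) pairs for one experiment mode, one factor varied at a
    time with the others at their defaults (beta=0.05, TG2, tau=omega=1)."""
    if mode == "blending":
        return [
            (f"ssGBLUP_G{1.0 - b:.2f}", HybridParams(beta=b)) for b in BLENDING_GRID
        ]
    if mode == "tuning":
        return [(f"ssGBLUP_{t}", HybridParams(tuning=t)) for t in TUNING_GRID]
    if mode == "scaling":
        out = [
            (f"ssGBLUP_τ{t:.2f}", HybridParams(tau=t)) for t in SCALING_GRID
        ]
        out += [
            (f"ssGBLUP_ω{w:.2f}", HybridParams(omega=w)) for w in SCALING_GRID
        ]
        return out
    raise ValueError(f"unknown sweep mode {mode!r}")


def run_sweep(
    data: EvaluationData,
    mode: str,
    traits: tuple = ("milk", "protein", "fat"),
    full_reference: str = "same",
) -> pd.DataFrame:
    """Fit full and reduced models and score each grid point by realized
    accuracy.

    Emits one row per grid point x trait plus a pedigree-model baseline row
    per trait (model label ``ABLUP``).  ``full_reference`` selects the
    full-data EBVs used in the correlation: ``same`` (the default — each
    variant is scored against its own full-data fit, the paired-analyses
    reading of realized accuracy) or ``ablup`` (every variant scored
    against the full-data pedigree fit, for sensitivity analysis).
    """
    if full_reference not in ("ablup", "same"):
        raise ValueError("full_reference must be 'ablup' or 'same'")
    grid = sweep_grid(mode)
    ids = data.plan.validation_ids
    rows = []
    for trait in traits:
        spec = data.specs[trait]
        full_ab = fit_ablup(data.plan.full_data, data, spec)
        red_ab = fit_ablup(data.plan.reduced_data, data, spec)
        rows.append(
            {
                "model": "ABLUP",
                "trait": trait,
                "accuracy": realized_accuracy(full_ab.ebv, red_ab.ebv, ids),
                "beta": np.nan, "tuning": "", "tau": np.nan, "omega": np.nan,
            }
        )
        for label, params in grid:
            red = fit_ssgblup(data.plan.reduced_data, data, spec, params)
            if full_reference == "same":
                full = fit_ssgblup(data.plan.full_data, data, spec, params)
            else:
                full = full_ab
            rows.append(
                {
                    "model": label,
                    "trait": trait,
                    "accuracy": realized_accuracy(full.ebv, red.ebv, ids),
                    "beta": params.beta,
                    "tuning": params.tuning,
                    "tau": params.tau,
                    "omega": params.omega,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end replicate on synthetic data
# ---------------------------------------------------------------------------

def prepare_synthetic_evaluation(
    cfg: SimConfig,
    n_validation: int = 100,
    traits: tuple = ("milk", "protein", "fat"),
) -> tuple[EvaluationData, pd.DataFrame]:
    """Simulate a population and package it for evaluation.

    Runs the generator, record editing is skipped (records are generated
    legal) but contemporary grouping and genotype QC are applied, the most
    recent ``n_validation`` genotyped cows are masked, and variance
    components are taken from the simulation truth.  Returns the evaluation
    bundle and the true breeding values.
    """
    ped, panel, true_bv = simulate_population(cfg)
    pheno = simulate_phenotypes(
        ped, true_bv, cfg, genotyped_ids=panel.individual_ids
    )
    records = form_contemporary_groups(pheno, ped)
    panel, _ = qc_filter(panel)
    plan = select_validation_cows(
        panel.individual_ids, records, ped, n=n_validation
    )
    specs = {
        t: ModelSpec.from_h2(
            t, cfg.phenotypic_var(t), cfg.traits[t].h2, cfg.repeatability
        )
        for t in traits
    }
    data = EvaluationData(
        ped=ped, records=records, panel=panel, plan=plan, specs=specs
    )
    return data, true_bv


def benchmark_replicate(
    cfg: SimConfig,
    n_validation: int = 100,
    trait: str = "milk",
    params: HybridParams | None = None,
    full_reference: str = "same",
) -> dict:
    """One paired ABLUP-vs-ssGBLUP comparison on a synthetic replicate.

    Returns realized accuracies (paired full/reduced analyses of the same
    model by default; ``full_reference='ablup'`` scores both models against
    the full-data pedigree fit) and true accuracies (correlation with
    simulated breeding values) for both models on the masked validation
    cows.
    """
    params = params or HybridParams()
    data, true_bv = prepare_synthetic_evaluation(cfg, n_validation, (trait,))
    spec = data.specs[trait]
    ids = data.plan.validation_ids

    full_ab = fit_ablup(data.plan.full_data, data, spec)
    red_ab = fit_ablup(data.plan.reduced_data, data, spec)
    red_ss = fit_ssgblup(data.plan.reduced_data, data, spec, params)
    if full_reference == "same":
        full_ss = fit_ssgblup(data.plan.full_data, data, spec, params)
    else:
        full_ss = full_ab

    return {
        "realized_ablup": realized_accuracy(full_ab.ebv, red_ab.ebv, ids),
        "realized_ssgblup": realized_accuracy(full_ss.ebv, red_ss.ebv, ids),
        "true_ablup": true_accuracy(red_ab.ebv, true_bv[trait], ids),
        "true_ssgblup": true_accuracy(red_ss.ebv, true_bv[trait], ids),
        "n_validation": len(ids),
        "n_records": len(data.plan.full_data),
    }
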