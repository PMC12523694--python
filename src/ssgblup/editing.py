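"""Lactation phenotype editing and contemporary-group formation.

Edits mirror routine national dairy evaluation practice: drop records with
unknown dates, enforce parity-specific age-at-calving windows, plausible
yield bounds, component-percentage bounds, and require every retained cow
to have a first-lactation record.  Contemporary groups are herd x calving
year x season; seasons follow the Southern-hemisphere convention with
summer spanning October-March and winter April-September.

All numeric windows are inclusive.  A record failing several rules is
attributed to the first failing rule in the stated order, so the report's
removal counts sum to rows(in) - rows(out).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
import numpy as np

from .pedigree import PedigreeTable

#: average month length in days, used when age at calving must be derived
DAYS_PER_MONTH = 30.4375

SUMMER_MONTHS = frozenset({10, 11, 12, 1, 2, 3})


@dataclass
class EditConfig:
    """Editing thresholds; defaults are the standard evaluation rules."""

    age_windows: dict = field(
        default_factory=lambda: {1: (20, 42), 2: (30, 54), 3: (40, 67)}
    )
    milk_range: tuple = (1000.0, 30000.0)
    pct_range: tuple = (2.0, 9.0)
    min_cg_animals: int = 5
    min_cg_sires: int = 2


@dataclass
class EditReport:
    removed_missing_dates: int = 0
    removed_age: int = 0
    removed_milk: int = 0
    removed_pct: int = 0
    removed_no_first_lactation: int = 0
    rows_in: int = 0
    rows_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("missing_dates", self.removed_missing_dates),
            ("age_window", self.removed_age),
            ("milk_yield", self.removed_milk),
            ("component_pct", self.removed_pct),
            ("no_first_lactation", self.removed_no_first_lactation),
        ]
        return pd.DataFrame(rows, columns=["rule", "n_removed"])

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def total_removed(self) -> int:
        return int(self.to_frame()["n_removed"].sum())


def assign_season(calving_date) -> str:
    """Season of calving: October-March is summer, April-September winter."""
    month = pd.Timestamp(calving_date).month
    return "summer" if month in SUMMER_MONTHS else "winter"


def _ensure_dates(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("calving_date", "birth_date"):
        if col in df.columns and not pd.api.types.is_datetime64_any_dtype(df[col]):
            df[col] = pd.to_datetime(df[col], errors="coerce")
    return df


def edit_lactations(
    raw: pd.DataFrame, rules: EditConfig | None = None
) -> tuple[pd.DataFrame, EditReport]:
    """Apply the record-level edits in order and report removals per rule.

    Expects columns ``cow``, ``herd``, ``parity``, ``calving_date``,
    ``birth_date``, ``milk_kg``, ``fat_kg``, ``protein_kg``; ``age_months``
    and the percentages are derived when absent.  Only parities 1-3 are
    legal input.  An empty result is allowed (with a warning).
    """
    rules = rules or EditConfig()
    df = _ensure_dates(raw.copy())
    report = EditReport(rows_in=len(df))

    if not df["parity"].isin(list(rules.age_windows)).all():
        bad = sorted(set(df["parity"]) - set(rules.age_windows))
        raise ValueError(f"parities outside {sorted(rules.age_windows)}: {bad}")
    dup = df.duplicated(subset=["cow", "parity"])
    if dup.any():
        raise ValueError(
            f"{dup.sum()} duplicate cow x parity records; one record per "
            "lactation expected"
        )

    derived_age = (df["calving_date"] - df["birth_date"]).dt.days / DAYS_PER_MONTH
    if "age_months" not in df.columns:
        df["age_months"] = derived_age
    else:
        df["age_months"] = df["age_months"].fillna(derived_age)
    for pct, kg in (("fat_pct", "fat_kg"), ("protein_pct", "protein_kg")):
        if pct not in df.columns:
            df[pct] = 100.0 * df[kg] / df["milk_kg"]

    ok_dates = df["calving_date"].notna() & df["birth_date"].notna()
    report.removed_missing_dates = int((~ok_dates).sum())

    lo = df["parity"].map(lambda p: rules.age_windows[p][0])
    hi = df["parity"].map(lambda p: rules.age_windows[p][1])
    ok_age = df["age_months"].between(lo, hi)
    report.removed_age = int((ok_dates & ~ok_age).sum())

    ok_milk = df["milk_kg"].between(*rules.milk_range)
    report.removed_milk = int((ok_dates & ok_age & ~ok_milk).sum())

    ok_pct = df["fat_pct"].between(*rules.pct_range) & df["protein_pct"].between(
        *rules.pct_range
    )
    report.removed_pct = int((ok_dates & ok_age & ok_milk & ~ok_pct).sum())

    kept = df[ok_dates & ok_age & ok_milk & ok_pct]
    with_first = set(kept.loc[kept["parity"] == 1, "cow"])
    ok_first = kept["cow"].isin(with_first)
    report.removed_no_first_lactation = int((~ok_first).sum())
    out = kept[ok_first].reset_index(drop=True)

    report.rows_out = len(out)
    if report.rows_out == 0:
        warnings.warn("all lactation records removed by editing", stacklevel=2)
    return out, report


def form_contemporary_groups(
    edited: pd.DataFrame,
    ped: PedigreeTable | None = None,
    min_animals: int = 5,
    min_sires: int = 2,
) -> pd.DataFrame:
    """Label records with herd-year-season groups and drop weak groups.

    A group must contain at least ``min_animals`` distinct cows and at least
    ``min_sires`` distinct known sires (via the pedigree).  Unknown sires do
    not contribute to the sire count.  Cows missing from the pedigree are
    counted with unknown sire, with a warning.  Re-applying this function to
    its own output is a fixed point.
    """
    df = _ensure_dates(edited.copy())
    year = df["calving_date"].dt.year.astype(int)
    season = df["calving_date"].map(assign_season)
    df["cg_id"] = (
        df["herd"].astype(str) + "_" + year.astype(str) + "_" + season
    )

    sire_of: dict[str, str | None] = {}
    if ped is not None:
        sire_of = dict(zip(ped.table["animal_id"], ped.table["sire_id"]))
        missing = set(df["cow"].astype(str)) - set(sire_of)
        if missing:
            warnings.warn(
                f"{len(missing)} cows not in pedigree; counted with unknown sire",
                stacklevel=2,
            )
    df["_sire"] = df["cow"].astype(str).map(lambda c: sire_of.get(c))

    grp = df.groupby("cg_id")
    n_cows = grp["cow"].nunique()
    n_sires = grp["_sire"].nunique(dropna=True)
    good = n_cows.index[(n_cows >= min_animals) & (n_sires >= min_sires)]
    out = df[df["cg_id"].isin(good)].drop(columns="_sire").reset_index(drop=True)
    return out
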