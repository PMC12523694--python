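"""Shared fixtures: toy pedigrees, random pedigree factories, and a small
simulated evaluation bundle reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from ssgblup import SimConfig, read_and_renumber


def random_pedigree_frame(n: int, rng: np.random.Generator,
                          p_founder: float = 0.15,
                          p_single_parent: float = 0.1) -> pd.DataFrame:
    """Random acyclic pedigree with inbreeding: parents drawn from earlier
    animals, some unknown."""
    rows = []
    for i in range(n):
        if i < 4 or rng.random() < p_founder:
            s = d = "0"
        else:
            s = f"a{int(rng.integers(1, i + 1))}"
            d = f"a{int(rng.integers(1, i + 1))}"
            if rng.random() < p_single_parent:
                d = "0"
        rows.append((f"a{i + 1}", s, d))
    return pd.DataFrame(rows, columns=["animal", "sire", "dam"])


@pytest.fixture
def trio_ped():
    """Unrelated sire and dam with one offspring."""
    return read_and_renumber(
        pd.DataFrame(
            {"animal": ["S", "D", "O"], "sire": ["0", "0", "S"], "dam": ["0", "0", "D"]}
        )
    )


@pytest.fixture
def fullsib_mating_ped():
    """S x D give full sibs X, Y; Z is the full-sib mating X x Y."""
    return read_and_renumber(
        pd.DataFrame(
            {
                "animal": ["S", "D", "X", "Y", "Z"],
                "sire": ["0", "0", "S", "S", "X"],
                "dam": ["0", "0", "D", "D", "Y"],
            }
        )
    )


def small_sim_config(seed: int = 11, **overrides) -> SimConfig:
    """Down-scaled population for fast end-to-end tests."""
    kw = dict(
        n_founders=80,
        n_generations=3,
        n_offspring_per_gen=420,
        n_sires_per_gen=15,
        n_sires_recent=60,
        n_snps=600,
        n_qtl=120,
        genotyped_fraction=120 / 1340,
        n_herds=8,
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def small_evaluation():
    """One small simulated evaluation bundle (pedigree, panel, records,
    validation plan, truth) shared by validation/model tests."""
    from ssgblup.validation import prepare_synthetic_evaluation

    cfg = small_sim_config(seed=11)
    data, true_bv = prepare_synthetic_evaluation(cfg, n_validation=30)
    return cfg, data, true_bv
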