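import numpy as np
import pandas as pd
import pytest

from contestmeta.dataio import ContestProfile, Dataset, EffectRecord
from contestmeta.synthetic import SimConfig, simulate_dataset


def make_record(effect_id, role, species="Aegla_longirostri", article="art1",
                r=0.3, n=20, study_type="laboratory", **kw):
    return EffectRecord(
        effect_id=effect_id, article_id=article, species=species,
        study_type=study_type, role=role, trait="body size",
        stat_kind="r", stat_value=r, n=n, **kw,
    )


@pytest.fixture
def toy_csv(tmp_path):
    """Two-row dataset CSV (one winner, one loser, r given, n=20)."""
    frame = pd.DataFrame(
        {
            "effect_id": ["e1", "e2"],
            "article_id": ["a1", "a1"],
            "species": ["Aegla longirostri", "Aegla longirostri"],
            "study_type": ["laboratory", "laboratory"],
            "role": ["loser", "winner"],
            "trait": ["body size", "body size"],
            "stat_kind": ["r", "r"],
            "stat_value": [0.4, -0.1],
            "df": [None, None],
            "n": [20, 20],
            "sign": ["+", "-"],
        }
    )
    path = tmp_path / "toy.csv"
    frame.to_csv(path, index=False)
    return path


@pytest.fixture
def toy_profiles_csv(tmp_path):
    frame = pd.DataFrame(
        {
            "species": ["Aegla longirostri"],
            "physical_contact": [True],
            "weapon_used_in_contact": [True],
            "escalation_observed": [True],
        }
    )
    path = tmp_path / "profiles.csv"
    frame.to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def default_sim():
    """One study-scale synthetic dataset (80 effects, 36 species)."""
    return simulate_dataset(SimConfig(seed=2024))


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset for fast model fits."""
    cfg = SimConfig(
        n_species=8,
        n_pairs_total=10,
        sigma2={"species": 0.02, "phylo": 0.0, "article": 0.04, "study_type": 0.0, "obs": 0.15},
        seed=7,
    )
    return simulate_dataset(cfg)
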