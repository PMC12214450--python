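import dataclasses

import numpy as np
import pytest

from contestmeta.dataio import tree_to_newick, write_dataset, read_dataset, write_profiles, read_profiles
from contestmeta.phylo import correlation_matrix
from contestmeta.synthetic import SimConfig, recovery_experiment, simulate_dataset, simulate_tree


def test_simulated_tree_is_seed_deterministic():
    a = tree_to_newick(simulate_tree(5, seed=1))
    b = tree_to_newick(simulate_tree(5, seed=1))
    assert a == b
    assert a != tree_to_newick(simulate_tree(5, seed=2))


def test_two_tip_tree_is_cherry_with_zero_correlation():
    corr = correlation_matrix(simulate_tree(2, seed=1))
    assert np.allclose(corr.matrix, np.eye(2))


def test_default_config_matches_study_conditions(default_sim):
    dataset, truth = default_sim
    assert len(dataset) == 80
    roles = [r.role for r in dataset.records]
    assert roles.count("loser") == 40 and roles.count("winner") == 40
    assert len(dataset.species) == 36
    cats = [p.cost_category for p in dataset.profiles.values()]
    assert cats.count("high") == 22 and cats.count("low") == 14
    esc_high = [p.escalation_observed for p in dataset.profiles.values() if p.cost_category == "high"]
    esc_low = [p.escalation_observed for p in dataset.profiles.values() if p.cost_category == "low"]
    assert sum(esc_high) == 20 and sum(esc_low) == 10


def test_simulated_dataset_survives_io_round_trip(tmp_path, default_sim):
    dataset, _ = default_sim
    write_dataset(dataset, tmp_path / "d.csv")
    write_profiles(dataset.profiles, tmp_path / "p.csv")
    again = read_dataset(tmp_path / "d.csv", profiles_path=tmp_path / "p.csv")
    assert len(again) == len(dataset)
    assert [r.z for r in again.records] == pytest.approx([r.z for r in dataset.records])


def test_generation_is_reproducible_and_records_pass_invariants():
    cfg = SimConfig(seed=99)
    ds1, _ = simulate_dataset(cfg)
    ds2, _ = simulate_dataset(cfg)
    assert ds1.records == ds2.records
    for rec in ds1.records:
        assert rec.v == 1.0 / (rec.n - 3)
        assert abs(rec.r) < 1


def test_noise_free_limit_recovers_cell_means():
    cfg = SimConfig(
        sigma2={"species": 0.0, "phylo": 0.0, "article": 0.0, "study_type": 0.0, "obs": 0.0},
        n_per_study=(10**6, 10**6),
        seed=13,
    )
    dataset, _ = simulate_dataset(cfg)
    for rec in dataset.records:
        cat = dataset.profiles[rec.species].cost_category
        truth = cfg.true_cell_means_z[(rec.role, cat)]
        assert rec.z == pytest.approx(truth, abs=0.01)


def test_suppression_yields_subset_of_unsuppressed():
    base = SimConfig(seed=21)
    full, _ = simulate_dataset(base)
    sup_cfg = dataclasses.replace(base, suppress_ns_prob=0.8)
    sup, truth = simulate_dataset(sup_cfg)
    full_ids = {r.effect_id: r for r in full.records}
    assert len(sup) < len(full)
    assert truth.n_suppressed == len(full) - len(sup)
    for rec in sup.records:
        assert full_ids[rec.effect_id] == rec


def test_total_variance_matches_law_of_total_variance():
    # at huge within-study n the empirical var of z converges to sum(sigma2)
    sigma2 = {"species": 0.05, "phylo": 0.0, "article": 0.05, "study_type": 0.0, "obs": 0.2}
    cfg = SimConfig(
        n_species=150,
        prop_high_cost=1.0,
        n_pairs_total=None,
        studies_per_species=(2, 2),
        n_per_study=(10**6, 10**6),
        true_cell_means_z={k: 0.0 for k in
                           [("loser", "high"), ("winner", "high"), ("loser", "low"), ("winner", "low")]},
        sigma2=sigma2,
        seed=31,
    )
    dataset, _ = simulate_dataset(cfg)
    z = np.array([r.z for r in dataset.records])
    assert z.var() == pytest.approx(sum(sigma2.values()), rel=0.15)


def test_recovery_experiment_reports_bias_and_rejection():
    rep = recovery_experiment(SimConfig(n_species=8, n_pairs_total=10, seed=3), n_reps=3,
                              random=("species", "obs"))
    assert rep["n_reps"] == 3
    assert rep["n_failures"] == 0
    assert set(rep["cells"]) == {"loser:high", "winner:high", "loser:low", "winner:low"}
    assert 0.0 <= rep["qm_rejection_rate_05"] <= 1.0


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(n_species=1)
    with pytest.raises(ValueError):
        SimConfig(n_per_study=(3, 10))
    with pytest.raises(ValueError):
        SimConfig(suppress_ns_prob=1.5)
    with pytest.raises(ValueError):
        SimConfig(sigma2={"obs": -0.1})
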