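"""Synthetic datasets with the structure the meta-analysis assumes.

The generator reproduces the generative form of the multilevel model:
each effect size is a cell mean (role x cost category) plus species,
phylogenetic, article, study-type and observation-level random intercepts
plus sampling noise with known variance 1/(n-3).  Defaults mirror the
study-scale conditions of the literature dataset the pipeline targets:
36 species (22 high-cost, 14 low-cost), 40 winner/loser pairs = 80 effect
sizes, escalation observed in 20 of 22 high-cost and 10 of 14 low-cost
species, heterogeneity dominated by the observation level with a small
article-level share and none attributable to species or phylogeny.

A single root seed feeds a named substream per level, so changing one
variance component never perturbs draws at other levels, and an optional
suppression step emulates publication bias by probabilistically discarding
non-significant effects after generation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from . import mlma
from .dataio import ContestProfile, Dataset, EffectRecord, normalize_species
from .effect_sizes import fisher_z
from .phylo import correlation_matrix, grafen_lengths

__all__ = ["SimConfig", "SimTruth", "simulate_tree", "simulate_dataset", "recovery_experiment"]

_STREAMS = {
    "tree": 1,
    "structure": 2,
    "species": 3,
    "phylo": 4,
    "article": 5,
    "study_type": 6,
    "obs": 7,
    "noise": 8,
    "suppression": 9,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


def _default_cell_means() -> dict:
    # Self-assessment pattern in the high-cost group (loser positive, winner
    # at zero); low-cost loser weakly positive, winner at zero.
    return {
        ("loser", "high"): 0.35,
        ("winner", "high"): 0.0,
        ("loser", "low"): 0.20,
        ("winner", "low"): 0.0,
    }


def _default_sigma2() -> dict:
    # Observation-level variance dominant, small article share, none at the
    # species / phylogeny / study-type levels.
    return {"species": 0.0, "phylo": 0.0, "article": 0.04, "study_type": 0.0, "obs": 0.35}


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of a synthetic contest-assessment dataset."""

    n_species: int = 36
    prop_high_cost: float = 22.0 / 36.0
    studies_per_species: tuple[int, int] = (1, 2)
    n_per_study: tuple[int, int] = (10, 60)
    n_pairs_total: Optional[int] = 40
    true_cell_means_z: dict = field(default_factory=_default_cell_means)
    sigma2: dict = field(default_factory=_default_sigma2)
    esc_rate_high: float = 20.0 / 22.0
    esc_rate_low: float = 10.0 / 14.0
    prop_field: float = 0.3
    suppress_ns_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        for lo, hi in (self.studies_per_species, self.n_per_study):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be nonempty with positive lower bound")
        if self.n_per_study[0] < 4:
            raise ValueError("n per study must be at least 4 (variance 1/(n-3))")
        for p in (self.prop_high_cost, self.suppress_ns_prob, self.prop_field,
                  self.esc_rate_high, self.esc_rate_low):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        for name, s2 in self.sigma2.items():
            if s2 < 0:
                raise ValueError(f"sigma2[{name!r}] must be nonnegative")


@dataclass
class SimTruth:
    """Realized random effects and design of one simulated dataset."""

    config: SimConfig
    newick: str
    cost_by_species: dict[str, str]
    species_effects: dict[str, float]
    phylo_effects: dict[str, float]
    article_effects: dict[str, float]
    study_type_effects: dict[str, float]
    n_suppressed: int = 0


def simulate_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Random labeled topology (uniform coalescent joins) with Grafen lengths.

    Tips are named ``Species_01 .. Species_NN``; the returned tree is
    ultrametric with depth 1 and deterministic given (n_species, seed).
    """
    if n_species < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = _rng(seed, "tree")
    taxa = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_species):
        taxon = dendropy.Taxon(label=f"Species_{i + 1:02d}")
        taxa.add_taxon(taxon)
        leaf = dendropy.Node(taxon=taxon)
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    tree.topology_only = True
    return grafen_lengths(tree)


def _species_names(n: int) -> list[str]:
    return [f"Species_{i + 1:02d}" for i in range(n)]


def _assign_categories(config: SimConfig) -> tuple[dict[str, str], dict[str, ContestProfile]]:
    names = _species_names(config.n_species)
    n_high = int(round(config.prop_high_cost * config.n_species))
    cost = {sp: ("high" if i < n_high else "low") for i, sp in enumerate(names)}
    n_esc_high = int(round(config.esc_rate_high * n_high))
    n_esc_low = int(round(config.esc_rate_low * (config.n_species - n_high)))
    profiles = {}
    high_seen = low_seen = 0
    for i, sp in enumerate(names):
        if cost[sp] == "high":
            esc = high_seen < n_esc_high
            high_seen += 1
            profiles[sp] = ContestProfile(sp, physical_contact=True,
                                          weapon_used_in_contact=True,
                                          escalation_observed=esc)
        else:
            esc = low_seen < n_esc_low
            contact = low_seen % 2 == 0  # mix of contact and display-only contests
            low_seen += 1
            profiles[sp] = ContestProfile(sp, physical_contact=contact,
                                          weapon_used_in_contact=False,
                                          escalation_observed=esc)
    return cost, profiles


def simulate_dataset(config: SimConfig) -> tuple[Dataset, SimTruth]:
    """Draw one dataset (paired winner/loser records) and its generating truth."""
    names = _species_names(config.n_species)
    cost, profiles = _assign_categories(config)
    tree = simulate_tree(config.n_species, config.seed)

    rng_struct = _rng(config.seed, "structure")
    lo, hi = config.studies_per_species
    studies_per = {sp: int(rng_struct.integers(lo, hi + 1)) for sp in names}
    if config.n_pairs_total is not None:
        for sp in names:
            studies_per[sp] = 1
        extra = config.n_pairs_total - config.n_species
        if extra < 0:
            raise ValueError("n_pairs_total smaller than n_species")
        for sp in rng_struct.choice(names, size=extra, replace=False if extra <= len(names) else True):
            studies_per[str(sp)] += 1

    s2 = {name: float(config.sigma2.get(name, 0.0)) for name in mlma.DEFAULT_RANDOM}
    u_species = {
        sp: val for sp, val in zip(
            names, math.sqrt(s2["species"]) * _rng(config.seed, "species").standard_normal(len(names))
        )
    }
    corr = correlation_matrix(tree, species_order=names)
    if s2["phylo"] > 0:
        chol = np.linalg.cholesky(corr.matrix + 1e-10 * np.eye(len(names)))
        u_ph = math.sqrt(s2["phylo"]) * (chol @ _rng(config.seed, "phylo").standard_normal(len(names)))
    else:
        u_ph = np.zeros(len(names))
    u_phylo = dict(zip(names, u_ph))
    u_study_type = {
        st: val for st, val in zip(
            ("field", "laboratory"),
            math.sqrt(s2["study_type"]) * _rng(config.seed, "study_type").standard_normal(2),
        )
    }

    rng_article = _rng(config.seed, "article")
    rng_obs = _rng(config.seed, "obs")
    rng_noise = _rng(config.seed, "noise")

    records: list[EffectRecord] = []
    u_article: dict[str, float] = {}
    art_counter = 0
    for sp in names:
        for _ in range(studies_per[sp]):
            art_counter += 1
            article_id = f"art{art_counter:03d}"
            u_article[article_id] = math.sqrt(s2["article"]) * float(rng_article.standard_normal())
            study_type = "field" if rng_struct.random() < config.prop_field else "laboratory"
            n = int(rng_struct.integers(config.n_per_study[0], config.n_per_study[1] + 1))
            v = 1.0 / (n - 3)
            for role in ("loser", "winner"):
                mu = (
                    config.true_cell_means_z[(role, cost[sp])]
                    + u_species[sp]
                    + u_phylo[sp]
                    + u_article[article_id]
                    + u_study_type[study_type]
                    + math.sqrt(s2["obs"]) * float(rng_obs.standard_normal())
                )
                z_obs = mu + math.sqrt(v) * float(rng_noise.standard_normal())
                r = math.tanh(z_obs)
                z_store = fisher_z(r)  # idempotent with the derivation path
                records.append(
                    EffectRecord(
                        effect_id=f"{article_id}_{role}",
                        article_id=article_id,
                        species=sp,
                        study_type=study_type,
                        role=role,
                        trait="rhp_trait",
                        stat_kind="r",
                        stat_value=r,
                        n=n,
                        sign="+" if r >= 0 else "-",
                        r=r,
                        z=z_store,
                        v=v,
                    )
                )

    n_suppressed = 0
    if config.suppress_ns_prob > 0:
        rng_sup = _rng(config.seed, "suppression")
        kept = []
        for rec in records:
            nonsig = abs(rec.z) / math.sqrt(rec.v) < 1.96
            if nonsig and rng_sup.random() < config.suppress_ns_prob:
                n_suppressed += 1
            else:
                kept.append(rec)
        records = kept

    dataset = Dataset(records=records, profiles=profiles)
    truth = SimTruth(
        config=config,
        newick=tree.as_string(schema="newick").strip(),
        cost_by_species=cost,
        species_effects=u_species,
        phylo_effects=u_phylo,
        article_effects=u_article,
        study_type_effects=u_study_type,
        n_suppressed=n_suppressed,
    )
    return dataset, truth


def recovery_experiment(
    config: SimConfig,
    n_reps: int,
    random: Sequence[str] = ("species", "article", "obs"),
    seed_offset: int = 10_000,
) -> dict:
    """Simulate-and-refit harness: bias/RMSE of cell means, QM rejection rate.

    Each replicate draws a dataset from ``config`` (seed advanced per rep),
    refits the moderated model with the requested random structure, and
    accumulates cell-mean estimates, variance components and the QM p-value.
    Fit failures are counted, not fatal.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    cells = mlma.MODERATOR_CELLS
    est = {cell: [] for cell in cells}
    sigma2_acc: dict[str, list[float]] = {}
    qm_p = []
    failures = 0
    for rep in range(n_reps):
        cfg = dataclasses.replace(config, seed=(config.seed + seed_offset + rep) % (2**31))
        dataset, _ = simulate_dataset(cfg)
        try:
            tree = simulate_tree(cfg.n_species, cfg.seed) if "phylo" in random else None
            fit = mlma.fit_dataset(dataset, tree=tree, random=random)
            means = {c.cell: c.mean_z for c in mlma.cell_means(fit, cells)}
            qm = mlma.wald_qm(fit)
        except Exception:
            failures += 1
            continue
        for cell in cells:
            est[cell].append(means[cell])
        for name, s2 in fit.sigma2.items():
            sigma2_acc.setdefault(name, []).append(s2)
        qm_p.append(qm.p)
    report = {
        "n_reps": n_reps,
        "n_failures": failures,
        "qm_rejection_rate_05": float(np.mean([p < 0.05 for p in qm_p])) if qm_p else float("nan"),
        "cells": {},
        "sigma2_mean": {k: float(np.mean(vals)) for k, vals in sigma2_acc.items()},
    }
    for cell in cells:
        vals = np.asarray(est[cell])
        truth = config.true_cell_means_z[cell]
        report["cells"]["{}:{}".format(*cell)] = {
            "truth": truth,
            "mean_estimate": float(vals.mean()) if vals.size else float("nan"),
            "bias": float(vals.mean() - truth) if vals.size else float("nan"),
            "rmse": float(np.sqrt(np.mean((vals - truth) ** 2))) if vals.size else float("nan"),
        }
    return report
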