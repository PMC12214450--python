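"""End-to-end pipeline: derive -> classify -> fit -> I2 -> Egger -> report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .classify import escalation_proportion, strategy_table
from .dataio import DataError, Dataset, read_dataset, read_newick, write_dataset
from .diagnostics import egger_test, funnel_frame, i2_multilevel
from .mlma import DEFAULT_RANDOM, cell_means, fit_dataset, wald_qm


@dataclass
class RunConfig:
    """Paths and model options for a full pipeline run."""

    dataset: str
    profiles: str
    tree: Optional[str] = None
    output_dir: str = "contestmeta_out"
    random: Sequence[str] = DEFAULT_RANDOM
    include_phylo_in_egger: bool = True
    moderators: bool = True
    seed: int = 0
    column_map: Optional[dict] = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def analyze_dataset(
    dataset: Dataset,
    tree=None,
    random: Sequence[str] = DEFAULT_RANDOM,
    include_phylo_in_egger: bool = True,
    moderators: bool = True,
) -> dict:
    """Run the analysis stages on an in-memory dataset; returns the summary dict."""
    random = tuple(random)
    if "phylo" in random and tree is None:
        raise DataError("stage 'phylo' failed: phylo random term requested but no tree supplied")
    fit = fit_dataset(dataset, tree=tree, moderators=moderators, random=random)
    qm = wald_qm(fit) if moderators else None
    het = i2_multilevel(fit)
    egger = egger_test(
        dataset, tree=tree, random=random, include_phylo=include_phylo_in_egger
    )
    calls = strategy_table(dataset)
    cells = cell_means(fit) if moderators else cell_means(fit, [("loser", "high")])
    summary = {
        "n_effect_sizes": len(dataset),
        "n_species": len(dataset.species),
        "coefficients": {
            name: {"estimate": float(fit.coef[name]), "se": float(fit.se[name])}
            for name in fit.coef_names
        },
        "sigma2": fit.sigma2,
        "loglik_reml": fit.loglik_reml,
        "converged": fit.converged,
        "qm": None if qm is None else {"statistic": qm.statistic, "df": qm.df, "p": qm.p},
        "cell_means": {
            "{}:{}".format(*c.cell): {
                "mean_z": c.mean_z,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "mean_r": c.mean_r,
            }
            for c in cells
        },
        "i2": het.to_dict(),
        "egger": egger.to_dict(),
        "strategy_calls": calls["call"].to_dict(),
    }
    by_cat = {}
    for cat in ("high", "low"):
        try:
            by_cat[cat] = {
                "n_species": sum(1 for p in dataset.profiles.values() if p.cost_category == cat),
                "escalation_pct": escalation_proportion(dataset.profiles, cat),
            }
        except DataError:
            by_cat[cat] = {"n_species": 0, "escalation_pct": None}
    summary["cost_categories"] = by_cat
    return summary


def run_full_analysis(config: RunConfig) -> dict:
    """Full pipeline over files; writes the report bundle and returns the summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    dataset = read_dataset(config.dataset, profiles_path=config.profiles,
                           column_map=config.column_map, derive=True)
    tree = read_newick(config.tree) if config.tree else None
    if tree is not None:
        dataset.validate_against_tree(tree)

    summary = analyze_dataset(
        dataset,
        tree=tree,
        random=config.random,
        include_phylo_in_egger=config.include_phylo_in_egger,
        moderators=config.moderators,
    )
    summary["meta"] = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    write_dataset(dataset, out / "dataset_derived.csv")
    strategy_table(dataset).to_csv(out / "strategy_calls.csv")
    funnel_frame(dataset).to_csv(out / "funnel.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
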