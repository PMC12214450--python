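"""Heterogeneity decomposition and publication-bias diagnostics.

Multilevel I²
-------------
With variance components ``sigma2_k`` from the fitted model and the
Higgins–Thompson "typical" sampling variance

    v_tilde = (k - 1) * sum(w_i) / ((sum w_i)^2 - sum w_i^2),   w_i = 1/v_i,

the share of total variance attributable to level k is

    I2_k = 100 * sigma2_k / (sum_j sigma2_j + v_tilde),

and the total I² is the sum over levels — the proportion of variance in
the effect sizes beyond what sampling error alone would produce.

Modified Egger test
-------------------
Publication bias (small-study effects) is probed by refitting the same
multilevel model with the sampling standard error ``sqrt(v_i)`` of each
effect as the sole moderator; a slope distinguishable from zero indicates
that smaller studies report systematically different effects.  The random
structure of the main analysis is retained (the phylogenetic term can be
toggled off).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import DataError, Dataset
from .mlma import (
    DEFAULT_RANDOM,
    MetaFit,
    RandomTerm,
    Z975,
    build_random_terms,
    dataset_frame,
    reml_fit,
)
from .phylo import PhyloCorrelation, correlation_matrix

__all__ = [
    "HeterogeneityReport",
    "EggerResult",
    "typical_sampling_variance",
    "i2_multilevel",
    "egger_test",
    "funnel_frame",
]


@dataclass(frozen=True)
class HeterogeneityReport:
    typical_v: float
    i2_total: float
    i2_by_level: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "typical_v": self.typical_v,
            "i2_total": self.i2_total,
            "i2_by_level": dict(self.i2_by_level),
        }


@dataclass(frozen=True)
class EggerResult:
    slope: float
    se: float
    ci_low: float
    ci_high: float
    p: float

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
        }


def typical_sampling_variance(v) -> float:
    """Higgins–Thompson typical within-study variance v-tilde."""
    v = np.asarray(v, float).ravel()
    if v.size < 2:
        raise DataError("typical sampling variance needs at least 2 effects")
    if np.any(v <= 0):
        raise DataError("sampling variances must be positive")
    w = 1.0 / v
    sw = w.sum()
    return float((v.size - 1) * sw / (sw**2 - (w**2).sum()))


def i2_multilevel(fit: MetaFit, v=None) -> HeterogeneityReport:
    """Decompose heterogeneity across the model's random-effect levels."""
    if not fit.converged:
        raise DataError("I2 decomposition requires a converged fit")
    v = fit.v if v is None else np.asarray(v, float).ravel()
    vt = typical_sampling_variance(v)
    total_sigma2 = float(sum(fit.sigma2.values()))
    denom = total_sigma2 + vt
    by_level = {name: 100.0 * s2 / denom for name, s2 in fit.sigma2.items()}
    return HeterogeneityReport(
        typical_v=vt,
        i2_total=100.0 * total_sigma2 / denom,
        i2_by_level=by_level,
    )


def egger_regression(
    y,
    v,
    random_terms: Sequence[RandomTerm] = (),
    **estimator_kwargs,
) -> tuple[EggerResult, MetaFit]:
    """Low-level Egger refit on arbitrary vectors (intercept + sqrt(v) moderator)."""
    y = np.asarray(y, float).ravel()
    v = np.asarray(v, float).ravel()
    se = np.sqrt(v)
    if np.unique(np.round(se, 12)).size < 2:
        raise DataError("Egger test undefined: sampling standard error is constant")
    X = pd.DataFrame({"intercept": np.ones_like(y), "sqrt_v": se})
    fit = reml_fit(y, v, X, random_terms, **estimator_kwargs)
    slope = float(fit.coef["sqrt_v"])
    slope_se = float(fit.se["sqrt_v"])
    z = slope / slope_se
    result = EggerResult(
        slope=slope,
        se=slope_se,
        ci_low=slope - Z975 * slope_se,
        ci_high=slope + Z975 * slope_se,
        p=float(2.0 * stats.norm.sf(abs(z))),
    )
    return result, fit


def egger_test(
    dataset: Dataset,
    tree=None,
    random: Sequence[str] = DEFAULT_RANDOM,
    include_phylo: bool = True,
    phylo_corr: Optional[PhyloCorrelation] = None,
    **estimator_kwargs,
) -> EggerResult:
    """Modified Egger publication-bias test on a derived dataset.

    Refits the multilevel model with sqrt(v) as the moderator, keeping the
    main analysis's random structure.  ``include_phylo=False`` drops the
    phylogenetic term (the variant without phylogeny).
    """
    frame = dataset_frame(dataset)
    random = tuple(r for r in random if include_phylo or r != "phylo")
    if "phylo" in random and phylo_corr is None:
        if tree is None:
            raise DataError("phylo random term requires a tree or a correlation matrix")
        phylo_corr = correlation_matrix(tree, species_order=sorted(set(frame["species"])))
    terms = build_random_terms(frame, random=random, phylo_corr=phylo_corr)
    result, _ = egger_regression(
        frame["z"].to_numpy(), frame["v"].to_numpy(), terms, **estimator_kwargs
    )
    return result


def funnel_frame(dataset: Dataset) -> pd.DataFrame:
    """Effect sizes against their standard errors, for funnel-style plots."""
    frame = dataset_frame(dataset)
    return pd.DataFrame(
        {
            "effect_id": frame["effect_id"],
            "z": frame["z"],
            "se": np.sqrt(frame["v"]),
        }
    )
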