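"""Categorical rules: contest-cost category and assessment-strategy diagnosis.

Cost category
-------------
Contests are binned by injury potential: *high* cost when rivals physically
use weapons (specialized structures that pierce, squeeze or impact) during
contact phases; *low* cost otherwise — whether contact occurs without
weapons or the contest is display-only, the decision to flee is then driven
mainly by energy expenditure.

Strategy diagnosis
------------------
Assessment strategies are diagnosed from the signs of the winner and loser
correlations between RHP traits and contest duration (Taylor–Elwood
framework):

==============  ==============  ============  =====================
loser sign      winner sign     escalation    call
==============  ==============  ============  =====================
positive        ns              any           self_WOA (WOA/E-WOA)
positive        negative        True          mutual_SAM
positive        negative        False/None    CAM_or_SAM
anything else                                 unresolved
==============  ==============  ============  =====================

Between-phase escalation (a trajectory from low-cost display behaviour to
high-cost contact/weapon behaviour) is the single pattern uniquely
predicted by the sequential assessment model, hence it is what separates
SAM from CAM when both signs fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .dataio import ContestProfile, DataError, Dataset

__all__ = [
    "Sign",
    "sign_from_ci",
    "cost_category",
    "StrategyCall",
    "strategy_call",
    "species_signs",
    "strategy_table",
    "escalation_proportion",
]

SIGNS = ("positive", "negative", "ns")
CALLS = ("self_WOA", "mutual_SAM", "CAM_or_SAM", "unresolved")

Sign = str

#: Normal 95% two-sided multiplier used for all interval decisions.
CI_MULTIPLIER = 1.959963984540054


def sign_from_ci(z: float, v: float, multiplier: float = CI_MULTIPLIER) -> Sign:
    """Classify an effect as positive / negative / ns from its Wald 95% CI.

    A CI that merely touches zero counts as ``ns`` (conservative tie-break).
    """
    if v <= 0:
        raise DataError(f"variance must be positive, got {v}")
    half = multiplier * math.sqrt(v)
    if z - half > 0:
        return "positive"
    if z + half < 0:
        return "negative"
    return "ns"


def cost_category(contact: bool, weapon_used_in_contact: bool) -> str:
    """Two-level cost classification: 'high' iff weapons are used in contact."""
    if weapon_used_in_contact and not contact:
        raise DataError("inconsistent profile: weapon use during contact without physical contact")
    return "high" if weapon_used_in_contact else "low"


@dataclass(frozen=True)
class StrategyCall:
    species: str
    loser_sign: Sign
    winner_sign: Sign
    escalation: Optional[bool]
    call: str


def strategy_call(
    loser_sign: Sign,
    winner_sign: Sign,
    escalation: Optional[bool],
    species: str = "",
) -> StrategyCall:
    """Deterministic, total mapping from the sign pattern to a strategy call."""
    for name, s in (("loser_sign", loser_sign), ("winner_sign", winner_sign)):
        if s not in SIGNS:
            raise DataError(f"{name} must be one of {SIGNS}, got {s!r}")
    if loser_sign == "positive" and winner_sign == "ns":
        call = "self_WOA"
    elif loser_sign == "positive" and winner_sign == "negative":
        call = "mutual_SAM" if escalation is True else "CAM_or_SAM"
    else:
        call = "unresolved"
    return StrategyCall(
        species=species,
        loser_sign=loser_sign,
        winner_sign=winner_sign,
        escalation=escalation,
        call=call,
    )


def species_signs(dataset: Dataset) -> pd.DataFrame:
    """Per-species winner/loser effect signs from inverse-variance pooling.

    Within each (species, role) cell the derived Fisher-Z values are pooled
    with fixed-effect weights 1/v; the pooled estimate's Wald 95% CI sets
    the sign.  Returns a frame indexed by species with columns
    ``loser_sign`` and ``winner_sign`` (NaN when a role is absent).
    """
    rows = []
    for rec in dataset.records:
        if rec.z is None or rec.v is None:
            raise DataError(f"{rec.effect_id}: derive z/v before classification")
        rows.append({"species": rec.species, "role": rec.role, "z": rec.z, "v": rec.v})
    df = pd.DataFrame(rows)
    out = {}
    for (sp, role), grp in df.groupby(["species", "role"]):
        w = 1.0 / grp["v"]
        pooled = float((w * grp["z"]).sum() / w.sum())
        pooled_v = float(1.0 / w.sum())
        out.setdefault(sp, {})[f"{role}_sign"] = sign_from_ci(pooled, pooled_v)
    return pd.DataFrame.from_dict(out, orient="index").rename_axis("species")


def strategy_table(dataset: Dataset) -> pd.DataFrame:
    """Strategy call per species, combining pooled signs with escalation evidence."""
    signs = species_signs(dataset)
    calls = []
    for sp, row in signs.iterrows():
        profile = dataset.profiles.get(sp)
        escalation = profile.escalation_observed if profile is not None else None
        loser = row.get("loser_sign")
        winner = row.get("winner_sign")
        if not isinstance(loser, str) or not isinstance(winner, str):
            calls.append(
                StrategyCall(sp, loser if isinstance(loser, str) else "ns",
                             winner if isinstance(winner, str) else "ns",
                             escalation, "unresolved")
            )
            continue
        calls.append(strategy_call(loser, winner, escalation, species=sp))
    frame = pd.DataFrame(
        [
            {
                "species": c.species,
                "loser_sign": c.loser_sign,
                "winner_sign": c.winner_sign,
                "escalation": c.escalation,
                "call": c.call,
            }
            for c in calls
        ]
    ).set_index("species").sort_index()
    return frame


def escalation_proportion(
    profiles: Iterable[ContestProfile] | Mapping[str, ContestProfile],
    category: str,
) -> float:
    """Percentage of species in a cost category with observed escalation.

    Requires escalation to be known (True/False) for every species in the
    category; reported to one decimal place.
    """
    if isinstance(profiles, Mapping):
        profiles = profiles.values()
    members = [p for p in profiles if p.cost_category == category]
    if not members:
        raise DataError(f"no species in cost category {category!r}")
    unknown = [p.species for p in members if p.escalation_observed is None]
    if unknown:
        raise DataError(f"escalation unknown for {sorted(unknown)} in category {category!r}")
    frac = sum(1 for p in members if p.escalation_observed) / len(members)
    return round(100.0 * frac, 1)
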