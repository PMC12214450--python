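"""Dataset schema and I/O for the contest meta-analysis.

The canonical input is a flat CSV with one row per winner-or-loser
correlation between contest duration and an RHP trait, plus a per-species
behavioural profile table and a Newick species tree.  Column names can be
remapped via a ``column_map`` so repository exports with arbitrary headers
can be read without editing the file.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import pandas as pd

from . import effect_sizes

__all__ = [
    "DataError",
    "EffectRecord",
    "ContestProfile",
    "Dataset",
    "read_dataset",
    "write_dataset",
    "read_profiles",
    "write_profiles",
    "read_newick",
    "normalize_species",
    "replace_record",
]

STUDY_TYPES = ("field", "laboratory")
ROLES = ("winner", "loser")
STAT_KINDS = ("r", "t", "F", "raw")

#: Mandatory dataset columns, in canonical order.
DATASET_COLUMNS = (
    "effect_id",
    "article_id",
    "species",
    "study_type",
    "role",
    "trait",
    "stat_kind",
    "stat_value",
    "df",
    "n",
    "sign",
)
DERIVED_COLUMNS = ("r", "z", "v")

PROFILE_COLUMNS = (
    "species",
    "physical_contact",
    "weapon_used_in_contact",
    "escalation_observed",
)


class DataError(ValueError):
    """Raised for schema violations or inconsistent records."""


def normalize_species(name: str) -> str:
    """Canonical species token: trimmed, internal spaces -> underscores.

    Exact-match policy — no fuzzy matching against tree labels, since a
    silently wrong match corrupts the phylogenetic correlation matrix.
    """
    return "_".join(str(name).strip().split())


@dataclass(frozen=True)
class EffectRecord:
    """One winner-or-loser correlation with its provenance.

    ``z`` (Fisher's Z) and ``v = 1/(n-3)`` are derived fields; they are
    populated by :func:`contestmeta.effect_sizes.derive_effect`.
    """

    effect_id: str
    article_id: str
    species: str
    study_type: str
    role: str
    trait: str = ""
    stat_kind: str = "r"
    stat_value: Optional[float] = None
    df: Optional[int] = None
    n: Optional[int] = None
    sign: Optional[str] = None
    r: Optional[float] = None
    z: Optional[float] = None
    v: Optional[float] = None
    raw_x: Optional[tuple] = None
    raw_y: Optional[tuple] = None
    extra: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if not self.species:
            raise DataError(f"{self.effect_id}: species must be nonempty")
        if self.role not in ROLES:
            raise DataError(f"{self.effect_id}: role must be one of {ROLES}, got {self.role!r}")
        if self.study_type not in STUDY_TYPES:
            raise DataError(
                f"{self.effect_id}: study_type must be one of {STUDY_TYPES}, got {self.study_type!r}"
            )
        if self.stat_kind not in STAT_KINDS:
            raise DataError(
                f"{self.effect_id}: stat_kind must be one of {STAT_KINDS}, got {self.stat_kind!r}"
            )
        if self.v is not None:
            if self.n is None or self.n < 4:
                raise DataError(f"{self.effect_id}: v present requires n >= 4 (got n={self.n})")
            if not math.isclose(self.v, 1.0 / (self.n - 3), rel_tol=0, abs_tol=1e-12):
                raise DataError(
                    f"{self.effect_id}: v={self.v!r} does not equal 1/(n-3)={1.0 / (self.n - 3)!r}"
                )
        if self.z is not None and not math.isfinite(self.z):
            raise DataError(f"{self.effect_id}: Fisher Z must be finite")


def replace_record(record: EffectRecord, **changes) -> EffectRecord:
    """`dataclasses.replace` wrapper (kept here so effect_sizes need not know the class)."""
    return dataclasses.replace(record, **changes)


@dataclass(frozen=True)
class ContestProfile:
    """Per-species contest descriptors and the derived cost category.

    ``escalation_observed`` is three-valued: True means the contest shows
    distinct phases escalating from low- to high-cost behaviour, False means
    phases were described without that trajectory, None means no usable
    description exists.  Unknown is deliberately not collapsed to False —
    escalation evidence is only needed to split sequential-assessment (SAM)
    from cumulative-assessment (CAM) diagnoses.
    """

    species: str
    physical_contact: bool
    weapon_used_in_contact: bool
    escalation_observed: Optional[bool] = None

    def __post_init__(self):
        if self.weapon_used_in_contact and not self.physical_contact:
            raise DataError(
                f"{self.species}: weapon use during contact implies physical contact"
            )

    @property
    def cost_category(self) -> str:
        from .classify import cost_category

        return cost_category(self.physical_contact, self.weapon_used_in_contact)


@dataclass
class Dataset:
    """Ordered effect records plus per-species contest profiles."""

    records: list[EffectRecord]
    profiles: dict[str, ContestProfile] = field(default_factory=dict)

    def __post_init__(self):
        ids = [rec.effect_id for rec in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise DataError(f"duplicate effect_id values: {sorted(dupes)}")
        if self.profiles:
            missing = {r.species for r in self.records} - set(self.profiles)
            if missing:
                raise DataError(f"species without a contest profile: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.species)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {col: getattr(rec, col) for col in DATASET_COLUMNS}
            for col in DERIVED_COLUMNS:
                row[col] = getattr(rec, col)
            row.update(rec.extra)
            rows.append(row)
        return pd.DataFrame(rows)

    def derive_effects(self) -> "Dataset":
        """Return a copy with z and v populated on every record."""
        return Dataset(
            records=[effect_sizes.derive_effect(rec) for rec in self.records],
            profiles=dict(self.profiles),
        )

    def validate_against_tree(self, tree: dendropy.Tree) -> None:
        tips = {normalize_species(t.label) for t in tree.taxon_namespace}
        missing = {rec.species for rec in self.records} - tips
        if missing:
            raise DataError(f"species absent from the tree: {sorted(missing)}")


def _clean(value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return value


def _record_from_row(row: Mapping[str, object], extra_cols: Sequence[str]) -> EffectRecord:
    n = _clean(row.get("n"))
    df_ = _clean(row.get("df"))
    stat_value = _clean(row.get("stat_value"))
    sign = _clean(row.get("sign"))
    if sign is not None:
        sign = str(sign).replace("−", "-").strip()
        if sign not in {"+", "-"}:
            raise DataError(f"{row.get('effect_id')}: sign must be '+' or '-', got {sign!r}")
    v = _clean(row.get("v"))
    n_int = int(n) if n is not None else None
    if v is not None and (n_int is None or n_int <= 3):
        raise DataError(
            f"{row.get('effect_id')}: sampling variance undefined for n={n_int} (needs n >= 4)"
        )
    return EffectRecord(
        effect_id=str(row["effect_id"]),
        article_id=str(row["article_id"]),
        species=normalize_species(str(row["species"])),
        study_type=str(row["study_type"]).strip(),
        role=str(row["role"]).strip(),
        trait=str(_clean(row.get("trait")) or ""),
        stat_kind=str(row["stat_kind"]).strip(),
        stat_value=float(stat_value) if stat_value is not None else None,
        df=int(df_) if df_ is not None else None,
        n=n_int,
        sign=sign,
        r=_clean(row.get("r")),
        z=_clean(row.get("z")),
        v=float(v) if v is not None else None,
        extra={c: row[c] for c in extra_cols},
    )


def read_dataset(
    path,
    profiles_path=None,
    column_map: Optional[Mapping[str, str]] = None,
    derive: bool = True,
) -> Dataset:
    """Read (and optionally derive z/v for) an effect-size CSV.

    Parameters
    ----------
    path
        CSV with at least the canonical columns (see ``DATASET_COLUMNS``).
    profiles_path
        Optional contest-profile CSV, attached to the dataset.
    column_map
        Mapping from canonical name to the column name actually present,
        e.g. ``{"species": "Species name"}``.
    derive
        If True (default), rows with a derivable effect size get z and v
        populated via the conversion chain.
    """
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns={actual: canon for canon, actual in column_map.items()})
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"dataset CSV is missing mandatory columns: {missing}")
    extra_cols = [c for c in frame.columns if c not in DATASET_COLUMNS + DERIVED_COLUMNS]
    records = [_record_from_row(row, extra_cols) for row in frame.to_dict("records")]
    profiles = read_profiles(profiles_path) if profiles_path is not None else {}
    ds = Dataset(records=records, profiles=profiles)
    if derive:
        ds = ds.derive_effects()
    return ds


def write_dataset(dataset: Dataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False, "yes": True, "no": False,
    "t": True, "f": False,
}


def _parse_bool(value, *, allow_unknown=False):
    value = _clean(value)
    if value is None or (isinstance(value, str) and value.strip().lower() in {"unknown", "na", "nan"}):
        if allow_unknown:
            return None
        raise DataError(f"boolean column has missing value {value!r}")
    if isinstance(value, (bool,)):
        return bool(value)
    key = str(value).strip().lower()
    if key not in _BOOL_MAP:
        raise DataError(f"cannot interpret {value!r} as a boolean")
    return _BOOL_MAP[key]


def read_profiles(path, column_map: Optional[Mapping[str, str]] = None) -> dict[str, ContestProfile]:
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns={actual: canon for canon, actual in column_map.items()})
    missing = [c for c in PROFILE_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"profile CSV is missing mandatory columns: {missing}")
    profiles: dict[str, ContestProfile] = {}
    for row in frame.to_dict("records"):
        sp = normalize_species(str(row["species"]))
        if sp in profiles:
            raise DataError(f"duplicate profile for species {sp}")
        profiles[sp] = ContestProfile(
            species=sp,
            physical_contact=_parse_bool(row["physical_contact"]),
            weapon_used_in_contact=_parse_bool(row["weapon_used_in_contact"]),
            escalation_observed=_parse_bool(row["escalation_observed"], allow_unknown=True),
        )
    return profiles


def write_profiles(profiles: Mapping[str, ContestProfile], path) -> None:
    rows = []
    for prof in profiles.values():
        esc = prof.escalation_observed
        rows.append(
            {
                "species": prof.species,
                "physical_contact": prof.physical_contact,
                "weapon_used_in_contact": prof.weapon_used_in_contact,
                "escalation_observed": "unknown" if esc is None else esc,
                "cost_category": prof.cost_category,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_newick(source) -> dendropy.Tree:
    """Read a rooted Newick tree from a path or a Newick string.

    The returned tree carries a ``topology_only`` attribute: True when no
    edge lengths are present (the tree then needs Grafen ultrametricization
    before a correlation matrix can be built).  Tip labels are normalized
    like species tokens and must be unique.
    """
    if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("("):
        text = str(source)
    else:
        text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise DataError(f"invalid Newick: {exc}") from exc
    labels = [normalize_species(t.label) for t in tree.taxon_namespace]
    if len(labels) < 2:
        raise DataError("tree must have at least 2 tips")
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise DataError(f"duplicate tip labels in tree: {sorted(dupes)}")
    for taxon, label in zip(tree.taxon_namespace, labels):
        taxon.label = label
    lengths = [e.length for e in tree.preorder_edge_iter() if e.head_node.parent_node is not None]
    tree.topology_only = all(l is None for l in lengths)
    if not tree.topology_only and any(l is None for l in lengths):
        raise DataError("tree mixes present and absent branch lengths")
    tree.is_rooted = True
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
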