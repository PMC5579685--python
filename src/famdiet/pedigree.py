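"""Nuclear-family pedigree handling.

Builds nuclear families from person/relationship records, applies the
eligibility rules of the analysis (half-siblings excluded, one member of
each twin/triplet set kept at random, families reduced below two members
dropped), enumerates relative pairs by subtype, and produces the kinship
(2*Phi) and household (H) matrices used by the variance-component model.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class PedigreeError(ValueError):
    """Raised for contradictory or malformed pedigree records."""


ROLES = ("mother", "father", "child")

#: Relative-pair subtype labels. Parent-offspring and spouse pairs are
#: interclass (members distinguishable); same-sex sibling pairs are
#: exchangeable and analysed intraclass via double entry.
PARENT_OFFSPRING_SUBTYPES = (
    "mother-daughter", "mother-son", "father-daughter", "father-son",
)
SIBLING_SUBTYPES = ("sister-sister", "sister-brother", "brother-brother")
SPOUSE_SUBTYPE = "mother-father"


@dataclass(frozen=True)
class Person:
    person_id: str
    family_id: str
    household_id: str
    role: str              # mother | father | child
    sex: str               # F | M
    age: int               # integer years
    country: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise PedigreeError(f"unknown role {self.role!r} for {self.person_id}")
        if self.sex not in ("F", "M"):
            raise PedigreeError(f"unknown sex {self.sex!r} for {self.person_id}")
        if self.role == "mother" and self.sex != "F":
            raise PedigreeError(f"mother {self.person_id} must have sex F")
        if self.role == "father" and self.sex != "M":
            raise PedigreeError(f"father {self.person_id} must have sex M")
        lo, hi = (2, 19) if self.role == "child" else (25, 65)
        if not lo <= self.age <= hi:
            warnings.warn(
                f"{self.role} {self.person_id} age {self.age} outside [{lo}, {hi}]",
                stacklevel=2,
            )


@dataclass
class Family:
    family_id: str
    members: list[Person]
    excluded_half_sibs: list[str] = field(default_factory=list)
    excluded_twins: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.members) < 2:
            raise PedigreeError(f"family {self.family_id} has fewer than 2 members")
        for role in ("mother", "father"):
            if sum(m.role == role for m in self.members) > 1:
                raise PedigreeError(f"family {self.family_id} has more than one {role}")

    @property
    def parents(self) -> list[Person]:
        return [m for m in self.members if m.role != "child"]

    @property
    def children(self) -> list[Person]:
        return [m for m in self.members if m.role == "child"]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def family_type(self) -> tuple[str, int]:
        roles = {m.role for m in self.parents}
        if roles == {"mother", "father"}:
            parents = "both"
        elif roles == {"mother"}:
            parents = "mother"
        elif roles == {"father"}:
            parents = "father"
        else:
            parents = "none"
        return parents, len(self.children)


@dataclass(frozen=True)
class RelativePair:
    person_a: Person
    person_b: Person
    main_type: str     # parent_offspring | sibling | spouse
    subtype: str
    exchangeable: bool


def _pair_label(a: Person, b: Person) -> tuple[str, str, bool, Person, Person]:
    """Classify an unordered dyad; returns (main, subtype, exchangeable, first, second).

    Ordering convention for interclass pairs: parent first for
    parent-offspring, mother first for spouses, sister first for
    opposite-sex sibling pairs.
    """
    roles = {a.role, b.role}
    if roles == {"mother", "father"}:
        mother = a if a.role == "mother" else b
        father = b if mother is a else a
        return "spouse", SPOUSE_SUBTYPE, False, mother, father
    if "child" in roles and roles != {"child"}:
        parent = a if a.role != "child" else b
        child = b if parent is a else a
        kid = "daughter" if child.sex == "F" else "son"
        return (
            "parent_offspring", f"{parent.role}-{kid}", False, parent, child,
        )
    if roles == {"child"}:
        sexes = sorted([a.sex, b.sex])
        if sexes == ["F", "F"]:
            return "sibling", "sister-sister", True, a, b
        if sexes == ["M", "M"]:
            return "sibling", "brother-brother", True, a, b
        sister = a if a.sex == "F" else b
        brother = b if sister is a else a
        return "sibling", "sister-brother", False, sister, brother
    raise PedigreeError(f"cannot classify pair ({a.person_id}, {b.person_id})")


def enumerate_relative_pairs(family: Family) -> list[RelativePair]:
    """All parent-offspring, sibling, and spouse dyads of a family, once each."""
    pairs = []
    members = family.members
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            main, subtype, exch, first, second = _pair_label(members[i], members[j])
            pairs.append(RelativePair(first, second, main, subtype, exch))
    return pairs


def pair_counts(families: Iterable[Family]) -> pd.Series:
    """Pair counts per subtype across families."""
    counts: dict[str, int] = {}
    for fam in families:
        for p in enumerate_relative_pairs(fam):
            counts[p.subtype] = counts.get(p.subtype, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def kinship_and_household(family: Family) -> tuple[np.ndarray, np.ndarray]:
    """Kinship (2*Phi) and household (H) matrices over family members.

    2*Phi is 1 on the diagonal, 0.5 for parent-offspring and full-sibling
    entries and 0 for spouses; H is all ones (one household per family).
    """
    members = family.members
    k = len(members)
    phi2 = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            main, *_ = _pair_label(members[i], members[j])
            phi2[i, j] = phi2[j, i] = 0.0 if main == "spouse" else 0.5
    household = np.ones((k, k))
    return phi2, household


# ---------------------------------------------------------------------------
# Family construction from flat records
# ---------------------------------------------------------------------------

def build_families(
    person_records: pd.DataFrame,
    relationship_records: pd.DataFrame | None = None,
    *,
    seed: int | np.random.Generator = 0,
) -> tuple[list[Family], dict[str, int]]:
    """Assemble eligible nuclear families from flat person records.

    ``person_records`` needs columns person_id, family_id, household_id,
    role, sex, age (country optional). ``relationship_records`` may carry
    columns (person_id, related_person_id, relation_code, biological) with
    relation codes ``half_sibling`` and ``twin`` identifying exclusions:
    half-siblings are dropped, and one member of each twin/triplet set is
    retained by seeded random choice. Families left with fewer than two
    members are dropped. Returns (families, exclusion_log).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    log = {"half_sibling": 0, "twin": 0, "small_family": 0}

    drop: dict[str, str] = {}
    if relationship_records is not None and len(relationship_records):
        rel = relationship_records
        known = set(person_records["person_id"])
        referenced = set(rel["person_id"]) | set(rel["related_person_id"])
        missing = referenced - known
        if missing:
            raise PedigreeError(f"relationship records reference unknown persons {sorted(missing)}")
        half = rel[rel["relation_code"] == "half_sibling"]
        for pid in half["person_id"]:
            if pid not in drop:
                drop[pid] = "half_sibling"
                log["half_sibling"] += 1
        # Twin/triplet sets: connected components of "twin" edges; keep one.
        twin = rel[rel["relation_code"] == "twin"]
        if len(twin):
            groups: dict[str, set[str]] = {}
            for a, b in zip(twin["person_id"], twin["related_person_id"]):
                ga, gb = groups.get(a), groups.get(b)
                if ga is None and gb is None:
                    g = {a, b}
                elif ga is not None and gb is None:
                    g = ga | {b}
                elif ga is None and gb is not None:
                    g = gb | {a}
                else:
                    g = ga | gb
                for m in g:
                    groups[m] = g
            seen: list[frozenset[str]] = []
            for g in groups.values():
                fg = frozenset(g)
                if fg not in seen:
                    seen.append(fg)
            for g in seen:
                ordered = sorted(g)
                keep = ordered[rng.integers(len(ordered))]
                for pid in ordered:
                    if pid != keep and pid not in drop:
                        drop[pid] = "twin"
                        log["twin"] += 1

    families: list[Family] = []
    for fid, group in person_records.groupby("family_id", sort=True):
        members, half_ex, twin_ex = [], [], []
        for rec in group.itertuples(index=False):
            reason = drop.get(rec.person_id)
            if reason is not None:
                (half_ex if reason == "half_sibling" else twin_ex).append(rec.person_id)
                continue
            members.append(
                Person(
                    person_id=str(rec.person_id),
                    family_id=str(fid),
                    household_id=str(rec.household_id),
                    role=rec.role,
                    sex=rec.sex,
                    age=int(rec.age),
                    country=str(getattr(rec, "country", "")),
                )
            )
        if len(members) < 2:
            log["small_family"] += 1
            continue
        families.append(
            Family(str(fid), members, excluded_half_sibs=half_ex, excluded_twins=twin_ex)
        )
    return families, log


def families_to_frame(families: Sequence[Family]) -> pd.DataFrame:
    rows = [
        {
            "person_id": m.person_id,
            "family_id": m.family_id,
            "household_id": m.household_id,
            "role": m.role,
            "sex": m.sex,
            "age": m.age,
            "country": m.country,
        }
        for fam in families
        for m in fam.members
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------

_TYPE_LABELS = {"mother": "Mother", "father": "Father", "both": "Mother, father", "none": ""}


def _type_label(ft: tuple[str, int]) -> str:
    parents, nc = ft
    child = "1 child" if nc == 1 else f"{nc} children"
    head = _TYPE_LABELS[parents]
    return f"{head}, {child}" if head else child


def tabulate_family_types(
    families: Sequence[Family] | None = None,
    *,
    type_counts: dict[tuple[str, int], int] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Family-type table plus summary statistics.

    Accepts either built families or a pre-counted ``type_counts`` mapping
    (parents-present, n_children) -> number of families, and returns the
    per-type table (count, percentage, individuals) and a summary dict with
    totals and one-decimal mean family and sibship sizes.
    """
    from .config import family_type_size

    if type_counts is None:
        if families is None:
            raise ValueError("provide families or type_counts")
        type_counts = {}
        for fam in families:
            ft = fam.family_type
            type_counts[ft] = type_counts.get(ft, 0) + 1

    n_families = sum(type_counts.values())
    rows = []
    for ft in sorted(type_counts, key=lambda t: ({"mother": 0, "father": 1, "both": 2, "none": 3}[t[0]], t[1])):
        count = type_counts[ft]
        size = family_type_size(ft)
        rows.append(
            {
                "family_type": _type_label(ft),
                "parents": ft[0],
                "n_children": ft[1],
                "n_families": count,
                "percentage": round(100.0 * count / n_families, 1),
                "n_individuals": count * size,
            }
        )
    table = pd.DataFrame(rows)

    n_parents = sum(
        c * {"mother": 1, "father": 1, "both": 2, "none": 0}[ft[0]]
        for ft, c in type_counts.items()
    )
    n_children = sum(c * ft[1] for ft, c in type_counts.items())
    n_individuals = n_parents + n_children
    summary = {
        "n_families": n_families,
        "n_individuals": n_individuals,
        "n_parents": n_parents,
        "n_children": n_children,
        "mean_family_size": round(n_individuals / n_families, 1),
        "mean_sibship_size": round(n_children / n_families, 1),
    }
    return table, summary


def split_children_by_age(
    families: Sequence[Family], cutoff_years: int = 11
) -> tuple[list[Family], list[Family]]:
    """Age-stratified family structures: (younger, older).

    Each stratum keeps the parents plus only the children on its side of
    the cutoff (age < cutoff -> younger); families whose remaining member
    count drops below two are dropped from that stratum.
    """
    younger, older = [], []
    for fam in families:
        for band, out in ((lambda a: a < cutoff_years, younger), (lambda a: a >= cutoff_years, older)):
            kept = fam.parents + [c for c in fam.children if band(c.age)]
            if len(kept) >= 2 and any(m.role == "child" for m in kept):
                out.append(Family(fam.family_id, kept))
    return younger, older
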