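"""ACMG/AMP 2015 evidence-combination engine.

Variants arrive with a set of evidence codes (PVS1, PS1-4, PM1-6, PP1-5 on
the pathogenic side; BA1, BS1-4, BP1-7 on the benign side) and the engine
combines them into the five-tier classification (pathogenic, likely
pathogenic, VUS, likely benign, benign) by the published combining rules.
Evidence assignment itself (e.g. deriving PM2 from population frequency)
is out of scope: codes are inputs, as they are in curated variant tables.

Rules are held as an explicit ordered clause table so the classification
can always be traced: ``explain`` reports every clause with its truth
value and ``classify`` names the first satisfied clause.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable

from .io_formats import ValidationError, VariantRecord

__all__ = [
    "Direction",
    "Strength",
    "Tier",
    "Criterion",
    "CriteriaSet",
    "Classification",
    "PATHOGENIC_CODES",
    "BENIGN_CODES",
    "ALL_CODES",
    "classify",
    "explain",
    "classify_table",
]


class Direction(str, Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


class Strength(str, Enum):
    STAND_ALONE = "stand_alone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


class Tier(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


#: code -> (direction, default strength)
_CODE_TABLE: dict[str, tuple[Direction, Strength]] = {}
_CODE_TABLE["PVS1"] = (Direction.PATHOGENIC, Strength.VERY_STRONG)
for _i in range(1, 5):
    _CODE_TABLE[f"PS{_i}"] = (Direction.PATHOGENIC, Strength.STRONG)
for _i in range(1, 7):
    _CODE_TABLE[f"PM{_i}"] = (Direction.PATHOGENIC, Strength.MODERATE)
for _i in range(1, 6):
    _CODE_TABLE[f"PP{_i}"] = (Direction.PATHOGENIC, Strength.SUPPORTING)
_CODE_TABLE["BA1"] = (Direction.BENIGN, Strength.STAND_ALONE)
for _i in range(1, 5):
    _CODE_TABLE[f"BS{_i}"] = (Direction.BENIGN, Strength.STRONG)
for _i in range(1, 8):
    _CODE_TABLE[f"BP{_i}"] = (Direction.BENIGN, Strength.SUPPORTING)

PATHOGENIC_CODES = frozenset(
    c for c, (d, _) in _CODE_TABLE.items() if d is Direction.PATHOGENIC
)
BENIGN_CODES = frozenset(
    c for c, (d, _) in _CODE_TABLE.items() if d is Direction.BENIGN
)
ALL_CODES = PATHOGENIC_CODES | BENIGN_CODES

#: codes later guidance deprecated (reputable-source assertions); accepted by
#: default because curated tables still use them, but can be switched off.
REPUTABLE_SOURCE_CODES = frozenset({"PP5", "BP6"})


@dataclass(frozen=True)
class Criterion:
    code: str
    strength_override: Strength | None = None

    def __post_init__(self) -> None:
        if self.code not in _CODE_TABLE:
            raise ValidationError(f"unknown ACMG/AMP code {self.code!r}")
        if self.strength_override is not None:
            if self.strength_override is Strength.STAND_ALONE and self.code != "BA1":
                raise ValidationError("stand_alone strength is reserved for BA1")

    @property
    def direction(self) -> Direction:
        return _CODE_TABLE[self.code][0]

    @property
    def strength(self) -> Strength:
        return self.strength_override or _CODE_TABLE[self.code][1]


class CriteriaSet:
    """Evidence codes for one variant; duplicate codes are rejected."""

    def __init__(self, criteria: Iterable[Criterion | str] = ()):
        self.criteria: list[Criterion] = []
        seen: set[str] = set()
        for item in criteria:
            criterion = Criterion(item) if isinstance(item, str) else item
            if criterion.code in seen:
                raise ValidationError(f"duplicate code {criterion.code}")
            seen.add(criterion.code)
            self.criteria.append(criterion)

    def codes(self) -> set[str]:
        return {c.code for c in self.criteria}

    def __iter__(self):
        return iter(self.criteria)

    def __len__(self) -> int:
        return len(self.criteria)

    def __repr__(self) -> str:
        return f"CriteriaSet({sorted(self.codes())})"


@dataclass
class Classification:
    tier: Tier
    matched_rule: str
    conflict_flag: bool = False

    def __post_init__(self) -> None:
        if self.conflict_flag and self.tier is not Tier.VUS:
            raise ValidationError("conflicting evidence must classify as VUS")

    @property
    def is_plp(self) -> bool:
        return self.tier in (Tier.PATHOGENIC, Tier.LIKELY_PATHOGENIC)


@dataclass(frozen=True)
class _Clause:
    tier: Tier
    name: str
    predicate: Callable[[dict[Strength, int]], bool]


def _counts(criteria: CriteriaSet, direction: Direction) -> dict[Strength, int]:
    counts = {s: 0 for s in Strength}
    for criterion in criteria:
        if criterion.direction is direction:
            counts[criterion.strength] += 1
    return counts


# Canonical clause ordering: pathogenic before likely-pathogenic, benign
# before likely-benign; within a tier, stronger-evidence clauses first.
_SA, _VS, _S, _M, _P = (
    Strength.STAND_ALONE,
    Strength.VERY_STRONG,
    Strength.STRONG,
    Strength.MODERATE,
    Strength.SUPPORTING,
)

_PATHOGENIC_CLAUSES: list[_Clause] = [
    _Clause(Tier.PATHOGENIC, "PVS + >=1 Strong", lambda c: c[_VS] >= 1 and c[_S] >= 1),
    _Clause(Tier.PATHOGENIC, "PVS + >=2 Moderate", lambda c: c[_VS] >= 1 and c[_M] >= 2),
    _Clause(
        Tier.PATHOGENIC,
        "PVS + 1 Moderate + 1 Supporting",
        lambda c: c[_VS] >= 1 and c[_M] >= 1 and c[_P] >= 1,
    ),
    _Clause(
        Tier.PATHOGENIC, "PVS + >=2 Supporting", lambda c: c[_VS] >= 1 and c[_P] >= 2
    ),
    _Clause(Tier.PATHOGENIC, ">=2 Strong", lambda c: c[_S] >= 2),
    _Clause(
        Tier.PATHOGENIC,
        "1 Strong + >=3 Moderate",
        lambda c: c[_S] >= 1 and c[_M] >= 3,
    ),
    _Clause(
        Tier.PATHOGENIC,
        "1 Strong + 2 Moderate + >=2 Supporting",
        lambda c: c[_S] >= 1 and c[_M] >= 2 and c[_P] >= 2,
    ),
    _Clause(
        Tier.PATHOGENIC,
        "1 Strong + 1 Moderate + >=4 Supporting",
        lambda c: c[_S] >= 1 and c[_M] >= 1 and c[_P] >= 4,
    ),
    _Clause(
        Tier.LIKELY_PATHOGENIC,
        "PVS + 1 Moderate",
        lambda c: c[_VS] >= 1 and c[_M] >= 1,
    ),
    _Clause(
        Tier.LIKELY_PATHOGENIC,
        "1 Strong + 1-2 Moderate",
        lambda c: c[_S] >= 1 and c[_M] >= 1,
    ),
    _Clause(
        Tier.LIKELY_PATHOGENIC,
        "1 Strong + >=2 Supporting",
        lambda c: c[_S] >= 1 and c[_P] >= 2,
    ),
    _Clause(Tier.LIKELY_PATHOGENIC, ">=3 Moderate", lambda c: c[_M] >= 3),
    _Clause(
        Tier.LIKELY_PATHOGENIC,
        ">=2 Moderate + >=2 Supporting",
        lambda c: c[_M] >= 2 and c[_P] >= 2,
    ),
    _Clause(
        Tier.LIKELY_PATHOGENIC,
        "1 Moderate + >=4 Supporting",
        lambda c: c[_M] >= 1 and c[_P] >= 4,
    ),
]

_BENIGN_CLAUSES: list[_Clause] = [
    _Clause(Tier.BENIGN, "BA1 stand-alone", lambda c: c[_SA] >= 1),
    _Clause(Tier.BENIGN, ">=2 Benign Strong", lambda c: c[_S] >= 2),
    _Clause(
        Tier.LIKELY_BENIGN,
        "1 Benign Strong + 1 Benign Supporting",
        lambda c: c[_S] >= 1 and c[_P] >= 1,
    ),
    _Clause(Tier.LIKELY_BENIGN, ">=2 Benign Supporting", lambda c: c[_P] >= 2),
]


def _validate(criteria: CriteriaSet, allow_reputable_source: bool) -> CriteriaSet:
    if not allow_reputable_source:
        dropped = criteria.codes() & REPUTABLE_SOURCE_CODES
        if dropped:
            criteria = CriteriaSet(
                [c for c in criteria if c.code not in REPUTABLE_SOURCE_CODES]
            )
    return criteria


def _first_match(
    clauses: list[_Clause], counts: dict[Strength, int]
) -> _Clause | None:
    for clause in clauses:
        if clause.predicate(counts):
            return clause
    return None


def classify(
    criteria: CriteriaSet | Iterable[str],
    allow_reputable_source: bool = True,
) -> Classification:
    """Combine evidence codes into a five-tier classification.

    When both a pathogenic-side and a benign-side clause are satisfied the
    evidence is contradictory and the variant is a VUS with
    ``conflict_flag`` set.  ``allow_reputable_source=False`` drops
    PP5/BP6 before combining.
    """
    if not isinstance(criteria, CriteriaSet):
        criteria = CriteriaSet(criteria)
    criteria = _validate(criteria, allow_reputable_source)
    path_match = _first_match(
        _PATHOGENIC_CLAUSES, _counts(criteria, Direction.PATHOGENIC)
    )
    benign_match = _first_match(_BENIGN_CLAUSES, _counts(criteria, Direction.BENIGN))
    if path_match and benign_match:
        return Classification(
            Tier.VUS,
            f"conflict: {path_match.name} vs {benign_match.name}",
            conflict_flag=True,
        )
    if path_match:
        return Classification(path_match.tier, path_match.name)
    if benign_match:
        return Classification(benign_match.tier, benign_match.name)
    return Classification(Tier.VUS, "no combining rule satisfied")


def explain(
    criteria: CriteriaSet | Iterable[str],
    allow_reputable_source: bool = True,
) -> list[tuple[str, bool]]:
    """Deterministic trace: every clause in canonical order with its truth.

    The first satisfied clause equals ``classify(...).matched_rule`` unless
    the evidence conflicts.
    """
    if not isinstance(criteria, CriteriaSet):
        criteria = CriteriaSet(criteria)
    criteria = _validate(criteria, allow_reputable_source)
    path_counts = _counts(criteria, Direction.PATHOGENIC)
    benign_counts = _counts(criteria, Direction.BENIGN)
    trace = [(cl.name, cl.predicate(path_counts)) for cl in _PATHOGENIC_CLAUSES]
    trace += [(cl.name, cl.predicate(benign_counts)) for cl in _BENIGN_CLAUSES]
    return trace


@dataclass
class ClassifiedVariant:
    """A variant with its evidence and resulting tier.

    The classification is computed from the criteria unless one is given
    explicitly (curated fixtures carry their published tiers verbatim)."""

    record: VariantRecord
    criteria: CriteriaSet
    classification: Classification | None = None

    def __post_init__(self) -> None:
        if self.classification is None:
            self.classification = classify(self.criteria)


def classify_table(
    records_with_criteria: Iterable[tuple[VariantRecord, CriteriaSet]],
    screen_mode: bool = False,
) -> list[ClassifiedVariant]:
    """Classify a variant table; in screen mode only P/LP records survive.

    Screen mode reproduces the reporting convention of predisposition
    screens, which carry only pathogenic / likely pathogenic findings
    forward to carrier counts and burden tests.
    """
    items = list(records_with_criteria)
    missing = [rec.variant_id for rec, crit in items if crit is None]
    if missing:
        raise ValidationError(f"records missing criteria: {missing}")
    classified = [ClassifiedVariant(rec, crit) for rec, crit in items]
    if screen_mode:
        classified = [cv for cv in classified if cv.classification.is_plp]
    return classified
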