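"""Domain types for the diary-to-questionnaire mapping pipeline.

The vocabulary mirrors dietary-assessment practice: a weighed food diary
(FD) records one row per eating occasion (EO); a short food questionnaire
(SFQ) defines a small set of food groups; mapping each diary food code onto
an SFQ group (or declaring it non-covered) yields an augmented database
from which coverage ratios are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


class MappingStatus(str, Enum):
    COVERED = "covered"
    PARTIAL = "partial"
    NON_COVERED = "non_covered"


class MatchStep(str, Enum):
    EXACT_NAME = "exact_name"
    EXACT_DESCRIPTION = "exact_description"
    FUZZY = "fuzzy"
    TOKEN = "token"
    MANUAL = "manual"
    NONE = "none"


class ValidationError(ValueError):
    """Raised when an input file or record violates the documented schema."""


@dataclass(frozen=True)
class FoodConsumption:
    """One eating occasion: who ate what, when, and how much (grams)."""

    subject_id: str
    day_index: int          # 1-based survey day
    weekday: str            # Mon..Sun
    meal_type: str
    food_code: str
    food_name: str
    food_description: str
    cooking_method: str
    food_group: str
    amount_g: float

    def __post_init__(self) -> None:
        if not self.food_code:
            raise ValidationError("food_code must be non-empty")
        if self.day_index < 1:
            raise ValidationError(f"day_index must be >= 1, got {self.day_index}")
        if self.weekday not in WEEKDAYS:
            raise ValidationError(f"weekday must be one of {WEEKDAYS}, got {self.weekday!r}")
        if not (self.amount_g >= 0):
            raise ValidationError(f"amount_g must be >= 0, got {self.amount_g}")


@dataclass(frozen=True)
class SFQGroup:
    """One questionnaire food group with its matching keywords.

    ``include_keywords`` are normalized phrases whose presence signals
    membership; ``exclude_keywords`` are tokens that veto a match (e.g. a
    fresh-fruit group excluding "juice" so fruit juices stay non-covered).
    """

    group_code: str
    label: str
    polarity: str  # "healthy" | "unhealthy"
    include_keywords: tuple[str, ...]
    exclude_keywords: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.group_code:
            raise ValidationError("group_code must be non-empty")
        if not self.include_keywords:
            raise ValidationError(f"group {self.group_code}: include_keywords must be non-empty")
        if self.polarity not in ("healthy", "unhealthy"):
            raise ValidationError(f"group {self.group_code}: polarity must be healthy/unhealthy")
        overlap = set(self.include_keywords) & set(self.exclude_keywords)
        if overlap:
            raise ValidationError(
                f"group {self.group_code}: keywords in both include and exclude: {sorted(overlap)}"
            )


@dataclass(frozen=True)
class CatalogueEntry:
    """One food code of the detailed survey's catalogue."""

    food_code: str
    name: str
    description: str = ""
    cooking_method: str = ""
    food_group: str = ""

    def __post_init__(self) -> None:
        if not self.food_code:
            raise ValidationError("food_code must be non-empty")


@dataclass(frozen=True)
class MappingEntry:
    """Verdict for one food code: covered / partial(fraction) / non-covered."""

    food_code: str
    status: MappingStatus
    target_group: Optional[str]
    coverage_fraction: float
    match_step: MatchStep
    similarity: Optional[float] = None
    needs_review: bool = False

    def __post_init__(self) -> None:
        validate_mapping_entry(self)


def validate_mapping_entry(e: "MappingEntry") -> None:
    if not e.food_code:
        raise ValidationError("MappingEntry.food_code must be non-empty")
    if not (0.0 <= e.coverage_fraction <= 1.0):
        raise ValidationError(f"{e.food_code}: coverage_fraction outside [0,1]")
    if e.status is MappingStatus.COVERED and e.coverage_fraction != 1.0:
        raise ValidationError(f"{e.food_code}: covered requires coverage_fraction=1")
    if e.status is MappingStatus.NON_COVERED:
        if e.coverage_fraction != 0.0:
            raise ValidationError(f"{e.food_code}: non_covered requires coverage_fraction=0")
        if e.target_group is not None:
            raise ValidationError(f"{e.food_code}: non_covered entry must have no target_group")
        if e.match_step is not MatchStep.NONE:
            raise ValidationError(f"{e.food_code}: non_covered requires match_step=none")
    else:
        if e.target_group is None:
            raise ValidationError(f"{e.food_code}: covered/partial entry requires a target_group")
        if e.status is MappingStatus.PARTIAL and not (0.0 < e.coverage_fraction < 1.0):
            raise ValidationError(f"{e.food_code}: partial requires 0 < coverage_fraction < 1")
    if (e.similarity is not None) != (e.match_step is MatchStep.FUZZY):
        raise ValidationError(f"{e.food_code}: similarity present iff match_step=fuzzy")
    if e.similarity is not None and not (0.0 <= e.similarity <= 1.0):
        raise ValidationError(f"{e.food_code}: similarity outside [0,1]")


@dataclass(frozen=True)
class AggregateSummary:
    """Mean, IQR, extrema, SD and SEM of a sample (sample SD, n-1)."""

    n: int
    mean: float
    sd: Optional[float]
    sem: Optional[float]
    q25: float
    q75: float
    min: float
    max: float


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample rank test.

    ``statistic`` is the rank sum W of the first sample (mid-ranks for
    ties); the two-sided p-value is computed from the distance of W to its
    null expectation under random relabelling.
    """

    statistic: float
    p_value: float
    method: str  # exact_enumeration | monte_carlo_permutation | normal_approximation
    n_x: int
    n_y: int
    n_perm: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0) and not math.isnan(self.p_value):
            raise ValidationError(f"p_value must lie in (0,1], got {self.p_value}")
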