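"""Readers and writers for the pipeline's flat files.

All files are UTF-8 comma-separated with a mandatory header row. The diary
reader takes an explicit column-name map because the source surveys'
headers are not standardized; everything downstream uses the canonical
names below.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .text import normalize_join
from .types import (
    CatalogueEntry,
    FoodConsumption,
    MappingEntry,
    MappingStatus,
    MatchStep,
    ValidationError,
    validate_mapping_entry,
)

PathLike = Union[str, Path]

DIARY_COLUMNS = (
    "subject_id", "day_index", "weekday", "meal_type", "food_code",
    "food_name", "food_description", "cooking_method", "food_group", "amount_g",
)
MAPPING_COLUMNS = (
    "food_code", "status", "target_group", "coverage_fraction",
    "match_step", "similarity", "needs_review",
)
CATALOGUE_COLUMNS = ("food_code", "name", "description", "cooking_method", "food_group")
AUGMENTED_COLUMNS = DIARY_COLUMNS + ("status", "target_group", "coverage_fraction", "match_step")


def default_sfq_path() -> Path:
    """Path of the 15-group questionnaire definition shipped with the package."""
    return Path(importlib.resources.files("dietmap") / "data" / "preschool_sfq.csv")


# ---------------------------------------------------------------- diary

def read_food_diary(
    path: PathLike,
    schema: Optional[Mapping[str, str]] = None,
) -> list[FoodConsumption]:
    """Read a food diary CSV into one ``FoodConsumption`` per row.

    ``schema`` maps canonical field names to the file's column names
    (identity by default). Missing columns raise a schema error naming the
    column; malformed rows (non-numeric or negative amount, bad day index)
    raise a validation error carrying 1-based data row numbers. Rows are
    never silently dropped.
    """
    schema = dict(schema or {})
    colmap = {field: schema.get(field, field) for field in DIARY_COLUMNS}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise ValidationError(f"diary file {path} lacks column(s): {', '.join(missing)}")

    records: list[FoodConsumption] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw = {field: getattr(row, src) for field, src in colmap.items()}
        try:
            records.append(
                FoodConsumption(
                    subject_id=raw["subject_id"],
                    day_index=_parse_int(raw["day_index"], "day_index"),
                    weekday=raw["weekday"],
                    meal_type=raw["meal_type"],
                    food_code=raw["food_code"],
                    food_name=raw["food_name"],
                    food_description=raw["food_description"],
                    cooking_method=raw["cooking_method"],
                    food_group=raw["food_group"],
                    amount_g=_parse_float(raw["amount_g"], "amount_g"),
                )
            )
        except ValidationError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError(
            f"diary file {path}: {len(errors)} invalid row(s):\n" + "\n".join(errors[:20])
        )
    return records


def _parse_int(value: str, name: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{name} is not an integer: {value!r}") from None


def _parse_float(value: str, name: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{name} is not numeric: {value!r}") from None


def write_food_diary(records: Sequence[FoodConsumption], path: PathLike) -> None:
    diary_to_frame(records).to_csv(path, index=False)


def diary_to_frame(records: Sequence[FoodConsumption]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=DIARY_COLUMNS)


# ---------------------------------------------------------------- SFQ definition

def read_sfq_definition(path: PathLike):
    """Read a questionnaire definition CSV into ordered ``SFQGroup`` records.

    Keyword cells hold ';'-separated phrases; each phrase is normalized on
    read. Duplicate group codes and empty include sets are rejected.
    """
    from .types import SFQGroup

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ("group_code", "label", "polarity", "include_keywords", "exclude_keywords")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"SFQ file {path} lacks column(s): {', '.join(missing)}")
    codes = df["group_code"].tolist()
    dupes = sorted({c for c in codes if codes.count(c) > 1})
    if dupes:
        raise ValidationError(f"SFQ file {path}: duplicate group codes: {', '.join(dupes)}")

    groups = []
    for row in df.itertuples(index=False):
        groups.append(
            SFQGroup(
                group_code=row.group_code,
                label=row.label,
                polarity=row.polarity,
                include_keywords=_split_keywords(row.include_keywords),
                exclude_keywords=_split_keywords(row.exclude_keywords),
            )
        )
    return groups


def _split_keywords(cell: str) -> tuple[str, ...]:
    phrases = [normalize_join(p) for p in str(cell).split(";")]
    return tuple(p for p in phrases if p)


# ---------------------------------------------------------------- catalogue

def read_catalogue(path: PathLike) -> list[CatalogueEntry]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CATALOGUE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"catalogue file {path} lacks column(s): {', '.join(missing)}")
    return [
        CatalogueEntry(
            food_code=row.food_code,
            name=row.name,
            description=row.description,
            cooking_method=row.cooking_method,
            food_group=row.food_group,
        )
        for row in df.itertuples(index=False)
    ]


def write_catalogue(entries: Sequence[CatalogueEntry], path: PathLike) -> None:
    pd.DataFrame([vars(e) for e in entries], columns=CATALOGUE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------- mapping table

def write_mapping_table(entries: Iterable[MappingEntry], path: PathLike) -> None:
    """Write a mapping table CSV; entries violating the invariants are refused."""
    rows = []
    for e in entries:
        validate_mapping_entry(e)
        rows.append(
            {
                "food_code": e.food_code,
                "status": e.status.value,
                "target_group": "" if e.target_group is None else e.target_group,
                "coverage_fraction": repr(e.coverage_fraction),
                "match_step": e.match_step.value,
                "similarity": "" if e.similarity is None else repr(e.similarity),
                "needs_review": str(bool(e.needs_review)),
            }
        )
    pd.DataFrame(rows, columns=MAPPING_COLUMNS).to_csv(path, index=False)


def read_mapping_table(path: PathLike) -> list[MappingEntry]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MAPPING_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"mapping file {path} lacks column(s): {', '.join(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            MappingEntry(
                food_code=row.food_code,
                status=MappingStatus(row.status),
                target_group=row.target_group or None,
                coverage_fraction=float(row.coverage_fraction),
                match_step=MatchStep(row.match_step),
                similarity=float(row.similarity) if row.similarity else None,
                needs_review=row.needs_review == "True",
            )
        )
    return entries


# ---------------------------------------------------------------- augmented / coverage frames

def write_augmented(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False)


def read_augmented(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "food_code": str, "target_group": str},
        keep_default_na=False,
        na_values=[],
    )
    for col in ("amount_g", "coverage_fraction"):
        df[col] = df[col].astype(float)
    df["day_index"] = df["day_index"].astype(int)
    return df


def write_coverage(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False)


def read_coverage(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str}, keep_default_na=False, na_values=[""])
    df["day_index"] = df["day_index"].astype(int)
    return df
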