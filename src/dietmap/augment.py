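"""Merge the food diary with the mapping table into the augmented database.

Each diary row (one eating occasion) gains the verdict of its food code:
status, target SFQ group, coverage fraction and the matching step that
produced the verdict. The covered weight of a consumption is its coverage
fraction; the non-covered weight is the complement, so the two always sum
to one per row.
"""

from __future__ import annotations

import warnings
from typing import Sequence, Union

import pandas as pd

from .io import AUGMENTED_COLUMNS, diary_to_frame
from .types import FoodConsumption, MappingEntry, ValidationError


def apply_mapping(
    diary: Union[Sequence[FoodConsumption], pd.DataFrame],
    mapping: Sequence[MappingEntry],
    force: bool = False,
) -> pd.DataFrame:
    """Return the augmented database: one output row per diary row.

    A diary food code absent from the mapping table aborts with an error
    naming the codes; coverage statistics computed after silently dropping
    or reclassifying rows would be meaningless. With ``force=True`` the
    error becomes a warning and the offending rows are classified
    non-covered with no matching step.
    """
    df = diary if isinstance(diary, pd.DataFrame) else diary_to_frame(diary)
    if df.empty:
        return pd.DataFrame(columns=AUGMENTED_COLUMNS)

    verdict = pd.DataFrame(
        {
            "food_code": [m.food_code for m in mapping],
            "status": [m.status.value for m in mapping],
            "target_group": [m.target_group or "" for m in mapping],
            "coverage_fraction": [m.coverage_fraction for m in mapping],
            "match_step": [m.match_step.value for m in mapping],
        }
    )
    unmapped = sorted(set(df["food_code"]) - set(verdict["food_code"]))
    if unmapped:
        msg = f"{len(unmapped)} diary food code(s) absent from mapping table: {unmapped[:10]}"
        if not force:
            raise ValidationError(msg)
        warnings.warn(msg + " — classified non_covered", stacklevel=2)
        extra = pd.DataFrame(
            {
                "food_code": unmapped,
                "status": "non_covered",
                "target_group": "",
                "coverage_fraction": 0.0,
                "match_step": "none",
            }
        )
        verdict = pd.concat([verdict, extra], ignore_index=True)

    out = df.merge(verdict, on="food_code", how="left", validate="many_to_one")
    assert len(out) == len(df), "augmentation must be row-conserving"
    return out[list(AUGMENTED_COLUMNS)]
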