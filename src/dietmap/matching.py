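"""Stepwise unidirectional mapping of catalogue food codes onto SFQ groups.

For each food code the steps are tried strictly in order:

1. exact match of the normalized food name against a group label or
   include phrase;
2. exact match of the normalized food description;
3. fuzzy match (length-normalized Levenshtein) of the name against every
   label and include phrase, accepted above a threshold;
4. token search: each word of the name, then of the description (cooking
   method included), looked up in the groups' include keywords, vetoed by
   exclude keywords.

The first successful step wins and later steps are never consulted. Fuzzy
and token verdicts carry a review flag: they stand in for the human
annotator who re-checked every automatic step in the original protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .text import normalize_join, normalize_text, similarity, tokens_of
from .types import (
    CatalogueEntry,
    FoodConsumption,
    MappingEntry,
    MappingStatus,
    MatchStep,
    SFQGroup,
    ValidationError,
)


@dataclass(frozen=True)
class MatchConfig:
    """Tunables of the matching protocol.

    fuzzy_threshold: minimum similarity for a fuzzy match (default 0.85:
        a one-character typo in a label of eight or more characters still
        matches, unrelated labels do not).
    review_band: similarity interval whose fuzzy matches are additionally
        flagged as borderline.
    """

    fuzzy_threshold: float = 0.85
    stopwords: frozenset[str] = frozenset()
    review_band: tuple[float, float] = (0.85, 0.95)
    fuzzy_enabled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.fuzzy_threshold <= 1.0):
            raise ValidationError("fuzzy_threshold must lie in (0, 1]")
        if self.review_band[0] > self.review_band[1]:
            raise ValidationError("review_band must satisfy lo <= hi")


def _group_phrases(g: SFQGroup, stopwords) -> list[str]:
    """Normalized label plus include phrases, deduplicated, order kept."""
    seen, out = set(), []
    for p in (normalize_join(g.label, stopwords), *g.include_keywords):
        if p and p not in seen:
            seen.add(p)
            out.append(p)
    return out


def exact_match_step(
    name_or_desc: str, groups: Sequence[SFQGroup], cfg: MatchConfig = MatchConfig()
) -> Optional[str]:
    """Group whose label or include phrase equals the normalized input."""
    text = normalize_join(name_or_desc, cfg.stopwords)
    if not text:
        return None
    for g in groups:
        if text in _group_phrases(g, cfg.stopwords):
            return g.group_code
    return None


def fuzzy_match_step(
    name_or_desc: str, groups: Sequence[SFQGroup], cfg: MatchConfig = MatchConfig()
) -> Optional[tuple[str, float, bool]]:
    """Best fuzzy match above threshold: (group_code, similarity, borderline).

    Ties are broken by higher similarity, then by group order in the SFQ
    definition (the first group scanned keeps the crown).
    """
    text = normalize_join(name_or_desc, cfg.stopwords)
    if not text:
        return None
    best: Optional[tuple[str, float]] = None
    for g in groups:
        for phrase in _group_phrases(g, cfg.stopwords):
            s = similarity(text, phrase)
            if best is None or s > best[1]:
                best = (g.group_code, s)
    if best is None or best[1] < cfg.fuzzy_threshold:
        return None
    borderline = cfg.review_band[0] <= best[1] <= cfg.review_band[1]
    return best[0], best[1], borderline


def token_search_step(
    name: str, desc: str, groups: Sequence[SFQGroup], cfg: MatchConfig = MatchConfig()
) -> Optional[str]:
    """First group holding a name/description token in its include keywords.

    Tokens are scanned in input order (name before description); a group is
    vetoed when any input token sits in its exclude keywords (this is what
    keeps "fruit juices" out of a fresh-fruit group excluding "juices").
    """
    name_tokens = normalize_text(name, cfg.stopwords)
    desc_tokens = normalize_text(desc, cfg.stopwords)
    all_tokens = set(name_tokens) | set(desc_tokens)
    include_sets = [tokens_of(_group_phrases(g, cfg.stopwords)) for g in groups]
    exclude_sets = [tokens_of(g.exclude_keywords) for g in groups]
    for tok in (*name_tokens, *desc_tokens):
        for g, inc, exc in zip(groups, include_sets, exclude_sets):
            if tok in inc and not (all_tokens & exc):
                return g.group_code
    return None


def map_food_code(
    entry: CatalogueEntry, groups: Sequence[SFQGroup], cfg: MatchConfig = MatchConfig()
) -> MappingEntry:
    """Apply the stepwise protocol to one catalogue entry."""
    if not entry.name:
        raise ValidationError(f"catalogue entry {entry.food_code}: empty name")
    if not groups:
        raise ValidationError("SFQ definition holds no groups")

    code = exact_match_step(entry.name, groups, cfg)
    if code is not None:
        return _covered(entry, code, MatchStep.EXACT_NAME)
    code = exact_match_step(entry.description, groups, cfg)
    if code is not None:
        return _covered(entry, code, MatchStep.EXACT_DESCRIPTION)
    if cfg.fuzzy_enabled:
        fuzzy = fuzzy_match_step(entry.name, groups, cfg)
        if fuzzy is not None:
            code, sim, _ = fuzzy
            return MappingEntry(
                food_code=entry.food_code,
                status=MappingStatus.COVERED,
                target_group=code,
                coverage_fraction=1.0,
                match_step=MatchStep.FUZZY,
                similarity=sim,
                needs_review=True,
            )
    desc = " ".join(p for p in (entry.description, entry.cooking_method) if p)
    code = token_search_step(entry.name, desc, groups, cfg)
    if code is not None:
        return MappingEntry(
            food_code=entry.food_code,
            status=MappingStatus.COVERED,
            target_group=code,
            coverage_fraction=1.0,
            match_step=MatchStep.TOKEN,
            needs_review=True,
        )
    return MappingEntry(
        food_code=entry.food_code,
        status=MappingStatus.NON_COVERED,
        target_group=None,
        coverage_fraction=0.0,
        match_step=MatchStep.NONE,
    )


def _covered(entry: CatalogueEntry, group_code: str, step: MatchStep) -> MappingEntry:
    return MappingEntry(
        food_code=entry.food_code,
        status=MappingStatus.COVERED,
        target_group=group_code,
        coverage_fraction=1.0,
        match_step=step,
    )


def build_mapping_table(
    catalogue: Sequence[CatalogueEntry],
    groups: Sequence[SFQGroup],
    cfg: MatchConfig = MatchConfig(),
    manual_overrides: Optional[Sequence[MappingEntry]] = None,
) -> list[MappingEntry]:
    """One verdict per food code; manual overrides replace algorithmic ones."""
    codes = [e.food_code for e in catalogue]
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        raise ValidationError(f"catalogue food codes not unique: {', '.join(dupes)}")
    table = {e.food_code: map_food_code(e, groups, cfg) for e in catalogue}
    for ov in manual_overrides or ():
        if ov.food_code not in table:
            raise ValidationError(f"override references unknown food code {ov.food_code}")
        step = MatchStep.NONE if ov.status is MappingStatus.NON_COVERED else MatchStep.MANUAL
        table[ov.food_code] = replace(ov, match_step=step, similarity=None)
    return [table[c] for c in codes]


def assign_partial_fraction(
    food_group_label: str,
    catalogue: Sequence[CatalogueEntry],
    mapping: Sequence[MappingEntry],
    diary: Optional[Sequence[FoodConsumption]] = None,
) -> float:
    """Non-covered fraction of one catalogue food group.

    Count-based by default (unmapped member codes / all member codes);
    consumption-weighted when a diary is supplied, so heavily consumed
    member codes dominate the fraction. Member codes keep their individual
    verdicts either way.
    """
    members = [e.food_code for e in catalogue if e.food_group == food_group_label]
    if not members:
        raise ValidationError(f"unknown catalogue food group: {food_group_label!r}")
    by_code = {m.food_code: m for m in mapping}
    noncov_weight = {c: 1.0 - by_code[c].coverage_fraction for c in members if c in by_code}
    if diary is None:
        return sum(noncov_weight.get(c, 1.0) for c in members) / len(members)
    counts = {c: 0 for c in members}
    for row in diary:
        if row.food_code in counts:
            counts[row.food_code] += 1
    total = sum(counts.values())
    if total == 0:
        return sum(noncov_weight.get(c, 1.0) for c in members) / len(members)
    return sum(counts[c] * noncov_weight.get(c, 1.0) for c in members) / total


@dataclass(frozen=True)
class DiscordanceReport:
    n_codes: int
    n_discordant: int
    discordant_codes: tuple[str, ...]


def compare_mappings(
    table_a: Sequence[MappingEntry], table_b: Sequence[MappingEntry]
) -> DiscordanceReport:
    """Annotator-agreement check: codes whose (status, target) verdicts differ."""
    a = {e.food_code: e for e in table_a}
    b = {e.food_code: e for e in table_b}
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))
        only_b = sorted(set(b) - set(a))
        raise ValidationError(
            f"mapping tables cover different code sets (only in A: {only_a[:10]}, "
            f"only in B: {only_b[:10]})"
        )
    discordant = tuple(
        sorted(c for c in a if (a[c].status, a[c].target_group) != (b[c].status, b[c].target_group))
    )
    return DiscordanceReport(n_codes=len(a), n_discordant=len(discordant), discordant_codes=discordant)
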