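"""Synthetic catalogue / questionnaire / diary generator with known truth.

The source microdata (a national preschool nutrition survey's weighed food
diary and a cohort study's short food questionnaire) are access-restricted,
so every pipeline stage is exercised on synthetic data that emulates their
published structure: ~1,652 food codes in 77 catalogue groups, 126 subjects
keeping a 4-day diary, and a 15-group questionnaire. A configured subset of
catalogue groups is truly mappable onto questionnaire groups (their food
names are built from the questionnaire's own keyword phrases, optionally
perturbed by typos); the rest are truly non-covered, named after the
commonly consumed non-covered items reported for the real survey (breakfast
cereals, fruit juices, sugars and syrups, ...). The planted labels are the
ground truth against which mapping and coverage recovery are scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import default_sfq_path, read_sfq_definition
from .text import normalize_join, tokens_of
from .types import CatalogueEntry, FoodConsumption, SFQGroup, ValidationError, WEEKDAYS

# Commonly consumed non-covered food groups of the source survey:
# (group name, eating occasions over the 4-day survey, mean g/day, SD g/day).
# EO counts weight the sampling of non-covered consumptions; the amount pair
# parameterizes the per-occasion lognormal serving model.
NONCOVERED_GROUP_TABLE: tuple[tuple[str, int, float, float], ...] = (
    ("ready to eat breakfast cereals", 351, 31, 17),
    ("white sliced bread and rolls", 239, 61, 34),
    ("other spreading fats", 224, 8, 5),
    ("wholemeal and brown bread and rolls", 192, 50, 29),
    ("fruit juices", 190, 173, 123),
    ("soups sauces and miscellaneous foods", 190, 52, 71),
    ("potatoes", 163, 79, 46),
    ("sugars syrups preserves and sweeteners", 158, 12, 13),
    ("bacon and ham", 148, 30, 25),
    ("rice and pasta flours grains and starch", 131, 86, 57),
    ("supplements", 124, 106, 60),
    ("meat products", 95, 52, 43),
    ("butter", 90, 9, 8),
    ("ice creams", 89, 57, 25),
    ("beef and veal dishes", 88, 129, 82),
    ("chicken turkey and game", 87, 44, 26),
    ("other breakfast cereals", 83, 130, 83),
    ("eggs and egg dishes", 64, 60, 30),
    ("fish and fish products", 62, 62, 32),
)

# Per-occasion serving means (g) cycled over mappable groups; they average
# 92 g, chosen so that at the default non-covered consumption probability
# of 0.44 the designed non-covered *amount* share is ~0.34.
_MAPPABLE_AMOUNT_MEANS = (52.0, 72.0, 92.0, 112.0, 132.0)
_MAPPABLE_SD_FACTOR = 0.65

# Qualifier vocabulary for name variants; deliberately disjoint from every
# questionnaire include/exclude keyword so qualifiers never drive a match.
_QUALIFIERS = ("plain", "homemade", "organic", "small", "large", "medium", "chilled", "frozen")

_MEAL_TYPES = ("breakfast", "lunch", "dinner", "snack")


@dataclass(frozen=True)
class SynthConfig:
    """Parameterization of the generator; defaults mirror the source surveys."""

    n_codes: int = 1652
    n_groups: int = 77
    n_sfq_groups: int = 15
    n_subjects: int = 126
    n_days: int = 4
    typo_rate: float = 0.0
    target_noncov_freq: float = 0.44      # designed P(consumption is non-covered)
    eo_mean: float = 17.0                 # eating occasions (diary entries) per subject-day
    eo_dispersion: float = 8.0            # negative-binomial shape (smaller = more spread)
    weekend_guarantee: bool = True        # every subject's window contains Sat or Sun
    amount_model: Optional[dict] = None   # group label -> (mean g, sd g) overrides
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_codes", "n_groups", "n_sfq_groups", "n_subjects", "n_days"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_groups > self.n_codes:
            raise ValidationError("n_groups cannot exceed n_codes")
        for name in ("typo_rate", "target_noncov_freq"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.eo_mean <= 0 or self.eo_dispersion <= 0:
            raise ValidationError("eo_mean and eo_dispersion must be positive")


@dataclass
class GroundTruth:
    """Planted labels: the oracle for mapping and coverage recovery tests."""

    code_to_sfq: dict[str, Optional[str]]          # food code -> true SFQ group (None = non-covered)
    group_to_sfq: dict[str, Optional[str]]         # catalogue group -> true SFQ group
    amount_params: dict[str, tuple[float, float]]  # catalogue group -> (mean g, sd g) per occasion
    group_weights: dict[str, float]                # sampling weight of each catalogue group


@dataclass(frozen=True)
class DesignedCoverage:
    """Exact non-covered fractions implied by the truth labels."""

    freq_fraction: float            # pooled: non-covered rows / all rows
    amount_fraction: float          # pooled: non-covered grams / all grams
    mean_daily_freq_ratio: float    # subject-day freq ratios averaged
    mean_daily_amount_ratio: float  # subject-day amount ratios averaged


# ---------------------------------------------------------------- SFQ definition

def generate_sfq_definition(cfg: SynthConfig) -> list[SFQGroup]:
    """The questionnaire the generator targets.

    The first (up to) 15 groups are the shipped questionnaire fixture; any
    surplus demanded by ``n_sfq_groups`` is filled with synthetic groups
    carrying unique keyword tokens.
    """
    base = read_sfq_definition(default_sfq_path())
    groups = base[: cfg.n_sfq_groups]
    for i in range(len(groups), cfg.n_sfq_groups):
        groups.append(
            SFQGroup(
                group_code=f"SYN{i:02d}",
                label=f"Synthetic category {i}",
                polarity="healthy" if i % 2 == 0 else "unhealthy",
                include_keywords=(f"synthcat{i} foods", f"synthcat{i}"),
            )
        )
    return groups


def signature_tokens(groups: Sequence[SFQGroup]) -> dict[str, str]:
    """One token per group found in no other group's keywords.

    Used to build token-matchable synthetic names that unambiguously route
    to their true group under the ordered token-search step.
    """
    include_sets = {
        g.group_code: tokens_of((normalize_join(g.label), *g.include_keywords)) for g in groups
    }
    all_excludes = tokens_of([kw for g in groups for kw in g.exclude_keywords])
    out: dict[str, str] = {}
    for g in groups:
        others = set().union(
            *(include_sets[h.group_code] for h in groups if h.group_code != g.group_code)
        ) if len(groups) > 1 else set()
        unique = sorted(include_sets[g.group_code] - others - all_excludes)
        if unique:
            out[g.group_code] = unique[0]
    return out


# ---------------------------------------------------------------- catalogue

def _apply_typo(text: str, rng: np.random.Generator) -> str:
    """One character substitution or deletion at a random position."""
    if len(text) < 2:
        return text
    pos = int(rng.integers(len(text)))
    if rng.random() < 0.5:
        return text[:pos] + text[pos + 1:]
    repl = chr(ord("a") + int(rng.integers(26)))
    return text[:pos] + repl + text[pos + 1:]


def generate_catalogue(cfg: SynthConfig) -> tuple[list[CatalogueEntry], GroundTruth]:
    """Build the food-code catalogue with planted mappability labels.

    Catalogue groups are split into truly non-covered groups (named after
    the survey's reported non-covered items, sampled in proportion to their
    reported eating-occasion counts) and mappable groups tied cyclically to
    questionnaire groups. Mappable food names are built from questionnaire
    phrases in four rotating forms that exercise every matching step:
    exact name, exact description, token-in-name, token-in-description.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    sfq = generate_sfq_definition(cfg)
    sig = signature_tokens(sfq)

    n_noncov = min(len(NONCOVERED_GROUP_TABLE), max(1, round(cfg.n_groups * 19 / 77)))
    if n_noncov >= cfg.n_groups:
        n_noncov = cfg.n_groups - 1 if cfg.n_groups > 1 else 1
    n_mappable = cfg.n_groups - n_noncov

    groups: list[tuple[str, Optional[str], tuple[float, float], float]] = []
    # label, true SFQ code, (amount mean, sd), sampling weight (within stratum)
    table_weight_total = sum(row[1] for row in NONCOVERED_GROUP_TABLE[:n_noncov])
    for name, eo, mean_g, sd_g in NONCOVERED_GROUP_TABLE[:n_noncov]:
        groups.append((name, None, (float(mean_g), float(sd_g)), eo / table_weight_total))
    sfq_with_sig = [g for g in sfq if g.group_code in sig] or sfq
    for i in range(n_mappable):
        target = sfq_with_sig[i % len(sfq_with_sig)]
        mean_g = _MAPPABLE_AMOUNT_MEANS[i % len(_MAPPABLE_AMOUNT_MEANS)]
        groups.append(
            (
                f"mappable group {i:02d} ({target.group_code})",
                target.group_code,
                (mean_g, mean_g * _MAPPABLE_SD_FACTOR),
                1.0 / n_mappable,
            )
        )

    if cfg.amount_model:
        groups = [
            (label, tgt, tuple(map(float, cfg.amount_model.get(label, amt))), w)
            for label, tgt, amt, w in groups
        ]

    sfq_by_code = {g.group_code: g for g in sfq}
    entries: list[CatalogueEntry] = []
    code_to_sfq: dict[str, Optional[str]] = {}
    forms = ("exact_name", "exact_desc", "token_name", "token_desc")
    next_code = 10001
    for j in range(cfg.n_codes):
        label, target, _, _ = groups[j % len(groups)]
        code = str(next_code)
        next_code += 1
        if target is None:
            variant = j // len(groups)
            name = label if variant == 0 else f"{label} type {variant}"
            entry = CatalogueEntry(code, name, "", "", label)
        else:
            g = sfq_by_code[target]
            phrases = list(g.include_keywords)
            phrase = phrases[(j // len(groups)) % len(phrases)]
            qualifier = _QUALIFIERS[(j // len(groups)) % len(_QUALIFIERS)]
            form = forms[j % len(forms)] if target in sig else forms[j % 2]
            if form == "exact_name":
                name, desc = phrase, ""
            elif form == "exact_desc":
                name, desc = f"item {code}", phrase
            elif form == "token_name":
                name, desc = f"{sig[target]} {qualifier}", ""
            else:
                name, desc = f"item {code}", f"{qualifier} {sig[target]}"
            if cfg.typo_rate > 0 and rng.random() < cfg.typo_rate:
                if name.startswith("item "):
                    desc = _apply_typo(desc, rng)
                else:
                    name = _apply_typo(name, rng)
            entry = CatalogueEntry(code, name, desc, "", label)
        entries.append(entry)
        code_to_sfq[code] = target

    truth = GroundTruth(
        code_to_sfq=code_to_sfq,
        group_to_sfq={label: tgt for label, tgt, _, _ in groups},
        amount_params={label: amt for label, _, amt, _ in groups},
        group_weights={label: w for label, _, _, w in groups},
    )
    return entries, truth


# ---------------------------------------------------------------- diary

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _weekday_layout(cfg: SynthConfig, rng: np.random.Generator) -> list[list[str]]:
    """Consecutive-weekday window per subject, optionally spanning a weekend."""
    layouts = []
    for _ in range(cfg.n_subjects):
        while True:
            start = int(rng.integers(7))
            days = [WEEKDAYS[(start + d) % 7] for d in range(cfg.n_days)]
            if not cfg.weekend_guarantee or {"Sat", "Sun"} & set(days) or cfg.n_days >= 7:
                break
        layouts.append(days)
    return layouts


def generate_diary(
    cfg: SynthConfig,
    catalogue: Sequence[CatalogueEntry],
    truth: GroundTruth,
    planted_group_counts: Optional[dict[str, int]] = None,
) -> list[FoodConsumption]:
    """Simulate the weighed food diary.

    Per subject-day the eating-occasion count is negative-binomial
    (truncated at 1); each occasion is non-covered with probability
    ``target_noncov_freq`` (group drawn by the configured weights within
    the stratum), amounts are lognormal per group. ``planted_group_counts``
    additionally plants an exact number of eating occasions for the named
    groups, spread round-robin over subject-days (used to reproduce
    reported per-group occasion counts exactly). Deterministic given seed.
    """
    if not catalogue:
        raise ValidationError("catalogue is empty")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))

    by_group: dict[str, list[CatalogueEntry]] = {}
    for e in catalogue:
        by_group.setdefault(e.food_group, []).append(e)
    noncov_groups = [g for g in by_group if truth.group_to_sfq.get(g) is None]
    mappable_groups = [g for g in by_group if truth.group_to_sfq.get(g) is not None]
    noncov_w = np.array([truth.group_weights[g] for g in noncov_groups], dtype=float)
    noncov_w = noncov_w / noncov_w.sum() if noncov_w.size else noncov_w
    mappable_w = np.array([truth.group_weights[g] for g in mappable_groups], dtype=float)
    mappable_w = mappable_w / mappable_w.sum() if mappable_w.size else mappable_w
    lognorm = {g: _lognormal_params(*truth.amount_params[g]) for g in by_group}

    p_nb = cfg.eo_dispersion / (cfg.eo_dispersion + cfg.eo_mean)
    layouts = _weekday_layout(cfg, rng)
    records: list[FoodConsumption] = []
    for s in range(cfg.n_subjects):
        subject = f"S{s + 1:04d}"
        for d in range(1, cfg.n_days + 1):
            n_eo = max(1, int(rng.negative_binomial(cfg.eo_dispersion, p_nb)))
            for k in range(n_eo):
                noncov = bool(rng.random() < cfg.target_noncov_freq)
                if noncov and noncov_groups:
                    grp = noncov_groups[int(rng.choice(len(noncov_groups), p=noncov_w))]
                elif mappable_groups:
                    grp = mappable_groups[int(rng.choice(len(mappable_groups), p=mappable_w))]
                else:
                    grp = noncov_groups[int(rng.choice(len(noncov_groups), p=noncov_w))]
                records.append(
                    _draw_consumption(rng, subject, d, layouts[s][d - 1], grp, by_group, lognorm, k)
                )

    if planted_group_counts:
        unknown = sorted(set(planted_group_counts) - set(by_group))
        if unknown:
            raise ValidationError(f"planted counts reference unknown groups: {unknown}")
        slot = 0
        n_slots = cfg.n_subjects * cfg.n_days
        for grp, count in planted_group_counts.items():
            for _ in range(count):
                s, d = divmod(slot % n_slots, cfg.n_days)
                records.append(
                    _draw_consumption(
                        rng, f"S{s + 1:04d}", d + 1, layouts[s][d], grp, by_group, lognorm, 99
                    )
                )
                slot += 1
    return records


def _draw_consumption(rng, subject, day, weekday, grp, by_group, lognorm, k) -> FoodConsumption:
    codes = by_group[grp]
    entry = codes[int(rng.integers(len(codes)))]
    mu, sigma = lognorm[grp]
    amount = float(rng.lognormal(mu, sigma))
    return FoodConsumption(
        subject_id=subject,
        day_index=day,
        weekday=weekday,
        meal_type=_MEAL_TYPES[k % len(_MEAL_TYPES)],
        food_code=entry.food_code,
        food_name=entry.name,
        food_description=entry.description,
        cooking_method=entry.cooking_method,
        food_group=entry.food_group,
        amount_g=round(amount, 2),
    )


# ---------------------------------------------------------------- truth coverage

def ground_truth_coverage(
    truth: GroundTruth, diary: Sequence[FoodConsumption]
) -> DesignedCoverage:
    """Exact non-covered fractions implied by the planted labels.

    Computed by direct recounting over diary rows (independently of the
    pipeline's own aggregation) so it can serve as the recovery oracle.
    """
    if not diary:
        raise ValidationError("diary is empty")
    n_noncov = 0
    g_total = g_noncov = 0.0
    per_day: dict[tuple[str, int], list[float]] = {}
    for row in diary:
        if row.food_code not in truth.code_to_sfq:
            raise ValidationError(f"diary food code {row.food_code} unknown to ground truth")
        nc = 1.0 if truth.code_to_sfq[row.food_code] is None else 0.0
        n_noncov += nc
        g_total += row.amount_g
        g_noncov += row.amount_g * nc
        key = (row.subject_id, row.day_index)
        per_day.setdefault(key, [0.0, 0.0, 0.0, 0.0])
        acc = per_day[key]
        acc[0] += 1
        acc[1] += nc
        acc[2] += row.amount_g
        acc[3] += row.amount_g * nc

    freq_ratios = [acc[1] / acc[0] for acc in per_day.values()]
    amount_ratios = [acc[3] / acc[2] for acc in per_day.values() if acc[2] > 0]
    return DesignedCoverage(
        freq_fraction=n_noncov / len(diary),
        amount_fraction=g_noncov / g_total if g_total > 0 else float("nan"),
        mean_daily_freq_ratio=float(np.mean(freq_ratios)),
        mean_daily_amount_ratio=float(np.mean(amount_ratios)) if amount_ratios else float("nan"),
    )
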