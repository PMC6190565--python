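"""The stepwise mapping protocol: step behavior, precedence, agreement."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietmap.matching import (
    MatchConfig,
    assign_partial_fraction,
    build_mapping_table,
    compare_mappings,
    exact_match_step,
    fuzzy_match_step,
    map_food_code,
    token_search_step,
)
from dietmap.simulate import generate_catalogue, generate_sfq_definition
from dietmap.types import (
    CatalogueEntry,
    MappingEntry,
    MappingStatus,
    MatchStep,
    SFQGroup,
    ValidationError,
)


_SFQ_CACHE: list[SFQGroup] | None = None


def _cached_sfq() -> list[SFQGroup]:
    global _SFQ_CACHE
    if _SFQ_CACHE is None:
        from dietmap.io import default_sfq_path, read_sfq_definition

        _SFQ_CACHE = read_sfq_definition(default_sfq_path())
    return _SFQ_CACHE


# ---------------------------------------------------------------- exact step

def test_exact_match_is_case_and_punctuation_insensitive(sfq_groups):
    assert exact_match_step("sweets", sfq_groups) == "C25m"
    assert exact_match_step("SWEETS!", sfq_groups) == "C25m"


def test_exact_match_misses_unlisted_food(sfq_groups):
    # a breakfast-cereal item has no questionnaire group to land in
    assert exact_match_step("Ready-to-eat breakfast cereals", sfq_groups) is None
    assert exact_match_step("", sfq_groups) is None


# ---------------------------------------------------------------- fuzzy step

def test_fuzzy_matches_misspelled_label(sfq_groups):
    res = fuzzy_match_step("crisps or savoury snacks", sfq_groups, MatchConfig())
    assert res is not None
    code, sim, borderline = res
    assert code == "C25k"
    # "savoury" -> "savor" is 2 edits over a 24-character label
    assert sim == pytest.approx(1 - 2 / 24, abs=1e-12)
    assert borderline  # inside the (0.85, 0.95) review band


def test_fuzzy_exact_input_scores_one(sfq_groups):
    res = fuzzy_match_step("Sweets", sfq_groups, MatchConfig())
    assert res is not None and res[1] == 1.0


def test_fuzzy_rejects_unrelated_input(sfq_groups):
    assert fuzzy_match_step("eggs", sfq_groups, MatchConfig()) is None


# ---------------------------------------------------------------- token step

def test_token_search_finds_group_via_description(sfq_groups):
    code = token_search_step("item 42", "grilled pork sausage", sfq_groups)
    assert code == "C25i"  # hamburger / hot dog / sausage / meat pie


def test_token_search_honors_exclude_keywords(sfq_groups):
    # the fresh-fruit group excludes "juice(s)": fruit juices stay unmatched
    assert token_search_step("fruit juices", "", sfq_groups) is None
    assert token_search_step("fresh fruit", "", sfq_groups) == "C25a"


def test_token_search_no_overlap_is_absent(sfq_groups):
    assert token_search_step("porridge", "oats", sfq_groups) is None


# ---------------------------------------------------------------- full protocol

def test_exact_name_match_gives_covered_verdict(sfq_groups):
    entry = CatalogueEntry("17377", "Crisps or savor snacks", "", "", "snacks")
    m = map_food_code(entry, sfq_groups)
    assert m.status is MappingStatus.COVERED
    assert m.target_group == "C25k"
    assert m.match_step is MatchStep.EXACT_NAME
    assert not m.needs_review


def test_unmatched_code_becomes_non_covered(sfq_groups):
    entry = CatalogueEntry("11453", "porridge oats", "", "", "cereals")
    m = map_food_code(entry, sfq_groups)
    assert m.status is MappingStatus.NON_COVERED
    assert m.target_group is None
    assert m.match_step is MatchStep.NONE
    assert m.coverage_fraction == 0.0


def test_fuzzy_and_token_verdicts_are_flagged_for_review(sfq_groups):
    fuzzy = map_food_code(CatalogueEntry("c1", "crisps or savoury snacks", "", "", "g"), sfq_groups)
    token = map_food_code(CatalogueEntry("c2", "item 2", "pork sausage", "", "g"), sfq_groups)
    assert fuzzy.match_step is MatchStep.FUZZY and fuzzy.needs_review
    assert fuzzy.similarity is not None
    assert token.match_step is MatchStep.TOKEN and token.needs_review


def test_exact_name_precedence_over_later_steps(sfq_groups):
    # name matches Sweets exactly; description would token-match elsewhere
    entry = CatalogueEntry("c1", "Sweets", "chocolate sausage roll", "", "g")
    m = map_food_code(entry, sfq_groups)
    assert m.match_step is MatchStep.EXACT_NAME and m.target_group == "C25m"


def test_empty_name_is_a_validation_error(sfq_groups):
    with pytest.raises(ValidationError, match="empty name"):
        map_food_code(CatalogueEntry("c1", "", "", "", "g"), sfq_groups)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.sampled_from(["sweets", "fresh fruit", "chips", "cooked vegetables", "fromage frais"]),
       st.text(alphabet="abcdefghij ", max_size=20))
def test_precedence_property_exact_wins_regardless_of_description(label, desc):
    """Whenever the exact step succeeds on the name, it owns the verdict."""
    sfq_groups = _cached_sfq()
    expected = exact_match_step(label, sfq_groups)
    assert expected is not None
    m = map_food_code(CatalogueEntry("c1", label, desc, "", "g"), sfq_groups)
    assert m.match_step in (MatchStep.EXACT_NAME,)
    assert m.target_group == expected


def test_raising_threshold_never_creates_coverage(sfq_groups, small_world):
    _, catalogue, _, _, _ = small_world
    low = build_mapping_table(catalogue, sfq_groups, MatchConfig(fuzzy_threshold=0.85))
    high = build_mapping_table(catalogue, sfq_groups, MatchConfig(fuzzy_threshold=0.95))
    for lo, hi in zip(low, high):
        if lo.status is MappingStatus.NON_COVERED:
            assert hi.status is MappingStatus.NON_COVERED


# ---------------------------------------------------------------- table building

def test_build_table_one_entry_per_code_and_counts(sfq_groups):
    catalogue = [
        CatalogueEntry("c1", "sweets", "", "", "g1"),
        CatalogueEntry("c2", "fresh fruit", "", "", "g2"),
        CatalogueEntry("c3", "porridge", "", "", "g3"),
        CatalogueEntry("c4", "semolina", "", "", "g3"),
    ]
    table = build_mapping_table(catalogue, sfq_groups)
    assert [m.food_code for m in table] == ["c1", "c2", "c3", "c4"]
    assert sum(m.status is MappingStatus.NON_COVERED for m in table) == 2


def test_manual_override_flips_verdict(sfq_groups):
    catalogue = [CatalogueEntry("c1", "porridge", "", "", "g1")]
    override = MappingEntry(
        food_code="c1", status=MappingStatus.COVERED, target_group="C25m",
        coverage_fraction=1.0, match_step=MatchStep.MANUAL,
    )
    table = build_mapping_table(catalogue, sfq_groups, manual_overrides=[override])
    assert table[0].status is MappingStatus.COVERED
    assert table[0].match_step is MatchStep.MANUAL


def test_override_for_unknown_code_errors(sfq_groups):
    catalogue = [CatalogueEntry("c1", "porridge", "", "", "g1")]
    override = MappingEntry(
        food_code="zz", status=MappingStatus.COVERED, target_group="C25m",
        coverage_fraction=1.0, match_step=MatchStep.MANUAL,
    )
    with pytest.raises(ValidationError, match="zz"):
        build_mapping_table(catalogue, sfq_groups, manual_overrides=[override])


def test_ground_truth_recovered_without_typos(small_world, small_mapping):
    _, catalogue, truth, _, _ = small_world
    for entry, verdict in zip(catalogue, small_mapping):
        expected = truth.code_to_sfq[entry.food_code]
        got = verdict.target_group if verdict.status is not MappingStatus.NON_COVERED else None
        assert got == expected


def test_determinism_identical_tables_for_identical_inputs(small_world, sfq_groups):
    _, catalogue, _, _, _ = small_world
    a = build_mapping_table(catalogue, sfq_groups)
    b = build_mapping_table(catalogue, sfq_groups)
    assert a == b


# ---------------------------------------------------------------- partial fractions

def _partial_fixture(n_mapped: int, n_total: int):
    catalogue = [
        CatalogueEntry(f"c{i}", "x", "", "", "other fruit") for i in range(n_total)
    ]
    mapping = []
    for i in range(n_total):
        if i < n_mapped:
            mapping.append(MappingEntry(f"c{i}", MappingStatus.COVERED, "C25a", 1.0, MatchStep.MANUAL))
        else:
            mapping.append(MappingEntry(f"c{i}", MappingStatus.NON_COVERED, None, 0.0, MatchStep.NONE))
    return catalogue, mapping


@pytest.mark.parametrize("n_mapped, n_total, expected", [(0, 5, 1.0), (5, 5, 0.0), (3, 8, 0.625)])
def test_partial_fraction_count_based(n_mapped, n_total, expected):
    catalogue, mapping = _partial_fixture(n_mapped, n_total)
    assert assign_partial_fraction("other fruit", catalogue, mapping) == pytest.approx(expected)


def test_partial_fraction_unknown_group_errors():
    catalogue, mapping = _partial_fixture(1, 2)
    with pytest.raises(ValidationError, match="unknown"):
        assign_partial_fraction("no such group", catalogue, mapping)


# ---------------------------------------------------------------- annotator agreement

def test_identical_tables_have_no_discordance(small_mapping):
    rep = compare_mappings(small_mapping, small_mapping)
    assert rep.n_discordant == 0


def test_single_code_disagreement_is_reported(small_mapping):
    from dataclasses import replace

    other = list(small_mapping)
    victim = next(i for i, m in enumerate(other) if m.status is MappingStatus.NON_COVERED)
    other[victim] = MappingEntry(
        other[victim].food_code, MappingStatus.COVERED, "C25m", 1.0, MatchStep.MANUAL
    )
    rep = compare_mappings(small_mapping, other)
    assert rep.n_discordant == 1
    assert rep.discordant_codes == (other[victim].food_code,)
    # symmetric
    assert compare_mappings(other, small_mapping).n_discordant == 1


def test_disjoint_code_sets_error(small_mapping):
    with pytest.raises(ValidationError, match="different code sets"):
        compare_mappings(small_mapping[:5], small_mapping[5:10])
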