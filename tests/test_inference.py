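"""Density estimation and rank tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta as beta_dist

from dietmap.inference import (
    day_of_week_tests,
    holm_adjust,
    pairwise_day_tests,
    ratio_density,
    wilcoxon_rank_sum,
)
from dietmap.types import ValidationError, WEEKDAYS

from oracles import enumerate_ranksum_p


# ---------------------------------------------------------------- density

def test_density_integrates_to_one_and_is_nonnegative():
    rng = np.random.default_rng(0)
    values = rng.beta(2, 5, size=400)
    grid, dens = ratio_density(values)
    assert (dens >= 0).all()
    assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)


def test_density_symmetric_for_symmetric_data():
    values = np.concatenate([[0.5 - d, 0.5 + d] for d in np.linspace(0.01, 0.45, 40)])
    grid, dens = ratio_density(values)
    assert np.allclose(dens, dens[::-1], atol=1e-9)


def test_density_rejects_out_of_range_values():
    with pytest.raises(ValidationError, match=r"\[0, 1\]"):
        ratio_density([0.2, 1.4])


def test_density_recovers_beta_shape():
    rng = np.random.default_rng(1)
    values = rng.beta(8, 10, size=10000)
    grid, dens = ratio_density(values)
    true = beta_dist.pdf(grid, 8, 10)
    # interior pointwise agreement; boundary reflection keeps edges sane
    inner = (grid > 0.1) & (grid < 0.9)
    assert np.max(np.abs(dens[inner] - true[inner])) < 0.35


def test_density_bin_mass_matches_empirical_frequencies():
    rng = np.random.default_rng(2)
    values = rng.beta(3, 3, size=20000)
    grid, dens = ratio_density(values)
    bins = np.linspace(0, 1, 11)
    emp, _ = np.histogram(values, bins=bins, density=False)
    emp = emp / len(values)
    for lo, hi, target in zip(bins[:-1], bins[1:], emp):
        sel = (grid >= lo) & (grid <= hi)
        mass = np.trapezoid(dens[sel], grid[sel])
        assert mass == pytest.approx(target, abs=0.02)


# ---------------------------------------------------------------- rank-sum test

def test_exact_toy_example_one_third():
    res = wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
    assert res.statistic == 3.0
    assert res.p_value == pytest.approx(2 / 6)
    assert res.method == "exact_enumeration"


def test_complete_ties_give_p_one():
    for mode in ("exact", "normal"):
        assert wilcoxon_rank_sum([5, 5, 5], [5, 5], mode=mode).p_value == 1.0


def test_permutation_add_one_estimator_floor():
    # observed more extreme than every shuffle -> p = 1/(n_perm + 1)
    x = np.arange(20) + 100.0
    y = np.arange(20) * 1.0
    res = wilcoxon_rank_sum(x, y, mode="permutation", n_perm=999, seed=5)
    assert res.p_value == pytest.approx(1 / 1000)
    assert res.method == "monte_carlo_permutation"


def test_empty_sample_errors():
    with pytest.raises(ValidationError):
        wilcoxon_rank_sum([], [1.0])


def test_permutation_is_reproducible_given_seed():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=15), rng.normal(0.3, size=20)
    a = wilcoxon_rank_sum(x, y, mode="permutation", n_perm=2000, seed=42)
    b = wilcoxon_rank_sum(x, y, mode="permutation", n_perm=2000, seed=42)
    assert a.p_value == b.p_value


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(0, 8), min_size=1, max_size=6),
    st.lists(st.integers(0, 8), min_size=1, max_size=6),
)
def test_exact_mode_matches_independent_enumeration(x, y):
    """Exact-mode p equals a separately written full enumeration (ties included)."""
    res = wilcoxon_rank_sum(x, y, mode="exact")
    w_oracle, p_oracle = enumerate_ranksum_p(x, y)
    assert res.statistic == pytest.approx(w_oracle)
    assert res.p_value == pytest.approx(p_oracle, abs=1e-12)


def test_permutation_agrees_with_exact_within_mc_error():
    rng = np.random.default_rng(7)
    for _ in range(5):
        x = rng.normal(size=6)
        y = rng.normal(0.5, size=6)
        exact = wilcoxon_rank_sum(x, y, mode="exact").p_value
        mc = wilcoxon_rank_sum(x, y, mode="permutation", n_perm=10000, seed=1).p_value
        se = np.sqrt(exact * (1 - exact) / 10000)
        assert abs(mc - exact) <= 3 * se + 2 / 10001


def test_normal_approximation_close_to_exact_moderate_n():
    rng = np.random.default_rng(11)
    x = rng.normal(size=8)
    y = rng.normal(0.8, size=8)
    exact = wilcoxon_rank_sum(x, y, mode="exact").p_value
    approx = wilcoxon_rank_sum(x, y, mode="normal").p_value
    assert approx == pytest.approx(exact, abs=0.03)


# ---------------------------------------------------------------- day-of-week tests

def _coverage_frame(rng, shift_day=None, shift=0.0, n_per_day=30):
    rows = []
    for day in WEEKDAYS:
        loc = 0.44 + (shift if day == shift_day else 0.0)
        for v in np.clip(rng.normal(loc, 0.12, size=n_per_day), 0, 1):
            rows.append(
                {"subject_id": "s", "day_index": 1, "weekday": day,
                 "freq_ratio": v, "amount_ratio": v}
            )
    return pd.DataFrame(rows)


def test_planted_friday_shift_is_flagged():
    rng = np.random.default_rng(21)
    cov = _coverage_frame(rng, shift_day="Fri", shift=0.15, n_per_day=60)
    rep = day_of_week_tests(cov, metric="freq_ratio", alpha=0.01, mode="permutation",
                            n_perm=1999, seed=9)
    assert "Fri" in rep.flagged
    assert rep.p_holm["Fri"] <= 7 * rep.results["Fri"].p_value


def test_single_weekday_errors():
    df = pd.DataFrame(
        {"subject_id": "s", "day_index": 1, "weekday": "Mon",
         "freq_ratio": np.linspace(0, 1, 10), "amount_ratio": np.linspace(0, 1, 10)}
    )
    with pytest.raises(ValidationError, match="2 distinct weekdays"):
        day_of_week_tests(df)


def test_sparse_weekday_is_skipped_not_tested():
    rng = np.random.default_rng(5)
    cov = _coverage_frame(rng, n_per_day=20)
    cov = cov[~((cov["weekday"] == "Tue") & (cov.groupby("weekday").cumcount() > 0))]
    rep = day_of_week_tests(cov, mode="normal")
    assert "Tue" in rep.skipped and "Tue" not in rep.results


def test_pairwise_variant_covers_all_pairs():
    rng = np.random.default_rng(6)
    cov = _coverage_frame(rng, n_per_day=10)
    out = pairwise_day_tests(cov, mode="normal")
    assert len(out) == 21  # C(7,2)


def test_holm_adjustment_monotone_and_bounded():
    raw = {"a": 0.001, "b": 0.02, "c": 0.04, "d": 0.5}
    adj = holm_adjust(raw)
    assert adj["a"] == pytest.approx(0.004)
    assert all(adj[k] >= raw[k] for k in raw)
    assert all(0 < v <= 1.0 for v in adj.values())
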