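"""Distributional summaries and rank tests for the coverage ratios.

Two tools: a Gaussian kernel density estimate with boundary reflection,
suited to ratios living on [0, 1], and a Wilcoxon rank-sum test whose null
distribution is obtained by exact enumeration, Monte-Carlo permutation, or
the tie-corrected normal approximation. Day-of-week structure is probed by
comparing each weekday's subject-day ratios against all other weekdays
pooled.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .types import TestResult, ValidationError, WEEKDAYS

_EPS = 1e-9


# ---------------------------------------------------------------- density

def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    sd = np.std(x, ddof=1)
    q25, q75 = np.percentile(x, [25, 75])
    spread = min(sd, (q75 - q25) / 1.34) if q75 > q25 else sd
    if spread <= 0:
        spread = max(sd, 1e-3)  # degenerate (near-constant) sample
    return 0.9 * spread * len(x) ** (-0.2)


def ratio_density(
    values: Sequence[float],
    bandwidth: Optional[float] = None,
    grid_size: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel density of ratio data on a fixed grid over [0, 1].

    Gaussian kernels with reflection at both boundaries, so no probability
    mass leaks outside the unit interval: the estimate at x sums kernel
    contributions from each data point and its mirror images at -v and
    2 - v. The returned density is non-negative and integrates to 1 (up to
    the grid's trapezoid error).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("density estimation needs at least 2 values")
    if np.any((x < 0) | (x > 1)):
        raise ValidationError("ratio values must lie in [0, 1]")
    h = silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValidationError("bandwidth must be positive")
    grid = np.linspace(0.0, 1.0, grid_size)
    diffs = grid[:, None] - x[None, :]
    dens = (
        norm.pdf(diffs, scale=h)
        + norm.pdf(grid[:, None] + x[None, :], scale=h)          # mirror at 0
        + norm.pdf(grid[:, None] - (2.0 - x[None, :]), scale=h)  # mirror at 1
    ).mean(axis=1)
    return grid, dens


# ---------------------------------------------------------------- rank-sum test

def _midranks(pooled: np.ndarray) -> np.ndarray:
    return rankdata(pooled, method="average")


def _null_moments(ranks: np.ndarray, n: int) -> tuple[float, float]:
    """Mean and SD of the rank sum of a size-n sample under relabelling."""
    N = len(ranks)
    mu = n * (N + 1) / 2.0
    # tie-corrected variance of W
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (N * (N - 1)) if N > 1 else 0.0
    var = n * (N - n) / 12.0 * ((N + 1) - tie_term)
    return mu, sqrt(max(var, 0.0))


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    n_perm: int = 9999,
    seed: Optional[int] = None,
    enumeration_cap: int = 20000,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test; statistic is the rank sum W of ``x``.

    Mid-ranks handle ties. ``mode``:

    - ``exact``: enumerate all C(n+m, n) label assignments; p is the exact
      fraction with |W' - E[W]| >= |W - E[W]|.
    - ``permutation``: ``n_perm`` random relabellings with the add-one
      estimator p = (1 + #{extreme}) / (1 + n_perm), reproducible via seed.
    - ``normal``: tie-corrected normal approximation.
    - ``auto``: exact when C(n+m, n) <= enumeration_cap, else permutation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w_obs = float(ranks[:n].sum())
    mu, sigma = _null_moments(ranks, n)
    d_obs = abs(w_obs - mu)

    if mode == "auto":
        mode = "exact" if comb(n + m, n) <= enumeration_cap else "permutation"

    if mode == "exact":
        total = comb(n + m, n)
        if total > enumeration_cap:
            raise ValidationError(
                f"exact enumeration of C({n + m},{n}) = {total} exceeds cap {enumeration_cap}"
            )
        extreme = sum(
            1
            for idx in combinations(range(n + m), n)
            if abs(ranks[list(idx)].sum() - mu) >= d_obs - _EPS
        )
        return TestResult(
            statistic=w_obs, p_value=extreme / total, method="exact_enumeration", n_x=n, n_y=m
        )
    if mode == "permutation":
        rng = np.random.default_rng(seed)
        # one argsort per shuffle, vectorized across all shuffles
        idx = np.argsort(rng.random((n_perm, n + m)), axis=1)[:, :n]
        w_perm = ranks[idx].sum(axis=1)
        extreme = int(np.sum(np.abs(w_perm - mu) >= d_obs - _EPS))
        return TestResult(
            statistic=w_obs,
            p_value=(1 + extreme) / (1 + n_perm),
            method="monte_carlo_permutation",
            n_x=n,
            n_y=m,
            n_perm=n_perm,
            seed=seed,
        )
    if mode == "normal":
        if sigma == 0:  # complete ties: no evidence against the null
            p = 1.0
        else:
            p = min(1.0, 2.0 * norm.sf(d_obs / sigma))
            p = max(p, np.finfo(float).tiny)
        return TestResult(statistic=w_obs, p_value=p, method="normal_approximation", n_x=n, n_y=m)
    raise ValidationError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------- day-of-week tests

@dataclass(frozen=True)
class DayOfWeekReport:
    """One rank test per weekday (that day vs all other days pooled)."""

    metric: str
    alpha: float
    results: dict[str, TestResult]
    p_holm: dict[str, float]
    flagged: tuple[str, ...]           # weekdays with raw p < alpha
    skipped: tuple[str, ...]           # weekdays with too few observations


def holm_adjust(pvals: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjustment of a small family of p-values."""
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    k = len(items)
    adjusted, running = {}, 0.0
    for i, (key, p) in enumerate(items):
        running = max(running, min(1.0, (k - i) * p))
        adjusted[key] = running
    return adjusted


def day_of_week_tests(
    coverage: pd.DataFrame,
    metric: str = "freq_ratio",
    alpha: float = 0.01,
    mode: str = "permutation",
    n_perm: int = 9999,
    seed: Optional[int] = None,
) -> DayOfWeekReport:
    """Test each weekday's ratio distribution against the other days pooled.

    Mirrors a leave-one-day-out permutation scheme: for weekday d, the
    subject-day ratios observed on d form one sample and the ratios of all
    remaining weekdays the other. Raw p-values are reported at ``alpha``
    (no adjustment, matching the source analysis); Holm-adjusted values
    are emitted alongside.
    """
    if metric not in ("freq_ratio", "amount_ratio"):
        raise ValidationError("metric must be freq_ratio or amount_ratio")
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")
    df = coverage.dropna(subset=[metric])
    present = [d for d in WEEKDAYS if d in set(df["weekday"])]
    if len(present) < 2:
        raise ValidationError("need ratios from at least 2 distinct weekdays")

    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    child_seeds = ss.generate_state(len(present))
    results: dict[str, TestResult] = {}
    skipped: list[str] = []
    for day, day_seed in zip(present, child_seeds):
        x = df.loc[df["weekday"] == day, metric].to_numpy()
        y = df.loc[df["weekday"] != day, metric].to_numpy()
        if len(x) < 2 or len(y) < 2:
            skipped.append(day)
            continue
        results[day] = wilcoxon_rank_sum(
            x, y, mode=mode, n_perm=n_perm, seed=int(day_seed % (2**31))
        )
    p_holm = holm_adjust({d: r.p_value for d, r in results.items()})
    flagged = tuple(d for d, r in results.items() if r.p_value < alpha)
    return DayOfWeekReport(
        metric=metric, alpha=alpha, results=results, p_holm=p_holm,
        flagged=flagged, skipped=tuple(skipped),
    )


def pairwise_day_tests(
    coverage: pd.DataFrame,
    metric: str = "freq_ratio",
    mode: str = "permutation",
    n_perm: int = 9999,
    seed: Optional[int] = None,
) -> dict[tuple[str, str], TestResult]:
    """All pairwise weekday comparisons (alternative reading of the scheme)."""
    df = coverage.dropna(subset=[metric])
    present = [d for d in WEEKDAYS if d in set(df["weekday"])]
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    out: dict[tuple[str, str], TestResult] = {}
    pairs = [(a, b) for i, a in enumerate(present) for b in present[i + 1:]]
    child_seeds = ss.generate_state(max(len(pairs), 1))
    for (a, b), s in zip(pairs, child_seeds):
        x = df.loc[df["weekday"] == a, metric].to_numpy()
        y = df.loc[df["weekday"] == b, metric].to_numpy()
        if len(x) < 2 or len(y) < 2:
            continue
        out[(a, b)] = wilcoxon_rank_sum(x, y, mode=mode, n_perm=n_perm, seed=int(s % (2**31)))
    return out


def test_results_frame(reports: Sequence[DayOfWeekReport]) -> pd.DataFrame:
    """Flatten day-of-week reports into the test-results CSV layout."""
    rows = []
    for rep in reports:
        for day, r in rep.results.items():
            rows.append(
                {
                    "weekday": day,
                    "metric": rep.metric,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "p_holm": rep.p_holm[day],
                    "significant": r.p_value < rep.alpha,
                    "method": r.method,
                    "n_perm": r.n_perm if r.n_perm is not None else "",
                    "seed": r.seed if r.seed is not None else "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "weekday", "metric", "statistic", "p_value", "p_holm",
            "significant", "method", "n_perm", "seed",
        ],
    )
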