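"""Independent oracles used by the test suite.

These re-derive expected values by brute force (textbook dynamic
programming, full enumeration) without touching the library code paths
they check.
"""

from __future__ import annotations

from itertools import combinations


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook O(len(a)*len(b)) dynamic-programming edit distance."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[m]


def oracle_normalize(s: str) -> str:
    """Independent re-statement of the normalization rule."""
    out = []
    for ch in s.lower():
        out.append(ch if ch.isalnum() else " ")
    return " ".join("".join(out).split())


def oracle_similarity(a: str, b: str) -> float:
    na, nb = oracle_normalize(a), oracle_normalize(b)
    if not na and not nb:
        return 1.0
    return 1.0 - dp_levenshtein(na, nb) / max(len(na), len(nb))


def _midranks(values):
    """Mid-ranks computed by explicit tie-group averaging."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def enumerate_ranksum_p(x, y) -> tuple[float, float]:
    """Exact two-sided rank-sum p-value by full enumeration.

    Returns (W of x, p). Enumerates every C(n+m, n) assignment of the
    pooled mid-ranks to the first sample; two-sided by |W - E[W]|.
    """
    n, m = len(x), len(y)
    ranks = _midranks(list(x) + list(y))
    w_obs = sum(ranks[:n])
    mu = n * (n + m + 1) / 2.0
    d_obs = abs(w_obs - mu)
    extreme = total = 0
    for idx in combinations(range(n + m), n):
        total += 1
        if abs(sum(ranks[i] for i in idx) - mu) >= d_obs - 1e-9:
            extreme += 1
    return w_obs, extreme / total
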