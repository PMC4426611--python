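"""Exact small-sample nonparametric tests by enumeration.

At the group sizes these incubations afford (3–10 animals), asymptotic
null distributions are unreliable; both tests here compute their p-values
by enumerating label arrangements of the observed (mid-)ranks. Exact
p-values are rational — numerator over C(n₁+n₂, n₁) arrangements — and the
fraction is exposed alongside the float.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as _st


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # exact | permutation | asymptotic
    n_per_group: tuple[int, ...]
    statistic_name: str = ""
    p_fraction: Fraction | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value must be in (0, 1]")


def _midranks(values: Sequence[float]) -> np.ndarray:
    return _st.rankdata(values, method="average")


def mann_whitney_exact(
    x: Sequence[float],
    y: Sequence[float],
    max_exact_n: int = 25,
    n_permutations: int = 20000,
    seed: int | None = None,
) -> TestResult:
    """Two-sided Mann–Whitney U test with a fully enumerated null.

    U is the number of (x, y) pairs with x > y (ties counted half),
    computed from mid-ranks. The two-sided p is 2·min(P(U ≤ u), P(U ≥ u))
    over all C(n₁+n₂, n₁) labelings of the observed ranks, capped at 1.
    Falls back to Monte-Carlo permutation above ``max_exact_n`` combined
    observations.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    ranks = _midranks(x + y)
    u_obs = float(np.sum(ranks[:n1])) - n1 * (n1 + 1) / 2.0

    if n1 + n2 <= max_exact_n:
        total = math.comb(n1 + n2, n1)
        le = ge = 0
        offset = n1 * (n1 + 1) / 2.0
        tol = 1e-9
        for idx in combinations(range(n1 + n2), n1):
            u = sum(ranks[i] for i in idx) - offset
            if u <= u_obs + tol:
                le += 1
            if u >= u_obs - tol:
                ge += 1
        frac = min(Fraction(2 * min(le, ge), total), Fraction(1))
        return TestResult(
            statistic=u_obs,
            p_value=float(frac),
            method="exact",
            n_per_group=(n1, n2),
            statistic_name="U",
            p_fraction=frac,
        )

    rng = np.random.default_rng(seed)
    offset = n1 * (n1 + 1) / 2.0
    perms = np.array(
        [rng.permutation(ranks)[:n1].sum() - offset for _ in range(n_permutations)]
    )
    le = int(np.sum(perms <= u_obs + 1e-9)) + 1
    ge = int(np.sum(perms >= u_obs - 1e-9)) + 1
    p = min(2.0 * min(le, ge) / (n_permutations + 1), 1.0)
    return TestResult(
        statistic=u_obs,
        p_value=p,
        method="permutation",
        n_per_group=(n1, n2),
        statistic_name="U",
    )


def _h_statistic(ranks: np.ndarray, sizes: Sequence[int], tie_factor: float) -> float:
    n = len(ranks)
    h = 0.0
    start = 0
    for m in sizes:
        rsum = float(ranks[start : start + m].sum())
        h += rsum * rsum / m
        start += m
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_factor if tie_factor > 0 else float("nan")


def _tie_factor(values: np.ndarray) -> float:
    n = len(values)
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    method: str = "auto",
    max_enum: int = 300_000,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> TestResult:
    """Kruskal–Wallis H test with tie correction and an enumerated null.

    ``auto`` fully enumerates the multinomial label arrangements when their
    count is at most ``max_enum`` (group sizes 5, 5, 4 give 252,252 and
    qualify) and otherwise uses the χ²(k−1) approximation. ``permutation``
    forces seeded Monte-Carlo resampling.
    """
    groups = [list(map(float, g)) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    sizes = [len(g) for g in groups]
    n = sum(sizes)
    pooled = np.concatenate([np.asarray(g) for g in groups])
    ranks = _midranks(pooled)
    tie = _tie_factor(pooled)
    if tie <= 0:  # every observation identical
        return TestResult(
            statistic=0.0,
            p_value=1.0,
            method="degenerate",
            n_per_group=tuple(sizes),
            statistic_name="H",
        )
    h_obs = _h_statistic(ranks, sizes, tie)

    n_arrangements = math.factorial(n)
    for m in sizes:
        n_arrangements //= math.factorial(m)

    if method == "auto":
        method = "exact" if n_arrangements <= max_enum else "asymptotic"

    if method == "exact":
        if n_arrangements > max_enum:
            raise ValueError(
                f"{n_arrangements} arrangements exceed max_enum={max_enum}"
            )
        ge = 0
        tol = 1e-9

        def recurse(avail: tuple[int, ...], gi: int, acc: list[float]) -> None:
            nonlocal ge
            if gi == len(sizes) - 1:
                acc.append(sum(ranks[i] for i in avail))
                h = _h_from_sums(acc, sizes, n, tie)
                if h >= h_obs - tol:
                    ge += 1
                acc.pop()
                return
            for idx in combinations(range(len(avail)), sizes[gi]):
                chosen = [avail[i] for i in idx]
                rest = tuple(a for j, a in enumerate(avail) if j not in set(idx))
                acc.append(sum(ranks[i] for i in chosen))
                recurse(rest, gi + 1, acc)
                acc.pop()

        recurse(tuple(range(n)), 0, [])
        frac = Fraction(ge, n_arrangements)
        return TestResult(
            statistic=h_obs,
            p_value=float(frac),
            method="exact",
            n_per_group=tuple(sizes),
            statistic_name="H",
            p_fraction=frac,
        )

    if method == "permutation":
        rng = np.random.default_rng(seed)
        perm_ranks = np.tile(ranks, (n_permutations, 1))
        perm_ranks = rng.permuted(perm_ranks, axis=1)
        ge = 1
        bounds = np.cumsum([0] + sizes)
        stats = np.zeros(n_permutations)
        for j in range(len(sizes)):
            seg = perm_ranks[:, bounds[j] : bounds[j + 1]].sum(axis=1)
            stats += seg * seg / sizes[j]
        stats = (12.0 / (n * (n + 1)) * stats - 3.0 * (n + 1)) / tie
        ge += int(np.sum(stats >= h_obs - 1e-9))
        return TestResult(
            statistic=h_obs,
            p_value=min(ge / (n_permutations + 1), 1.0),
            method="permutation",
            n_per_group=tuple(sizes),
            statistic_name="H",
        )

    if method == "asymptotic":
        p = float(_st.chi2.sf(h_obs, df=len(sizes) - 1))
        return TestResult(
            statistic=h_obs,
            p_value=max(min(p, 1.0), np.nextafter(0, 1)),
            method="asymptotic",
            n_per_group=tuple(sizes),
            statistic_name="H",
        )

    raise ValueError(f"unknown method {method!r}")


def _h_from_sums(rank_sums: Sequence[float], sizes: Sequence[int], n: int, tie: float) -> float:
    total = n * (n + 1) / 2.0
    last = total - sum(rank_sums[:-1])  # rank_sums[-1] holds leftover indices' sum
    acc = 0.0
    for rsum, m in zip(list(rank_sums[:-1]) + [last], sizes):
        acc += rsum * rsum / m
    return (12.0 / (n * (n + 1)) * acc - 3.0 * (n + 1)) / tie
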