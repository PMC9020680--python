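"""Randomization test for a difference in two complication proportions.

The test statistic is the signed difference in observed complication
proportions, D = x1/n1 − x2/n2, with group 1 the stratum of interest
(prophylaxis, or SIV/SHIV-infected).  The empirical null is built by
re-assigning the x1+x2 complications at random among the n1+n2 procedures
while preserving group sizes; the p-value is the upper-tail proportion of
permuted differences **as large or larger** than D (ties count).  The
default number of permutations is B = 50,000 and the raw proportion b/B is
reported (an add-one estimator is available behind a flag).

Under this label permutation the group-1 complication count is exactly
hypergeometric with the table margins, which gives both a cheap sampling
mechanism (draw the count per replicate instead of shuffling an array) and
an analytic oracle: the exact p-value is the hypergeometric upper tail at
the smallest count whose implied difference reaches D.  A literal
array-shuffle mode is kept for audit; the two agree in distribution.

Published tables often print only (rate %, n) per cell;
:func:`reconstruct_counts` recovers the integer counts by rounding rate×n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import floor, sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "TwoByTwo",
    "RandTestResult",
    "reconstruct_counts",
    "observed_diff",
    "exact_p",
    "randomization_test",
    "run_comparisons",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Complication counts for one two-group comparison.

    ``x1`` of ``n1`` procedures in group 1 (listed first: the prophylaxis or
    infected stratum) and ``x2`` of ``n2`` in group 2.
    """

    x1: int
    n1: int
    x2: int
    n2: int
    labels: tuple[str, str] = ("group1", "group2")
    name: str = ""

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("group sizes must be positive")
        if not (0 <= self.x1 <= self.n1 and 0 <= self.x2 <= self.n2):
            raise ValueError("counts must satisfy 0 <= x <= n in each group")


@dataclass(frozen=True)
class RandTestResult:
    """Outcome of one randomization test.

    ``p_mc`` is the Monte-Carlo p-value with standard error ``mc_se`` =
    sqrt(p(1−p)/B); ``p_exact`` is the hypergeometric-tail oracle for the
    same null and tail convention.
    """

    table: TwoByTwo
    d_obs: float
    B: int
    p_mc: float
    mc_se: float
    p_exact: float
    seed: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_mc < self.alpha


def reconstruct_counts(rate_percent: float, n: int) -> int:
    """Recover an integer count from a printed (rate %, n) cell.

    Returns rate×n rounded to the nearest integer (half away from zero) and
    warns when the product is further than 0.1 from any integer, i.e. when
    the reconstruction is ambiguous at the printed precision.
    """
    if not 0.0 <= rate_percent <= 100.0:
        raise ValueError(f"rate_percent must lie in [0, 100], got {rate_percent}")
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    product = rate_percent / 100.0 * n
    count = floor(product + 0.5)
    if abs(product - count) > 0.1:
        warnings.warn(
            f"count reconstruction ambiguous: {rate_percent}% of {n} = "
            f"{product:.3f} is {abs(product - count):.3f} from an integer",
            stacklevel=2,
        )
    return count


def observed_diff(t: TwoByTwo) -> float:
    """Signed difference in proportions, group 1 minus group 2."""
    return t.x1 / t.n1 - t.x2 / t.n2


def _threshold_count(t: TwoByTwo) -> int:
    """Smallest group-1 count k whose implied difference reaches d_obs.

    With the margins fixed, a permuted assignment putting k complications in
    group 1 has difference d(k) = k/n1 − (K−k)/n2, which is strictly
    increasing in k; in integer arithmetic d(k) ≥ d_obs reduces to
    k·(n1+n2) ≥ x1·(n1+n2), i.e. k ≥ x1.  Kept as a function so tie
    handling is exact (no float comparisons) in both the sampler and the
    oracle.
    """
    return t.x1


def exact_p(t: TwoByTwo) -> float:
    """Exact upper-tail p-value of the permutation null.

    P(X ≥ k*) for X ~ Hypergeometric(N = n1+n2, K = x1+x2, draws = n1),
    summed over the support, with k* from :func:`_threshold_count`.
    """
    N, K = t.n1 + t.n2, t.x1 + t.x2
    k_star = _threshold_count(t)
    lo = max(0, K - t.n2)
    hi = min(K, t.n1)
    if k_star <= lo:
        return 1.0
    support = np.arange(k_star, hi + 1)
    return float(hypergeom.pmf(support, N, K, t.n1).sum())


def randomization_test(
    t: TwoByTwo,
    B: int = 50_000,
    seed: int | None = None,
    method: str = "counts",
    add_one: bool = False,
    alpha: float = 0.05,
) -> RandTestResult:
    """Monte-Carlo randomization test on a 2×2 table.

    Parameters
    ----------
    t
        the observed table; group 1 is the stratum of interest.
    B
        number of permutation replicates (≥ 1).
    seed
        RNG seed; drawn from OS entropy and recorded in the result when
        omitted.
    method
        ``"counts"`` draws the group-1 complication count per replicate from
        the hypergeometric null (vectorized, the default); ``"shuffle"``
        literally permutes the 0/1 outcome vector and re-splits it — an
        audit mode, identical in distribution but far slower.
    add_one
        report (b+1)/(B+1) instead of the raw proportion b/B.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(seed)

    N, K = t.n1 + t.n2, t.x1 + t.x2
    k_star = _threshold_count(t)

    if method == "counts":
        draws = rng.hypergeometric(K, N - K, t.n1, size=B)
    elif method == "shuffle":
        outcomes = np.zeros(N, dtype=np.int8)
        outcomes[:K] = 1
        draws = np.empty(B, dtype=np.int64)
        for b in range(B):
            rng.shuffle(outcomes)
            draws[b] = int(outcomes[: t.n1].sum())
    else:
        raise ValueError(f"unknown method {method!r}")

    exceed = int(np.count_nonzero(draws >= k_star))
    p_mc = (exceed + 1) / (B + 1) if add_one else exceed / B
    return RandTestResult(
        table=t,
        d_obs=observed_diff(t),
        B=B,
        p_mc=p_mc,
        mc_se=sqrt(p_mc * (1.0 - p_mc) / B),
        p_exact=exact_p(t),
        seed=seed,
        alpha=alpha,
    )


def _resolve_stratum(
    tallies: pd.DataFrame, selector: Mapping[str, object], name: str
) -> tuple[int, int]:
    mask = pd.Series(True, index=tallies.index)
    for col, value in selector.items():
        if col not in tallies.columns:
            raise ValueError(f"comparison {name!r}: unknown stratifier {col!r}")
        v = value.value if hasattr(value, "value") else value
        mask &= tallies[col] == v
    hits = tallies[mask]
    if len(hits) != 1:
        raise ValueError(
            f"comparison {name!r}: selector {dict(selector)} matched "
            f"{len(hits)} strata (need exactly 1)"
        )
    row = hits.iloc[0]
    return int(row["complications"]), int(row["procedures"])


def run_comparisons(
    tallies: pd.DataFrame,
    plan: Sequence[Mapping[str, object]],
    B: int = 50_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> list[RandTestResult]:
    """Run one randomization test per planned stratum comparison.

    Each plan entry is ``{"name": ..., "group1": {column: value, ...},
    "group2": {...}}``; each selector must match exactly one tally row.
    Per-comparison seeds are spawned deterministically from ``seed``.
    """
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    results = []
    for i, comp in enumerate(plan):
        name = str(comp.get("name", f"comparison_{i}"))
        x1, n1 = _resolve_stratum(tallies, comp["group1"], name)
        x2, n2 = _resolve_stratum(tallies, comp["group2"], name)
        table = TwoByTwo(
            x1, n1, x2, n2,
            labels=(str(comp.get("label1", "group1")), str(comp.get("label2", "group2"))),
            name=name,
        )
        child_seed = int((seed * 1_000_003 + i) % (2**31))
        results.append(randomization_test(table, B=B, seed=child_seed, alpha=alpha))
    return results
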