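"""Randomization test, exact hypergeometric oracle and count reconstruction.

The independent oracle used throughout is full enumeration of label
assignments: place the K complications in every possible subset of the
N = n1 + n2 procedure slots and compute the exact upper-tail probability
with Fraction arithmetic.  It shares no code with the implementation.
"""

import math
import warnings
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surgcomp.stats import (
    TwoByTwo,
    exact_p,
    observed_diff,
    randomization_test,
    reconstruct_counts,
    run_comparisons,
)
from surgcomp.flagging import tally


def enumeration_p(x1: int, n1: int, x2: int, n2: int) -> Fraction:
    """Exact upper-tail permutation p by brute-force label enumeration."""
    N, K = n1 + n2, x1 + x2
    d_obs = Fraction(x1, n1) - Fraction(x2, n2)
    hits = 0
    total = 0
    for positions in combinations(range(N), K):
        k = sum(1 for p in positions if p < n1)
        d = Fraction(k, n1) - Fraction(K - k, n2)
        hits += d >= d_obs
        total += 1
    return Fraction(hits, total)


SMALL_TABLES = [
    (1, 3, 2, 5),
    (2, 4, 1, 6),
    (0, 5, 3, 7),
    (3, 3, 0, 4),
    (2, 6, 2, 6),
    (1, 2, 4, 9),
    (4, 7, 1, 5),
]


class TestReconstructCounts:
    @pytest.mark.parametrize(
        "rate,n,expected",
        [
            (2.37, 1011, 24),
            (3.61, 83, 3),
            (0.76, 1316, 10),
            (2.20, 2230, 49),
            (0.93, 1399, 13),
            (0.0, 500, 0),
        ],
    )
    def test_nearest_integer(self, rate, n, expected):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            assert reconstruct_counts(rate, n) == expected

    def test_ambiguous_reconstruction_warns(self):
        with pytest.warns(UserWarning, match="ambiguous"):
            reconstruct_counts(2.5, 100)  # 2.5 exactly between usable? 2.5*1 = 2.5
            reconstruct_counts(1.15, 200)  # 2.3 -> 0.3 from an integer

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            reconstruct_counts(-1.0, 10)
        with pytest.raises(ValueError):
            reconstruct_counts(101.0, 10)


class TestObservedDiff:
    def test_signed_arithmetic(self):
        assert observed_diff(TwoByTwo(3, 83, 10, 1316)) == pytest.approx(
            3 / 83 - 10 / 1316
        )

    def test_symmetry_zero(self):
        assert observed_diff(TwoByTwo(2, 9, 2, 9)) == 0.0
        assert observed_diff(TwoByTwo(0, 5, 0, 8)) == 0.0

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(5, 4, 0, 3)
        with pytest.raises(ValueError):
            TwoByTwo(0, 0, 0, 3)


class TestExactOracle:
    @pytest.mark.parametrize("x1,n1,x2,n2", SMALL_TABLES)
    def test_matches_brute_force_enumeration(self, x1, n1, x2, n2):
        expected = enumeration_p(x1, n1, x2, n2)
        assert exact_p(TwoByTwo(x1, n1, x2, n2)) == pytest.approx(float(expected))

    @settings(derandomize=True, max_examples=60)
    @given(
        n1=st.integers(1, 6),
        n2=st.integers(1, 6),
        data=st.data(),
    )
    def test_matches_enumeration_on_random_small_tables(self, n1, n2, data):
        x1 = data.draw(st.integers(0, n1))
        x2 = data.draw(st.integers(0, n2))
        expected = enumeration_p(x1, n1, x2, n2)
        assert exact_p(TwoByTwo(x1, n1, x2, n2)) == pytest.approx(float(expected))

    def test_degenerate_tables_give_one(self):
        assert exact_p(TwoByTwo(0, 10, 0, 15)) == 1.0
        assert exact_p(TwoByTwo(10, 10, 15, 15)) == 1.0

    def test_upper_tail_monotone_in_x1_exhaustive(self):
        """Shifting a complication into group 1 (margins fixed) never raises p."""
        for n1 in range(1, 8):
            for n2 in range(1, 8):
                for K in range(0, n1 + n2 + 1):
                    lo, hi = max(0, K - n2), min(K, n1)
                    ps = [exact_p(TwoByTwo(k, n1, K - k, n2)) for k in range(lo, hi + 1)]
                    assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_tie_mass_accounting(self):
        """p(1 vs 2) + p(2 vs 1) = 1 + P(tie at the observed split)."""
        from scipy.stats import hypergeom

        for x1, n1, x2, n2 in SMALL_TABLES:
            forward = exact_p(TwoByTwo(x1, n1, x2, n2))
            backward = exact_p(TwoByTwo(x2, n2, x1, n1))
            tie = hypergeom.pmf(x1, n1 + n2, x1 + x2, n1)
            assert forward + backward == pytest.approx(1.0 + tie)


class TestRandomizationTest:
    def test_seed_reproducibility_bit_identical(self):
        t = TwoByTwo(3, 83, 10, 1316)
        a = randomization_test(t, B=2000, seed=123)
        b = randomization_test(t, B=2000, seed=123)
        assert a.p_mc == b.p_mc and a.seed == b.seed
        c = randomization_test(t, B=2000, seed=124)
        assert c.p_mc != a.p_mc or c.seed != a.seed

    def test_degenerate_all_ties_give_one(self):
        res = randomization_test(TwoByTwo(0, 12, 0, 30), B=500, seed=1)
        assert res.p_mc == 1.0 and res.p_exact == 1.0
        res = randomization_test(TwoByTwo(12, 12, 30, 30), B=500, seed=1)
        assert res.p_mc == 1.0 and res.p_exact == 1.0

    def test_invalid_b_rejected(self):
        with pytest.raises(ValueError):
            randomization_test(TwoByTwo(1, 5, 1, 5), B=0, seed=1)

    def test_add_one_estimator(self):
        t = TwoByTwo(3, 83, 10, 1316)
        raw = randomization_test(t, B=1000, seed=5)
        shifted = randomization_test(t, B=1000, seed=5, add_one=True)
        assert shifted.p_mc == pytest.approx((raw.p_mc * 1000 + 1) / 1001)

    def test_shuffle_mode_agrees_with_count_sampling(self):
        """The literal label-shuffle audit mode matches within MC error."""
        t = TwoByTwo(2, 15, 3, 25)
        counts = randomization_test(t, B=4000, seed=11, method="counts")
        shuffle = randomization_test(t, B=4000, seed=11, method="shuffle")
        se = math.sqrt(counts.p_exact * (1 - counts.p_exact) / 4000)
        assert abs(counts.p_mc - shuffle.p_mc) <= 8 * se
        assert abs(shuffle.p_mc - counts.p_exact) <= 5 * se

    def test_monte_carlo_converges_to_exact_over_many_seeds(self):
        """|p_mc - p_exact| <= 4 SE in at least 99% of 120 seeded runs."""
        B = 2000
        failures = 0
        runs = 0
        for x1, n1, x2, n2 in [(1, 3, 2, 5), (2, 6, 2, 6), (3, 10, 1, 9)]:
            t = TwoByTwo(x1, n1, x2, n2)
            pe = exact_p(t)
            bound = 4 * math.sqrt(pe * (1 - pe) / B)
            for seed in range(40):
                runs += 1
                res = randomization_test(t, B=B, seed=1000 + seed)
                failures += abs(res.p_mc - pe) > bound
        assert runs >= 120
        assert failures / runs <= 0.01


class TestRunComparisons:
    def _tally(self):
        from .conftest import make_procedure
        from surgcomp.flagging import flag_and_adjudicate
        from surgcomp.records import InfectionStatus

        procs = [
            make_procedure(pid=f"P{i}", prophylaxis=(i < 4),
                           observation=9 if i in (0, 5) else 7)
            for i in range(10)
        ]
        calls = flag_and_adjudicate(procs, {})
        return tally(calls, procs, ("prophylaxis",))

    def test_comparison_resolves_and_reports(self):
        df = self._tally()
        (res,) = run_comparisons(
            df,
            [{"name": "proph", "group1": {"prophylaxis": True},
              "group2": {"prophylaxis": False}}],
            B=1000,
            seed=3,
        )
        assert res.table.x1 == 1 and res.table.n1 == 4
        assert res.table.x2 == 1 and res.table.n2 == 6
        assert 0 <= res.p_mc <= 1

    def test_self_comparison_zero_diff_upper_half(self):
        """Comparing a stratum with itself: d_obs = 0, so by the symmetry of
        the null around zero (ties included) the upper-tail p is >= 1/2, and
        it equals 1 exactly when the stratum has no complications."""
        df = self._tally()
        (res,) = run_comparisons(
            df,
            [{"name": "self", "group1": {"prophylaxis": True},
              "group2": {"prophylaxis": True}}],
            B=500,
            seed=3,
        )
        assert res.d_obs == 0.0 and res.p_mc >= 0.5
        none = randomization_test(TwoByTwo(0, 4, 0, 4), B=200, seed=1)
        assert none.p_mc == 1.0 and none.p_exact == 1.0

    def test_empty_plan_empty_results(self):
        assert run_comparisons(self._tally(), [], seed=1) == []

    def test_unresolved_stratum_is_plan_error(self):
        with pytest.raises(ValueError, match="matched 0"):
            run_comparisons(
                self._tally(),
                [{"name": "bad", "group1": {"prophylaxis": "maybe"},
                  "group2": {"prophylaxis": False}}],
                seed=1,
            )
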