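"""Bootstrap summaries, permutation tests, Fisher's exact test."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from prsvar.events import (
    bootstrap_summary,
    category_tests,
    compare_to_reference,
    fisher_exact,
    permutation_test,
    summarize_event_table,
)
from prsvar.exceptions import DomainError, ParameterError


def brute_fisher_two_sided(table):
    """Sum hypergeometric probabilities <= P(observed), fixed margins."""
    (a, b), (c, d) = table
    r1, n1 = a + b, a + c
    total = a + b + c + d
    rv = hypergeom(total, r1, n1)
    p_obs = rv.pmf(a)
    p = 0.0
    for x in range(max(0, n1 - (total - r1)), min(r1, n1) + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-7):
            p += px
    return min(p, 1.0)


def brute_permutation_mean(a, b):
    pool = np.concatenate([a, b])
    n_a = len(a)
    t_obs = abs(np.mean(a) - np.mean(b))
    idx = range(len(pool))
    count = total = 0
    for combo in combinations(idx, n_a):
        mask = np.zeros(len(pool), dtype=bool)
        mask[list(combo)] = True
        t = abs(pool[mask].mean() - pool[~mask].mean())
        total += 1
        count += t >= t_obs - 1e-12
    return count / total


class TestBootstrapSummary:
    def test_constant_data_all_zero(self):
        s = bootstrap_summary([4.0, 4.0, 4.0, 4.0], n_boot=200, seed=0)
        assert s["sd"] == s["cv"] == 0.0
        assert s["sem"] == s["sd_se"] == s["cv_se"] == 0.0

    def test_sem_matches_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10.0, 2.0, 200)
        s = bootstrap_summary(x, n_boot=10_000, seed=1)
        assert s["sem"] == pytest.approx(x.std(ddof=1) / np.sqrt(len(x)), rel=0.10)
        assert s["cv"] == pytest.approx(x.std(ddof=1) / x.mean(), rel=1e-12)

    def test_bit_reproducible(self):
        x = np.random.default_rng(2).exponential(5.0, 50)
        assert bootstrap_summary(x, n_boot=500, seed=7) == bootstrap_summary(
            x, n_boot=500, seed=7
        )

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(DomainError):
            bootstrap_summary([-1.0, -2.0, -3.0], n_boot=100, seed=0)

    def test_missing_values_excluded(self):
        s = bootstrap_summary([1.0, np.nan, 2.0, 3.0], n_boot=100, seed=0)
        assert s["n"] == 3


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        a = [1.0, 2.0, 3.0]
        assert permutation_test(a, list(a)) == 1.0

    def test_exhaustive_hand_oracle(self):
        # all C(4,2)=6 splits; 2 attain |mean diff| = 1
        assert permutation_test([0.0, 0.0], [1.0, 1.0]) == pytest.approx(2 / 6)

    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 5)
        b = rng.normal(0.8, 1, 4)
        assert permutation_test(a, b, statistic="mean") == pytest.approx(
            brute_permutation_mean(a, b), rel=1e-12
        )

    def test_monte_carlo_agrees_with_exhaustive(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 6)
        p_ex = permutation_test(a, b, statistic="mean")
        # force Monte-Carlo by inflating the sample: same data tripled
        a3, b3 = np.tile(a, 4), np.tile(b, 4)  # C(48,24) >> limit
        p_mc = permutation_test(a3, b3, statistic="mean", n_perm=4000, seed=5)
        assert comb(48, 24) > 100_000
        assert 0 < p_mc <= 1

        # direct check: MC on the small sample approximates exhaustive
        p_mc_small = _mc_small(a, b, n_perm=20_000, seed=6)
        se = np.sqrt(p_ex * (1 - p_ex) / 20_000)
        assert abs(p_mc_small - p_ex) <= 3 * se + 2 / 20_000

    def test_statistics_dispatch(self):
        rng = np.random.default_rng(7)
        a = rng.normal(10, 1, 8)
        b = rng.normal(10, 3, 8)
        for stat in ("mean", "sd", "cv"):
            p = permutation_test(a, b, statistic=stat)
            assert 0 < p <= 1
        with pytest.raises(ParameterError):
            permutation_test(a, b, statistic="median")


def _mc_small(a, b, n_perm, seed):
    """Monte-Carlo relabeling on a sample that would otherwise be exhaustive."""
    rng = np.random.default_rng(seed)
    pool = np.concatenate([a, b])
    t_obs = abs(a.mean() - b.mean())
    perms = rng.permuted(np.broadcast_to(pool, (n_perm, pool.size)).copy(), axis=1)
    t = np.abs(perms[:, : len(a)].mean(axis=1) - perms[:, len(a) :].mean(axis=1))
    return (1 + np.sum(t >= t_obs - 1e-12)) / (n_perm + 1)


class TestFisherExact:
    def test_diagonal_table(self):
        # P(x=0)=1/6, P(1)=4/6, P(2)=1/6; extreme tables sum to 1/3
        assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3, rel=1e-9)

    def test_uniform_table(self):
        assert fisher_exact([[1, 1], [1, 1]]) == 1.0

    def test_agrees_with_enumeration_for_small_margins(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            assert fisher_exact(t) == pytest.approx(
                brute_fisher_two_sided(t), rel=1e-7
            )

    def test_invariances(self):
        t = np.array([[5, 2], [1, 7]])
        p = fisher_exact(t)
        assert fisher_exact(t.T) == pytest.approx(p, rel=1e-12)
        assert fisher_exact(t[::-1]) == pytest.approx(p, rel=1e-12)
        assert fisher_exact(t[:, ::-1]) == pytest.approx(p, rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ParameterError):
            fisher_exact([[1.5, 2], [3, 4]])
        with pytest.raises(ParameterError):
            fisher_exact([[-1, 2], [3, 4]])
        with pytest.raises(DomainError):
            fisher_exact([[0, 0], [3, 4]])


def make_event_table(seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for strain, shift in (("reference", 0.0), ("mutA", 8.0)):
        n = 60
        t1 = rng.normal(30 + shift, 6, n)
        rows.append(
            pd.DataFrame(
                {
                    "strain": strain,
                    "time_to_first_patch": t1,
                    "duration_first": rng.normal(80, 15, n),
                    "duration_second": rng.normal(60, 12, n),
                    "gap_or_overlap": rng.normal(0, 10, n),
                    "no_polarization": rng.random(n) < (0.05 if shift == 0 else 0.2),
                    "gap": rng.random(n) < 0.3,
                    "overlap": rng.random(n) < 0.3,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestEventTables:
    def test_summary_layout(self):
        table = make_event_table()
        out = summarize_event_table(table, n_boot=300, seed=0)
        assert {"mean", "sem", "sd", "sd_se", "cv", "cv_se"} <= set(out.columns)
        assert set(out["strain"]) == {"reference", "mutA"}

    def test_comparison_detects_shift(self):
        table = make_event_table()
        tests = compare_to_reference(table, "reference", n_perm=500, seed=1)
        row = tests[
            (tests["variable"] == "time_to_first_patch") & (tests["statistic"] == "mean")
        ]
        assert row["p_value"].iloc[0] < 0.01

    def test_category_tests_and_bh(self):
        table = make_event_table()
        out = category_tests(table, "reference", correction="bh")
        assert {"p_value", "p_adjusted"} <= set(out.columns)
        assert (out["p_adjusted"] >= out["p_value"] - 1e-12).all()
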