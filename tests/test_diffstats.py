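"""Differential testing: exact-test oracle agreement, interval coverage
properties, and the BH step-up contract."""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ventmag import synth
from ventmag.diffstats import (ContingencyTable, bh_adjust,
                               compare_metagenomes, fisher_exact_two_sided,
                               newcombe_diff_interval, wilson_interval)


def fisher_oracle(a, b, c, d):
    """Exact-integer hypergeometric enumeration with the same 1e-7
    relative tie tolerance on the mass comparison (independent of the
    float implementation)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if c1 == 0 or (b + d) == 0:
        return 1.0
    kmin, kmax = max(0, r1 + c1 - n), min(r1, c1)
    weights = {k: comb(r1, k) * comb(n - r1, c1 - k)
               for k in range(kmin, kmax + 1)}
    w_obs = weights[a]
    # w <= w_obs * (1 + 1e-7) in exact integer arithmetic
    num = sum(w for w in weights.values()
              if w * 10 ** 7 <= w_obs * (10 ** 7 + 1))
    return num / comb(n, c1)


class TestFisher:
    def test_balanced_table_is_one(self):
        assert fisher_exact_two_sided(ContingencyTable(5, 5, 5, 5)) == 1.0

    def test_enumeration_example(self):
        p = fisher_exact_two_sided(ContingencyTable(5, 5, 1, 9))
        assert p == pytest.approx(5460 / 38760, rel=1e-9)

    def test_row_swap_symmetry(self):
        t1 = fisher_exact_two_sided(ContingencyTable(7, 3, 2, 8))
        t2 = fisher_exact_two_sided(ContingencyTable(2, 8, 7, 3))
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_degenerate_margin(self):
        assert fisher_exact_two_sided(ContingencyTable(0, 5, 0, 5)) == 1.0

    def test_matches_integer_oracle_on_small_grid(self):
        # full agreement on every table with N <= 25 (the acceptance
        # suite extends this to N <= 60)
        for n in range(2, 26):
            for r1 in range(n + 1):
                for c1 in range(1, n):
                    kmin = max(0, r1 + c1 - n)
                    kmax = min(r1, c1)
                    for a in range(kmin, kmax + 1):
                        b, c = r1 - a, c1 - a
                        d = n - r1 - c
                        if a + b == 0 or c + d == 0:
                            continue
                        t = ContingencyTable(a, b, c, d)
                        assert fisher_exact_two_sided(t) == pytest.approx(
                            fisher_oracle(a, b, c, d), abs=1e-9)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, size=4)
            if a + b == 0 or c + d == 0:
                continue
            ours = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)


class TestWilson:
    def test_closed_form_example(self):
        low, high = wilson_interval(5, 10, 0.95)
        assert low == pytest.approx(0.2366, abs=1e-4)
        assert high == pytest.approx(0.7634, abs=1e-4)

    def test_boundaries(self):
        assert wilson_interval(0, 10)[0] == 0.0
        assert wilson_interval(10, 10)[1] == 1.0

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint
        for x, n in [(3, 17), (0, 9), (12, 12), (40, 100)]:
            ours = wilson_interval(x, n, 0.95)
            ref = proportion_confint(x, n, alpha=0.05, method="wilson")
            assert ours == pytest.approx(ref, abs=1e-10)

    @given(st.integers(1, 200), st.data())
    @settings(max_examples=100, deadline=None)
    def test_contains_point_estimate(self, n, data):
        x = data.draw(st.integers(0, n))
        low, high = wilson_interval(x, n)
        assert 0.0 <= low <= x / n <= high <= 1.0


class TestNewcombe:
    def test_identical_samples_symmetric_about_zero(self):
        low, high = newcombe_diff_interval(4, 12, 4, 12)
        assert low == pytest.approx(-high, abs=1e-12)
        assert low < 0 < high

    def test_limit_toward_unit_difference(self):
        low, high = newcombe_diff_interval(1000, 1000, 0, 1000)
        assert high == pytest.approx(1.0, abs=1e-2)
        assert low == pytest.approx(1.0, abs=1e-2)

    def test_composition_from_wilson_bounds(self):
        x1, n1, x2, n2 = 5, 10, 1, 10
        l1, u1 = wilson_interval(x1, n1)
        l2, u2 = wilson_interval(x2, n2)
        p1, p2 = x1 / n1, x2 / n2
        delta = p1 - p2
        low, high = newcombe_diff_interval(x1, n1, x2, n2)
        assert low == pytest.approx(
            delta - math.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2), abs=1e-4)
        assert high == pytest.approx(
            delta + math.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2), abs=1e-4)

    def test_coverage_at_95(self, rng):
        # >= 93% empirical coverage of the true difference over 2000 trials
        covered = 0
        trials = 2000
        for i in range(trials):
            p1, p2, n = [(0.3, 0.1, 80), (0.05, 0.05, 200),
                         (0.5, 0.45, 150)][i % 3]
            x1 = rng.binomial(n, p1)
            x2 = rng.binomial(n, p2)
            low, high = newcombe_diff_interval(x1, n, x2, n)
            covered += low <= p1 - p2 <= high
        assert covered / trials >= 0.93


def bh_oracle(p):
    """Literal step-up: find the largest i with p_(i) <= i*alpha/m by
    scanning, expressed as adjusted values via suffix minima."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        q[order[rank]] = running
    return q


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]).tolist() == [0.123]

    def test_step_up_arithmetic(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q.tolist() == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle_and_dominates_p(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert q.tolist() == pytest.approx(bh_oracle(p))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=200)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=31)
        perm = rng.permutation(31)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestCompareMetagenomes:
    def test_identical_samples_nothing_flagged(self, gene_tables):
        genes_a, _ = gene_tables
        res = compare_metagenomes(genes_a, genes_a.copy(), alpha=0.5)
        assert not res["significant"].any()
        assert (res["p"] == 1.0).all()

    def test_constructed_enrichment_flagged(self, gene_tables):
        genes_a, genes_b = gene_tables
        res = compare_metagenomes(genes_a, genes_b).set_index("symbol")
        for s in synth.ENRICHED_IN_A:
            assert res.loc[s, "significant"]
            assert res.loc[s, "enriched_in"] == "A"
        for s in synth.ENRICHED_IN_B:
            assert res.loc[s, "significant"]
            assert res.loc[s, "enriched_in"] == "B"

    def test_sample_order_antisymmetry(self, gene_tables):
        genes_a, genes_b = gene_tables
        fwd = compare_metagenomes(genes_a, genes_b).set_index("symbol")
        rev = compare_metagenomes(genes_b, genes_a).set_index("symbol")
        np.testing.assert_allclose(fwd["delta"], -rev["delta"])
        np.testing.assert_allclose(fwd["p"], rev["p"])
        flipped = rev["enriched_in"].map({"A": "B", "B": "A", "": ""})
        assert (fwd["enriched_in"] == flipped).all()

    def test_absent_symbol_skipped(self, gene_tables):
        genes_a, genes_b = gene_tables
        res = compare_metagenomes(genes_a, genes_b,
                                  symbols=["soxB", "not_a_gene"])
        assert res["symbol"].tolist() == ["soxB"]

    def test_type_one_error_rate_under_null(self, rng):
        # both samples drawn from one multinomial; Fisher is conservative
        reject = 0
        trials = 2000
        n = 200_000
        for i in range(trials):
            p = 10 ** rng.uniform(-4, -2.5)
            x1, x2 = rng.binomial(n, p, size=2)
            t = ContingencyTable(int(x1), n - int(x1), int(x2), n - int(x2))
            reject += fisher_exact_two_sided(t) < 0.05
        assert reject / trials <= 0.06
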