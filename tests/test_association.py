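"""Contingency chi-square association and Benjamini-Hochberg control."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscan import (
    NucleotideCounts,
    association_test,
    bh_mask,
    bh_thresholds,
    pearson_chi2,
)
from poolscan.association import NEG_LOG10_CAP, pearson_chi2_batch


def bh_brute_force(pvals, alpha):
    """Direct step-up definition: largest k with p_(k) <= k*alpha/m, then
    flag everything at or below p_(k)."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.sort(p)
    k = 0
    for i in range(m, 0, -1):
        if order[i - 1] <= i * alpha / m:
            k = i
            break
    if k == 0:
        return np.zeros(m, bool)
    return p <= order[k - 1]


class TestChiSquare:
    def test_no_divergence_scores_zero(self):
        rec = association_test(
            [NucleotideCounts(a=100, c=100)], [NucleotideCounts(a=100, c=100)]
        )
        assert rec.chi2 == 0.0 and rec.p == 1.0 and rec.neg_log10_p == 0.0

    def test_worked_divergent_table(self):
        """Hand Pearson computation: expected 107.5/92.5 per group."""
        rec = association_test(
            [NucleotideCounts(a=100, c=20), NucleotideCounts(a=75, c=5)],
            [NucleotideCounts(a=30, c=90), NucleotideCounts(a=10, c=70)],
        )
        assert rec.chi2 == pytest.approx(183.281, abs=1e-3)
        assert rec.df == 1
        # p follows from the chi-square survival function
        from scipy.stats import chi2 as chi2_dist

        assert rec.p == pytest.approx(float(chi2_dist.sf(rec.chi2, 1)), rel=1e-12)

    def test_replicates_are_summed_not_averaged(self):
        a = association_test(
            [NucleotideCounts(a=175, c=25)], [NucleotideCounts(a=40, c=160)]
        )
        b = association_test(
            [NucleotideCounts(a=100, c=20), NucleotideCounts(a=75, c=5)],
            [NucleotideCounts(a=30, c=90), NucleotideCounts(a=10, c=70)],
        )
        assert a.chi2 == pytest.approx(b.chi2)

    def test_monomorphic_table_is_an_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            association_test([NucleotideCounts(a=10)], [NucleotideCounts(a=20)])

    def test_all_zero_row_is_an_error(self):
        with pytest.raises(ValueError, match="all-zero row"):
            pearson_chi2([[0, 0], [5, 5]])

    def test_two_by_two_equals_squared_z(self):
        """Chi-square of a 2x2 equals the squared two-proportion z statistic."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 200, size=4)
            chi2, df, _ = pearson_chi2([[a, b], [c, d]])
            n1, n2 = a + b, c + d
            p1, p2 = a / n1, c / n2
            pbar = (a + c) / (n1 + n2)
            z = (p1 - p2) / math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
            assert chi2 == pytest.approx(z * z, rel=1e-10)
            assert df == 1

    def test_zero_count_alleles_reduce_df(self):
        chi2, df, _ = pearson_chi2([[50, 50, 0, 0], [60, 40, 0, 0]])
        assert df == 1

    def test_underflow_capped_and_flagged(self):
        rec = association_test(
            [NucleotideCounts(a=100000)], [NucleotideCounts(c=100000)]
        )
        assert rec.p == 0.0
        assert rec.neg_log10_p == NEG_LOG10_CAP and rec.p_capped

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(3)
        tables = rng.integers(0, 80, size=(300, 2, 4))
        tables[:, :, 0] += 1  # no all-zero rows
        chi2, df, p = pearson_chi2_batch(tables)
        for i in range(len(tables)):
            c, d, q = pearson_chi2(tables[i])
            assert chi2[i] == pytest.approx(c, rel=1e-12, abs=1e-12)
            assert df[i] == d
            assert p[i] == pytest.approx(q, rel=1e-12, abs=1e-300)


class TestBenjaminiHochberg:
    def test_step_up_rescues_smaller_p(self):
        mask = bh_mask([0.001, 0.008, 0.039, 0.041], alpha=0.05)
        assert mask.all()  # 0.041 <= 4/4*0.05 rescues 0.039
        [res] = bh_thresholds({"1": [0.001, 0.008, 0.039, 0.041]}, alpha=0.05)
        assert res.k == 4
        assert res.threshold_neg_log10 == pytest.approx(1.3872, abs=1e-4)

    def test_partial_discoveries(self):
        [res] = bh_thresholds({"1": [0.001, 0.02, 0.06, 0.9]}, alpha=0.05)
        assert res.k == 2
        assert res.threshold_neg_log10 == pytest.approx(1.6990, abs=1e-4)

    def test_no_discoveries(self):
        [res] = bh_thresholds({"1": [1.0, 1.0, 1.0]}, alpha=0.05)
        assert res.k == 0 and res.threshold_neg_log10 is None

    def test_empty_chromosome(self):
        [res] = bh_thresholds({"1": []}, alpha=0.05)
        assert res.m == 0 and res.k == 0 and res.threshold_neg_log10 is None

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            alpha = rng.uniform(0.001, 0.2)
            assert np.array_equal(bh_mask(p, alpha), bh_brute_force(p, alpha))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.random(rng.integers(2, 200))
            reject, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert np.array_equal(bh_mask(p, 0.05), reject)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_discoveries_monotone_in_alpha(self, data):
        p = data.draw(
            st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30), label="p"
        )
        a1 = data.draw(st.floats(0.001, 0.5), label="alpha1")
        a2 = data.draw(st.floats(0.001, 0.5), label="alpha2")
        lo, hi = sorted((a1, a2))
        assert bh_mask(p, lo).sum() <= bh_mask(p, hi).sum()
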