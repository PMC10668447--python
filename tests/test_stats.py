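"""Group-level nonparametric tests against closed forms and oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from vrsearch.atypicality import build_summary_matrix
from vrsearch.metrics import compute_metric_vector
from vrsearch.stats import (
    ContingencyTable2x2,
    chisq_2x2,
    levene_test,
    rank_sum_test,
    signed_rank_test,
    typicality_counts,
)

from conftest import perm_p_ranksum, perm_p_signed_rank


class TestChiSquare:
    def test_balanced_table_is_zero(self):
        stat, p = chisq_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_example(self):
        # N(ad−bc)² / ((a+b)(c+d)(a+c)(b+d)) for [[8,5],[2,7]]
        stat, _ = chisq_2x2(ContingencyTable2x2(8, 5, 2, 7))
        n, ad_bc = 22, 8 * 7 - 5 * 2
        expected = n * ad_bc**2 / (13 * 9 * 10 * 12)
        assert stat == pytest.approx(expected)
        assert stat == pytest.approx(3.3162, abs=1e-3)

    def test_matches_scipy_without_correction(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 40, size=4)
            stat, p = chisq_2x2(ContingencyTable2x2(a, b, c, d))
            ref = sps.chi2_contingency([[a, b], [c, d]], correction=False)
            assert stat == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_label_swap_invariance(self):
        s1, _ = chisq_2x2(ContingencyTable2x2(8, 5, 2, 7))
        s2, _ = chisq_2x2(ContingencyTable2x2(2, 7, 8, 5))  # swap rows
        s3, _ = chisq_2x2(ContingencyTable2x2(5, 8, 7, 2))  # swap columns
        assert s1 == pytest.approx(s2) == pytest.approx(s3)

    def test_equals_squared_two_proportion_z(self):
        a, b, c, d = 12, 30, 4, 38
        stat, _ = chisq_2x2(ContingencyTable2x2(a, b, c, d))
        p1, p2 = a / (a + b), c / (c + d)
        pbar = (a + c) / (a + b + c + d)
        z = (p1 - p2) / np.sqrt(pbar * (1 - pbar) * (1 / (a + b) + 1 / (c + d)))
        assert stat == pytest.approx(z**2)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_2x2(ContingencyTable2x2(0, 0, 3, 4))


class TestRankSum:
    def test_identical_samples(self):
        z, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert z == pytest.approx(0.0)
        assert p >= 0.99

    def test_minimum_rank_sum(self):
        # x = [1, 2] takes ranks 1+2 = 3, the minimum of the 4!/(2!2!)=6
        # equally likely assignments; z must be maximally negative
        z, _ = rank_sum_test([1.0, 2.0], [3.0, 4.0])
        ranks_sum = 3
        expected_z = (ranks_sum - 2 * 5 / 2) / np.sqrt(2 * 2 / 12 * 5)
        assert z == pytest.approx(expected_z)

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(21)
        for i in range(30):
            n1, n2 = rng.integers(8, 13, size=2)
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.6, 1, n2)
            _, p = rank_sum_test(x, y)
            assert p == pytest.approx(perm_p_ranksum(x, y, seed=i), abs=0.02)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=10), rng.normal(0.5, 1, size=12)
        z1, p1 = rank_sum_test(x, y)
        z2, p2 = rank_sum_test(np.exp(x), np.exp(y))
        assert (z1, p1) == (pytest.approx(z2), pytest.approx(p2))


class TestSignedRank:
    def test_all_zero_differences(self):
        w, p = signed_rank_test([1.0, 2.0], [1.0, 2.0])
        assert (w, p) == (0.0, 1.0)

    def test_midrank_hand_enumeration(self):
        # diffs [+1, −1, +2]: |d| = [1, 1, 2] → midranks [1.5, 1.5, 3];
        # negative-sign rank sum = 1.5 = the smaller sum
        w, _ = signed_rank_test([1.0, 0.0, 2.0], [0.0, 1.0, 0.0])
        assert w == pytest.approx(1.5)

    def test_statistic_matches_scipy_convention(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=15)
        y = x + rng.normal(0.4, 1, size=15)
        w, _ = signed_rank_test(x, y)
        ref = sps.wilcoxon(x, y, zero_method="wilcox", correction=True)
        assert w == pytest.approx(ref.statistic)

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(31)
        for i in range(30):
            n = rng.integers(10, 16)
            x = rng.normal(0, 1, n)
            y = x + rng.normal(0.4, 1, n)
            _, p = signed_rank_test(x, y)
            assert p == pytest.approx(perm_p_signed_rank(x, y, seed=i), abs=0.02)

    def test_p_values_in_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            _, p1 = signed_rank_test(x, y)
            _, p2 = rank_sum_test(x, y)
            assert 0 <= p1 <= 1 and 0 <= p2 <= 1


class TestLevene:
    def test_identical_groups_zero(self):
        stat, _ = levene_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == pytest.approx(0.0)

    def test_matches_anova_on_absolute_deviations(self):
        # median-centred Levene = one-way ANOVA F on |value − group median|
        x = np.array([0.0, 0.0, 10.0, 10.0])
        y = np.array([5.0, 5.0, 5.0, 5.0])
        zx = np.abs(x - np.median(x))
        zy = np.abs(y - np.median(y))
        f_oracle = sps.f_oneway(zx, zy).statistic
        stat, _ = levene_test(x, y)
        assert stat == pytest.approx(f_oracle)

    def test_degenerate_groups(self):
        stat, p = levene_test([2.0, 2.0, 2.0], [5.0, 5.0, 5.0])
        assert stat == 0.0 and p == 1.0


class TestTypicalityCounts:
    def test_counts_match_manual_tally(self, fixture_cohort):
        sessions, _ = fixture_cohort
        m = build_summary_matrix([compute_metric_vector(s) for s in sessions])
        table = typicality_counts(m, grain="boolean")
        flags = m.flags.dropna(subset=["flag"])
        manual_atyp = flags.groupby("group")["flag"].sum()
        assert table.patients_atypical == int(manual_atyp.get("patient", 0))
        assert table.controls_atypical == int(manual_atyp.get("control", 0))
        total = table.total
        assert total == len(flags)

    def test_all_zero_matrix_gives_empty_atypical_column(self, fixture_cohort):
        sessions, _ = fixture_cohort
        clones = []
        for i in range(4):
            v = compute_metric_vector(sessions[0])
            v.player_id = f"c{i}" if i < 2 else f"p{i}"
            v.group = "control" if i < 2 else "patient"
            clones.append(v)
        m = build_summary_matrix(clones)
        t = typicality_counts(m)
        assert t.patients_atypical == 0 and t.controls_atypical == 0

    def test_cell_grain_thresholds_proportions(self, fixture_cohort):
        sessions, _ = fixture_cohort
        m = build_summary_matrix([compute_metric_vector(s) for s in sessions])
        t = typicality_counts(m, grain="cell")
        n_cells = m.cells.notna().sum().sum()
        assert t.total == n_cells
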