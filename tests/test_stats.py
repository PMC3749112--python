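"""Validation regression and the statistical comparison toolbox."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from canesim import stats


@pytest.fixture(scope="module")
def yield_records():
    return stats.load_yield_table()


class TestYieldTable:
    def test_twenty_one_sites(self, yield_records):
        assert len(yield_records) == 21

    @pytest.mark.parametrize("site,lit,model", [
        ("Auburn, AL", 26.1, 25.4),
        ("Pahokee, FL", 60.5, 65.5),
        ("Hillsboro, FL", 60.7, 62.5),
    ])
    def test_known_rows(self, yield_records, site, lit, model):
        rec = next(r for r in yield_records if r.site == site)
        assert (rec.lit_yield, rec.model_yield) == (lit, model)

    def test_alias_for_validation_workflow(self):
        assert stats.load_table2_fixture is stats.load_yield_table


class TestYieldRegression:
    def test_packaged_table_r_squared(self, yield_records):
        res = stats.yield_regression(yield_records)
        assert round(res.r_squared, 2) == 0.82
        assert res.n == 21

    def test_r_squared_symmetric_in_orientation(self, yield_records):
        fwd = stats.yield_regression(yield_records).r_squared
        swapped = [stats.YieldRecord(r.site, r.model_yield, r.lit_yield,
                                     r.tmax, r.tmin, r.precip, r.latitude,
                                     r.longitude) for r in yield_records]
        assert stats.yield_regression(swapped).r_squared == \
            pytest.approx(fwd, rel=1e-12)

    def test_collinear_records_give_unit_r_squared(self):
        recs = [stats.YieldRecord(f"s{i}", x, 2.0 * x + 1.0, 25, 15, 1000,
                                  27.0, -81.0)
                for i, x in enumerate([10.0, 20.0, 30.0, 40.0])]
        assert stats.yield_regression(recs).r_squared == pytest.approx(1.0)

    def test_orthogonal_noise_gives_near_zero_r_squared(self):
        rng = np.random.default_rng(0)
        x = np.linspace(10, 60, 40)
        noise = rng.normal(0, 5, 40)
        noise -= np.polyval(np.polyfit(x, noise, 1), x)  # de-trend exactly
        recs = [stats.YieldRecord(f"s{i}", xi, 30.0 + ni, 25, 15, 1000,
                                  27.0, -81.0)
                for i, (xi, ni) in enumerate(zip(x, noise))]
        assert stats.yield_regression(recs).r_squared < 1e-20

    def test_degenerate_predictor_rejected(self):
        recs = [stats.YieldRecord(f"s{i}", 10.0, 10.0 + i, 25, 15, 1000,
                                  27.0, -81.0) for i in range(4)]
        with pytest.raises(ValueError):
            stats.yield_regression(recs)


class TestPairedT:
    def test_hand_computed_example(self):
        res = stats.paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.df == 2

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
        res = stats.paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert stats.paired_t(x, y).statistic == pytest.approx(
            -stats.paired_t(y, x).statistic, rel=1e-12)

    def test_zero_difference_variance_rejected(self):
        with pytest.raises(ValueError):
            stats.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def brute_force_u(x, y):
    """Mann-Whitney U of x by direct pair counting (ties count half)."""
    return sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0
               for xi in x for yi in y)


class TestWilcoxonRankSum:
    def test_complete_separation_of_two_n15_samples(self):
        x = np.arange(100, 115, dtype=float)
        y = np.arange(0, 15, dtype=float)
        res = stats.wilcoxon_rank_sum(x, y)
        assert res.statistic == 225.0  # maximal W for n = m = 15
        assert res.p_value < 0.001

    def test_u_statistics_sum_to_nm(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=12), rng.normal(size=9)
        u_x = stats.wilcoxon_rank_sum(x, y).statistic
        u_y = stats.wilcoxon_rank_sum(y, x).statistic
        assert u_x + u_y == pytest.approx(12 * 9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 10, size=7).astype(float)
        y = rng.integers(0, 10, size=6).astype(float)
        assert stats.wilcoxon_rank_sum(x, y).statistic == \
            pytest.approx(brute_force_u(x, y))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            stats.wilcoxon_rank_sum([], [1.0])


class TestFlignerKilleen:
    def test_equal_spread_groups_not_flagged(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = stats.fligner_killeen(a, a + 100.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.95

    def test_detects_strong_heteroscedasticity(self):
        rng = np.random.default_rng(6)
        res = stats.fligner_killeen(rng.normal(0, 1, 50),
                                    rng.normal(0, 10, 50))
        assert res.p_value < 0.01

    def test_permutation_invariance_within_groups(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=8), rng.normal(0, 3, size=8)
        res1 = stats.fligner_killeen(a, b)
        res2 = stats.fligner_killeen(a[::-1], rng.permutation(b))
        assert res1.statistic == pytest.approx(res2.statistic, rel=1e-12)

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            stats.fligner_killeen([1.0, 2.0])


class TestStoreyFdr:
    def test_all_tiny_pvalues(self):
        pi0, q = stats.storey_fdr([1e-6] * 10, 0.5)
        assert pi0 == 0.0
        assert np.allclose(q, 0.0)

    def test_hand_computed_step_formula(self):
        # five p = 0.01 and five p = 0.8 with lambda 0.5: pi0 = 5/(0.5*10) = 1,
        # q for the small ps = min_j>=i 1*10*p_(j)/j = 10*0.01/5 = 0.02
        p = [0.01] * 5 + [0.8] * 5
        pi0, q = stats.storey_fdr(p, 0.5)
        assert pi0 == 1.0
        assert np.allclose(q[:5], 0.02)

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=50)
        _, q = stats.storey_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_equals_pi0_scaled_benjamini_hochberg(self):
        # before clipping at 1, Storey q-values are exactly pi0 * BH q-values
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(9)
        p = np.concatenate([rng.uniform(0, 0.01, 10), rng.uniform(size=40)])
        pi0, q = stats.storey_fdr(p, 0.5)
        _, q_bh, *_ = multipletests(p, method="fdr_bh")
        assert pi0 < 1.0
        mask = pi0 * q_bh < 1.0
        assert np.allclose(q[mask], pi0 * q_bh[mask])
        assert (q <= q_bh + 1e-12).all()

    @pytest.mark.parametrize("bad", [[], [1.2], [-0.1]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            stats.storey_fdr(bad)


class TestComparisonMatrix:
    def test_matrix_with_q_column(self, spodosol_run, histosol_run):
        frames = {"spodosol": spodosol_run.cane_frame(),
                  "histosol": histosol_run.cane_frame()}
        table = stats.comparison_matrix(
            frames, [("histosol", "spodosol")],
            variables=["rh", "ag_production", "n2o_n"])
        assert len(table) == 3
        assert set(table["df"]) == {14.0}
        assert "q_value" in table.columns
        # heterotrophic respiration is decisively higher on the muck
        rh_row = table[table["variable"] == "rh"].iloc[0]
        assert rh_row["t"] > 0 and rh_row["p_value"] < 0.001
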