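"""Fisher combination, empirical null, rank products, BH q-values, ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from methrank.combine import (
    EmpiricalNull,
    assemble_ranking,
    bh_qvalues,
    chi2_fisher_pvalue,
    empirical_pb_pvalue,
    fisher_mult,
    fisher_pb,
    rank_products,
)


class TestFisherPB:
    @pytest.mark.parametrize(
        "pp, pb, expected",
        [
            (1.0, 1.0, 0.0),
            (math.exp(-1), math.exp(-1), 4.0),
            (0.05, 0.2, -2 * math.log(0.05) - 2 * math.log(0.2)),
        ],
    )
    def test_examples(self, pp, pb, expected):
        assert fisher_pb(pp, pb) == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_pb(0.0, 0.5)


class TestEmpiricalNull:
    def test_midpoint(self):
        null = EmpiricalNull(np.array([1.0, 2.0, 3.0, 4.0]))
        assert empirical_pb_pvalue(2.5, null) == pytest.approx(0.5)

    def test_below_all_values(self):
        null = EmpiricalNull(np.array([1.0, 2.0, 3.0, 4.0]))
        assert empirical_pb_pvalue(0.5, null) == 1.0

    def test_beyond_all_values_clamped(self):
        null = EmpiricalNull(np.array([1.0, 2.0, 3.0, 4.0]))
        assert empirical_pb_pvalue(10.0, null) == pytest.approx(0.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            EmpiricalNull(np.array([]))


class TestChi2Fisher:
    def test_closed_forms(self):
        # df=2: p = exp(-t/2); df=4: p = exp(-t/2) (1 + t/2)
        t2 = -2 * math.log(0.05)
        assert chi2_fisher_pvalue(t2, 2) == pytest.approx(0.05, abs=1e-9)
        t4 = -2 * math.log(0.05) - 2 * math.log(0.2)
        expected4 = math.exp(-t4 / 2) * (1 + t4 / 2)
        assert chi2_fisher_pvalue(t4, 4) == pytest.approx(expected4, abs=1e-9)
        assert expected4 == pytest.approx(0.056052, abs=1e-6)
        assert chi2_fisher_pvalue(0.0, 8) == 1.0

    def test_odd_df_rejected(self):
        with pytest.raises(ValueError):
            chi2_fisher_pvalue(1.0, 3)


class TestFisherMult:
    def test_single_comparison_is_identity(self):
        t, p = fisher_mult([0.05])
        assert t == pytest.approx(-2 * math.log(0.05))
        assert p == pytest.approx(0.05, abs=1e-9)

    def test_all_ones(self):
        t, p = fisher_mult([1.0, 1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_two_comparisons(self):
        t, p = fisher_mult([0.05, 0.2])
        assert t == pytest.approx(-2 * math.log(0.01), abs=1e-9)
        assert p == pytest.approx(math.exp(-t / 2) * (1 + t / 2), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fisher_mult([])


class TestRankProducts:
    def test_geometric_mean(self):
        np.testing.assert_allclose(rank_products([[2, 8]]), [4.0])

    def test_identical_rankings_preserved(self):
        ranks = np.tile(np.array([[3], [1], [2]]), (1, 4))
        rp = rank_products(ranks)
        assert list(np.argsort(rp)) == [1, 2, 0]

    def test_single_column_identity(self):
        np.testing.assert_allclose(
            rank_products([[1], [5], [3]]), [1.0, 5.0, 3.0]
        )


class TestBH:
    def test_worked_example(self):
        q = bh_qvalues([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5], atol=1e-12)

    def test_degenerate_cases(self):
        np.testing.assert_allclose(bh_qvalues([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(bh_qvalues([0.2]), [0.2])

    def test_monotone_when_sorted_by_p(self, rng):
        p = np.sort(rng.uniform(0, 1, 500))
        assert np.all(np.diff(bh_qvalues(p)) >= -1e-15)


class TestAssembleRanking:
    def _scores(self, pvals):
        return pd.DataFrame(
            {"feature_id": [f"f{i}" for i in range(len(pvals))], "p": pvals}
        )

    def test_rank_product_breaks_ties(self):
        # equal products of per-comparison p-values -> identical combined p;
        # f1 has the worst rank product, f0/f2 tie and fall back to id order
        a = self._scores([0.001, 0.01, 0.05])
        b = self._scores([0.1, 0.01, 0.002])
        tab = assemble_ranking({"c1": a, "c2": b}, "custom")
        assert tab["p_combined"].nunique() == 1
        assert list(tab.index) == ["f0", "f2", "f1"]
        assert tab["rank_product"].iloc[0] < tab["rank_product"].iloc[2]

    def test_deterministic(self, rng):
        scores = {
            f"c{i}": self._scores(rng.uniform(0, 1, 50)) for i in range(3)
        }
        t1 = assemble_ranking(scores, "custom")
        t2 = assemble_ranking(scores, "custom")
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_promoter_or_body_drops_from_pb(self):
        null = EmpiricalNull(np.linspace(0.1, 20, 100))
        df = pd.DataFrame(
            {
                "feature_id": ["a", "b", "c"],
                "p_promoter": [0.1, np.nan, 0.5],
                "p_body": [0.2, 0.3, 0.4],
            }
        )
        tab = assemble_ranking({"c1": df}, "pb", null)
        assert set(tab.index) == {"a", "c"}

    def test_pb_requires_null(self):
        df = pd.DataFrame(
            {"feature_id": ["a"], "p_promoter": [0.1], "p_body": [0.2]}
        )
        with pytest.raises(ValueError, match="empirical null"):
            assemble_ranking({"c1": df}, "pb")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            assemble_ranking({}, "custom")


def test_correlated_pb_needs_empirical_null(rng):
    """With strongly correlated promoter/body p-values the chi2(4) reference
    is anticonservative while the empirical null restores uniformity."""
    from scipy.stats import kstest, norm

    def draw(n):
        z0 = rng.normal(size=n)
        z1 = 0.9 * z0 + math.sqrt(1 - 0.81) * rng.normal(size=n)
        z2 = 0.9 * z0 + math.sqrt(1 - 0.81) * rng.normal(size=n)
        pp, pb = norm.sf(z1), norm.sf(z2)
        return -2 * np.log(pp) - 2 * np.log(pb)

    null = EmpiricalNull(draw(100000))
    t_obs = draw(5000)
    p_emp = np.array([empirical_pb_pvalue(t, null) for t in t_obs])
    p_chi = np.array([chi2_fisher_pvalue(t, 4) for t in t_obs])
    assert kstest(p_emp, "uniform").pvalue > 0.01
    assert kstest(p_chi, "uniform").pvalue < 1e-6
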