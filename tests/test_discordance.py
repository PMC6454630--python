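"""JSD, mutual information, and the T statistic."""

import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon

from methrank.discordance import (
    GUComparison,
    average_mutual_information,
    gu_mutual_information,
    jsd,
    t_statistic,
)
from methrank.ising import MethylationPMF

from conftest import random_pmf


def _pmf(*probs):
    return MethylationPMF(len(probs) - 1, np.array(probs, float))


class TestJSD:
    def test_identity_of_indiscernibles(self, rng):
        for _ in range(20):
            p = random_pmf(rng, int(rng.integers(1, 8)))
            assert jsd(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_reach_one_bit(self):
        assert jsd(_pmf(1, 0, 0), _pmf(0, 0, 1)) == pytest.approx(1.0)

    def test_worked_example(self):
        # KL terms of (1/2,1/2) vs (1,0) against their mixture (3/4,1/4):
        # divergence = 0.5*(1 - 0.5*log2 3) + 0.5*(2 - log2 3) bits
        div = 1.5 - 0.75 * np.log2(3.0)
        assert jsd(_pmf(0.5, 0.5), _pmf(1.0, 0.0)) == pytest.approx(
            np.sqrt(div), abs=1e-12
        )

    def test_against_scipy_oracle(self, rng):
        for _ in range(100):
            L = int(rng.integers(1, 10))
            p, q = random_pmf(rng, L), random_pmf(rng, L)
            assert jsd(p, q) == pytest.approx(
                jensenshannon(p.probs, q.probs, base=2), abs=1e-10
            )

    def test_metric_axioms(self, rng):
        for _ in range(300):
            L = int(rng.integers(1, 6))
            p, q, r = (random_pmf(rng, L) for _ in range(3))
            d_pq, d_qr, d_pr = jsd(p, q), jsd(q, r), jsd(p, r)
            assert d_pq == pytest.approx(jsd(q, p), abs=1e-12)  # symmetry
            assert 0.0 <= d_pq <= 1.0
            assert d_pq + d_qr >= d_pr - 1e-12  # triangle inequality

    def test_mismatched_support_rejected(self):
        with pytest.raises(ValueError, match="supports differ"):
            jsd(_pmf(0.5, 0.5), _pmf(0.3, 0.3, 0.4))


class TestTStatistic:
    @pytest.mark.parametrize(
        "jsds, expected",
        [
            ((0.0, 0.0, 0.0), 0.0),
            ((1.0, 1.0, 1.0, 1.0, 1.0), 1.0),
            ((0.3, 0.4), np.sqrt(0.125)),
        ],
    )
    def test_examples(self, jsds, expected):
        assert t_statistic(jsds) == pytest.approx(expected, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            t_statistic([])

    def test_phenotype_triangle_inequality(self, rng):
        """T(q1,q2) + T(q1,q3) >= T(q2,q3) over per-GU PMF assignments."""
        for _ in range(200):
            K = int(rng.integers(1, 5))
            Ls = [int(rng.integers(1, 5)) for _ in range(K)]
            a = [random_pmf(rng, L) for L in Ls]
            b = [random_pmf(rng, L) for L in Ls]
            c = [random_pmf(rng, L) for L in Ls]
            t_ab = t_statistic([jsd(x, y) for x, y in zip(a, b)])
            t_ac = t_statistic([jsd(x, y) for x, y in zip(a, c)])
            t_bc = t_statistic([jsd(x, y) for x, y in zip(b, c)])
            assert t_ab + t_ac >= t_bc - 1e-12


class TestMutualInformation:
    def test_identical_distributions_carry_no_information(self, rng):
        p = random_pmf(rng, 4)
        for prior in (0.1, 0.5, 0.9):
            assert gu_mutual_information(p, p, prior) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_disjoint_point_masses_give_one_bit(self):
        got = gu_mutual_information(_pmf(1, 0, 0), _pmf(0, 0, 1), 0.5)
        assert got == pytest.approx(1.0, abs=1e-12)

    def test_equals_squared_jsd_at_uniform_prior(self, rng):
        p, q = _pmf(0.5, 0.5), _pmf(1.0, 0.0)
        assert gu_mutual_information(p, q, 0.5) == pytest.approx(
            0.311278, abs=1e-6
        )
        for _ in range(100):
            L = int(rng.integers(1, 8))
            p, q = random_pmf(rng, L), random_pmf(rng, L)
            assert gu_mutual_information(p, q, 0.5) == pytest.approx(
                jsd(p, q) ** 2, abs=1e-12
            )

    def test_average_equals_squared_t_at_uniform_prior(self, rng):
        for _ in range(50):
            K = int(rng.integers(1, 6))
            pairs = []
            for _ in range(K):
                L = int(rng.integers(1, 6))
                pairs.append((random_pmf(rng, L), random_pmf(rng, L)))
            jsds = [jsd(p, q) for p, q in pairs]
            assert average_mutual_information(pairs, 0.5) == pytest.approx(
                t_statistic(jsds) ** 2, abs=1e-10
            )

    def test_single_gu_reduces_to_gu_mi(self, rng):
        p, q = random_pmf(rng, 3), random_pmf(rng, 3)
        assert average_mutual_information([(p, q)], 0.3) == pytest.approx(
            gu_mutual_information(p, q, 0.3)
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_mutual_information([], 0.5)


def test_gu_comparison_validation():
    with pytest.raises(ValueError, match="jsd"):
        GUComparison("chr1", 0, 150, 1.5)
    with pytest.raises(ValueError, match="empty"):
        GUComparison("chr1", 150, 150, 0.2)
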