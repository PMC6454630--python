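"""Feature derivation, GU assignment, size filtering and scoring."""

import math

import numpy as np
import pytest

from methrank.discordance import GUComparison
from methrank.features import (
    FeatureScore,
    GeneModel,
    GenomicFeature,
    GUIndex,
    assign_gus,
    derive_gene_body,
    derive_promoter,
    score_feature,
    score_features,
    size_filter,
)
from methrank.null_model import FitConfig, fit_null_model
from methrank.simulate import simulate_null_observations


@pytest.fixture(scope="module")
def small_model():
    obs = simulate_null_observations(
        dict(mu=-2.0, sigma=0.5, nu=1.2, tau=6.0), 2000, (1, 6), seed=3
    )
    return fit_null_model(obs, FitConfig(basis="constant"))


def _grid_track(chrom="chr1", n=10, width=150, jsd=0.2):
    return [
        GUComparison(chrom, i * width, (i + 1) * width, jsd) for i in range(n)
    ]


class TestDerivation:
    def test_plus_strand_promoter_centered_at_tss(self):
        gene = GeneModel("g", "chr1", 10000, 20000, "+")
        prom = derive_promoter(gene)
        assert (prom.start, prom.end) == (8000, 12000)

    def test_minus_strand_promoter_centered_at_end(self):
        gene = GeneModel("g", "chr1", 10000, 20000, "-")
        prom = derive_promoter(gene)
        assert (prom.start, prom.end) == (18000, 22000)

    def test_promoter_floored_at_chromosome_start(self):
        prom = derive_promoter(GeneModel("g", "chr1", 1000, 5000, "+"))
        assert (prom.start, prom.end) == (0, 3000)

    def test_body_is_gene_minus_promoter(self):
        assert (
            derive_gene_body(GeneModel("g", "chr1", 10000, 20000, "+")).start,
            derive_gene_body(GeneModel("g", "chr1", 10000, 20000, "+")).end,
        ) == (12000, 20000)
        body = derive_gene_body(GeneModel("g", "chr1", 10000, 20000, "-"))
        assert (body.start, body.end) == (10000, 18000)

    def test_gene_inside_promoter_gives_empty_body(self):
        body = derive_gene_body(GeneModel("g", "chr1", 10000, 11000, "+"))
        assert body.is_empty

    def test_promoter_body_never_overlap(self, rng):
        for _ in range(200):
            start = int(rng.integers(0, 100000))
            end = start + int(rng.integers(1, 50000))
            strand = "+" if rng.random() < 0.5 else "-"
            g = GeneModel("g", "chr1", start, end, strand)
            p, b = derive_promoter(g), derive_gene_body(g)
            assert p.end - p.start == 4000 or p.start == 0
            if not b.is_empty:
                assert b.end <= p.start or b.start >= p.end
                assert b.start >= g.start and b.end <= g.end


class TestAssignment:
    def test_exact_cover(self):
        track = _grid_track()
        K, jsds = assign_gus(GenomicFeature("f", "chr1", 300, 600), track)
        assert K == 2 and len(jsds) == 2

    def test_one_bp_overlap_counts(self):
        track = _grid_track()
        K, _ = assign_gus(GenomicFeature("f", "chr1", 290, 310), track)
        assert K == 2

    def test_midpoint_rule_is_stricter(self):
        track = _grid_track()
        feature = GenomicFeature("f", "chr1", 290, 310)
        K, _ = assign_gus(feature, track, overlap="midpoint")
        assert K == 0

    def test_no_data_gives_zero(self):
        K, jsds = assign_gus(
            GenomicFeature("f", "chr2", 0, 1000), _grid_track()
        )
        assert K == 0 and len(jsds) == 0

    def test_overlapping_gus_rejected(self):
        recs = [
            GUComparison("chr1", 0, 150, 0.1),
            GUComparison("chr1", 100, 250, 0.1),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            GUIndex(recs)


class TestFilterAndScore:
    def test_size_filter_thresholds(self):
        scores = [
            FeatureScore(f"f{k}", k, math.log2(k), 0.2, 0.5)
            for k in (8, 9, 10, 11, 12)
        ]
        kept = size_filter(scores, 10)
        assert len(kept) == 3 and min(sc.K for sc in kept) == 10
        assert size_filter(scores, 1) == scores
        scores2 = [
            FeatureScore(f"f{k}", k, math.log2(k), 0.2, 0.5) for k in (4, 5, 6)
        ]
        assert len(size_filter(scores2, 5)) == 2

    def test_zero_jsds_score_p_one(self, small_model):
        track = _grid_track(jsd=0.0)
        sc = score_feature(
            GenomicFeature("f", "chr1", 0, 1500), track, small_model
        )
        assert sc.t_stat == 0.0 and sc.p == 1.0
        assert sc.K == 10 and sc.s == pytest.approx(math.log2(10))

    def test_planted_discordance_is_significant(self, small_model):
        track = [
            GUComparison("chr1", i * 150, (i + 1) * 150, 0.85)
            for i in range(16)
        ]
        sc = score_feature(
            GenomicFeature("f", "chr1", 0, 2400), track, small_model
        )
        assert sc.p < 0.001

    def test_unscorable_feature_returns_none(self, small_model):
        assert (
            score_feature(
                GenomicFeature("f", "chrX", 0, 100), _grid_track(), small_model
            )
            is None
        )

    def test_scoring_invariant_to_record_order(self, rng, small_model):
        track = _grid_track(n=20, jsd=0.0)
        track = [
            GUComparison(r.chrom, r.start, r.end, float(rng.uniform(0, 0.6)))
            for r in track
        ]
        feats = [GenomicFeature("f", "chr1", 0, 3000)]
        a = score_features(feats, list(track), small_model)
        shuffled = list(track)
        rng.shuffle(shuffled)
        b = score_features(feats, shuffled, small_model)
        assert a.equals(b)
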