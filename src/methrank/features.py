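"""Genomic features: promoters, gene bodies, custom intervals, and scoring.

Coordinates are 0-based half-open throughout.  A gene's promoter is a
window of 2*half_width bp (default 4 kb) centered at its TSS (strand
aware: TSS = start on '+', end on '-'), floored at position 0.  The gene
body is the gene interval minus its promoter; a gene entirely inside its
promoter window yields an empty sentinel body (start == end).

A feature is scored against one test/reference comparison by collecting
the JSD values of the K data-bearing GUs that overlap it (>= 1 bp by
default), computing T = rms(JSDs), the size s = log2 K, and the p-value
from a fitted size-dependent null model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .discordance import GUComparison, t_statistic
from .null_model import NullModel, null_pvalue

__all__ = [
    "GeneModel",
    "GenomicFeature",
    "FeatureScore",
    "derive_promoter",
    "derive_gene_body",
    "assign_gus",
    "size_filter",
    "score_feature",
    "score_features",
    "collect_t_observations",
]

OverlapRule = Literal["any", "midpoint"]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start must precede end "
                f"({self.start} >= {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class GenomicFeature:
    feature_id: str
    chrom: str
    start: int
    end: int
    kind: str = "custom"
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"feature {self.feature_id}: start > end ({self.start} > {self.end})"
            )

    @property
    def is_empty(self) -> bool:
        return self.start == self.end


@dataclass(frozen=True)
class FeatureScore:
    feature_id: str
    K: int
    s: float
    t_stat: float
    p: float

    def __post_init__(self) -> None:
        if self.K >= 1 and abs(self.s - math.log2(self.K)) > 1e-12:
            raise ValueError("s must equal log2(K)")


def derive_promoter(gene: GeneModel, half_width: int = 2000) -> GenomicFeature:
    """Promoter: [TSS - half_width, TSS + half_width), floored at 0."""
    start = max(gene.tss - half_width, 0)
    return GenomicFeature(
        gene.gene_id, gene.chrom, start, gene.tss + half_width, "promoter",
        gene.strand,
    )


def derive_gene_body(gene: GeneModel, half_width: int = 2000) -> GenomicFeature:
    """Gene body: the gene interval minus its promoter window.

    On '+' the promoter covers the gene's 5' end, so the body is
    [promoter_end, gene_end); on '-' it is [gene_start, promoter_start).
    Returns an empty sentinel (start == end) when the promoter covers the
    whole gene.
    """
    prom = derive_promoter(gene, half_width)
    if gene.strand == "+":
        start, end = max(gene.start, prom.end), gene.end
    else:
        start, end = gene.start, min(gene.end, prom.start)
    if start >= end:
        start = end = gene.start  # empty sentinel
    return GenomicFeature(gene.gene_id, gene.chrom, start, end, "gene_body",
                          gene.strand)


class GUIndex:
    """Sorted per-chromosome index over non-overlapping GU comparison records.

    Accepts a sequence of :class:`GUComparison` records or a DataFrame with
    columns chrom, start, end, jsd.
    """

    def __init__(self, records: Iterable[GUComparison] | pd.DataFrame):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._jsds: dict[str, np.ndarray] = {}
        if isinstance(records, pd.DataFrame):
            for chrom, grp in records.groupby("chrom", sort=False):
                grp = grp.sort_values("start", kind="mergesort")
                self._add(str(chrom), grp["start"].to_numpy(),
                          grp["end"].to_numpy(), grp["jsd"].to_numpy(float))
            return
        by_chrom: dict[str, list[GUComparison]] = {}
        for r in records:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: r.start)
            self._add(
                chrom,
                np.array([r.start for r in recs]),
                np.array([r.end for r in recs]),
                np.array([r.jsd for r in recs]),
            )

    def _add(self, chrom: str, starts, ends, jsds) -> None:
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping GUs on {chrom}")
        self._starts[chrom] = starts
        self._ends[chrom] = ends
        self._jsds[chrom] = jsds

    def query(
        self, feature: GenomicFeature, overlap: OverlapRule = "any"
    ) -> np.ndarray:
        """JSDs of data-bearing GUs overlapping the feature, in genomic order."""
        if feature.chrom not in self._starts or feature.is_empty:
            return np.empty(0)
        starts = self._starts[feature.chrom]
        ends = self._ends[feature.chrom]
        if overlap == "any":
            lo = np.searchsorted(ends, feature.start, side="right")
            hi = np.searchsorted(starts, feature.end, side="left")
        elif overlap == "midpoint":
            mids = (starts + ends) / 2.0
            lo = np.searchsorted(mids, feature.start, side="left")
            hi = np.searchsorted(mids, feature.end, side="left")
        else:
            raise ValueError(f"unknown overlap rule {overlap!r}")
        return self._jsds[feature.chrom][lo:hi]


def assign_gus(
    feature: GenomicFeature,
    gu_comparisons: Sequence[GUComparison] | GUIndex,
    overlap: OverlapRule = "any",
) -> tuple[int, np.ndarray]:
    """Number K of data-bearing GUs overlapping the feature and their JSDs."""
    index = (
        gu_comparisons
        if isinstance(gu_comparisons, GUIndex)
        else GUIndex(gu_comparisons)
    )
    jsds = index.query(feature, overlap)
    return len(jsds), jsds


def size_filter(scores: Sequence[FeatureScore], k_min: int) -> list[FeatureScore]:
    """Retain features with at least ``k_min`` data-bearing GUs."""
    if k_min < 1:
        raise ValueError(f"k_min must be >= 1, got {k_min}")
    return [sc for sc in scores if sc.K >= k_min]


def score_feature(
    feature: GenomicFeature,
    gu_comparisons: Sequence[GUComparison] | GUIndex,
    model: NullModel,
    overlap: OverlapRule = "any",
) -> Optional[FeatureScore]:
    """Score one feature; None when no data-bearing GU overlaps it (K = 0)."""
    K, jsds = assign_gus(feature, gu_comparisons, overlap)
    if K == 0:
        return None
    t = t_statistic(jsds)
    s = math.log2(K)
    return FeatureScore(feature.feature_id, K, s, t, null_pvalue(t, s, model))


def _t_and_s(
    features: Sequence[GenomicFeature],
    index: GUIndex,
    k_min: int,
    overlap: OverlapRule,
) -> pd.DataFrame:
    rows = []
    for f in features:
        jsds = index.query(f, overlap)
        K = len(jsds)
        if K >= k_min:
            rows.append((f.feature_id, K, math.log2(K), t_statistic(jsds)))
    return pd.DataFrame(rows, columns=["feature_id", "K", "s", "t"])


def score_features(
    features: Sequence[GenomicFeature],
    gu_comparisons: Sequence[GUComparison] | GUIndex,
    model: NullModel,
    k_min: int = 1,
    overlap: OverlapRule = "any",
) -> pd.DataFrame:
    """Score many features against one comparison.

    Returns a DataFrame with columns feature_id, K, s, t, p containing only
    features with K >= k_min.
    """
    if k_min < 1:
        raise ValueError(f"k_min must be >= 1, got {k_min}")
    index = (
        gu_comparisons
        if isinstance(gu_comparisons, GUIndex)
        else GUIndex(gu_comparisons)
    )
    df = _t_and_s(features, index, k_min, overlap)
    from .null_model import null_pvalues

    df["p"] = (
        null_pvalues(df["t"].to_numpy(), df["s"].to_numpy(), model)
        if len(df)
        else np.empty(0)
    )
    return df


def collect_t_observations(
    features: Sequence[GenomicFeature],
    gu_comparisons: Sequence[GUComparison] | GUIndex,
    k_min: int = 1,
    overlap: OverlapRule = "any",
) -> pd.DataFrame:
    """(t, s) pairs for one reference/reference comparison, for null fitting."""
    index = (
        gu_comparisons
        if isinstance(gu_comparisons, GUIndex)
        else GUIndex(gu_comparisons)
    )
    return _t_and_s(features, index, k_min, overlap)[["feature_id", "t", "s"]]
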