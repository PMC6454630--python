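"""Per-GU discordance measures and the feature-level test statistic T.

Methylation discordance between a test and a reference phenotype is measured
per GU by the Jensen-Shannon distance (JSD, base-2 logs) between the two
conditional methylation-level PMFs.  A genomic feature overlapping K
data-bearing GUs is scored by the root-mean-square of its per-GU JSDs,

    T = sqrt( (1/K) sum_k JSD(k)^2 ),

which lies in [0, 1], equals 0 iff every per-GU pair of PMFs is identical,
equals 1 iff every pair has disjoint support, and — at a uniform phenotype
prior Pr[Q=1] = 1/2 — satisfies T^2 = average mutual information between the
per-GU methylation levels and the phenotype, in bits.  T also satisfies the
triangle inequality across phenotypes, which the plain mean of squared JSDs
does not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ising import MethylationPMF

__all__ = [
    "GUComparison",
    "jsd",
    "t_statistic",
    "gu_mutual_information",
    "average_mutual_information",
]


@dataclass(frozen=True)
class GUComparison:
    """One GU's test/reference comparison record (bedGraph-style)."""

    chrom: str
    start: int
    end: int
    jsd: float
    mml_test: Optional[float] = None
    mml_ref: Optional[float] = None
    nme_test: Optional[float] = None
    nme_ref: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty GU interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if not 0.0 <= self.jsd <= 1.0:
            raise ValueError(f"jsd must be in [0, 1], got {self.jsd}")


def _kl_bits(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) in bits with the 0 log 0 := 0 convention."""
    nz = p > 0
    return float(np.sum(p[nz] * (np.log2(p[nz]) - np.log2(q[nz]))))


def _check_same_support(p: MethylationPMF, q: MethylationPMF) -> None:
    if p.cpg_count != q.cpg_count:
        raise ValueError(
            f"PMF supports differ: L={p.cpg_count} vs L={q.cpg_count}; "
            "GUs are fixed genomic intervals so supports must agree"
        )


def jsd(p: MethylationPMF, q: MethylationPMF) -> float:
    """Jensen-Shannon distance between two level PMFs on the same support.

    The square root of the Jensen-Shannon divergence with base-2 logarithms:
    JSD^2 = KL(p||m)/2 + KL(q||m)/2 with m = (p+q)/2.  A bounded metric on
    PMFs, 0 iff p = q and 1 iff the supports are disjoint.
    """
    _check_same_support(p, q)
    pa, qa = p.probs, q.probs
    m = 0.5 * (pa + qa)
    div = 0.5 * _kl_bits(pa, m) + 0.5 * _kl_bits(qa, m)
    return float(np.sqrt(max(div, 0.0)))


def t_statistic(jsds: Sequence[float]) -> float:
    """Root-mean-square of per-GU JSDs over a feature's K data-bearing GUs."""
    arr = np.asarray(jsds, dtype=float)
    if arr.size == 0:
        raise ValueError("t_statistic requires at least one JSD value")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("JSD values must lie in [0, 1]")
    return float(np.sqrt(np.mean(arr**2)))


def gu_mutual_information(
    p_test: MethylationPMF, p_ref: MethylationPMF, prior_test: float = 0.5
) -> float:
    """Mutual information I(M_k; Q) in bits between one GU's methylation
    level and the binary phenotype Q, with Pr[Q=1] = ``prior_test``.

    With a uniform prior this equals the squared Jensen-Shannon distance
    between the test and reference PMFs.
    """
    _check_same_support(p_test, p_ref)
    if not 0.0 < prior_test < 1.0:
        raise ValueError(f"prior_test must be in (0, 1), got {prior_test}")
    pi1, pi0 = prior_test, 1.0 - prior_test
    mix = pi1 * p_test.probs + pi0 * p_ref.probs
    return pi1 * _kl_bits(p_test.probs, mix) + pi0 * _kl_bits(p_ref.probs, mix)


def average_mutual_information(
    gu_pairs: Sequence[tuple[MethylationPMF, MethylationPMF]],
    prior_test: float = 0.5,
) -> float:
    """Average of per-GU mutual informations over a feature, in bits.

    At prior 1/2 this equals t_statistic(per-GU JSDs) squared.
    """
    if len(gu_pairs) == 0:
        raise ValueError("average_mutual_information requires at least one GU")
    return float(
        np.mean([gu_mutual_information(p, q, prior_test) for p, q in gu_pairs])
    )
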