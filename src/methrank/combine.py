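"""Combining p-values within and across comparisons; final rankings.

Within one test/reference comparison, a gene's promoter and body p-values
are combined with Fisher's statistic T_pb = -2 ln P_p - 2 ln P_b.  Because
promoter and body methylation are correlated, T_pb is referred not to the
theoretical chi-squared(4) law but to an empirical null CDF built from the
same statistic computed on reference/reference comparisons.

Across N_t independent test/reference comparisons, per-comparison p-values
are combined with T_mult = -2 sum ln P^(n), referred to chi-squared(2 N_t).
Ties in the combined p-values are broken by rank products (geometric mean
of per-comparison ranks), and FDR is controlled with Benjamini-Hochberg
q-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EmpiricalNull",
    "fisher_pb",
    "empirical_pb_pvalue",
    "chi2_fisher_pvalue",
    "fisher_mult",
    "rank_products",
    "bh_qvalues",
    "assemble_ranking",
]

_P_FLOOR = 1e-300  # keeps ln P finite for analytic p-values


@dataclass(frozen=True)
class EmpiricalNull:
    """Sorted null sample of the Fisher statistic T_pb from ref/ref data."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.sort(np.asarray(self.values, dtype=float))
        if v.size == 0:
            raise ValueError("empirical null requires at least one observation")
        if np.any(~np.isfinite(v)) or np.any(v < 0):
            raise ValueError("null values must be finite and nonnegative")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)


def fisher_pb(p_p: float, p_b: float) -> float:
    """Fisher's summary statistic for one gene's promoter and body p-values."""
    if not (0.0 < p_p <= 1.0 and 0.0 < p_b <= 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return -2.0 * math.log(p_p) - 2.0 * math.log(p_b)


def empirical_pb_pvalue(t_star: float, null: EmpiricalNull) -> float:
    """p-value 1 - F_pb_hat(t*), floored at 1/(N_r + 1).

    The floor reflects the resolution of an empirical CDF built from N_r
    observations: a statistic beyond every null value is not evidence of a
    p-value of exactly zero.
    """
    count = np.searchsorted(null.values, t_star, side="right")
    p = 1.0 - count / null.n
    return float(max(p, 1.0 / (null.n + 1)))


def chi2_fisher_pvalue(t: float, df: int) -> float:
    """Upper tail of chi-squared(df) at t; df must be a positive even integer."""
    if df <= 0 or df % 2 != 0:
        raise ValueError(f"df must be a positive even integer, got {df}")
    if t < 0:
        raise ValueError(f"statistic must be nonnegative, got {t}")
    return float(chi2.sf(t, df))


def fisher_mult(pvals: Sequence[float]) -> tuple[float, float]:
    """Fisher combination across comparisons: (T_mult, chi-squared p-value)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("fisher_mult requires at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    t = float(-2.0 * np.sum(np.log(p)))
    return t, chi2_fisher_pvalue(t, 2 * p.size)


def rank_products(rank_matrix) -> np.ndarray:
    """Geometric mean of per-comparison ranks, one value per feature (row)."""
    r = np.asarray(rank_matrix, dtype=float)
    if r.ndim != 2:
        raise ValueError("rank matrix must be two-dimensional")
    if np.any(r <= 0):
        raise ValueError("ranks must be positive")
    return np.exp(np.mean(np.log(r), axis=1))


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, in [0, 1])."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _per_comparison_pvalues(
    per_comparison: Mapping[str, pd.DataFrame],
    mode: str,
    empirical_null: Optional[EmpiricalNull],
) -> pd.DataFrame:
    """One column of p-values per comparison, indexed by feature_id.

    Features lacking a required p-value in a comparison carry NaN there.
    """
    cols = {}
    for name, df in per_comparison.items():
        df = df.set_index("feature_id") if "feature_id" in df.columns else df
        if mode == "pb":
            if empirical_null is None:
                raise ValueError("pb mode requires an empirical null")
            both = df[["p_promoter", "p_body"]].dropna()
            t_pb = (-2.0 * np.log(both["p_promoter"].clip(lower=_P_FLOOR))
                    - 2.0 * np.log(both["p_body"].clip(lower=_P_FLOOR)))
            cols[name] = pd.Series(
                [empirical_pb_pvalue(t, empirical_null) for t in t_pb],
                index=both.index,
            )
        else:
            cols[name] = df["p"].dropna()
    return pd.DataFrame(cols)


def assemble_ranking(
    per_comparison: Mapping[str, pd.DataFrame],
    mode: str = "custom",
    empirical_null: Optional[EmpiricalNull] = None,
) -> pd.DataFrame:
    """Build the final ranked table from per-comparison feature scores.

    ``per_comparison`` maps comparison names to DataFrames with a
    ``feature_id`` column (or index) and either a ``p`` column (modes
    promoter/gb/custom) or ``p_promoter``/``p_body`` columns (mode ``pb``).
    Only features with a valid p-value in every comparison are ranked.

    Returns a DataFrame sorted by combined p (ascending), ties broken by
    rank product then feature_id, with columns: per-comparison p-values,
    combined_stat, p_combined, rank_product, q, rank.
    """
    if len(per_comparison) == 0:
        raise ValueError("at least one comparison is required")
    if mode not in ("promoter", "gene_body", "pb", "custom"):
        raise ValueError(f"unknown mode {mode!r}")

    pmat = _per_comparison_pvalues(per_comparison, mode, empirical_null).dropna()
    if len(pmat) == 0:
        raise ValueError("no feature has a p-value in every comparison")
    names = list(pmat.columns)
    n_t = len(names)

    clipped = pmat.clip(lower=_P_FLOOR, upper=1.0)
    if n_t == 1:
        combined_stat = -2.0 * np.log(clipped[names[0]].to_numpy())
        p_combined = pmat[names[0]].to_numpy()
    else:
        combined_stat = -2.0 * np.log(clipped).sum(axis=1).to_numpy()
        p_combined = chi2.sf(combined_stat, 2 * n_t)

    ranks = clipped.rank(axis=0, method="average").to_numpy()
    rp = rank_products(ranks)

    out = pd.DataFrame(
        {
            **{f"p_{c}": pmat[c].to_numpy() for c in names},
            "combined_stat": combined_stat,
            "p_combined": p_combined,
            "rank_product": rp,
        },
        index=pmat.index,
    )
    out = (
        out.assign(_fid=out.index)
        .sort_values(by=["p_combined", "rank_product", "_fid"], kind="mergesort")
        .drop(columns="_fid")
    )
    out["q"] = bh_qvalues(out["p_combined"].to_numpy())
    out["rank"] = np.arange(1, len(out) + 1)
    out.index.name = "feature_id"
    return out
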