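"""Methylation-level distributions within genomic units (GUs).

A GU is a short (default 150 bp) genomic window containing ``L`` CpG sites.
The binary methylation state ``X = (X_1, ..., X_L)`` is modeled by a
nearest-neighbor one-dimensional Ising distribution

    Pr[X = x]  ∝  exp( sum_n a_n x_n  +  sum_n b_n x_n x_{n+1} ),

with per-site field potentials ``a_n`` (methylation propensity) and coupling
potentials ``b_n`` (correlation between adjacent sites).  The methylation
level ``M = (1/L) sum_l X_l`` then has a probability mass function (PMF) over
the L+1 values {0, 1/L, ..., 1}.  This module computes that PMF exactly, and
the two scalar summaries used throughout:

* MML — mean methylation level, E[M];
* NME — normalized methylation entropy, the base-2 Shannon entropy of M
  divided by log2(L+1), so that NME is 0 for a point mass and 1 for the
  uniform distribution over levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IsingGU",
    "MethylationPMF",
    "level_pmf_from_ising",
    "batch_level_pmfs",
    "mml",
    "nme",
]

_PMF_TOL = 1e-8


@dataclass(frozen=True)
class IsingGU:
    """Nearest-neighbor Ising parameters for one GU with ``cpg_count`` sites."""

    cpg_count: int
    field: np.ndarray
    coupling: np.ndarray

    def __post_init__(self) -> None:
        L = self.cpg_count
        if L < 1:
            raise ValueError(f"cpg_count must be >= 1, got {L}")
        f = np.asarray(self.field, dtype=float)
        c = np.asarray(self.coupling, dtype=float)
        if f.shape != (L,):
            raise ValueError(f"field must have length {L}, got shape {f.shape}")
        if c.shape != (max(L - 1, 0),):
            raise ValueError(
                f"coupling must have length {L - 1}, got shape {c.shape}"
            )
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(c))):
            raise ValueError("Ising parameters must be finite")
        object.__setattr__(self, "field", f)
        object.__setattr__(self, "coupling", c)


@dataclass(frozen=True)
class MethylationPMF:
    """PMF of the methylation level M over {0, 1/L, ..., 1}."""

    cpg_count: int
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        L = self.cpg_count
        if L < 1:
            raise ValueError(f"cpg_count must be >= 1, got {L}")
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (L + 1,):
            raise ValueError(f"probs must have length {L + 1}, got shape {p.shape}")
        if np.any(p < -_PMF_TOL) or not np.all(np.isfinite(p)):
            raise ValueError("probabilities must be finite and nonnegative")
        total = p.sum()
        if abs(total - 1.0) > _PMF_TOL:
            raise ValueError(f"probabilities must sum to 1 (got {total!r})")
        object.__setattr__(self, "probs", np.clip(p, 0.0, None) / p.clip(0).sum())

    @property
    def levels(self) -> np.ndarray:
        return np.arange(self.cpg_count + 1) / self.cpg_count

    @classmethod
    def point_mass(cls, cpg_count: int, level_index: int) -> "MethylationPMF":
        p = np.zeros(cpg_count + 1)
        p[level_index] = 1.0
        return cls(cpg_count, p)


def batch_level_pmfs(fields: np.ndarray, couplings: np.ndarray) -> np.ndarray:
    """Exact level PMFs for a batch of GUs sharing the same CpG count.

    ``fields`` has shape (G, L) and ``couplings`` shape (G, L-1); the result
    has shape (G, L+1).  Uses a transfer-matrix style dynamic program over
    (site, methylated count, current site state); cost O(L^2) per GU.
    """
    fields = np.atleast_2d(np.asarray(fields, dtype=float))
    G, L = fields.shape
    couplings = np.asarray(couplings, dtype=float).reshape(G, max(L - 1, 0))
    if not (np.all(np.isfinite(fields)) and np.all(np.isfinite(couplings))):
        raise ValueError("Ising parameters must be finite")

    # dp[:, c, x] = sum of Boltzmann weights over prefixes with c methylated
    # sites and current state x; weights rescaled per site for stability.
    dp = np.zeros((G, L + 1, 2))
    dp[:, 0, 0] = 1.0
    dp[:, 1, 1] = np.exp(fields[:, 0])
    for n in range(1, L):
        ea = np.exp(fields[:, n])[:, None]
        eab = np.exp(fields[:, n] + couplings[:, n - 1])[:, None]
        new = np.zeros_like(dp)
        new[:, :, 0] = dp[:, :, 0] + dp[:, :, 1]
        new[:, 1:, 1] = dp[:, :-1, 0] * ea + dp[:, :-1, 1] * eab
        norm = new.sum(axis=(1, 2), keepdims=True)
        dp = new / norm
    pmf = dp.sum(axis=2)
    return pmf / pmf.sum(axis=1, keepdims=True)


def level_pmf_from_ising(gu: IsingGU) -> MethylationPMF:
    """Exact PMF of M = (1/L) sum_l X_l under the GU's Ising distribution."""
    probs = batch_level_pmfs(gu.field[None, :], gu.coupling[None, :])[0]
    return MethylationPMF(gu.cpg_count, probs)


def mml(pmf: MethylationPMF) -> float:
    """Mean methylation level E[M]."""
    return float(np.dot(pmf.levels, pmf.probs))


def nme(pmf: MethylationPMF) -> float:
    """Normalized methylation entropy: H(M) in bits / log2(L+1), in [0, 1].

    Uses the 0·log 0 = 0 convention.  For L = 1 ... the normalizer log2(2)=1.
    """
    p = pmf.probs
    nz = p > 0
    h = -np.sum(p[nz] * np.log2(p[nz]))
    return float(h / np.log2(pmf.cpg_count + 1))
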