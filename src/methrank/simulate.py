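"""Synthetic cohorts with known ground truth.

The generator emulates the study design the pipeline targets: a cohort of
replicate reference methylomes plus test samples carrying planted
discordant features.  Every sample's per-GU methylation-level PMF comes
from the nearest-neighbor Ising forward model; biological/technical
replicate variability is injected as i.i.d. Gaussian perturbations of the
per-GU field potential, so that reference/reference comparisons exhibit
nonzero JSD absorbing exactly the kind of variability the null model is
fitted to.  Test samples additionally shift the field downward (hypo-
methylation) and weaken the coupling (methylation-entropy gain) inside
planted features — qualitatively the dysregulation signature seen in
aggressively hypomethylated tumors.

Defaults: 4 reference replicates and 3 test samples (each test compared
against a distinct reference so multi-comparison combination operates on
independent comparisons), 150-bp GUs with 3-10 CpG sites, bimodal base
fields (70% methylated-leaning N(0.8, 0.4), 30% unmethylated N(-0.8,
0.4)), couplings N(0.4, 0.2), replicate field noise sd 0.6, features
spanning 5-40 GUs, 5% of GUs masked per sample as missing data, planted
effect = field shift -3.0 with coupling scaled by 0.3.

Also provides direct (t, s) sampling from a known logitSST parameter
surface for exercising the null-model regression in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Union

import numpy as np
import pandas as pd

from .ising import batch_level_pmfs
from .null_model import LogitSSTParams, SizedObservation
from .skewt import logitsst_ppf

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_null_observations",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort."""

    n_chroms: int = 1
    gus_per_chrom: int = 2000
    gu_width: int = 150
    cpgs_per_gu: tuple[int, int] = (3, 10)
    n_ref_replicates: int = 4
    n_test_samples: int = 3
    replicate_noise_sd: float = 0.6
    planted_fraction: float = 0.1
    effect_size: float = 3.0
    coupling_factor: float = 0.3
    feature_gus: tuple[int, int] = (5, 40)
    feature_gap_gus: int = 1
    mask_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_chroms, self.gus_per_chrom, self.gu_width,
            self.n_ref_replicates, self.n_test_samples,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all cohort counts must be positive")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must lie in [0, 1]")
        if not 0.0 <= self.mask_fraction < 1.0:
            raise ValueError("mask_fraction must lie in [0, 1)")
        if self.cpgs_per_gu[0] < 1 or self.cpgs_per_gu[0] > self.cpgs_per_gu[1]:
            raise ValueError("cpgs_per_gu must be an increasing range from >= 1")
        if self.feature_gus[0] < 1 or self.feature_gus[0] > self.feature_gus[1]:
            raise ValueError("feature_gus must be an increasing range from >= 1")
        if self.replicate_noise_sd < 0 or self.coupling_factor < 0:
            raise ValueError("noise sd and coupling factor must be nonnegative")


@dataclass
class SyntheticCohort:
    """In-memory result of :func:`simulate_cohort`."""

    config: CohortConfig
    gus: pd.DataFrame  # chrom, start, end, L, feature_idx (-1 = intergenic)
    features: pd.DataFrame  # feature_id, chrom, start, end, n_gus, planted
    sample_names: list[str]
    ref_names: list[str]
    test_names: list[str]
    pmfs: dict[str, list]  # sample -> per-GU PMF array or None (masked)
    comparisons: dict[str, pd.DataFrame] = field(repr=False)
    ref_ref_names: list[str] = field(default_factory=list)
    test_ref_names: list[str] = field(default_factory=list)


def _sample_pmfs(
    L: np.ndarray, fields: np.ndarray, couplings: np.ndarray, mask: np.ndarray
) -> list:
    """Per-GU level PMFs (None where masked), batched by CpG count."""
    out: list = [None] * L.size
    for ell in np.unique(L):
        idx = np.nonzero((L == ell) & ~mask)[0]
        if idx.size == 0:
            continue
        f = np.repeat(fields[idx, None], ell, axis=1)
        c = np.repeat(couplings[idx, None], max(ell - 1, 0), axis=1)
        pmfs = batch_level_pmfs(f, c)
        for row, i in enumerate(idx):
            out[i] = pmfs[row]
    return out


def _batch_jsd(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Row-wise base-2 Jensen-Shannon distance for stacked PMFs."""
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_p = np.where(p > 0, p * (np.log2(p) - np.log2(m)), 0.0).sum(axis=1)
        kl_q = np.where(q > 0, q * (np.log2(q) - np.log2(m)), 0.0).sum(axis=1)
    return np.sqrt(np.clip(0.5 * kl_p + 0.5 * kl_q, 0.0, None))


def _summaries(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(MML, NME) for stacked PMFs of a common CpG count."""
    n_levels = p.shape[1]
    levels = np.arange(n_levels) / (n_levels - 1)
    mml = p @ levels
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
    return mml, h / np.log2(n_levels)


def _compare(
    gus: pd.DataFrame, pmf_a: list, pmf_b: list
) -> pd.DataFrame:
    """JSD/MML/NME comparison records for GUs with data in both samples."""
    L = gus["L"].to_numpy()
    have = np.array([pmf_a[i] is not None and pmf_b[i] is not None
                     for i in range(len(pmf_a))])
    rows = {
        "chrom": gus["chrom"].to_numpy()[have],
        "start": gus["start"].to_numpy()[have],
        "end": gus["end"].to_numpy()[have],
    }
    idx_all = np.nonzero(have)[0]
    jsd = np.empty(idx_all.size)
    mml_t = np.empty(idx_all.size)
    mml_r = np.empty(idx_all.size)
    nme_t = np.empty(idx_all.size)
    nme_r = np.empty(idx_all.size)
    for ell in np.unique(L[have]):
        sel = L[idx_all] == ell
        idx = idx_all[sel]
        pa = np.stack([pmf_a[i] for i in idx])
        pb = np.stack([pmf_b[i] for i in idx])
        k = np.nonzero(sel)[0]
        jsd[k] = _batch_jsd(pa, pb)
        mml_t[k], nme_t[k] = _summaries(pa)
        mml_r[k], nme_r[k] = _summaries(pb)
    rows.update(
        jsd=jsd, mml_test=mml_t, mml_ref=mml_r, nme_test=nme_t, nme_ref=nme_r
    )
    return pd.DataFrame(rows)


def simulate_cohort(config: CohortConfig = CohortConfig()) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_gus = config.n_chroms * config.gus_per_chrom

    chroms = np.repeat(
        [f"chr{i + 1}" for i in range(config.n_chroms)], config.gus_per_chrom
    )
    within = np.tile(np.arange(config.gus_per_chrom), config.n_chroms)
    starts = within * config.gu_width
    ends = starts + config.gu_width
    L = rng.integers(config.cpgs_per_gu[0], config.cpgs_per_gu[1] + 1, n_gus)

    # Base Ising parameters: bimodal fields (methylated- vs unmethylated-
    # leaning GUs), positive couplings.  The mode separation is kept modest
    # so the replicate-to-replicate discordance scale is comparable across
    # GUs: strongly saturated GUs would respond to field noise far less
    # than intermediate ones, making null T statistics of different
    # features heterogeneous beyond what their size s explains (and the
    # per-feature comparisons correlated through the shared base).
    meth = rng.random(n_gus) < 0.7
    a0 = np.where(
        meth, rng.normal(0.8, 0.4, n_gus), rng.normal(-0.8, 0.4, n_gus)
    )
    b0 = rng.normal(0.4, 0.2, n_gus)

    # features: runs of consecutive GUs separated by small gaps
    feature_idx = np.full(n_gus, -1)
    feat_rows = []
    log_lo, log_hi = np.log(config.feature_gus[0]), np.log(config.feature_gus[1])
    for c in range(config.n_chroms):
        base = c * config.gus_per_chrom
        i = 0
        while i < config.gus_per_chrom:
            k = int(round(np.exp(rng.uniform(log_lo, log_hi))))
            if i + k > config.gus_per_chrom:
                break
            fid = len(feat_rows)
            feature_idx[base + i : base + i + k] = fid
            planted = bool(rng.random() < config.planted_fraction)
            feat_rows.append(
                (
                    f"feat{fid:05d}",
                    f"chr{c + 1}",
                    int(starts[base + i]),
                    int(ends[base + i + k - 1]),
                    k,
                    planted,
                )
            )
            i += k + config.feature_gap_gus
    features = pd.DataFrame(
        feat_rows,
        columns=["feature_id", "chrom", "start", "end", "n_gus", "planted"],
    )
    planted_gu = np.zeros(n_gus, dtype=bool)
    planted_ids = set(features.index[features["planted"]])
    planted_gu[np.isin(feature_idx, list(planted_ids))] = True

    gus = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "L": L,
         "feature_idx": feature_idx}
    )

    ref_names = [f"R{i + 1}" for i in range(config.n_ref_replicates)]
    test_names = [f"T{i + 1}" for i in range(config.n_test_samples)]
    pmfs: dict[str, list] = {}
    for name in ref_names + test_names:
        delta = rng.normal(0.0, config.replicate_noise_sd, n_gus)
        fields = a0 + delta
        couplings = b0.copy()
        if name in test_names:
            fields = np.where(planted_gu, fields - config.effect_size, fields)
            couplings = np.where(
                planted_gu, couplings * config.coupling_factor, couplings
            )
        mask = rng.random(n_gus) < config.mask_fraction
        pmfs[name] = _sample_pmfs(L, fields, couplings, mask)

    comparisons: dict[str, pd.DataFrame] = {}
    ref_ref, test_ref = [], []
    for i in range(len(ref_names)):
        for j in range(i + 1, len(ref_names)):
            name = f"{ref_names[i]}_vs_{ref_names[j]}"
            comparisons[name] = _compare(gus, pmfs[ref_names[i]],
                                         pmfs[ref_names[j]])
            ref_ref.append(name)
    for i, tname in enumerate(test_names):
        rname = ref_names[i % len(ref_names)]
        name = f"{tname}_vs_{rname}"
        comparisons[name] = _compare(gus, pmfs[tname], pmfs[rname])
        test_ref.append(name)

    return SyntheticCohort(
        config=config,
        gus=gus,
        features=features,
        sample_names=ref_names + test_names,
        ref_names=ref_names,
        test_names=test_names,
        pmfs=pmfs,
        comparisons=comparisons,
        ref_ref_names=ref_ref,
        test_ref_names=test_ref,
    )


ParamFun = Union[float, Callable[[np.ndarray], np.ndarray]]


def _eval_surface(surface: Mapping[str, ParamFun], s: np.ndarray):
    vals = {}
    for name in ("mu", "sigma", "nu", "tau"):
        if name not in surface:
            raise ValueError(f"surface is missing parameter {name!r}")
        f = surface[name]
        vals[name] = (
            np.broadcast_to(np.asarray(f(s), dtype=float), s.shape)
            if callable(f)
            else np.full(s.shape, float(f))
        )
    # validity check at the extremes and a midpoint
    for i in (0, s.size // 2, s.size - 1):
        LogitSSTParams(
            vals["mu"][i], vals["sigma"][i], vals["nu"][i], vals["tau"][i]
        )
    return vals["mu"], vals["sigma"], vals["nu"], vals["tau"]


def simulate_null_observations(
    surface: Mapping[str, ParamFun],
    n: int,
    s_range: tuple[float, float],
    seed: int = 0,
) -> list[SizedObservation]:
    """Draw (t, s) pairs: s ~ Uniform(s_range), t ~ logitSST(params(s)).

    ``surface`` maps 'mu', 'sigma', 'nu', 'tau' to constants or callables
    of s.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be positive")
    lo, hi = map(float, s_range)
    if not lo <= hi:
        raise ValueError("invalid s_range")
    rng = np.random.default_rng(seed)
    s = rng.uniform(lo, hi, n)
    mu, sigma, nu, tau = _eval_surface(surface, s)
    u = rng.uniform(1e-12, 1 - 1e-12, n)
    t = logitsst_ppf(u, mu, sigma, nu, tau)
    return [SizedObservation(float(ti), float(si)) for ti, si in zip(t, s)]
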