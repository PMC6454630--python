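"""End-to-end orchestration: fit null -> score -> combine -> rank.

``run_pipeline`` consumes a :class:`~methrank.io.RunConfig`, reads JSD
tracks for reference/reference and test/reference comparisons plus a
feature source (BED of custom features, or gene models from which
promoters and bodies are derived), fits the size-dependent null model
from the reference/reference observations (or loads a pre-fitted one),
scores every feature in every test/reference comparison, assembles ranked
lists (PR/GB/PB for gene models, a single list for custom features;
multiple comparisons are Fisher-combined), writes TSV outputs plus a
diagnostics report, and returns a summary of all counts.  On any stage
failure, files already written by this run are removed.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import features as feat
from . import io as mio
from .combine import EmpiricalNull, assemble_ranking, fisher_pb
from .features import GUIndex
from .null_model import (
    FitConfig,
    NullModel,
    centile_coverage,
    fit_null_model,
    null_pvalues,
    quantile_residuals,
)

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger("methrank")


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


def _score_with_counts(
    feature_list, index: GUIndex, model: NullModel, k_min: int, overlap: str
) -> tuple[pd.DataFrame, dict[str, int]]:
    rows, n_unscored, n_filtered = [], 0, 0
    for f in feature_list:
        jsds = index.query(f, overlap)
        K = len(jsds)
        if K == 0:
            n_unscored += 1
        elif K < k_min:
            n_filtered += 1
        else:
            t = float(np.sqrt(np.mean(np.asarray(jsds) ** 2)))
            rows.append((f.feature_id, K, math.log2(K), t))
    df = pd.DataFrame(rows, columns=["feature_id", "K", "s", "t"])
    df["p"] = (
        null_pvalues(df["t"].to_numpy(), df["s"].to_numpy(), model)
        if len(df)
        else np.empty(0)
    )
    counts = {
        "input": len(feature_list),
        "scored": len(df),
        "unscored_no_data": n_unscored,
        "filtered_below_k_min": n_filtered,
    }
    return df, counts


def _fit_kind(
    kind: str,
    feature_list,
    ref_indexes: dict[str, GUIndex],
    k_min: int,
    overlap: str,
    fit_config: FitConfig,
) -> tuple[NullModel, pd.DataFrame]:
    frames = []
    for name, index in ref_indexes.items():
        df = feat.collect_t_observations(feature_list, index, k_min, overlap)
        df["comparison"] = name
        frames.append(df)
    obs = pd.concat(frames, ignore_index=True)
    logger.info("null fit [%s]: %d observations from %d ref/ref comparisons",
                kind, len(obs), len(ref_indexes))
    if len(obs) == 0:
        raise ValueError("no reference/reference observations available")
    model = fit_null_model(obs[["t", "s"]], fit_config)
    return model, obs


def run_pipeline(
    config: mio.RunConfig, fit_config: Optional[FitConfig] = None
) -> dict:
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    logger.info("run seed=%d mode=%s", config.seed, config.mode)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    fit_config = fit_config or FitConfig()

    def _emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    stage = "load-inputs"
    try:
        # -- feature source ------------------------------------------------
        kinds: dict[str, list] = {}
        if config.gene_models:
            genes = mio.read_gene_models(config.gene_models)
            kinds["promoter"] = [
                feat.derive_promoter(g, config.half_width) for g in genes
            ]
            kinds["gene_body"] = [
                b
                for g in genes
                if not (b := feat.derive_gene_body(g, config.half_width)).is_empty
            ]
        elif config.features_bed:
            kinds["custom"] = mio.read_bed(config.features_bed)
        else:
            raise ValueError("config provides neither gene_models nor features_bed")

        # -- tracks --------------------------------------------------------
        stage = "load-tracks"
        ref_indexes = {
            name: GUIndex(mio.read_track(path))
            for name, path in config.ref_ref_tracks.items()
        }
        test_indexes = {
            name: GUIndex(mio.read_track(path))
            for name, path in config.test_ref_tracks.items()
        }
        if not test_indexes:
            raise ValueError("no test/reference tracks configured")

        # -- null models ---------------------------------------------------
        stage = "fit-null"
        models: dict[str, NullModel] = {}
        null_obs: dict[str, pd.DataFrame] = {}
        for kind, flist in kinds.items():
            k_min = config.k_min.get(kind, 1)
            if config.null_model:
                models[kind] = mio.load_null_model(config.null_model)
                null_obs[kind] = pd.DataFrame(columns=["feature_id", "t", "s"])
            else:
                if not ref_indexes:
                    raise ValueError(
                        "no reference/reference input: cannot fit the null model"
                    )
                models[kind], null_obs[kind] = _fit_kind(
                    kind, flist, ref_indexes, k_min, config.overlap, fit_config
                )
            _emit(f"null_model_{kind}.json",
                  lambda p, m=models[kind]: mio.save_null_model(m, p))

        # -- scoring -------------------------------------------------------
        stage = "score"
        scores: dict[str, dict[str, pd.DataFrame]] = {k: {} for k in kinds}
        counts: dict[str, dict[str, dict[str, int]]] = {k: {} for k in kinds}
        for kind, flist in kinds.items():
            k_min = config.k_min.get(kind, 1)
            for name, index in test_indexes.items():
                df, c = _score_with_counts(
                    flist, index, models[kind], k_min, config.overlap
                )
                scores[kind][name] = df
                counts[kind][name] = c
                logger.info(
                    "score [%s] %s: %d input = %d scored + %d no-data + "
                    "%d below k_min", kind, name, c["input"], c["scored"],
                    c["unscored_no_data"], c["filtered_below_k_min"],
                )
                _emit(
                    f"scores_{kind}_{name}.tsv",
                    lambda p, d=df: d.to_csv(p, sep="\t", index=False,
                                             float_format="%.10g"),
                )

        # -- combine & rank ------------------------------------------------
        stage = "combine"
        rankings: dict[str, pd.DataFrame] = {}
        if "custom" in kinds:
            rankings["ranked"] = assemble_ranking(scores["custom"], "custom")
        else:
            rankings["pr"] = assemble_ranking(scores["promoter"], "promoter")
            rankings["gb"] = assemble_ranking(scores["gene_body"], "gene_body")
            # empirical null of T_pb pooled over features and ref/ref pairs
            tpb_values = []
            for name, index in ref_indexes.items():
                dfp, _ = _score_with_counts(
                    kinds["promoter"], index, models["promoter"],
                    config.k_min.get("promoter", 1), config.overlap,
                )
                dfb, _ = _score_with_counts(
                    kinds["gene_body"], index, models["gene_body"],
                    config.k_min.get("gene_body", 1), config.overlap,
                )
                merged = dfp.merge(dfb, on="feature_id", suffixes=("_p", "_b"))
                tpb_values.extend(
                    fisher_pb(max(pp, 1e-300), max(pb, 1e-300))
                    for pp, pb in zip(merged["p_p"], merged["p_b"])
                )
            emp_null = EmpiricalNull(np.asarray(tpb_values))
            pb_inputs = {}
            for name in test_indexes:
                merged = scores["promoter"][name].merge(
                    scores["gene_body"][name], on="feature_id",
                    suffixes=("_p", "_b"),
                )
                pb_inputs[name] = pd.DataFrame(
                    {
                        "feature_id": merged["feature_id"],
                        "p_promoter": merged["p_p"],
                        "p_body": merged["p_b"],
                    }
                )
            rankings["pb"] = assemble_ranking(pb_inputs, "pb", emp_null)
        for lname, table in rankings.items():
            _emit(
                f"ranked_{lname}.tsv",
                lambda p, d=table: d.to_csv(p, sep="\t", float_format="%.10g"),
            )

        # -- diagnostics ---------------------------------------------------
        stage = "diagnose"
        diagnostics = {}
        for kind, obs in null_obs.items():
            if len(obs) == 0:
                continue
            res = quantile_residuals(obs[["t", "s"]], models[kind])
            diagnostics[kind] = {
                "n_null_obs": int(len(obs)),
                "quantile_residuals": {
                    "mean": float(np.mean(res)),
                    "sd": float(np.std(res)),
                },
                "centile_coverage": {
                    str(a): centile_coverage(a, obs[["t", "s"]], models[kind])
                    for a in (5, 25, 50, 75, 95)
                },
                "edf": models[kind].edf,
                "converged": models[kind].converged,
            }
        summary = {
            "seed": config.seed,
            "counts": counts,
            "rankings": {k: len(v) for k, v in rankings.items()},
            "diagnostics": diagnostics,
            "outputs": [str(p) for p in written],
        }
        _emit(
            "diagnostics.json",
            lambda p: p.write_text(json.dumps(summary, indent=1) + "\n"),
        )
        return summary
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
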