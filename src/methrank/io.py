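"""Readers and writers for the text formats the pipeline speaks.

All genomic coordinates are 0-based half-open, matching BED and bedGraph
native conventions.  Formats:

* BED3/BED6 — genomic features (name = feature_id, strand honored);
* bedGraph — per-GU tracks (chrom, start, end, value), e.g. JSD tracks;
* gene-model TSV — header gene_id, chrom, start, end, strand;
* PMF TSV — chrom, start, end, L, then L+1 probability columns (ragged);
* (t, s) observation TSV — header t, s;
* null-model JSON — a versioned serialization of a fitted NullModel;
* YAML run configuration.

Malformed lines raise :class:`ParseError` naming the file and line number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .discordance import GUComparison
from .features import GeneModel, GenomicFeature
from .ising import MethylationPMF
from .null_model import NullModel

__all__ = [
    "ParseError",
    "RunConfig",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_track",
    "write_track",
    "read_pmf_table",
    "write_pmf_table",
    "read_observations",
    "write_observations",
    "load_null_model",
    "save_null_model",
    "write_cohort",
]


class ParseError(ValueError):
    """A malformed input line, reported with file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _int_coord(path, lineno, token, what):
    try:
        value = int(token)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {what}: {token!r}") from None
    if value < 0:
        raise ParseError(path, lineno, f"negative {what}: {value}")
    return value


# ---------------------------------------------------------------------------
# BED features
# ---------------------------------------------------------------------------


def read_bed(path) -> list[GenomicFeature]:
    """Read BED3/BED6 features; name defaults to 'chrom:start-end'."""
    feats = []
    for lineno, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(path, lineno, "BED needs at least 3 columns")
        chrom = parts[0]
        start = _int_coord(path, lineno, parts[1], "start")
        end = _int_coord(path, lineno, parts[2], "end")
        if start >= end:
            raise ParseError(path, lineno, f"start >= end ({start} >= {end})")
        name = parts[3] if len(parts) > 3 and parts[3] != "." else (
            f"{chrom}:{start}-{end}"
        )
        strand = parts[5] if len(parts) > 5 else "."
        feats.append(GenomicFeature(name, chrom, start, end, "custom", strand))
    return feats


def write_bed(features: Sequence[GenomicFeature], path, scores=None) -> None:
    with open(path, "w") as fh:
        for i, f in enumerate(features):
            score = 0 if scores is None else scores[i]
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t{score}\t"
                f"{f.strand}\n"
            )


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

_GENE_COLS = ["gene_id", "chrom", "start", "end", "strand"]


def read_gene_models(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _GENE_COLS if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing gene-model columns: {missing}")
    genes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            genes.append(
                GeneModel(
                    row.gene_id, row.chrom, int(row.start), int(row.end),
                    row.strand,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(path, i, str(exc)) from None
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------


def read_track(
    path, value_range: Optional[tuple[float, float]] = (0.0, 1.0)
) -> list[GUComparison]:
    """Read a 4-column bedGraph into GU comparison records.

    GUs must be non-overlapping within each chromosome; the 4th column is
    range-checked (default [0, 1], the JSD range; pass None to disable).
    """
    rows = []
    for lineno, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 4:
            raise ParseError(path, lineno, "bedGraph needs 4 columns")
        chrom = parts[0]
        start = _int_coord(path, lineno, parts[1], "start")
        end = _int_coord(path, lineno, parts[2], "end")
        if start >= end:
            raise ParseError(path, lineno, f"start >= end ({start} >= {end})")
        try:
            value = float(parts[3])
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric value: {parts[3]!r}")
        if value_range is not None and not (
            value_range[0] <= value <= value_range[1]
        ):
            raise ParseError(
                path, lineno,
                f"value {value} outside [{value_range[0]}, {value_range[1]}]",
            )
        rows.append((chrom, start, end, value, lineno))

    last_end: dict[str, int] = {}
    for chrom, start, end, _value, lineno in sorted(
        rows, key=lambda r: (r[0], r[1])
    ):
        if chrom in last_end and start < last_end[chrom]:
            raise ParseError(path, lineno, f"overlapping GUs on {chrom}")
        last_end[chrom] = end
    return [GUComparison(c, s, e, v) for c, s, e, v, _ in rows]


def write_track(records, path) -> None:
    """Write GU comparison records (or a DataFrame) as a 4-column bedGraph."""
    if isinstance(records, pd.DataFrame):
        it = records[["chrom", "start", "end", "jsd"]].itertuples(index=False)
        rows = [(r[0], int(r[1]), int(r[2]), float(r[3])) for r in it]
    else:
        rows = [(r.chrom, r.start, r.end, r.jsd) for r in records]
    with open(path, "w") as fh:
        for chrom, start, end, value in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.10g}\n")


# ---------------------------------------------------------------------------
# PMF tables
# ---------------------------------------------------------------------------


def read_pmf_table(path) -> list[tuple[str, int, int, MethylationPMF]]:
    """Read a PMF TSV: chrom, start, end, L, then L+1 probability columns."""
    out = []
    for lineno, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 5:
            raise ParseError(path, lineno, "PMF table needs >= 5 columns")
        chrom = parts[0]
        start = _int_coord(path, lineno, parts[1], "start")
        end = _int_coord(path, lineno, parts[2], "end")
        L = _int_coord(path, lineno, parts[3], "L")
        if len(parts) != 4 + L + 1:
            raise ParseError(
                path, lineno,
                f"expected {L + 1} probability columns, found {len(parts) - 4}",
            )
        try:
            probs = np.array([float(x) for x in parts[4:]])
        except ValueError:
            raise ParseError(path, lineno, "non-numeric probability")
        try:
            pmf = MethylationPMF(L, probs)
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
        out.append((chrom, start, end, pmf))
    return out


def write_pmf_table(records, path) -> None:
    """Write (chrom, start, end, MethylationPMF) rows as a ragged TSV."""
    with open(path, "w") as fh:
        for chrom, start, end, pmf in records:
            probs = "\t".join(f"{p:.10g}" for p in pmf.probs)
            fh.write(f"{chrom}\t{start}\t{end}\t{pmf.cpg_count}\t{probs}\n")


# ---------------------------------------------------------------------------
# (t, s) observations, null model, config
# ---------------------------------------------------------------------------


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"t", "s"} <= set(df.columns):
        raise ParseError(path, 1, "observation TSV needs columns t and s")
    return df


def write_observations(obs, path) -> None:
    if isinstance(obs, pd.DataFrame):
        df = obs
    else:
        df = pd.DataFrame(
            {"t": [o.t for o in obs], "s": [o.s for o in obs]}
        )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def save_null_model(model: NullModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
        fh.write("\n")


def load_null_model(path) -> NullModel:
    with open(path) as fh:
        return NullModel.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML-loadable)."""

    output_dir: str = "methrank_out"
    mode: str = "custom"  # promoter | gene_body | pb | multi | custom
    ref_ref_tracks: dict[str, str] = dc_field(default_factory=dict)
    test_ref_tracks: dict[str, str] = dc_field(default_factory=dict)
    features_bed: Optional[str] = None
    gene_models: Optional[str] = None
    null_model: Optional[str] = None  # pre-fitted model; else fit from refs
    gu_width: int = 150
    half_width: int = 2000
    k_min: dict = dc_field(
        default_factory=lambda: {"promoter": 10, "gene_body": 10, "custom": 5}
    )
    overlap: str = "any"
    seed: int = 1
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.k_min.values()):
            raise ValueError("k_min values must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_min" in data:
            base = cls().k_min
            base.update(data["k_min"])
            data["k_min"] = base
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            k: getattr(self, k) for k in self.__dataclass_fields__
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# cohort export
# ---------------------------------------------------------------------------


def write_cohort(cohort, outdir) -> dict[str, object]:
    """Write a synthetic cohort to disk in the dialects the pipeline reads.

    Emits per-sample PMF tables and MML/NME bedGraphs, per-comparison JSD
    bedGraphs, and a BED6 of features whose score column is the truth label
    (1 = planted discordance).  Returns the manifest of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "pmf_tables": {}, "jsd_tracks": {}, "mml_tracks": {}, "nme_tracks": {},
    }

    gus = cohort.gus
    for name in cohort.sample_names:
        pmfs = cohort.pmfs[name]
        rows = []
        for i in range(len(gus)):
            if pmfs[i] is None:
                continue
            rows.append(
                (
                    gus["chrom"].iat[i],
                    int(gus["start"].iat[i]),
                    int(gus["end"].iat[i]),
                    MethylationPMF(int(gus["L"].iat[i]), pmfs[i]),
                )
            )
        p = outdir / f"pmf_{name}.tsv"
        write_pmf_table(rows, p)
        manifest["pmf_tables"][name] = str(p)

    for cname, df in cohort.comparisons.items():
        p = outdir / f"jsd_{cname}.bedGraph"
        write_track(df, p)
        manifest["jsd_tracks"][cname] = str(p)
        for col, key in (("mml_test", "mml_tracks"), ("nme_test", "nme_tracks")):
            q = outdir / f"{col.split('_')[0]}_{cname}.bedGraph"
            sub = df[["chrom", "start", "end", col]].rename(
                columns={col: "jsd"}
            )
            write_track(sub, q)
            manifest[key][cname] = str(q)

    feats = [
        GenomicFeature(r.feature_id, r.chrom, int(r.start), int(r.end), "custom")
        for r in cohort.features.itertuples(index=False)
    ]
    bed = outdir / "features.bed"
    write_bed(feats, bed, scores=cohort.features["planted"].astype(int).tolist())
    manifest["features_bed"] = str(bed)
    return manifest
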