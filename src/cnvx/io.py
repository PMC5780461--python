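"""Readers and writers for the plain-text formats the pipeline speaks.

All genomic coordinates are 0-based, half-open (BED convention); readers
accept ``one_based=True`` to convert inclusive 1-based starts on the fly.
Malformed lines raise with a ``file:line`` location, and ``start < end`` is
enforced on read. Reading back a written file reproduces the in-memory
object (round-trip identity on the canonical form).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .expr_assoc import CountMatrix

CALL_COLUMNS = ["sample", "chrom", "start", "end", "cn", "source"]


class FormatError(ValueError):
    pass


def _check_coords(df: pd.DataFrame, path) -> None:
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise FormatError(f"{path}:{bad[0] + 2}: start >= end")


def read_calls(path, one_based: bool = False) -> pd.DataFrame:
    """CNV calls TSV: sample, chrom, start, end, cn, source [, quality, q0]."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}:1: missing column(s) {missing}")
    if one_based:
        df["start"] = df["start"] - 1
    for col in ("quality", "q0"):
        if col not in df.columns:
            df[col] = float("nan")
    try:
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        df["cn"] = df["cn"].astype(int)
    except (ValueError, TypeError) as e:
        raise FormatError(f"{path}: non-integer coordinate or CN ({e})") from e
    _check_coords(df, path)
    return df


def write_calls(df: pd.DataFrame, path) -> None:
    cols = CALL_COLUMNS + [c for c in ("quality", "q0") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def read_regions_bed(path, one_based: bool = False) -> pd.DataFrame:
    """Regions BED: chrom, start, end, region_id (no header)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "region_id"])
    if df["region_id"].isna().any():
        raise FormatError(f"{path}: BED requires 4 columns (chrom,start,end,name)")
    if one_based:
        df["start"] = df["start"] - 1
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    _check_coords(df, path)
    return df[["region_id", "chrom", "start", "end"]]


def write_regions_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "region_id"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_counts(path) -> CountMatrix:
    """Gene x sample count TSV; first column = gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty count table")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative count")
    return CountMatrix.from_frame(df.astype(int))


def write_counts(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_gebvs(path) -> pd.DataFrame:
    """Sample x trait GEBV TSV; first column = sample id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gebvs(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_gene_annotation(path, one_based: bool = False) -> pd.DataFrame:
    """Gene annotation TSV: gene_id, chrom, start, end, strand."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    need = ["gene_id", "chrom", "start", "end", "strand"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}:1: missing column(s) {missing}")
    if one_based:
        df["start"] = df["start"] - 1
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise FormatError(f"{path}:{df.index[bad][0] + 2}: strand must be + or -")
    _check_coords(df, path)
    return df[need]


def write_gene_annotation(df: pd.DataFrame, path) -> None:
    df[["gene_id", "chrom", "start", "end", "strand"]].to_csv(path, sep="\t", index=False)


def read_feature_bed(path, one_based: bool = False) -> pd.DataFrame:
    """Feature BED: chrom, start, end, label [, weight] (no header)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] == 4:
        df.columns = ["chrom", "start", "end", "label"]
        df["weight"] = 1.0
    elif df.shape[1] >= 5:
        df = df.iloc[:, :5]
        df.columns = ["chrom", "start", "end", "label", "weight"]
    else:
        raise FormatError(f"{path}: feature BED needs >= 4 columns")
    if one_based:
        df["start"] = df["start"] - 1
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["weight"] = df["weight"].astype(float)
    _check_coords(df, path)
    if (df["label"].astype(str).str.len() == 0).any():
        raise FormatError(f"{path}: empty feature label")
    return df


def write_feature_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "label", "weight"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{i}: GMT line needs >= 3 fields")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_chrom_sizes(path) -> dict[str, int]:
    """chrom-sizes TSV: chrom <tab> length."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{i}: expected 'chrom\\tlength'")
            try:
                out[parts[0]] = int(parts[1])
            except ValueError as e:
                raise FormatError(f"{path}:{i}: bad length {parts[1]!r}") from e
    return out


def write_chrom_sizes(genome: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")


def write_bedgraph(track, state: int, path) -> None:
    """One pileup state as bedGraph (chrom, binstart, binend, count)."""
    edges = track.bin_edges()
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.cohort}_state{state}"\n')
        vec = track.counts[state]
        for i, (s, e) in enumerate(zip(edges[:-1], edges[1:])):
            fh.write(f"{track.chrom}\t{int(s)}\t{int(e)}\t{int(vec.iloc[i])}\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
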