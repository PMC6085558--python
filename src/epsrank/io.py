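"""Reading and writing external artifacts.

Supported formats:

* count matrix -- TSV, genes as rows, header row of sample ids;
* per-sample `htseq-count` output -- two tab-separated columns
  (gene_id, count), special counters prefixed ``__`` dropped on load;
* sample metadata -- TSV with columns sample_id, condition,
  survival_time, event;
* gene rankings -- TSV with columns rank, gene_id, score, method.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GeneRanking, SampleMetadata

HTSEQ_SPECIAL_PREFIX = "__"


def read_counts_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(list(df.index), [str(c) for c in df.columns], df.to_numpy())


def write_counts_tsv(matrix: ExpressionMatrix, path) -> None:
    df = matrix.to_frame()
    if not matrix.normalized:
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_htseq_dir(directory) -> ExpressionMatrix:
    """Assemble a count matrix from a directory of htseq-count files.

    The sample id is the file name without extension.  Rows whose gene id
    starts with ``__`` (e.g. __no_feature, __ambiguous) are dropped.  All
    files must report the identical gene set.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"no HTSeq count files found in {directory}")
    gene_ids: list[str] | None = None
    columns = []
    sample_ids = []
    for p in files:
        df = pd.read_csv(p, sep="\t", header=None, names=["gene_id", "count"])
        df["gene_id"] = df["gene_id"].astype(str)
        df = df[~df["gene_id"].str.startswith(HTSEQ_SPECIAL_PREFIX)]
        genes = list(df["gene_id"])
        if gene_ids is None:
            gene_ids = genes
        elif genes != gene_ids:
            raise ValueError(
                f"HTSeq file {p.name} has a gene set inconsistent with {files[0].name}"
            )
        columns.append(df["count"].to_numpy())
        sample_ids.append(p.stem)
    assert gene_ids is not None
    return ExpressionMatrix(gene_ids, sample_ids, np.column_stack(columns))


def read_metadata_tsv(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_metadata_tsv(metadata: SampleMetadata, path) -> None:
    metadata.table.to_csv(path, sep="\t", index_label="sample_id")


def load_dataset(counts_source, metadata_path) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Load counts (TSV file or HTSeq directory) plus metadata, and check
    that the two agree on the sample set."""
    if os.path.isdir(counts_source):
        matrix = read_htseq_dir(counts_source)
    else:
        matrix = read_counts_tsv(counts_source)
    metadata = read_metadata_tsv(metadata_path)
    missing = [s for s in matrix.sample_ids if s not in metadata.table.index]
    if missing:
        raise ValueError(
            f"samples present in counts but absent from metadata: {missing[:5]}"
        )
    metadata = metadata.subset(matrix.sample_ids)
    return matrix, metadata


def write_ranking_tsv(ranking: GeneRanking, path) -> None:
    df = ranking.to_frame()
    df["score"] = [("" if np.isnan(s) else f"{s:.12g}") for s in df["score"]]
    df.to_csv(path, sep="\t", index=False)


def read_ranking_tsv(path) -> GeneRanking:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"rank", "gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"ranking file must have columns {sorted(required)}")
    df = df.sort_values("rank")
    ranks = df["rank"].to_numpy()
    if not np.array_equal(ranks, np.arange(1, len(df) + 1)):
        raise ValueError("ranking file has non-contiguous ranks (expected 1..G)")
    if "score" in df.columns:
        scores = pd.to_numeric(df["score"], errors="coerce").to_numpy(dtype=float)
    else:
        scores = np.full(len(df), np.nan)
    method = "imported"
    if "method" in df.columns and df["method"].notna().all():
        methods = set(df["method"])
        if len(methods) == 1:
            method = methods.pop()
    return GeneRanking(method, list(df["gene_id"]), scores)
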