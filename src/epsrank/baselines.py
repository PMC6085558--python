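"""Comparator gene rankings: fold change, univariate test, imports.

The univariate ranking is a Welch t-test on transformed expression with
Benjamini-Hochberg adjustment; it plays the role of a differential
expression ranking when no external DE tool output is supplied.  Only
training samples are ever consulted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import (
    CASE,
    CONTROL,
    ExpressionMatrix,
    FeatureMatrix,
    GeneRanking,
    SampleMetadata,
    SplitSpec,
)

FC_PSEUDOCOUNT = 0.5


def _training_classes(
    labels: SampleMetadata, split: SplitSpec
) -> tuple[list[str], list[str]]:
    train = set(split.training_ids)
    cases = [s for s in labels.case_ids if s in train]
    controls = [s for s in labels.control_ids if s in train]
    return cases, controls


def rank_by_fold_change(
    matrix: ExpressionMatrix, labels: SampleMetadata, split: SplitSpec
) -> GeneRanking:
    """Rank genes by |log2 fold change| of training class means.

    A pseudocount of 0.5 guards against zero class means.  Ties are broken
    lexicographically by gene id.
    """
    if not matrix.normalized:
        raise ValueError("fold-change ranking expects a normalized matrix")
    cases, controls = _training_classes(labels, split)
    mean_case = matrix.values[:, matrix.sample_index(cases)].mean(axis=1)
    mean_control = matrix.values[:, matrix.sample_index(controls)].mean(axis=1)
    score = np.abs(
        np.log2((mean_case + FC_PSEUDOCOUNT) / (mean_control + FC_PSEUDOCOUNT))
    )
    df = pd.DataFrame({"gene_id": matrix.gene_ids, "score": score})
    df = df.sort_values(["score", "gene_id"], ascending=[False, True])
    return GeneRanking("FC", list(df["gene_id"]), df["score"].to_numpy())


def rank_by_univariate_test(
    features: FeatureMatrix, labels: SampleMetadata, split: SplitSpec
) -> GeneRanking:
    """Per-gene Welch t-test on transformed expression, BH-adjusted.

    Ranking ascends in adjusted p, ties broken by raw p then gene id;
    genes constant across the training samples are assigned p = 1.  The
    reported score is -log10(adjusted p).
    """
    cases, controls = _training_classes(labels, split)
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("each training class needs at least 2 samples")
    xc = features.rows(cases)
    xn = features.rows(controls)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance genes yield nan
        _, pvals = stats.ttest_ind(xc, xn, axis=0, equal_var=False)
    constant = np.vstack([xc, xn]).std(axis=0) == 0
    pvals = np.where(constant | ~np.isfinite(pvals), 1.0, pvals)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    df = pd.DataFrame({"gene_id": features.gene_ids, "p": pvals, "padj": padj})
    df = df.sort_values(["padj", "p", "gene_id"])
    score = -np.log10(np.clip(df["padj"].to_numpy(), 1e-300, None))
    return GeneRanking("DE", list(df["gene_id"]), score)


def import_external_ranking(
    path, gene_universe: list[str] | None = None
) -> GeneRanking:
    """Load an externally produced DE ranking (TSV).

    The file must carry ``gene_id`` plus either ``rank`` or an adjusted
    p-value column (``padj``/``p_adj``/``adjusted_p``).  Genes outside
    ``gene_universe`` (when given) are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ValueError("external ranking needs a gene_id column")
    pcol = next((c for c in ("padj", "p_adj", "adjusted_p") if c in df.columns), None)
    if pcol is None and "rank" not in df.columns:
        raise ValueError("external ranking needs a rank or adjusted-p column")

    if gene_universe is not None:
        known = set(gene_universe)
        unknown = [g for g in df["gene_id"] if g not in known]
        if unknown:
            warnings.warn(
                f"dropping {len(unknown)} genes absent from the study matrix: "
                f"{unknown[:5]}",
                stacklevel=2,
            )
            df = df[df["gene_id"].isin(known)]
    if pcol is not None:
        df = df.sort_values([pcol, "gene_id"])
        scores = df[pcol].to_numpy(dtype=float)
    else:
        df = df.sort_values("rank")
        scores = np.full(len(df), np.nan)
    return GeneRanking("imported", list(df["gene_id"]), scores)
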