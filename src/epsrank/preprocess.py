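"""Normalization, feature transformation and the train/validation split.

Size factors follow the median-of-ratios scheme: each sample's factor is
the median, over genes with a strictly positive geometric mean across
samples, of that sample's count divided by the gene's geometric mean.
The split is the balanced design used throughout the pipeline: *all*
control (healthy) samples plus an equal number of randomly chosen case
samples form the training set; the remaining cases form a cases-only
validation set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, FeatureMatrix, SampleMetadata, SplitSpec

TRANSFORMS = ("log2p1", "log2p1_zscore")


def estimate_size_factors(matrix: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (one positive real per sample)."""
    if matrix.normalized:
        raise ValueError("size factors are estimated on raw counts")
    counts = matrix.values
    with np.errstate(divide="ignore"):
        log_geomean = np.mean(np.log(counts), axis=1)  # -inf if any zero
    reference = np.isfinite(log_geomean)
    if not reference.any():
        raise ValueError(
            "no gene has strictly positive counts in every sample; "
            "prefilter all-zero/sparse genes before normalization"
        )
    ratios = np.log(counts[reference]) - log_geomean[reference, None]
    log_factors = np.median(ratios, axis=0)
    # rescale to geometric mean 1: only relative depth is identifiable,
    # and this removes the global Jensen bias of the geometric-mean
    # pseudo-reference, so normalizing is idempotent up to that scale
    factors = np.exp(log_factors - log_factors.mean())
    return pd.Series(factors, index=matrix.sample_ids, name="size_factor")


def normalize(matrix: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    """Divide each sample's counts by its size factor."""
    missing = [s for s in matrix.sample_ids if s not in factors.index]
    if missing:
        raise ValueError(f"size factor missing for samples: {missing[:5]}")
    f = factors.reindex(matrix.sample_ids).to_numpy(dtype=float)
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        raise ValueError("size factors must be positive and finite")
    return ExpressionMatrix(
        list(matrix.gene_ids),
        list(matrix.sample_ids),
        matrix.values / f[None, :],
        normalized=True,
    )


def make_split(metadata: SampleMetadata, seed: int) -> SplitSpec:
    """All n controls + n seeded-random cases train; the N - n other cases
    validate."""
    controls = metadata.control_ids
    cases = metadata.case_ids
    if len(controls) == 0:
        raise ValueError("need at least one control sample")
    if len(cases) <= len(controls):
        raise ValueError(
            f"need more cases ({len(cases)}) than controls ({len(controls)}); "
            "the validation set would be empty"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(cases), size=len(controls), replace=False)
    chosen_set = set(chosen.tolist())
    training = list(controls) + [cases[i] for i in sorted(chosen_set)]
    validation = [c for i, c in enumerate(cases) if i not in chosen_set]
    return SplitSpec(training_ids=training, validation_ids=validation, seed=seed)


def transform_features(
    matrix: ExpressionMatrix,
    split: SplitSpec,
    transform: str = "log2p1_zscore",
) -> FeatureMatrix:
    """log2(x+1), optionally z-scored per gene with training-set statistics.

    Centering/scale constants are computed on the training samples only and
    reused for validation samples, so no validation information leaks into
    the representation.  Genes constant on the training set get scale 1 and
    therefore map to 0 under z-scoring.  Gene columns are ordered
    lexicographically so downstream rankings do not depend on the on-disk
    gene order.
    """
    if not matrix.normalized:
        raise ValueError("transform_features expects a normalized matrix")
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    order = np.argsort(np.asarray(matrix.gene_ids, dtype=object))
    gene_ids = [matrix.gene_ids[i] for i in order]
    sample_ids = list(split.training_ids) + list(split.validation_ids)
    values = np.log2(matrix.values[order][:, matrix.sample_index(sample_ids)].T + 1.0)

    n_train = len(split.training_ids)
    if transform == "log2p1_zscore":
        train = values[:n_train]
        constant = train.max(axis=0) == train.min(axis=0)
        center = np.where(constant, train[0], train.mean(axis=0))
        scale = np.where(constant, 1.0, train.std(axis=0))
        values = (values - center[None, :]) / scale[None, :]
    else:
        center = np.zeros(len(gene_ids))
        scale = np.ones(len(gene_ids))
    return FeatureMatrix(
        sample_ids=sample_ids,
        gene_ids=gene_ids,
        values=values,
        transform=transform,
        center=center,
        scale=scale,
    )


def inverse_transform(features: FeatureMatrix) -> np.ndarray:
    """Map feature values back to the normalized-expression scale."""
    v = features.values * features.scale[None, :] + features.center[None, :]
    return np.exp2(v) - 1.0
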