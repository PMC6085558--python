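"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`ExpressionMatrix`, a genes x samples count
matrix with identifier bookkeeping and a ``normalized`` flag.  Sample-level
annotations (case/control label, survival time, event indicator) live in
:class:`SampleMetadata`, and every gene-selection method returns a
:class:`GeneRanking` -- an ordered gene list with per-gene scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"

RANKING_METHODS = ("RF", "EPS", "DE", "FC", "imported")


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    Raw matrices hold non-negative integers (read counts); normalized
    matrices hold non-negative reals (counts divided by size factors).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite and non-negative")
        if not self.normalized and not np.array_equal(self.values, np.round(self.values)):
            bad = np.argwhere(self.values != np.round(self.values))[0]
            raise ValueError(
                "raw counts must be integers; found non-integer value for gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not present in matrix") from None

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = self.sample_index(sample_ids)
        return ExpressionMatrix(
            list(self.gene_ids), [self.sample_ids[i] for i in idx],
            self.values[:, idx], normalized=self.normalized,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleMetadata:
    """Per-sample condition label plus optional survival annotations.

    Stored as a DataFrame indexed by sample_id with columns ``condition``
    ({case, control}), ``survival_time`` (days, NaN when unknown) and
    ``event`` (1 = death observed, 0 = censored, NaN when unknown).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        if "sample_id" in t.columns:
            t = t.set_index("sample_id")
        t.index = t.index.astype(str)
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValueError(f"duplicate sample_id in metadata: {dup!r}")
        if "condition" not in t.columns:
            raise ValueError("metadata requires a 'condition' column")
        bad = set(t["condition"]) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"condition must be 'case' or 'control', got {sorted(bad)}")
        for col in ("survival_time", "event"):
            if col not in t.columns:
                t[col] = np.nan
            t[col] = pd.to_numeric(t[col], errors="raise")
        has_time = t["survival_time"].notna()
        if (has_time & t["event"].isna()).any():
            s = t.index[has_time & t["event"].isna()][0]
            raise ValueError(f"sample {s!r} has survival_time but no event flag")
        if (t.loc[has_time, "survival_time"] < 0).any():
            raise ValueError("survival_time must be non-negative")
        ev = t["event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValueError("event must be 0 or 1")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def condition(self) -> pd.Series:
        return self.table["condition"]

    def ids_of(self, condition: str) -> list[str]:
        return list(self.table.index[self.table["condition"] == condition])

    @property
    def case_ids(self) -> list[str]:
        return self.ids_of(CASE)

    @property
    def control_ids(self) -> list[str]:
        return self.ids_of(CONTROL)

    def with_survival(self) -> pd.DataFrame:
        """Rows with complete (time, event) survival information."""
        t = self.table
        return t[t["survival_time"].notna() & t["event"].notna()]

    def subset(self, sample_ids) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples absent from metadata: {missing[:5]}")
        return SampleMetadata(self.table.loc[list(sample_ids)].copy())


@dataclass
class GeneRanking:
    """Ordered gene list produced by one ranking method.

    Rank i (1-based) is the position in ``gene_ids``; ``scores`` may be NaN
    for imported rankings that carry no score column.
    """

    method: str
    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.method not in RANKING_METHODS:
            raise ValueError(f"unknown ranking method {self.method!r}")
        self.gene_ids = [str(g) for g in self.gene_ids]
        _check_unique(self.gene_ids, "gene")
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.gene_ids),):
            raise ValueError("scores must align with gene_ids")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def top(self, k: int) -> list[str]:
        return self.gene_ids[:k]

    def rank_of(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "gene_id": self.gene_ids,
                "score": self.scores,
                "method": self.method,
            }
        )


@dataclass
class SplitSpec:
    """Balanced training set (all controls + as many cases) and a
    cases-only validation set."""

    training_ids: list[str]
    validation_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.training_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"training/validation overlap: {sorted(overlap)[:5]}")


@dataclass
class FeatureMatrix:
    """Model-input features: samples x genes, transformed expression.

    ``center``/``scale`` hold the per-gene training-set statistics so that
    validation samples are always mapped with training constants.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # shape (n_samples, n_genes)
    transform: str  # "log2p1" or "log2p1_zscore"
    center: np.ndarray = field(default=None)  # type: ignore[assignment]
    scale: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("feature values must be samples x genes")
        if self.transform not in ("log2p1", "log2p1_zscore"):
            raise ValueError(f"unknown transform {self.transform!r}")

    def rows(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return self.values[idx]
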