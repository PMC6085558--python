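"""Survival-signature benchmark and stability/subsample experiments.

Each ranking method yields nested signatures sig_i = {top i genes},
i = 1..20 by default.  A signature is evaluated on the cases-only
validation cohort: a Cox proportional-hazards model with the signature
genes' standardized log expression as covariates provides a risk score,
the cohort is split at the median score, and a two-group log-rank test
compares the survival of the halves.  Methods are then compared by
counting, over the signature-size grid, how often one method's log-rank
p-value is strictly smaller than another's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test

from .data import ExpressionMatrix, GeneRanking, SampleMetadata, SplitSpec

DEFAULT_I_MAX = 20
COX_L2 = 1e-4


@dataclass
class SignatureFamily:
    """Nested top-i prefixes of one ranking."""

    method: str
    signatures: list[list[str]]  # signatures[i-1] has i genes

    def __post_init__(self) -> None:
        for i, sig in enumerate(self.signatures, start=1):
            if len(sig) != i or sig[: i - 1] != (self.signatures[i - 2] if i > 1 else []):
                raise ValueError("signatures must be nested prefixes of sizes 1..i_max")

    @property
    def i_max(self) -> int:
        return len(self.signatures)


@dataclass
class LogRankResult:
    method: str
    size: int
    statistic: float
    p_value: float
    n_high: int
    n_low: int
    converged: bool = True


@dataclass
class ComparisonTable:
    """Pairwise strict-win counts over the signature-size grid."""

    i_max: int
    pairs: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"method_a": a, "method_b": b, **counts}
            for (a, b), counts in self.pairs.items()
        ]
        return pd.DataFrame(rows)


def build_signatures(ranking: GeneRanking, i_max: int = DEFAULT_I_MAX) -> SignatureFamily:
    if i_max > len(ranking):
        raise ValueError(f"i_max={i_max} exceeds the {len(ranking)}-gene ranking")
    return SignatureFamily(
        ranking.method, [ranking.top(i) for i in range(1, i_max + 1)]
    )


def _validation_survival(
    matrix: ExpressionMatrix, metadata: SampleMetadata, split: SplitSpec
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    surv = metadata.with_survival()
    ids = [s for s in split.validation_ids if s in surv.index]
    return matrix.subset_samples(ids), surv.loc[ids]


def evaluate_signature(
    signature: list[str],
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    split: SplitSpec,
    method: str = "",
) -> LogRankResult:
    """Cox risk score, median split, two-group log-rank on the validation
    cohort.

    Scores equal to the median go to the high-risk group.  A Cox fit that
    fails to converge yields a flagged result with missing p, excluded
    from comparisons.
    """
    if not matrix.normalized:
        raise ValueError("evaluate_signature expects a normalized matrix")
    vmat, vsurv = _validation_survival(matrix, metadata, split)
    if len(vsurv) < 4:
        raise ValueError("need >= 4 validation samples with complete survival")

    gene_pos = {g: i for i, g in enumerate(vmat.gene_ids)}
    try:
        rows = [gene_pos[g] for g in signature]
    except KeyError as exc:
        raise KeyError(f"signature gene {exc.args[0]!r} absent from matrix") from None
    expr = np.log2(vmat.values[rows] + 1.0)
    # standardize within the evaluation cohort; constant genes carry nothing
    sd = expr.std(axis=1)
    sd[sd == 0] = 1.0
    expr = (expr - expr.mean(axis=1, keepdims=True)) / sd[:, None]

    df = pd.DataFrame(
        expr.T, columns=[f"g{i}" for i in range(len(signature))], index=vsurv.index
    )
    df["duration"] = vsurv["survival_time"]
    df["event"] = vsurv["event"]
    size = len(signature)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter(penalizer=COX_L2, l1_ratio=0.0)
            cph.fit(df, duration_col="duration", event_col="event")
        score = cph.predict_log_partial_hazard(df)
    except Exception as exc:  # lifelines convergence failures
        warnings.warn(f"Cox fit failed for {method} signature of size {size}: {exc}",
                      stacklevel=2)
        return LogRankResult(method, size, np.nan, np.nan, 0, 0, converged=False)

    high = score >= score.median()
    n_high, n_low = int(high.sum()), int((~high).sum())
    if min(n_high, n_low) < 2:
        warnings.warn(
            f"degenerate median split for {method} signature of size {size}",
            stacklevel=2,
        )
        return LogRankResult(method, size, np.nan, np.nan, n_high, n_low, converged=False)
    res = logrank_test(
        df.loc[high, "duration"],
        df.loc[~high, "duration"],
        event_observed_A=df.loc[high, "event"],
        event_observed_B=df.loc[~high, "event"],
    )
    return LogRankResult(
        method, size, float(res.test_statistic), float(res.p_value), n_high, n_low
    )


def evaluate_family(
    family: SignatureFamily,
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    split: SplitSpec,
) -> list[LogRankResult]:
    return [
        evaluate_signature(sig, matrix, metadata, split, method=family.method)
        for sig in family.signatures
    ]


def compare_methods(results: dict[str, list[LogRankResult]]) -> ComparisonTable:
    """Strict-inequality win counts for every ordered method pair.

    Signature sizes where either p-value is missing (failed fit) are
    excluded and reported in ``skipped``.
    """
    grids = {m: [r.size for r in rs] for m, rs in results.items()}
    grid = next(iter(grids.values()))
    if any(g != grid for g in grids.values()):
        raise ValueError(f"signature-size grids differ between methods: {grids}")
    table = ComparisonTable(i_max=len(grid))
    for a, ra in results.items():
        for b, rb in results.items():
            if a == b:
                continue
            wins = ties = skipped = 0
            for x, y in zip(ra, rb):
                if np.isnan(x.p_value) or np.isnan(y.p_value):
                    skipped += 1
                elif x.p_value < y.p_value:
                    wins += 1
                elif x.p_value == y.p_value:
                    ties += 1
            table.pairs[(a, b)] = {"wins": wins, "ties": ties, "skipped": skipped}
    return table


@dataclass
class StabilityReport:
    top_sets: list[set[str]]
    mean_pairwise_overlap: float
    rank_stats: pd.DataFrame  # per gene: mean_rank, sd_rank

    @property
    def n_iterations(self) -> int:
        return len(self.top_sets)


def stability_analysis(
    pipeline: Callable[[int], GeneRanking],
    n_iter: int = 10,
    k: int = 20,
    seeds: list[int] | None = None,
) -> StabilityReport:
    """Re-run a seeded ranking procedure and measure top-k agreement.

    Reports the mean pairwise |top-k intersection| over all iteration
    pairs and the per-gene mean/SD of rank across iterations.
    """
    if n_iter < 2:
        raise ValueError("stability analysis needs n_iter >= 2")
    if seeds is None:
        seeds = list(range(n_iter))
    if len(seeds) != n_iter:
        raise ValueError("need one seed per iteration")
    rankings = [pipeline(s) for s in seeds]
    top_sets = [set(r.top(k)) for r in rankings]
    overlaps = [
        len(top_sets[i] & top_sets[j])
        for i in range(n_iter)
        for j in range(i + 1, n_iter)
    ]
    ranks = pd.DataFrame(
        {
            f"iter{i}": pd.Series(
                np.arange(1, len(r) + 1), index=r.gene_ids, dtype=float
            )
            for i, r in enumerate(rankings)
        }
    )
    stats = pd.DataFrame(
        {"mean_rank": ranks.mean(axis=1), "sd_rank": ranks.std(axis=1, ddof=0)}
    )
    return StabilityReport(top_sets, float(np.mean(overlaps)), stats)


def subsample_ids(
    metadata: SampleMetadata,
    fraction: float = 0.2,
    min_controls: int = 20,
    seed: int = 0,
) -> list[str]:
    """Class-stratified subsample of ceil(fraction * N) samples, with the
    control share topped up to ``min_controls`` when stratification would
    fall below it."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    cases = metadata.case_ids
    controls = metadata.control_ids
    total = int(np.ceil(fraction * (len(cases) + len(controls))))
    n_ctrl = int(round(fraction * len(controls)))
    if n_ctrl < min_controls:
        n_ctrl = min_controls
    n_case = total - n_ctrl
    if n_ctrl > len(controls) or n_case > len(cases) or n_case <= n_ctrl:
        raise ValueError(
            f"infeasible subsample: {n_case} cases / {n_ctrl} controls requested "
            f"from {len(cases)} cases / {len(controls)} controls"
        )
    rng = np.random.default_rng(seed)
    pick_case = sorted(rng.choice(len(cases), size=n_case, replace=False).tolist())
    pick_ctrl = sorted(rng.choice(len(controls), size=n_ctrl, replace=False).tolist())
    return [cases[i] for i in pick_case] + [controls[i] for i in pick_ctrl]


def subsample_experiment(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    fraction: float = 0.2,
    min_controls: int = 20,
    seed: int = 0,
    **config_overrides,
):
    """Run the full method comparison on a stratified subsample."""
    from .workflow import RunConfig, full_comparison

    ids = subsample_ids(metadata, fraction, min_controls, seed)
    sub_matrix = matrix.subset_samples(ids)
    sub_meta = metadata.subset(ids)
    config = RunConfig(**config_overrides)
    return full_comparison(sub_matrix, sub_meta, config)
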