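"""One-command orchestration of the full per-dataset methodology.

normalize -> balanced split -> rankings (DE stand-in or imported, RF,
EPS, optionally FC) -> nested signatures -> Cox / median-split /
log-rank evaluation -> pairwise comparison.  Every stage consumes its own
explicit seed so one stage can be re-randomized without disturbing the
others (the stability experiment relies on this), and a manifest with
checksums makes reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .baselines import import_external_ranking, rank_by_fold_change, rank_by_univariate_test
from .data import ExpressionMatrix, GeneRanking, SampleMetadata, SplitSpec
from .eps import eps_ranking
from .evaluation import (
    ComparisonTable,
    LogRankResult,
    build_signatures,
    compare_methods,
    evaluate_family,
)
from .io import load_dataset, write_counts_tsv, write_metadata_tsv, write_ranking_tsv
from .preprocess import estimate_size_factors, make_split, normalize, transform_features
from .rf import ForestConfig, rank_by_random_forest
from .synthetic import simulate_dataset, simulate_survival
from .vae import VAEArchitecture

logger = logging.getLogger("epsrank")


@dataclass
class Seeds:
    split: int = 0
    rf: int = 1
    vae: int = 2
    sampling: int = 3
    survival: int = 4

    @classmethod
    def from_base(cls, base: int) -> "Seeds":
        s = np.random.SeedSequence(base).generate_state(5) % (2**31 - 1)
        return cls(*[int(x) for x in s])


@dataclass
class RunConfig:
    """Everything one run needs; serializable to/from YAML."""

    counts: str | None = None
    metadata: str | None = None
    simulate: dict | None = None  # kwargs of simulate_dataset (+ survival keys)
    de_ranking: str | None = None  # externally computed DE ranking TSV
    methods: tuple[str, ...] = ("DE", "RF", "EPS")
    i_max: int = 20
    n_pseudo: int = 400
    q: float = 0.1
    epochs: int = 300
    kl_weight: float = 0.2
    learning_rate: float = 2e-3
    rf_preset: str = "desk"
    vae_preset: str = "desk"
    transform: str = "log2p1_zscore"
    fraction: float = 0.2
    seeds: Seeds = field(default_factory=Seeds)

    def __post_init__(self) -> None:
        if isinstance(self.seeds, dict):
            self.seeds = Seeds(**self.seeds)
        self.methods = tuple(self.methods)
        unknown = set(self.methods) - {"DE", "RF", "EPS", "FC"}
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class FullComparisonResult:
    split: SplitSpec
    rankings: dict[str, GeneRanking]
    logrank: dict[str, list[LogRankResult]]
    table: ComparisonTable

    @property
    def n_logrank_tests(self) -> int:
        return sum(len(v) for v in self.logrank.values())

    def logrank_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "method": r.method,
                    "size": r.size,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "n_high": r.n_high,
                    "n_low": r.n_low,
                    "converged": r.converged,
                }
                for rs in self.logrank.values()
                for r in rs
            ]
        )


def _stage(name: str, t0: float, **info) -> None:
    detail = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0, detail)


def compute_rankings(
    matrix_norm: ExpressionMatrix,
    metadata: SampleMetadata,
    split: SplitSpec,
    config: RunConfig,
) -> dict[str, GeneRanking]:
    """All requested rankings from one normalized matrix and split."""
    features = transform_features(matrix_norm, split, config.transform)
    rankings: dict[str, GeneRanking] = {}
    for method in config.methods:
        t0 = time.time()
        if method == "FC":
            rankings[method] = rank_by_fold_change(matrix_norm, metadata, split)
        elif method == "DE":
            if config.de_ranking:
                rankings[method] = import_external_ranking(
                    config.de_ranking, gene_universe=matrix_norm.gene_ids
                )
            else:
                rankings[method] = rank_by_univariate_test(features, metadata, split)
        elif method == "RF":
            fc = (
                ForestConfig.paper(seed=config.seeds.rf)
                if config.rf_preset == "paper"
                else ForestConfig.desk(seed=config.seeds.rf)
            )
            rankings[method], _ = rank_by_random_forest(features, metadata, split, fc)
        elif method == "EPS":
            arch = (
                VAEArchitecture.paper()
                if config.vae_preset == "paper"
                else VAEArchitecture.desk(len(features.gene_ids))
            )
            result = eps_ranking(
                features,
                metadata,
                split,
                arch=arch,
                epochs=config.epochs,
                kl_weight=config.kl_weight,
                quantile_q=config.q,
                n_per_class=config.n_pseudo,
                seed=config.seeds.vae,
                learning_rate=config.learning_rate,
            )
            rankings[method] = result.ranking
        _stage(f"rank-{method}", t0, genes=len(rankings[method]))
    return rankings


def full_comparison(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    config: RunConfig | None = None,
) -> FullComparisonResult:
    """Run the complete methodology in memory on a raw count matrix."""
    if config is None:
        config = RunConfig()
    t0 = time.time()
    factors = estimate_size_factors(matrix)
    matrix_norm = normalize(matrix, factors)
    _stage("normalize", t0, samples=matrix.n_samples, genes=matrix.n_genes)
    split = make_split(metadata, seed=config.seeds.split)
    rankings = compute_rankings(matrix_norm, metadata, split, config)
    t0 = time.time()
    logrank = {
        m: evaluate_family(
            build_signatures(r, config.i_max), matrix_norm, metadata, split
        )
        for m, r in rankings.items()
    }
    table = compare_methods(logrank)
    _stage("evaluate", t0, tests=sum(len(v) for v in logrank.values()))
    return FullComparisonResult(split, rankings, logrank, table)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_comparison(config: RunConfig, out_dir) -> Path:
    """Execute the methodology and write all artifacts plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        sim = dict(config.simulate)
        survival_kwargs = {
            k: sim.pop(k) for k in ("baseline_hazard", "censor_rate") if k in sim
        }
        matrix, metadata, truth = simulate_dataset(**sim)
        factors = estimate_size_factors(matrix)
        metadata = simulate_survival(
            normalize(matrix, factors),
            truth,
            seed=config.seeds.survival,
            metadata=metadata,
            **survival_kwargs,
        )
        truth.to_json(out / "truth.json")
        write_counts_tsv(matrix, out / "counts.tsv")
        write_metadata_tsv(metadata, out / "metadata.tsv")
    elif config.counts and config.metadata:
        matrix, metadata = load_dataset(config.counts, config.metadata)
    else:
        raise ValueError("config must provide counts+metadata paths or simulate block")

    result = full_comparison(matrix, metadata, config)

    for method, ranking in result.rankings.items():
        write_ranking_tsv(ranking, out / f"ranking_{method}.tsv")
    result.logrank_frame().to_csv(out / "logrank.tsv", sep="\t", index=False)
    with open(out / "comparison.json", "w") as fh:
        json.dump(
            {
                f"{a}_vs_{b}": counts
                for (a, b), counts in result.table.pairs.items()
            },
            fh,
            indent=2,
        )
    with open(out / "split.json", "w") as fh:
        json.dump(
            {
                "training_ids": result.split.training_ids,
                "validation_ids": result.split.validation_ids,
                "seed": result.split.seed,
            },
            fh,
            indent=2,
        )
    config.to_yaml(out / "config.yaml")

    files = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "epsrank_version": __version__,
        "config_hash": config.config_hash(),
        "seeds": asdict(config.seeds),
        "n_logrank_tests": result.n_logrank_tests,
        "files": {p.name: _sha256(p) for p in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
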