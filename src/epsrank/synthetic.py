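"""Case-control RNA-Seq count simulator with known planted truth.

Counts are negative binomial (variance mu + dispersion * mu^2) with
gene-level baseline means spanning several orders of magnitude and
per-sample size factors drawn log-uniformly from [0.5, 2].  A chosen subset
of *signal* genes has its case-class mean shifted by a stated log2
fold-change; optional gene blocks share a latent Gaussian factor on the log
scale, emulating co-expressed modules.  Survival times follow an
exponential proportional-hazards model whose linear predictor is a linear
combination of standardized signal-gene expression, so the power of
downstream survival analyses is analytically predictable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CASE, CONTROL, ExpressionMatrix, SampleMetadata

#: log-scale SD of the shared block factor (co-expression strength).
BLOCK_SIGMA = 0.3
#: genes per correlated block.
BLOCK_SIZE = 10


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`simulate_dataset`."""

    signal_genes: list[str]
    log2fc: pd.Series  # per gene; nonzero exactly on signal genes
    blocks: list[list[str]]
    survival_beta: pd.Series  # per gene; nonzero only on signal genes
    size_factors: pd.Series  # per sample, the planted depth factors
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "signal_genes": self.signal_genes,
            "log2fc": {g: v for g, v in self.log2fc.items() if v != 0},
            "blocks": self.blocks,
            "survival_beta": {g: v for g, v in self.survival_beta.items() if v != 0},
            "size_factors": self.size_factors.to_dict(),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with variance mean + dispersion * mean^2 (Poisson when dispersion=0)."""
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_dataset(
    n_genes: int = 2000,
    n_case: int = 150,
    n_control: int = 50,
    n_signal: int = 10,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.1,
    n_blocks: int = 0,
    block_rho: float = 0.5,
    seed: int = 0,
    survival_beta: float = 0.5,
) -> tuple[ExpressionMatrix, SampleMetadata, SyntheticTruth]:
    """Simulate a raw count matrix with planted class signal.

    ``survival_beta`` is assigned to the first half (rounded up) of the
    signal genes; :func:`simulate_survival` consumes it.  The generator is
    a pure function of its arguments and seed.
    """
    if n_genes <= 0 or n_case <= 0 or n_control <= 0:
        raise ValueError("n_genes, n_case and n_control must be positive")
    if n_signal < 0 or n_signal > n_genes:
        raise ValueError("need 0 <= n_signal <= n_genes")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if not (0 <= block_rho < 1):
        raise ValueError("block_rho must lie in [0, 1)")
    if n_blocks < 0 or n_blocks * BLOCK_SIZE > n_genes - n_signal:
        raise ValueError("too many blocks for the gene universe")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    sample_ids = [f"case_{i:03d}" for i in range(n_case)] + [
        f"control_{i:03d}" for i in range(n_control)
    ]
    is_case = np.array([1] * n_case + [0] * n_control, dtype=bool)
    n_samples = n_case + n_control

    # baseline means span ~4 orders of magnitude
    base_mean = 10.0 ** rng.uniform(0.0, 4.0, size=n_genes)
    log_sf = rng.uniform(np.log(0.5), np.log(2.0), size=n_samples)
    # center to geometric mean 1: the depth scale is otherwise
    # unidentifiable, and normalization should recover these exactly
    size_factors = np.exp(log_sf - log_sf.mean())

    signal_idx = rng.choice(n_genes, size=n_signal, replace=False)
    log2fc = np.zeros(n_genes)
    log2fc[signal_idx] = effect_log2fc

    # disjoint co-expression blocks drawn from the non-signal genes
    other = np.setdiff1d(np.arange(n_genes), signal_idx)
    block_members = rng.choice(other, size=n_blocks * BLOCK_SIZE, replace=False)
    blocks = [
        sorted(block_members[b * BLOCK_SIZE : (b + 1) * BLOCK_SIZE].tolist())
        for b in range(n_blocks)
    ]

    mu = base_mean[:, None] * (2.0 ** (log2fc[:, None] * is_case[None, :]))
    if n_blocks:
        factor = rng.standard_normal((n_blocks, n_samples))
        noise = rng.standard_normal((n_blocks * BLOCK_SIZE, n_samples))
        for b, members in enumerate(blocks):
            own = noise[b * BLOCK_SIZE : (b + 1) * BLOCK_SIZE]
            latent = np.sqrt(block_rho) * factor[b][None, :] + np.sqrt(1 - block_rho) * own
            mu[members] = mu[members] * np.exp(
                BLOCK_SIGMA * latent - 0.5 * BLOCK_SIGMA**2
            )
    mu = mu * size_factors[None, :]

    counts = _nb_draw(rng, mu, dispersion)
    matrix = ExpressionMatrix(gene_ids, sample_ids, counts.astype(np.int64))

    condition = np.where(is_case, CASE, CONTROL)
    metadata = SampleMetadata(
        pd.DataFrame({"sample_id": sample_ids, "condition": condition})
    )

    beta = np.zeros(n_genes)
    signal_sorted = sorted(signal_idx.tolist())
    n_surv = (n_signal + 1) // 2
    beta[signal_sorted[:n_surv]] = survival_beta
    truth = SyntheticTruth(
        signal_genes=[gene_ids[i] for i in signal_sorted],
        log2fc=pd.Series(log2fc, index=gene_ids),
        blocks=[[gene_ids[i] for i in m] for m in blocks],
        survival_beta=pd.Series(beta, index=gene_ids),
        size_factors=pd.Series(size_factors, index=sample_ids),
        seed=seed,
    )
    return matrix, metadata, truth


def _censor_scale(times: np.ndarray, censor_rate: float) -> float:
    """Upper bound m of a Uniform(0, m) censor achieving the target rate.

    For C ~ U(0, m) the expected censored fraction is
    mean(min(T_i, m)) / m, which decreases monotonically in m; solve by
    bisection on the realized event times.
    """
    lo, hi = 1e-9, float(times.max()) * 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        frac = float(np.mean(np.minimum(times, mid)) / mid)
        if frac > censor_rate:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def simulate_survival(
    matrix: ExpressionMatrix,
    truth: SyntheticTruth,
    baseline_hazard: float = 1e-3,
    censor_rate: float = 0.3,
    seed: int = 0,
    metadata: SampleMetadata | None = None,
) -> SampleMetadata:
    """Attach exponential proportional-hazards survival to every sample.

    The linear predictor is sum_g beta_g * z_g with z the per-gene
    standardized log2(x+1) of the normalized expression.  Censoring is
    independent Uniform(0, m) with m tuned so the realized censored
    fraction approximates ``censor_rate``; ``censor_rate=0`` disables it.
    """
    if not matrix.normalized:
        raise ValueError("simulate_survival expects a normalized matrix")
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    beta = truth.survival_beta.reindex(matrix.gene_ids).fillna(0.0).to_numpy()
    logx = np.log2(matrix.values + 1.0)
    sd = logx.std(axis=1)
    sd[sd == 0] = 1.0
    z = (logx - logx.mean(axis=1, keepdims=True)) / sd[:, None]
    lp = beta @ z  # per sample

    rate = baseline_hazard * np.exp(lp)
    times = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        m = _censor_scale(times, censor_rate)
        censor = rng.uniform(0.0, m, size=times.shape)
        event = (times <= censor).astype(int)
        observed = np.minimum(times, censor)
    else:
        event = np.ones(times.shape, dtype=int)
        observed = times

    if metadata is not None:
        table = metadata.subset(matrix.sample_ids).table.copy()
        condition = table["condition"].to_numpy()
    else:
        condition = np.array(
            [CASE if s.startswith("case") else CONTROL for s in matrix.sample_ids]
        )
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": matrix.sample_ids,
                "condition": condition,
                "survival_time": observed,
                "event": event,
            }
        )
    )
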