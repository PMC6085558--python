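"""Independent brute-force oracles used only by the tests.

These deliberately avoid the implementation's vectorized code paths: the
size-factor oracle loops over genes and samples with explicit ratio
lists, and the log-rank oracle walks the event times one by one.
"""

from __future__ import annotations

import math

import numpy as np


def size_factors_bruteforce(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios per sample, straight from the definition."""
    n_genes, n_samples = counts.shape
    geomeans = []
    for g in range(n_genes):
        logs = [math.log(counts[g, j]) if counts[g, j] > 0 else -math.inf
                for j in range(n_samples)]
        if any(v == -math.inf for v in logs):
            geomeans.append(0.0)
        else:
            geomeans.append(math.exp(sum(logs) / n_samples))
    factors = []
    for j in range(n_samples):
        ratios = sorted(
            counts[g, j] / geomeans[g] for g in range(n_genes) if geomeans[g] > 0
        )
        k = len(ratios)
        if k % 2 == 1:
            med = ratios[k // 2]
        else:
            # ratios are multiplicative quantities: geometric midpoint,
            # as the reference normalization's log-scale median implies
            med = math.sqrt(ratios[k // 2 - 1] * ratios[k // 2])
        factors.append(float(med))
    # report factors relative to their geometric mean
    log_f = [math.log(f) for f in factors]
    shift = math.exp(sum(log_f) / len(log_f))
    return np.array([f / shift for f in factors])


def logrank_bruteforce(
    time_a, event_a, time_b, event_b
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) via the O-E / hypergeometric
    variance sums at each distinct event time."""
    from scipy.stats import chi2

    times = sorted(
        {t for t, e in zip(list(time_a) + list(time_b), list(event_a) + list(event_b)) if e}
    )
    obs_a = exp_a = var = 0.0
    for t in times:
        n_a = sum(1 for x in time_a if x >= t)
        n_b = sum(1 for x in time_b if x >= t)
        d_a = sum(1 for x, e in zip(time_a, event_a) if x == t and e)
        d_b = sum(1 for x, e in zip(time_b, event_b) if x == t and e)
        n = n_a + n_b
        d = d_a + d_b
        if n < 1 or d < 1:
            continue
        obs_a += d_a
        exp_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    stat = (obs_a - exp_a) ** 2 / var
    return stat, float(chi2.sf(stat, 1))
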