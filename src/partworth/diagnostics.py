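"""Gelman-Rubin potential scale reduction factor (PSRF) across chains.

The classic formula from parallel chains of length n:

    W     = mean within-chain variance
    B / n = variance of the chain means
    var+  = ((n - 1) / n) W + B / n
    PSRF  = sqrt(var+ / W)

Values close to 1 indicate the chains have mixed into a common
distribution; < 1.10 is the conventional convergence threshold.  Sampling
noise can push var+ marginally below W, so the reported factor is floored
at 1 (identical chains therefore give exactly 1).  Computed without chain
splitting by default; pass ``split=True`` for the split-chain variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hb import HBPosterior

__all__ = ["psrf", "gelman_rubin", "GelmanRubinReport", "PSRF_THRESHOLD"]

PSRF_THRESHOLD = 1.10


def psrf(chains: np.ndarray, split: bool = False) -> float:
    """PSRF for one scalar parameter from draws shaped (n_chains, n_draws).

    Returns NaN (degenerate) when every chain has zero internal variance.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be (n_chains, n_draws)")
    if chains.shape[0] < 2:
        raise ValueError("need >= 2 chains")
    if chains.shape[1] < 10:
        raise ValueError("need >= 10 draws per chain")
    if split:
        half = chains.shape[1] // 2
        chains = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    n = chains.shape[1]
    w = chains.var(axis=1, ddof=1).mean()
    if w == 0.0:
        return float("nan")
    b_over_n = chains.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * w + b_over_n
    return max(float(np.sqrt(var_plus / w)), 1.0)


@dataclass
class GelmanRubinReport:
    values: dict[str, float]
    degenerate: list[str]
    max_psrf: float
    converged: bool

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def gelman_rubin(
    posterior: HBPosterior,
    include_beta: bool = False,
    split: bool = False,
    threshold: float = PSRF_THRESHOLD,
) -> GelmanRubinReport:
    """PSRF per scalar parameter of an HB posterior.

    Monitors every component of the population mean and the diagonal of the
    population covariance; ``include_beta=True`` adds all individual
    part-worth components (slower, rarely needed).
    """
    series: dict[str, np.ndarray] = {}
    p = posterior.p
    for j in range(p):
        series[f"mu[{j}]"] = posterior.mu[:, :, j]
    for j in range(p):
        series[f"sigma[{j},{j}]"] = posterior.sigma[:, :, j, j]
    if include_beta:
        n = posterior.beta.shape[2]
        for i in range(n):
            for j in range(p):
                series[f"beta[{i},{j}]"] = posterior.beta[:, :, i, j]
    values: dict[str, float] = {}
    degenerate: list[str] = []
    for name, arr in series.items():
        r = psrf(arr, split=split)
        values[name] = r
        if np.isnan(r):
            degenerate.append(name)
    finite = [v for v in values.values() if np.isfinite(v)]
    max_r = max(finite) if finite else float("nan")
    return GelmanRubinReport(
        values=values,
        degenerate=degenerate,
        max_psrf=max_r,
        converged=bool(np.isfinite(max_r) and max_r < threshold),
    )
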