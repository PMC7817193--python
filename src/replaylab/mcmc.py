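"""Small adaptive MCMC engine for the hierarchical models.

Adaptive Metropolis-within-Gibbs: each coordinate keeps its own proposal
scale, adapted during warmup toward ~44% acceptance (Roberts & Rosenthal
style log-scale adaptation).  All chains are updated in lockstep with
vectorized log-posterior evaluations, which keeps pure-numpy sampling fast
enough for the model sizes used here.  Convergence is judged by split-R-hat
and effective sample size, not by the sampler's pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class McmcResult:
    draws: np.ndarray          # (chains, samples, dim)
    accept_rate: np.ndarray    # (dim,)

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])


def sample(
    log_post,
    x0: np.ndarray,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_samples: int = 1000,
    seed: int = 0,
    init_scale: float = 0.5,
    jitter: float = 0.5,
) -> McmcResult:
    """Sample from ``log_post`` (vectorized: (chains, dim) -> (chains,)).

    ``x0`` is a (dim,) starting point; chains start at jittered copies.
    """
    rng = np.random.default_rng(seed)
    x0 = np.asarray(x0, dtype=float)
    dim = x0.size
    x = x0[None, :] + jitter * rng.standard_normal((n_chains, dim))
    lp = log_post(x)
    log_scale = np.full(dim, np.log(init_scale))
    acc = np.zeros(dim)
    n_acc_batch = np.zeros(dim)
    batch = 50
    target = 0.44

    total = n_warmup + n_samples
    draws = np.empty((n_chains, n_samples, dim))
    for it in range(total):
        steps = rng.standard_normal((dim, n_chains)) * np.exp(log_scale)[:, None]
        logu = np.log(rng.random((dim, n_chains)))
        for d in range(dim):
            prop = x.copy()
            prop[:, d] += steps[d]
            lp_prop = log_post(prop)
            ok = logu[d] < (lp_prop - lp)
            x[ok] = prop[ok]
            lp[ok] = lp_prop[ok]
            frac = ok.mean()
            acc[d] += frac
            n_acc_batch[d] += frac
        if it < n_warmup and (it + 1) % batch == 0:
            delta = min(0.25, 2.0 / np.sqrt((it + 1) / batch))
            rate = n_acc_batch / batch
            log_scale += np.where(rate > target, delta, -delta)
            n_acc_batch[:] = 0
        if it >= n_warmup:
            draws[:, it - n_warmup, :] = x
    return McmcResult(draws=draws, accept_rate=acc / total)


def split_rhat(chain_draws: np.ndarray) -> float:
    """Split-R-hat for one scalar parameter, draws shaped (chains, samples)."""
    c, s = chain_draws.shape
    half = s // 2
    if half < 2:
        return np.nan
    segs = np.concatenate(
        [chain_draws[:, :half], chain_draws[:, half:2 * half]], axis=0)
    m, n = segs.shape
    means = segs.mean(axis=1)
    b = n * means.var(ddof=1)
    w = segs.var(axis=1, ddof=1).mean()
    if w <= 0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def ess_bulk(chain_draws: np.ndarray) -> float:
    """Effective sample size via arviz (falls back to n if unavailable)."""
    try:
        import arviz as az

        return float(az.ess(np.asarray(chain_draws)[None].swapaxes(0, 1)
                            if chain_draws.ndim == 1 else chain_draws))
    except Exception:
        return float(chain_draws.size)
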