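"""Hierarchical Bayesian models for event rates and category proportions.

Rates: count ~ Poisson(exposure * rate), log rate = phase effect + rat
random intercept (non-centered, half-Normal(1) scale).  Proportions:
multinomial with softmax link and per-category rat random effects.  Both are
sampled with the in-package adaptive MCMC and gated on split-R-hat / ESS
diagnostics; the reported quantities are posterior draws, means, and 50/95%
credible intervals of derived quantities (percent change vs. the reference
phase, per-category proportions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import mcmc


class StatsError(ValueError):
    pass


@dataclass
class PosteriorSummary:
    draws: dict[str, np.ndarray]          # name -> (chains, samples)
    summary: pd.DataFrame                 # mean, ci50/ci95 bounds, rhat, ess
    converged: bool
    notes: list[str] = field(default_factory=list)

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = (1 - level) / 2
        d = self.flat(name)
        return float(np.quantile(d, a)), float(np.quantile(d, 1 - a))


def _summarize(named_draws: dict[str, np.ndarray], rhat_max: float = 1.05,
               ess_min: float = 100.0) -> tuple[pd.DataFrame, bool, list[str]]:
    rows, notes = [], []
    ok = True
    for name, d in named_draws.items():
        flat = d.reshape(-1)
        rhat = mcmc.split_rhat(d)
        ess = mcmc.ess_bulk(d)
        rows.append({
            "parameter": name,
            "mean": float(flat.mean()),
            "ci50_lo": float(np.quantile(flat, 0.25)),
            "ci50_hi": float(np.quantile(flat, 0.75)),
            "ci95_lo": float(np.quantile(flat, 0.025)),
            "ci95_hi": float(np.quantile(flat, 0.975)),
            "rhat": rhat,
            "ess": ess,
        })
        if np.isfinite(rhat) and rhat > rhat_max:
            ok = False
            notes.append(f"{name}: rhat={rhat:.3f} > {rhat_max}")
        if np.isfinite(ess) and ess < ess_min:
            ok = False
            notes.append(f"{name}: ess={ess:.0f} < {ess_min}")
    return pd.DataFrame(rows), ok, notes


# --------------------------------------------------------------------------
# Poisson rate model
# --------------------------------------------------------------------------

def fit_rate_model(
    data: pd.DataFrame,
    phases: Sequence[str] = ("pre", "learning", "post"),
    reference: str = "pre",
    n_chains: int = 4,
    n_warmup: int = 800,
    n_samples: int = 800,
    seed: int = 0,
    prior_sd: float = 1.5,
    rat_sd_scale: float = 1.0,
) -> PosteriorSummary:
    """Partial-pooling Poisson rate model on (rat, phase) count/exposure data.

    ``data`` needs columns rat, phase, count, exposure_s (rows may be
    per-trial; they are aggregated, which is sufficient for the Poisson
    likelihood).  Derived draws ``pct_change_<phase>`` give
    100*(rate_phase/rate_ref - 1).
    """
    req = {"rat", "phase", "count", "exposure_s"}
    if not req.issubset(data.columns):
        raise StatsError(f"data must have columns {sorted(req)}")
    data = data[data["phase"].isin(phases)]
    agg = data.groupby(["rat", "phase"]).agg(
        count=("count", "sum"), exposure=("exposure_s", "sum")).reset_index()
    if (agg["exposure"] <= 0).any():
        raise StatsError("non-positive exposure")
    rats = sorted(agg["rat"].unique())
    pooled = len(rats) < 2
    if pooled:
        warnings.warn("single rat: model degrades to a fixed-effect fit",
                      stacklevel=2)
    present = [ph for ph in phases if ph in set(agg["phase"])]
    if reference not in present or len(present) < 2:
        raise StatsError("need the reference phase and at least one other")
    R, P = len(rats), len(present)
    C = np.zeros((R, P))
    E = np.zeros((R, P))
    for _, row in agg.iterrows():
        i = rats.index(row["rat"])
        j = present.index(row["phase"])
        C[i, j] = row["count"]
        E[i, j] = row["exposure"]
    logE = np.where(E > 0, np.log(np.maximum(E, 1e-12)), -np.inf)
    obs = E > 0

    # params: beta (P), then (unless pooled) eta (R) and log_sigma
    dim = P if pooled else P + R + 1

    def log_post(x):
        with np.errstate(over="ignore", invalid="ignore"):
            beta = x[:, :P]
            if pooled:
                mu = beta[:, None, :] + logE           # (nc, R, P)
                lp = np.zeros(x.shape[0])
            else:
                eta = x[:, P:P + R]
                sigma = np.exp(x[:, -1])
                u = sigma[:, None] * eta               # (nc, R)
                mu = beta[:, None, :] + u[:, :, None] + logE
                lp = -0.5 * (eta ** 2).sum(axis=1)
                # sigma ~ HalfNormal(rat_sd_scale), sampled on the log scale
                lp += -0.5 * (sigma / rat_sd_scale) ** 2 + x[:, -1]
            ll = np.where(obs, C * mu - np.exp(np.where(obs, mu, 0.0)), 0.0)
            ll = ll.sum(axis=(1, 2))
            lp += (-0.5 * (beta / prior_sd) ** 2).sum(axis=1)
            return np.nan_to_num(ll + lp, nan=-np.inf)

    mean_rate = max(C.sum() / max(E.sum(), 1e-9), 1e-6)
    x0 = np.full(P, np.log(mean_rate))
    if not pooled:
        x0 = np.concatenate([x0, np.zeros(R), [-1.0]])
    res = mcmc.sample(log_post, x0, n_chains=n_chains, n_warmup=n_warmup,
                      n_samples=n_samples, seed=seed, init_scale=0.1,
                      jitter=0.2)
    named = {}
    for j, ph in enumerate(present):
        named[f"log_rate_{ph}"] = res.draws[:, :, j]
    if not pooled:
        named["rat_sd"] = np.exp(res.draws[:, :, -1])
    ref = present.index(reference)
    for j, ph in enumerate(present):
        if ph == reference:
            continue
        named[f"pct_change_{ph}"] = 100.0 * (
            np.exp(res.draws[:, :, j] - res.draws[:, :, ref]) - 1.0)
    summary, ok, notes = _summarize(named)
    if not ok:
        warnings.warn("rate model convergence diagnostics failed: "
                      + "; ".join(notes), stacklevel=2)
    return PosteriorSummary(draws=named, summary=summary, converged=ok,
                            notes=notes)


# --------------------------------------------------------------------------
# proportion model
# --------------------------------------------------------------------------

def fit_proportion_model(
    data: pd.DataFrame,
    categories: Sequence[str],
    windows: Optional[Sequence[str]] = None,
    n_chains: int = 4,
    n_warmup: int = 800,
    n_samples: int = 800,
    seed: int = 0,
    prior_sd: float = 1.5,
    rat_sd_scale: float = 1.0,
) -> PosteriorSummary:
    """Multinomial proportion model with rat random effects.

    ``data``: one row per (rat, window, category) with column ``count``.
    Derived draws ``p_<window>_<category>`` are population-level proportions
    (softmax of the window's category logits); they sum to 1 draw-wise.
    """
    req = {"rat", "window", "category", "count"}
    if not req.issubset(data.columns):
        raise StatsError(f"data must have columns {sorted(req)}")
    cats = list(categories)
    if windows is None:
        windows = sorted(data["window"].unique())
    windows = list(windows)
    rats = sorted(data["rat"].unique())
    R, W, Ccat = len(rats), len(windows), len(cats)
    K = np.zeros((R, W, Ccat))
    for _, row in data.iterrows():
        if row["category"] not in cats or row["window"] not in windows:
            continue
        K[rats.index(row["rat"]), windows.index(row["window"]),
          cats.index(row["category"])] += row["count"]
    tot = K.sum(axis=2)
    dropped = []
    for i in range(R):
        for w in range(W):
            if tot[i, w] == 0:
                dropped.append((rats[i], windows[w]))
    if dropped:
        warnings.warn(f"dropping empty cells: {dropped}", stacklevel=2)

    # params: beta (W, C-1) free logits vs category 0, eta (R, C-1), log_sigma
    nb = W * (Ccat - 1)
    ne = R * (Ccat - 1)
    dim = nb + ne + 1

    def log_post(x):
        nc = x.shape[0]
        beta = x[:, :nb].reshape(nc, W, Ccat - 1)
        eta = x[:, nb:nb + ne].reshape(nc, R, Ccat - 1)
        sigma = np.exp(x[:, -1])
        u = sigma[:, None, None] * eta
        logits = np.zeros((nc, R, W, Ccat))
        logits[:, :, :, 1:] = beta[:, None, :, :] + u[:, :, None, :]
        lse = np.log(np.exp(logits - logits.max(axis=3, keepdims=True))
                     .sum(axis=3)) + logits.max(axis=3, keepdims=True)[..., 0]
        ll = (K[None] * logits).sum(axis=3) - tot[None] * lse
        ll = ll.sum(axis=(1, 2))
        lp = -0.5 * (x[:, :nb] / prior_sd) ** 2
        lp = lp.sum(axis=1) - 0.5 * (x[:, nb:nb + ne] ** 2).sum(axis=1)
        lp += -0.5 * (sigma / rat_sd_scale) ** 2 + x[:, -1]
        return ll + lp

    x0 = np.zeros(dim)
    x0[-1] = -1.0
    res = mcmc.sample(log_post, x0, n_chains=n_chains, n_warmup=n_warmup,
                      n_samples=n_samples, seed=seed, init_scale=0.2,
                      jitter=0.2)
    named = {}
    nc, ns = res.draws.shape[:2]
    beta = res.draws[:, :, :nb].reshape(nc, ns, W, Ccat - 1)
    logits = np.zeros((nc, ns, W, Ccat))
    logits[..., 1:] = beta
    p = np.exp(logits - logits.max(axis=3, keepdims=True))
    p /= p.sum(axis=3, keepdims=True)
    for w, win in enumerate(windows):
        for c, cat in enumerate(cats):
            named[f"p_{win}_{cat}"] = p[:, :, w, c]
    named["rat_sd"] = np.exp(res.draws[:, :, -1])
    summary, ok, notes = _summarize(named)
    if not ok:
        warnings.warn("proportion model convergence diagnostics failed: "
                      + "; ".join(notes), stacklevel=2)
    return PosteriorSummary(draws=named, summary=summary, converged=ok,
                            notes=notes)


# --------------------------------------------------------------------------
# overlap
# --------------------------------------------------------------------------

def posterior_overlap(draws_a: np.ndarray, draws_b: np.ndarray,
                      n_bins: int = 256) -> float:
    """Integral of min(density_a, density_b) on a shared histogram grid.

    The grid spans the pooled 0.1-99.9 percentile range.  Degenerate
    (constant) draw sets are compared directly.
    """
    a = np.asarray(draws_a, dtype=float).reshape(-1)
    b = np.asarray(draws_b, dtype=float).reshape(-1)
    if a.size < 1 or b.size < 1:
        raise StatsError("empty draw sets")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if np.isclose(a[0], b[0]) else 0.0
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        return 1.0
    pooled = np.concatenate([a, b])
    lo, hi = np.percentile(pooled, [0.1, 99.9])
    if hi <= lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    pa = pa / a.size
    pb = pb / b.size
    return float(np.minimum(pa, pb).sum())


def learning_thirds(trials: pd.DataFrame) -> dict[int, int]:
    """Map learning-phase trial -> third (1..3); ties go to the earlier third."""
    lt = trials.loc[trials["phase"] == "learning", "trial"].sort_values().tolist()
    n = len(lt)
    out = {}
    for i, tr in enumerate(lt):
        out[tr] = min(3, 1 + (3 * i) // n) if n else 1
    return out
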