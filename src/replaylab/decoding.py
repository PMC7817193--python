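"""Memoryless Bayesian position decoding from population spike counts.

The decoder is the standard Poisson one: with per-state expected rates
lambda_i(x) taken from linearized rate maps,

    P(x | n) ∝ prior(x) * prod_i lambda_i(x)^n_i * exp(-tau * sum_i lambda_i(x))

computed in log space and normalized per time bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .linearize import linearize_position
from .maze import FIELD_PATHS
from .tuning import (
    RateMap,
    ratemap_from_histograms,
    trial_path_histograms,
)


class DecodingError(ValueError):
    pass


@dataclass
class Encoder:
    """Per-state expected firing rates for a unit population."""

    unit_ids: list[int]
    states: pd.DataFrame            # columns: path, bin, pos_cm
    rates: np.ndarray               # (n_units, n_states), Hz, floored at eps
    eps: float

    @property
    def n_states(self) -> int:
        return len(self.states)

    def path_slice(self, path: str) -> np.ndarray:
        return (self.states["path"] == path).to_numpy()

    def permuted(self, perm: np.ndarray) -> "Encoder":
        """Encoder with tuning curves reassigned across units (identity shuffle)."""
        return Encoder(self.unit_ids, self.states, self.rates[perm], self.eps)


@dataclass
class DecodedPosterior:
    bin_edges: np.ndarray           # (T+1,) seconds
    states: pd.DataFrame
    posterior: np.ndarray           # (T, n_states), rows sum to 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def map_states(self) -> np.ndarray:
        return np.argmax(self.posterior, axis=1)


def fit_encoder(
    maps: dict[tuple[int, str, str], RateMap],
    phases: Sequence[str],
    paths: Sequence[str] = FIELD_PATHS,
    eps: float = 0.01,
) -> Encoder:
    """Build the per-state rate table from rate maps, averaging over ``phases``
    where a unit has maps in more than one. Rates are floored at ``eps`` Hz."""
    units = sorted({uid for uid, _, _ in maps})
    if not units:
        raise DecodingError("no units")
    cols, meta = [], []
    for path in paths:
        sample = next((maps[k] for k in maps if k[1] in phases and k[2] == path), None)
        if sample is None:
            continue
        nbin = len(sample.centers)
        block = np.zeros((len(units), nbin))
        for k, u in enumerate(units):
            acc, cnt = np.zeros(nbin), 0
            for ph in phases:
                rm = maps.get((u, ph, path))
                if rm is not None:
                    acc += np.nan_to_num(rm.rate_hz)
                    cnt += 1
            block[k] = acc / max(cnt, 1)
        cols.append(block)
        for b in range(nbin):
            meta.append({"path": path, "bin": b, "pos_cm": sample.centers[b]})
    if not cols:
        raise DecodingError("no rate maps for requested phases")
    rates = np.maximum(np.concatenate(cols, axis=1), eps)
    return Encoder(unit_ids=units, states=pd.DataFrame(meta), rates=rates, eps=eps)


def bin_spikes(
    spikes: dict[int, np.ndarray],
    unit_ids: Sequence[int],
    t_start: float,
    t_end: float,
    bin_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike-count matrix (T, n_units) on a regular grid."""
    edges = np.arange(t_start, t_end + bin_s * 0.5, bin_s)
    if len(edges) < 2:
        edges = np.array([t_start, t_start + bin_s])
    counts = np.zeros((len(edges) - 1, len(unit_ids)), dtype=int)
    for k, uid in enumerate(unit_ids):
        st = spikes.get(uid, np.empty(0))
        counts[:, k], _ = np.histogram(st, bins=edges)
    return counts, edges


def decode(
    counts: np.ndarray,
    encoder: Encoder,
    bin_s: float,
    bin_edges: Optional[np.ndarray] = None,
    prior: Optional[np.ndarray] = None,
) -> DecodedPosterior:
    """Per-bin posterior over (path, bin) states from spike counts."""
    counts = np.atleast_2d(np.asarray(counts))
    if bin_s <= 0:
        raise DecodingError("bin width must be positive")
    if counts.shape[1] != len(encoder.unit_ids):
        raise DecodingError("counts/units mismatch")
    with np.errstate(divide="ignore"):  # eps=0 encoders carry true zeros
        log_lam = np.log(encoder.rates)           # (U, S)
    log_post = counts @ log_lam - bin_s * encoder.rates.sum(axis=0)
    if prior is not None:
        prior = np.asarray(prior, dtype=float)
        if prior.shape != (encoder.n_states,) or np.any(prior < 0):
            raise DecodingError("bad prior")
        with np.errstate(divide="ignore"):
            log_post = log_post + np.log(prior)
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    if bin_edges is None:
        bin_edges = np.arange(counts.shape[0] + 1) * bin_s
    return DecodedPosterior(
        bin_edges=np.asarray(bin_edges, dtype=float),
        states=encoder.states,
        posterior=np.exp(log_post),
    )


def _map_error(
    post: DecodedPosterior,
    true_path: np.ndarray,
    true_pos: np.ndarray,
    path_lengths: dict[str, float],
) -> np.ndarray:
    """|MAP - true| within the active path; cross-path errors get the
    maximum in-path distance (conservative)."""
    mp = post.map_states()
    dec_path = post.states["path"].to_numpy()[mp]
    dec_pos = post.states["pos_cm"].to_numpy()[mp]
    err = np.empty(len(mp))
    for i in range(len(mp)):
        L = path_lengths.get(true_path[i], np.nan)
        if dec_path[i] == true_path[i]:
            err[i] = abs(dec_pos[i] - true_pos[i])
        else:
            err[i] = L
    return err


def encoder_from_histograms(
    occ: dict,
    cnt: dict,
    edges_by_path: dict,
    unit_ids: Sequence[int],
    train_trials: Sequence[int],
    paths: Sequence[str] = FIELD_PATHS,
    smooth_cm: float = 5.0,
    eps: float = 0.01,
) -> Encoder:
    """Encoder from summed per-trial histograms (fast leave-one-out refits)."""
    from scipy.ndimage import gaussian_filter1d

    cols, meta = [], []
    for path in paths:
        edges = edges_by_path[path]
        nbin = len(edges) - 1
        occ_sum = np.zeros(nbin)
        cnt_sum = np.zeros((len(unit_ids), nbin))
        for tr in train_trials:
            if (tr, path) in occ:
                occ_sum += occ[(tr, path)]
                cnt_sum += cnt[(tr, path)]
        if occ_sum.sum() <= 0:
            continue
        bin_cm = edges[1] - edges[0]
        sigma = smooth_cm / bin_cm
        occ_s = gaussian_filter1d(occ_sum, sigma, mode="constant")
        cnt_s = gaussian_filter1d(cnt_sum, sigma, axis=1, mode="constant")
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(occ_s > 0, cnt_s / occ_s, 0.0)
        cols.append(rate)
        centers = 0.5 * (edges[:-1] + edges[1:])
        for b in range(nbin):
            meta.append({"path": path, "bin": b, "pos_cm": centers[b]})
    if not cols:
        raise DecodingError("no occupancy in training trials")
    rates = np.maximum(np.concatenate(cols, axis=1), eps)
    return Encoder(unit_ids=list(unit_ids), states=pd.DataFrame(meta),
                   rates=rates, eps=eps)


def loo_position_error(
    session,
    bin_s: float = 0.2,
    condition: str = "within",
    speed_threshold: float = 4.0,
    shuffle_units: bool = False,
    seed: int = 0,
    bin_cm: float = 2.0,
    smooth_cm: float = 5.0,
) -> pd.DataFrame:
    """Leave-one-out decoding error per time bin.

    ``condition='within'`` fits the encoder on the held-out trial's own phase;
    ``'pooled'`` fits on all remaining trials of the session.
    ``shuffle_units`` permutes tuning-curve identities (chance control).
    Returns one row per decoded time bin with columns trial, phase, error_cm.
    """
    rng = np.random.default_rng(seed)
    lin = linearize_position(session.position, session.maze)
    speed = session.speed
    path_lengths = {p: session.maze.paths[p].length for p in FIELD_PATHS}
    trials = session.trials
    if (trials.groupby("phase")["trial"].count() < 2).any():
        raise DecodingError("need >= 2 trials per phase for leave-one-out")

    occ, cnt, edges_by_path, unit_ids = trial_path_histograms(
        session, bin_cm=bin_cm, speed_threshold=speed_threshold)
    phase_of = dict(zip(trials["trial"], trials["phase"]))
    t_arr = session.position["t_s"].to_numpy()
    all_trials = trials["trial"].tolist()
    rows = []
    for _, tr in trials.iterrows():
        k, phase = int(tr["trial"]), tr["phase"]
        if condition == "within":
            train = [j for j in all_trials if j != k and phase_of[j] == phase]
        else:
            train = [j for j in all_trials if j != k]
        enc = encoder_from_histograms(
            occ, cnt, edges_by_path, unit_ids, train, smooth_cm=smooth_cm)
        if shuffle_units:
            enc = enc.permuted(rng.permutation(len(enc.unit_ids)))
        counts, edges = bin_spikes(
            session.spikes, enc.unit_ids, tr["t_start"], tr["t_end"], bin_s)
        post = decode(counts, enc, bin_s, bin_edges=edges)
        centers = post.bin_centers
        idx = np.clip(np.searchsorted(t_arr, centers) - 1, 0, len(t_arr) - 1)
        tp = lin["path"].to_numpy()[idx]
        pos = lin["linpos_cm"].to_numpy()[idx]
        ok = (np.asarray([p in path_lengths for p in tp])
              & (speed[idx] > speed_threshold))
        if not ok.any():
            continue
        sub = DecodedPosterior(post.bin_edges, post.states, post.posterior[ok])
        err = _map_error(sub, tp[ok], pos[ok], path_lengths)
        for e in err:
            rows.append({"trial": k, "phase": phase, "error_cm": float(e)})
    return pd.DataFrame(rows)
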