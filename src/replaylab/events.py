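"""Synchronous/SWR event detection, per-event decoding, and replay scoring.

Scoring pipeline per candidate event: fine-bin Bayesian decoding ->
representation rates per path (reprate, repZ) -> posterior-weighted
time-position correlation (r) on the represented path -> shuffle-normalized
sequence score (rZ), sequential/direction labels, trajectory-event flag ->
population-level participation, per-cell contribution, ensemble correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, hilbert, sosfiltfilt

from .decoding import DecodedPosterior, Encoder, bin_spikes, decode
from .maze import FIELD_PATHS


class EventError(ValueError):
    pass


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------

def detect_swr(
    lfp: np.ndarray,
    lfp_rate: float,
    speed_at: np.ndarray,
    position_t: np.ndarray,
    band: tuple[float, float] = (150.0, 250.0),
    z_high: float = 3.0,
    z_low: float = 0.5,
    smooth_s: float = 0.015,
    merge_gap_s: float = 0.05,
    duration_bounds_s: tuple[float, float] = (0.02, 0.5),
    min_high_s: float = 0.025,
    immobility_threshold: float = 4.0,
) -> pd.DataFrame:
    """Ripple-band events: band-pass, Hilbert envelope smoothed and z-scored
    against immobility samples; crossings of ``z_high`` sustained for at
    least ``min_high_s`` are extended to ``z_low`` boundaries, merged and
    duration-filtered.  The sustain requirement keeps the false-positive
    rate on noise below ~1/min."""
    if len(lfp) == 0:
        raise EventError("empty LFP")
    if lfp_rate < 600:
        raise EventError("LFP rate must be >= 600 Hz for the ripple band")
    nyq = lfp_rate / 2
    hi = min(band[1], nyq * 0.95)
    sos = butter(3, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    filt = sosfiltfilt(sos, lfp)
    env = np.abs(hilbert(filt))
    if smooth_s > 0:
        env = gaussian_filter1d(env, smooth_s * lfp_rate)
    t = np.arange(len(lfp)) / lfp_rate
    idx = np.clip(np.searchsorted(position_t, t) - 1, 0, len(position_t) - 1)
    immobile = speed_at[idx] < immobility_threshold
    if not immobile.any():
        raise EventError("no immobility samples for the envelope baseline")
    mu, sd = env[immobile].mean(), env[immobile].std()
    z = (env - mu) / sd

    above = z > z_high
    min_high = int(min_high_s * lfp_rate)
    events = []
    i = 0
    n = len(z)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        if j - i >= min_high:
            a = i
            while a > 0 and z[a - 1] > z_low:
                a -= 1
            b = j - 1
            while b < n - 1 and z[b + 1] > z_low:
                b += 1
            events.append([a, b + 1, i])
        i = j
    merged = []
    for a, b, core in events:
        if merged and (a - merged[-1][1]) / lfp_rate < merge_gap_s:
            merged[-1][1] = b
        else:
            merged.append([a, b, core])
    rows = []
    for a, b, core in merged:
        dur = (b - a) / lfp_rate
        if duration_bounds_s[0] <= dur <= duration_bounds_s[1] and immobile[a:b].mean() > 0.5:
            seg = z[a:b]
            rows.append({
                "t_start": a / lfp_rate, "t_end": b / lfp_rate,
                "t_core": core / lfp_rate,   # first sustained z_high sample
                "duration_s": dur, "peak_z": float(seg.max()),
            })
    return pd.DataFrame(
        rows, columns=["t_start", "t_end", "t_core", "duration_s", "peak_z"])


def detect_synchronous_events(
    spikes: dict[int, np.ndarray],
    speed_at: np.ndarray,
    position_t: np.ndarray,
    swr: Optional[pd.DataFrame] = None,
    step_s: float = 0.01,
    smooth_s: float = 0.015,
    z_threshold: float = 3.0,
    min_unit_fraction: float = 0.1,
    immobility_threshold: float = 4.0,
    duration_bounds_s: tuple[float, float] = (0.05, 0.5),
    require_swr: bool = False,
) -> pd.DataFrame:
    """Population-burst candidates during immobility.

    Multi-unit counts in 10 ms steps are smoothed and z-scored on immobility;
    contiguous runs above ``z_threshold`` with at least ``min_unit_fraction``
    of units firing become candidates, optionally required to overlap an SWR.
    """
    if len(spikes) < 10:
        raise EventError("need >= 10 units for synchronous-event detection")
    t_end = position_t[-1]
    edges = np.arange(0.0, t_end + step_s, step_s)
    all_spikes = np.sort(np.concatenate([st for st in spikes.values()]))
    mua, _ = np.histogram(all_spikes, bins=edges)
    mua = gaussian_filter1d(mua.astype(float), smooth_s / step_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.searchsorted(position_t, centers) - 1, 0, len(position_t) - 1)
    immobile = speed_at[idx] < immobility_threshold
    if not immobile.any():
        raise EventError("no immobility baseline")
    mu, sd = mua[immobile].mean(), mua[immobile].std()
    if sd == 0:
        return pd.DataFrame(columns=["t_start", "t_end", "duration_s", "n_units"])
    z = (mua - mu) / sd

    cand = (z > z_threshold) & immobile
    rows = []
    i = 0
    while i < len(cand):
        if not cand[i]:
            i += 1
            continue
        j = i
        while j < len(cand) and cand[j]:
            j += 1
        a, b = edges[i], edges[j]
        # extend to half-max boundaries within immobility
        while i > 0 and z[i - 1] > 0.5 and immobile[i - 1]:
            i -= 1
            a = edges[i]
        while j < len(z) and z[j] > 0.5 and immobile[min(j, len(immobile) - 1)]:
            j += 1
            b = edges[min(j, len(edges) - 1)]
        dur = b - a
        active = sum(
            1 for st in spikes.values()
            if np.any((st >= a) & (st < b))
        )
        if (duration_bounds_s[0] <= dur <= duration_bounds_s[1]
                and active >= min_unit_fraction * len(spikes)):
            rows.append({"t_start": a, "t_end": b, "duration_s": dur,
                         "n_units": active})
        i = j + 1
    out = pd.DataFrame(rows, columns=["t_start", "t_end", "duration_s", "n_units"])
    # merge overlapping (extension can make neighbours touch)
    if len(out) > 1:
        keep = [dict(out.iloc[0])]
        for _, r in out.iloc[1:].iterrows():
            if r["t_start"] <= keep[-1]["t_end"]:
                keep[-1]["t_end"] = max(keep[-1]["t_end"], r["t_end"])
                keep[-1]["duration_s"] = keep[-1]["t_end"] - keep[-1]["t_start"]
                keep[-1]["n_units"] = max(keep[-1]["n_units"], r["n_units"])
            else:
                keep.append(dict(r))
        out = pd.DataFrame(keep)
    if require_swr and swr is not None and len(out):
        ok = []
        for _, r in out.iterrows():
            ok.append(bool(((swr["t_start"] < r["t_end"])
                            & (swr["t_end"] > r["t_start"])).any()))
        out = out[np.array(ok, dtype=bool)].reset_index(drop=True)
    return out


# --------------------------------------------------------------------------
# per-event scoring
# --------------------------------------------------------------------------

@dataclass
class CandidateEvent:
    t_start: float
    t_end: float
    area: str = ""
    location_cm: float = np.nan
    counts: np.ndarray = None              # (T, n_units) fine-bin counts
    posterior: DecodedPosterior = None
    reprates: dict = field(default_factory=dict)
    repz: dict = field(default_factory=dict)
    represented_path: Optional[str] = None
    r: Optional[float] = None
    rz: Optional[float] = None
    direction: str = "none"
    is_sequential: bool = False
    is_trajectory_event: bool = False
    participating_units: list = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


def decode_event(
    event_start: float,
    event_end: float,
    spikes: dict[int, np.ndarray],
    encoder: Encoder,
    bin_s: float = 0.02,
) -> tuple[np.ndarray, DecodedPosterior]:
    counts, edges = bin_spikes(spikes, encoder.unit_ids, event_start, event_end, bin_s)
    post = decode(counts, encoder, bin_s, bin_edges=edges)
    return counts, post


def reprate(post: DecodedPosterior, paths: Sequence[str] = FIELD_PATHS
            ) -> tuple[dict[str, float], str]:
    """Mean posterior mass per path over event time bins, and the represented
    path (argmax; ties broken by longest contiguous run of per-bin wins, then
    lexicographically)."""
    if post is None or post.posterior.size == 0:
        raise EventError("empty posterior")
    P = post.posterior
    path_arr = post.states["path"].to_numpy()
    rates = {}
    per_bin_mass = {}
    for p in paths:
        sl = path_arr == p
        mass = P[:, sl].sum(axis=1)
        per_bin_mass[p] = mass
        rates[p] = float(mass.mean())
    best = max(rates.values())
    tied = sorted(p for p, v in rates.items() if np.isclose(v, best, atol=1e-12))
    if len(tied) > 1:
        def run_len(p):
            wins = per_bin_mass[p] >= np.maximum.reduce(
                [per_bin_mass[q] for q in paths])
            best_run = cur = 0
            for w in wins:
                cur = cur + 1 if w else 0
                best_run = max(best_run, cur)
            return best_run
        tied.sort(key=lambda p: (-run_len(p), p))
    return rates, tied[0]


def repz(
    counts: np.ndarray,
    encoder: Encoder,
    bin_s: float,
    n_shuffles: int = 500,
    seed: int = 0,
    paths: Sequence[str] = FIELD_PATHS,
) -> dict[str, float]:
    """Unit-identity-shuffle z-score of each path's representation rate."""
    import warnings

    if n_shuffles < 100:
        warnings.warn("repz with < 100 shuffles is unreliable", stacklevel=2)
    rng = np.random.default_rng(seed)
    obs, _ = reprate(decode(counts, encoder, bin_s), paths)
    null = {p: [] for p in paths}
    for _ in range(n_shuffles):
        perm = rng.permutation(len(encoder.unit_ids))
        r_s, _ = reprate(decode(counts, encoder.permuted(perm), bin_s), paths)
        for p in paths:
            null[p].append(r_s[p])
    out = {}
    for p in paths:
        arr = np.asarray(null[p])
        sd = arr.std()
        out[p] = float((obs[p] - arr.mean()) / sd) if sd > 0 else np.nan
    return out


def weighted_corr(
    posterior: np.ndarray,
    t: Optional[np.ndarray] = None,
    x: Optional[np.ndarray] = None,
) -> Optional[float]:
    """Posterior-weighted Pearson correlation between time and position.

    ``posterior`` is (T, X) non-negative weights; ``t``/``x`` default to bin
    indices.  None when the weighted variance of either coordinate is zero.
    """
    w = np.asarray(posterior, dtype=float)
    if w.ndim != 2:
        raise EventError("posterior must be 2D")
    T, X = w.shape
    if T < 3:
        raise EventError("need >= 3 time bins")
    t = np.arange(T, dtype=float) if t is None else np.asarray(t, dtype=float)
    x = np.arange(X, dtype=float) if x is None else np.asarray(x, dtype=float)
    W = w.sum()
    if W <= 0:
        return None
    tt = np.broadcast_to(t[:, None], w.shape)
    xx = np.broadcast_to(x[None, :], w.shape)
    mt = (w * tt).sum() / W
    mx = (w * xx).sum() / W
    cov_tx = (w * (tt - mt) * (xx - mx)).sum() / W
    var_t = (w * (tt - mt) ** 2).sum() / W
    var_x = (w * (xx - mx) ** 2).sum() / W
    if var_t <= 0 or var_x <= 0:
        return None
    return float(cov_tx / np.sqrt(var_t * var_x))


def sequence_score(
    post: DecodedPosterior,
    path: str,
    n_shuffles: int = 500,
    seed: int = 0,
    r_threshold: float = 0.5,
) -> tuple[Optional[float], Optional[float], bool, str]:
    """(r, rZ, is_sequential, direction) for the represented path.

    Null: independent circular shift of each time bin's position distribution
    (column-cycle shuffle).  rZ = (|r| - mean|r_null|) / SD|r_null|.
    Direction follows the sign of r on the start->destination axis: positive
    = forward.
    """
    sl = (post.states["path"] == path).to_numpy()
    P = post.posterior[:, sl]
    x = post.states["pos_cm"].to_numpy()[sl]
    t = post.bin_centers
    occupied = P.sum(axis=1) > 1e-12
    if occupied.sum() < 3:
        return None, None, False, "none"
    r = weighted_corr(P, t, x)
    if r is None:
        return None, None, False, "none"
    is_seq = abs(r) >= r_threshold
    direction = "none"
    if is_seq:
        direction = "forward" if r > 0 else "reverse"
    if n_shuffles == 0:  # r and labels only, no null distribution
        return r, None, is_seq, direction
    rng = np.random.default_rng(seed)
    T, X = P.shape
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shifts = rng.integers(0, X, size=T)
        Ps = np.empty_like(P)
        for i in range(T):
            Ps[i] = np.roll(P[i], shifts[i])
        rn = weighted_corr(Ps, t, x)
        null[s] = np.nan if rn is None else abs(rn)
    null = null[~np.isnan(null)]
    sd = null.std() if len(null) else 0.0
    rz = float((abs(r) - null.mean()) / sd) if sd > 0 else None
    return r, rz, is_seq, direction


def trajectory_event(
    post: DecodedPosterior,
    path: str,
    path_length: float,
    min_span_fraction: float = 0.3,
    max_jump_fraction: float = 0.2,
    min_run_bins: int = 3,
) -> bool:
    """MAP trace spans enough of the path with bounded per-step jumps."""
    sl = (post.states["path"] == path).to_numpy()
    P = post.posterior[:, sl]
    x = post.states["pos_cm"].to_numpy()[sl]
    if P.shape[0] < min_run_bins or P.shape[1] == 0:
        return False
    trace = x[np.argmax(P, axis=1)]
    jumps = np.abs(np.diff(trace))
    ok = jumps <= max_jump_fraction * path_length
    # longest run of bins with bounded jumps
    i = 0
    while i < len(ok):
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < len(ok) and ok[j]:
            j += 1
        seg = trace[i:j + 1]
        if (len(seg) >= min_run_bins
                and seg.max() - seg.min() >= min_span_fraction * path_length):
            return True
        i = j + 1
    return False


def score_events(
    intervals: pd.DataFrame,
    spikes: dict[int, np.ndarray],
    encoder: Encoder,
    path_lengths: dict[str, float],
    bin_s: float = 0.02,
    n_shuffles: int = 200,
    repz_shuffles: int = 200,
    seed: int = 0,
    compute_repz: bool = True,
    paths: Sequence[str] = FIELD_PATHS,
) -> list[CandidateEvent]:
    """Full scoring of candidate intervals into :class:`CandidateEvent`s."""
    root = np.random.SeedSequence(seed)
    events = []
    for k, (_, row) in enumerate(intervals.iterrows()):
        ss = root.spawn(1)[0]
        s1, s2 = [int(s.generate_state(1)[0]) for s in ss.spawn(2)]
        counts, post = decode_event(row["t_start"], row["t_end"], spikes,
                                    encoder, bin_s)
        ev = CandidateEvent(t_start=float(row["t_start"]),
                            t_end=float(row["t_end"]),
                            counts=counts, posterior=post)
        ev.participating_units = [
            uid for uid, st in spikes.items()
            if np.any((st >= ev.t_start) & (st < ev.t_end))
        ]
        try:
            ev.reprates, ev.represented_path = reprate(post, paths)
        except EventError:
            events.append(ev)
            continue
        if compute_repz:
            ev.repz = repz(counts, encoder, bin_s, repz_shuffles, seed=s1,
                           paths=paths)
        try:
            r, rz, is_seq, direction = sequence_score(
                post, ev.represented_path, n_shuffles, seed=s2)
        except EventError:
            r, rz, is_seq, direction = None, None, False, "none"
        ev.r, ev.rz, ev.is_sequential, ev.direction = r, rz, is_seq, direction
        ev.is_trajectory_event = trajectory_event(
            post, ev.represented_path, path_lengths[ev.represented_path])
        events.append(ev)
    return events


# --------------------------------------------------------------------------
# population-level summaries
# --------------------------------------------------------------------------

def event_rate_maps(
    events: Sequence[CandidateEvent] | pd.DataFrame,
    pauses: pd.DataFrame,
    trials: pd.DataFrame,
) -> pd.DataFrame:
    """Per (trial, area): event count and immobility exposure (s).

    This is the count/exposure table consumed by the hierarchical rate model.
    Events are assigned to the pause containing their onset.
    """
    if isinstance(events, pd.DataFrame):
        starts = events["t_start"].to_numpy()
    else:
        starts = np.array([ev.t_start for ev in events])
    phase_of = dict(zip(trials["trial"], trials["phase"]))
    rows = []
    for (trial, area), grp in pauses.groupby(["trial", "area"]):
        exposure = float((grp["t_end"] - grp["t_start"]).sum())
        cnt = 0
        for _, p in grp.iterrows():
            cnt += int(np.sum((starts >= p["t_start"]) & (starts < p["t_end"])))
        rows.append({"trial": int(trial), "area": area,
                     "phase": phase_of.get(trial, ""),
                     "count": cnt, "exposure_s": exposure})
    return pd.DataFrame(rows)


def assign_event_areas(events: Sequence[CandidateEvent], pauses: pd.DataFrame):
    for ev in events:
        hit = pauses[(pauses["t_start"] <= ev.t_start)
                     & (pauses["t_end"] > ev.t_start)]
        ev.area = hit["area"].iloc[0] if len(hit) else ""


def participation_and_pcc(
    events: Sequence[CandidateEvent],
    encoder: Encoder,
    bin_s: float = 0.02,
    n_shuffles: int = 100,
    seed: int = 0,
    unit_classes: Optional[dict[int, str]] = None,
) -> pd.DataFrame:
    """Participation rate and per-cell contribution (PCC) per unit.

    participation = fraction of events with >= 1 spike from the unit.
    PCC = mean over sequential events containing the unit of
    rZ(event) - rZ(event with the unit's spikes removed).
    """
    unit_ids = encoder.unit_ids
    n_ev = len(events)
    rows = []
    rng = np.random.default_rng(seed)
    for k, uid in enumerate(unit_ids):
        part = sum(1 for ev in events if uid in ev.participating_units)
        deltas = []
        for ev in events:
            if not ev.is_sequential or uid not in ev.participating_units:
                continue
            if ev.rz is None:
                continue
            seed_ev = int(rng.integers(2**32))
            # baseline rZ recomputed at the PCC shuffle budget for a fair delta
            _, rz_full, _, _ = sequence_score(
                ev.posterior, ev.represented_path, n_shuffles, seed=seed_ev)
            counts = ev.counts.copy()
            counts[:, k] = 0
            post = decode(counts, encoder, bin_s, bin_edges=ev.posterior.bin_edges)
            _, rz_wo, _, _ = sequence_score(
                post, ev.represented_path, n_shuffles, seed=seed_ev)
            if rz_full is not None and rz_wo is not None:
                deltas.append(rz_full - rz_wo)
        rows.append({
            "unit_id": uid,
            "class": (unit_classes or {}).get(uid, ""),
            "participation": part / n_ev if n_ev else np.nan,
            "pcc": float(np.mean(deltas)) if deltas else np.nan,
            "n_pcc_events": len(deltas),
        })
    return pd.DataFrame(rows)


def pcc_t_statistic(pcc_values: np.ndarray) -> tuple[float, float]:
    """One-sample t statistic of PCC values against 0."""
    from scipy import stats

    vals = np.asarray(pcc_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    t, p = stats.ttest_1samp(vals, 0.0)
    return float(t), float(p)


def ensemble_correlations(
    events: Sequence[CandidateEvent],
    unit_ids: Sequence[int],
    trial_of_event: Optional[Sequence[int]] = None,
) -> tuple[np.ndarray, Optional[pd.DataFrame]]:
    """Pearson correlations of per-event unit-spike-count vectors.

    Returns the event-pair matrix and, when trial assignments are given, the
    trial-pair mean correlation table.  Zero-variance vectors yield NaN rows.
    """
    if len(events) < 2:
        raise EventError("need >= 2 events")
    vecs = np.array([ev.counts.sum(axis=0) for ev in events], dtype=float)
    sd = vecs.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vecs - vecs.mean(axis=1, keepdims=True)) / sd[:, None]
    z[sd == 0] = np.nan
    corr = (z @ z.T) / vecs.shape[1]
    np.fill_diagonal(corr, 1.0)
    trial_table = None
    if trial_of_event is not None:
        trial_of_event = np.asarray(trial_of_event)
        rows = []
        for a in np.unique(trial_of_event):
            for b in np.unique(trial_of_event):
                if b < a:
                    continue
                ia = np.where(trial_of_event == a)[0]
                ib = np.where(trial_of_event == b)[0]
                block = corr[np.ix_(ia, ib)]
                if a == b:
                    iu = np.triu_indices_from(block, k=1)
                    block = block[iu]
                rows.append({"trial_a": int(a), "trial_b": int(b),
                             "mean_corr": float(np.nanmean(block))
                             if np.size(block) else np.nan})
        trial_table = pd.DataFrame(rows)
    return corr, trial_table


def events_table(events: Sequence[CandidateEvent]) -> pd.DataFrame:
    """Flat one-row-per-event table for export."""
    rows = []
    for ev in events:
        row = {
            "t_start": ev.t_start, "t_end": ev.t_end, "area": ev.area,
            "represented_path": ev.represented_path, "r": ev.r, "rz": ev.rz,
            "direction": ev.direction, "is_sequential": ev.is_sequential,
            "is_trajectory_event": ev.is_trajectory_event,
            "n_units": len(ev.participating_units),
        }
        for p, v in ev.reprates.items():
            row[f"reprate_{p}"] = v
        for p, v in ev.repz.items():
            row[f"repz_{p}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
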