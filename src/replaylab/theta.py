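"""Theta-cycle segmentation and quadrant-score quantification of theta sequences."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .decoding import Encoder, bin_spikes, decode
from .linearize import linearize_position
from .maze import FIELD_PATHS


class ThetaError(ValueError):
    pass


@dataclass
class ThetaCycles:
    """Trough-to-trough theta cycles during running."""

    intervals_s: np.ndarray           # (n_cycles, 2) start/end trough times
    filtered: np.ndarray              # band-passed LFP
    lfp_rate: float

    @property
    def n_cycles(self) -> int:
        return len(self.intervals_s)

    @property
    def durations_s(self) -> np.ndarray:
        if self.n_cycles == 0:
            return np.empty(0)
        return self.intervals_s[:, 1] - self.intervals_s[:, 0]


def detect_theta_cycles(
    lfp: np.ndarray,
    lfp_rate: float,
    speed_at: Optional[np.ndarray] = None,
    position_t: Optional[np.ndarray] = None,
    band: tuple[float, float] = (6.0, 10.0),
    running_threshold: float = 4.0,
    duration_bounds: tuple[float, float] = (1.0 / 12.0, 1.0 / 5.0),
) -> ThetaCycles:
    """Zero-phase band-pass, cut at filtered-signal troughs, duration-gated.

    Cycles whose mean running speed is below ``running_threshold`` are
    discarded when a speed trace is given.
    """
    if lfp_rate < 250:
        raise ThetaError("LFP rate must be >= 250 Hz")
    if len(lfp) < 2 * lfp_rate / band[0]:
        raise ThetaError("LFP shorter than two theta cycles")
    nyq = lfp_rate / 2
    sos = butter(3, [band[0] / nyq, band[1] / nyq], btype="band", output="sos")
    filt = sosfiltfilt(sos, lfp)
    # troughs = local minima of the filtered trace
    d = np.diff(filt)
    trough = np.where((d[:-1] < 0) & (d[1:] >= 0))[0] + 1
    tt = trough / lfp_rate

    keep = []
    lo, hi = duration_bounds
    for a, b in zip(tt[:-1], tt[1:]):
        if not (lo <= b - a <= hi):
            continue
        if speed_at is not None and position_t is not None:
            i0 = np.searchsorted(position_t, a)
            i1 = max(i0 + 1, np.searchsorted(position_t, b))
            if np.mean(speed_at[i0:i1]) <= running_threshold:
                continue
        keep.append((a, b))
    iv = (np.asarray(keep).reshape(-1, 2) if keep
          else np.empty((0, 2)))
    return ThetaCycles(intervals_s=iv, filtered=filt, lfp_rate=lfp_rate)


def cycle_pairs(cycles: ThetaCycles) -> list[tuple[float, float, float]]:
    """(start, mid, end) for every pair of contiguous consecutive cycles."""
    iv = cycles.intervals_s
    out = []
    for i in range(len(iv) - 1):
        if np.isclose(iv[i, 1], iv[i + 1, 0], atol=1e-9):
            out.append((iv[i, 0], iv[i, 1], iv[i + 1, 1]))
    return out


@dataclass
class QuadrantScore:
    matrix: np.ndarray                # (n_pos_bins, n_time_bins) averaged posterior
    pos_edges_cm: np.ndarray          # relative position
    n_windows: int
    q: tuple[float, float, float, float]   # QI..QIV masses
    score: Optional[float]


def quadrant_score_from_matrix(
    matrix: np.ndarray, pos_edges: np.ndarray
) -> tuple[tuple[float, float, float, float], float]:
    """Quadrant masses and score about the center (current position, cycle
    midpoint).  Rows = relative position (ascending, 0 at center), columns =
    time through the two-cycle window.  The center row and (for odd column
    counts) center column are excluded.

    Quadrant convention: QII = early/behind, QIV = late/ahead, QI =
    early/ahead, QIII = late/behind, so
    score = ((QII + QIV) - (QI + QIII)) / total is positive for a
    behind-early -> ahead-late (forward) sweep.
    """
    n_pos, n_t = matrix.shape
    centers = 0.5 * (pos_edges[:-1] + pos_edges[1:])
    behind = centers < 0
    ahead = centers > 0
    half = n_t // 2
    early = np.zeros(n_t, dtype=bool)
    early[:half] = True
    late = np.zeros(n_t, dtype=bool)
    late[-half:] = True
    q1 = matrix[np.ix_(ahead, early)].sum()   # early / ahead
    q2 = matrix[np.ix_(behind, early)].sum()  # early / behind
    q3 = matrix[np.ix_(behind, late)].sum()   # late / behind
    q4 = matrix[np.ix_(ahead, late)].sum()    # late / ahead
    total = q1 + q2 + q3 + q4
    score = float(((q2 + q4) - (q1 + q3)) / total) if total > 0 else None
    return (float(q1), float(q2), float(q3), float(q4)), score


def quadrant_score(
    session,
    encoder: Encoder,
    cycles: ThetaCycles,
    path: str,
    phase: Optional[str] = None,
    bin_s: float = 0.02,
    rel_window_cm: float = 50.0,
    rel_bin_cm: float = 2.0,
    n_time_bins: int = 20,
    min_cycles: int = 20,
) -> Optional[QuadrantScore]:
    """Average decoded posterior over two-cycle windows, aligned to the
    animal's current position, and its quadrant score.  None when fewer than
    ``min_cycles`` qualifying windows exist."""
    lin = linearize_position(session.position, session.maze)
    t_arr = session.position["t_s"].to_numpy()
    lin_path = lin["path"].to_numpy()
    lin_pos = lin["linpos_cm"].to_numpy()
    phase_of = dict(zip(session.trials["trial"], session.trials["phase"]))
    trial_arr = session.position["trial"].to_numpy()

    sl = encoder.path_slice(path)
    state_pos = encoder.states["pos_cm"].to_numpy()[sl]
    pos_edges = np.arange(-rel_window_cm, rel_window_cm + rel_bin_cm, rel_bin_cm)
    acc = np.zeros((len(pos_edges) - 1, n_time_bins))
    n_win = 0
    for a, m, c in cycle_pairs(cycles):
        i = np.clip(np.searchsorted(t_arr, m) - 1, 0, len(t_arr) - 1)
        if lin_path[i] != path:
            continue
        if phase is not None and phase_of.get(trial_arr[i]) != phase:
            continue
        cur = lin_pos[i]
        counts, edges = bin_spikes(session.spikes, encoder.unit_ids, a, c, bin_s)
        if counts.sum() == 0:
            continue
        post = decode(counts, encoder, bin_s, bin_edges=edges)
        pp = post.posterior[:, sl]
        # accumulate onto (relative position, normalized window time)
        tmid = post.bin_centers
        tb = np.clip(((tmid - a) / (c - a) * n_time_bins).astype(int), 0,
                     n_time_bins - 1)
        rel = state_pos - cur
        pb = np.floor((rel - pos_edges[0]) / rel_bin_cm).astype(int)
        okp = (pb >= 0) & (pb < len(pos_edges) - 1)
        for ti in range(pp.shape[0]):
            np.add.at(acc[:, tb[ti]], pb[okp], pp[ti, okp])
        n_win += 1
    if n_win < min_cycles:
        return None
    acc /= n_win
    q, score = quadrant_score_from_matrix(acc, pos_edges)
    return QuadrantScore(matrix=acc, pos_edges_cm=pos_edges,
                         n_windows=n_win, q=q, score=score)


def score_table(
    session,
    encoder: Encoder,
    cycles: ThetaCycles,
    paths: Sequence[str] = FIELD_PATHS,
    phases: Sequence[str] = ("pre", "learning", "post"),
    **kwargs,
) -> pd.DataFrame:
    """Per-(path, phase) quadrant scores for cross-condition comparisons."""
    rows = []
    for path in paths:
        for ph in phases:
            qs = quadrant_score(session, encoder, cycles, path, phase=ph, **kwargs)
            rows.append({
                "path": path, "phase": ph,
                "score": None if qs is None else qs.score,
                "n_windows": 0 if qs is None else qs.n_windows,
            })
    return pd.DataFrame(rows)
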