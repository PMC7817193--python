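"""Assign each position sample to its active path and linearized coordinate.

Trials are segmented at landmark entries (S, C1, C2, G); every sample between
two consecutive landmarks inherits the path label defined by that landmark
pair and is projected onto the corresponding template polyline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .maze import MazeSpec, OTHER, segment_label


def compute_speed(position: pd.DataFrame, smooth_s: float = 0.25) -> np.ndarray:
    """Running speed (cm/s) from position samples, boxcar-smoothed."""
    t = position["t_s"].to_numpy()
    xy = position[["x_cm", "y_cm"]].to_numpy()
    dt = np.diff(t)
    dt[dt <= 0] = np.nan
    v = np.linalg.norm(np.diff(xy, axis=0), axis=1) / dt
    v = np.concatenate([[v[0]], v])
    v = np.nan_to_num(v)
    if smooth_s > 0 and len(t) > 2:
        rate = 1.0 / np.median(np.diff(t))
        k = max(1, int(round(smooth_s * rate)))
        v = np.convolve(v, np.ones(k) / k, mode="same")
    return v


def _landmark_per_sample(position: pd.DataFrame, maze: MazeSpec) -> np.ndarray:
    xy = position[["x_cm", "y_cm"]].to_numpy()
    regions = maze.region_of(xy)
    cells = maze.lattice_cell_of(xy)
    out = np.full(len(xy), "", dtype=object)
    out[regions == "S"] = "S"
    out[regions == "G"] = "G"
    c1, c2 = maze.c1_cell, maze.c2_cell
    is_c1 = (cells[:, 0] == c1[0]) & (cells[:, 1] == c1[1])
    is_c2 = (cells[:, 0] == c2[0]) & (cells[:, 1] == c2[1])
    out[is_c1] = "C1"
    out[is_c2] = "C2"
    return out


def linearize_position(position: pd.DataFrame, maze: MazeSpec) -> pd.DataFrame:
    """Per-sample (path, linpos_cm); path = '' where no named path applies."""
    lm = _landmark_per_sample(position, maze)
    n = len(position)
    path = np.full(n, "", dtype=object)
    linpos = np.full(n, np.nan)
    xy = position[["x_cm", "y_cm"]].to_numpy()

    for _, idx in position.groupby("trial", sort=True).indices.items():
        idx = np.sort(idx)
        lmt = lm[idx]
        # landmark entry points within the trial
        entries = []
        prev = None
        for k, name in enumerate(lmt):
            name = name or None
            if name is not None and name != prev:
                entries.append((name, k))
            if name is not None:
                prev = name
            # leaving a landmark keeps `prev` so re-entries are not duplicated
        for (a, ka), (b, kb) in zip(entries[:-1], entries[1:]):
            lab = segment_label(a, b)
            if lab == OTHER:
                continue
            tpl = maze.paths[lab]
            sl = idx[ka:kb + 1]
            s, _ = tpl.project(xy[sl])
            path[sl] = lab
            linpos[sl] = s
    out = position[["t_s"]].copy()
    out["path"] = path
    out["linpos_cm"] = linpos
    if "trial" in position:
        out["trial"] = position["trial"].to_numpy()
    return out


def spike_path_positions(
    spike_times: np.ndarray, position: pd.DataFrame, lin: pd.DataFrame
) -> pd.DataFrame:
    """Path label and linearized position at each spike time (nearest sample)."""
    t = position["t_s"].to_numpy()
    idx = np.clip(np.searchsorted(t, spike_times) - 1, 0, len(t) - 1)
    return pd.DataFrame({
        "t_s": spike_times,
        "path": lin["path"].to_numpy()[idx],
        "linpos_cm": lin["linpos_cm"].to_numpy()[idx],
        "sample": idx,
    })
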