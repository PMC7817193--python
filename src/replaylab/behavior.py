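"""Trial-level behavior: path strings, path labels, learning curve, distances."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .maze import OTHER, PATH_LABELS, MazeSpec, segment_label


class BehaviorError(ValueError):
    pass


@dataclass
class TrialPath:
    """Discretized trajectory of one trial."""

    trial: int
    cells: list[tuple[int, int]]         # lattice cells, duplicates collapsed
    visits: list[str]                    # landmark visit order (S/C1/C2/G)
    distance_cm: float
    duration_s: float

    @property
    def string_length(self) -> int:
        return len(self.cells)


def discretize_trajectory(
    position: pd.DataFrame, maze: MazeSpec, trial: Optional[int] = None
) -> TrialPath | list[TrialPath]:
    """Collapse a trial's position samples to a lattice-cell string.

    Landmark visits (S, C1, C2, G) are annotated in the order entered; the
    checkpoints count as visited when their lattice cell is entered.
    """
    if trial is None:
        return [
            discretize_trajectory(g, maze, trial=k)
            for k, g in position.groupby("trial", sort=True)
        ]
    if len(position) < 2:
        raise BehaviorError(f"trial {trial}: need >= 2 position samples")
    xy = position[["x_cm", "y_cm"]].to_numpy()
    t = position["t_s"].to_numpy()
    cells = maze.lattice_cell_of(xy)
    regions = maze.region_of(xy)

    cell_str: list[tuple[int, int]] = []
    for c, r in cells:
        if c == 0:
            continue
        if not cell_str or cell_str[-1] != (c, r):
            cell_str.append((int(c), int(r)))

    c1, c2 = tuple(maze.c1_cell), tuple(maze.c2_cell)
    visits: list[str] = []
    state = None
    for i in range(len(xy)):
        here = None
        if regions[i] == "S":
            here = "S"
        elif regions[i] == "G":
            here = "G"
        elif cells[i, 0] != 0:
            cell = (cells[i, 0], cells[i, 1])
            if cell == c1:
                here = "C1"
            elif cell == c2:
                here = "C2"
        if here is not None and here != state:
            visits.append(here)
            state = here
    dist = float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))
    return TrialPath(trial=int(trial), cells=cell_str, visits=visits,
                     distance_cm=dist, duration_s=float(t[-1] - t[0]))


def classify_paths(trial_path: TrialPath, maze: MazeSpec = None) -> list[str]:
    """Label each inter-landmark segment by its endpoints.

    Segments whose endpoint pair is not one of the five named paths or the
    return alleyway are labeled ``other``.
    """
    visits = trial_path.visits
    return [segment_label(a, b) for a, b in zip(visits[:-1], visits[1:])]


def path_proportions(labels_per_trial: Sequence[Sequence[str]]) -> pd.Series:
    """Fraction of traversed segments per label (including ``other``); sums to 1."""
    flat = [lab for labs in labels_per_trial for lab in labs]
    counts = pd.Series(flat).value_counts()
    idx = list(PATH_LABELS) + [OTHER]
    counts = counts.reindex(idx, fill_value=0).astype(float)
    total = counts.sum()
    return counts / total if total else counts


@dataclass
class LearningCurve:
    efficiency: np.ndarray               # per-trial 0/1 indicator
    moving_average: np.ndarray           # centered moving average in [0, 1]
    window: int
    learning_point: Optional[int]        # 1-based trial, or None
    reward_replacement_trial: int


def _is_efficient(labels: Sequence[str]) -> bool:
    field = [lab for lab in labels if lab != "return"]
    return field == ["S-C2", "C2-G"]


def learning_point(
    labels_per_trial: Sequence[Sequence[str]],
    reward_replacement_trial: int,
    window: int = 5,
) -> LearningCurve:
    """Moving-average learning curve and the learning point.

    A trial is efficient iff its in-field label sequence is exactly
    [S-C2, C2-G].  The learning point is the first trial at or after the
    reward replacement whose centered moving average reaches 0.5 and stays
    at or above 0.5 through the end of the session; None if never reached.
    """
    n = len(labels_per_trial)
    if window < 3 or window % 2 == 0:
        raise BehaviorError("window must be odd and >= 3")
    if window > n:
        raise BehaviorError("window larger than trial count")
    eff = np.array([float(_is_efficient(labs)) for labs in labels_per_trial])
    half = window // 2
    ma = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        ma[i] = eff[lo:hi].mean()
    lp = None
    for i in range(reward_replacement_trial - 1, n):
        if np.all(ma[i:] >= 0.5):
            lp = i + 1
            break
    return LearningCurve(
        efficiency=eff, moving_average=ma, window=window,
        learning_point=lp, reward_replacement_trial=reward_replacement_trial,
    )


def trajectory_distance(a: Sequence, b: Sequence) -> int:
    """Levenshtein edit distance between two lattice-cell strings."""
    if len(a) == 0 or len(b) == 0:
        raise BehaviorError("path strings must be nonempty")
    a, b = list(a), list(b)
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, start=1):
        cur = np.empty(len(b) + 1, dtype=int)
        cur[0] = i
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return int(prev[-1])


def prob_behavior_change(
    trial_paths: Sequence[TrialPath],
    labels_per_trial: Sequence[Sequence[str]],
    threshold: int = 2,
) -> Optional[float]:
    """Fraction of successive-trial pairs with edit distance >= ``threshold``,
    counted from the first trial that takes path S-C2 onward. None if fewer
    than two qualifying trials."""
    first = None
    for i, labs in enumerate(labels_per_trial):
        if "S-C2" in labs:
            first = i
            break
    if first is None:
        return None
    qualifying = trial_paths[first:]
    if len(qualifying) < 2:
        return None
    dists = [
        trajectory_distance(p.cells, q.cells)
        for p, q in zip(qualifying[:-1], qualifying[1:])
    ]
    return float(np.mean([d >= threshold for d in dists]))


def summarize_trials(
    position: pd.DataFrame, trials: pd.DataFrame, maze: MazeSpec
) -> pd.DataFrame:
    """Per-trial summary table: string length, distance, duration, labels."""
    tps = discretize_trajectory(position, maze)
    phase_of = dict(zip(trials["trial"], trials["phase"]))
    rows = []
    for tp in tps:
        labels = classify_paths(tp, maze)
        rows.append({
            "trial": tp.trial,
            "phase": phase_of.get(tp.trial, ""),
            "string_length": tp.string_length,
            "distance_cm": tp.distance_cm,
            "duration_s": tp.duration_s,
            "visits": "-".join(tp.visits),
            "labels": ",".join(labels),
            "efficient": int(_is_efficient(labels)),
        })
    return pd.DataFrame(rows)
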