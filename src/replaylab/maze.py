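"""Lattice-maze geometry: regions, canonical path templates, linearization.

The arena is an open field of ``lattice_cols x lattice_rows`` square cells
flanked by a start box (S, below the first column), a goal box (G, above the
last column), and a peripheral return alleyway running along the right edge
from G back to S.  Two lattice cells act as checkpoints (C1, C2).  Every
analysis in this package works on linearized coordinates along one of the
canonical piecewise-linear path templates defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: canonical path labels, in a fixed deterministic order
PATH_LABELS = ("S-C1", "C1-G", "G-C2", "S-C2", "C2-G", "return")
#: the five in-field paths (everything except the return alleyway)
FIELD_PATHS = PATH_LABELS[:5]
OTHER = "other"

#: analogous-path pairs used for context-dependent field correspondence;
#: the first group approaches a checkpoint, the second approaches the goal
CHECKPOINT_PATHS = ("S-C1", "S-C2", "G-C2")
GOAL_PATHS = ("C1-G", "C2-G")

LANDMARKS = ("S", "C1", "C2", "G")

#: landmark-pair -> path label (direction-sensitive)
_SEGMENT_LABELS = {
    ("S", "C1"): "S-C1",
    ("C1", "G"): "C1-G",
    ("G", "C2"): "G-C2",
    ("S", "C2"): "S-C2",
    ("C2", "G"): "C2-G",
    ("G", "S"): "return",
}


class MazeConfigError(ValueError):
    """Raised when a maze configuration violates its invariants."""


@dataclass(frozen=True)
class PathTemplate:
    """A canonical path as a piecewise-linear chain of 2D waypoints (cm)."""

    label: str
    waypoints: np.ndarray  # (n, 2)

    def __post_init__(self):
        wp = np.asarray(self.waypoints, dtype=float)
        if wp.ndim != 2 or wp.shape[0] < 2 or wp.shape[1] != 2:
            raise MazeConfigError("path template needs >= 2 waypoints")
        object.__setattr__(self, "waypoints", wp)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.waypoints, axis=0), axis=1)

    @property
    def cum_lengths(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])

    @property
    def length(self) -> float:
        return float(self.cum_lengths[-1])

    def point_at(self, s) -> np.ndarray:
        """2D point(s) at arclength ``s`` (clipped to [0, length])."""
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, self.length)
        cum = self.cum_lengths
        seg = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(cum) - 2)
        seg_len = np.maximum(self.segment_lengths[seg], 1e-12)
        frac = (s - cum[seg]) / seg_len
        p0 = self.waypoints[seg]
        p1 = self.waypoints[seg + 1]
        out = p0 + frac[:, None] * (p1 - p0)
        return out if out.shape[0] > 1 else out[0]

    def project(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project 2D points onto the polyline.

        Returns (arclength cm, euclidean distance to the polyline cm).
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        best_d2 = np.full(len(xy), np.inf)
        best_s = np.zeros(len(xy))
        cum = self.cum_lengths
        for i in range(len(self.waypoints) - 1):
            a = self.waypoints[i]
            b = self.waypoints[i + 1]
            ab = b - a
            denom = max(float(ab @ ab), 1e-12)
            t = np.clip((xy - a) @ ab / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d2 = np.sum((xy - proj) ** 2, axis=1)
            better = d2 < best_d2
            best_d2[better] = d2[better]
            best_s[better] = cum[i] + t[better] * np.sqrt(denom)
        return best_s, np.sqrt(best_d2)


@dataclass(frozen=True)
class MazeSpec:
    """Maze geometry. Checkpoint cells are (col, row), 1-based from left/bottom."""

    lattice_cols: int = 5
    lattice_rows: int = 5
    cell_size: float = 20.0
    c1_cell: tuple[int, int] = (4, 2)
    c2_cell: tuple[int, int] = (2, 4)
    region_depth: float = 20.0  # S/G box depth and alleyway width, cm
    paths: dict[str, PathTemplate] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.lattice_cols < 4 or self.lattice_rows < 4:
            raise MazeConfigError("lattice must be at least 4x4")
        if self.cell_size <= 0:
            raise MazeConfigError("cell_size must be positive")
        for name, (c, r) in (("c1", self.c1_cell), ("c2", self.c2_cell)):
            if not (1 <= c <= self.lattice_cols and 1 <= r <= self.lattice_rows):
                raise MazeConfigError(
                    f"checkpoint {name} cell {(c, r)} outside "
                    f"{self.lattice_cols}x{self.lattice_rows} lattice"
                )
        if tuple(self.c1_cell) == tuple(self.c2_cell):
            raise MazeConfigError("c1 and c2 must be distinct lattice cells")
        if not self.paths:
            object.__setattr__(self, "paths", _build_templates(self))

    # -- geometry helpers -------------------------------------------------
    @property
    def field_width(self) -> float:
        return self.lattice_cols * self.cell_size

    @property
    def field_height(self) -> float:
        return self.lattice_rows * self.cell_size

    def cell_center(self, cell: tuple[int, int]) -> np.ndarray:
        c, r = cell
        return np.array([(c - 0.5) * self.cell_size, (r - 0.5) * self.cell_size])

    @property
    def start_center(self) -> np.ndarray:
        return np.array([0.5 * self.cell_size, -0.5 * self.region_depth])

    @property
    def goal_center(self) -> np.ndarray:
        return np.array(
            [self.field_width - 0.5 * self.cell_size,
             self.field_height + 0.5 * self.region_depth]
        )

    def region_of(self, xy: np.ndarray) -> np.ndarray:
        """Label each 2D sample: 'S', 'G', 'alley', 'field', or 'out'.

        The S box sits below column 1, the G box above the last column, and
        the alleyway is the L-shaped strip right of the field connecting them.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        x, y = xy[:, 0], xy[:, 1]
        w, h, d = self.field_width, self.field_height, self.region_depth
        cs = self.cell_size
        out = np.full(len(xy), "out", dtype=object)
        in_field = (x >= 0) & (x < w) & (y >= 0) & (y < h)
        out[in_field] = "field"
        in_s = (x >= 0) & (x < cs) & (y >= -d) & (y < 0)
        out[in_s] = "S"
        in_g = (x >= w - cs) & (x < w) & (y >= h) & (y < h + d)
        out[in_g] = "G"
        # alleyway: vertical strip right of the field plus the bottom strip
        # leading back to S (excluding the S box itself)
        in_alley = ((x >= w) & (x < w + d) & (y >= -d) & (y < h + d)) | (
            (x >= cs) & (x < w) & (y >= -d) & (y < 0)
        )
        out[in_alley] = "alley"
        return out

    def lattice_cell_of(self, xy: np.ndarray) -> np.ndarray:
        """Map samples to 1-based (col, row); (0, 0) outside the field."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        col = np.floor(xy[:, 0] / self.cell_size).astype(int) + 1
        row = np.floor(xy[:, 1] / self.cell_size).astype(int) + 1
        inside = (
            (col >= 1) & (col <= self.lattice_cols)
            & (row >= 1) & (row <= self.lattice_rows)
        )
        col[~inside] = 0
        row[~inside] = 0
        return np.stack([col, row], axis=1)

    def checkpoint_center(self, name: str) -> np.ndarray:
        if name == "C1":
            return self.cell_center(self.c1_cell)
        if name == "C2":
            return self.cell_center(self.c2_cell)
        raise KeyError(name)

    def landmark_center(self, name: str) -> np.ndarray:
        if name == "S":
            return self.start_center
        if name == "G":
            return self.goal_center
        return self.checkpoint_center(name)

    def to_dict(self) -> dict:
        return {
            "lattice_cols": self.lattice_cols,
            "lattice_rows": self.lattice_rows,
            "cell_size": self.cell_size,
            "c1_cell": list(self.c1_cell),
            "c2_cell": list(self.c2_cell),
            "region_depth": self.region_depth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MazeSpec":
        return cls(
            lattice_cols=int(d["lattice_cols"]),
            lattice_rows=int(d["lattice_rows"]),
            cell_size=float(d["cell_size"]),
            c1_cell=tuple(d["c1_cell"]),
            c2_cell=tuple(d["c2_cell"]),
            region_depth=float(d.get("region_depth", 20.0)),
        )


def _lattice_route(maze: MazeSpec, a: tuple[int, int], b: tuple[int, int],
                   first_axis: str) -> list[np.ndarray]:
    """L-shaped route between two cells through cell centers."""
    pts = [maze.cell_center(a)]
    ca, ra = a
    cb, rb = b
    if first_axis == "col":
        if ca != cb:
            pts.append(maze.cell_center((cb, ra)))
    else:
        if ra != rb:
            pts.append(maze.cell_center((ca, rb)))
    end = maze.cell_center(b)
    if not np.allclose(pts[-1], end):
        pts.append(end)
    return pts


def _build_templates(maze: MazeSpec) -> dict[str, PathTemplate]:
    s_entry = (1, 1)  # first lattice cell after the start box
    g_entry = (maze.lattice_cols, maze.lattice_rows)  # last cell before goal
    c1, c2 = maze.c1_cell, maze.c2_cell
    S, G = maze.start_center, maze.goal_center

    def tpl(label, pts):
        # drop consecutive duplicate waypoints
        keep = [pts[0]]
        for p in pts[1:]:
            if not np.allclose(p, keep[-1]):
                keep.append(p)
        return PathTemplate(label, np.array(keep))

    paths = {
        "S-C1": tpl("S-C1", [S, maze.cell_center(s_entry)]
                    + _lattice_route(maze, s_entry, c1, "col")[1:]),
        "C1-G": tpl("C1-G", _lattice_route(maze, c1, g_entry, "row")
                    + [G]),
        "G-C2": tpl("G-C2", [G, maze.cell_center(g_entry)]
                    + _lattice_route(maze, g_entry, c2, "col")[1:]),
        "S-C2": tpl("S-C2", [S, maze.cell_center(s_entry)]
                    + _lattice_route(maze, s_entry, c2, "row")[1:]),
        "C2-G": tpl("C2-G", _lattice_route(maze, c2, g_entry, "col")
                    + [G]),
    }
    # return alleyway: G -> right edge -> down -> along the bottom -> S
    w, h, d = maze.field_width, maze.field_height, maze.region_depth
    mid = 0.5 * d
    paths["return"] = tpl("return", [
        G,
        np.array([w + mid, h + mid]),
        np.array([w + mid, -mid]),
        S,
    ])
    return paths


def make_maze(
    lattice_cols: int = 5,
    lattice_rows: int = 5,
    cell_size: float = 20.0,
    c1_cell: Sequence[int] = (4, 2),
    c2_cell: Sequence[int] = (2, 4),
    region_depth: float = 20.0,
) -> MazeSpec:
    """Build a validated :class:`MazeSpec` with its six path templates."""
    return MazeSpec(
        lattice_cols=lattice_cols,
        lattice_rows=lattice_rows,
        cell_size=cell_size,
        c1_cell=tuple(int(v) for v in c1_cell),
        c2_cell=tuple(int(v) for v in c2_cell),
        region_depth=region_depth,
    )


def segment_label(a: str, b: str) -> str:
    """Path label for a traversal from landmark ``a`` to landmark ``b``."""
    return _SEGMENT_LABELS.get((a, b), OTHER)
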