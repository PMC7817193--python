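"""Ground-truth synthetic sessions: behavior, spiking, LFP, injected replays.

The generator produces everything the downstream analyses consume — position
samples on a lattice maze, theta-modulated place-cell spike trains with phase
precession, a broadband LFP with ripple bursts, and time-compressed replay
spike sequences embedded at immobility pauses — together with a
:class:`GroundTruth` record of every programmed quantity, so each analysis
stage can be validated against what was actually injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .maze import (
    CHECKPOINT_PATHS,
    FIELD_PATHS,
    GOAL_PATHS,
    MazeSpec,
    make_maze,
)

PHASES = ("pre", "learning", "post")
CELL_TYPES = ("stable", "context-dependent", "on", "off", "nonplace")

# traversal plans per phase: each trial visits these paths in order
_PHASE_PLANS = {
    "pre": ("S-C1", "C1-G", "return"),
    "learning": ("S-C1", "C1-G", "G-C2", "C2-G", "return"),
    "post": ("S-C2", "C2-G", "return"),
}
# pause location after completing each path (landmark reached)
_PATH_DEST = {
    "S-C1": "C1", "C1-G": "G", "G-C2": "C2", "S-C2": "C2",
    "C2-G": "G", "return": "S",
}
_LOC_AREA = {"S": "start", "C1": "field", "C2": "field", "G": "goal"}


class SimulationError(ValueError):
    pass


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ThetaParams:
    freq_hz: float = 8.0
    mod_depth: float = 0.9           # rate modulation amplitude in [0, 1]
    precession_deg: float = 270.0    # phase advance across the field
    precession: bool = True


@dataclass(frozen=True)
class UnitSpec:
    """Programmed tuning for one unit.

    ``center`` is a linearized position (cm from path start) for stable /
    on / off units; for context-dependent units it is the distance from the
    *destination* landmark, expressed on every analogous path of ``family``.
    """

    unit_id: int
    cell_type: str
    path: Optional[str] = None         # home path (stable/on/off)
    family: Optional[str] = None       # 'checkpoint' | 'goal' (context-dep.)
    center: float = 50.0
    sigma: float = 10.0
    peak_rate: float = 15.0
    baseline_rate: float = 0.2

    def __post_init__(self):
        if self.cell_type not in CELL_TYPES:
            raise SimulationError(f"unknown cell type {self.cell_type!r}")
        if self.peak_rate < 0:
            raise SimulationError("peak rate must be non-negative")

    def fields_by_phase(self, maze: MazeSpec) -> dict[str, list[tuple[str, float]]]:
        """(path, linearized center cm) pairs active in each phase."""
        out = {ph: [] for ph in PHASES}
        if self.cell_type == "nonplace":
            return out
        if self.cell_type == "context-dependent":
            paths = CHECKPOINT_PATHS if self.family == "checkpoint" else GOAL_PATHS
            fields = [(p, maze.paths[p].length - self.center) for p in paths]
            for ph in PHASES:
                out[ph] = list(fields)
            return out
        fields = [(self.path, self.center)]
        if self.cell_type == "stable":
            active = PHASES
        elif self.cell_type == "on":
            active = ("learning", "post")
        else:  # off
            active = ("pre",)
        for ph in active:
            out[ph] = list(fields)
        return out


@dataclass(frozen=True)
class SimConfig:
    n_trials_per_phase: tuple[int, int, int] = (8, 12, 8)
    run_speed: float = 30.0            # cm/s nominal
    speed_jitter: float = 3.0          # SD of per-leg speed, cm/s
    pause_median_s: float = 3.0        # lognormal median of pause durations
    pause_sigma: float = 0.3           # lognormal shape
    position_rate: float = 50.0        # Hz
    position_noise: float = 0.5        # cm, isotropic
    lfp_rate: float = 1250.0           # Hz
    theta: ThetaParams = ThetaParams()
    refractory_s: float = 0.002
    # replay injection
    replay_compression: float = 15.0
    replay_prob_per_pause: float = 0.8
    replay_spikes_per_unit: int = 2
    replay_jitter_s: float = 0.004
    ripple_freq_hz: float = 200.0
    ripple_snr: float = 6.0            # burst amplitude in ripple-band SDs
    seed: int = 0


# --------------------------------------------------------------------------
# session containers
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    cell_types: dict[int, str]
    field_centers: dict[int, dict[str, list[tuple[str, float]]]]
    replay_schedule: list[dict]
    learning_point_trial: int          # 1-based trial index
    reward_replacement_trial: int      # 1-based; first learning trial
    phase_of_trial: list[str]


@dataclass
class Session:
    """One synthetic recording with time-aligned streams and ground truth."""

    maze: MazeSpec
    spikes: dict[int, np.ndarray]          # unit id -> sorted times (s)
    position: pd.DataFrame                 # t_s, x_cm, y_cm
    speed: np.ndarray                      # cm/s at position samples
    lfp: np.ndarray
    lfp_rate: float
    trials: pd.DataFrame                   # trial, t_start, t_end, phase
    units: list[UnitSpec]
    ground_truth: GroundTruth
    # generator-internal truth at position samples (analyses recompute these)
    true_path: np.ndarray = None           # path label or '' per sample
    true_linpos: np.ndarray = None         # cm, NaN off-path
    pauses: pd.DataFrame = None            # t_start, t_end, location, trial

    @property
    def duration(self) -> float:
        return float(self.position["t_s"].iloc[-1])

    @property
    def n_units(self) -> int:
        return len(self.spikes)


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

def _plan_legs(maze, n_trials_per_phase, cfg: SimConfig, rng) -> tuple[list, list]:
    """Build the leg timeline: ('pause', loc, dur, trial) / ('run', path, dur, trial)."""
    n_pre, n_learn, n_post = n_trials_per_phase
    phases = ["pre"] * n_pre + ["learning"] * n_learn + ["post"] * n_post
    legs = []
    for trial_idx, phase in enumerate(phases, start=1):
        plan = _PHASE_PLANS[phase]
        legs.append(("pause", "S", _pause_dur(cfg, rng), trial_idx))
        for path in plan:
            speed = max(5.0, rng.normal(cfg.run_speed, cfg.speed_jitter))
            dur = maze.paths[path].length / speed
            legs.append(("run", path, dur, trial_idx))
            dest = _PATH_DEST[path]
            if dest != "S":  # the return pause merges with next trial's S pause
                legs.append(("pause", dest, _pause_dur(cfg, rng), trial_idx))
    return legs, phases


def _pause_dur(cfg, rng) -> float:
    return float(rng.lognormal(np.log(cfg.pause_median_s), cfg.pause_sigma))


def simulate_behavior(
    maze: MazeSpec,
    n_trials_per_phase: Sequence[int] = (8, 12, 8),
    config: SimConfig = None,
    seed: int = 0,
):
    """Simulate trajectories through the three learning phases.

    Returns (position DataFrame, trials DataFrame, pauses DataFrame,
    true_path, true_linpos, speed, phase_of_trial).
    """
    cfg = config or SimConfig()
    n_trials_per_phase = tuple(int(n) for n in n_trials_per_phase)
    if any(n < 1 for n in n_trials_per_phase):
        raise SimulationError("need at least 1 trial per phase")
    rng = np.random.default_rng(seed)
    legs, phases = _plan_legs(maze, n_trials_per_phase, cfg, rng)

    dt = 1.0 / cfg.position_rate
    rows_t, rows_xy, rows_path, rows_lin, rows_speed, rows_trial = [], [], [], [], [], []
    pauses = []
    trial_bounds: dict[int, list] = {}
    t0 = 0.0
    for kind, what, dur, trial in legs:
        n = max(1, int(round(dur / dt)))
        tt = t0 + np.arange(n) * dt
        if kind == "pause":
            xy = np.tile(maze.landmark_center(what), (n, 1))
            rows_path.append(np.full(n, "", dtype=object))
            rows_lin.append(np.full(n, np.nan))
            rows_speed.append(np.zeros(n))
            pauses.append((t0, t0 + n * dt, what, trial))
        else:
            tpl = maze.paths[what]
            s = tpl.length * (np.arange(n) + 0.5) / n
            xy = np.atleast_2d(tpl.point_at(s))
            rows_path.append(np.full(n, what, dtype=object))
            rows_lin.append(s)
            rows_speed.append(np.full(n, tpl.length / (n * dt)))
        rows_t.append(tt)
        rows_xy.append(xy)
        rows_trial.append(np.full(n, trial))
        trial_bounds.setdefault(trial, [t0, t0]).__setitem__(1, t0 + n * dt)
        trial_bounds[trial][0] = min(trial_bounds[trial][0], t0)
        t0 += n * dt

    t = np.concatenate(rows_t)
    xy = np.concatenate(rows_xy, axis=0)
    if cfg.position_noise > 0:
        xy = xy + rng.normal(0, cfg.position_noise, xy.shape)
    position = pd.DataFrame(
        {"t_s": t, "x_cm": xy[:, 0], "y_cm": xy[:, 1],
         "trial": np.concatenate(rows_trial)}
    )
    trials = pd.DataFrame(
        [
            {"trial": k, "t_start": v[0], "t_end": v[1], "phase": phases[k - 1]}
            for k, v in sorted(trial_bounds.items())
        ]
    )
    # fix trial starts: first leg of each trial defines the start
    starts = {}
    off = 0.0
    for kind, what, dur, trial in legs:
        n = max(1, int(round(dur / dt)))
        starts.setdefault(trial, off)
        off += n * dt
    trials["t_start"] = trials["trial"].map(starts)
    pauses_df = pd.DataFrame(pauses, columns=["t_start", "t_end", "location", "trial"])
    pauses_df["area"] = pauses_df["location"].map(_LOC_AREA)
    return (
        position,
        trials,
        pauses_df,
        np.concatenate(rows_path),
        np.concatenate(rows_lin),
        np.concatenate(rows_speed),
        phases,
    )


# --------------------------------------------------------------------------
# unit population
# --------------------------------------------------------------------------

def default_units(
    n_stable: int = 24,
    n_context: int = 8,
    n_on: int = 4,
    n_off: int = 4,
    n_nonplace: int = 4,
    maze: MazeSpec = None,
    peak_rate: float = 15.0,
    sigma: float = 8.0,
    seed: int = 0,
    stable_paths: Optional[Sequence[str]] = None,
) -> list[UnitSpec]:
    """A tiling place-cell population.

    By default stable fields are placed only on paths observable in >= 2
    phases (S-C1, C1-G in pre+learning; C2-G in learning+post), which keeps
    the ground-truth labels recoverable by cross-phase joint classification.
    Pass ``stable_paths=FIELD_PATHS`` to tile every path (better replay
    content separation, at the cost of classifiable stability).
    """
    maze = maze or make_maze()
    rng = np.random.default_rng(seed)
    units = []
    uid = 0
    paths = list(stable_paths) if stable_paths else ["S-C1", "C1-G", "C2-G"]
    for i in range(n_stable):
        path = paths[i % len(paths)]
        L = maze.paths[path].length
        frac = (i // len(paths) + 0.5) / max(1, -(-n_stable // len(paths)))
        center = np.clip(frac * L + rng.normal(0, 3.0), 0.05 * L, 0.95 * L)
        units.append(UnitSpec(uid, "stable", path=path, center=float(center),
                              sigma=sigma, peak_rate=peak_rate))
        uid += 1
    for i in range(n_context):
        family = "checkpoint" if i % 2 == 0 else "goal"
        ref = CHECKPOINT_PATHS[0] if family == "checkpoint" else GOAL_PATHS[0]
        L = maze.paths[ref].length
        d = float(np.clip(rng.uniform(5, 0.5 * L), 5, 0.6 * L))
        units.append(UnitSpec(uid, "context-dependent", family=family, center=d,
                              sigma=sigma, peak_rate=peak_rate))
        uid += 1
    # on/off switch at the reward replacement, so their paths must be
    # observable both before and after it
    onoff_paths = ["S-C1", "C1-G"]
    for kind, n in (("on", n_on), ("off", n_off)):
        for i in range(n):
            path = onoff_paths[int(rng.integers(len(onoff_paths)))]
            L = maze.paths[path].length
            units.append(UnitSpec(uid, kind, path=path,
                                  center=float(rng.uniform(0.1 * L, 0.9 * L)),
                                  sigma=sigma, peak_rate=peak_rate))
            uid += 1
    for i in range(n_nonplace):
        units.append(UnitSpec(uid, "nonplace", baseline_rate=1.5, peak_rate=0.0))
        uid += 1
    return units


# --------------------------------------------------------------------------
# spiking
# --------------------------------------------------------------------------

def _fine_grid(position, true_path, true_linpos, speed, trials, cfg):
    """Resample behavior truth onto the LFP-rate grid."""
    t_pos = position["t_s"].to_numpy()
    t_end = t_pos[-1] + 1.0 / cfg.position_rate
    n = int(t_end * cfg.lfp_rate)
    t = np.arange(n) / cfg.lfp_rate
    idx = np.clip(np.searchsorted(t_pos, t, side="right") - 1, 0, len(t_pos) - 1)
    phase_of_trial = dict(zip(trials["trial"], trials["phase"]))
    trial_of = position["trial"].to_numpy()[idx]
    beh_phase = np.array([phase_of_trial[tr] for tr in trial_of], dtype=object)
    return t, true_path[idx], true_linpos[idx], speed[idx], beh_phase


def _unit_rate(unit: UnitSpec, maze, grid, theta: ThetaParams, run_thresh=4.0):
    """Instantaneous firing rate (Hz) for one unit on the fine grid."""
    t, path, lin, speed, phase = grid
    rate = np.full(len(t), unit.baseline_rate)
    if unit.peak_rate <= 0:
        return rate
    fields = unit.fields_by_phase(maze)
    theta_phase = 2 * np.pi * theta.freq_hz * t
    running = speed > run_thresh
    for ph in PHASES:
        in_ph = phase == ph
        for fpath, center in fields[ph]:
            m = in_ph & (path == fpath) & running
            if not m.any():
                continue
            d = lin[m] - center
            g = unit.peak_rate * np.exp(-0.5 * (d / unit.sigma) ** 2)
            # precession across the field core (+-1.5 sigma), where the cell
            # actually fires; a wider span dilutes the within-cycle sweep
            span = 1.5 * unit.sigma
            frac = np.clip((d + span) / (2 * span), 0.0, 1.0)
            if theta.precession:
                pref = 2 * np.pi - np.deg2rad(theta.precession_deg) * frac
            else:
                pref = np.pi
            mod = 1.0 + theta.mod_depth * np.cos(theta_phase[m] - pref)
            rate[m] = unit.baseline_rate + g * mod
    return rate


def _thin_spikes(rate, t, dt, rng, refractory):
    p = rate * dt
    hits = rng.random(len(rate)) < p
    st = t[hits]
    return _apply_refractory(st, refractory)


def _apply_refractory(st, refractory):
    if len(st) == 0:
        return st
    keep = [st[0]]
    for s in st[1:]:
        if s - keep[-1] >= refractory:
            keep.append(s)
    return np.asarray(keep)


def simulate_spikes(
    maze: MazeSpec,
    position: pd.DataFrame,
    true_path: np.ndarray,
    true_linpos: np.ndarray,
    speed: np.ndarray,
    trials: pd.DataFrame,
    units: list[UnitSpec],
    config: SimConfig = None,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Inhomogeneous-Poisson spikes: Gaussian place tuning x theta modulation.

    Phase precession advances each unit's preferred theta phase linearly
    across its field span; disabled via ``config.theta.precession = False``.
    """
    cfg = config or SimConfig()
    if not units:
        raise SimulationError("at least one unit required")
    rng = np.random.default_rng(seed)
    grid = _fine_grid(position, true_path, true_linpos, speed, trials, cfg)
    t = grid[0]
    dt = 1.0 / cfg.lfp_rate
    spikes = {}
    for unit in units:
        rate = _unit_rate(unit, maze, grid, cfg.theta)
        spikes[unit.unit_id] = _thin_spikes(rate, t, dt, rng, cfg.refractory_s)
    return spikes


# --------------------------------------------------------------------------
# replay schedule + LFP
# --------------------------------------------------------------------------

def default_replay_content(phase: str, learning_third: int, rng) -> tuple[str, str]:
    """Draw (path, direction) mirroring the programmed content switch.

    Pre: previously-rewarded route.  Learning thirds 1-2: mostly the
    trial-and-error detour {G-C2, C2-G}.  Learning third 3 and post: mostly
    the efficient novel path S-C2.
    """
    if phase == "pre":
        probs = {"S-C1": 0.45, "C1-G": 0.45, "S-C2": 0.04, "G-C2": 0.03, "C2-G": 0.03}
    elif phase == "learning" and learning_third < 3:
        probs = {"G-C2": 0.4, "C2-G": 0.35, "S-C1": 0.1, "C1-G": 0.1, "S-C2": 0.05}
    elif phase == "learning":
        probs = {"S-C2": 0.6, "G-C2": 0.15, "C2-G": 0.15, "S-C1": 0.05, "C1-G": 0.05}
    else:
        probs = {"S-C2": 0.5, "C2-G": 0.35, "S-C1": 0.05, "C1-G": 0.05, "G-C2": 0.05}
    paths = list(probs)
    path = paths[rng.choice(len(paths), p=np.array(list(probs.values())))]
    direction = "forward" if rng.random() < 0.55 else "reverse"
    return path, direction


def make_replay_schedule(
    pauses: pd.DataFrame,
    trials: pd.DataFrame,
    maze: MazeSpec,
    config: SimConfig = None,
    seed: int = 0,
    content_fn=default_replay_content,
) -> list[dict]:
    """One candidate replay per pause (with configured probability)."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    phase_of_trial = dict(zip(trials["trial"], trials["phase"]))
    learn_trials = trials.loc[trials["phase"] == "learning", "trial"].to_numpy()
    schedule = []
    for _, row in pauses.iterrows():
        if rng.random() > cfg.replay_prob_per_pause:
            continue
        phase = phase_of_trial[row["trial"]]
        third = 1
        if phase == "learning" and len(learn_trials):
            pos = np.searchsorted(learn_trials, row["trial"], side="right")
            third = min(3, 1 + (3 * (pos - 1)) // max(1, len(learn_trials)))
        path, direction = content_fn(phase, third, rng)
        dur = maze.paths[path].length / (cfg.run_speed * cfg.replay_compression)
        dur = float(np.clip(dur, 0.05, 0.4))
        slack = (row["t_end"] - row["t_start"]) - dur - 0.2
        if slack <= 0:
            continue
        t_start = row["t_start"] + 0.1 + rng.random() * slack
        schedule.append({
            "t_start": float(t_start), "duration": dur, "path": path,
            "direction": direction, "trial": int(row["trial"]),
            "phase": phase, "learning_third": third,
            "location": row["location"], "area": row["area"],
            "compression": cfg.replay_compression,
        })
    return schedule


def replay_spike_times(
    event: dict,
    units: list[UnitSpec],
    maze: MazeSpec,
    rng,
    n_spikes: int = 2,
    jitter: float = 0.004,
) -> dict[int, np.ndarray]:
    """Spike times for one replay: units ordered by field position on the path,
    compressed into the event window; time-mirrored for reverse events."""
    path = event["path"]
    L = maze.paths[path].length
    t0, dur = event["t_start"], event["duration"]
    out = {}
    for unit in units:
        fields = unit.fields_by_phase(maze)[event["phase"]]
        pos = [c for p, c in fields if p == path and 0 <= c <= L]
        if not pos:
            continue
        frac = pos[0] / L
        if event["direction"] == "reverse":
            frac = 1.0 - frac
        base = t0 + frac * dur
        st = base + rng.normal(0, jitter, n_spikes)
        out[unit.unit_id] = np.sort(np.clip(st, t0, t0 + dur - 1e-4))
    return out


def _pink_noise(n, rng):
    """1/f-amplitude noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]
    spec /= np.sqrt(freqs)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def simulate_lfp_and_replays(
    maze: MazeSpec,
    position: pd.DataFrame,
    speed: np.ndarray,
    pauses: pd.DataFrame,
    spikes: dict[int, np.ndarray],
    schedule: list[dict],
    units: list[UnitSpec],
    config: SimConfig = None,
    seed: int = 0,
) -> tuple[np.ndarray, dict[int, np.ndarray], list[dict]]:
    """Synthesize LFP and merge replay spikes into the spike trains.

    LFP = pink noise + theta while running + ripple-band bursts at scheduled
    events.  Returns (lfp, updated spikes, schedule annotated with
    participating units).
    """
    from scipy.signal import butter, sosfiltfilt

    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    t_pos = position["t_s"].to_numpy()
    dur_total = t_pos[-1] + 1.0 / cfg.position_rate
    n = int(dur_total * cfg.lfp_rate)
    t = np.arange(n) / cfg.lfp_rate

    # validate schedule against immobility pauses
    for ev in schedule:
        inside = (
            (pauses["t_start"] <= ev["t_start"])
            & (pauses["t_end"] >= ev["t_start"] + ev["duration"])
        ).any()
        if not inside:
            raise SimulationError(
                f"replay at t={ev['t_start']:.2f}s falls outside immobility"
            )

    lfp = _pink_noise(n, rng)
    # theta during running, smoothly gated by speed
    idx = np.clip(np.searchsorted(t_pos, t, side="right") - 1, 0, len(t_pos) - 1)
    gate = (speed[idx] > 4.0).astype(float)
    k = int(0.25 * cfg.lfp_rate)
    if k > 1:
        gate = np.convolve(gate, np.ones(k) / k, mode="same")
    lfp = lfp + 1.5 * gate * np.sin(2 * np.pi * cfg.theta.freq_hz * t)

    # ripple bursts scaled against the background's own ripple-band SD
    nyq = cfg.lfp_rate / 2
    sos = butter(3, [150 / nyq, min(250, nyq * 0.95) / nyq], btype="band", output="sos")
    band_sd = float(sosfiltfilt(sos, lfp).std())
    new_spikes = {uid: [st] for uid, st in spikes.items()}
    annotated = []
    for ev in schedule:
        i0 = int(ev["t_start"] * cfg.lfp_rate)
        i1 = min(n, i0 + int(ev["duration"] * cfg.lfp_rate))
        win = np.hanning(i1 - i0)
        tt = t[i0:i1]
        lfp[i0:i1] += cfg.ripple_snr * band_sd * win * np.sin(
            2 * np.pi * cfg.ripple_freq_hz * tt
        )
        ev_spikes = replay_spike_times(
            ev, units, maze, rng,
            n_spikes=cfg.replay_spikes_per_unit, jitter=cfg.replay_jitter_s,
        )
        for uid, st in ev_spikes.items():
            new_spikes[uid].append(st)
        ev = dict(ev)
        ev["participating_units"] = sorted(ev_spikes)
        annotated.append(ev)

    merged = {}
    for uid, parts in new_spikes.items():
        st = np.sort(np.concatenate(parts))
        merged[uid] = _apply_refractory(st, cfg.refractory_s)
    return lfp, merged, annotated


# --------------------------------------------------------------------------
# end-to-end
# --------------------------------------------------------------------------

def simulate_session(
    config: SimConfig = None,
    maze: MazeSpec = None,
    units: list[UnitSpec] = None,
    schedule: list[dict] = None,
    seed: int = None,
) -> Session:
    """Generate a complete annotated session from one seed."""
    cfg = config or SimConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    maze = maze or make_maze()
    units = units if units is not None else default_units(maze=maze, seed=cfg.seed)
    root = np.random.SeedSequence(cfg.seed)
    s_beh, s_spk, s_sched, s_lfp = [int(s.generate_state(1)[0]) for s in root.spawn(4)]

    position, trials, pauses, tpath, tlin, speed, phases = simulate_behavior(
        maze, cfg.n_trials_per_phase, cfg, seed=s_beh
    )
    if units:
        spikes = simulate_spikes(
            maze, position, tpath, tlin, speed, trials, units, cfg, seed=s_spk
        )
    else:  # behavior-only session; downstream spike analyses will reject it
        spikes = {}
    if schedule is None:
        schedule = make_replay_schedule(pauses, trials, maze, cfg, seed=s_sched)
    lfp, spikes, schedule = simulate_lfp_and_replays(
        maze, position, speed, pauses, spikes, schedule, units, cfg, seed=s_lfp
    )
    n_pre, n_learn, n_post = cfg.n_trials_per_phase
    gt = GroundTruth(
        cell_types={u.unit_id: u.cell_type for u in units},
        field_centers={u.unit_id: u.fields_by_phase(maze) for u in units},
        replay_schedule=schedule,
        learning_point_trial=n_pre + n_learn + 1,
        reward_replacement_trial=n_pre + 1,
        phase_of_trial=list(phases),
    )
    return Session(
        maze=maze, spikes=spikes, position=position, speed=speed,
        lfp=lfp, lfp_rate=cfg.lfp_rate, trials=trials, units=list(units),
        ground_truth=gt, true_path=tpath, true_linpos=tlin, pauses=pauses,
    )
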