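"""Spatial tuning: linearized rate maps, place fields, joint classification,
and population-vector correlation matrices."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .linearize import compute_speed, linearize_position, spike_path_positions
from .maze import CHECKPOINT_PATHS, FIELD_PATHS, GOAL_PATHS, MazeSpec, PATH_LABELS

#: analogous-path pairs for context-dependent correspondence
ANALOGOUS_PAIRS = tuple(
    [(a, b) for i, a in enumerate(CHECKPOINT_PATHS)
     for b in CHECKPOINT_PATHS[i + 1:]]
    + [(a, b) for i, a in enumerate(GOAL_PATHS) for b in GOAL_PATHS[i + 1:]]
)


class TuningError(ValueError):
    pass


@dataclass
class RateMap:
    unit_id: int
    phase: str
    path: str
    bin_edges: np.ndarray          # cm
    occupancy_s: np.ndarray
    rate_hz: np.ndarray            # NaN where occupancy below mask
    smoothing_bins: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PlaceField:
    unit_id: int
    phase: str
    path: str
    peak_rate_hz: float
    peak_pos_cm: float
    start_cm: float
    end_cm: float


def compute_rate_map(
    spike_times: np.ndarray,
    position: pd.DataFrame,
    lin: pd.DataFrame,
    path: str,
    path_length: float,
    speed: Optional[np.ndarray] = None,
    speed_threshold: float = 4.0,
    bin_cm: float = 2.0,
    smooth_cm: float = 5.0,
    min_occupancy_s: float = 0.1,
    unit_id: int = -1,
    phase: str = "",
    sample_mask: Optional[np.ndarray] = None,
) -> RateMap:
    """Occupancy-normalized, Gaussian-smoothed linearized rate map.

    rate = smoothed(spike count) / smoothed(occupancy); bins whose raw
    occupancy is below ``min_occupancy_s`` are masked to NaN.
    """
    t = position["t_s"].to_numpy()
    if speed is None:
        speed = compute_speed(position)
    dt = np.median(np.diff(t)) if len(t) > 1 else 0.0
    mask = (lin["path"].to_numpy() == path) & (speed > speed_threshold)
    if sample_mask is not None:
        mask &= sample_mask
    edges = np.arange(0.0, path_length + bin_cm, bin_cm)
    occ, _ = np.histogram(lin["linpos_cm"].to_numpy()[mask], bins=edges)
    occ = occ * dt
    if occ.sum() <= 0:
        raise TuningError(f"no occupancy on path {path}")

    sp = spike_path_positions(np.asarray(spike_times, dtype=float), position, lin)
    smask = (sp["path"].to_numpy() == path)
    smask &= speed[sp["sample"].to_numpy()] > speed_threshold
    if sample_mask is not None:
        smask &= sample_mask[sp["sample"].to_numpy()]
    cnt, _ = np.histogram(sp["linpos_cm"].to_numpy()[smask], bins=edges)

    sigma_bins = smooth_cm / bin_cm
    occ_s = gaussian_filter1d(occ.astype(float), sigma_bins, mode="constant")
    cnt_s = gaussian_filter1d(cnt.astype(float), sigma_bins, mode="constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ_s > 0, cnt_s / occ_s, 0.0)
    rate[occ < min_occupancy_s] = np.nan
    return RateMap(unit_id=unit_id, phase=phase, path=path, bin_edges=edges,
                   occupancy_s=occ, rate_hz=rate, smoothing_bins=sigma_bins)


def detect_fields(
    rate_map: RateMap,
    peak_floor_hz: float = 3.0,
    field_fraction: float = 0.2,
    abs_floor_hz: float = 1.0,
    min_bins: int = 3,
    max_extent_fraction: float = 0.6,
) -> list[PlaceField]:
    """Maximal contiguous runs above max(fraction x peak, absolute floor).

    Runs wider than ``max_extent_fraction`` of the map are rejected — those
    are spatially untuned elevations, not fields.
    """
    rate = np.nan_to_num(rate_map.rate_hz)
    peak = rate.max() if rate.size else 0.0
    if peak < peak_floor_hz:
        return []
    thr = max(field_fraction * peak, abs_floor_hz)
    above = rate >= thr
    fields = []
    centers = rate_map.centers
    i = 0
    while i < len(above):
        if not above[i]:
            i += 1
            continue
        j = i
        while j < len(above) and above[j]:
            j += 1
        if min_bins <= j - i <= max_extent_fraction * len(above):
            seg = rate[i:j]
            if seg.max() >= peak_floor_hz:
                k = i + int(np.argmax(seg))
                fields.append(PlaceField(
                    unit_id=rate_map.unit_id, phase=rate_map.phase,
                    path=rate_map.path, peak_rate_hz=float(seg.max()),
                    peak_pos_cm=float(centers[k]),
                    start_cm=float(rate_map.bin_edges[i]),
                    end_cm=float(rate_map.bin_edges[j]),
                ))
        i = j
    return fields


def compute_session_rate_maps(
    session,
    phases: Sequence[str] = ("pre", "learning", "post"),
    paths: Sequence[str] = FIELD_PATHS,
    speed_threshold: float = 4.0,
    bin_cm: float = 2.0,
    smooth_cm: float = 5.0,
    trials_subset: Optional[Sequence[int]] = None,
) -> dict[tuple[int, str, str], RateMap]:
    """Rate maps for every (unit, phase, path) with occupancy."""
    lin = linearize_position(session.position, session.maze)
    speed = session.speed
    phase_of = dict(zip(session.trials["trial"], session.trials["phase"]))
    trial_arr = session.position["trial"].to_numpy()
    maps = {}
    for ph in phases:
        ph_trials = {
            tr for tr, p in phase_of.items()
            if p == ph and (trials_subset is None or tr in trials_subset)
        }
        if not ph_trials:
            continue
        pmask = np.isin(trial_arr, list(ph_trials))
        for path in paths:
            L = session.maze.paths[path].length
            for uid, st in session.spikes.items():
                try:
                    rm = compute_rate_map(
                        st, session.position, lin, path, L, speed=speed,
                        speed_threshold=speed_threshold, bin_cm=bin_cm,
                        smooth_cm=smooth_cm, unit_id=uid, phase=ph,
                        sample_mask=pmask,
                    )
                except TuningError:
                    continue
                maps[(uid, ph, path)] = rm
    return maps


def trial_path_histograms(
    session,
    paths: Sequence[str] = FIELD_PATHS,
    bin_cm: float = 2.0,
    speed_threshold: float = 4.0,
):
    """Raw per-(trial, path) occupancy and per-unit spike-count histograms.

    Enables cheap leave-one-out refits: maps for any trial subset are sums of
    these histograms.  Returns (occ, cnt, edges_by_path, unit_ids) where
    ``occ[(trial, path)]`` is seconds per bin and ``cnt[(trial, path)]`` is a
    (n_units, n_bins) count matrix.
    """
    lin = linearize_position(session.position, session.maze)
    speed = session.speed
    t = session.position["t_s"].to_numpy()
    dt = np.median(np.diff(t))
    trial_arr = session.position["trial"].to_numpy()
    path_arr = lin["path"].to_numpy()
    pos_arr = lin["linpos_cm"].to_numpy()
    unit_ids = sorted(session.spikes)
    edges_by_path = {
        p: np.arange(0.0, session.maze.paths[p].length + bin_cm, bin_cm)
        for p in paths
    }
    # spike sample assignment once per unit
    spk_sample = {
        uid: np.clip(np.searchsorted(t, st) - 1, 0, len(t) - 1)
        for uid, st in session.spikes.items()
    }
    occ, cnt = {}, {}
    moving = speed > speed_threshold
    for trial in session.trials["trial"]:
        tmask = trial_arr == trial
        for path in paths:
            m = tmask & (path_arr == path) & moving
            edges = edges_by_path[path]
            occ[(trial, path)] = np.histogram(pos_arr[m], bins=edges)[0] * dt
            block = np.zeros((len(unit_ids), len(edges) - 1))
            for k, uid in enumerate(unit_ids):
                si = spk_sample[uid]
                sm = m[si]
                if sm.any():
                    block[k] = np.histogram(pos_arr[si[sm]], bins=edges)[0]
            cnt[(trial, path)] = block
    return occ, cnt, edges_by_path, unit_ids


def ratemap_from_histograms(
    occ: np.ndarray,
    cnt: np.ndarray,
    edges: np.ndarray,
    smooth_cm: float = 5.0,
    min_occupancy_s: float = 0.1,
    unit_id: int = -1,
    phase: str = "",
    path: str = "",
) -> RateMap:
    """Smoothed occupancy-normalized map from raw histograms."""
    bin_cm = edges[1] - edges[0]
    sigma = smooth_cm / bin_cm
    occ_s = gaussian_filter1d(occ.astype(float), sigma, mode="constant")
    cnt_s = gaussian_filter1d(cnt.astype(float), sigma, mode="constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ_s > 0, cnt_s / occ_s, 0.0)
    rate[occ < min_occupancy_s] = np.nan
    return RateMap(unit_id=unit_id, phase=phase, path=path, bin_edges=edges,
                   occupancy_s=occ, rate_hz=rate, smoothing_bins=sigma)


@dataclass
class FieldPairClass:
    unit_id: int
    phase_a: str
    phase_b: str
    label: str                     # stable / context-dependent / on / off / unrelated
    field_a: Optional[PlaceField] = None
    field_b: Optional[PlaceField] = None


def _analogous(pa: str, pb: str) -> bool:
    return (pa, pb) in ANALOGOUS_PAIRS or (pb, pa) in ANALOGOUS_PAIRS


def joint_classify(
    fields_a: Sequence[PlaceField],
    fields_b: Sequence[PlaceField],
    path_lengths: dict[str, float],
    tolerance_cm: float = 10.0,
) -> list[FieldPairClass]:
    """Classify place-field pairs across two phases for one unit.

    stable: same path, peak positions within tolerance.  context-dependent:
    analogous paths with matching destination-aligned positions (distance to
    the segment end).  Fields with no counterpart: 'off' (phase A only) or
    'on' (phase B only).
    """
    known = set(path_lengths)
    for f in list(fields_a) + list(fields_b):
        if f.path not in known:
            raise TuningError(f"unknown path label {f.path!r}")
    out = []
    matched_a, matched_b = set(), set()
    for i, fa in enumerate(fields_a):
        for j, fb in enumerate(fields_b):
            uid = fa.unit_id
            if fa.path == fb.path and abs(fa.peak_pos_cm - fb.peak_pos_cm) <= tolerance_cm:
                out.append(FieldPairClass(uid, fa.phase, fb.phase, "stable", fa, fb))
                matched_a.add(i)
                matched_b.add(j)
            elif _analogous(fa.path, fb.path):
                da = path_lengths[fa.path] - fa.peak_pos_cm
                db = path_lengths[fb.path] - fb.peak_pos_cm
                if abs(da - db) <= tolerance_cm:
                    out.append(FieldPairClass(
                        uid, fa.phase, fb.phase, "context-dependent", fa, fb))
                    matched_a.add(i)
                    matched_b.add(j)
    for i, fa in enumerate(fields_a):
        if i not in matched_a:
            out.append(FieldPairClass(fa.unit_id, fa.phase, fa.phase, "off", fa, None))
    for j, fb in enumerate(fields_b):
        if j not in matched_b:
            out.append(FieldPairClass(fb.unit_id, fb.phase, fb.phase, "on", None, fb))
    return out


def classify_units(
    maps: dict[tuple[int, str, str], RateMap],
    phases: Sequence[str] = ("pre", "learning", "post"),
    path_lengths: dict[str, float] = None,
    tolerance_cm: float = 10.0,
    **field_kwargs,
) -> pd.DataFrame:
    """Per-unit summary labels from joint classification over all phase pairs.

    Precedence: 'context-dependent' when any field pair (across phases, or
    across different paths within one phase) matches at corresponding
    destination-aligned positions on analogous paths and the unit fires on
    more than one path; else 'stable' on any cross-phase same-path match;
    else 'off'/'on' when fields exist only before/only after the phase
    boundary; 'nonplace' with no fields anywhere.
    """
    if path_lengths is None:
        raise TuningError("path_lengths required")
    units = sorted({uid for uid, _, _ in maps})
    phases = [ph for ph in phases if any(k[1] == ph for k in maps)]
    rows = []
    for uid in units:
        fields = {
            ph: [f for (u, p, _), rm in maps.items() if u == uid and p == ph
                 for f in detect_fields(rm, **field_kwargs)]
            for ph in phases
        }
        any_stable = any_context = False
        for i, pa in enumerate(phases):
            for pb in phases[i:]:
                pairs = joint_classify(fields[pa], fields[pb], path_lengths,
                                       tolerance_cm)
                for pr in pairs:
                    if pr.label == "context-dependent":
                        any_context = True
                    elif pr.label == "stable" and pa != pb:
                        any_stable = True
        all_fields = [f for fl in fields.values() for f in fl]
        n_paths = len({f.path for f in all_fields})
        pre_only = bool(fields.get(phases[0])) and not any(
            fields[ph] for ph in phases[1:])
        later_only = not fields.get(phases[0]) and any(
            fields[ph] for ph in phases[1:])
        if not all_fields:
            label = "nonplace"
        elif any_context and n_paths > 1:
            label = "context-dependent"
        elif any_stable:
            label = "stable"
        elif pre_only:
            label = "off"
        elif later_only:
            label = "on"
        else:
            label = "unrelated"
        rows.append({
            "unit_id": uid, "label": label,
            "any_stable": int(any_stable), "any_context": int(any_context),
            "n_fields": len(all_fields), "n_paths": n_paths,
        })
    return pd.DataFrame(rows)


def population_vector_matrix(
    maps: dict[tuple[int, str, str], RateMap],
    phases: Sequence[str],
    paths: Sequence[str] = FIELD_PATHS,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Pearson correlation between population rate vectors at all location bins.

    Returns (matrix, state table with phase/path/bin columns).  Bins where a
    population vector is constant are NaN-masked in the matrix.
    """
    units = sorted({uid for uid, _, _ in maps})
    if len(units) < 2:
        raise TuningError("need >= 2 units")
    cols, meta = [], []
    for ph in phases:
        for path in paths:
            sample = next(
                (maps[(u, ph, path)] for u in units if (u, ph, path) in maps), None)
            if sample is None:
                continue
            nbin = len(sample.centers)
            block = np.zeros((len(units), nbin))
            for k, u in enumerate(units):
                rm = maps.get((u, ph, path))
                if rm is not None:
                    block[k] = np.nan_to_num(rm.rate_hz)
            cols.append(block)
            for b in range(nbin):
                meta.append({"phase": ph, "path": path, "bin": b,
                             "pos_cm": sample.centers[b]})
    pv = np.concatenate(cols, axis=1)  # units x states
    sd = pv.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (pv - pv.mean(axis=0)) / sd
    z[:, sd == 0] = np.nan
    corr = (z.T @ z) / len(units)
    return corr, pd.DataFrame(meta)
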