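"""End-to-end orchestration: generate -> analyze -> report, reproducibly."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import decoding, events, io, stats, theta, tuning
from .maze import FIELD_PATHS, make_maze
from .synth import default_units, simulate_session


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return None if np.isnan(o) else float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def run_pipeline(
    config: dict = None,
    outdir: str | Path = "run",
    seed: int = 0,
    n_units: dict = None,
    write_session: bool = True,
) -> dict:
    """Run the full synthetic pipeline; returns the machine-readable report.

    Any stage failure raises :class:`StageError` naming the stage; outputs of
    completed stages remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = dict(config or {})
    config.setdefault("seed", seed)
    sim_cfg = io.config_to_simconfig(dict(config))
    report = {"seed": sim_cfg.seed, "config": asdict(sim_cfg),
              "python": platform.python_version()}
    io.dump_config(json.loads(json.dumps(asdict(sim_cfg))),
                   outdir / "config.json")
    manifest = ["config.json"]

    stage = "simulate"
    try:
        maze = make_maze()
        # stable fields tile every path so replay content is separable;
        # override stable_paths via n_units for classification studies
        unit_kwargs = {"stable_paths": FIELD_PATHS}
        unit_kwargs.update(n_units or {})
        units = default_units(maze=maze, seed=sim_cfg.seed, **unit_kwargs)
        session = simulate_session(sim_cfg, maze=maze, units=units)
        if write_session:
            io.write_session(session, outdir / "session")
            manifest.append("session/")
    except Exception as e:  # noqa: BLE001 - re-tagged with the stage name
        raise StageError(stage, e)

    stage = "behavior"
    try:
        summary = beh.summarize_trials(session.position, session.trials, maze)
        summary.to_csv(outdir / "trial_summary.tsv", sep="\t", index=False)
        manifest.append("trial_summary.tsv")
        labels = [row.split(",") if row else [] for row in summary["labels"]]
        lc = beh.learning_point(
            labels, session.ground_truth.reward_replacement_trial)
        report["behavior"] = {
            "learning_point": lc.learning_point,
            "true_learning_point": session.ground_truth.learning_point_trial,
            "path_proportions": beh.path_proportions(labels).to_dict(),
        }
    except Exception as e:
        raise StageError(stage, e)

    stage = "tuning"
    try:
        if not session.spikes:
            raise ValueError("no units to analyze")
        maps = tuning.compute_session_rate_maps(session)
        path_lengths = {p: maze.paths[p].length for p in FIELD_PATHS}
        classes = tuning.classify_units(maps, path_lengths=path_lengths)
        classes.to_csv(outdir / "unit_classes.tsv", sep="\t", index=False)
        manifest.append("unit_classes.tsv")
        truth = session.ground_truth.cell_types
        merged = classes.assign(
            truth=classes["unit_id"].map(truth))
        for lab in ("stable", "context-dependent"):
            sub = merged[merged["truth"] == lab]
            report.setdefault("tuning", {})[f"recovery_{lab}"] = (
                float((sub["label"] == lab).mean()) if len(sub) else None)
    except Exception as e:
        raise StageError(stage, e)

    stage = "decode"
    try:
        err = decoding.loo_position_error(session, bin_s=0.2)
        err.to_csv(outdir / "decoding_errors.tsv", sep="\t", index=False)
        manifest.append("decoding_errors.tsv")
        report["decoding"] = {
            "median_error_cm": float(err["error_cm"].median()),
            "n_bins": int(len(err)),
        }
    except Exception as e:
        raise StageError(stage, e)

    stage = "theta"
    try:
        pos_t = session.position["t_s"].to_numpy()
        cycles = theta.detect_theta_cycles(
            session.lfp, session.lfp_rate, session.speed, pos_t)
        enc = decoding.fit_encoder(maps, ("pre", "learning", "post"))
        ttab = theta.score_table(session, enc, cycles, min_cycles=5)
        ttab.to_csv(outdir / "theta_scores.tsv", sep="\t", index=False)
        manifest.append("theta_scores.tsv")
        report["theta"] = {"n_cycles": cycles.n_cycles}
    except Exception as e:
        raise StageError(stage, e)

    stage = "replay"
    try:
        swr = events.detect_swr(session.lfp, session.lfp_rate, session.speed,
                                pos_t)
        cand = events.detect_synchronous_events(
            session.spikes, session.speed, pos_t, swr)
        evs = events.score_events(
            cand, session.spikes, enc,
            {p: maze.paths[p].length for p in FIELD_PATHS},
            n_shuffles=100, repz_shuffles=100, seed=sim_cfg.seed,
        )
        events.assign_event_areas(evs, session.pauses)
        etab = events.events_table(evs)
        etab.to_csv(outdir / "events.tsv", sep="\t", index=False)
        manifest.append("events.tsv")
        rate_tab = events.event_rate_maps(etab, session.pauses, session.trials)
        rate_tab.to_csv(outdir / "event_rates.tsv", sep="\t", index=False)
        manifest.append("event_rates.tsv")
        # represented-path majority per learning third vs the schedule
        thirds = stats.learning_thirds(session.trials)
        trial_of = _event_trials(etab, session.trials)
        majors, sched_majors = {}, {}
        sched = pd.DataFrame(session.ground_truth.replay_schedule)
        for third in (1, 2, 3):
            tr_in = [t for t, th in thirds.items() if th == third]
            sub = etab[np.isin(trial_of, tr_in) & etab["represented_path"].notna()]
            majors[third] = (sub["represented_path"].mode().iloc[0]
                             if len(sub) else None)
            ssub = sched[(sched["phase"] == "learning")
                         & (sched["learning_third"] == third)]
            sched_majors[third] = (ssub["path"].mode().iloc[0]
                                   if len(ssub) else None)
        report["replay"] = {
            "n_swr": int(len(swr)),
            "n_events": int(len(evs)),
            "n_sequential": int(etab["is_sequential"].sum()) if len(etab) else 0,
            "majority_per_third": majors,
            "schedule_majority_per_third": sched_majors,
        }
    except Exception as e:
        raise StageError(stage, e)

    stage = "stats"
    try:
        rate_tab = rate_tab.assign(rat="synthetic")
        fit = stats.fit_rate_model(
            rate_tab,
            seed=sim_cfg.seed, n_warmup=400, n_samples=400, n_chains=2)
        fit.summary.to_csv(outdir / "rate_model_summary.tsv", sep="\t",
                           index=False)
        manifest.append("rate_model_summary.tsv")
        report["stats"] = {
            "converged": bool(fit.converged),
            "pct_change": {
                ph: fit.summary.set_index("parameter").loc[
                    f"pct_change_{ph}", "mean"]
                for ph in ("learning", "post")
                if f"pct_change_{ph}" in set(fit.summary["parameter"])
            },
        }
    except Exception as e:
        raise StageError(stage, e)

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default))
    manifest.append("report.json")
    (outdir / "manifest.txt").write_text("\n".join(manifest) + "\n")
    return report


def _event_trials(etab: pd.DataFrame, trials: pd.DataFrame) -> np.ndarray:
    """Trial index containing each event onset."""
    if not len(etab):
        return np.array([], dtype=int)
    starts = trials["t_start"].to_numpy()
    order = np.argsort(starts)
    idx = np.clip(np.searchsorted(starts[order], etab["t_start"].to_numpy(),
                                  side="right") - 1, 0, len(starts) - 1)
    return trials["trial"].to_numpy()[order][idx]
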