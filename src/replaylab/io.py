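"""Plain-text readers/writers for session streams and run configs.

All coordinates are cm, times seconds with origin at session start.  Formats:
spikes and trials as TSV, position as TSV, LFP as TSV (t_s, lfp) with a JSON
sidecar carrying the sample rate, ground truth and configs as JSON/YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .maze import MazeSpec, make_maze
from .synth import GroundTruth, Session, SimConfig, ThetaParams, UnitSpec


def write_session(session: Session, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        {"unit_id": uid, "t_s": t}
        for uid in sorted(session.spikes) for t in session.spikes[uid]
    ]
    pd.DataFrame(rows, columns=["unit_id", "t_s"]).to_csv(
        outdir / "spikes.tsv", sep="\t", index=False)
    session.position.to_csv(outdir / "position.tsv", sep="\t", index=False)
    session.trials.to_csv(outdir / "trials.tsv", sep="\t", index=False)
    session.pauses.to_csv(outdir / "pauses.tsv", sep="\t", index=False)
    lfp_df = pd.DataFrame({
        "t_s": np.arange(len(session.lfp)) / session.lfp_rate,
        "lfp": session.lfp,
    })
    lfp_df.to_csv(outdir / "lfp.tsv", sep="\t", index=False,
                  float_format="%.6f")
    (outdir / "lfp.json").write_text(json.dumps(
        {"rate_hz": session.lfp_rate, "units": "arbitrary"}, indent=2))
    (outdir / "maze.json").write_text(json.dumps(session.maze.to_dict(),
                                                 indent=2))
    gt = session.ground_truth
    (outdir / "ground_truth.json").write_text(json.dumps({
        "cell_types": {str(k): v for k, v in gt.cell_types.items()},
        "field_centers": {str(k): v for k, v in gt.field_centers.items()},
        "replay_schedule": gt.replay_schedule,
        "learning_point_trial": gt.learning_point_trial,
        "reward_replacement_trial": gt.reward_replacement_trial,
        "phase_of_trial": gt.phase_of_trial,
    }, indent=2, default=float))
    units = [asdict(u) for u in session.units]
    (outdir / "units.json").write_text(json.dumps(units, indent=2))
    return outdir


def read_session(indir: str | Path) -> Session:
    indir = Path(indir)
    maze = MazeSpec.from_dict(json.loads((indir / "maze.json").read_text()))
    spikes_df = pd.read_csv(indir / "spikes.tsv", sep="\t")
    spikes = {
        int(uid): np.sort(grp["t_s"].to_numpy())
        for uid, grp in spikes_df.groupby("unit_id")
    }
    position = pd.read_csv(indir / "position.tsv", sep="\t")
    trials = pd.read_csv(indir / "trials.tsv", sep="\t")
    pauses = pd.read_csv(indir / "pauses.tsv", sep="\t")
    lfp_meta = json.loads((indir / "lfp.json").read_text())
    lfp = pd.read_csv(indir / "lfp.tsv", sep="\t")["lfp"].to_numpy()
    gt_raw = json.loads((indir / "ground_truth.json").read_text())
    gt = GroundTruth(
        cell_types={int(k): v for k, v in gt_raw["cell_types"].items()},
        field_centers={
            int(k): {ph: [tuple(f) for f in fl] for ph, fl in v.items()}
            for k, v in gt_raw["field_centers"].items()},
        replay_schedule=gt_raw["replay_schedule"],
        learning_point_trial=gt_raw["learning_point_trial"],
        reward_replacement_trial=gt_raw["reward_replacement_trial"],
        phase_of_trial=gt_raw["phase_of_trial"],
    )
    units = [UnitSpec(**u)
             for u in json.loads((indir / "units.json").read_text())]
    from .linearize import compute_speed

    return Session(
        maze=maze, spikes=spikes, position=position,
        speed=compute_speed(position), lfp=lfp,
        lfp_rate=float(lfp_meta["rate_hz"]), trials=trials, units=units,
        ground_truth=gt, pauses=pauses,
    )


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def config_to_simconfig(cfg: dict) -> SimConfig:
    theta = ThetaParams(**cfg.pop("theta", {}))
    known = {k: v for k, v in cfg.items()
             if k in SimConfig.__dataclass_fields__}
    known.pop("theta", None)
    if "n_trials_per_phase" in known:
        known["n_trials_per_phase"] = tuple(known["n_trials_per_phase"])
    return SimConfig(theta=theta, **known)


def dump_config(cfg: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True))
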