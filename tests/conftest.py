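import warnings

import pytest

import replaylab as rl
from replaylab import tuning
from replaylab.maze import FIELD_PATHS

warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture(scope="session")
def maze():
    return rl.make_maze()


@pytest.fixture(scope="session")
def small_session():
    """Default-population session, small but complete (shared, read-only)."""
    cfg = rl.SimConfig(n_trials_per_phase=(4, 6, 4), pause_median_s=2.0, seed=1)
    return rl.simulate_session(cfg)


@pytest.fixture(scope="session")
def null_session():
    """Same behavior statistics but no injected replays."""
    cfg = rl.SimConfig(n_trials_per_phase=(3, 4, 3), pause_median_s=2.0, seed=3)
    return rl.simulate_session(cfg, schedule=[])


@pytest.fixture(scope="session")
def tiling_session():
    """Stable fields on every path: best replay-content separability."""
    cfg = rl.SimConfig(n_trials_per_phase=(3, 4, 3), pause_median_s=2.0, seed=2)
    units = rl.synth.default_units(
        maze=rl.make_maze(), seed=2, n_stable=40, n_context=0, n_on=0,
        n_off=0, n_nonplace=0, stable_paths=FIELD_PATHS)
    return rl.simulate_session(cfg, units=units)


@pytest.fixture(scope="session")
def small_maps(small_session):
    return tuning.compute_session_rate_maps(small_session)


@pytest.fixture(scope="session")
def path_lengths(maze):
    return {p: maze.paths[p].length for p in FIELD_PATHS}
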