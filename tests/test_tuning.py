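import numpy as np
import pandas as pd
import pytest

import replaylab as rl
from replaylab import tuning
from replaylab.tuning import (
    PlaceField,
    RateMap,
    TuningError,
    compute_rate_map,
    detect_fields,
    joint_classify,
    population_vector_matrix,
)


def _uniform_run(path_length=100.0, n_laps=30, speed=25.0, rate=50.0):
    """Synthetic back-and-forth traversal of one linear path."""
    lap = np.arange(0, path_length, speed / rate)
    pos = np.concatenate([lap] * n_laps)
    t = np.arange(len(pos)) / rate
    position = pd.DataFrame({"t_s": t, "x_cm": pos, "y_cm": 0.0,
                             "trial": 1 + (np.arange(len(pos)) // len(lap))})
    lin = pd.DataFrame({"t_s": t, "path": "S-C1", "linpos_cm": pos,
                        "trial": position["trial"]})
    speed_arr = np.full(len(pos), speed)
    return position, lin, speed_arr


class TestRateMap:
    def test_zero_spikes_zero_map(self):
        position, lin, speed = _uniform_run()
        rm = compute_rate_map(np.array([]), position, lin, "S-C1", 100.0,
                              speed=speed)
        assert np.nanmax(rm.rate_hz) == 0.0
        assert (np.nan_to_num(rm.rate_hz) >= 0).all()

    def test_no_occupancy_rejected(self):
        position, lin, speed = _uniform_run()
        with pytest.raises(TuningError):
            compute_rate_map(np.array([]), position, lin, "C1-G", 100.0,
                             speed=speed)

    def test_uniform_poisson_recovers_lambda(self):
        rng = np.random.default_rng(0)
        position, lin, speed = _uniform_run(n_laps=60)
        T = position["t_s"].iloc[-1]
        lam = 8.0
        spikes = np.sort(rng.uniform(0, T, rng.poisson(lam * T)))
        rm = compute_rate_map(spikes, position, lin, "S-C1", 100.0,
                              speed=speed)
        interior = rm.rate_hz[5:-5]
        assert np.nanmean(interior) == pytest.approx(lam, rel=0.15)

    def test_rate_times_occupancy_matches_spike_count(self):
        rng = np.random.default_rng(1)
        position, lin, speed = _uniform_run(n_laps=40)
        T = position["t_s"].iloc[-1]
        spikes = np.sort(rng.uniform(0, T, 2000))
        rm = compute_rate_map(spikes, position, lin, "S-C1", 100.0,
                              speed=speed)
        recon = np.nansum(rm.rate_hz * rm.occupancy_s)
        assert recon == pytest.approx(len(spikes), rel=0.05)

    def test_synthetic_stable_unit_peak_recovered(self, small_session,
                                                  small_maps):
        unit = small_session.units[0]
        rm = small_maps[(unit.unit_id, "pre", unit.path)]
        peak_pos = rm.centers[np.nanargmax(rm.rate_hz)]
        assert abs(peak_pos - unit.center) <= 2 * 2.0  # 2 bins of 2 cm


def _bump_map(centers_amps, n_bins=50, path="S-C1", phase="pre", unit=0):
    x = np.arange(n_bins) * 2.0 + 1.0
    rate = np.zeros(n_bins)
    for c, a in centers_amps:
        rate += a * np.exp(-0.5 * ((x - c) / 6.0) ** 2)
    return RateMap(unit_id=unit, phase=phase, path=path,
                   bin_edges=np.arange(n_bins + 1) * 2.0,
                   occupancy_s=np.ones(n_bins), rate_hz=rate,
                   smoothing_bins=1.0)


class TestDetectFields:
    def test_flat_below_floor_no_fields(self):
        rm = _bump_map([])
        assert detect_fields(rm) == []

    def test_single_bump_single_field(self):
        rm = _bump_map([(50.0, 10.0)])
        fields = detect_fields(rm, peak_floor_hz=1.0)
        assert len(fields) == 1
        f = fields[0]
        assert f.start_cm <= 50.0 <= f.end_cm
        assert f.peak_rate_hz == pytest.approx(10.0, abs=0.2)

    def test_two_bumps_two_fields(self):
        rm = _bump_map([(20.0, 10.0), (80.0, 8.0)])
        fields = detect_fields(rm, peak_floor_hz=1.0)
        assert len(fields) == 2

    def test_untuned_elevation_rejected(self):
        rm = _bump_map([])
        rm.rate_hz[:] = 5.0  # flat, above every floor
        assert detect_fields(rm) == []


class TestJointClassify:
    def _field(self, path, pos, phase, unit=0):
        return PlaceField(unit_id=unit, phase=phase, path=path,
                          peak_rate_hz=10.0, peak_pos_cm=pos,
                          start_cm=pos - 10, end_cm=pos + 10)

    def test_same_path_same_position_stable(self, path_lengths):
        out = joint_classify([self._field("S-C1", 40, "pre")],
                             [self._field("S-C1", 44, "learning")],
                             path_lengths)
        assert [p.label for p in out] == ["stable"]

    def test_pre_c1_approach_vs_learning_c2_approach_context(self,
                                                             path_lengths):
        # 10 cm before C1 on S-C1 vs 10 cm before C2 on S-C2
        fa = self._field("S-C1", path_lengths["S-C1"] - 10, "pre")
        fb = self._field("S-C2", path_lengths["S-C2"] - 10, "learning")
        out = joint_classify([fa], [fb], path_lengths)
        assert [p.label for p in out] == ["context-dependent"]

    def test_field_in_first_phase_only_off(self, path_lengths):
        out = joint_classify([self._field("S-C1", 40, "pre")], [],
                             path_lengths)
        assert [p.label for p in out] == ["off"]

    def test_unknown_path_rejected(self, path_lengths):
        with pytest.raises(TuningError):
            joint_classify([self._field("X-Y", 40, "pre")], [], path_lengths)

    def test_goal_family_not_matched_to_checkpoint_family(self, path_lengths):
        fa = self._field("C1-G", 50, "pre")
        fb = self._field("S-C2", 50, "learning")
        out = joint_classify([fa], [fb], path_lengths)
        assert {p.label for p in out} == {"off", "on"}


class TestClassifyUnits:
    def test_ground_truth_recovery(self, small_session, small_maps,
                                   path_lengths):
        cls = tuning.classify_units(small_maps, path_lengths=path_lengths)
        truth = small_session.ground_truth.cell_types
        merged = cls.assign(truth=cls["unit_id"].map(truth))
        for lab in ("stable", "context-dependent"):
            sub = merged[merged["truth"] == lab]
            assert (sub["label"] == lab).mean() >= 0.9


class TestPopulationVector:
    def test_within_phase_diagonal_one(self, small_maps):
        corr, meta = population_vector_matrix(small_maps, ["pre"])
        d = np.diag(corr)
        d = d[~np.isnan(d)]
        np.testing.assert_allclose(d, 1.0, atol=1e-9)

    def test_symmetric(self, small_maps):
        corr, _ = population_vector_matrix(small_maps, ["pre", "learning"])
        np.testing.assert_allclose(corr, corr.T, atol=1e-12, equal_nan=True)

    def test_needs_two_units(self, small_maps):
        solo = {k: v for k, v in small_maps.items() if k[0] == 0}
        with pytest.raises(TuningError):
            population_vector_matrix(solo, ["pre"])

    def test_independent_random_maps_uncorrelated(self):
        rng = np.random.default_rng(0)
        n_units, n_bins = 40, 50
        maps = {}
        for u in range(n_units):
            for ph in ("pre", "learning"):
                maps[(u, ph, "S-C1")] = RateMap(
                    unit_id=u, phase=ph, path="S-C1",
                    bin_edges=np.arange(n_bins + 1) * 2.0,
                    occupancy_s=np.ones(n_bins),
                    rate_hz=rng.exponential(5.0, n_bins),
                    smoothing_bins=0.0)
        corr, meta = population_vector_matrix(maps, ["pre", "learning"],
                                              paths=["S-C1"])
        pre = (meta["phase"] == "pre").to_numpy()
        cross = corr[np.ix_(pre, ~pre)]
        assert abs(np.nanmean(cross)) < 3.0 / np.sqrt(n_units)

    def test_context_population_elevates_destination_bins(self,
                                                          tiling_session):
        # build an all-context population and look at analogous-path blocks
        units = [
            rl.synth.UnitSpec(i, "context-dependent",
                              family="checkpoint", center=10.0 + 5 * i,
                              sigma=8.0)
            for i in range(10)
        ]
        cfg = rl.SimConfig(n_trials_per_phase=(3, 4, 3), pause_median_s=1.0,
                           seed=5)
        s = rl.simulate_session(cfg, units=units, schedule=[])
        maps = tuning.compute_session_rate_maps(s)
        corr, meta = population_vector_matrix(maps, ["pre", "learning"])
        # S-C1 bins (pre) vs G-C2 bins (learning): aligned by distance to the
        # destination, so the anti-diagonal region should carry correlation
        a = ((meta["phase"] == "pre") & (meta["path"] == "S-C1")).to_numpy()
        b = ((meta["phase"] == "learning") & (meta["path"] == "G-C2")).to_numpy()
        block = corr[np.ix_(a, b)]
        pos_a = meta.loc[a, "pos_cm"].to_numpy()
        pos_b = meta.loc[b, "pos_cm"].to_numpy()
        # corresponding bins (same distance from destination) vs mismatched
        same = np.abs(pos_a[:, None] - pos_b[None, :]) < 6
        far = np.abs(pos_a[:, None] - pos_b[None, :]) > 30
        assert np.nanmean(block[same]) > np.nanmean(block[far]) + 0.2
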