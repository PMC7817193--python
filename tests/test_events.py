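import numpy as np
import pandas as pd
import pytest

import replaylab as rl
from replaylab import decoding, events, tuning
from replaylab.events import (
    CandidateEvent,
    EventError,
    detect_swr,
    detect_synchronous_events,
    ensemble_correlations,
    event_rate_maps,
    repz,
    reprate,
    sequence_score,
    trajectory_event,
    weighted_corr,
)
from replaylab.maze import FIELD_PATHS


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------

class TestDetectSwr:
    def test_empty_lfp_rejected(self):
        with pytest.raises(EventError):
            detect_swr(np.empty(0), 1250.0, np.zeros(10), np.arange(10.0))

    def test_low_rate_rejected(self):
        with pytest.raises(EventError):
            detect_swr(np.zeros(1000), 500.0, np.zeros(10), np.arange(10.0))

    def test_injected_burst_detected_with_onset_accuracy(self):
        rng = np.random.default_rng(0)
        sr = 1250.0
        n = int(60 * sr)
        lfp = rng.standard_normal(n)
        from scipy.signal import butter, sosfiltfilt

        sos = butter(3, [150 / (sr / 2), 250 / (sr / 2)], btype="band",
                     output="sos")
        band_sd = sosfiltfilt(sos, lfp).std()
        onset = 30.0
        dur = 0.07
        idx = slice(int(onset * sr), int((onset + dur) * sr))
        tt = np.arange(int(dur * sr)) / sr
        lfp[idx] += 5 * band_sd * np.hanning(len(tt)) * np.sin(
            2 * np.pi * 200 * tt)
        pos_t = np.arange(0, 60, 0.02)
        swr = detect_swr(lfp, sr, np.zeros(len(pos_t)), pos_t)
        hits = swr[(swr["t_start"] < onset + dur) & (swr["t_end"] > onset)]
        assert len(hits) == 1
        # the z>3 core rises ~15 ms into the Hanning envelope; allow that
        # plus the +-10 ms detection tolerance
        assert abs(hits["t_core"].iloc[0] - onset) < 0.010 + 0.020

    def test_noise_false_positive_rate(self, null_session):
        pos_t = null_session.position["t_s"].to_numpy()
        swr = detect_swr(null_session.lfp, null_session.lfp_rate,
                         null_session.speed, pos_t)
        assert len(swr) / (null_session.duration / 60) < 1.0


class TestDetectSynchronous:
    def _poisson_population(self, n_units=20, T=120.0, rate=1.0, seed=0):
        rng = np.random.default_rng(seed)
        return {
            u: np.sort(rng.uniform(0, T, rng.poisson(rate * T)))
            for u in range(n_units)
        }

    def test_too_few_units_rejected(self):
        with pytest.raises(EventError):
            detect_synchronous_events({0: np.array([1.0])}, np.zeros(10),
                                      np.arange(10.0))

    def test_homogeneous_population_low_candidate_rate(self):
        spikes = self._poisson_population()
        pos_t = np.arange(0, 120, 0.02)
        out = detect_synchronous_events(spikes, np.zeros(len(pos_t)), pos_t)
        assert len(out) / 120.0 < 0.4  # order-of-magnitude null bound

    def test_injected_burst_found(self):
        spikes = self._poisson_population(n_units=30, rate=0.5, seed=1)
        rng = np.random.default_rng(2)
        for u in range(30):
            spikes[u] = np.sort(np.append(
                spikes[u], 60.0 + rng.uniform(0, 0.08, 2)))
        pos_t = np.arange(0, 120, 0.02)
        out = detect_synchronous_events(spikes, np.zeros(len(pos_t)), pos_t)
        hits = out[(out["t_start"] < 60.1) & (out["t_end"] > 60.0)]
        assert len(hits) == 1
        assert hits["n_units"].iloc[0] >= 25

    def test_event_during_running_excluded(self):
        spikes = self._poisson_population(n_units=30, rate=0.5, seed=1)
        rng = np.random.default_rng(2)
        for u in range(30):
            spikes[u] = np.sort(np.append(
                spikes[u], 60.0 + rng.uniform(0, 0.08, 2)))
        pos_t = np.arange(0, 120, 0.02)
        speed = np.zeros(len(pos_t))
        speed[(pos_t > 59) & (pos_t < 61)] = 30.0  # running at burst time
        out = detect_synchronous_events(spikes, speed, pos_t)
        hits = out[(out["t_start"] < 60.1) & (out["t_end"] > 60.0)]
        assert len(hits) == 0


# --------------------------------------------------------------------------
# weighted correlation
# --------------------------------------------------------------------------

def _brute_weighted_corr(w, t, x):
    num_t = 0.0
    W = w.sum()
    mt = sum(w[i, j] * t[i] for i in range(w.shape[0])
             for j in range(w.shape[1])) / W
    mx = sum(w[i, j] * x[j] for i in range(w.shape[0])
             for j in range(w.shape[1])) / W
    ctx = ctt = cxx = 0.0
    for i in range(w.shape[0]):
        for j in range(w.shape[1]):
            ctx += w[i, j] * (t[i] - mt) * (x[j] - mx)
            ctt += w[i, j] * (t[i] - mt) ** 2
            cxx += w[i, j] * (x[j] - mx) ** 2
    return ctx / np.sqrt(ctt * cxx)


class TestWeightedCorr:
    def test_perfect_diagonal(self):
        w = np.eye(5)
        assert weighted_corr(w) == pytest.approx(1.0, abs=1e-12)

    def test_time_mirror_negates_exactly(self):
        rng = np.random.default_rng(0)
        w = rng.random((6, 8))
        r1 = weighted_corr(w)
        r2 = weighted_corr(w[::-1])
        assert r1 == pytest.approx(-r2, abs=1e-12)

    def test_uniform_weights_match_pearson(self):
        rng = np.random.default_rng(1)
        t = rng.random(5)
        x = rng.random(4)
        w = np.ones((5, 4))
        # with uniform weights over a grid, r reduces to the product-moment
        # correlation of the *marginal* coordinates, which is 0 for a grid
        assert weighted_corr(w, t, x) is None or abs(weighted_corr(w, t, x)) < 1e-9

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            T = int(rng.integers(3, 6))
            X = int(rng.integers(2, 6))
            w = rng.random((T, X))
            t = np.sort(rng.random(T))
            x = rng.random(X)
            got = weighted_corr(w, t, x)
            want = _brute_weighted_corr(w, t, x)
            assert got == pytest.approx(want, abs=1e-12)

    def test_zero_variance_returns_none(self):
        w = np.zeros((4, 4))
        w[:, 2] = 1.0  # all mass at one position
        assert weighted_corr(w) is None

    def test_too_few_bins_rejected(self):
        with pytest.raises(EventError):
            weighted_corr(np.ones((2, 4)))

    def test_equal_weights_pearson_identity(self):
        # explicit oracle: duplicate each (t, x) sample into a weight matrix
        rng = np.random.default_rng(3)
        t = rng.random(6)
        x = rng.random(6)
        w = np.zeros((6, 6))
        w[np.arange(6), np.arange(6)] = 1.0  # delta mass -> paired samples
        got = weighted_corr(w, t, x)
        want = np.corrcoef(t, x)[0, 1]
        assert got == pytest.approx(want, abs=1e-12)


# --------------------------------------------------------------------------
# reprate / repz / sequence scoring
# --------------------------------------------------------------------------

def _posterior_on(path, states, mass_fn, n_t=10):
    """Posterior concentrated by mass_fn(path) over state table."""
    P = np.zeros((n_t, len(states)))
    for j, p in enumerate(states["path"]):
        P[:, j] = mass_fn(p)
    P /= P.sum(axis=1, keepdims=True)
    from replaylab.decoding import DecodedPosterior

    return DecodedPosterior(
        bin_edges=np.arange(n_t + 1) * 0.02, states=states, posterior=P)


@pytest.fixture(scope="module")
def states():
    rows = []
    for p in FIELD_PATHS:
        for b in range(50):
            rows.append({"path": p, "bin": b, "pos_cm": 2.0 * b + 1.0})
    return pd.DataFrame(rows)


class TestReprate:
    def test_all_mass_single_path(self, states):
        post = _posterior_on("S-C2", states,
                             lambda p: 1.0 if p == "S-C2" else 0.0)
        rates, rep = reprate(post)
        assert rates["S-C2"] == pytest.approx(1.0)
        assert rep == "S-C2"
        assert sum(rates.values()) == pytest.approx(1.0)

    def test_uniform_tie_break_deterministic(self, states):
        post = _posterior_on("", states, lambda p: 1.0)
        rates, rep = reprate(post)
        for p in FIELD_PATHS:
            assert rates[p] == pytest.approx(0.2)
        assert rep == sorted(FIELD_PATHS)[0]  # lexicographic tie-break

    def test_empty_posterior_rejected(self):
        with pytest.raises(EventError):
            reprate(None)

    def test_permutation_equivariance(self, states):
        rng = np.random.default_rng(0)
        from replaylab.decoding import DecodedPosterior

        P = rng.random((8, len(states)))
        P /= P.sum(axis=1, keepdims=True)
        post = DecodedPosterior(np.arange(9) * 0.02, states, P)
        rates, _ = reprate(post)
        # relabeling paths permutes the reprate vector identically
        perm = {"S-C1": "C2-G", "C2-G": "S-C1"}
        states2 = states.copy()
        states2["path"] = [perm.get(p, p) for p in states["path"]]
        post2 = DecodedPosterior(np.arange(9) * 0.02, states2, P)
        rates2, _ = reprate(post2)
        assert rates2["C2-G"] == pytest.approx(rates["S-C1"])
        assert rates2["S-C1"] == pytest.approx(rates["C2-G"])


@pytest.fixture(scope="module")
def event_setup(tiling_session):
    s = tiling_session
    maps = tuning.compute_session_rate_maps(s)
    enc = decoding.fit_encoder(maps, ("pre", "learning", "post"))
    ev = s.ground_truth.replay_schedule[0]
    counts, _ = decoding.bin_spikes(
        s.spikes, enc.unit_ids, ev["t_start"],
        ev["t_start"] + ev["duration"], 0.02)
    return ev, counts, enc


class TestRepz:
    def test_injected_path_strong(self, event_setup):
        ev, counts, enc = event_setup
        z = repz(counts, enc, 0.02, n_shuffles=150, seed=0)
        assert z[ev["path"]] > 2.0

    def test_determinism(self, event_setup):
        _, counts, enc = event_setup
        z1 = repz(counts, enc, 0.02, n_shuffles=120, seed=5)
        z2 = repz(counts, enc, 0.02, n_shuffles=120, seed=5)
        assert z1 == z2

    def test_few_shuffles_warns(self, event_setup):
        _, counts, enc = event_setup
        with pytest.warns(UserWarning):
            repz(counts, enc, 0.02, n_shuffles=50, seed=0)


class TestSequenceScore:
    def _diag_post(self, states, path="S-C2", reverse=False, n_t=10):
        from replaylab.decoding import DecodedPosterior

        P = np.zeros((n_t, len(states)))
        sl = (states["path"] == path).to_numpy()
        idx = np.where(sl)[0]
        take = np.linspace(0, len(idx) - 1, n_t).astype(int)
        if reverse:
            take = take[::-1]
        for i, j in enumerate(take):
            P[i, idx[j]] = 1.0
        return DecodedPosterior(np.arange(n_t + 1) * 0.02, states, P)

    def test_forward_diag_classified_forward(self, states):
        post = self._diag_post(states)
        r, rz, seq, direction = sequence_score(post, "S-C2", n_shuffles=100,
                                               seed=0)
        assert r > 0.99 and seq and direction == "forward"
        assert rz > 2

    def test_reverse_diag_classified_reverse(self, states):
        post = self._diag_post(states, reverse=True)
        r, rz, seq, direction = sequence_score(post, "S-C2", n_shuffles=100,
                                               seed=0)
        assert r < -0.99 and seq and direction == "reverse"

    def test_threshold_is_half(self, states):
        # construct a posterior with known weighted correlation just below 0.5
        from replaylab.decoding import DecodedPosterior

        rng = np.random.default_rng(4)
        sl = (states["path"] == "S-C2").to_numpy()
        idx = np.where(sl)[0]
        for _ in range(50):
            P = np.zeros((10, len(states)))
            P[:, idx] = rng.random((10, len(idx)))
            P /= P.sum(axis=1, keepdims=True)
            post = DecodedPosterior(np.arange(11) * 0.02, states, P)
            r, _, seq, direction = sequence_score(post, "S-C2",
                                                  n_shuffles=30, seed=0)
            assert seq == (abs(r) >= 0.5)
            if not seq:
                assert direction == "none"


class TestTrajectoryEvent:
    def test_static_map_trace_false(self, states):
        from replaylab.decoding import DecodedPosterior

        P = np.zeros((10, len(states)))
        P[:, 10] = 1.0
        post = DecodedPosterior(np.arange(11) * 0.02, states, P)
        assert not trajectory_event(post, "S-C1", 100.0)

    def test_monotone_sweep_true(self, states):
        from replaylab.decoding import DecodedPosterior

        sl = np.where((states["path"] == "S-C2").to_numpy())[0]
        P = np.zeros((10, len(states)))
        take = np.linspace(5, 45, 10).astype(int)  # 80% span
        for i, j in enumerate(take):
            P[i, sl[j]] = 1.0
        post = DecodedPosterior(np.arange(11) * 0.02, states, P)
        assert trajectory_event(post, "S-C2", 100.0)


class TestPopulationSummaries:
    def test_participation_bounds(self):
        evs = []
        for k in range(4):
            ev = CandidateEvent(t_start=k, t_end=k + 0.1)
            ev.participating_units = [0] if k < 2 else [0, 1]
            evs.append(ev)
        # unit 0 in all events, unit 1 in half
        from replaylab.decoding import Encoder

        enc = Encoder([0, 1], pd.DataFrame({"path": ["S-C1"], "bin": [0],
                                            "pos_cm": [1.0]}),
                      np.ones((2, 1)), 0.01)
        tab = events.participation_and_pcc(evs, enc)
        assert tab.set_index("unit_id").loc[0, "participation"] == 1.0
        assert tab.set_index("unit_id").loc[1, "participation"] == 0.5

    def test_ensemble_identical_events_corr_one(self):
        ev = CandidateEvent(0, 0.1, counts=np.array([[1, 2, 0, 3]]))
        ev2 = CandidateEvent(1, 1.1, counts=np.array([[1, 2, 0, 3]]))
        corr, _ = ensemble_correlations([ev, ev2], [0, 1, 2, 3])
        assert corr[0, 1] == pytest.approx(1.0)

    def test_ensemble_disjoint_events_nonpositive(self):
        ev = CandidateEvent(0, 0.1, counts=np.array([[3, 2, 0, 0]]))
        ev2 = CandidateEvent(1, 1.1, counts=np.array([[0, 0, 2, 3]]))
        corr, _ = ensemble_correlations([ev, ev2], [0, 1, 2, 3])
        assert corr[0, 1] <= 0

    def test_ensemble_needs_two(self):
        with pytest.raises(EventError):
            ensemble_correlations([CandidateEvent(0, 1)], [0])

    def test_event_rate_maps_no_events(self, small_session):
        tab = event_rate_maps(pd.DataFrame({"t_start": []}),
                              small_session.pauses, small_session.trials)
        assert (tab["count"] == 0).all()
        assert (tab["exposure_s"] > 0).all()

    def test_event_rate_maps_counts_and_exposure(self, small_session):
        sched = pd.DataFrame(small_session.ground_truth.replay_schedule)
        tab = event_rate_maps(sched, small_session.pauses,
                              small_session.trials)
        assert tab["count"].sum() == len(sched)


class TestEndToEnd:
    def test_direction_labels_invert_under_time_reversal(self,
                                                         tiling_session):
        s = tiling_session
        maps = tuning.compute_session_rate_maps(s)
        enc = decoding.fit_encoder(maps, ("pre", "learning", "post"))
        pl = {p: s.maze.paths[p].length for p in FIELD_PATHS}
        sched = s.ground_truth.replay_schedule[:10]
        iv = pd.DataFrame({
            "t_start": [ev["t_start"] for ev in sched],
            "t_end": [ev["t_start"] + ev["duration"] for ev in sched],
        })
        evs = events.score_events(iv, s.spikes, enc, pl, n_shuffles=60,
                                  compute_repz=False, seed=0)
        mirrored = {
            uid: np.sort(np.concatenate([
                st[(st < a) | (st >= b)],
                (a + b - st[(st >= a) & (st < b)])[::-1],
            ]))
            for uid, st in s.spikes.items()
            for a, b in [(0.0, 0.0)]
        }
        # mirror each event window independently
        mirrored = {uid: st.copy() for uid, st in s.spikes.items()}
        for ev in sched:
            a = ev["t_start"]
            b = a + 0.02 * round(ev["duration"] / 0.02)  # bin-aligned end
            for uid in mirrored:
                st = mirrored[uid]
                inside = (st >= a) & (st < b)
                st[inside] = a + b - st[inside] - 1e-9
                mirrored[uid] = np.sort(st)
        iv2 = iv.copy()
        iv2["t_end"] = [ev["t_start"] + 0.02 * round(ev["duration"] / 0.02)
                        for ev in sched]
        evs_m = events.score_events(iv2, s.spikes, enc, pl, n_shuffles=60,
                                    compute_repz=False, seed=0)
        evs_m2 = events.score_events(iv2, mirrored, enc, pl, n_shuffles=60,
                                     compute_repz=False, seed=0)
        flips = {"forward": "reverse", "reverse": "forward", "none": "none"}
        for e1, e2 in zip(evs_m, evs_m2):
            if e1.represented_path == e2.represented_path:
                assert e2.direction == flips[e1.direction]
                if e1.r is not None and e2.r is not None:
                    assert e2.r == pytest.approx(-e1.r, abs=1e-9)
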