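import numpy as np
import pytest

from oracles import (
    bf_best_fit_line,
    bf_line_mass,
    bf_weighted_correlation,
    random_pmat,
)
from wmazeseq import testing as tt
from wmazeseq import thetaseq as ts


# ------------------------------------------------------------------ scores
def test_weighted_correlation_delta_diagonal():
    P = np.eye(8)
    assert ts.weighted_correlation(P) == pytest.approx(1.0)
    assert ts.weighted_correlation(P[::-1]) == pytest.approx(-1.0)


def test_weighted_correlation_uniform_zero():
    P = np.full((10, 6), 1.0 / 60)
    assert ts.weighted_correlation(P) == pytest.approx(0.0, abs=1e-12)


def test_weighted_correlation_spec_matrix():
    P = np.array([[0.5, 0.1, 0.0], [0.1, 0.3, 0.1], [0.0, 0.1, 0.5]])
    assert ts.weighted_correlation(P) == pytest.approx(
        bf_weighted_correlation(P), abs=1e-12
    )
    assert ts.weighted_correlation(P) > 0.5


def test_weighted_correlation_oracle_random(rng):
    for _ in range(100):
        P = random_pmat(rng, int(rng.integers(3, 25)), int(rng.integers(3, 15)))
        assert ts.weighted_correlation(P) == pytest.approx(
            bf_weighted_correlation(P), abs=1e-12
        )


def test_weighted_correlation_degenerate():
    assert np.isnan(ts.weighted_correlation(np.zeros((4, 4))))
    one_col = np.zeros((4, 3))
    one_col[2, :] = 1.0  # no variance in x
    assert np.isnan(ts.weighted_correlation(one_col))


def test_best_fit_line_matches_bruteforce(rng):
    for _ in range(8):
        D, T = int(rng.integers(10, 22)), int(rng.integers(4, 10))
        P = random_pmat(rng, D, T)
        got = ts.best_fit_line(P, 2.0, dt_s=0.01)
        r_ref, v_ref, rho_ref = bf_best_fit_line(P, 2.0, 0.01)
        assert got.r_max == pytest.approx(r_ref, abs=1e-12)
        assert got.v_mps == pytest.approx(v_ref)
        assert got.rho_cm == pytest.approx(rho_ref)


def test_best_fit_line_recovers_planted_slope():
    D, T = 60, 14
    bin_cm, dt = 2.0, 0.01
    v_true = 5.0  # m/s
    P = np.zeros((D, T))
    for k in range(T):
        pos = 20.0 + 100 * v_true * k * dt
        j = int(pos / bin_cm)
        P[j, k] = 1.0
    line = ts.best_fit_line(P, bin_cm, dt_s=dt)
    assert abs(line.v_mps - v_true) <= 0.25  # one grid step
    assert line.r_max == pytest.approx(1.0)


def test_best_fit_line_uniform_mass_fraction():
    D, T = 60, 10
    P = np.full((D, T), 1.0 / (D * T))
    line = ts.best_fit_line(P, 2.0, dt_s=0.01)
    # within +-8 cm of any interior line: 8 or 9 of 60 bin centers
    assert 0.10 < line.r_max < 0.17
    # R is flat across slopes for uniform mass (interior lines)
    vals = [bf_line_mass(P, v, 60.0, 2.0, 0.01, 8.0) for v in (150.0, 300.0)]
    assert vals[0] == pytest.approx(vals[1], abs=0.03)


def test_shuffle_preserves_column_mass(rng):
    P = random_pmat(rng, 20, 8)
    sh = ts.space_circular_shuffle(P, rng)
    np.testing.assert_allclose(sh.sum(axis=0), P.sum(axis=0), atol=1e-12)
    assert not np.allclose(sh, P)


def test_shuffle_significance_deterministic(rng):
    P = random_pmat(rng, 30, 10)
    a = ts.shuffle_significance(P, 2.0, 200, np.random.default_rng(77))
    b = ts.shuffle_significance(P, 2.0, 200, np.random.default_rng(77))
    assert a.r_lo == b.r_lo and a.r_hi == b.r_hi and a.rmax_thr == b.rmax_thr


def test_shuffle_warns_below_100():
    P = np.full((10, 5), 0.02)
    with pytest.warns(UserWarning):
        ts.shuffle_significance(P, 2.0, 50, np.random.default_rng(0))


# ------------------------------------------------------------- event level
@pytest.fixture(scope="module")
def toy_model():
    return tt.toy_encoding_model(rng=np.random.default_rng(1))


def test_decode_event_window_count(toy_model):
    # 150 ms cycle -> 14 windows of 20 ms stepped 10 ms
    rng = np.random.default_rng(3)
    trains = tt.planted_sweep_spikes(toy_model, "L", 20.0, 4.0, 5.0, 0.15, rng)
    cand = tt.planted_candidate(0, 5.0, 0.15, "L", 50.0)
    ep = ts.decode_event(toy_model, trains, cand)
    assert ep is not None
    assert len(ep.window_centers) <= 14
    assert ep.pmats["L"].shape[1] == len(ep.window_centers)


def test_decode_event_too_few_windows(toy_model):
    cand = tt.planted_candidate(0, 5.0, 0.15, "L", 50.0)
    empty = {uid: np.empty(0) for uid in toy_model.unit_ids}
    assert ts.decode_event(toy_model, empty, cand) is None


def test_planted_event_detected_forward(toy_model):
    rng = np.random.default_rng(11)
    trains = tt.planted_sweep_spikes(toy_model, "L", 20.0, 5.0, 5.0, 0.15, rng)
    cand = tt.planted_candidate(0, 5.0, 0.15, "L", 55.0)
    res = ts.score_event(toy_model, trains, cand, 200, np.random.default_rng(5))
    assert res is not None and res.significant
    assert res.decoded_side == "L"
    assert res.direction == "forward"
    assert res.represents == "actual"
    assert res.slope_mps == pytest.approx(5.0, abs=2.5)


def test_alternative_representation_label(toy_model):
    rng = np.random.default_rng(12)
    trains = tt.planted_sweep_spikes(toy_model, "R", 20.0, 5.0, 5.0, 0.15, rng)
    cand = tt.planted_candidate(0, 5.0, 0.15, "L", 55.0)  # animal chose L
    res = ts.score_event(toy_model, trains, cand, 200, np.random.default_rng(6))
    assert res is not None and res.significant
    assert res.decoded_side == "R"
    assert res.represents == "alternative"


def test_time_reversal_flips_direction(toy_model):
    rng = np.random.default_rng(13)
    trains = tt.planted_sweep_spikes(toy_model, "L", 20.0, 5.0, 5.0, 0.15, rng)
    t0, t1 = 5.0, 5.15
    reversed_trains = {
        uid: np.sort(t0 + (t1 - st[::-1])) for uid, st in trains.items()
    }
    fwd = ts.score_event(toy_model, trains,
                         tt.planted_candidate(0, t0, 0.15, "L", 55.0),
                         200, np.random.default_rng(7))
    rev = ts.score_event(toy_model, reversed_trains,
                         tt.planted_candidate(0, t0, 0.15, "L", 55.0),
                         200, np.random.default_rng(7))
    assert fwd.direction == "forward" and rev.direction == "reverse"
    assert rev.slope_mps == pytest.approx(fwd.slope_mps, abs=0.5)


def test_inbound_orientation_forward(toy_model):
    """A sweep toward the center well during inbound travel is forward."""
    model = tt.toy_encoding_model(travel="inbound", rng=np.random.default_rng(2))
    rng = np.random.default_rng(14)
    # position decreasing from 100 cm toward the center well
    trains = tt.planted_sweep_spikes(model, "L", 100.0, -5.0, 5.0, 0.15, rng)
    cand = tt.planted_candidate(0, 5.0, 0.15, "L", 65.0, travel="inbound")
    res = ts.score_event(model, trains, cand, 200, np.random.default_rng(8))
    assert res is not None and res.significant
    assert res.direction == "forward"


# --------------------------------------------------------- candidate gates
def test_find_candidates_gates(small_session, small_prepared):
    from wmazeseq import lfp as lfpmod
    from wmazeseq.lfp import ThetaCycle

    linearized, trials = small_prepared[0], small_prepared[1]
    trains = small_session.spikes.trains
    uids = small_session.spikes.unit_ids("CA1")
    run = small_session.ground_truth.run_intervals.iloc[2]
    mid = 0.5 * (run.start_s + run.end_s)
    good = ThetaCycle(mid, mid + 0.15)
    short = ThetaCycle(mid, mid + 0.09)
    slow_t = float(trials.iloc[0].arrival_trigger_s + 0.5)  # at the well
    slow = ThetaCycle(slow_t, slow_t + 0.15)
    cands = ts.find_candidates([good, short, slow], trains, uids,
                               linearized, trials, "CA1")
    assert all(0.1 <= c.duration_s <= 0.2 for c in cands)
    assert all(c.speed_cm_s > 10 for c in cands)
    assert all(c.n_active >= 5 for c in cands)
    # the short and slow cycles can never appear
    assert len(cands) <= 1


def test_find_candidates_unit_count_gate(small_session, small_prepared):
    from wmazeseq.lfp import ThetaCycle

    linearized, trials = small_prepared[0], small_prepared[1]
    run = small_session.ground_truth.run_intervals.iloc[2]
    mid = 0.5 * (run.start_s + run.end_s)
    cyc = [ThetaCycle(mid, mid + 0.15)]
    uids = small_session.spikes.unit_ids("CA1")
    lots = ts.find_candidates(cyc, small_session.spikes.trains, uids,
                              linearized, trials, "CA1", min_active=999)
    assert lots == []


# ------------------------------------------------------------ aggregations
def test_distance_index_bounds(toy_model):
    rng = np.random.default_rng(20)
    from wmazeseq.lfp import ThetaPhaseSeries

    t = np.arange(0, 20, 1 / 1500)
    phase = np.angle(np.exp(1j * 2 * np.pi * 8.0 * t))
    ph = ThetaPhaseSeries(time=t, phase=phase, amplitude=np.ones_like(t))

    trains = tt.planted_sweep_spikes(toy_model, "L", 30.0, 5.0, 5.0, 0.15, rng)
    cand = tt.planted_candidate(0, 5.0, 0.15, "L", 60.0)
    ep = ts.decode_event(toy_model, trains, cand)
    res = ts.score_event(toy_model, trains, cand, 100, np.random.default_rng(9))
    di = ts.distance_index([ep], [res], ph)
    assert di is not None
    assert -1 <= di.first_half <= 1 and -1 <= di.second_half <= 1


def test_choice_representation_counts(toy_model):
    results = []
    for i, (side, choice) in enumerate(
        [("L", "L"), ("L", "L"), ("R", "L"), ("L", "L")]
    ):
        rng = np.random.default_rng(30 + i)
        trains = tt.planted_sweep_spikes(toy_model, side, 20.0, 5.0, 5.0, 0.15, rng)
        cand = tt.planted_candidate(i, 5.0, 0.15, choice, 55.0)
        res = ts.score_event(toy_model, trains, cand, 150, np.random.default_rng(i))
        if res is not None:
            res.segment = "before_cp"
            results.append(res)
    pct_act, pct_alt, per_trial = ts.choice_representation(results, "before_cp")
    assert pct_act + pct_alt == pytest.approx(100.0)
    assert per_trial.n_actual.sum() + per_trial.n_alternative.sum() == sum(
        r.significant for r in results
    )


def test_coherent_pairs_fully_coupled(toy_model):
    def _mk(side, choice, eid):
        rng = np.random.default_rng(40 + eid)
        trains = tt.planted_sweep_spikes(toy_model, side, 20.0, 5.0,
                                         5.0 + eid, 0.15, rng)
        cand = tt.planted_candidate(eid, 5.0 + eid, 0.15, choice, 55.0)
        return ts.score_event(toy_model, trains, cand, 150,
                              np.random.default_rng(eid))

    ca1 = [_mk("L", "L", i) for i in range(6)]
    pfc = [_mk("L", "L", i) for i in range(6)]
    ca1 = [r for r in ca1 if r and r.significant]
    pfc = [r for r in pfc if r and r.significant]
    tbl = ts.coherent_pairs(ca1, pfc, min_events=3)
    assert tbl is not None
    assert tbl.p_pfc_actual_given_ca1_actual.iloc[0] == pytest.approx(1.0)


def test_coherent_pairs_no_overlap_returns_none():
    assert ts.coherent_pairs([], [], min_events=1) is None
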