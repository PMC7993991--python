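import numpy as np
import pytest

from wmazeseq import replay as rp
from wmazeseq import testing as tt
from wmazeseq.lfp import SWREvent
from wmazeseq.ratemaps import RateMap


@pytest.fixture(scope="module")
def model():
    return tt.toy_encoding_model(rng=np.random.default_rng(21))


def _planted_swr(model, side, v_mps, start_s, dur=0.15, seed=0):
    rng = np.random.default_rng(seed)
    span = abs(v_mps) * 100 * dur
    start_pos = 5.0 if v_mps > 0 else 5.0 + span
    trains = tt.planted_sweep_spikes(
        model, side, start_pos, v_mps, start_s, dur, rng, rate_gain=2.0
    )
    ev = SWREvent(swr_id=seed, start_s=start_s, end_s=start_s + dur, peak_z=5.0)
    return ev, trains


def test_collinear_map_positions_r2_one():
    y = np.array([10.0, 20.0, 30.0, 40.0])
    r2, slope = rp._regress_r2(y)
    assert r2 == pytest.approx(1.0)
    assert slope == pytest.approx(10.0)


def test_planted_forward_replay_detected(model):
    ev, trains = _planted_swr(model, "L", 6.0, 100.0, seed=1)
    res = rp.detect_replay(model, [ev], trains, 200, np.random.default_rng(0))
    assert len(res) == 1
    assert res[0].significant
    assert res[0].decoded_side == "L"
    assert res[0].direction == "forward"


def test_planted_reverse_replay_detected(model):
    ev, trains = _planted_swr(model, "R", -6.0, 100.0, seed=2)
    res = rp.detect_replay(model, [ev], trains, 200, np.random.default_rng(0))
    assert res[0].significant
    assert res[0].decoded_side == "R"
    assert res[0].direction == "reverse"


def test_short_swr_excluded(model):
    ev, trains = _planted_swr(model, "L", 6.0, 100.0, dur=0.04, seed=3)
    res = rp.detect_replay(model, [ev], trains, 50, np.random.default_rng(0))
    assert res == []


def test_few_cells_not_candidate(model):
    ev = SWREvent(swr_id=0, start_s=100.0, end_s=100.15, peak_z=5.0)
    trains = {uid: np.empty(0) for uid in model.unit_ids}
    trains[model.unit_ids[0]] = np.array([100.05])
    res = rp.detect_replay(model, [ev], trains, 50, np.random.default_rng(0))
    assert len(res) == 1
    assert not res[0].candidate and not res[0].significant


def test_matrix_correlation_identity():
    rng = np.random.default_rng(4)
    C = rng.normal(0, 1, (6, 7))
    assert rp.matrix_correlation(C, C.copy()) == pytest.approx(1.0)


def test_matrix_correlation_invariant_to_joint_relabeling():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, (6, 7))
    b = rng.normal(0, 1, (6, 7))
    r0 = rp.matrix_correlation(a, b)
    pi = rng.permutation(6)
    pj = rng.permutation(7)
    r1 = rp.matrix_correlation(a[np.ix_(pi, pj)], b[np.ix_(pi, pj)])
    assert r1 == pytest.approx(r0, abs=1e-12)


def _toy_maps_and_trains(seed, coupled):
    """CA1/PFC with Gaussian maps; event trains either track the maps
    (coupled) or are independent Poisson."""
    rng = np.random.default_rng(seed)
    edges = np.arange(0.0, 122.0, 2.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ca1_ids = list(range(8))
    pfc_ids = list(range(100, 107))
    maps = {}
    unit_centers = {}
    for uid in ca1_ids + pfc_ids:
        c = rng.uniform(10, 110)
        unit_centers[uid] = c
        rate = 20 * np.exp(-0.5 * ((centers - c) / 10.0) ** 2)
        maps[(uid, "C-to-L")] = RateMap(uid, "C-to-L", edges, rate, np.ones(60), 500)
    start, end = 50.0, 50.2
    trains = {}
    for uid in ca1_ids + pfc_ids:
        if coupled:
            # spike time encodes field center -> co-firing mirrors map overlap
            t_mid = start + (unit_centers[uid] / 120.0) * (end - start)
            trains[uid] = np.sort(t_mid + rng.normal(0, 0.004, 4))
        else:
            trains[uid] = np.sort(rng.uniform(start, end, 4))
    ev = SWREvent(swr_id=0, start_s=start, end_s=end, peak_z=5.0)
    return ev, trains, maps, ca1_ids, pfc_ids


def test_reactivation_coupled_exceeds_independent():
    r_coupled, r_indep = [], []
    for seed in range(6):
        ev, trains, maps, ca1, pfc = _toy_maps_and_trains(seed, coupled=True)
        res = rp.reactivation_strength(ev, trains, maps, ca1, pfc,
                                       ["C-to-L"], 100,
                                       np.random.default_rng(seed))
        r_coupled.append(res.strength["C-to-L"])
        ev, trains, maps, ca1, pfc = _toy_maps_and_trains(seed, coupled=False)
        res = rp.reactivation_strength(ev, trains, maps, ca1, pfc,
                                       ["C-to-L"], 100,
                                       np.random.default_rng(seed))
        r_indep.append(res.strength["C-to-L"])
    assert np.nanmean(r_coupled) > 0.3
    assert abs(np.nanmean(r_indep)) < 0.25


def test_reactivation_independent_within_shuffle_ci():
    inside = 0
    n = 8
    for seed in range(n):
        ev, trains, maps, ca1, pfc = _toy_maps_and_trains(100 + seed, coupled=False)
        res = rp.reactivation_strength(ev, trains, maps, ca1, pfc,
                                       ["C-to-L"], 200,
                                       np.random.default_rng(seed))
        lo, hi = res.shuffle_ci["C-to-L"]
        r = res.strength["C-to-L"]
        if np.isfinite(r) and lo <= r <= hi:
            inside += 1
    assert inside >= n - 2  # nominal 95% coverage


def test_reactivation_requires_five_cells():
    ev, trains, maps, ca1, pfc = _toy_maps_and_trains(0, coupled=True)
    res = rp.reactivation_strength(ev, trains, maps, ca1[:3], pfc,
                                   ["C-to-L"], 50, np.random.default_rng(0))
    assert res is None
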