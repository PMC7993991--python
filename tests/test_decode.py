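import numpy as np
import pytest

from oracles import bf_log_posterior
from wmazeseq import decode as dec
from wmazeseq import testing as tt
from wmazeseq.ratemaps import RateMap


def _model_from_rates(rates):
    rates = np.asarray(rates, float)
    n, _, D = rates.shape
    edges = np.arange(0.0, (D + 1) * 2.0, 2.0)
    return dec.EncodingModel(
        travel="outbound", region="CA1", unit_ids=list(range(n)),
        bin_edges=edges, rates=np.maximum(rates, dec.RATE_FLOOR_HZ),
    )


def test_hand_computed_two_state_posterior():
    # one unit, 1 spike, tau=0.1 s, rates (10, 20) Hz on a 2-state space
    model = _model_from_rates([[[10.0], [20.0]]])
    P = dec.posterior(model, np.array([[1.0]]), 0.1)[0].ravel()
    num = np.array([10 * np.exp(-1.0), 20 * np.exp(-2.0)])
    np.testing.assert_allclose(P, num / num.sum(), atol=1e-12)
    assert P[0] == pytest.approx(0.576, abs=0.001)


def test_zero_spikes_mass_at_low_rate_states():
    rates = np.zeros((2, 2, 3))
    rates[:, 0, :] = 20.0   # high-rate trajectory
    rates[:, 1, :] = 1.0    # low-rate trajectory
    model = _model_from_rates(rates)
    P = dec.posterior(model, np.zeros((1, 2)), 0.1)[0]
    assert P[1].sum() > 0.9  # mass on the lowest summed-rate states


def test_posterior_matches_bruteforce_oracle(rng):
    for _ in range(25):
        n = rng.integers(2, 6)
        D = rng.integers(2, 8)
        rates = rng.uniform(0.01, 30.0, size=(n, 2, D))
        counts = rng.poisson(1.0, size=n).astype(float)
        tau = float(rng.uniform(0.01, 0.2))
        model = _model_from_rates(rates)
        lp = dec.log_posterior(model, counts[None, :], tau)[0].reshape(-1)
        ref = bf_log_posterior(model.rates.reshape(n, -1), counts, tau)
        np.testing.assert_allclose(lp, ref, atol=1e-12)


def test_posterior_columns_sum_to_one(rng):
    rates = rng.uniform(0.01, 20.0, size=(8, 2, 30))
    model = _model_from_rates(rates)
    counts = rng.poisson(0.8, size=(50, 8)).astype(float)
    P = dec.posterior(model, counts, 0.02)
    np.testing.assert_allclose(P.sum(axis=(1, 2)), 1.0, atol=1e-9)
    assert (P >= 0).all()


def test_build_templates_floor_and_grid():
    edges = np.arange(0.0, 13.0, 2.0)
    maps = {}
    for uid in range(5):
        maps[(uid, "C-to-L")] = RateMap(uid, "C-to-L", edges,
                                        np.full(6, 5.0), np.ones(6), 200)
    # unit 0 missing on C-to-R -> floor template there
    for uid in range(1, 5):
        maps[(uid, "C-to-R")] = RateMap(uid, "C-to-R", edges,
                                        np.full(6, 4.0), np.ones(6), 200)
    model = dec.build_templates(maps, "outbound", "CA1", list(range(5)))
    i0 = model.unit_ids.index(0)
    np.testing.assert_allclose(model.rates[i0, 1], dec.RATE_FLOOR_HZ)
    assert model.n_bins == 6


def test_build_templates_needs_five_units():
    edges = np.arange(0.0, 13.0, 2.0)
    maps = {
        (0, "C-to-L"): RateMap(0, "C-to-L", edges, np.full(6, 5.0), np.ones(6), 200)
    }
    with pytest.raises(ValueError):
        dec.build_templates(maps, "outbound", "CA1", [0])


def test_build_templates_rejects_mismatched_grids():
    edges_a = np.arange(0.0, 13.0, 2.0)
    edges_b = np.arange(0.0, 15.0, 2.0)
    maps = {
        (0, "C-to-L"): RateMap(0, "C-to-L", edges_a, np.full(6, 5.0), np.ones(6), 200),
        (1, "C-to-L"): RateMap(1, "C-to-L", edges_b, np.full(7, 5.0), np.ones(7), 200),
    }
    with pytest.raises(ValueError):
        dec.build_templates(maps, "outbound", "CA1", [0, 1], min_units=2)


def test_equal_templates_give_even_trajectory_marginal(rng):
    f = rng.uniform(0.5, 10.0, size=(6, 1, 10))
    rates = np.concatenate([f, f], axis=1)
    model = _model_from_rates(rates)
    counts = rng.poisson(1.0, size=(20, 6)).astype(float)
    P = dec.posterior(model, counts, 0.1)
    np.testing.assert_allclose(P[:, 0, :].sum(axis=1), 0.5, atol=1e-9)


def test_swapped_templates_flip_choice(rng):
    model = tt.toy_encoding_model(n_units=20, rng=rng)
    swapped = dec.EncodingModel(
        travel=model.travel, region=model.region, unit_ids=model.unit_ids,
        bin_edges=model.bin_edges, rates=model.rates[:, ::-1, :].copy(),
    )
    counts = np.random.default_rng(5).poisson(
        model.rates[:, 0, :].mean(axis=1) * 0.12, size=(30, 20)
    ).astype(float)
    P1 = dec.posterior(model, counts, 0.12)
    P2 = dec.posterior(swapped, counts, 0.12)
    np.testing.assert_allclose(P1[:, 0, :], P2[:, 1, :], atol=1e-12)


def test_window_counts_half_open(rng):
    trains = {0: np.array([1.0, 1.12, 2.0])}
    counts = dec.count_spikes_in_windows(trains, [0], np.array([1.0, 1.12]), 0.12)
    # spike at a boundary belongs to the later window
    np.testing.assert_array_equal(counts.ravel(), [1, 1])
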