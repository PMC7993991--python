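import numpy as np
import pandas as pd
import pytest

from wmazeseq import ratemaps as rm


def _uniform_linearized(duration_s=600.0, fs=30.0, track_cm=120.0, speed=20.0):
    """Back-and-forth sweeps at constant speed labeled as one trajectory."""
    t = np.arange(0, duration_s, 1 / fs)
    period = 2 * track_cm / speed
    saw = np.abs((t % period) / period * 2 - 1)  # 1 -> 0 -> 1
    lin = track_cm * (1 - saw)
    return pd.DataFrame(
        {
            "time_s": t,
            "linear_cm": lin,
            "traj_type": "C-to-L",
            "speed_cm_s": speed,
            "trial_id": 0,
        }
    )


def _poisson_spikes_from_rate(lin_df, rate_fn, rng):
    t = lin_df.time_s.to_numpy()
    dt = 1 / 30.0
    lam = rate_fn(lin_df.linear_cm.to_numpy()) * dt
    return t[rng.random(len(t)) < lam]


def test_uniform_rate_recovered(rng):
    lin = _uniform_linearized()
    spikes = _poisson_spikes_from_rate(lin, lambda x: np.full_like(x, 2.0), rng)
    out = rm.compute_rate_map(spikes, lin, "C-to-L", 120.0)
    mid = out.rate_hz[5:-5]
    assert np.nanmean(mid) == pytest.approx(2.0, rel=0.15)
    assert out.peak_rate_hz < 3.0  # not a place cell


def test_planted_gaussian_field_recovered(rng):
    lin = _uniform_linearized(duration_s=900.0)
    rate_fn = lambda x: 10.0 * np.exp(-0.5 * ((x - 60.0) / 8.0) ** 2)
    spikes = _poisson_spikes_from_rate(lin, rate_fn, rng)
    out = rm.compute_rate_map(spikes, lin, "C-to-L", 120.0)
    assert out.peak_rate_hz == pytest.approx(10.0, rel=0.2)
    peak_cm = out.bin_centers[np.nanargmax(out.rate_hz)]
    assert abs(peak_cm - 60.0) <= 4.0


def test_mass_conservation_before_smoothing(rng):
    lin = _uniform_linearized()
    spikes = _poisson_spikes_from_rate(lin, lambda x: np.full_like(x, 5.0), rng)
    out = rm.compute_rate_map(spikes, lin, "C-to-L", 120.0)
    assert out.n_spikes == len(spikes)


def _flat_map(rate, traj="C-to-L", n=60):
    edges = np.arange(0, (n + 1) * 2.0, 2.0)
    return rm.RateMap(
        unit_id=0, traj_type=traj, bin_edges=edges,
        rate_hz=np.full(n, float(rate)), occupancy_s=np.ones(n), n_spikes=100,
    )


def test_si_formula_and_thresholds():
    res = rm.selectivity_index(_flat_map(15.0), _flat_map(5.0), 0, "CA1", "outbound")
    assert res.si == pytest.approx(0.5)
    assert res.selective and res.preferred == "L"
    # |SI| = 0.35: below the CA1 threshold, above the PFC threshold
    r_ca1 = rm.selectivity_index(_flat_map(13.5), _flat_map(6.5), 0, "CA1", "outbound")
    r_pfc = rm.selectivity_index(_flat_map(13.5), _flat_map(6.5), 0, "PFC", "outbound")
    assert r_ca1.si == pytest.approx(0.35)
    assert not r_ca1.selective and r_pfc.selective


def test_si_symmetry_and_antisymmetry():
    equal = rm.selectivity_index(_flat_map(8.0), _flat_map(8.0), 0, "CA1", "outbound")
    assert equal.si == pytest.approx(0.0)
    a = rm.selectivity_index(_flat_map(12.0), _flat_map(4.0), 0, "CA1", "outbound")
    b = rm.selectivity_index(_flat_map(4.0), _flat_map(12.0), 0, "CA1", "outbound")
    assert a.si == pytest.approx(-b.si)


def test_si_requires_place_cell_peak():
    assert rm.selectivity_index(_flat_map(2.9), _flat_map(1.0), 0, "CA1", "outbound") is None


def _map_from_profile(rate):
    n = len(rate)
    edges = np.arange(0, (n + 1) * 2.0, 2.0)
    return rm.RateMap(0, "C-to-L", edges, np.asarray(rate, float),
                      np.ones(n), int(np.sum(rate)))


def test_detect_fields_single_bump():
    x = np.arange(60) * 2.0 + 1.0
    rate = 10 * np.exp(-0.5 * ((x - 60) / 8) ** 2)
    fields = rm.detect_fields(_map_from_profile(rate))
    assert len(fields) == 1
    lo, hi, peak = fields[0]
    assert lo < 60 < hi
    assert hi - lo >= 8.0


def test_two_bumps_15cm_apart_merge():
    x = np.arange(60) * 2.0 + 1.0
    rate = 10 * np.exp(-0.5 * ((x - 50) / 3) ** 2) + 9 * np.exp(
        -0.5 * ((x - 65) / 3) ** 2
    )
    fields = rm.detect_fields(_map_from_profile(rate))
    assert len(fields) == 1  # 20-cm minimum peak separation


def test_narrow_bump_rejected():
    x = np.arange(60) * 2.0 + 1.0
    rate = np.where(np.abs(x - 60) <= 2.0, 10.0, 0.0)  # ~6 cm wide
    assert rm.detect_fields(_map_from_profile(rate)) == []


def test_subthreshold_peak_no_fields():
    assert rm.detect_fields(_flat_map(2.0)) == []


def test_asymmetry_symmetric_triangle_zero():
    x = np.arange(60) * 2.0 + 1.0
    rate = np.clip(10 - np.abs(x - 60.0) / 2.0, 0, None)
    res = rm.asymmetry_index(_map_from_profile(rate), (40.0, 80.0, 60.0))
    assert res.ai == pytest.approx(0.0, abs=0.05)


def test_asymmetry_linear_ramp_is_half():
    # ramp 0 -> peak across the field; analytic areas 0.125 / 0.375
    x = np.arange(60) * 2.0 + 1.0
    lo, hi = 40.0, 80.0
    rate = np.clip((x - lo) / (hi - lo), 0, 1) * np.where(x <= hi, 10.0, 0.0)
    rate[x > hi] = 0.0
    res = rm.asymmetry_index(_map_from_profile(rate), (lo, hi, 70.0))
    assert res.ai == pytest.approx(0.5, abs=0.05)
    mirrored = rm.asymmetry_index(
        _map_from_profile(rate[::-1].copy()), (120.0 - hi, 120.0 - lo, 50.0)
    )
    assert mirrored.ai == pytest.approx(-res.ai, abs=1e-9)


def test_asymmetry_requires_20cm_field():
    x = np.arange(60) * 2.0 + 1.0
    rate = 10 * np.exp(-0.5 * ((x - 60) / 4) ** 2)
    assert rm.asymmetry_index(_map_from_profile(rate), (52.0, 68.0, 60.0)) is None


def test_selective_fraction_matches_generator(small_cfg, small_session, small_prepared):
    from wmazeseq.pipeline import compute_maps

    maps, sel = compute_maps(small_session, small_prepared[0], np.empty((0, 2)))
    gt = small_session.ground_truth.units.set_index("unit_id")
    merged = sel.join(gt[["selective", "si_true"]], on="unit_id", rsuffix="_true")
    # planted selective units are overwhelmingly recovered as selective
    ca1 = merged[merged.region == "CA1"]
    if len(ca1) >= 10:
        agree = (ca1.selective == ca1.selective_true).mean()
        assert agree > 0.8
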