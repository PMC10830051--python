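"""Generator tests: schedule stratification, behaviour model, planted EEG."""

import numpy as np
import pandas as pd
import pytest

from spocrt import (RTModel, SimConfig, SourceSpec, generate_resting_state,
                    generate_schedule, simulate_behaviour, synthesize_eeg)
from spocrt.simdata import _standardized_log_rt


def test_default_schedule_is_exactly_stratified():
    cfg = SimConfig(seed=1)
    sched = generate_schedule(cfg)
    assert len(sched) == 192
    cells = sched.groupby(["angle", "mirrored"]).size()
    assert len(cells) == 8
    assert (cells == 24).all()
    # pair ids are sampled without replacement from the 384-pair pool
    assert sched["pair_id"].is_unique
    assert sched["pair_id"].between(0, 383).all()


def test_degenerate_single_angle_schedule():
    cfg = SimConfig(n_channels=4, angles=(0.0,), n_trials=2, pool_size=4,
                    accuracy_by_angle={0.0: 1.0})
    sched = generate_schedule(cfg)
    assert len(sched) == 2
    assert (sched["angle"] == 0.0).all()


def test_schedule_deterministic_and_fixation_range():
    cfg = SimConfig(seed=42)
    a, b = generate_schedule(cfg), generate_schedule(cfg)
    pd.testing.assert_frame_equal(a, b)
    assert a["fixation_ms"].between(1000, 3000).all()


def test_indivisible_trial_count_rejected():
    with pytest.raises(ValueError, match="divisible"):
        SimConfig(n_trials=190)


def test_noiseless_behaviour_gives_constant_rt():
    cfg = SimConfig(n_channels=4, n_trials=16, pool_size=32, seed=0,
                    rt_model=RTModel(baseline_log_ms=np.log(1500.0),
                                     slope_per_degree=0.0, sd_log=0.0))
    trials = simulate_behaviour(generate_schedule(cfg), cfg)
    # constant up to sampling-grid rounding (1 ms at 1 kHz)
    assert np.allclose(trials["reaction_time_ms"], 1500.0, atol=1.0)
    assert not trials["timeout"].any()


def test_perfect_accuracy_yields_all_correct():
    cfg = SimConfig(n_channels=4, n_trials=16, pool_size=32, seed=0,
                    accuracy_by_angle={a: 1.0 for a in (0., 50., 100., 150.)})
    trials = simulate_behaviour(generate_schedule(cfg), cfg)
    assert trials["correct"].all()


def test_mean_log_rt_tracks_generative_line():
    m = RTModel(baseline_log_ms=7.0, slope_per_degree=0.003, sd_log=0.2)
    cfg = SimConfig(n_channels=4, n_trials=10000, pool_size=10000,
                    rt_model=m, seed=5)
    trials = simulate_behaviour(generate_schedule(cfg), cfg)
    for angle, grp in trials.groupby("angle"):
        expected = m.baseline_log_ms + m.slope_per_degree * angle
        got = np.log(grp["reaction_time_ms"]).mean()
        se = m.sd_log / np.sqrt(len(grp))
        assert abs(got - expected) < 3 * se + 1e-3  # 1 ms grid slack
    means = trials.groupby("angle")["reaction_time_ms"].apply(
        lambda r: np.log(r).mean())
    assert means.is_monotonic_increasing


def _projected_epoch_logvar(session):
    gt = session.ground_truth
    topo = np.array(gt["sources"][0]["topography"])
    out = []
    for a, b in gt["epoch_windows"]:
        seg = topo @ session.signal[:, a:b]
        out.append(np.log(seg.var(ddof=1)))
    return np.array(out), np.array(gt["z"])


@pytest.mark.parametrize("alpha,check", [(0.0, "null"), (0.8, "strong")])
def test_planted_comodulation_strength(alpha, check):
    topo = np.zeros(8)
    topo[0] = 1.0
    cfg = SimConfig(n_channels=8, sampling_rate=250.0, n_trials=192,
                    pool_size=384, noise_sd=0.1, background_sd=0.5,
                    blink=__import__("spocrt").BlinkSpec(rate_per_min=0),
                    source_specs=[SourceSpec(band_center=10.0,
                                             comodulation=alpha,
                                             topography=topo)],
                    seed=11)
    trials = simulate_behaviour(generate_schedule(cfg), cfg)
    session = synthesize_eeg(trials, cfg)
    logvar, z = _projected_epoch_logvar(session)
    r = np.corrcoef(logvar, z)[0, 1]
    if check == "null":
        assert abs(r) < 0.1
    else:
        assert r > 0.6


def test_comodulation_monotone_in_alpha():
    corrs = []
    for alpha in (0.0, 0.2, 0.5, 0.8):
        topo = np.zeros(6)
        topo[1] = 1.0
        cfg = SimConfig(n_channels=6, sampling_rate=250.0, n_trials=96,
                        pool_size=192, noise_sd=0.1, background_sd=0.5,
                        source_specs=[SourceSpec(band_center=10.0,
                                                 comodulation=alpha,
                                                 topography=topo)],
                        seed=3)
        trials = simulate_behaviour(generate_schedule(cfg), cfg)
        session = synthesize_eeg(trials, cfg)
        logvar, z = _projected_epoch_logvar(session)
        corrs.append(np.corrcoef(logvar, z)[0, 1])
    assert all(b > a for a, b in zip(corrs, corrs[1:]))


def test_single_source_no_noise_is_rank_one():
    topo = np.ones(4) / 2.0
    cfg = SimConfig(n_channels=4, sampling_rate=250.0, n_trials=8,
                    pool_size=16, noise_sd=0.0, n_background=0,
                    blink=__import__("spocrt").BlinkSpec(rate_per_min=0),
                    source_specs=[SourceSpec(band_center=10.0,
                                             topography=topo)],
                    seed=2)
    trials = simulate_behaviour(generate_schedule(cfg), cfg)
    session = synthesize_eeg(trials, cfg)
    s = session.signal
    assert np.linalg.matrix_rank(s @ s.T, tol=1e-6 * np.trace(s @ s.T)) == 1
    r = np.corrcoef(s[0], s[1])[0, 1]
    assert abs(abs(r) - 1.0) < 1e-9


def test_session_events_complete_and_deterministic(small_config):
    from spocrt import simulate_participant

    task1, _ = simulate_participant(small_config)
    task2, _ = simulate_participant(small_config)
    assert np.array_equal(task1.signal, task2.signal)
    task1.validate()  # one fixation/stimulus/response-or-timeout per trial
    counts = task1.events["marker"].value_counts()
    n = small_config.n_trials
    assert counts["fixation_on"] == n and counts["stimulus_on"] == n
    assert counts.get("response", 0) + counts.get("timeout", 0) == n


def test_resting_state_duration_and_blinks():
    cfg = SimConfig(seed=9)  # default 32 ch, 1 kHz, 60 s
    rest = generate_resting_state(cfg)
    assert rest.n_samples == 60000
    n_blinks = rest.ground_truth["n_blinks"]
    # Poisson(10): essentially always within +-5 sd
    assert 0 < n_blinks < 10 + 5 * np.sqrt(10)
    assert len(rest.ground_truth["blink_onsets"]) == n_blinks


def test_zero_blink_rate_gives_no_transients():
    from spocrt import BlinkSpec

    cfg = SimConfig(n_channels=8, sampling_rate=250.0,
                    blink=BlinkSpec(rate_per_min=0), resting_seconds=20.0,
                    n_trials=8, pool_size=16, seed=4)
    rest = generate_resting_state(cfg)
    assert rest.ground_truth["n_blinks"] == 0
    # broadband envelope comparable across channels (no frontal spikes)
    peak = np.abs(rest.signal).max(axis=1)
    assert peak.max() / peak.min() < 3.0


def test_band_above_nyquist_rejected():
    with pytest.raises(ValueError, match="Nyquist"):
        cfg = SimConfig(n_channels=4, sampling_rate=50.0, n_trials=8,
                        pool_size=16,
                        source_specs=[SourceSpec(band_center=30.0)])
        trials = simulate_behaviour(generate_schedule(cfg), cfg)
        synthesize_eeg(trials, cfg)


def test_standardized_log_rt_is_per_angle_zscore(small_config):
    sched = generate_schedule(small_config)
    trials = simulate_behaviour(sched, small_config)
    z = _standardized_log_rt(trials)
    ok = ~trials["timeout"].to_numpy()
    for angle in small_config.angles:
        sel = ok & (trials["angle"] == angle).to_numpy()
        assert abs(z[sel].mean()) < 1e-9
        assert abs(z[sel].std() - 1.0) < 1e-9
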