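"""ICA cleaning, filter-bank contracts, epoching and retention rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spocrt import (BlinkSpec, SimConfig, SourceSpec, apply_filter_bank,
                    apply_ica_cleaning, epoch_session, filter_and_crop_epochs,
                    fit_ica, make_filter_bank, select_artifact_components,
                    simulate_participant)
from spocrt.preprocess import EpochSet, _zero_phase
from spocrt.simdata import RawSession


def _session(signal, fs, names=None, **kw):
    names = names or [f"CH{i}" for i in range(signal.shape[0])]
    events = pd.DataFrame(columns=["sample", "marker", "trial_index"])
    return RawSession(signal, fs, names, events, **kw)


def _cos(a, b):
    return abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

def _bursty_source(rng, n, fs, f0):
    """Amplitude-modulated narrowband source (super-Gaussian, ICA-friendly)."""
    t = np.arange(n) / fs
    env = (rng.uniform(size=n // int(fs) + 1) > 0.5).astype(float)
    env = np.repeat(env, int(fs))[:n]
    return np.sin(2 * np.pi * f0 * t) * env + 0.01 * rng.standard_normal(n)


def test_ica_recovers_planted_mixing_topographies(rng):
    fs, n = 200.0, 200 * 40
    s1 = _bursty_source(rng, n, fs, 10.0)
    s2 = np.zeros(n)
    spikes = rng.integers(0, n - 80, size=30)
    for o in spikes:
        s2[o:o + 60] += np.hanning(60)
    A = np.array([[1.0, 0.1], [0.8, 0.3], [0.1, 1.0], [0.2, 0.9]])
    X = A @ np.vstack([s1, s2]) + 0.01 * rng.standard_normal((4, n))
    ica = fit_ica(_session(X, fs), seed=0)
    for col in A.T:
        best = max(_cos(ica.mixing[:, k], col) for k in range(4))
        assert best > 0.95


def test_ica_identity_mixing_recovers_permutation(rng):
    fs, n = 200.0, 200 * 30
    X = rng.laplace(size=(3, n))
    ica = fit_ica(_session(X, fs), seed=1)
    # each unmixing row is dominated by one channel
    rows = np.abs(ica.unmixing) / np.linalg.norm(ica.unmixing, axis=1,
                                                 keepdims=True)
    assert np.all(rows.max(axis=1) > 0.95)
    assert sorted(rows.argmax(axis=1)) == [0, 1, 2]


def test_ica_deterministic(rng):
    fs, n = 200.0, 200 * 20
    X = rng.laplace(size=(3, n))
    a = fit_ica(_session(X, fs), seed=3)
    b = fit_ica(_session(X, fs), seed=3)
    assert np.array_equal(a.unmixing, b.unmixing)


def test_ica_rank_deficient_names_channels(rng):
    fs, n = 200.0, 200 * 20
    x = rng.standard_normal(n)
    X = np.vstack([x, x, rng.standard_normal(n)])  # duplicated channel
    with pytest.raises(ValueError, match="rank-deficient"):
        fit_ica(_session(X, fs, names=["A", "B", "C"]), seed=0)


def test_ica_short_resting_rejected(rng):
    with pytest.raises(ValueError, match="10 s"):
        fit_ica(_session(rng.standard_normal((2, 100)), 200.0), seed=0)


def test_cleaning_identity_when_nothing_rejected(rng):
    fs, n = 200.0, 200 * 20
    X = rng.laplace(size=(3, n))
    sess = _session(X, fs)
    ica = fit_ica(sess, seed=0)
    out = apply_ica_cleaning(sess, ica)
    rel = np.abs(out.signal - X).max() / np.abs(X).max()
    assert rel < 1e-6


def test_cleaning_reject_all_zeroes_signal(rng):
    fs, n = 200.0, 200 * 20
    X = rng.laplace(size=(3, n))
    sess = _session(X, fs)
    ica = fit_ica(sess, seed=0)
    ica.rejected = list(range(ica.n_components))
    out = apply_ica_cleaning(sess, ica)
    # only the per-channel mean survives
    assert np.abs(out.signal - out.signal.mean(axis=1, keepdims=True)).max() \
        < 1e-6 * np.abs(X).max()


def test_cleaning_channel_mismatch(rng):
    fs, n = 200.0, 200 * 20
    sess = _session(rng.laplace(size=(3, n)), fs)
    ica = fit_ica(sess, seed=0)
    with pytest.raises(ValueError, match="channel count"):
        apply_ica_cleaning(_session(rng.laplace(size=(4, n)), fs), ica)


@pytest.fixture(scope="module")
def blink_setup():
    topo = np.zeros(16)
    topo[5] = 1.0
    cfg = SimConfig(n_channels=16, sampling_rate=100.0, n_trials=24,
                    pool_size=48, blink=BlinkSpec(rate_per_min=15),
                    source_specs=[SourceSpec(band_center=10.0,
                                             comodulation=0.8,
                                             topography=topo)],
                    resting_seconds=60.0, seed=21)
    task, rest = simulate_participant(cfg)
    ica = fit_ica(rest, seed=0)
    return cfg, task, rest, ica


def test_explicit_rejection_list_returned_verbatim(blink_setup):
    _, _, rest, ica = blink_setup
    assert select_artifact_components(ica, rest, explicit=[0, 3]) == [0, 3]


def test_auto_rejection_finds_blink_component(blink_setup):
    _, task, rest, ica = blink_setup
    bad = select_artifact_components(ica, rest)
    assert len(bad) >= 1
    blink_topo = np.array(rest.ground_truth["blink_topography"])
    assert max(_cos(ica.mixing[:, k], blink_topo) for k in bad) > 0.9

    ica.rejected = bad
    cleaned = apply_ica_cleaning(task, ica)
    trace = task.ground_truth["blink_trace"]
    frontal = int(np.argmax(blink_topo))
    r_before = np.corrcoef(task.signal[frontal], trace)[0, 1]
    r_after = np.corrcoef(cleaned.signal[frontal], trace)[0, 1]
    assert abs(r_before) > 0.5  # blink clearly present before cleaning
    assert abs(r_after) < 0.1
    src_topo = np.array(task.ground_truth["sources"][0]["topography"])
    proj_before = src_topo @ task.signal
    proj_after = src_topo @ cleaned.signal
    assert np.corrcoef(proj_before, proj_after)[0, 1] > 0.9


def test_auto_rejection_empty_without_blinks():
    cfg = SimConfig(n_channels=8, sampling_rate=100.0, n_trials=8,
                    pool_size=16, blink=BlinkSpec(rate_per_min=0),
                    resting_seconds=30.0, seed=5)
    from spocrt import generate_resting_state

    rest = generate_resting_state(cfg)
    ica = fit_ica(rest, seed=0)
    assert select_artifact_components(ica, rest) == []


# ---------------------------------------------------------------------------
# filter bank
# ---------------------------------------------------------------------------

def test_filter_bank_has_ten_symmetric_bands():
    bank = make_filter_bank(1000.0)
    assert len(bank) == 10
    assert [b.center for b in bank] == [2, 6, 10, 14, 18, 22, 26, 30, 34, 38]
    for b in bank:
        assert b.high - max(b.low, 0.0) <= 4.0 + 1e-9
        assert np.allclose(b.taps, b.taps[::-1])  # linear phase


def test_passband_sinusoid_preserved_with_zero_lag():
    fs, dur = 1000.0, 10.0
    t = np.arange(int(fs * dur)) / fs
    x = np.sin(2 * np.pi * 10.0 * t)[None, :]
    band10 = make_filter_bank(fs)[2]
    y = _zero_phase(x, band10.taps)
    core = slice(2000, -2000)  # away from edges
    ratio = np.abs(y[0, core]).max() / np.abs(x[0, core]).max()
    assert 0.95 < ratio < 1.05
    xc = np.correlate(y[0, core], x[0, core], mode="full")
    lag = np.argmax(xc) - (len(xc) // 2)
    assert lag == 0


def test_stopband_attenuation():
    fs = 1000.0
    t = np.arange(int(fs * 10)) / fs
    x = np.sin(2 * np.pi * 10.0 * t)[None, :]
    band22 = make_filter_bank(fs)[5]
    y = _zero_phase(x, band22.taps)
    core = slice(2000, -2000)
    assert np.sqrt(np.mean(y[0, core] ** 2)) <= 0.1 * np.sqrt(
        np.mean(x[0, core] ** 2))


def test_zero_signal_stays_zero():
    bank = make_filter_bank(250.0)
    y = _zero_phase(np.zeros((2, 5000)), bank[0].taps)
    assert np.allclose(y, 0.0)


def test_band_above_nyquist_rejected():
    with pytest.raises(ValueError, match="Nyquist"):
        make_filter_bank(60.0)


# ---------------------------------------------------------------------------
# epoching and retention
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_epochs(small_participant):
    task, _ = small_participant
    bank = make_filter_bank(task.sampling_rate, centers=(10.0, 22.0))
    bands = apply_filter_bank(task, bank)
    return epoch_session(bands, bank), task


def test_complete_session_yields_two_epochs_per_trial(small_epochs):
    epochs, task = small_epochs
    n = len(task.trials)
    assert epochs.n_epochs == 2 * n
    assert (epochs.metadata["epoch_type"] == "fixation").sum() == n
    assert (epochs.metadata["epoch_type"] == "stimulus").sum() == n


def test_stimulus_epoch_equals_raw_slice(small_epochs):
    epochs, task = small_epochs
    meta = epochs.metadata
    i = meta.index[meta["epoch_type"] == "stimulus"][0]
    a, b = int(meta.loc[i, "onset_sample"]), int(meta.loc[i, "end_sample"])
    # band 0 session slice equals the stored epoch (views, half-open window)
    bank = make_filter_bank(task.sampling_rate, centers=(10.0, 22.0))
    band0 = apply_filter_bank(task, bank)[0]
    assert np.array_equal(epochs.bands[0][i], band0.signal[:, a:b])


def test_truncated_session_epochs(small_participant):
    task, _ = small_participant
    one_trial = task.events[task.events["trial_index"] == 0]
    sess = RawSession(task.signal, task.sampling_rate, task.channel_names,
                      one_trial, trials=task.trials.iloc[:1])
    bank = make_filter_bank(task.sampling_rate, centers=(10.0,))
    epochs = epoch_session(apply_filter_bank(sess, bank), bank)
    assert epochs.n_epochs == 2


def test_orphan_markers_rejected(small_participant):
    task, _ = small_participant
    broken = task.events[~((task.events["trial_index"] == 3)
                           & (task.events["marker"] == "stimulus_on"))]
    sess = RawSession(task.signal, task.sampling_rate, task.channel_names,
                      broken, trials=task.trials)
    bank = make_filter_bank(task.sampling_rate, centers=(10.0,))
    with pytest.raises(ValueError, match=r"orphan markers.*3"):
        epoch_session(apply_filter_bank(sess, bank), bank)


def _toy_epochset(rows, fs=1000.0, n_ch=2):
    blocks = []
    for r in rows:
        length = int(r["end_sample"] - r["onset_sample"])
        blocks.append(np.random.default_rng(1).standard_normal((n_ch, length)))
    meta = pd.DataFrame(rows)
    return EpochSet({0: blocks}, meta, fs, [f"C{i}" for i in range(n_ch)],
                    {0: 10.0})


def _stim_row(trial, rt_ms, correct=True, timeout=False, fs=1000.0):
    onset = trial * 20000
    return {"epoch_type": "stimulus", "trial_index": trial,
            "onset_sample": onset,
            "end_sample": onset + int(rt_ms * fs / 1000), "angle": 0.0,
            "mirrored": False, "reaction_time_ms": rt_ms,
            "correct": correct, "timeout": timeout}


def test_retention_boundaries_at_700ms():
    rows = [_stim_row(0, 699.0), _stim_row(1, 700.0), _stim_row(2, 1500.0),
            _stim_row(3, 1500.0, correct=False),
            _stim_row(4, 7500.0, correct=False, timeout=True),
            dict(_stim_row(5, 1500.0), epoch_type="fixation")]
    out = filter_and_crop_epochs(_toy_epochset(rows))
    assert list(out.metadata["trial_index"]) == [1, 2]
    assert out.bands[0].shape == (2, 2, 500)
    assert out.removal_counts == {"fixation": 1, "incorrect_or_missing": 2,
                                  "too_fast": 1, "retained": 2}
    # retained window never overlaps the final 200 ms before the response
    for r in out.metadata.itertuples():
        assert 500 <= r.reaction_time_ms - 200


def test_full_retention_when_all_slow_and_correct():
    rows = [_stim_row(i, 800.0 + i) for i in range(10)]
    out = filter_and_crop_epochs(_toy_epochset(rows))
    assert out.n_epochs == 10


def test_empty_result_warns():
    rows = [_stim_row(0, 400.0)]
    with pytest.warns(UserWarning, match="no epochs retained"):
        out = filter_and_crop_epochs(_toy_epochset(rows))
    assert out.n_epochs == 0


@settings(max_examples=25, deadline=None)
@given(st.lists(st.tuples(st.floats(300, 3000), st.booleans(), st.booleans()),
                min_size=1, max_size=20))
def test_retention_rules_order_independent(spec):
    rows = []
    for i, (rt, correct, fixation) in enumerate(spec):
        r = _stim_row(i, float(rt), correct=correct)
        if fixation:
            r["epoch_type"] = "fixation"
        rows.append(r)
    meta = pd.DataFrame(rows)
    rules = {
        "a": (meta["epoch_type"] == "stimulus").to_numpy(),
        "b": (meta["correct"] & ~meta["timeout"]).to_numpy(),
        "c": (meta["reaction_time_ms"] >= 700).to_numpy(),
    }
    import itertools
    reference = rules["a"] & rules["b"] & rules["c"]
    for order in itertools.permutations("abc"):
        mask = np.ones(len(meta), bool)
        for key in order:
            mask &= rules[key]
        assert np.array_equal(mask, reference)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = filter_and_crop_epochs(_toy_epochset(rows))
    assert np.array_equal(
        out.metadata["trial_index"].to_numpy(),
        meta.loc[reference, "trial_index"].to_numpy())


def test_epochset_hdf5_round_trip(tmp_path, small_epochs):
    epochs, _ = small_epochs
    out = filter_and_crop_epochs(epochs)
    path = tmp_path / "epochs.h5"
    out.save(path)
    back = EpochSet.load(path)
    assert back.n_epochs == out.n_epochs
    for b in out.bands:
        assert np.allclose(back.bands[b], out.bands[b])
    assert back.removal_counts == out.removal_counts
    assert list(back.metadata.columns) == list(out.metadata.columns)
    assert np.allclose(back.metadata["reaction_time_ms"],
                       out.metadata["reaction_time_ms"])


def test_band_shapes_consistent_across_bands(small_epochs):
    epochs, _ = small_epochs
    out = filter_and_crop_epochs(epochs)
    shapes = {b: arr.shape for b, arr in out.bands.items()}
    assert len(set(shapes.values())) == 1
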