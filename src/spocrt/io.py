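"""On-disk session layout: EDF raw signal + BIDS-style TSV/JSON sidecars.

A session directory contains::

    <name>_eeg.edf          16-bit EDF, one channel per electrode, microvolts
    <name>_events.tsv       onset, duration, trial_type, trial metadata
    <name>_trials.tsv       full trial table (task sessions only)
    <name>_channels.tsv     name, type, units
    <name>_session.json     sampling rate, exact sample count
    <name>_ground_truth.json  planted-source record (simulated sessions)

The EDF writer is intentionally minimal (16-bit, one data record per second,
zero-padded final record; the exact sample count lives in the JSON sidecar).
Reading goes through :func:`mne.io.read_raw_edf`, so round-trips are checked
against an independent EDF implementation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import RawSession

__all__ = ["write_edf", "write_session", "read_session"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: Path, signal: np.ndarray, sfreq: float,
              ch_names: list[str]) -> None:
    """Write channels x samples microvolt data as 16-bit EDF."""
    signal = np.asarray(signal, float)
    n_ch, n_samples = signal.shape
    if len(ch_names) != n_ch:
        raise ValueError("channel name count does not match signal")
    spr = int(round(sfreq))  # one-second data records
    n_records = int(np.ceil(n_samples / spr))

    pmin = signal.min(axis=1)
    pmax = signal.max(axis=1)
    flat = pmax - pmin < 1e-9
    pmin[flat] -= 1.0
    pmax[flat] += 1.0

    header = b"".join([
        _pad("0", 8), _pad("X X X X", 80), _pad("Startdate 01-JAN-2000 X X X", 80),
        _pad("01.01.00", 8), _pad("00.00.00", 8),
        _pad(str(256 * (1 + n_ch)), 8), _pad("", 44),
        _pad(str(n_records), 8), _pad("1", 8), _pad(str(n_ch), 4),
    ])
    fields = [
        [_pad(name, 16) for name in ch_names],
        [_pad("AgAgCl electrode", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(f"{v:.3f}"[:8], 8) for v in pmin],
        [_pad(f"{v:.3f}"[:8], 8) for v in pmax],
        [_pad(str(_DIG_MIN), 8)] * n_ch,
        [_pad(str(_DIG_MAX), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(spr), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    # re-read physical bounds exactly as printed so scaling is self-consistent
    pmin_q = np.array([float(f.decode()) for f in fields[3]])
    pmax_q = np.array([float(f.decode()) for f in fields[4]])
    scale = (_DIG_MAX - _DIG_MIN) / (pmax_q - pmin_q)

    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_samples] = signal
    padded[:, n_samples:] = pmin_q[:, None]  # pad at physical minimum
    digital = np.round((padded - pmin_q[:, None]) * scale[:, None]
                       + _DIG_MIN).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for col in fields:
            fh.write(b"".join(col))
        for r in range(n_records):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def write_session(session: RawSession, directory: str | Path,
                  name: str = "session") -> Path:
    """Persist a session to ``directory``; returns the directory path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fs = session.sampling_rate
    write_edf(directory / f"{name}_eeg.edf", session.signal, fs,
              session.channel_names)

    ev = session.events.copy()
    rows = []
    trials = session.trials
    for e in ev.itertuples():
        dur = 0.0
        extra: dict = {}
        if trials is not None and e.trial_index >= 0:
            t = trials.loc[trials["trial_index"] == e.trial_index].iloc[0]
            if e.marker == "fixation_on":
                dur = (t["stimulus_onset"] - t["fixation_onset"]) / fs
            elif e.marker == "stimulus_on":
                dur = (t["response_sample"] - t["stimulus_onset"]) / fs
            extra = {
                "angle": t["angle"], "mirrored": bool(t["mirrored"]),
                "response": "timeout" if t["timeout"] else "pressed",
                "reaction_time_ms": t["reaction_time_ms"],
                "correct": bool(t["correct"]),
            }
        rows.append({"onset": e.sample / fs, "duration": dur,
                     "trial_type": e.marker, "trial_index": e.trial_index,
                     **extra})
    ev_cols = ["onset", "duration", "trial_type", "trial_index"]
    ev_out = pd.DataFrame(rows) if rows else pd.DataFrame(columns=ev_cols)
    ev_out.to_csv(directory / f"{name}_events.tsv", sep="\t", index=False)
    if trials is not None:
        trials.to_csv(directory / f"{name}_trials.tsv", sep="\t", index=False)

    pd.DataFrame({
        "name": session.channel_names,
        "type": ["EEG"] * len(session.channel_names),
        "units": ["uV"] * len(session.channel_names),
    }).to_csv(directory / f"{name}_channels.tsv", sep="\t", index=False)

    meta = {"sampling_rate": fs, "n_samples": int(session.n_samples),
            "n_channels": len(session.channel_names)}
    (directory / f"{name}_session.json").write_text(json.dumps(meta))

    if session.ground_truth is not None:
        gt = {k: v for k, v in session.ground_truth.items() if k != "blink_trace"}
        (directory / f"{name}_ground_truth.json").write_text(json.dumps(gt))
    return directory


def _rebuild_blink_trace(gt: dict, n_samples: int, fs: float) -> None:
    onsets = gt.get("blink_onsets")
    if onsets is None:
        return
    dur = max(int(round(300.0 * fs / 1000.0)), 3)
    shape = np.hanning(dur)
    trace = np.zeros(n_samples)
    for o in onsets:
        trace[o:o + dur] += shape[: n_samples - o]
    gt["blink_trace"] = trace


def read_session(directory: str | Path, name: str = "session") -> RawSession:
    """Load a session written by :func:`write_session`."""
    import mne

    directory = Path(directory)
    edf = directory / f"{name}_eeg.edf"
    meta_path = directory / f"{name}_session.json"
    for p in (edf, meta_path):
        if not p.exists():
            raise IOError(f"missing session file: {p}")
    meta = json.loads(meta_path.read_text())
    try:
        raw = mne.io.read_raw_edf(edf, preload=True, verbose="error")
    except Exception as exc:  # corrupted header etc.
        raise IOError(f"cannot read EDF file {edf}: {exc}") from exc
    signal = raw.get_data() * 1e6  # MNE returns volts for uV channels
    if signal.shape[1] < meta["n_samples"]:
        raise IOError(f"{edf} holds fewer samples than recorded in {meta_path}")
    signal = signal[:, : meta["n_samples"]]
    fs = meta["sampling_rate"]

    ev_path = directory / f"{name}_events.tsv"
    if not ev_path.exists():
        raise IOError(f"missing session file: {ev_path}")
    ev = pd.read_csv(ev_path, sep="\t")
    events = pd.DataFrame({
        "sample": np.round(ev["onset"].to_numpy(float) * fs).astype(int),
        "marker": ev["trial_type"],
        "trial_index": ev["trial_index"].astype(int),
    })

    trials_path = directory / f"{name}_trials.tsv"
    trials = pd.read_csv(trials_path, sep="\t") if trials_path.exists() else None

    gt_path = directory / f"{name}_ground_truth.json"
    gt = None
    if gt_path.exists():
        gt = json.loads(gt_path.read_text())
        _rebuild_blink_trace(gt, meta["n_samples"], fs)

    session = RawSession(signal, fs, list(raw.ch_names), events,
                         trials=trials, ground_truth=gt)
    session.validate()
    return session
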