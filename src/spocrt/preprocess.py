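"""EEG cleaning, filter-bank decomposition, epoching and epoch retention.

The cleaning chain mirrors a standard band-power decoding workflow:

1. ICA fitted on a 1 Hz high-passed copy of the resting-state segment;
   artifact components are zeroed in source space and the mixing matrix
   reconstructs the cleaned signal from the *raw, unfiltered* recording.
2. A bank of ten 4 Hz-wide, Hamming-windowed, linear-phase FIR band-pass
   filters (centers 2..38 Hz), applied in one pass with group-delay
   compensation so the net response is zero-phase.
3. Marker-based epoching: one epoch per presentation phase (fixation and
   stimulus), then retention rules — drop fixation epochs, incorrect or
   missing responses, and reaction times under 700 ms — and a crop to the
   first 500 ms of the stimulus phase. Because retained trials have
   RT >= 700 ms, the 500 ms window never overlaps the final 200 ms of
   motor preparation before the response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.decomposition import FastICA

from .simdata import RawSession

__all__ = [
    "IcaDecomposition",
    "BandDefinition",
    "EpochSet",
    "DEFAULT_CENTERS",
    "fit_ica",
    "select_artifact_components",
    "apply_ica_cleaning",
    "make_filter_bank",
    "apply_filter_bank",
    "epoch_session",
    "filter_and_crop_epochs",
    "preprocess_session",
]

#: Ten 4 Hz-wide bands; centers continue the arithmetic progression to 38 Hz.
DEFAULT_CENTERS = (2.0, 6.0, 10.0, 14.0, 18.0, 22.0, 26.0, 30.0, 34.0, 38.0)

MIN_RT_MS = 700.0
CROP_MS = 500.0
MOTOR_GUARD_MS = 200.0


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

@dataclass
class IcaDecomposition:
    unmixing: np.ndarray  # components x channels
    mixing: np.ndarray  # channels x components
    mean: np.ndarray  # per-channel mean removed before unmixing
    rejected: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]


def _highpass_1hz(signal: np.ndarray, fs: float) -> np.ndarray:
    numtaps = min(int(3.3 * fs / 1.0) | 1, (signal.shape[1] // 3) | 1)
    taps = sps.firwin(numtaps, 1.0, pass_zero=False, window="hamming", fs=fs)
    return _zero_phase(signal, taps)


def fit_ica(resting: RawSession, seed: int = 0) -> IcaDecomposition:
    """Fit FastICA on a 1 Hz high-passed copy of the resting recording."""
    fs = resting.sampling_rate
    if resting.n_samples < 10 * fs:
        raise ValueError("resting segment shorter than 10 s")
    X = resting.signal
    cov = np.cov(X)
    eigvals, eigvecs = np.linalg.eigh(cov)
    deficient = eigvals < 1e-10 * eigvals.max()
    if deficient.any():
        names = [resting.channel_names[int(np.argmax(np.abs(eigvecs[:, i])))]
                 for i in np.where(deficient)[0]]
        raise ValueError(f"rank-deficient input; implicated channels: {names}")
    hp = _highpass_1hz(X, fs)
    ica = FastICA(n_components=X.shape[0], whiten="unit-variance",
                  random_state=seed, max_iter=2000, tol=1e-7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on tiny fixtures
        ica.fit(hp.T)
    return IcaDecomposition(unmixing=ica.components_.copy(),
                            mixing=ica.mixing_.copy(),
                            mean=ica.mean_.copy())


def select_artifact_components(ica: IcaDecomposition, resting: RawSession,
                               explicit: list[int] | None = None,
                               threshold: float = 0.8) -> list[int]:
    """Choose components to reject.

    An explicit configured list wins; otherwise components whose resting
    time course correlates |r| >= ``threshold`` with the blink reference are
    flagged. The reference is the simulated session's ground-truth blink
    trace when available, else a low-passed frontal-channel average.
    """
    if explicit is not None:
        bad = [int(i) for i in explicit]
        for i in bad:
            if not 0 <= i < ica.n_components:
                raise ValueError(f"component index {i} out of range")
        return bad
    fs = resting.sampling_rate
    gt = resting.ground_truth or {}
    ref = gt.get("blink_trace")
    if ref is None:
        frontal = [i for i, n in enumerate(resting.channel_names)
                   if n.startswith(("Fp", "F"))] or [0]
        sos = sps.butter(4, 5.0, btype="low", fs=fs, output="sos")
        ref = sps.sosfiltfilt(sos, resting.signal[frontal].mean(axis=0))
    ref = np.asarray(ref, float)
    if ref.std() == 0:
        return []
    sources = ica.unmixing @ (resting.signal - ica.mean[:, None])
    bad = []
    for i, s in enumerate(sources):
        if s.std() == 0:
            continue
        r = np.corrcoef(s, ref)[0, 1]
        if abs(r) >= threshold:
            bad.append(i)
    return bad


def apply_ica_cleaning(raw: RawSession, ica: IcaDecomposition) -> RawSession:
    """Zero rejected sources and reconstruct from the raw unfiltered signal."""
    if raw.signal.shape[0] != ica.unmixing.shape[1]:
        raise ValueError("channel count does not match ICA decomposition")
    sources = ica.unmixing @ (raw.signal - ica.mean[:, None])
    if ica.rejected:
        sources[ica.rejected] = 0.0
    cleaned = ica.mixing @ sources + ica.mean[:, None]
    return RawSession(cleaned, raw.sampling_rate, list(raw.channel_names),
                      raw.events, trials=raw.trials,
                      ground_truth=raw.ground_truth)


# ---------------------------------------------------------------------------
# filter bank
# ---------------------------------------------------------------------------

@dataclass
class BandDefinition:
    index: int
    center: float
    low: float
    high: float
    taps: np.ndarray


def make_filter_bank(fs: float, centers: tuple[float, ...] = DEFAULT_CENTERS,
                     width: float = 4.0,
                     transition: float = 2.0) -> list[BandDefinition]:
    """Design the Hamming-window FIR band-pass bank.

    The lowest band's lower edge touches 0 Hz and degrades to a low-pass
    design. Filter order follows the Hamming-window transition-width rule
    (about 3.3 / (transition / fs) taps, forced odd for exact linear phase).
    """
    bands = []
    numtaps = int(np.ceil(3.3 * fs / transition)) | 1
    for i, c in enumerate(centers):
        low, high = c - width / 2, c + width / 2
        if high >= fs / 2:
            raise ValueError(f"band {c} Hz exceeds Nyquist ({fs / 2} Hz)")
        if low <= 0:
            taps = sps.firwin(numtaps, high, pass_zero=True, window="hamming",
                              fs=fs)
        else:
            taps = sps.firwin(numtaps, [low, high], pass_zero=False,
                              window="hamming", fs=fs)
        bands.append(BandDefinition(i, c, max(low, 0.0), high, taps))
    return bands


def _zero_phase(signal: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """One-pass zero-phase filtering of channels x samples data.

    Symmetric (linear-phase) taps applied once; the group delay of
    (numtaps-1)/2 samples is removed by centered convolution. Edges are
    reflect-padded by one filter length and trimmed afterwards.
    """
    n = signal.shape[1]
    pad = min(len(taps), n - 1)
    padded = np.pad(signal, [(0, 0), (pad, pad)], mode="reflect")
    out = sps.fftconvolve(padded, taps[None, :], mode="same", axes=1)
    return out[:, pad:pad + n]


def apply_filter_bank(raw: RawSession,
                      bands: list[BandDefinition]) -> list[RawSession]:
    """Apply every band filter; returns one session per band."""
    out = []
    for band in bands:
        filt = _zero_phase(raw.signal, band.taps)
        out.append(RawSession(filt, raw.sampling_rate, list(raw.channel_names),
                              raw.events, trials=raw.trials,
                              ground_truth=raw.ground_truth))
    return out


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Per-band epoch blocks plus 1:1-aligned trial metadata.

    ``bands`` maps band index -> (epochs x channels x samples) array; before
    cropping the per-band entries are lists of variable-length views.
    ``removal_counts`` records how many epochs each retention rule dropped.
    """

    bands: dict[int, np.ndarray]
    metadata: pd.DataFrame
    sampling_rate: float
    channel_names: list[str]
    band_centers: dict[int, float]
    removal_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.metadata)

    def select(self, indices) -> "EpochSet":
        """Row-subset (e.g. chronological train/hold-out split); copies blocks."""
        indices = np.asarray(indices)
        bands = {b: np.asarray(blk)[indices] for b, blk in self.bands.items()}
        meta = self.metadata.iloc[indices].reset_index(drop=True)
        return EpochSet(bands, meta, self.sampling_rate,
                        list(self.channel_names), dict(self.band_centers),
                        dict(self.removal_counts))

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["sampling_rate"] = self.sampling_rate
            f.attrs["channel_names"] = [str(c) for c in self.channel_names]
            grp = f.create_group("bands")
            for b, block in self.bands.items():
                d = grp.create_dataset(f"band_{b:02d}", data=np.asarray(block))
                d.attrs["center"] = self.band_centers[b]
            meta = f.create_group("metadata")
            meta.attrs["column_order"] = [str(c) for c in self.metadata.columns]
            for col in self.metadata.columns:
                v = self.metadata[col].to_numpy()
                if v.dtype == object:
                    v = v.astype("S")
                meta.create_dataset(col, data=v)
            rem = f.create_group("removal_counts")
            for k, v in self.removal_counts.items():
                rem.attrs[k] = v

    @classmethod
    def load(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            bands, centers = {}, {}
            for name, d in f["bands"].items():
                b = int(name.split("_")[1])
                bands[b] = d[()]
                centers[b] = float(d.attrs["center"])
            cols = {}
            for col, d in f["metadata"].items():
                v = d[()]
                if v.dtype.kind == "S":
                    v = v.astype(str)
                cols[col] = v
            order = [str(c) for c in f["metadata"].attrs["column_order"]]
            meta = pd.DataFrame(cols)[order]
            counts = dict(f["removal_counts"].attrs)
            return cls(bands, meta, float(f.attrs["sampling_rate"]),
                       [str(c) for c in f.attrs["channel_names"]], centers,
                       {k: int(v) for k, v in counts.items()})


def epoch_session(band_sessions: list[RawSession],
                  bands: list[BandDefinition]) -> EpochSet:
    """Cut every band session into presentation-phase epochs.

    One epoch per phase: fixation [fixation_on, stimulus_on) and stimulus
    [stimulus_on, response-or-timeout). Sample indexing is 0-based with
    half-open windows. Epoch arrays are views into the band signals (no copy
    until cropping). A complete 192-trial session yields 384 epochs.
    """
    ref = band_sessions[0]
    ev = ref.events
    trials = ref.trials
    by_trial: dict[int, dict[str, int]] = {}
    for e in ev.itertuples():
        if e.trial_index < 0:
            continue
        by_trial.setdefault(int(e.trial_index), {})[e.marker] = int(e.sample)
    orphans = [t for t, m in by_trial.items()
               if "fixation_on" not in m or "stimulus_on" not in m
               or ("response" not in m and "timeout" not in m)]
    if orphans:
        raise ValueError(f"orphan markers for trials {sorted(orphans)}")

    rows, slices = [], []
    for t in sorted(by_trial):
        m = by_trial[t]
        end = m.get("response", m.get("timeout"))
        info: dict = {"trial_index": t}
        if trials is not None:
            tr = trials.loc[trials["trial_index"] == t].iloc[0]
            info.update(angle=float(tr["angle"]), mirrored=bool(tr["mirrored"]),
                        reaction_time_ms=float(tr["reaction_time_ms"]),
                        correct=bool(tr["correct"]), timeout=bool(tr["timeout"]))
        for phase, (a, b) in (("fixation", (m["fixation_on"], m["stimulus_on"])),
                              ("stimulus", (m["stimulus_on"], end))):
            rows.append({"epoch_type": phase, "onset_sample": a,
                         "end_sample": b, **info})
            slices.append((a, b))
    meta = pd.DataFrame(rows)
    band_blocks = {band.index: [s.signal[:, a:b] for (a, b) in slices]
                   for band, s in zip(bands, band_sessions)}
    return EpochSet(band_blocks, meta, ref.sampling_rate,
                    list(ref.channel_names), {b.index: b.center for b in bands})


def filter_and_crop_epochs(epochs: EpochSet,
                           min_rt_ms: float = MIN_RT_MS,
                           crop_ms: float = CROP_MS) -> EpochSet:
    """Apply the retention rules and crop to the initial stimulus window.

    Drops (a) fixation epochs, (b) incorrect or missing (timeout) responses,
    (c) reaction times below ``min_rt_ms`` (700 ms: a 700 ms response is
    retained). Remaining epochs are cropped to [0, crop_ms) from stimulus
    onset. The retained window then always ends at least 200 ms before the
    response. The rules commute: the retained set is order-independent.
    """
    meta = epochs.metadata
    is_stim = (meta["epoch_type"] == "stimulus").to_numpy()
    correct = meta.get("correct", pd.Series(True, index=meta.index)).to_numpy(bool)
    timeout = meta.get("timeout", pd.Series(False, index=meta.index)).to_numpy(bool)
    rt = meta.get("reaction_time_ms",
                  pd.Series(np.inf, index=meta.index)).to_numpy(float)
    keep = is_stim & correct & ~timeout & (rt >= min_rt_ms)

    counts = {
        "fixation": int((~is_stim).sum()),
        "incorrect_or_missing": int((is_stim & (~correct | timeout)).sum()),
        "too_fast": int((is_stim & correct & ~timeout & (rt < min_rt_ms)).sum()),
        "retained": int(keep.sum()),
    }
    if counts["retained"] == 0:
        warnings.warn("no epochs retained after filtering", stacklevel=2)

    fs = epochs.sampling_rate
    n_crop = int(round(crop_ms * fs / 1000.0))
    guard = int(round(MOTOR_GUARD_MS * fs / 1000.0))
    idx = np.where(keep)[0]
    new_meta = meta.iloc[idx].reset_index(drop=True)
    new_bands = {}
    for b, blocks in epochs.bands.items():
        out = np.empty((len(idx), len(epochs.channel_names), n_crop))
        for j, i in enumerate(idx):
            e = blocks[i]
            if e.shape[1] < n_crop:
                raise ValueError(f"epoch {i} shorter than the crop window")
            assert n_crop <= e.shape[1] - guard, \
                "retained window overlaps the motor-preparation guard"
            out[j] = e[:, :n_crop]
        new_bands[b] = out
    return EpochSet(new_bands, new_meta, fs, list(epochs.channel_names),
                    dict(epochs.band_centers), counts)


def preprocess_session(task: RawSession, rest: RawSession | None = None,
                       ica_reject: list[int] | None = None,
                       ica_mode: str = "auto",
                       centers: tuple[float, ...] = DEFAULT_CENTERS,
                       seed: int = 0) -> EpochSet:
    """Full cleaning chain: ICA -> filter bank -> epoch -> retain/crop.

    ``ica_mode`` is "auto" (heuristic blink rejection), "list" (use
    ``ica_reject`` verbatim) or "none" (skip ICA entirely).
    """
    cleaned = task
    if ica_mode != "none":
        if rest is None:
            raise ValueError("resting session required unless ica_mode='none'")
        ica = fit_ica(rest, seed=seed)
        ica.rejected = select_artifact_components(
            ica, rest, explicit=ica_reject if ica_mode == "list" else None)
        cleaned = apply_ica_cleaning(task, ica)
    bank = make_filter_bank(task.sampling_rate, centers=centers)
    band_sessions = apply_filter_bank(cleaned, bank)
    epochs = epoch_session(band_sessions, bank)
    return filter_and_crop_epochs(epochs)
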