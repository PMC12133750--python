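"""Preprocessing pipeline for continuous motor-imagery EEG.

Fixed stage order: 4th-order Butterworth bandpass (0.5-100 Hz, zero-phase)
-> polyphase resampling (default 1000 -> 128 Hz) -> optional ICA-based
artifact-component rejection -> epoching around each trigger (default
-0.5 .. +1.5 s, i.e. 2-s epochs) -> per-(trial, channel) z-scoring.

Filtering is applied forward-backward (zero-phase), so amplitude
attenuation follows the *squared* Butterworth magnitude response; phase
is untouched, which matters downstream for phase-locking estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.stats import kurtosis as _kurtosis

from .montage import Montage
from .synth import RawRecording

__all__ = [
    "FilterSpec",
    "EpochSet",
    "bandpass",
    "resample",
    "reject_artifact_components",
    "epoch",
    "zscore",
    "preprocess_recording",
    "save_epochs_h5",
    "load_epochs_h5",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass parameters (family is fixed to Butterworth)."""

    order: int = 4
    low: float = 0.5
    high: float = 100.0

    def validate(self, fs: float) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"need 0 < low < high, got [{self.low}, {self.high}]")
        if self.high >= fs / 2:
            raise ValueError(
                f"high edge {self.high} Hz is at or above the Nyquist limit {fs / 2} Hz"
            )


@dataclass(frozen=True)
class EpochSet:
    """Epoched trials: ``data`` is trials x channels x time.

    ``window`` is the (t_start, t_end) epoch window in seconds relative
    to the trigger; ``labels`` holds one class label per trial.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    window: tuple[float, float]
    montage: Montage

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        labels = np.asarray(self.labels)
        if data.ndim != 3:
            raise ValueError(f"data must be trials x channels x time, got shape {data.shape}")
        if data.shape[1] != self.montage.n_channels:
            raise ValueError("channel axis does not match montage")
        if labels.shape != (data.shape[0],):
            raise ValueError("labels length must equal number of trials")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]


def bandpass(rec: RawRecording, spec: FilterSpec = FilterSpec()) -> RawRecording:
    """Zero-phase Butterworth bandpass, applied per channel."""
    spec.validate(rec.fs)
    sos = signal.butter(spec.order, [spec.low, spec.high], btype="bandpass", fs=rec.fs, output="sos")
    out = np.empty_like(rec.data)
    for c in range(rec.data.shape[0]):
        out[c] = signal.sosfiltfilt(sos, rec.data[c])
    return RawRecording(data=out, fs=rec.fs, montage=rec.montage, events=rec.events)


def resample(rec: RawRecording, fs_out: float) -> RawRecording:
    """Polyphase resampling; event trigger indices rescale with the rate.

    The output length is ``round(n * fs_out / fs)``; triggers are
    rescaled by the same ratio with round-half-even.
    """
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    if fs_out > rec.fs:
        raise ValueError(f"fs_out={fs_out} exceeds the recording rate {rec.fs}")
    if fs_out == rec.fs:
        return rec
    frac = Fraction(fs_out / rec.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(rec.data, up, down, axis=1)
    n_target = int(np.rint(rec.data.shape[1] * fs_out / rec.fs))
    out = out[:, :n_target]
    ratio = fs_out / rec.fs
    events = tuple(
        (int(np.rint(s * ratio)), c)
        for s, c in rec.events
    )
    return RawRecording(data=out, fs=fs_out, montage=rec.montage, events=events)


def reject_artifact_components(
    rec: RawRecording,
    frontal_channels: tuple[str, ...] = ("Fp1", "Fp2"),
    corr_threshold: float = 0.8,
    kurtosis_threshold: float = 8.0,
    seed: int = 0,
) -> RawRecording:
    """ICA decomposition with heuristic component rejection.

    Components whose time course correlates with any frontal channel
    above ``corr_threshold`` (ocular surrogate) OR whose excess kurtosis
    exceeds ``kurtosis_threshold`` (spiky/muscular surrogate) are zeroed
    before reconstruction.  The decomposition is FastICA with a fixed
    seed, so the stage is deterministic.
    """
    from sklearn.decomposition import FastICA

    C = rec.data.shape[0]
    if C < 2:
        raise ValueError("artifact rejection needs at least 2 channels")
    frontal_idx = [rec.montage.index(ch) for ch in frontal_channels]

    X = rec.data.T  # samples x channels
    ica = FastICA(n_components=C, random_state=seed, whiten="unit-variance", max_iter=1000)
    try:
        S = ica.fit_transform(X)
    except Exception as exc:  # rank-deficient or non-converging input
        raise ValueError(
            "ICA decomposition failed (input may be rank-deficient); "
            "consider dropping duplicate channels or adding noise"
        ) from exc

    keep = np.ones(C, dtype=bool)
    for k in range(C):
        comp = S[:, k]
        corr = max(
            abs(np.corrcoef(comp, rec.data[i])[0, 1]) for i in frontal_idx
        )
        if corr > corr_threshold or _kurtosis(comp, fisher=True) > kurtosis_threshold:
            keep[k] = False
    S_clean = S * keep[None, :]
    X_clean = ica.inverse_transform(S_clean)
    n_removed = int((~keep).sum())
    out = RawRecording(data=X_clean.T, fs=rec.fs, montage=rec.montage, events=rec.events)
    out = replace_n_removed(out, n_removed)
    return out


def replace_n_removed(rec: RawRecording, n: int) -> RawRecording:
    # piggy-back the count without widening the frozen dataclass contract
    object.__setattr__(rec, "n_removed_components", n)
    return rec


def epoch(rec: RawRecording, t_start: float = -0.5, t_end: float = 1.5) -> EpochSet:
    """Cut one epoch per event over the half-open window [t_start, t_end).

    Sample range per event: ``[trigger + rint(t_start*fs),
    trigger + rint(t_end*fs))`` with 0-based indices.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    off0 = int(np.rint(t_start * rec.fs))
    off1 = int(np.rint(t_end * rec.fs))
    n_t = off1 - off0
    bad = [
        (s, c) for s, c in rec.events
        if s + off0 < 0 or s + off1 > rec.n_samples
    ]
    if bad:
        raise ValueError(
            "epoch window out of bounds for trigger(s): "
            + ", ".join(f"{s} (class {c}, window [{s + off0}, {s + off1}))" for s, c in bad)
        )
    n_trials = len(rec.events)
    data = np.empty((n_trials, rec.data.shape[0], n_t))
    labels = np.empty(n_trials, dtype=int)
    for i, (s, c) in enumerate(rec.events):
        data[i] = rec.data[:, s + off0 : s + off1]
        labels[i] = c
    return EpochSet(data=data, labels=labels, fs=rec.fs, window=(t_start, t_end), montage=rec.montage)


def zscore(ep: EpochSet) -> EpochSet:
    """Per-(trial, channel) z-scoring with population std (denominator T)."""
    mean = ep.data.mean(axis=2, keepdims=True)
    std = ep.data.std(axis=2, keepdims=True)  # ddof=0
    zero = np.argwhere(std[:, :, 0] == 0)
    if zero.size:
        t, c = zero[0]
        raise ValueError(
            f"zero-variance channel: trial {t}, channel {ep.montage.channel_names[c]!r}"
        )
    out = (ep.data - mean) / std
    return EpochSet(data=out, labels=ep.labels, fs=ep.fs, window=ep.window, montage=ep.montage)


def preprocess_recording(
    rec: RawRecording,
    filter_spec: FilterSpec = FilterSpec(),
    fs_out: float = 128.0,
    ica: bool = False,
    frontal_channels: tuple[str, ...] = ("Fp1", "Fp2"),
    corr_threshold: float = 0.8,
    kurtosis_threshold: float = 8.0,
    t_start: float = -0.5,
    t_end: float = 1.5,
    ica_seed: int = 0,
) -> EpochSet:
    """Run the full fixed-order pipeline and return z-scored epochs.

    Artifact-component rejection is opt-in (``ica=True``): recordings from
    the bundled generator contain no ocular/muscular sources, and the
    stage is comparatively expensive on long recordings.
    """
    rec = bandpass(rec, filter_spec)
    rec = resample(rec, fs_out)
    if ica:
        rec = reject_artifact_components(
            rec, frontal_channels, corr_threshold, kurtosis_threshold, seed=ica_seed
        )
    ep = epoch(rec, t_start, t_end)
    return zscore(ep)


# -- container I/O -----------------------------------------------------------

def save_epochs_h5(ep: EpochSet, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ep.data)
        f.create_dataset("labels", data=np.asarray(ep.labels, dtype=np.int64))
        f.create_dataset("fs", data=float(ep.fs))
        f.create_dataset("window", data=np.array(ep.window, dtype=float))
        f.create_dataset(
            "channel_names",
            data=np.array(ep.montage.channel_names, dtype=h5py.string_dtype()),
        )
        f.create_dataset("positions", data=ep.montage.positions)


def load_epochs_h5(path) -> EpochSet:
    import h5py

    with h5py.File(path, "r") as f:
        names = tuple(n.decode() if isinstance(n, bytes) else str(n) for n in f["channel_names"][()])
        mont = Montage(channel_names=names, positions=f["positions"][()])
        w = f["window"][()]
        return EpochSet(
            data=f["data"][()],
            labels=f["labels"][()],
            fs=float(f["fs"][()]),
            window=(float(w[0]), float(w[1])),
            montage=mont,
        )
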