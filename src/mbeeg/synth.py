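"""Synthetic five-class motor-imagery EEG with known ground truth.

The generator emulates the structure of a 22-channel, 1000 Hz, cue-based
five-class finger motor-imagery recording: every trial is a 4-s segment of
1/f background noise plus narrow-band oscillations in the five canonical
bands.  Class identity is encoded as event-related desynchronisation
(ERD): for the trial's class, the oscillation amplitude of configured
(channel, band) pairs is multiplied by a factor < 1 (or > 1 for ERS)
during the post-trigger window, concentrated by default at the motor
electrodes C3/C4/Cz in the Beta band.  Inter-channel phase coupling is
injected by mixing a shared oscillator into both channels of a coupled
pair, which gives a controllable phase-locking ground truth.

Container formats
-----------------
``save_recording_h5`` / ``save_recording_npz`` write a recording with the
datasets/arrays ``data`` (channels x samples, microvolts), ``fs`` (Hz),
``channel_names``, ``positions`` (channels x 3), and ``events``
(n_events x 2 integer array of [trigger_sample, class_label]).  The
matching loaders restore an identical :class:`RawRecording`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bands import BandSpec, default_bands
from .montage import Montage, standard_1020_montage

__all__ = [
    "SynthSpec",
    "RawRecording",
    "default_erd_map",
    "generate_recording",
    "generate_epochs",
    "save_recording_h5",
    "load_recording_h5",
    "save_recording_npz",
    "load_recording_npz",
]

#: Relative base amplitude of each band's oscillator (before SNR scaling);
#: roughly follows the 1/f envelope of resting EEG with a prominent Alpha.
_BAND_REL_AMP = {"Delta": 1.0, "Theta": 0.8, "Alpha": 1.0, "Beta": 0.7, "Gamma": 0.4}

_NOISE_RMS_UV = 10.0  # background-noise RMS, microvolts


def default_erd_map(factor: float = 0.5) -> dict[int, dict[str, dict[str, float]]]:
    """Class -> channel -> band -> amplitude factor for the default task.

    The five classes suppress Beta amplitude at distinct subsets of the
    motor electrodes, mimicking contralateral/midline ERD patterns:
    class 1 at C3, class 2 at C4, class 3 at Cz, class 4 at C3+C4,
    class 5 at all three.
    """
    return {
        1: {"C3": {"Beta": factor}},
        2: {"C4": {"Beta": factor}},
        3: {"Cz": {"Beta": factor}},
        4: {"C3": {"Beta": factor}, "C4": {"Beta": factor}},
        5: {"C3": {"Beta": factor}, "C4": {"Beta": factor}, "Cz": {"Beta": factor}},
    }


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic recording.

    Attributes
    ----------
    n_trials_per_class
        Trials generated for each class (balance is exact by construction).
    fs
        Sampling rate in Hz.
    trial_len
        Trial duration in seconds; the trigger sits ``trigger_offset``
        seconds into the trial and ERD applies from trigger to trial end.
    classes
        Class labels (default 1..5).
    erd_channels
        class -> channel -> band-name -> amplitude factor in (0, 2].
    coupling_pairs
        (channel_a, channel_b, band_name, strength in [0, 1]); both
        channels share a band oscillator mixed in proportion to strength.
    noise_exponent
        Slope of the 1/f background-noise spectrum.
    snr
        Ratio of total oscillation RMS to noise RMS per channel.
    """

    n_trials_per_class: int = 10
    fs: float = 1000.0
    trial_len: float = 4.0
    classes: tuple[int, ...] = (1, 2, 3, 4, 5)
    erd_channels: dict = field(default_factory=default_erd_map)
    coupling_pairs: tuple = (("C3", "C4", "Beta", 0.8),)
    noise_exponent: float = 1.0
    snr: float = 1.0
    seed: int = 0
    trigger_offset: float = 1.0
    inter_trial_gap: float = 0.5
    montage: Montage = field(default_factory=standard_1020_montage)

    def __post_init__(self) -> None:
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if not 0 < self.trigger_offset < self.trial_len:
            raise ValueError("trigger_offset must fall inside the trial")
        bands = {b.name: b for b in default_bands(self.fs)}
        for cls, chmap in self.erd_channels.items():
            if cls not in self.classes:
                raise ValueError(f"ERD map references unknown class {cls}")
            for ch, bmap in chmap.items():
                if ch not in self.montage.channel_names:
                    raise ValueError(f"ERD channel {ch!r} not in montage")
                for bname, fac in bmap.items():
                    if bname not in bands:
                        raise ValueError(f"unknown band {bname!r} in ERD map")
                    if not 0 < fac <= 2:
                        raise ValueError(f"ERD factor {fac} outside (0, 2]")
        for a, b, bname, strength in self.coupling_pairs:
            for ch in (a, b):
                if ch not in self.montage.channel_names:
                    raise ValueError(f"coupling channel {ch!r} not in montage")
            if bname not in bands:
                raise ValueError(f"unknown band {bname!r} in coupling pair")
            if not 0 <= strength <= 1:
                raise ValueError(f"coupling strength {strength} outside [0, 1]")
        highest = max(b.high for b in default_bands(self.fs))
        if self.fs <= 2 * highest:
            raise ValueError(f"fs={self.fs} must exceed twice the highest band edge {highest}")


@dataclass(frozen=True)
class RawRecording:
    """Continuous multichannel recording with event markers.

    ``data`` is channels x samples in microvolts; ``events`` is a list of
    ``(trigger_sample, class_label)`` pairs with 0-based sample indices.
    """

    data: np.ndarray
    fs: float
    montage: Montage
    events: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data must be (n_channels={self.montage.n_channels}, n_samples), got {data.shape}"
            )
        events = tuple((int(s), int(c)) for s, c in self.events)
        for s, _ in events:
            if not 0 <= s < data.shape[1]:
                raise ValueError(f"event trigger sample {s} outside recording")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "events", events)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _one_over_f_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Gaussian noise with a |f|^-exponent amplitude spectrum, unit RMS."""
    from scipy.fft import irfft, next_fast_len, rfft

    n_fft = next_fast_len(n)  # pad to a friendly FFT length, then crop
    white = rng.standard_normal(n_fft)
    spec = rfft(white)
    freqs = np.fft.rfftfreq(n_fft, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # zero-mean
    out = irfft(spec * scale, n=n_fft)[:n]
    return out / out.std()


def _oscillator_phase(rng: np.random.Generator, n: int, band: BandSpec, fs: float) -> np.ndarray:
    """Phase track of a narrow-band oscillator centred in ``band``.

    Centre-frequency ramp plus a phase random walk whose step size keeps
    the instantaneous frequency well inside the band.
    """
    fc = 0.5 * (band.low + band.high)
    step = 2 * np.pi * (band.high - band.low) / 20.0 / np.sqrt(fs)
    walk = np.cumsum(rng.standard_normal(n)) * step
    phi0 = rng.uniform(-np.pi, np.pi)
    t = np.arange(n) / fs
    return 2 * np.pi * fc * t + walk + phi0


def generate_recording(spec: SynthSpec) -> RawRecording:
    """Generate a continuous recording per ``spec``; reproducible from its seed."""
    rng = np.random.default_rng(spec.seed)
    mont = spec.montage
    C = mont.n_channels
    fs = spec.fs
    bands = default_bands(fs)
    trial_n = int(round(spec.trial_len * fs))
    gap_n = int(round(spec.inter_trial_gap * fs))
    trig_n = int(round(spec.trigger_offset * fs))

    labels = np.repeat(np.asarray(spec.classes), spec.n_trials_per_class)
    rng.shuffle(labels)
    n_trials = labels.size
    total_n = n_trials * (trial_n + gap_n) + gap_n

    data = np.empty((C, total_n))
    for c in range(C):
        data[c] = _one_over_f_noise(rng, total_n, spec.noise_exponent) * _NOISE_RMS_UV

    # amplitude scale so per-channel oscillation RMS = snr * noise RMS
    rel = np.array([_BAND_REL_AMP[b.name] for b in bands])
    total_pow = np.sum(rel**2 / 2.0)
    amp_scale = spec.snr * _NOISE_RMS_UV / np.sqrt(total_pow)
    base_amp = {b.name: _BAND_REL_AMP[b.name] * amp_scale for b in bands}

    coupling = {}  # (channel, band) -> (partner_key, strength) resolved below
    shared_phase_keys: dict[tuple[str, str], int] = {}
    for a, b, bname, strength in spec.coupling_pairs:
        key = (a, b, bname)
        shared_phase_keys[key] = len(shared_phase_keys)
        coupling[(a, bname)] = (key, strength)
        coupling[(b, bname)] = (key, strength)

    n_bands = len(bands)
    t_axis = np.arange(trial_n) / fs
    fc = np.array([0.5 * (b.low + b.high) for b in bands])
    walk_step = np.array([2 * np.pi * (b.high - b.low) / 20.0 / np.sqrt(fs) for b in bands])
    ramp = 2 * np.pi * fc[:, None] * t_axis[None, :]  # n_bands x T

    events = []
    start = gap_n
    for ti in range(n_trials):
        cls = int(labels[ti])
        sl = slice(start, start + trial_n)
        # shared oscillators for this trial, one per coupling pair+band
        shared = {
            key: _oscillator_phase(rng, trial_n, next(bb for bb in bands if bb.name == key[2]), fs)
            for key in shared_phase_keys
        }
        # all per-channel oscillator phases in one vectorised draw
        walks = np.cumsum(rng.standard_normal((C, n_bands, trial_n)), axis=-1)
        walks *= walk_step[None, :, None]
        phases = ramp[None] + walks + rng.uniform(-np.pi, np.pi, size=(C, n_bands))[:, :, None]
        osc = np.cos(phases)  # C x n_bands x T
        for (ch_a, ch_b, bname), key_idx in shared_phase_keys.items():
            bi = next(i for i, b in enumerate(bands) if b.name == bname)
            shared_cos = np.cos(shared[(ch_a, ch_b, bname)])
            strength = coupling[(ch_a, bname)][1]
            for ch in (ch_a, ch_b):
                ci = mont.index(ch)
                osc[ci, bi] = strength * shared_cos + (1.0 - strength) * osc[ci, bi]
        amps = np.tile(
            np.array([base_amp[b.name] for b in bands])[None, :, None], (C, 1, trial_n)
        )
        erd_for_cls = spec.erd_channels.get(cls, {})
        for ch, bmap in erd_for_cls.items():
            ci = mont.index(ch)
            for bname, factor in bmap.items():
                bi = next(i for i, b in enumerate(bands) if b.name == bname)
                amps[ci, bi, trig_n:] *= factor
        data[:, sl] += np.einsum("cbt,cbt->ct", amps, osc)
        events.append((start + trig_n, cls))
        start += trial_n + gap_n

    return RawRecording(data=data, fs=fs, montage=mont, events=tuple(events))


def generate_epochs(spec: SynthSpec, fs_out: float = 128.0, ica: bool = False):
    """Generate a recording and push it through the default preprocessing.

    Convenience wrapper: :func:`generate_recording` followed by the
    standard pipeline (bandpass 0.5-100 Hz, resample to ``fs_out``,
    optional artifact-component rejection, epoch -0.5..+1.5 s, z-score).
    Returns a labelled ``EpochSet``.
    """
    from .preprocess import preprocess_recording

    rec = generate_recording(spec)
    return preprocess_recording(rec, fs_out=fs_out, ica=ica)


# -- container I/O -----------------------------------------------------------

def save_recording_h5(rec: RawRecording, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset(
            "channel_names",
            data=np.array(rec.montage.channel_names, dtype=h5py.string_dtype()),
        )
        f.create_dataset("positions", data=rec.montage.positions)
        f.create_dataset("events", data=np.array(rec.events, dtype=np.int64).reshape(-1, 2))


def load_recording_h5(path) -> RawRecording:
    import h5py

    with h5py.File(path, "r") as f:
        names = tuple(n.decode() if isinstance(n, bytes) else str(n) for n in f["channel_names"][()])
        mont = Montage(channel_names=names, positions=f["positions"][()])
        events = tuple((int(s), int(c)) for s, c in f["events"][()])
        return RawRecording(data=f["data"][()], fs=float(f["fs"][()]), montage=mont, events=events)


def save_recording_npz(rec: RawRecording, path) -> None:
    np.savez(
        path,
        data=rec.data,
        fs=np.array(rec.fs),
        channel_names=np.array(rec.montage.channel_names),
        positions=rec.montage.positions,
        events=np.array(rec.events, dtype=np.int64).reshape(-1, 2),
    )


def load_recording_npz(path) -> RawRecording:
    with np.load(path, allow_pickle=False) as f:
        names = tuple(str(n) for n in f["channel_names"])
        mont = Montage(channel_names=names, positions=f["positions"])
        events = tuple((int(s), int(c)) for s, c in f["events"])
        return RawRecording(data=f["data"], fs=float(f["fs"]), montage=mont, events=events)
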