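"""Phase-locking connectivity and adjacency-graph construction.

The phase-locking value (PLV) between two channels is the magnitude of
the time-averaged unit phasor of their phase difference,

    PLV = | (1/T) * sum_t exp(i * dPhi(t)) |,

which is 1 for a constant phase offset and tends to the T-dependent
noise floor (~sqrt(pi)/(2 sqrt(T))) for independent phases.  Phase is
extracted as the analytic-signal angle of the band-passed trace.

Adjacency builders for the spatial attention branch:

- ``distance``: binary edges between electrodes closer than a threshold
  ``d`` (montage units, unit-sphere coordinates);
- ``plv``: keep channel pairs whose PLV exceeds a percentile of the
  off-diagonal distribution, optionally weighted by the PLV values;
- ``hybrid``: the distance mask multiplied by PLV weights (default used
  by the model: local anatomical support with a synchrony prior).

All builders return symmetric matrices with self-loops, which the
attention layer requires so each node attends to itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .bands import BandSpec, default_bands
from .montage import Montage
from .preprocess import EpochSet

__all__ = [
    "PLVMatrix",
    "AdjacencyGraph",
    "instantaneous_phase",
    "plv",
    "plv_matrix",
    "adjacency_from_distance",
    "adjacency_from_plv",
    "adjacency_hybrid",
]


@dataclass(frozen=True)
class PLVMatrix:
    """Per-band symmetric channels x channels phase-locking matrix."""

    band: BandSpec
    values: np.ndarray
    n_time: int
    n_trials: int
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLV matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("PLV matrix must be symmetric")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("PLV entries must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValueError("PLV diagonal must be 1")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    def to_frame(self):
        import pandas as pd

        names = self.channel_names or tuple(str(i) for i in range(self.values.shape[0]))
        return pd.DataFrame(self.values, index=list(names), columns=list(names))


@dataclass(frozen=True)
class AdjacencyGraph:
    """Non-negative symmetric edge weights with builder provenance."""

    weights: np.ndarray
    builder: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(w, w.T, atol=1e-9):
            raise ValueError("adjacency must be symmetric")
        if w.min() < 0:
            raise ValueError("adjacency weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def _bandpass_epochs(data: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Zero-phase Butterworth bandpass along the last axis."""
    band.validate_for_fs(fs)
    sos = signal.butter(4, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def instantaneous_phase(ep: EpochSet, band: BandSpec) -> np.ndarray:
    """Analytic-signal phase per trial and channel, radians in (-pi, pi].

    The epoch is band-passed (zero-phase Butterworth) and the angle of
    its Hilbert analytic signal is returned, shape trials x channels x
    time.
    """
    filtered = _bandpass_epochs(ep.data, band, ep.fs)
    return np.angle(signal.hilbert(filtered, axis=-1))


def plv(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Phase-locking value of two equal-length phase series."""
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"phase series length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("phase series must have T >= 1")
    return float(np.abs(np.mean(np.exp(1j * (a - b)))))


def plv_matrix(ep: EpochSet, band: BandSpec) -> PLVMatrix:
    """Pairwise PLV per trial, averaged across trials.

    The per-trial estimate uses the epoch's full time axis (T points);
    averaging over trials reduces estimator variance and yields the
    training-set-level synchrony prior used for the adjacency graph.
    """
    if ep.n_trials < 1:
        raise ValueError("need at least one trial")
    phases = instantaneous_phase(ep, band)  # trials x C x T
    phasors = np.exp(1j * phases)
    # PLV_ij per trial = |mean_t z_i(t) * conj(z_j(t))|
    per_trial = np.abs(np.einsum("nct,nmt->ncm", phasors, np.conj(phasors))) / ep.n_times
    values = per_trial.mean(axis=0)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    return PLVMatrix(
        band=band,
        values=np.clip(values, 0.0, 1.0),
        n_time=ep.n_times,
        n_trials=ep.n_trials,
        channel_names=ep.montage.channel_names,
    )


def mean_plv_matrix(ep: EpochSet, bands: list[BandSpec] | None = None) -> PLVMatrix:
    """PLV averaged over all bands ("across frequency bands" prior)."""
    bands = bands if bands is not None else default_bands(ep.fs)
    mats = [plv_matrix(ep, b) for b in bands]
    values = np.mean([m.values for m in mats], axis=0)
    np.fill_diagonal(values, 1.0)
    lo = min(b.low for b in bands)
    hi = max(b.high for b in bands)
    return PLVMatrix(
        band=BandSpec("broadband", lo, hi),
        values=values,
        n_time=ep.n_times,
        n_trials=ep.n_trials,
        channel_names=ep.montage.channel_names,
    )


def adjacency_from_distance(montage: Montage, d: float = 0.35) -> AdjacencyGraph:
    """Binary adjacency: edge weight 1 iff electrode distance < d.

    Distances are Euclidean in unit-sphere montage coordinates; the
    diagonal is forced to 1 (self-loops).
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    dist = montage.distances()
    w = (dist < d).astype(float)
    np.fill_diagonal(w, 1.0)
    return AdjacencyGraph(weights=w, builder="distance", params={"d": d})


def adjacency_from_plv(
    plvm: PLVMatrix, percentile: float = 75.0, weighted: bool = True
) -> AdjacencyGraph:
    """Threshold a PLV matrix at a percentile of its off-diagonal values.

    Off-diagonal entries at or above the percentile survive; they keep
    their PLV value when ``weighted`` else become 1.  Self-loops are
    always present.
    """
    if not 0 <= percentile < 100:
        raise ValueError("percentile must be in [0, 100)")
    v = plvm.values
    C = v.shape[0]
    off = v[~np.eye(C, dtype=bool)]
    if np.ptp(off) == 0:
        warnings.warn("degenerate PLV matrix (all off-diagonals equal); keeping all edges")
        thresh = off[0] if off.size else 0.0
    else:
        thresh = np.percentile(off, percentile)
    mask = v >= thresh
    w = np.where(mask, v if weighted else 1.0, 0.0)
    w = np.maximum(w, w.T)  # percentile ties keep symmetry
    np.fill_diagonal(w, 1.0)
    return AdjacencyGraph(
        weights=w,
        builder="plv",
        params={"percentile": percentile, "weighted": weighted, "band": plvm.band.name},
    )


def adjacency_hybrid(montage: Montage, plvm: PLVMatrix, d: float = 0.35) -> AdjacencyGraph:
    """Distance mask times PLV weights: local edges weighted by synchrony."""
    mask = adjacency_from_distance(montage, d).weights
    w = mask * plvm.values
    np.fill_diagonal(w, 1.0)
    return AdjacencyGraph(weights=w, builder="hybrid", params={"d": d, "band": plvm.band.name})
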