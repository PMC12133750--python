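"""Attribution of model decisions over channels, time, and bands, and the
joint attribution-connectivity report.

Two attribution backends share one contract (the Shapley axioms,
testable on toy models):

- ``sampling-shapley`` (reference): channels are the players of a
  cooperative game; a coalition's value is the model's predicted-class
  probability when coalition channels carry the trial's data and the
  rest carry the background mean.  Shapley values are estimated by
  permutation sampling, which satisfies efficiency exactly for every
  sample: per-permutation marginal contributions telescope to
  f(x) - f(baseline).
- ``gradient-x-input`` (fast, approximate): gradient of the
  predicted-class probability times (input - baseline), exact for
  linear models only.

Band importance is measured by perturbation: one band's spectral
content is swapped for the background's and the drop of the
predicted-class probability is recorded, so importances are probability
drops in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .autodiff import Tensor, no_grad
from .bands import BandSpec
from .connectivity import PLVMatrix
from .model import TrainedModel
from .preprocess import EpochSet

__all__ = [
    "AttributionReport",
    "JointReport",
    "attribute",
    "sampling_shapley",
    "band_attribution",
    "joint_report",
]


@dataclass
class AttributionReport:
    """Per-element attributions toward each trial's predicted class.

    ``values`` is trials x channels x time; for channel-level Shapley
    values the channel's value is spread uniformly over its time axis so
    the per-trial sum is preserved.  ``channel_summary`` is the mean
    over trials of |per-channel total attribution|.  ``baseline`` is the
    model output on the background mean, per trial (the reference the
    efficiency axiom is stated against).
    """

    values: np.ndarray
    channel_summary: np.ndarray
    baseline: np.ndarray
    predicted_class: np.ndarray
    output: np.ndarray
    method: str
    channel_names: tuple = ()
    band_summary: dict = field(default_factory=dict)

    def top_channels(self, k: int) -> list[str]:
        order = np.argsort(self.channel_summary)[::-1][:k]
        names = self.channel_names or tuple(str(i) for i in range(len(self.channel_summary)))
        return [names[i] for i in order]


@dataclass
class JointReport:
    """Attribution ranking joined with phase-locking connectivity.

    ``concordance`` maps band name -> Spearman rank correlation between
    a top channel's attribution and its mean PLV to the other top
    channels; ``None`` flags a degenerate (constant-rank) case.
    """

    top_channels: list
    top_bands: list
    plv_submatrices: dict
    concordance: dict

    def summary(self) -> str:
        lines = [
            "Joint attribution-connectivity report",
            f"  top channels by attribution: {', '.join(self.top_channels)}",
        ]
        if self.top_bands:
            lines.append(f"  top bands by attribution:    {', '.join(self.top_bands)}")
        for band, rho in self.concordance.items():
            shown = "undefined (constant ranks)" if rho is None else f"{rho:+.3f}"
            lines.append(f"  concordance [{band}]: {shown}")
        return "\n".join(lines)


def _predict_fn(model):
    """Normalise a model to a probability callable f(batch) -> (n, K)."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba
    if callable(model):
        return model
    raise TypeError("model must expose predict_proba or be callable")


def sampling_shapley(
    f,
    x: np.ndarray,
    baseline: np.ndarray,
    target: int,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation-sampling Shapley values of channel players.

    ``x`` and ``baseline`` are (C, T); returns per-channel values whose
    sum equals f(x) - f(baseline) on the target class exactly.
    """
    C = x.shape[0]
    phi = np.zeros(C)
    for _ in range(n_permutations):
        order = rng.permutation(C)
        # batch the C+1 cumulative coalitions of this permutation
        batch = np.empty((C + 1,) + x.shape)
        current = baseline.copy()
        batch[0] = current
        for j, ch in enumerate(order):
            current = current.copy()
            current[ch] = x[ch]
            batch[j + 1] = current
        vals = f(batch)[:, target]
        phi[order] += np.diff(vals)
    return phi / n_permutations


def attribute(
    model,
    trials: EpochSet,
    background: EpochSet,
    method: str = "sampling-shapley",
    n_permutations: int = 200,
    seed: int = 0,
) -> AttributionReport:
    """Attribute each trial's predicted-class probability to its inputs."""
    if background.n_trials == 0:
        raise ValueError("background must be non-empty")
    if background.data.shape[1:] != trials.data.shape[1:]:
        raise ValueError("background and trials must share (channels, time) shape")
    if method not in ("sampling-shapley", "gradient-x-input"):
        raise ValueError(f"unknown attribution method {method!r}")

    f = _predict_fn(model)
    base = background.data.mean(axis=0)  # C x T
    n, C, T = trials.data.shape
    proba = f(trials.data)
    pred = np.argmax(proba, axis=1)
    out = proba[np.arange(n), pred]
    base_out = f(base[None])[0][pred]

    values = np.zeros((n, C, T))
    if method == "sampling-shapley":
        rng = np.random.default_rng(seed)
        for i in range(n):
            phi = sampling_shapley(f, trials.data[i], base, int(pred[i]), n_permutations, rng)
            values[i] = phi[:, None] / T  # spread evenly over time; sum preserved
    else:
        if not isinstance(model, TrainedModel):
            raise TypeError("gradient-x-input requires a TrainedModel")
        net = model.network
        net.training = False
        xt = Tensor(trials.data, requires_grad=True)
        probs = net.predict_proba_tensor(xt, model.adjacency.weights)
        sel = probs[np.arange(n), pred]
        sel.sum().backward()
        values = xt.grad * (trials.data - base[None])

    channel_summary = np.abs(values.sum(axis=2)).mean(axis=0)
    return AttributionReport(
        values=values,
        channel_summary=channel_summary,
        baseline=base_out,
        predicted_class=pred,
        output=out,
        method=method,
        channel_names=trials.montage.channel_names,
    )


def band_attribution(
    model,
    trials: EpochSet,
    bands: list[BandSpec],
    background: EpochSet | None = None,
) -> dict:
    """Band importance via band-content replacement.

    For each band, the trials' spectral content inside the band is
    swapped for the background's (zeroed when no background is given)
    and the mean drop of the predicted-class probability is reported.
    """
    for band in bands:
        band.validate_for_fs(trials.fs)
    f = _predict_fn(model)
    n = trials.n_trials
    T = trials.n_times
    proba = f(trials.data)
    pred = np.argmax(proba, axis=1)
    out = proba[np.arange(n), pred]
    freqs = np.fft.rfftfreq(T, d=1.0 / trials.fs)
    base = background.data.mean(axis=0) if background is not None else None

    importances = {}
    for band in bands:
        mask = (freqs >= band.low) & (freqs <= band.high)
        spec = np.fft.rfft(trials.data, axis=-1)
        spec[..., mask] = 0.0
        perturbed = np.fft.irfft(spec, n=T, axis=-1)
        if base is not None:
            bspec = np.fft.rfft(base, axis=-1)
            bspec[..., ~mask] = 0.0
            perturbed = perturbed + np.fft.irfft(bspec, n=T, axis=-1)[None]
        p2 = f(perturbed)[np.arange(n), pred]
        importances[band.name] = float(np.mean(out - p2))
    return importances


def joint_report(
    attr: AttributionReport,
    plvs: list[PLVMatrix],
    k_top: int = 5,
    band_summary: dict | None = None,
) -> JointReport:
    """Join the attribution ranking with phase-locking connectivity."""
    C = len(attr.channel_summary)
    if k_top > C:
        raise ValueError(f"k_top={k_top} exceeds the {C} available channels")
    names = list(attr.channel_names or (str(i) for i in range(C)))
    order = np.argsort(attr.channel_summary)[::-1][:k_top]
    top = [names[i] for i in order]

    band_summary = band_summary if band_summary is not None else attr.band_summary
    top_bands = (
        [b for b, _ in sorted(band_summary.items(), key=lambda kv: kv[1], reverse=True)]
        if band_summary
        else []
    )

    submats, concordance = {}, {}
    attr_top = attr.channel_summary[order]
    for plvm in plvs:
        sub = plvm.values[np.ix_(order, order)]
        submats[plvm.band.name] = sub
        mean_plv = (sub.sum(axis=1) - 1.0) / max(k_top - 1, 1)  # exclude the unit diagonal
        if np.ptp(attr_top) == 0 or np.ptp(mean_plv) == 0:
            concordance[plvm.band.name] = None
        else:
            rho = spearmanr(attr_top, mean_plv).statistic
            concordance[plvm.band.name] = None if np.isnan(rho) else float(rho)
    return JointReport(
        top_channels=top, top_bands=top_bands, plv_submatrices=submats, concordance=concordance
    )
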