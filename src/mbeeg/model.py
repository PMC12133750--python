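"""The multi-branch GAT-GRU-Transformer classifier.

Three parallel branches consume each z-scored trial (channels x time):

- **spatial**: each channel's time course is projected to a node feature
  vector; a hierarchical graph-attention stack (low-level layers for
  local inter-channel interactions, one high-level layer for global
  patterns) over the electrode adjacency graph yields ``F_spatial``
  of shape C x D;
- **temporal**: the trial is read as a T-step sequence of channel
  vectors through a unidirectional GRU (hidden D'), learnable additive
  temporal embeddings, and a pre-norm Transformer encoder stack,
  yielding ``F_time`` of shape T x D'';
- **frequency**: the trial is split into the five canonical bands and
  each band runs an independent 1-D CNN stack (kernels 5 then 3,
  stride 1, ReLU, max pooling), concatenated to a D'''-wide map.

Fusion applies global average pooling over each branch's non-feature
axes and concatenates to a vector of length D + D'' + D''' which a
small 1-D-conv + dense head maps to class logits.  Any branch can be
disabled for ablation; the fusion width shrinks accordingly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, band_mask_fft, concat, dropout, maxpool1d, no_grad, softmax
from .connectivity import AdjacencyGraph
from .nn import (
    Conv1dLayer,
    DepthwiseConv1dLayer,
    GATLayer,
    GRU,
    Linear,
    Module,
    TransformerEncoderLayer,
)

__all__ = ["ModelConfig", "MultiBranchModel", "TrainedModel", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the printed constraints (4-8 attention heads, GRU
    hidden 128, conv kernels 3-5 with stride 1); widths left open are
    chosen small enough for CPU training.  ``temporal_pool`` average-
    pools the time axis by that factor before the GRU, trading temporal
    resolution for speed.
    """

    n_channels: int = 22
    n_time: int = 256
    n_classes: int = 5
    # spatial branch
    gat_heads: int = 4
    gat_low_layers: int = 2
    gat_high_layers: int = 1
    d_low: int = 16
    d_spatial: int = 32
    # temporal branch
    gru_hidden: int = 128
    transformer_layers: int = 2
    attn_heads: int = 4
    d_time: int = 64
    ff_width: int = 256
    temporal_pool: int = 1
    # frequency branch
    bands: tuple = (
        ("Delta", 0.5, 4.0),
        ("Theta", 4.0, 8.0),
        ("Alpha", 8.0, 13.0),
        ("Beta", 13.0, 30.0),
        ("Gamma", 30.0, 62.7),
    )
    conv_channels: int = 8
    conv_kernels: tuple = (5, 3)
    pool_size: int = 4
    # fusion / head
    head_conv_channels: int = 4
    dropout: float = 0.3
    branch_dropout: float = 0.0
    aux_weight: float = 0.0  # per-branch auxiliary-loss weight at train time
    seed: int = 0
    # ablation switches
    use_spatial: bool = True
    use_temporal: bool = True
    use_transformer: bool = True
    use_frequency: bool = True

    def __post_init__(self) -> None:
        if not 4 <= self.gat_heads <= 8:
            raise ValueError("gat_heads must be within 4-8")
        if any(not 3 <= k <= 5 for k in self.conv_kernels):
            raise ValueError("conv kernels must be within 3-5")
        if self.d_low % self.gat_heads:
            raise ValueError("d_low must be divisible by gat_heads")
        if not (self.use_spatial or self.use_temporal or self.use_frequency):
            raise ValueError("at least one branch must be enabled")

    @property
    def fusion_width(self) -> int:
        w = 0
        if self.use_spatial:
            w += self.d_spatial
        if self.use_temporal:
            w += self.d_time
        if self.use_frequency:
            w += self.conv_channels * len(self.bands)
        return w

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [list(b) for b in self.bands]
        d["conv_kernels"] = list(self.conv_kernels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["bands"] = tuple(tuple(b) for b in d["bands"])
        d["conv_kernels"] = tuple(d["conv_kernels"])
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class SpatialBranch(Module):
    """Hierarchical GAT over the electrode graph -> C x D features."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.proj = Linear(cfg.n_time, cfg.d_low, rng)
        per_head = cfg.d_low // cfg.gat_heads
        self.low = [
            GATLayer(cfg.d_low, per_head, cfg.gat_heads, rng, concat_heads=True)
            for _ in range(cfg.gat_low_layers)
        ]
        self.high = [
            GATLayer(cfg.d_low, cfg.d_spatial, cfg.gat_heads, rng, concat_heads=False, activation=False)
            for _ in range(cfg.gat_high_layers)
        ]

    def __call__(self, x: Tensor, adjacency: np.ndarray) -> Tensor:
        h = self.proj(x)  # B x C x d_low
        for layer in self.low:
            h = layer(h, adjacency)
        for layer in self.high:
            h = layer(h, adjacency)
        return h  # B x C x D


class TemporalBranch(Module):
    """GRU + temporal embeddings + Transformer encoder -> T x D'' features."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        t_eff = cfg.n_time // cfg.temporal_pool
        self.gru = GRU(cfg.n_channels, cfg.gru_hidden, rng)
        self.pos = Tensor(0.01 * rng.standard_normal((t_eff, cfg.gru_hidden)), requires_grad=True)
        self.encoder = (
            [TransformerEncoderLayer(cfg.gru_hidden, cfg.attn_heads, cfg.ff_width, rng)
             for _ in range(cfg.transformer_layers)]
            if cfg.use_transformer
            else []
        )
        self.out = Linear(cfg.gru_hidden, cfg.d_time, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, T = x.shape
        p = self.cfg.temporal_pool
        if p > 1:
            x = x[:, :, : (T // p) * p].reshape(B, C, T // p, p).mean(axis=-1)
        seq = x.swapaxes(1, 2)  # B x T' x C
        h = self.gru(seq)
        if self.encoder:
            h = h + self.pos
            for layer in self.encoder:
                h = layer(h)
        return self.out(h)  # B x T' x D''


class FrequencyBranch(Module):
    """Per-band 1-D CNN stacks, concatenated on the feature axis.

    Each band stack is a depthwise temporal convolution (kernel 5,
    per-channel — preserves per-channel band amplitude) followed by a
    channel-mixing convolution (kernel 3), each with ReLU and max
    pooling, stride 1 throughout.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.stacks = []
        k1, k2 = cfg.conv_kernels
        for _ in cfg.bands:
            self.stacks.append([
                DepthwiseConv1dLayer(cfg.n_channels, k1, rng),
                Conv1dLayer(cfg.n_channels, cfg.conv_channels, k2, rng),
            ])

    def __call__(self, x: Tensor, fs: float) -> Tensor:
        outs = []
        for (name, low, high), convs in zip(self.cfg.bands, self.stacks):
            if high > fs / 2:
                raise ValueError(f"band {name} upper edge {high} Hz exceeds Nyquist {fs / 2} Hz")
            h = band_mask_fft(x, low, high, fs)
            for conv in convs:
                h = maxpool1d(conv(h).relu(), self.cfg.pool_size)
            outs.append(h)  # B x conv_channels x T''
        return concat(outs, axis=1)  # B x D''' x T''


class MultiBranchModel(Module):
    """Full three-branch network with fusion and classifier head."""

    def __init__(self, cfg: ModelConfig, fs: float = 128.0):
        self.cfg = cfg
        self.fs = fs
        rng = np.random.default_rng(cfg.seed)
        self.spatial = SpatialBranch(cfg, rng) if cfg.use_spatial else None
        self.temporal = TemporalBranch(cfg, rng) if cfg.use_temporal else None
        self.frequency = FrequencyBranch(cfg, rng) if cfg.use_frequency else None
        L = cfg.fusion_width
        self.head_conv = Conv1dLayer(1, cfg.head_conv_channels, 3, rng)
        self.head_dense = Linear(cfg.head_conv_channels * L, cfg.n_classes, rng)
        # auxiliary classifiers (deep supervision; training-time only)
        self.aux_heads = []
        if cfg.use_spatial:
            self.aux_heads.append(Linear(cfg.d_spatial, cfg.n_classes, rng))
        if cfg.use_temporal:
            self.aux_heads.append(Linear(cfg.d_time, cfg.n_classes, rng))
        if cfg.use_frequency:
            self.aux_heads.append(Linear(cfg.conv_channels * len(cfg.bands), cfg.n_classes, rng))
        self._drop_rng = np.random.default_rng(cfg.seed + 1)
        self.training = False

    def branch_features(self, x: Tensor, adjacency: np.ndarray) -> dict:
        """Per-branch feature tensors for one batch (diagnostics)."""
        feats = {}
        if self.spatial is not None:
            feats["F_spatial"] = self.spatial(x, adjacency)
        if self.temporal is not None:
            feats["F_time"] = self.temporal(x)
        if self.frequency is not None:
            feats["F_freq"] = self.frequency(x, self.fs)
        return feats

    def logits(
        self,
        x: Tensor,
        adjacency: np.ndarray,
        return_aux: bool = False,
        branch_mask: tuple | None = None,
    ):
        """Class logits; ``branch_mask`` (spatial, temporal, frequency)
        replaces a branch's pooled features with zeros without running
        it — used by warm-up schedules; the fusion width is unchanged."""
        if x.ndim != 3:
            raise ValueError(f"expected batch of trials (B, C, T), got shape {x.shape}")
        B, C, T = x.shape
        if C != self.cfg.n_channels or T != self.cfg.n_time:
            raise ValueError(
                f"batch shape ({C}, {T}) does not match config "
                f"({self.cfg.n_channels}, {self.cfg.n_time})"
            )
        mask = branch_mask if branch_mask is not None else (True, True, True)
        pooled = []
        if self.spatial is not None:
            pooled.append(
                self.spatial(x, adjacency).mean(axis=1)  # GAP over channels
                if mask[0] else Tensor(np.zeros((B, self.cfg.d_spatial)))
            )
        if self.temporal is not None:
            pooled.append(
                self.temporal(x).mean(axis=1)  # GAP over time
                if mask[1] else Tensor(np.zeros((B, self.cfg.d_time)))
            )
        if self.frequency is not None:
            pooled.append(
                self.frequency(x, self.fs).mean(axis=2)  # GAP over time
                if mask[2] else Tensor(np.zeros((B, self.cfg.conv_channels * len(self.cfg.bands))))
            )
        aux = [head(f) for head, f in zip(self.aux_heads, pooled)] if return_aux else None
        if self.training and self.cfg.branch_dropout > 0 and len(pooled) > 1:
            # modality dropout: zero whole branches per batch so the head
            # cannot rely on any single branch; rescale survivors
            p = self.cfg.branch_dropout
            keep = self._drop_rng.random(len(pooled)) >= p
            if not keep.any():
                keep[self._drop_rng.integers(len(pooled))] = True
            scale = len(pooled) / keep.sum()
            pooled = [f * (scale if k else 0.0) for f, k in zip(pooled, keep)]
        f_pool = concat(pooled, axis=-1)  # B x (D + D'' + D''')
        f_pool = dropout(f_pool, self.cfg.dropout, self._drop_rng, self.training)
        h = self.head_conv(f_pool.reshape(B, 1, f_pool.shape[-1])).relu()
        h = h.reshape(B, h.shape[1] * h.shape[2])
        out = self.head_dense(h)
        return (out, aux) if return_aux else out

    def predict_proba_tensor(self, x: Tensor, adjacency: np.ndarray) -> Tensor:
        return softmax(self.logits(x, adjacency), axis=-1)


@dataclass
class TrainedModel:
    """A model plus everything needed to reuse it: config, adjacency, labels."""

    config: ModelConfig
    network: MultiBranchModel
    adjacency: AdjacencyGraph
    class_labels: tuple = (1, 2, 3, 4, 5)
    fs: float = 128.0

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """Class probabilities for a (trials, C, T) batch, eval mode."""
        self.network.training = False
        with no_grad():
            out = self.network.predict_proba_tensor(Tensor(batch), self.adjacency.weights)
        return out.data

    def predict(self, batch: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(batch)
        return np.asarray(self.class_labels)[np.argmax(proba, axis=1)]


def save_checkpoint(model: TrainedModel, path_params, path_config) -> None:
    """Serialise parameters (.npz) plus a JSON config sidecar with hash."""
    params = model.network.parameters()
    np.savez(path_params, **{f"p{i}": p.data for i, p in enumerate(params)})
    sidecar = {
        "config": model.config.to_dict(),
        "config_hash": model.config.hash(),
        "class_labels": list(model.class_labels),
        "fs": model.fs,
        "adjacency": model.adjacency.weights.tolist(),
        "adjacency_builder": model.adjacency.builder,
    }
    with open(path_config, "w") as f:
        json.dump(sidecar, f)


def load_checkpoint(path_params, path_config) -> TrainedModel:
    with open(path_config) as f:
        sidecar = json.load(f)
    cfg = ModelConfig.from_dict(sidecar["config"])
    if cfg.hash() != sidecar["config_hash"]:
        raise ValueError("config hash mismatch: checkpoint does not match its sidecar")
    net = MultiBranchModel(cfg, fs=sidecar["fs"])
    params = net.parameters()
    with np.load(path_params) as data:
        if len(data.files) != len(params):
            raise ValueError("parameter count mismatch between checkpoint and config")
        for i, p in enumerate(params):
            loaded = data[f"p{i}"]
            if loaded.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch")
            p.data = loaded
    adj = AdjacencyGraph(
        weights=np.array(sidecar["adjacency"]), builder=sidecar["adjacency_builder"]
    )
    return TrainedModel(
        config=cfg,
        network=net,
        adjacency=adj,
        class_labels=tuple(sidecar["class_labels"]),
        fs=sidecar["fs"],
    )
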