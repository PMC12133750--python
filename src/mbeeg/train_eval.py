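"""Training loop, classification metrics, McNemar comparison, ablations.

Metrics follow the one-vs-rest decomposition of the multiclass
confusion matrix: per class, precision = TP/(TP+FP), recall =
TP/(TP+FN), F1 = 2PR/(P+R); overall accuracy is the confusion trace
over the total.  The McNemar test compares two paired classifiers
through their discordant counts b and c: the uncorrected statistic is
(b-c)^2/(b+c), the continuity-corrected one (|b-c|-1)^2/(b+c), both
referred to a chi-square distribution with 1 degree of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .autodiff import Tensor
from .connectivity import AdjacencyGraph, adjacency_hybrid, mean_plv_matrix
from .model import ModelConfig, MultiBranchModel, TrainedModel
from .nn import Adam, cross_entropy
from .preprocess import EpochSet

__all__ = [
    "TrainSpec",
    "PredictionReport",
    "ContingencyTable",
    "stratified_split",
    "train",
    "evaluate",
    "mcnemar",
    "run_ablation",
]


@dataclass(frozen=True)
class TrainSpec:
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    warmup_epochs: int = 0  # frequency-branch-only epochs before joint training
    finetune_lr_factor: float = 1.0  # lr multiplier for the joint phase after warm-up
    optimizer: str = "adam"
    train_frac: float = 0.8
    stratified: bool = True
    seed: int = 0
    patience: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class PredictionReport:
    """Confusion matrix (rows = true, cols = predicted) and derived metrics.

    Metrics for a class absent from both truth and prediction are NaN
    and listed in ``undefined_classes`` rather than reported as 0.
    """

    confusion: np.ndarray
    accuracy: float
    precision: dict
    recall: dict
    f1: dict
    n_test: int
    class_labels: tuple
    undefined_classes: tuple = ()

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": {str(k): v for k, v in self.precision.items()},
            "recall": {str(k): v for k, v in self.recall.items()},
            "f1": {str(k): v for k, v in self.f1.items()},
            "n_test": self.n_test,
            "class_labels": list(self.class_labels),
            "undefined_classes": list(self.undefined_classes),
        }


@dataclass(frozen=True)
class ContingencyTable:
    """Paired-classifier outcome counts: a both correct, b only model A,
    c only model B, d both incorrect."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


def stratified_split(labels: np.ndarray, train_frac: float, seed: int, stratified: bool = True):
    """Index split; stratification keeps per-class proportions."""
    rng = np.random.default_rng(seed)
    n = len(labels)
    if stratified:
        train_idx, test_idx = [], []
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            k = int(round(train_frac * len(idx)))
            if k == 0 or k == len(idx):
                raise ValueError(f"class {cls}: split leaves an empty side (n={len(idx)})")
            train_idx.extend(idx[:k])
            test_idx.extend(idx[k:])
        train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)
    else:
        perm = rng.permutation(n)
        k = int(round(train_frac * n))
        train_idx, test_idx = np.sort(perm[:k]), np.sort(perm[k:])
    return train_idx, test_idx


def _default_adjacency(data: EpochSet, cfg: ModelConfig) -> AdjacencyGraph:
    """Hybrid adjacency: distance mask x band-averaged PLV weights,
    computed on the given (training) epochs."""
    from .bands import available_bands

    plvm = mean_plv_matrix(data, bands=available_bands(data.fs))
    return adjacency_hybrid(data.montage, plvm, d=0.35)


def train(
    model_cfg: ModelConfig,
    data: EpochSet,
    spec: TrainSpec = TrainSpec(),
    adjacency: AdjacencyGraph | None = None,
    validation: EpochSet | None = None,
):
    """Train the multi-branch network with Adam on cross-entropy.

    Returns ``(TrainedModel, history)`` where history is a dict of
    per-epoch lists (``loss``, ``train_accuracy``, and
    ``val_accuracy`` when a validation set is given).  Fully seeded:
    parameter init from the model config seed, batch order and dropout
    from the train spec seed.
    """
    labels = np.asarray(data.labels)
    classes = tuple(int(c) for c in np.unique(labels))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    if spec.optimizer.lower() != "adam":
        raise ValueError(f"unsupported optimizer {spec.optimizer!r}")

    adjacency = adjacency if adjacency is not None else _default_adjacency(data, model_cfg)
    net = MultiBranchModel(model_cfg, fs=data.fs)
    net._drop_rng = np.random.default_rng(spec.seed + 10_007)
    opt = Adam(net.parameters(), lr=spec.learning_rate, weight_decay=spec.weight_decay)
    rng = np.random.default_rng(spec.seed)
    label_to_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([label_to_idx[int(v)] for v in labels])
    X = data.data

    history: dict[str, list] = {"loss": [], "train_accuracy": []}
    if validation is not None:
        history["val_accuracy"] = []
    model = TrainedModel(
        config=model_cfg, network=net, adjacency=adjacency, class_labels=classes, fs=data.fs
    )

    warmup_active = spec.warmup_epochs > 0 and model_cfg.use_frequency
    best_val, stall = -np.inf, 0
    for ep in range(spec.epochs):
        in_warmup = warmup_active and ep < spec.warmup_epochs
        mask = (False, False, True) if in_warmup else None
        if warmup_active and ep == spec.warmup_epochs:
            opt.lr = spec.learning_rate * spec.finetune_lr_factor
        order = rng.permutation(len(y))
        net.training = True
        ep_loss, n_seen = 0.0, 0
        for start in range(0, len(order), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            use_aux = model_cfg.aux_weight > 0 and not in_warmup
            out = net.logits(
                Tensor(X[idx]), adjacency.weights, return_aux=use_aux, branch_mask=mask
            )
            if use_aux:
                logits, aux = out
                loss = cross_entropy(logits, y[idx])
                for a in aux:
                    loss = loss + model_cfg.aux_weight * cross_entropy(a, y[idx])
            else:
                loss = cross_entropy(out, y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {ep}, batch starting {start}; "
                    "reduce the learning rate or inspect the input scaling"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(idx)
            n_seen += len(idx)
        net.training = False
        history["loss"].append(ep_loss / n_seen)
        history["train_accuracy"].append(float(np.mean(model.predict(X) == labels)))
        if validation is not None:
            val_acc = float(np.mean(model.predict(validation.data) == np.asarray(validation.labels)))
            history["val_accuracy"].append(val_acc)
            if spec.patience is not None:
                if val_acc > best_val + 1e-12:
                    best_val, stall = val_acc, 0
                else:
                    stall += 1
                    if stall > spec.patience:
                        break
    return model, history


def evaluate(model: TrainedModel, data: EpochSet) -> PredictionReport:
    """Argmax predictions, confusion matrix, and one-vs-rest metrics."""
    if data.n_trials == 0:
        raise ValueError("empty test set")
    y_true = np.asarray(data.labels)
    y_pred = model.predict(data.data)
    return prediction_report(y_true, y_pred, class_labels=model.class_labels)


def prediction_report(y_true, y_pred, class_labels=None) -> PredictionReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if class_labels is None:
        class_labels = tuple(int(c) for c in np.unique(np.concatenate([y_true, y_pred])))
    k = len(class_labels)
    idx = {c: i for i, c in enumerate(class_labels)}
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[idx[int(t)], idx[int(p)]] += 1
    total = conf.sum()
    accuracy = float(np.trace(conf) / total)
    precision, recall, f1 = {}, {}, {}
    undefined = []
    for c in class_labels:
        i = idx[c]
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        if tp + fp + fn == 0:
            precision[c] = recall[c] = f1[c] = float("nan")
            undefined.append(c)
            continue
        precision[c] = float(tp / (tp + fp)) if tp + fp else float("nan")
        recall[c] = float(tp / (tp + fn)) if tp + fn else float("nan")
        # count form 2TP/(2TP+FP+FN) equals 2PR/(P+R) wherever both are
        # defined, and stays defined whenever the class occurs at all
        f1[c] = float(2 * tp / (2 * tp + fp + fn))
        if np.isnan(precision[c]) or np.isnan(recall[c]):
            if c not in undefined:
                undefined.append(c)
    return PredictionReport(
        confusion=conf,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        n_test=int(total),
        class_labels=tuple(class_labels),
        undefined_classes=tuple(undefined),
    )


def mcnemar(t: ContingencyTable) -> dict:
    """Both McNemar variants on the discordant counts.

    Returns ``statistic`` (b-c)^2/(b+c) and ``statistic_corrected``
    (|b-c|-1)^2/(b+c), each with its chi-square(1) upper-tail p-value.
    """
    b, c = t.b, t.c
    if b + c == 0:
        warnings.warn("b = c = 0: no discordant pairs; statistic is 0, p = 1")
        return {
            "statistic": 0.0,
            "p_value": 1.0,
            "statistic_corrected": 0.0,
            "p_value_corrected": 1.0,
        }
    stat = (b - c) ** 2 / (b + c)
    stat_corr = max(abs(b - c) - 1, 0) ** 2 / (b + c)
    return {
        "statistic": float(stat),
        "p_value": float(stats.chi2.sf(stat, df=1)),
        "statistic_corrected": float(stat_corr),
        "p_value_corrected": float(stats.chi2.sf(stat_corr, df=1)),
    }


ABLATION_VARIANTS = ("full", "no_gat", "no_transformer", "no_1dcnn")


def ablation_config(base: ModelConfig, variant: str) -> ModelConfig:
    import dataclasses

    if variant == "full":
        return base
    if variant == "no_gat":
        return dataclasses.replace(base, use_spatial=False)
    if variant == "no_transformer":
        return dataclasses.replace(base, use_transformer=False)
    if variant == "no_1dcnn":
        return dataclasses.replace(base, use_frequency=False)
    raise ValueError(f"unknown ablation variant {variant!r}")


def run_ablation(data: EpochSet, base_cfg: ModelConfig, spec: TrainSpec = TrainSpec()) -> dict:
    """Train the full model and the three ablated variants on one split.

    All variants share the identical train/test split and seeds; the
    ``no_transformer`` variant keeps the GRU.  Returns
    variant -> {"accuracy", "n_parameters", "report"}.
    """
    labels = np.asarray(data.labels)
    tr, te = stratified_split(labels, spec.train_frac, spec.seed, spec.stratified)
    train_set = EpochSet(
        data=data.data[tr], labels=labels[tr], fs=data.fs, window=data.window, montage=data.montage
    )
    test_set = EpochSet(
        data=data.data[te], labels=labels[te], fs=data.fs, window=data.window, montage=data.montage
    )
    adjacency = _default_adjacency(train_set, base_cfg)
    results = {}
    for variant in ABLATION_VARIANTS:
        cfg = ablation_config(base_cfg, variant)
        model, _ = train(cfg, train_set, spec, adjacency=adjacency)
        report = evaluate(model, test_set)
        results[variant] = {
            "accuracy": report.accuracy,
            "n_parameters": model.network.n_parameters(),
            "report": report,
        }
    return results
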