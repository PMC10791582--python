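"""tRNet: a dilated convolutional network predicting tRNA gene activity
class (housekeeping / repressed / inactive) from the 200-bp 5' flanking
sequence.

Architecture (BPNet-style): an initial convolution (128 filters, width
20), eight dilated convolutions (128 filters, width 10, dilation
doubling layer by layer), each followed by a rectified linear unit;
global max pooling; a 32-unit hidden layer; and either a 3-way softmax
head (multiclass) or a single sigmoid unit (binary).  The dilation
schedule gives a receptive field of 20 + 9*(2+4+...+256) = 4,610 bp,
comfortably covering the 200-bp input.

Training uses Adam (learning rate 0.00025), cross-entropy loss, an
80/20 train/validation split and early stopping with patience 10
(best-validation weights restored).  Transfer learning proceeds in three
phases: (1) train a binary housekeeping-vs-inactive model — the two
most sequence-distinct classes; (2) freeze everything, swap the head for
a 3-way softmax and train; (3) unfreeze the last convolutional layer and
train once more.  Evaluation reports stratified k-fold (k=5)
accuracy/loss and one-vs-rest AUROC per class with the macro average.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .nn import (
    Adam,
    Conv1D,
    Dense,
    GlobalMaxPool,
    ReLU,
    Residual,
    Sequential,
    sigmoid,
    sigmoid_cross_entropy,
    softmax,
    softmax_cross_entropy,
)

__all__ = [
    "CLASS_NAMES",
    "TRNetSpec",
    "TrainConfig",
    "TRNetModel",
    "one_hot",
    "decode_one_hot",
    "build_model",
    "train",
    "evaluate",
    "transfer_learn",
    "TransferResult",
    "kfold_evaluate",
    "roc_auc_one_vs_rest",
]

CLASS_NAMES = ("housekeeping", "repressed", "inactive")

_ONE_HOT = {"A": 0, "C": 1, "G": 2, "T": 3}


def one_hot(sequence: str) -> np.ndarray:
    """Encode DNA as L x 4 over channel order (A, C, G, T); N rows are
    all-zero."""
    seq = sequence.upper()
    out = np.zeros((len(seq), 4), dtype=np.float32)
    for i, ch in enumerate(seq):
        if ch == "N":
            continue
        try:
            out[i, _ONE_HOT[ch]] = 1.0
        except KeyError:
            raise ValueError(f"invalid base {ch!r} at position {i}") from None
    return out


def decode_one_hot(x: np.ndarray) -> str:
    bases = np.array(list("ACGT"))
    out = []
    for row in x:
        out.append("N" if row.sum() == 0 else bases[int(row.argmax())])
    return "".join(out)


@dataclass(frozen=True)
class TRNetSpec:
    """Architecture hyperparameters; defaults are the full network."""

    input_length: int = 200
    conv0_filters: int = 128
    conv0_width: int = 20
    n_dilated: int = 8
    dilated_filters: int = 128
    dilated_width: int = 10
    dilation_start: int = 2  # first dilated layer; doubles per layer
    hidden_units: int = 32
    # residual branches start near zero so the network begins close to
    # the shallow conv0 model and grows depth as training proceeds
    residual_init_scale: float = 0.05

    def dilations(self) -> list[int]:
        return [self.dilation_start * 2**i for i in range(self.n_dilated)]

    def receptive_field(self) -> int:
        rf = self.conv0_width
        for d in self.dilations():
            rf += (self.dilated_width - 1) * d
        return rf

    def __post_init__(self) -> None:
        if self.receptive_field() < self.input_length:
            raise ValueError(
                f"receptive field {self.receptive_field()} < input length "
                f"{self.input_length}"
            )

    def param_count(self, head: str = "multiclass") -> int:
        """Closed-form trainable parameter count."""
        n_out = 3 if head == "multiclass" else 1
        total = 4 * self.conv0_width * self.conv0_filters + self.conv0_filters
        c = self.conv0_filters
        for _ in range(self.n_dilated):
            total += c * self.dilated_width * self.dilated_filters + self.dilated_filters
            c = self.dilated_filters
        total += c * self.hidden_units + self.hidden_units
        total += self.hidden_units * n_out + n_out
        return total


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings shared by every training phase."""

    learning_rate: float = 0.00025
    patience: int = 10
    train_fraction: float = 0.8
    k: int = 5
    batch_size: int = 32
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


class TRNetModel:
    """A built tRNet: the layer stack plus head bookkeeping."""

    def __init__(self, spec: TRNetSpec, head: str, rng: np.random.Generator):
        if head not in ("binary", "multiclass"):
            raise ValueError("head must be 'binary' or 'multiclass'")
        self.spec = spec
        self.head = head
        n_out = 3 if head == "multiclass" else 1
        self.conv_layers: list[Conv1D] = [
            Conv1D(4, spec.conv0_filters, spec.conv0_width, 1, rng)
        ]
        layers: list = [self.conv_layers[0], ReLU()]
        c = spec.conv0_filters
        for d in spec.dilations():
            conv = Conv1D(c, spec.dilated_filters, spec.dilated_width, d, rng)
            self.conv_layers.append(conv)
            if spec.dilated_filters == c:
                # BPNet-style residual skip around each dilated conv
                conv.w *= spec.residual_init_scale
                layers.append(Residual([conv, ReLU()]))
            else:
                layers += [conv, ReLU()]
            c = spec.dilated_filters
        self.hidden = Dense(c, spec.hidden_units, rng)
        self.head_dense = Dense(spec.hidden_units, n_out, rng)
        layers += [GlobalMaxPool(), self.hidden, ReLU(), self.head_dense]
        self.net = Sequential(layers)

    # -- inference ---------------------------------------------------------
    def logits(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = [self.net.forward(x[i : i + batch_size])
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        z = self.logits(x, batch_size)
        if self.head == "binary":
            p = sigmoid(z).ravel()
            return np.column_stack([1 - p, p])
        return softmax(z.astype(np.float64))

    def input_gradient(self, x: np.ndarray, task: int) -> np.ndarray:
        """d logit[task] / d input, per sequence in the batch."""
        z = self.net.forward(x)
        if not 0 <= task < z.shape[1]:
            raise ValueError(f"task index {task} out of range")
        dz = np.zeros_like(z)
        dz[:, task] = 1.0
        return self.net.backward(dz)

    # -- structure ---------------------------------------------------------
    def param_count(self) -> int:
        return self.net.param_count()

    def trainable_param_count(self) -> int:
        return sum(
            int(p.size)
            for layer in self.net.atomic_layers()
            if layer.trainable
            for p in layer.params()
        )

    def layer_weights(self) -> dict[str, list[np.ndarray]]:
        out = {"conv0": [p.copy() for p in self.conv_layers[0].params()]}
        for i, conv in enumerate(self.conv_layers[1:], start=1):
            out[f"dilated{i}"] = [p.copy() for p in conv.params()]
        out["hidden"] = [p.copy() for p in self.hidden.params()]
        out["head"] = [p.copy() for p in self.head_dense.params()]
        return out

    def set_trainable(self, *, conv: bool, hidden: bool, head: bool,
                      last_conv: bool | None = None) -> None:
        for layer in self.conv_layers:
            layer.trainable = conv
        if last_conv is not None:
            self.conv_layers[-1].trainable = last_conv
        self.hidden.trainable = hidden
        self.head_dense.trainable = head


def build_model(spec: TRNetSpec, head: str = "multiclass",
                seed: int = 0) -> TRNetModel:
    return TRNetModel(spec, head, np.random.default_rng(seed))


def _loss_fn(head: str):
    return sigmoid_cross_entropy if head == "binary" else softmax_cross_entropy


def evaluate(model: TRNetModel, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(mean loss, accuracy) on a labelled set."""
    z = model.logits(x)
    loss, _ = _loss_fn(model.head)(z, y)
    if model.head == "binary":
        pred = (z.ravel() > 0).astype(int)
    else:
        pred = z.argmax(axis=1)
    return loss, float((pred == y).mean())


def train(
    model: TRNetModel,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    *,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    early_stopping: bool = True,
) -> pd.DataFrame:
    """Minibatch Adam with early stopping on validation loss.

    When no validation set is passed, a stratified ``1 -
    train_fraction`` share of the data is held out for it.  Training
    stops once validation loss has failed to improve for ``patience``
    epochs; the best-validation weights are restored.  Returns the
    per-epoch history.

    With ``early_stopping=False`` the model instead trains on all of
    ``x`` for exactly ``max_epochs`` and keeps the final weights (the
    fixed-schedule mode used for small data sets, where a validation
    holdout both starves training and stops it prematurely: validation
    cross-entropy rises from overconfidence while discrimination is
    still improving).  The history then reports training metrics only.
    """
    if len(x) != len(y):
        raise ValueError("X and y length mismatch")
    y = np.asarray(y, dtype=int)
    if model.head == "multiclass" and len(np.unique(y)) < 2:
        raise ValueError("multiclass training requires >=2 classes present")
    rng = np.random.default_rng(config.seed)
    if not early_stopping:
        xtr, ytr = x, y
        xval, yval = x, y
    elif validation is None:
        xtr, xval, ytr, yval = train_test_split(
            x, y, train_size=config.train_fraction, stratify=y,
            random_state=config.seed % (2**32),
        )
    else:
        xtr, ytr = x, y
        xval, yval = validation

    opt = Adam(model.net, lr=config.learning_rate)
    loss_fn = _loss_fn(model.head)
    best_loss = np.inf
    best_weights = model.net.get_weights()
    stale = 0
    history = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(xtr))
        tr_losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            z = model.net.forward(xtr[idx])
            loss, dz = loss_fn(z, ytr[idx])
            model.net.backward(dz)
            opt.step()
            tr_losses.append(loss)
        val_loss, val_acc = evaluate(model, xval, yval)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(tr_losses)),
             "val_loss": val_loss, "val_acc": val_acc}
        )
        if not early_stopping:
            continue
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_weights = model.net.get_weights()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if early_stopping:
        model.net.set_weights(best_weights)
    return pd.DataFrame(history)


def roc_auc_one_vs_rest(y: np.ndarray, proba: np.ndarray,
                        class_names=CLASS_NAMES) -> dict[str, float]:
    """Per-class one-vs-rest AUROC plus the unweighted macro average."""
    y = np.asarray(y, dtype=int)
    out = {}
    for c, name in enumerate(class_names[: proba.shape[1]]):
        out[name] = float(roc_auc_score((y == c).astype(int), proba[:, c]))
    out["macro"] = float(np.mean([v for k, v in out.items() if k != "macro"]))
    return out


@dataclass
class TransferResult:
    model: TRNetModel
    binary_model: TRNetModel
    histories: dict[str, pd.DataFrame]
    snapshots: dict[str, dict[str, list[np.ndarray]]]
    trainable_counts: dict[str, int]


def transfer_learn(
    x: np.ndarray,
    y3: np.ndarray,
    config: TrainConfig,
    spec: TRNetSpec | None = None,
    *,
    early_stopping: bool = True,
) -> TransferResult:
    """Three-phase transfer learning to the 3-class model.

    Phase 1 trains a binary model on housekeeping (label 0, target 1)
    vs inactive (label 2, target 0) sequences only.  Phase 2 freezes
    every trained layer, replaces the head with a 3-way softmax and
    trains on all classes.  Phase 3 unfreezes the last convolutional
    layer and trains again.  Each phase reuses the same optimisation
    settings.  Weight snapshots and trainable-parameter counts are kept
    per phase so the freezing contract is checkable.
    """
    spec = spec or TRNetSpec()
    y3 = np.asarray(y3, dtype=int)
    present = set(np.unique(y3))
    if not {0, 1, 2} <= present:
        raise ValueError("transfer learning requires all three classes present")

    mask = np.isin(y3, [0, 2])
    xb = x[mask]
    yb = (y3[mask] == 0).astype(int)  # housekeeping = positive

    binary = build_model(spec, "binary", seed=config.seed)
    hist1 = train(binary, xb, yb, config, early_stopping=early_stopping)
    snap1 = binary.layer_weights()
    count1 = binary.trainable_param_count()

    multi = build_model(spec, "multiclass", seed=config.seed + 1)
    # carry over every trained layer except the head
    for src, dst in zip(binary.conv_layers, multi.conv_layers):
        dst.w[...] = src.w
        dst.b[...] = src.b
    multi.hidden.w[...] = binary.hidden.w
    multi.hidden.b[...] = binary.hidden.b
    multi.set_trainable(conv=False, hidden=False, head=True)
    hist2 = train(multi, x, y3, replace(config, seed=config.seed + 2),
                  early_stopping=early_stopping)
    snap2 = multi.layer_weights()
    count2 = multi.trainable_param_count()

    multi.set_trainable(conv=False, hidden=False, head=True, last_conv=True)
    hist3 = train(multi, x, y3, replace(config, seed=config.seed + 3),
                  early_stopping=early_stopping)
    snap3 = multi.layer_weights()
    count3 = multi.trainable_param_count()

    return TransferResult(
        model=multi,
        binary_model=binary,
        histories={"binary": hist1, "frozen": hist2, "finetune": hist3},
        snapshots={"binary": snap1, "frozen": snap2, "finetune": snap3},
        trainable_counts={"binary": count1, "frozen": count2, "finetune": count3},
    )


def kfold_evaluate(
    x: np.ndarray,
    y3: np.ndarray,
    config: TrainConfig,
    spec: TRNetSpec | None = None,
    *,
    mode: str = "direct",
    early_stopping: bool = True,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Stratified k-fold training and one-vs-rest AUROC evaluation.

    Each fold trains a fresh model (direct multiclass training or the
    transfer-learning protocol) and is scored on its held-out split.
    Returns per-fold records and AUROCs pooled over all held-out
    predictions (per class + macro).
    """
    y3 = np.asarray(y3, dtype=int)
    counts = np.bincount(y3, minlength=3)
    if (counts < config.k).any():
        raise ValueError("each class needs at least k examples")
    skf = StratifiedKFold(n_splits=config.k, shuffle=True,
                          random_state=config.seed % (2**32))
    records = []
    pooled_proba = np.zeros((len(y3), 3))
    for fold, (tr, te) in enumerate(skf.split(x, y3)):
        fold_cfg = replace(config, seed=config.seed + 1000 * (fold + 1))
        if mode == "transfer":
            result = transfer_learn(x[tr], y3[tr], fold_cfg, spec,
                                    early_stopping=early_stopping)
            model = result.model
        else:
            model = build_model(spec or TRNetSpec(), "multiclass", seed=fold_cfg.seed)
            train(model, x[tr], y3[tr], fold_cfg, early_stopping=early_stopping)
        loss, acc = evaluate(model, x[te], y3[te])
        proba = model.predict_proba(x[te])
        pooled_proba[te] = proba
        auc = roc_auc_one_vs_rest(y3[te], proba)
        records.append({"fold": fold, "test_loss": loss, "test_acc": acc, **auc})
    summary = roc_auc_one_vs_rest(y3, pooled_proba)
    return pd.DataFrame(records), summary
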