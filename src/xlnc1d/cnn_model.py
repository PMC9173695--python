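"""The 1D-CNN transcript classifier: build, train, predict, grid search.

Architecture: three convolution blocks (conv1d kernel 57 stride 1 -> ReLU
-> max-pool 2 -> dropout 0.3), then flatten, two dense-256 blocks with
dropout 0.5, and a two-unit softmax head. Training uses plain SGD with
momentum 0.9, learning rate 0.01, 120 epochs, batch size 128 on two-class
cross-entropy; all of these live in :class:`ModelConfig` and can be scaled
down for desk-size experiments.

The two output units are initialized identically (and biases to zero), so
an untrained model is exactly indifferent — p = (0.5, 0.5) for every input
— and retraining with swapped label encoding is an exact column swap.

Class convention everywhere: index 1 = lncRNA (positive), index 0 = mRNA.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import nn
from .sequence_io import LNCRNA, MRNA, EncodedDataset

SCHEMA_VERSION = 1
CLASS_INDEX = {0: MRNA, 1: LNCRNA}


@dataclass(frozen=True)
class ModelConfig:
    """All architecture and training hyperparameters."""

    n_conv_blocks: int = 3
    kernel_size: int = 57
    stride: int = 1
    filters_per_block: int = 128
    pool_size: int = 2
    conv_dropout: float = 0.3
    dense_units: tuple[int, int] = (256, 256)
    dense_dropout: float = 0.5
    n_classes: int = 2
    input_length: int = 3000
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 120
    batch_size: int = 128
    seed: int = 0
    conv_padding: str = "same"

    def __post_init__(self):
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not (0 <= self.conv_dropout < 1 and 0 <= self.dense_dropout < 1):
            raise ValueError("dropout rates must be in [0, 1)")
        if self.input_length < self.kernel_size:
            raise ValueError("input_length must be >= kernel_size")
        if self.n_classes != 2:
            raise ValueError("only two-class models are supported")
        if self.conv_padding not in ("same", "valid"):
            raise ValueError("conv_padding must be 'same' or 'valid'")
        # every conv/pool stage must leave at least one position
        L = self.input_length
        for _ in range(self.n_conv_blocks):
            if self.conv_padding == "valid":
                L = L - self.kernel_size + 1
            L = -(-L // self.stride)  # ceil for 'same'; conv output then strided
            L //= self.pool_size
            if L < 1:
                raise ValueError(
                    f"input_length {self.input_length} too small for "
                    f"{self.n_conv_blocks} conv/pool stages"
                )

    @classmethod
    def scaled_down(cls, **overrides) -> "ModelConfig":
        """Desk-scale profile: 16 filters, 600-nt input, 25 epochs, batch 32,
        dropout off.

        The smaller batch keeps the number of SGD updates per epoch sensible
        for datasets of a few hundred sequences. Dropout is disabled: the
        full profile's rates are sized for corpus-scale training, and at a
        few hundred samples they stall SGD on a chance-level plateau for
        many seeds; a desk-scale separability study needs no regularization.
        Everything else follows the full recipe.
        """
        base = dict(filters_per_block=16, input_length=600, epochs=25,
                    batch_size=32, conv_dropout=0.0, dense_dropout=0.0)
        base.update(overrides)
        return cls(**base)

    def flat_features(self) -> int:
        L = self.input_length
        for _ in range(self.n_conv_blocks):
            if self.conv_padding == "valid":
                L = L - self.kernel_size + 1
            L = -(-L // self.stride)
            L //= self.pool_size
        return L * self.filters_per_block

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dense_units"] = list(self.dense_units)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        d = dict(d)
        d["dense_units"] = tuple(d["dense_units"])
        return cls(**d)


@dataclass
class PredictionRecord:
    """Per-sequence softmax output; lncRNA wins ties at p = 0.5."""

    id: str
    p_lncRNA: float
    p_mRNA: float
    predicted_label: str = field(init=False)

    def __post_init__(self):
        if abs(self.p_lncRNA + self.p_mRNA - 1.0) > 1e-6:
            raise ValueError("class probabilities must sum to 1")
        self.predicted_label = LNCRNA if self.p_lncRNA >= 0.5 else MRNA


class XlncModel:
    """Trained-model handle: network, config, class map, training history."""

    def __init__(self, network: nn.Network, config: ModelConfig):
        self.network = network
        self.config = config
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}
        self.class_index = dict(CLASS_INDEX)
        self.trained = False

    def save(self, path: str | Path) -> None:
        meta = {
            "schema_version": SCHEMA_VERSION,
            "config": self.config.to_dict(),
            "class_index": {str(k): v for k, v in self.class_index.items()},
            "history": self.history,
            "trained": self.trained,
        }
        arrays = {f"w{i}": w for i, w in enumerate(self.network.get_weights())}
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "XlncModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]))
            if meta.get("schema_version") != SCHEMA_VERSION:
                raise ValueError(f"unsupported model schema: {meta.get('schema_version')}")
            config = ModelConfig.from_dict(meta["config"])
            model = build_model(config)
            n = len(model.network.params())
            model.network.set_weights([data[f"w{i}"] for i in range(n)])
        model.history = meta["history"]
        model.class_index = {int(k): v for k, v in meta["class_index"].items()}
        model.trained = meta["trained"]
        return model


def _rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    init_ss, drop_ss, shuffle_ss = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(init_ss),
        np.random.default_rng(drop_ss),
        np.random.default_rng(shuffle_ss),
    )


def build_model(config: ModelConfig) -> XlncModel:
    """Assemble the (untrained) network for ``config``."""
    rng_init, rng_drop, _ = _rngs(config.seed)
    layers: list[nn.Layer] = []
    c_in = 4
    for _ in range(config.n_conv_blocks):
        layers.append(
            nn.Conv1D(c_in, config.filters_per_block, config.kernel_size, rng_init,
                      padding=config.conv_padding, stride=config.stride)
        )
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool1D(config.pool_size))
        layers.append(nn.Dropout(config.conv_dropout, rng_drop))
        c_in = config.filters_per_block
    layers.append(nn.Flatten())
    n_in = config.flat_features()
    for units in config.dense_units:
        layers.append(nn.Dense(n_in, units, rng_init))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(config.dense_dropout, rng_drop))
        n_in = units
    head = nn.Dense(n_in, config.n_classes, rng_init)
    head.W[:, 1] = head.W[:, 0]  # symmetric head: untrained model is indifferent
    layers.append(head)
    return XlncModel(nn.Network(layers), config)


def parameter_count(config: ModelConfig) -> int:
    """Closed-form parameter count: conv (k*c_in+1)*c_out per block, dense (n_in+1)*n_out."""
    total = 0
    c_in = 4
    for _ in range(config.n_conv_blocks):
        total += (config.kernel_size * c_in + 1) * config.filters_per_block
        c_in = config.filters_per_block
    n_in = config.flat_features()
    for units in config.dense_units:
        total += (n_in + 1) * units
        n_in = units
    total += (n_in + 1) * config.n_classes
    return total


def train(
    model: XlncModel, train_set: EncodedDataset, config: ModelConfig | None = None
) -> XlncModel:
    """SGD-momentum training on two-class cross-entropy; mutates ``model``.

    Per-epoch loss/accuracy (computed on the training batches, dropout
    active) are appended to ``model.history``. Initialization and batch
    order are deterministic given ``config.seed``.
    """
    config = config or model.config
    classes = np.unique(train_set.labels)
    if len(classes) < 2:
        raise ValueError(f"training set has a single class: {classes.tolist()}")
    if train_set.input_length != config.input_length:
        raise ValueError(
            f"expected input length {config.input_length}, got {train_set.input_length}"
        )
    _, _, rng_shuffle = _rngs(config.seed)
    opt = nn.SGDMomentum(model.network.params(), config.learning_rate, config.momentum)
    n = len(train_set)
    x_all = train_set.tensor.astype(nn.DTYPE, copy=False)
    y_all = train_set.labels
    for _ in range(config.epochs):
        order = rng_shuffle.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            x, y = x_all[idx], y_all[idx]
            logits = model.network.forward(x, train=True)
            probs = nn.softmax(logits)
            losses.append(nn.cross_entropy(probs, y) * len(idx))
            correct += int((probs.argmax(axis=1) == y).sum())
            dlogits = probs.copy()
            dlogits[np.arange(len(idx)), y] -= 1.0
            dlogits /= len(idx)
            model.network.backward(dlogits.astype(nn.DTYPE))
            opt.step(model.network.grads())
        model.history["loss"].append(float(np.sum(losses) / n))
        model.history["accuracy"].append(correct / n)
    model.trained = True
    return model


def predict(
    model: XlncModel, batch: EncodedDataset, chunk: int = 256
) -> list[PredictionRecord]:
    """Softmax probabilities per record, dropout inactive, input order kept."""
    if batch.input_length != model.config.input_length:
        raise ValueError(
            f"shape mismatch: model expects input length {model.config.input_length}, "
            f"received {batch.input_length}"
        )
    probs = predict_proba(model, batch.tensor, chunk=chunk)
    ids = batch.ids or [str(i) for i in range(len(batch))]
    return [
        PredictionRecord(id=ids[i], p_lncRNA=float(probs[i, 1]), p_mRNA=float(probs[i, 0]))
        for i in range(len(batch))
    ]


def predict_proba(model: XlncModel, tensor: np.ndarray, chunk: int = 256) -> np.ndarray:
    """(N, 2) class probabilities, columns (mRNA, lncRNA)."""
    out = []
    for lo in range(0, len(tensor), chunk):
        out.append(model.network.predict_proba(tensor[lo : lo + chunk].astype(nn.DTYPE)))
    return np.concatenate(out) if out else np.zeros((0, 2))


def predictions_to_tsv(preds: Sequence[PredictionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(p.id, p.p_lncRNA, p.p_mRNA, p.predicted_label) for p in preds],
        columns=["id", "p_lncRNA", "p_mRNA", "predicted_label"],
    ).to_csv(path, sep="\t", index=False)


def read_predictions_tsv(path: str | Path) -> list[PredictionRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        PredictionRecord(id=str(r.id), p_lncRNA=float(r.p_lncRNA), p_mRNA=float(r.p_mRNA))
        for r in df.itertuples()
    ]


def grid_search(
    train_set: EncodedDataset,
    grid: Mapping[str, Sequence],
    base_config: ModelConfig | None = None,
    val_fraction: float = 0.10,
    seed: int = 0,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Exhaustive hyperparameter search scored on a held-out validation slice.

    Every grid point is trained on the remaining data and scored by
    validation accuracy; ties break toward the first point in lexicographic
    grid order (sorted keys, given value order). Structurally impossible
    configurations are skipped with a warning and a NaN score.
    """
    from sklearn.model_selection import train_test_split

    if not grid:
        raise ValueError("grid must be non-empty")
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must be in (0, 1)")
    base = base_config or ModelConfig()
    keys = sorted(grid)
    idx = np.arange(len(train_set))
    tr_idx, val_idx = train_test_split(
        idx, test_size=val_fraction, stratify=train_set.labels, random_state=seed
    )
    tr, val = train_set.subset(tr_idx), train_set.subset(val_idx)

    rows = []
    best: tuple[float, ModelConfig] | None = None
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        row = dict(params)
        try:
            cfg = replace(base, seed=seed, **params)
            model = train(build_model(cfg), tr, cfg)
            probs = predict_proba(model, val.tensor)
            acc = float((probs.argmax(axis=1) == val.labels).mean())
        except ValueError as exc:
            warnings.warn(f"grid point {params} skipped: {exc}")
            row["val_accuracy"] = float("nan")
            rows.append(row)
            continue
        row["val_accuracy"] = acc
        rows.append(row)
        if best is None or acc > best[0]:
            best = (acc, cfg)
    if best is None:
        raise ValueError("no grid point produced a valid model")
    return best[1], pd.DataFrame(rows)
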