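"""The three 1-D CNN gait classifiers and their training loop.

Three architectures share one input contract — a window tensor of shape
``(Nw, Wl, Nch)`` — and one training recipe (Adam on categorical
cross-entropy, early stopping on validation macro-recall with best-weight
restoration):

* ``mCNN-1D`` — multi-branch: one branch per IMU component, each branch
  conv1d(64, k=5) -> ReLU -> maxpool(2) -> conv1d(128, k=5) -> ReLU ->
  global average pooling; branches concatenated, dense(128), softmax.
* ``smCNN-1D`` — simplified multi-branch: a single conv1d(128, k=5) layer
  per branch and one dense(128) layer; trained with batch size 256.
* ``sCNN-1D`` — sequential: the simplified stack without branch splitting,
  so single-component inputs are natural.

The user-facing surface follows the model/results idiom: ``GaitCNN`` binds
architecture to training and validation data, ``fit`` returns a
``GaitCNNResults`` carrying the trained network, its history and
diagnostics.  Thin functional wrappers (``build_model``, ``train``,
``predict``, ``measure_inference_time``) expose the same operations.
"""

from __future__ import annotations

import dataclasses
import time

import numpy as np
import pandas as pd

from . import _net
from .io import ValidationError, WindowedDataset

__all__ = ["ARCHITECTURES", "ModelSpec", "TrainConfig", "build_model",
           "train", "predict", "measure_inference_time", "GaitCNN",
           "GaitCNNResults", "component_branch_split"]

ARCHITECTURES = ("mCNN-1D", "smCNN-1D", "sCNN-1D")
_MULTIBRANCH = {"mCNN-1D", "smCNN-1D"}
_DEFAULT_BATCH = {"mCNN-1D": 32, "smCNN-1D": 256, "sCNN-1D": 32}
# learning rate scales with batch size (linear-scaling heuristic)
_DEFAULT_LR = {"mCNN-1D": 1e-3, "smCNN-1D": 4e-3, "sCNN-1D": 1e-3}


def component_branch_split(n_sensors: int, n_components: int,
                           ) -> list[list[int]]:
    """Per-component channel groups for the canonical sensor-major layout.

    Channels are ordered sensor-major then component-major, so component
    ``c`` owns 3 consecutive columns inside every sensor's block.
    """
    block = 3 * n_components
    return [[s * block + c * 3 + a
             for s in range(n_sensors) for a in range(3)]
            for c in range(n_components)]


@dataclasses.dataclass
class ModelSpec:
    architecture: str
    input_shape: tuple[int, int]  # (Wl, Nch)
    n_classes: int = 5
    branch_split: list[list[int]] | None = None

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValidationError(
                f"unknown architecture {self.architecture!r}; "
                f"valid: {ARCHITECTURES}")
        wl, nch = self.input_shape
        if wl < 5 or nch < 1:
            raise ValidationError(f"invalid input_shape {self.input_shape}")
        multi = self.architecture in _MULTIBRANCH
        if multi:
            if self.branch_split is None:
                raise ValidationError(
                    f"{self.architecture} requires branch_split")
            flat = sorted(i for g in self.branch_split for i in g)
            if flat != list(range(nch)):
                raise ValidationError(
                    "branch_split must partition the channel indices "
                    f"0..{nch - 1}")
        elif self.branch_split is not None:
            raise ValidationError("sCNN-1D takes no branch_split")


@dataclasses.dataclass
class TrainConfig:
    max_epochs: int = 100
    batch_size: int | None = None  # None -> architecture default
    learning_rate: float | None = None  # None -> architecture default
    early_stop_metric: str = "val_macro_recall"
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.patience < 1:
            raise ValidationError("max_epochs and patience must be >= 1")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.learning_rate is not None and self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.early_stop_metric != "val_macro_recall":
            raise ValidationError(
                "early stopping monitors validation macro-recall")


def _branch(arch: str, c_in: int, rng) -> _net.Sequential:
    if arch == "mCNN-1D":
        return _net.Sequential([
            _net.Conv1D(c_in, 64, 5, rng), _net.ReLU(), _net.MaxPool1D(2),
            _net.Conv1D(64, 128, 5, rng), _net.ReLU(),
            _net.GlobalAvgPool()])
    return _net.Sequential([
        _net.Conv1D(c_in, 128, 5, rng), _net.ReLU(), _net.GlobalAvgPool()])


def build_model(spec: ModelSpec, seed: int = 0) -> _net.Network:
    """Instantiate the network for a spec; parameter count is a pure
    function of the spec (initial values depend on the seed)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
    wl, nch = spec.input_shape
    if spec.architecture in _MULTIBRANCH:
        groups = [list(g) for g in spec.branch_split]
        subnets = [_branch(spec.architecture, len(g), rng) for g in groups]
        feature = _net.ChannelBranches(groups, subnets)
        n_feat = 128 * len(groups)
        head = [feature]
    else:
        head = [_branch("sCNN-1D", nch, rng)]
        n_feat = 128
    stack = _net.Sequential(head + [
        _net.Dense(n_feat, 128, rng), _net.ReLU(),
        _net.Dropout(0.5, np.random.default_rng(
            np.random.SeedSequence((seed, 23)))),
        _net.Dense(128, spec.n_classes, rng)])
    return _net.Network(stack, spec.n_classes)


def _macro_recall(y_true: np.ndarray, y_pred: np.ndarray,
                  n_classes: int) -> float:
    vals = []
    for c in range(n_classes):
        mask = y_true == c
        vals.append(float((y_pred[mask] == c).mean()))
    return float(np.mean(vals))


def _check_classes(labels: np.ndarray, n_classes: int, name: str) -> None:
    present = set(np.unique(labels).tolist())
    missing = sorted(set(range(n_classes)) - present)
    if missing:
        raise ValidationError(
            f"classes {missing} absent from the {name} set; "
            "macro-recall is undefined")
    extra = sorted(present - set(range(n_classes)))
    if extra:
        raise ValidationError(f"labels {extra} outside [0, {n_classes})")


def train(model: _net.Network, train_data: WindowedDataset,
          val_data: WindowedDataset, cfg: TrainConfig,
          architecture: str = "sCNN-1D") -> pd.DataFrame:
    """Fit a network in place; returns the per-epoch history.

    Optimises categorical cross-entropy with Adam; stops when validation
    macro-recall has not improved for ``cfg.patience`` epochs and restores
    the weights of the best epoch.
    """
    if set(train_data.subject_ids) & set(val_data.subject_ids):
        raise ValidationError("train and validation subjects overlap")
    _check_classes(train_data.labels, model.n_classes, "training")
    _check_classes(val_data.labels, model.n_classes, "validation")

    batch = cfg.batch_size or _DEFAULT_BATCH[architecture]
    lr = cfg.learning_rate or _DEFAULT_LR[architecture]
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 31)))
    opt = _net.Adam(model.stack.params(), lr=lr)

    x_tr = train_data.tensor
    y_tr = train_data.labels
    best_metric, best_weights, wait = -np.inf, model.get_weights(), 0
    rows = []
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(x_tr.shape[0])
        losses = []
        for start in range(0, len(order), batch):
            idx = order[start:start + batch]
            losses.append(model.loss_and_grad(x_tr[idx], y_tr[idx]))
            opt.step(model.stack.grads())
        val_pred = model.predict_proba(val_data.tensor).argmax(axis=1)
        metric = _macro_recall(val_data.labels, val_pred, model.n_classes)
        rows.append({"epoch": epoch, "loss": float(np.mean(losses)),
                     "val_macro_recall": metric})
        if metric >= best_metric - 1e-12:
            # among equal-best epochs keep the most-trained weights
            best_weights = model.get_weights()
        if metric > best_metric + 1e-12:
            best_metric, wait = metric, 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    model.set_weights(best_weights)
    return pd.DataFrame(rows)


def predict(model: _net.Network, windows: np.ndarray,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Class labels (argmax, ties to the lowest index) and probabilities."""
    windows = np.asarray(windows)
    if windows.ndim != 3:
        raise ValidationError("windows must have shape (Nw, Wl, Nch)")
    probs = model.predict_proba(windows)
    return probs.argmax(axis=1), probs


def measure_inference_time(model: _net.Network, windows: np.ndarray,
                           n_trials: int = 5) -> dict:
    """Wall-clock time of a full forward pass over ``windows``.

    One untimed warm-up call precedes the trials; the timed span covers
    exactly input-to-label inference, no metric computation.
    """
    windows = np.asarray(windows)
    if windows.ndim != 3 or windows.shape[0] == 0:
        raise ValidationError("need a non-empty (Nw, Wl, Nch) window set")
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    model.predict_proba(windows)  # warm-up
    times = []
    for _ in range(n_trials):
        t0 = time.perf_counter()
        model.predict_proba(windows).argmax(axis=1)
        times.append(time.perf_counter() - t0)
    times_arr = np.array(times)
    q1, med, q3 = np.percentile(times_arr, [25, 50, 75])
    return {
        "trial_times_s": times,
        "median_s": float(med),
        "iqr_s": float(q3 - q1),
        "per_window_s": float(med / windows.shape[0]),
        "n_windows": int(windows.shape[0]),
    }


class GaitCNN:
    """A gait classifier bound to training and validation windows.

    Parameters
    ----------
    train_data, val_data : WindowedDataset
        Subject-disjoint training and validation windows sharing one
        sensor/component selection.
    architecture : str
        One of ``mCNN-1D``, ``smCNN-1D``, ``sCNN-1D``.
    n_classes : int
        Number of gait classes (5: WN, WH, WF, WA, WP).
    branch_split : list of channel-index lists, optional
        Channel partition for multi-branch architectures; derived from the
        selection's components when omitted.
    """

    def __init__(self, train_data: WindowedDataset,
                 val_data: WindowedDataset, architecture: str = "smCNN-1D",
                 n_classes: int = 5,
                 branch_split: list[list[int]] | None = None):
        if train_data.selection != val_data.selection:
            raise ValidationError(
                "train and validation selections must match")
        wl, nch = train_data.tensor.shape[1], train_data.tensor.shape[2]
        if branch_split is None and architecture in _MULTIBRANCH:
            sel = train_data.selection
            branch_split = component_branch_split(len(sel.sensors),
                                                 len(sel.components))
        self.spec = ModelSpec(architecture, (wl, nch), n_classes,
                              branch_split)
        self.train_data = train_data
        self.val_data = val_data

    def fit(self, cfg: TrainConfig | None = None) -> "GaitCNNResults":
        cfg = cfg or TrainConfig()
        model = build_model(self.spec, seed=cfg.seed)
        history = train(model, self.train_data, self.val_data, cfg,
                        architecture=self.spec.architecture)
        return GaitCNNResults(self, model, history, cfg)


class GaitCNNResults:
    """Trained classifier plus its history and diagnostics."""

    def __init__(self, model_def: GaitCNN, network: _net.Network,
                 history: pd.DataFrame, cfg: TrainConfig):
        self.model_def = model_def
        self.network = network
        self.history = history
        self.train_config = cfg

    @property
    def spec(self) -> ModelSpec:
        return self.model_def.spec

    @property
    def n_params(self) -> int:
        return self.network.n_params

    @property
    def n_epochs(self) -> int:
        return len(self.history)

    @property
    def best_val_macro_recall(self) -> float:
        return float(self.history["val_macro_recall"].max())

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return predict(self.network, windows)[0]

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        return predict(self.network, windows)[1]

    def measure_inference_time(self, windows: np.ndarray,
                               n_trials: int = 5) -> dict:
        return measure_inference_time(self.network, windows, n_trials)

    def summary(self) -> str:
        spec = self.spec
        sel = self.model_def.train_data.selection
        lines = [
            "Gait CNN classifier results",
            "=" * 44,
            f"architecture:        {spec.architecture}",
            f"input shape (Wl,Nch): {spec.input_shape}",
            f"classes:             {spec.n_classes}",
            f"sensors:             {'+'.join(sel.sensors)}",
            f"components:          {'+'.join(sel.components)}",
            f"parameters:          {self.n_params}",
            f"training windows:    {self.model_def.train_data.n_windows}",
            f"epochs trained:      {self.n_epochs}",
            f"best val macro-recall: {self.best_val_macro_recall:.4f}",
            f"final train loss:    {self.history['loss'].iloc[-1]:.4f}",
        ]
        return "\n".join(lines)
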