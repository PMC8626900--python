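"""Model configuration, normalization protocol, and the batch-size-1
training loop for per-timestep freeze classification.

The classifier is a stacked sequence-to-sequence LSTM (tanh activation)
with a time-distributed 2-unit softmax head, trained with Adam
(beta1=0.9, beta2=0.999), cross-entropy loss, and a batch size of 1 so
variable-length training instances need no padding. The learning rate
starts at 0.01 and halves every 5 epochs. Reference configurations:
2 layers x 16 units trained 30 epochs for detection; for prediction the
same architectures are stopped early (4 epochs for 2-layer, 3 for
3-layer models).

Features are z-scored with mean/SD pooled over the entire training split;
the statistics are recomputed whenever the training split changes (e.g.,
per cross-validation fold) and are stored with the model so classification
is self-contained.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import AdamState, LSTMNetwork, cross_entropy

__all__ = [
    "ModelConfig",
    "NormalizationStats",
    "FogClassifier",
    "lr_at_epoch",
    "fit_normalizer",
    "build_model",
    "train",
    "classify",
    "save_model",
    "load_model",
]

SD_FLOOR = 1e-8

DETECTION_EPOCHS = 30
PREDICTION_EPOCHS = {2: 4, 3: 3}  # early stopping by layer count


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one training run.

    ``batch_size`` is fixed at 1 (variable-length sequences); the output
    head always has 2 units. ``epochs`` defaults to the 30-epoch detection
    schedule; use :data:`PREDICTION_EPOCHS` for prediction models.
    """

    n_layers: int = 2
    units: int = 16
    initial_lr: float = 0.01
    lr_halving_every: int = 5
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 1
    epochs: int = DETECTION_EPOCHS
    n_features: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_layers <= 5:
            raise ValueError("n_layers must be in 1..5")
        if self.units not in (16, 32, 64):
            raise ValueError("units must be one of 16, 32, 64")
        if self.batch_size != 1:
            raise ValueError("batch_size is fixed at 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


def lr_at_epoch(epoch: int, config: ModelConfig | None = None) -> float:
    """Learning rate at a 0-based epoch: halved every 5 epochs from 0.01."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    cfg = config or ModelConfig()
    return cfg.initial_lr * 0.5 ** (epoch // cfg.lr_halving_every)


@dataclass
class NormalizationStats:
    """Per-feature z-score statistics, fit on the training split only."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.maximum(np.asarray(self.sd, dtype=np.float64), SD_FLOOR)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.sd


def fit_normalizer(feature_arrays: list[np.ndarray]) -> NormalizationStats:
    """Pool all training samples and compute per-feature mean and SD.

    SDs are floored at 1e-8 so constant features normalize to zero rather
    than dividing by zero.
    """
    if not feature_arrays:
        raise ValueError("cannot fit normalizer on an empty training set")
    pooled = np.concatenate([np.asarray(a, dtype=np.float64) for a in feature_arrays])
    if len(pooled) < 2:
        raise ValueError("need at least 2 training samples to fit a normalizer")
    return NormalizationStats(mean=pooled.mean(axis=0), sd=pooled.std(axis=0))


@dataclass
class FogClassifier:
    """A configured network plus (after training) its normalization stats."""

    config: ModelConfig
    network: LSTMNetwork
    stats: NormalizationStats | None = None
    loss_log: list[float] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return self.network.n_parameters

    @property
    def serialized_size_bytes(self) -> int:
        """Float32 storage footprint of the weights (wearable deployment)."""
        return self.n_parameters * 4


def build_model(config: ModelConfig) -> FogClassifier:
    """Instantiate the network for a config; weights depend only on seed."""
    network = LSTMNetwork(
        n_layers=config.n_layers,
        units=config.units,
        n_features=config.n_features,
        n_classes=2,
        seed=config.seed,
    )
    return FogClassifier(config=config, network=network)


def train(
    model: FogClassifier,
    sequences: list[tuple[np.ndarray, np.ndarray]],
    stats: NormalizationStats,
) -> list[float]:
    """Train on normalized variable-length sequences, one per gradient step.

    ``sequences`` holds (features, binary targets) pairs in raw feature
    units; normalization with ``stats`` is applied here. Instance
    presentation order is reshuffled every epoch under the run seed. The
    hidden state is reset between instances. Returns the per-epoch mean
    loss log (also stored on the model). Raises on non-finite loss.
    """
    cfg = model.config
    model.stats = stats
    norm = [(stats.apply(X), np.asarray(y, dtype=np.int64)) for X, y in sequences]
    adam = AdamState(
        model.network.parameters(), beta1=cfg.adam_beta1, beta2=cfg.adam_beta2
    )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7A1]))
    log: list[float] = []
    for epoch in range(cfg.epochs):
        lr = lr_at_epoch(epoch, cfg)
        order = rng.permutation(len(norm))
        losses = []
        for idx in order:
            X, y = norm[idx]
            probs, caches = model.network.forward(X, return_cache=True)
            loss = cross_entropy(probs, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, instance {idx}; "
                    "check feature scaling and learning rate"
                )
            grads = model.network.backward(probs, caches, y)
            adam.step(model.network.parameters(), grads, lr)
            losses.append(loss)
        log.append(float(np.mean(losses)) if losses else float("nan"))
    model.loss_log = log
    return log


def classify(
    model: FogClassifier,
    features: np.ndarray,
    stats: NormalizationStats | None = None,
) -> np.ndarray:
    """Per-timestep argmax class (0 = non-target, 1 = target) for a trial.

    Applies the model's training-fold normalization, then one causal
    forward pass over the full, unbalanced sequence.
    """
    use = stats if stats is not None else model.stats
    if use is None:
        raise ValueError("model has no normalization stats; train first or pass stats")
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[1] != model.config.n_features:
        raise ValueError(
            f"expected (T, {model.config.n_features}) features, got {features.shape}"
        )
    probs = model.network.forward(use.apply(features))
    return probs.argmax(axis=1)


def predict_proba(
    model: FogClassifier,
    features: np.ndarray,
    stats: NormalizationStats | None = None,
) -> np.ndarray:
    """Per-timestep class probabilities (rows sum to 1)."""
    use = stats if stats is not None else model.stats
    if use is None:
        raise ValueError("model has no normalization stats; train first or pass stats")
    return model.network.forward(use.apply(features))


def save_model(model: FogClassifier, path: str | Path) -> Path:
    """Serialize weights, config, and normalization stats to one .npz."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = {k: v for k, v in model.network.get_state().items()}
    meta = {"config": asdict(model.config), "loss_log": model.loss_log}
    payload = dict(state)
    payload["_meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    if model.stats is not None:
        payload["_stats_mean"] = model.stats.mean
        payload["_stats_sd"] = model.stats.sd
    np.savez(path, **payload)
    return path


def load_model(path: str | Path) -> FogClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta_json"]).decode())
        config = ModelConfig(**meta["config"])
        model = build_model(config)
        model.network.set_state({k: data[k] for k in data.files
                                 if not k.startswith("_")})
        model.loss_log = list(meta.get("loss_log", []))
        if "_stats_mean" in data.files:
            model.stats = NormalizationStats(data["_stats_mean"], data["_stats_sd"])
    return model
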