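"""LVQ1 nearest-prototype classifier.

One prototype (weight vector) per class lives in the zone-feature
space.  Training sweeps the samples in a fixed order for up to
``max_epoch`` epochs: each sample pulls its nearest prototype toward
itself when the classes agree,

    w <- w + alpha * (x - w),

and pushes it away when they disagree,

    w <- w - alpha * (x - w).

After every epoch the learning rate decays multiplicatively,
``alpha <- alpha * dec_alpha``, and training stops early once alpha
falls to ``eps`` or below.  Prediction returns the label of the
nearest prototype under Euclidean distance, with ties broken by class
declaration order.  The whole procedure is deterministic: no RNG, and
sample order is the dataset order.

Prototypes are bootstrapped from the data itself: the first training
sample of each class becomes that class's initial prototype and is
removed from the iteration set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionMismatchError, MissingClassError, ModelFormatError

__all__ = [
    "LVQConfig",
    "LVQModel",
    "TrainingSet",
    "init_model",
    "distance",
    "train",
    "predict",
    "fit",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class LVQConfig:
    """Training hyperparameters.

    alpha : initial learning rate, in (eps, 1].
    dec_alpha : per-epoch multiplicative decay of alpha, in (0, 1).
    max_epoch : maximum number of passes over the training set.
    eps : learning-rate floor; training stops once alpha <= eps.
    """

    alpha: float = 0.05
    dec_alpha: float = 0.9
    max_epoch: int = 100
    eps: float = 1e-4

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (0 < self.dec_alpha < 1):
            raise ValueError(f"dec_alpha must be in (0, 1), got {self.dec_alpha}")
        if self.max_epoch < 1:
            raise ValueError(f"max_epoch must be >= 1, got {self.max_epoch}")
        if self.eps < 0 or self.eps >= self.alpha:
            raise ValueError(f"need alpha > eps >= 0, got alpha={self.alpha}, eps={self.eps}")


@dataclass
class TrainingSet:
    """Feature vectors with matching class labels."""

    samples: np.ndarray  # (n_samples, feature_dim)
    labels: list[str]

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.samples.shape[0]} samples but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class LVQModel:
    """One prototype vector per class plus the training configuration."""

    class_labels: tuple[str, ...]
    prototypes: dict[str, np.ndarray]
    feature_dim: int
    config: LVQConfig = field(default_factory=LVQConfig)
    training_log: list[dict] = field(default_factory=list)

    def copy(self) -> "LVQModel":
        return LVQModel(
            class_labels=self.class_labels,
            prototypes={k: v.copy() for k, v in self.prototypes.items()},
            feature_dim=self.feature_dim,
            config=self.config,
            training_log=[dict(e) for e in self.training_log],
        )


def init_model(
    training: TrainingSet,
    config: LVQConfig | None = None,
    class_labels: tuple[str, ...] = ("normal", "suspected"),
) -> tuple[LVQModel, TrainingSet]:
    """Bootstrap prototypes from the first sample of each class.

    Returns the initialized model and the remaining iteration set (the
    training set minus the samples consumed as prototypes).  Fully
    deterministic.

    Raises
    ------
    MissingClassError
        If any declared class has no training sample.
    """
    if config is None:
        config = LVQConfig()
    prototypes: dict[str, np.ndarray] = {}
    used: list[int] = []
    for label in class_labels:
        try:
            i = training.labels.index(label)
        except ValueError:
            raise MissingClassError(f"no training sample for class {label!r}") from None
        prototypes[label] = training.samples[i].astype(np.float64).copy()
        used.append(i)
    for lab in training.labels:
        if lab not in class_labels:
            raise MissingClassError(f"training label {lab!r} is not a declared class")
    keep = [i for i in range(len(training)) if i not in used]
    remainder = TrainingSet(
        samples=training.samples[keep] if keep else np.empty((0, training.samples.shape[1])),
        labels=[training.labels[i] for i in keep],
    )
    model = LVQModel(
        class_labels=tuple(class_labels),
        prototypes=prototypes,
        feature_dim=training.samples.shape[1],
        config=config,
    )
    return model, remainder


def distance(x: np.ndarray, w: np.ndarray) -> float:
    """Euclidean distance between a feature vector and a prototype."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if x.shape != w.shape:
        raise DimensionMismatchError(f"dimension mismatch: {x.shape} vs {w.shape}")
    return float(np.linalg.norm(x - w))


def _nearest(model: LVQModel, x: np.ndarray) -> tuple[str, dict[str, float]]:
    dists = {lab: distance(x, model.prototypes[lab]) for lab in model.class_labels}
    best = min(model.class_labels, key=lambda lab: dists[lab])  # ties: earliest class
    return best, dists


def train(model: LVQModel, training: TrainingSet) -> tuple[LVQModel, list[dict]]:
    """Run the LVQ1 epoch loop; returns a new model and a per-epoch log.

    The input model is left untouched.  Each log entry records the
    epoch number, the learning rate in force, and how many samples were
    nearest to a wrong-class prototype during that pass.
    """
    out = model.copy()
    log: list[dict] = []
    if len(training) == 0:
        log.append({"epoch": 0, "alpha": model.config.alpha, "errors": 0,
                    "warning": "empty iteration set; prototypes unchanged"})
        out.training_log = log
        return out, log
    if training.samples.shape[1] != model.feature_dim:
        raise DimensionMismatchError(
            f"training feature dim {training.samples.shape[1]} != model dim {model.feature_dim}"
        )
    alpha = model.config.alpha
    for epoch in range(1, model.config.max_epoch + 1):
        if alpha <= model.config.eps:
            break
        errors = 0
        for x, lab in zip(training.samples, training.labels):
            winner, _ = _nearest(out, x)
            w = out.prototypes[winner]
            if winner == lab:
                w += alpha * (x - w)
            else:
                w -= alpha * (x - w)
                errors += 1
        log.append({"epoch": epoch, "alpha": alpha, "errors": errors})
        alpha *= model.config.dec_alpha
    out.training_log = log
    return out, log


def predict(model: LVQModel, x: np.ndarray) -> tuple[str, dict[str, float]]:
    """Classify a feature vector by its nearest prototype.

    Returns the winning label and the distance to every class
    prototype (the per-class "weight" columns of a results table).
    Ties go to the class listed first in ``class_labels``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (model.feature_dim,):
        raise DimensionMismatchError(
            f"feature vector shape {x.shape} != (feature_dim={model.feature_dim},)"
        )
    return _nearest(model, x)


def fit(
    training: TrainingSet,
    config: LVQConfig | None = None,
    class_labels: tuple[str, ...] = ("normal", "suspected"),
) -> LVQModel:
    """Convenience: bootstrap prototypes then run the training loop."""
    model, remainder = init_model(training, config, class_labels)
    trained, _ = train(model, remainder)
    return trained


def save_model(model: LVQModel, path: str | Path) -> None:
    """Persist a model as a JSON document (prototypes bit-exact via repr floats)."""
    doc = {
        "classes": list(model.class_labels),
        "feature_dim": model.feature_dim,
        "prototypes": {lab: model.prototypes[lab].tolist() for lab in model.class_labels},
        "config": {
            "alpha": model.config.alpha,
            "dec_alpha": model.config.dec_alpha,
            "max_epoch": model.config.max_epoch,
            "eps": model.config.eps,
        },
        "training_log": model.training_log,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path: str | Path) -> LVQModel:
    """Load a model saved by :func:`save_model`.

    Raises
    ------
    ModelFormatError
        If the file is not valid JSON or lacks required fields.
    """
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    for key in ("classes", "feature_dim", "prototypes", "config"):
        if key not in doc:
            raise ModelFormatError(f"{path}: missing required field {key!r}")
    classes = tuple(doc["classes"])
    prototypes = {}
    for lab in classes:
        if lab not in doc["prototypes"]:
            raise ModelFormatError(f"{path}: missing prototype for class {lab!r}")
        vec = np.asarray(doc["prototypes"][lab], dtype=np.float64)
        if vec.shape != (doc["feature_dim"],):
            raise ModelFormatError(
                f"{path}: prototype for {lab!r} has {vec.size} values, "
                f"expected {doc['feature_dim']}"
            )
        prototypes[lab] = vec
    cfg = LVQConfig(**doc["config"])
    return LVQModel(
        class_labels=classes,
        prototypes=prototypes,
        feature_dim=int(doc["feature_dim"]),
        config=cfg,
        training_log=list(doc.get("training_log", [])),
    )
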