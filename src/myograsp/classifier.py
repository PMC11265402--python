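"""Per-sample pose classification.

A two-layer feed-forward network (logistic-sigmoid hidden layer, softmax
output) maps each 3-channel normalized envelope sample to one of the five
pose classes.  Training minimizes mean cross-entropy with Moller's scaled
conjugate gradient (SCG): a conjugate-gradient method whose step size
comes from a finite-difference Hessian-vector product regularized by a
Levenberg-Marquardt scale, so it needs no line search.

The feature space is only 3-dimensional and the class geometry simple, so
a small hidden layer (default 10 units) suffices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .poses import CLASS_ORDER, N_CLASSES, PoseClass
from .preprocess import EnvelopeStream
from .simulate import label_runs


class ClassifierError(ValueError):
    pass


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Labeled envelope samples ready for training/evaluation."""

    features: np.ndarray          # [n x channels]
    targets: np.ndarray           # [n] int class codes
    provenance: np.ndarray | None = None   # source sample indices

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.targets = np.asarray(self.targets, dtype=np.int8)
        if len(self.features) != len(self.targets):
            raise ClassifierError("features/targets length mismatch")
        if len(self.features) and not np.all(np.isfinite(self.features)):
            raise ClassifierError("features must be finite")

    def __len__(self) -> int:
        return len(self.targets)


def extract_dataset(envelope: EnvelopeStream, trim: float = 2.0) -> Dataset:
    """Keep only steady-state samples: within each contiguous same-label
    block, discard ``trim`` seconds at both ends (transition artifacts and
    reaction time), retaining the middle of the block.  Rest blocks are
    trimmed identically and contribute R samples.
    """
    if envelope.labels is None:
        raise ClassifierError("envelope stream carries no labels")
    if trim < 0:
        raise ClassifierError("trim must be >= 0")
    fs = envelope.sampling_rate
    trim_n = int(round(trim * fs))
    keep: list[np.ndarray] = []
    for start, end, _cls in label_runs(envelope.labels):
        if end - start < 2 * trim_n:
            raise ClassifierError(
                f"label block [{start}, {end}) is shorter than twice the "
                f"trim window ({trim} s each side)"
            )
        keep.append(np.arange(start + trim_n, end - trim_n))
    idx = np.concatenate(keep) if keep else np.zeros(0, dtype=int)
    return Dataset(
        features=envelope.values[idx],
        targets=envelope.labels[idx],
        provenance=idx,
    )


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ClassifierError("train_fraction must lie in (0, 1)")


def split_train_test(dataset: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset]:
    """Seeded uniform sample-level split: round(train_fraction * n) samples
    for training, the remainder held out; disjoint union of the input."""
    n = len(dataset)
    if n == 0:
        raise ClassifierError("cannot split an empty dataset")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = int(round(spec.train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    tr, te = perm[:n_train], perm[n_train:]
    prov = dataset.provenance if dataset.provenance is not None else np.arange(n)
    return (
        Dataset(dataset.features[tr], dataset.targets[tr], prov[tr]),
        Dataset(dataset.features[te], dataset.targets[te], prov[te]),
    )


# ---------------------------------------------------------------------------
# network model
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


@dataclass
class ClassifierModel:
    """Two-layer network: sigmoid hidden layer, softmax output over the
    five pose classes in the fixed order R, TVG, LP, EG, E."""

    hidden_weights: np.ndarray     # [in x H]
    hidden_bias: np.ndarray        # [H]
    output_weights: np.ndarray     # [H x n_classes]
    output_bias: np.ndarray        # [n_classes]
    training_log: dict = field(default_factory=dict)
    hidden_activation: str = "sigmoid"
    output_activation: str = "softmax"

    def __post_init__(self) -> None:
        for name in ("hidden_weights", "hidden_bias", "output_weights",
                     "output_bias"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if not np.all(np.isfinite(arr)):
                raise ClassifierError(f"{name} contains non-finite values")

    @property
    def n_inputs(self) -> int:
        return self.hidden_weights.shape[0]

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != self.n_inputs:
            raise ClassifierError(
                f"expected {self.n_inputs} input channels, got {features.shape[1]}"
            )
        hidden = _sigmoid(features @ self.hidden_weights + self.hidden_bias)
        return _softmax(hidden @ self.output_weights + self.output_bias)

    def predict(self, features: np.ndarray) -> np.ndarray:
        # argmax returns the first maximum: ties resolve to the lowest
        # class code, i.e. the fixed order R < TVG < LP < EG < E.
        return np.argmax(self.predict_proba(features), axis=1).astype(np.int8)

    # -- persistence --------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "layer_sizes": [self.n_inputs,
                                self.hidden_weights.shape[1],
                                self.output_weights.shape[1]],
                "hidden_weights": self.hidden_weights.tolist(),
                "hidden_bias": self.hidden_bias.tolist(),
                "output_weights": self.output_weights.tolist(),
                "output_bias": self.output_bias.tolist(),
                "hidden_activation": self.hidden_activation,
                "output_activation": self.output_activation,
                "training_log": self.training_log,
                "class_order": [c.code for c in CLASS_ORDER],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        d = json.loads(text)
        return cls(
            hidden_weights=np.array(d["hidden_weights"]),
            hidden_bias=np.array(d["hidden_bias"]),
            output_weights=np.array(d["output_weights"]),
            output_bias=np.array(d["output_bias"]),
            training_log=d.get("training_log", {}),
            hidden_activation=d.get("hidden_activation", "sigmoid"),
            output_activation=d.get("output_activation", "softmax"),
        )


# ---------------------------------------------------------------------------
# scaled-conjugate-gradient training
# ---------------------------------------------------------------------------

def _pack(w1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def _unpack(theta: np.ndarray, n_in: int, h: int, n_out: int):
    i = 0
    w1 = theta[i:i + n_in * h].reshape(n_in, h); i += n_in * h
    b1 = theta[i:i + h]; i += h
    w2 = theta[i:i + h * n_out].reshape(h, n_out); i += h * n_out
    b2 = theta[i:i + n_out]
    return w1, b1, w2, b2


def _loss_grad(theta, X, Y, n_in, h, n_out, want_grad=True):
    w1, b1, w2, b2 = _unpack(theta, n_in, h, n_out)
    a1 = _sigmoid(X @ w1 + b1)
    p = _softmax(a1 @ w2 + b2)
    n = len(X)
    loss = -np.mean(np.log(np.clip(p[Y.astype(bool)], 1e-300, None)))
    if not want_grad:
        return loss, None
    dz2 = (p - Y) / n
    gw2 = a1.T @ dz2
    gb2 = dz2.sum(axis=0)
    dz1 = (dz2 @ w2.T) * a1 * (1.0 - a1)
    gw1 = X.T @ dz1
    gb1 = dz1.sum(axis=0)
    return loss, _pack(gw1, gb1, gw2, gb2)


def train_mlp_scg(
    train: Dataset,
    hidden_units: int = 10,
    max_iterations: int = 500,
    seed: int = 0,
    sigma: float = 1e-4,
    initial_lambda: float = 1e-6,
    grad_tol: float = 1e-6,
) -> ClassifierModel:
    """Train the pose network with Moller's scaled conjugate gradient.

    The curvature along the search direction p is estimated from a
    one-sided finite difference of the gradient (step sigma/|p|) and kept
    positive-definite by a Levenberg-Marquardt scale lambda that is raised
    when a step fails and lowered when the quadratic model fits well.
    The direction resets to steepest descent every |theta| iterations.
    Deterministic given the seed; the loss at accepted steps never
    increases.  Stops when the gradient norm drops below ``grad_tol`` or
    after ``max_iterations``.
    """
    if hidden_units < 1:
        raise ClassifierError("hidden_units must be >= 1")
    classes = np.unique(train.targets)
    if len(classes) < 2:
        raise ClassifierError("training set must contain at least two classes")
    X = train.features
    n_in, n_out = X.shape[1], N_CLASSES
    Y = np.zeros((len(X), n_out))
    Y[np.arange(len(X)), train.targets] = 1.0

    rng = np.random.default_rng(seed)
    n_params = n_in * hidden_units + hidden_units + hidden_units * n_out + n_out
    theta = rng.uniform(-0.5, 0.5, size=n_params)

    loss, grad = _loss_grad(theta, X, Y, n_in, hidden_units, n_out)
    r = -grad
    p = r.copy()
    success = True
    lam, lam_bar = initial_lambda, 0.0
    delta = 0.0
    losses = [float(loss)]
    restart_every = n_params
    k = 1
    while k <= max_iterations and np.linalg.norm(r) > grad_tol:
        p_norm2 = float(p @ p)
        if p_norm2 == 0.0:
            break
        if success:
            sk = sigma / np.sqrt(p_norm2)
            _, grad_s = _loss_grad(theta + sk * p, X, Y, n_in, hidden_units, n_out)
            s = (grad_s - grad) / sk
            delta = float(p @ s)
        delta += (lam - lam_bar) * p_norm2
        if delta <= 0:                       # make the Hessian model positive definite
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta = -delta + lam * p_norm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        loss_new, _ = _loss_grad(theta + alpha * p, X, Y, n_in, hidden_units,
                                 n_out, want_grad=False)
        comparison = 2.0 * delta * (loss - loss_new) / (mu * mu)
        if comparison >= 0:                  # successful step
            theta = theta + alpha * p
            loss, grad = _loss_grad(theta, X, Y, n_in, hidden_units, n_out)
            r_new = -grad
            lam_bar = 0.0
            success = True
            if k % restart_every == 0:
                p = r_new.copy()
            else:
                beta = float(r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            losses.append(float(loss))
            if comparison >= 0.75:
                lam = max(lam / 4.0, 1e-20)
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam = min(lam + delta * (1.0 - comparison) / p_norm2, 1e100)
        k += 1

    w1, b1, w2, b2 = _unpack(theta, n_in, hidden_units, n_out)
    return ClassifierModel(
        hidden_weights=w1, hidden_bias=b1, output_weights=w2, output_bias=b2,
        training_log={
            "iterations": k - 1,
            "loss_trajectory": losses,
            "final_loss": losses[-1],
            "final_gradient_norm": float(np.linalg.norm(r)),
            "seed": seed,
            "hidden_units": hidden_units,
        },
    )


# ---------------------------------------------------------------------------
# application and scoring
# ---------------------------------------------------------------------------

def classify_stream(
    model: ClassifierModel, envelope: EnvelopeStream
) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass over every envelope sample.  Returns (class-probability
    stream [n x 5], predicted label stream [n])."""
    probs = model.predict_proba(envelope.values)
    return probs, np.argmax(probs, axis=1).astype(np.int8)


@dataclass
class ConfusionMatrix:
    """Counts[i, j] = samples of true class i predicted as class j,
    classes ordered R, TVG, LP, EG, E."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        """Overall accuracy in percent (trace over total)."""
        return 100.0 * np.trace(self.counts) / self.total if self.total else np.nan

    @property
    def per_class_accuracy(self) -> np.ndarray:
        """Per-class accuracy in percent; NaN for absent classes."""
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, 100.0 * np.diag(self.counts) / row, np.nan)


def confusion(predicted: np.ndarray, truth: np.ndarray) -> ConfusionMatrix:
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ClassifierError("predicted/truth length mismatch")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (truth.astype(int), predicted.astype(int)), 1)
    return ConfusionMatrix(counts)
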