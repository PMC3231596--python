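"""Three-layer perceptron identifier and PCA reduction.

The identifier is a fully-connected network with one hidden layer of
logistic-sigmoid units and a symmetric-sigmoid (tanh) output layer, one
output unit per enrolled user.  Training is supervised one-vs-rest with
+1/-1 targets, minimising the mean squared error over the full batch with
nonlinear conjugate gradient; training stops when the MSE reaches
``mse_goal`` or after ``max_epochs`` iterations.  Because the outputs live in (-1, 1) the
per-user scores can be fused across classifiers without renormalisation.

High-dimensional stepping vectors (2560 inputs at the finest sampling
time) are optionally reduced by PCA before the network; 248 components is
the conventional operating point for that dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.decomposition import PCA


@dataclass(frozen=True)
class TrainConfig:
    """MLP training hyper-parameters.

    Defaults per modality are exposed as :data:`WALKING_TRAIN` (800
    epochs, MSE goal 1e-3) and :data:`STEPPING_TRAIN` (115 epochs, goal
    1e-5), both with 30 hidden nodes — enough for the accuracy plateau on
    ten-user cohorts.
    """

    hidden_nodes: int = 30
    max_epochs: int = 800
    mse_goal: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mse_goal <= 0:
            raise ValueError(f"mse_goal must be positive, got {self.mse_goal}")
        if self.hidden_nodes < 1 or self.max_epochs < 1:
            raise ValueError("hidden_nodes and max_epochs must be >= 1")


WALKING_TRAIN = TrainConfig(hidden_nodes=30, max_epochs=800, mse_goal=1e-3)
STEPPING_TRAIN = TrainConfig(hidden_nodes=30, max_epochs=115, mse_goal=1e-5)


@dataclass
class MLPModel:
    """A trained identifier: architecture, weights and training record."""

    classes: list
    W1: np.ndarray  # (P1, P2)
    b1: np.ndarray  # (P2,)
    W2: np.ndarray  # (P2, P3)
    b2: np.ndarray  # (P3,)
    config: TrainConfig
    epochs_run: int = 0
    final_mse: float = np.inf
    mse_trace: list[float] = field(default_factory=list)

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.W2.shape[1]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _unpack(theta: np.ndarray, p1: int, p2: int, p3: int):
    i = 0
    W1 = theta[i : i + p1 * p2].reshape(p1, p2)
    i += p1 * p2
    b1 = theta[i : i + p2]
    i += p2
    W2 = theta[i : i + p2 * p3].reshape(p2, p3)
    i += p2 * p3
    b2 = theta[i : i + p3]
    return W1, b1, W2, b2


def _mse_and_grad(theta, X, T, p1, p2, p3):
    W1, b1, W2, b2 = _unpack(theta, p1, p2, p3)
    n = X.shape[0]
    H = _sigmoid(X @ W1 + b1)
    O = np.tanh(H @ W2 + b2)
    E = O - T
    mse = float(np.mean(E**2))
    # d mse / d pre-activation of the output layer
    dO = (2.0 / E.size) * E * (1.0 - O**2)
    gW2 = H.T @ dO
    gb2 = dO.sum(axis=0)
    dH = (dO @ W2.T) * H * (1.0 - H)
    gW1 = X.T @ dH
    gb1 = dH.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
    return mse, grad


def train_mlp(X: np.ndarray, labels, config: TrainConfig | None = None) -> MLPModel:
    """Train the identifier on feature vectors ``X`` with class ``labels``.

    Targets are one-vs-rest: +1 on the true class's output, -1 elsewhere.
    Weights start at small seeded uniform values; full-batch nonlinear
    conjugate gradient (Polak-Ribiere with a Wolfe line search) minimises
    the batch MSE until it reaches ``mse_goal`` or ``max_epochs``
    iterations have run.  The MSE after each accepted iterate is recorded
    on ``mse_trace``; the line search keeps it non-increasing.
    Deterministic given the config seed.
    """
    config = config or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("training inputs contain NaN or infinite values")
    labels = list(labels)
    if len(labels) != X.shape[0]:
        raise ValueError(f"{X.shape[0]} rows but {len(labels)} labels")
    classes = sorted(set(labels))
    class_index = {c: i for i, c in enumerate(classes)}
    p1, p2, p3 = X.shape[1], config.hidden_nodes, len(classes)
    T = -np.ones((X.shape[0], p3))
    for row, lab in enumerate(labels):
        T[row, class_index[lab]] = 1.0

    rng = np.random.default_rng(config.seed)
    scale1 = 1.0 / np.sqrt(p1)
    scale2 = 1.0 / np.sqrt(p2)
    theta0 = np.concatenate(
        [
            rng.uniform(-scale1, scale1, p1 * p2),
            np.zeros(p2),
            rng.uniform(-scale2, scale2, p2 * p3),
            np.zeros(p3),
        ]
    )

    trace: list[float] = []

    def callback(xk):
        mse = _mse_and_grad(xk, X, T, p1, p2, p3)[0]
        trace.append(mse)
        if mse <= config.mse_goal:
            # scipy treats StopIteration from a callback as clean termination
            raise StopIteration

    # CG may halt early when a line search stalls; restarting from the
    # current iterate (steepest-descent direction) spends the remaining
    # iteration budget, keeping the stopping rule = (mse_goal, max_epochs).
    theta = theta0
    while len(trace) < config.max_epochs:
        before = len(trace)
        res = minimize(
            _mse_and_grad,
            theta,
            args=(X, T, p1, p2, p3),
            jac=True,
            method="CG",
            callback=callback,
            options={"maxiter": config.max_epochs - before, "gtol": 0.0},
        )
        theta = res.x
        if trace and trace[-1] <= config.mse_goal:
            break
        if len(trace) == before:  # no further progress possible
            break

    W1, b1, W2, b2 = (a.copy() for a in _unpack(theta, p1, p2, p3))
    final_mse = _mse_and_grad(theta, X, T, p1, p2, p3)[0]
    return MLPModel(
        classes=classes,
        W1=W1,
        b1=b1,
        W2=W2,
        b2=b2,
        config=config,
        epochs_run=len(trace),
        final_mse=final_mse,
        mse_trace=trace,
    )


def predict_scores(model: MLPModel, x: np.ndarray) -> np.ndarray:
    """Per-user matching scores in (-1, 1) for one feature vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != model.n_inputs:
        raise ValueError(
            f"expected a vector of length {model.n_inputs}, got shape {x.shape}"
        )
    return predict_scores_batch(model, x[None, :])[0]


def predict_scores_batch(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Score matrix (n_samples, n_users) for a batch of feature vectors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_inputs:
        raise ValueError(
            f"expected vectors of length {model.n_inputs}, got {X.shape[1]}"
        )
    H = _sigmoid(X @ model.W1 + model.b1)
    return np.tanh(H @ model.W2 + model.b2)


# ---------------------------------------------------------------------------
# PCA reduction (delegates to scikit-learn)
# ---------------------------------------------------------------------------

@dataclass
class PCAProjection:
    """Mean vector plus the top-k orthonormal principal directions."""

    mean: np.ndarray
    components: np.ndarray  # (k, dim)
    explained_variance: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[0]


def pca_fit(X: np.ndarray, k: int, seed: int = 0) -> PCAProjection:
    """Fit a k-component PCA to mean-centred data."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the input dimension {X.shape[1]}")
    k_eff = min(k, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k_eff, svd_solver="auto", random_state=seed)
    pca.fit(X)
    return PCAProjection(
        mean=pca.mean_.copy(),
        components=pca.components_.copy(),
        explained_variance=pca.explained_variance_.copy(),
    )


def pca_apply(proj: PCAProjection, X: np.ndarray) -> np.ndarray:
    """Project vectors onto the fitted components."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    out = (np.atleast_2d(X) - proj.mean) @ proj.components.T
    return out[0] if single else out
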