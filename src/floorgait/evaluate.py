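"""Identification decision, score-level fusion, and cross-validated evaluation.

Identification picks the enrolled user whose classifier output is largest
(argmax over the score vector).  The walking and stepping classifiers are
combined at the matching-score level: the fused score of user *i* is

    O_G(i) = W_W * O_W(i) + W_S * O_S(i)

with non-negative weights, and the argmax decision is applied to the
fused vector.  Because both networks emit scores in (-1, 1), no score
normalisation is needed before fusing, and joint positive rescaling of
the weights cannot change the decision.

Evaluation is repeated stratified k-fold cross-validation.  Inside each
training fold: walking min-max normalisation is fitted, the stepping PCA
is fitted, both MLPs are trained, and the fusion weights are selected by
grid search on an inner validation split carved from the training fold —
test folds never influence fitting.  Results aggregate into per-fold
accuracies and a confusion matrix accumulated over all repetitions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .features import NormalizationParams, apply_normalization, fit_normalization
from .mlp import (
    STEPPING_TRAIN,
    WALKING_TRAIN,
    MLPModel,
    PCAProjection,
    TrainConfig,
    pca_apply,
    pca_fit,
    predict_scores_batch,
    train_mlp,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FusionWeights:
    """Matching-score weights for the walking and stepping classifiers."""

    w_walking: float = 0.96
    w_stepping: float = 0.92

    def __post_init__(self) -> None:
        if self.w_walking < 0 or self.w_stepping < 0:
            raise ValueError("fusion weights must be non-negative")
        if self.w_walking == 0 and self.w_stepping == 0:
            raise ValueError("at least one fusion weight must be positive")


def identify(scores: np.ndarray) -> int:
    """Index of the identified user: argmax, ties to the lowest index."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot identify from an empty score vector")
    return int(np.argmax(scores))


def fuse_scores(
    scores_walking: np.ndarray, scores_stepping: np.ndarray, weights: FusionWeights
) -> np.ndarray:
    """Weighted sum of the two modalities' per-user score vectors."""
    ow = np.asarray(scores_walking, dtype=float)
    os_ = np.asarray(scores_stepping, dtype=float)
    if ow.shape != os_.shape:
        raise ValueError(f"score shapes differ: {ow.shape} vs {os_.shape}")
    return weights.w_walking * ow + weights.w_stepping * os_


def default_weight_grid(step: float = 0.02) -> np.ndarray:
    """The {0, step, 2*step, ..., 1}^2 grid searched for fusion weights."""
    axis = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    return np.array([(a, b) for a in axis for b in axis if a > 0 or b > 0])


def select_fusion_weights(
    val_scores_walking: np.ndarray,
    val_scores_stepping: np.ndarray,
    val_labels: np.ndarray,
    grid: np.ndarray | None = None,
) -> FusionWeights:
    """Grid-search the weights maximising validation identification accuracy.

    ``val_labels`` are class *indices* into the score columns.  Ties are
    broken toward the smaller weight norm, then lexicographically.
    """
    if grid is None:
        grid = default_weight_grid()
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty fusion weight grid")
    W = np.asarray(val_scores_walking, dtype=float)
    S = np.asarray(val_scores_stepping, dtype=float)
    y = np.asarray(val_labels)
    # fused[g, n, c] = grid[g,0] * W[n,c] + grid[g,1] * S[n,c]
    fused = grid[:, 0, None, None] * W[None] + grid[:, 1, None, None] * S[None]
    preds = fused.argmax(axis=2)
    accs = (preds == y[None, :]).mean(axis=1)
    norms = np.linalg.norm(grid, axis=1)
    order = np.lexsort((grid[:, 1], grid[:, 0], norms, -accs))
    ww, ws = grid[order[0]]
    return FusionWeights(w_walking=float(ww), w_stepping=float(ws))


# ---------------------------------------------------------------------------
# Cross-validated evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalConfig:
    """Pipeline configuration for one evaluation run."""

    walking_train: TrainConfig = WALKING_TRAIN
    stepping_train: TrainConfig = STEPPING_TRAIN
    pca_components: int | None = 248
    weight_grid_step: float = 0.02
    inner_val_fraction: float = 0.25
    modality: str = "both"  # "walking" | "stepping" | "both"


@dataclass
class EvalReport:
    """Aggregated cross-validation results.

    Confusion matrices are counts accumulated over every repetition, so
    row ``i`` sums to ``repetitions * n_samples(user i)``.
    """

    classes: list
    folds: int
    repetitions: int
    seed: int
    fold_accuracies: dict[str, list[float]]
    confusion: dict[str, np.ndarray]
    config: EvalConfig

    def accuracy(self, modality: str) -> float:
        cm = self.confusion[modality]
        return float(np.trace(cm) / cm.sum())

    def accuracy_sd(self, modality: str) -> float:
        return float(np.std(self.fold_accuracies[modality], ddof=1))

    def false_positive_rates(self, modality: str) -> np.ndarray:
        """Per-user rate of other users' samples identified as that user."""
        cm = self.confusion[modality]
        fp = cm.sum(axis=0) - np.diag(cm)
        negatives = cm.sum() - cm.sum(axis=1)
        return fp / np.maximum(negatives, 1)

    def to_text(self) -> str:
        lines = [
            "# floorgait-eval v1",
            f"# folds={self.folds} repetitions={self.repetitions} seed={self.seed}",
            f"# modality={self.config.modality} pca={self.config.pca_components}",
            f"# classes: {' '.join(map(str, self.classes))}",
        ]
        for modality in self.fold_accuracies:
            lines.append(
                f"accuracy\t{modality}\t{100 * self.accuracy(modality):.2f}"
                f"\t+-{100 * self.accuracy_sd(modality):.2f}"
            )
        for modality, cm in self.confusion.items():
            lines.append(f"confusion\t{modality}")
            for row in cm:
                lines.append("\t".join(str(int(v)) for v in row))
        return "\n".join(lines) + "\n"


def _fit_and_score(
    Xw_train, Xs_train, y_train, Xw_eval, Xs_eval, config: EvalConfig, seed: int
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Fit both modality pipelines on the training part, score the eval part.

    Returns (walking scores, stepping scores); a modality excluded by the
    config comes back as None.  Label order of the score columns follows
    sorted(set(y_train)).
    """
    scores_w = scores_s = None
    if config.modality in ("walking", "both"):
        norm = fit_normalization(Xw_train)
        model_w = train_mlp(
            apply_normalization(Xw_train, norm),
            y_train,
            replace(config.walking_train, seed=seed),
        )
        scores_w = predict_scores_batch(model_w, apply_normalization(Xw_eval, norm))
    if config.modality in ("stepping", "both"):
        Xs_t, Xs_e = Xs_train, Xs_eval
        if config.pca_components is not None:
            proj = pca_fit(Xs_train, config.pca_components, seed=seed)
            Xs_t = pca_apply(proj, Xs_train)
            Xs_e = pca_apply(proj, Xs_eval)
        model_s = train_mlp(Xs_t, y_train, replace(config.stepping_train, seed=seed))
        scores_s = predict_scores_batch(model_s, Xs_e)
    return scores_w, scores_s


def cross_validate(
    Xw: np.ndarray,
    Xs: np.ndarray,
    labels,
    config: EvalConfig | None = None,
    folds: int = 10,
    repetitions: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Repeated stratified k-fold evaluation of both modalities and fusion.

    ``Xw``/``Xs`` are the raw walking and stepping feature matrices (one
    row per walk); all fitting (normalisation, PCA, MLP training, fusion
    weight selection) happens inside each training fold.  Deterministic
    given ``seed``.
    """
    config = config or EvalConfig()
    y_labels = np.asarray(list(labels))
    classes = sorted(set(y_labels.tolist()))
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[c] for c in y_labels])
    counts = np.bincount(y, minlength=len(classes))
    if counts.min() < folds:
        lacking = classes[int(np.argmin(counts))]
        raise ValueError(
            f"class {lacking!r} has {counts.min()} samples, fewer than {folds} folds"
        )
    Xw = np.atleast_2d(np.asarray(Xw, dtype=float))
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))

    modalities = {
        "walking": ["walking"],
        "stepping": ["stepping"],
        "both": ["walking", "stepping", "fused"],
    }[config.modality]
    fold_acc: dict[str, list[float]] = {m: [] for m in modalities}
    confusion = {m: np.zeros((len(classes), len(classes)), dtype=int) for m in modalities}

    for rep in range(repetitions):
        rep_ss = np.random.SeedSequence((seed, rep))
        split_seed, inner_seed, train_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in rep_ss.spawn(3)
        )
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=split_seed)
        for fold, (train_idx, test_idx) in enumerate(skf.split(Xw, y)):
            y_train = y_labels[train_idx]
            scores_w, scores_s = _fit_and_score(
                Xw[train_idx],
                Xs[train_idx],
                y_train,
                Xw[test_idx],
                Xs[test_idx],
                config,
                seed=train_seed + fold,
            )
            preds: dict[str, np.ndarray] = {}
            if scores_w is not None:
                preds["walking"] = scores_w.argmax(axis=1)
            if scores_s is not None:
                preds["stepping"] = scores_s.argmax(axis=1)
            if config.modality == "both":
                # Inner split of the training fold for weight selection.
                inner_train, inner_val = train_test_split(
                    np.arange(len(train_idx)),
                    test_size=config.inner_val_fraction,
                    random_state=inner_seed + fold,
                    stratify=y[train_idx],
                )
                vw, vs = _fit_and_score(
                    Xw[train_idx][inner_train],
                    Xs[train_idx][inner_train],
                    y_labels[train_idx][inner_train],
                    Xw[train_idx][inner_val],
                    Xs[train_idx][inner_val],
                    config,
                    seed=train_seed + fold,
                )
                weights = select_fusion_weights(
                    vw,
                    vs,
                    y[train_idx][inner_val],
                    default_weight_grid(config.weight_grid_step),
                )
                fused = fuse_scores(scores_w, scores_s, weights)
                preds["fused"] = fused.argmax(axis=1)
            for modality, pred in preds.items():
                fold_acc[modality].append(float((pred == y[test_idx]).mean()))
                np.add.at(confusion[modality], (y[test_idx], pred), 1)

    return EvalReport(
        classes=classes,
        folds=folds,
        repetitions=repetitions,
        seed=seed,
        fold_accuracies=fold_acc,
        confusion=confusion,
        config=config,
    )

# ---------------------------------------------------------------------------
# Deployable identifier: train once, identify single walks
# ---------------------------------------------------------------------------

@dataclass
class IdentifierBundle:
    """Everything needed to identify a new walk: both trained pipelines.

    Built by :func:`train_identifier`; fusion weights are selected on an
    inner validation split of the supplied training data.
    """

    classes: list
    normalization: NormalizationParams
    walking_model: MLPModel
    pca: PCAProjection | None
    stepping_model: MLPModel
    weights: FusionWeights
    config: EvalConfig


def train_identifier(
    Xw: np.ndarray,
    Xs: np.ndarray,
    labels,
    config: EvalConfig | None = None,
    seed: int = 0,
) -> IdentifierBundle:
    """Train both modality pipelines on a full enrolment set."""
    config = config or EvalConfig()
    y_labels = np.asarray(list(labels))
    classes = sorted(set(y_labels.tolist()))
    Xw = np.atleast_2d(np.asarray(Xw, dtype=float))
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))

    norm = fit_normalization(Xw)
    walking_model = train_mlp(
        apply_normalization(Xw, norm), y_labels, replace(config.walking_train, seed=seed)
    )
    proj = None
    Xs_in = Xs
    if config.pca_components is not None:
        proj = pca_fit(Xs, config.pca_components, seed=seed)
        Xs_in = pca_apply(proj, Xs)
    stepping_model = train_mlp(Xs_in, y_labels, replace(config.stepping_train, seed=seed))

    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[c] for c in y_labels])
    inner_train, inner_val = train_test_split(
        np.arange(len(y)),
        test_size=config.inner_val_fraction,
        random_state=seed % (2**31),
        stratify=y,
    )
    vw, vs = _fit_and_score(
        Xw[inner_train], Xs[inner_train], y_labels[inner_train],
        Xw[inner_val], Xs[inner_val], config, seed=seed,
    )
    weights = select_fusion_weights(
        vw, vs, y[inner_val], default_weight_grid(config.weight_grid_step)
    )
    return IdentifierBundle(
        classes=classes,
        normalization=norm,
        walking_model=walking_model,
        pca=proj,
        stepping_model=stepping_model,
        weights=weights,
        config=config,
    )


def identify_walk(
    bundle: IdentifierBundle, wvec: np.ndarray, svec: np.ndarray
):
    """Identify one walk from its raw feature vectors.

    Returns ``(user_label, fused_scores)``.
    """
    wn = apply_normalization(np.atleast_2d(wvec), bundle.normalization)
    sw = predict_scores_batch(bundle.walking_model, wn)[0]
    sv = np.atleast_2d(svec)
    if bundle.pca is not None:
        sv = pca_apply(bundle.pca, sv)
    ss = predict_scores_batch(bundle.stepping_model, sv)[0]
    fused = fuse_scores(sw, ss, bundle.weights)
    return bundle.classes[identify(fused)], fused


def _mlp_to_dict(model: MLPModel) -> dict:
    return {
        "classes": model.classes,
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "W2": model.W2.tolist(),
        "b2": model.b2.tolist(),
        "hidden_nodes": model.config.hidden_nodes,
        "max_epochs": model.config.max_epochs,
        "mse_goal": model.config.mse_goal,
        "seed": model.config.seed,
        "epochs_run": model.epochs_run,
        "final_mse": model.final_mse,
    }


def _mlp_from_dict(d: dict) -> MLPModel:
    return MLPModel(
        classes=d["classes"],
        W1=np.asarray(d["W1"]),
        b1=np.asarray(d["b1"]),
        W2=np.asarray(d["W2"]),
        b2=np.asarray(d["b2"]),
        config=TrainConfig(
            hidden_nodes=d["hidden_nodes"],
            max_epochs=d["max_epochs"],
            mse_goal=d["mse_goal"],
            seed=d["seed"],
        ),
        epochs_run=d["epochs_run"],
        final_mse=d["final_mse"],
    )


def save_identifier(bundle: IdentifierBundle, path) -> None:
    """Serialize a trained identifier to versioned JSON text."""
    payload = {
        "format": "floorgait-identifier",
        "version": 1,
        "classes": bundle.classes,
        "normalization": {
            "mins": bundle.normalization.mins.tolist(),
            "maxs": bundle.normalization.maxs.tolist(),
        },
        "walking_model": _mlp_to_dict(bundle.walking_model),
        "pca": None
        if bundle.pca is None
        else {
            "mean": bundle.pca.mean.tolist(),
            "components": bundle.pca.components.tolist(),
            "explained_variance": bundle.pca.explained_variance.tolist(),
        },
        "stepping_model": _mlp_to_dict(bundle.stepping_model),
        "weights": {
            "w_walking": bundle.weights.w_walking,
            "w_stepping": bundle.weights.w_stepping,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_identifier(path) -> IdentifierBundle:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != "floorgait-identifier" or payload.get("version") != 1:
        raise ValueError(f"{path}: not a floorgait identifier file")
    pca = None
    if payload["pca"] is not None:
        pca = PCAProjection(
            mean=np.asarray(payload["pca"]["mean"]),
            components=np.asarray(payload["pca"]["components"]),
            explained_variance=np.asarray(payload["pca"]["explained_variance"]),
        )
    return IdentifierBundle(
        classes=payload["classes"],
        normalization=NormalizationParams(
            mins=np.asarray(payload["normalization"]["mins"]),
            maxs=np.asarray(payload["normalization"]["maxs"]),
        ),
        walking_model=_mlp_from_dict(payload["walking_model"]),
        pca=pca,
        stepping_model=_mlp_from_dict(payload["stepping_model"]),
        weights=FusionWeights(**payload["weights"]),
        config=EvalConfig(),
    )
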