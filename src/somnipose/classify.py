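"""Posture classifiers: one-against-all SVM with RBF kernel, and random forest.

The one-against-all (OAA) strategy builds one soft-margin binary SVM per
posture class, each trained on ±1 relabeled data. Prediction tallies votes
literally: a binary model whose decision sign is "+" adds one vote to its
own class; a "−" outcome adds one vote to every *other* class. The class
with the most votes wins; ties go to the earliest class in the fixed order.

The binary dual problem

    max_λ  Σ λ_i − ½ Σ_ij λ_i λ_j ŷ_i ŷ_j K(x_i, x_j)
    s.t.   Σ λ_i ŷ_i = 0,   0 ≤ λ_i ≤ C

with the RBF kernel K(a, b) = exp(−γ‖a−b‖²) is delegated to libsvm's
sequential-minimal-optimization solver (via scikit-learn); everything
around it — relabeling, per-class assembly, the kernel-expansion decision
rule, vote tallying — is implemented here, and the stored dual solution is
evaluated natively at prediction time.

The random forest is a bootstrap ensemble of Gini decision trees with
random feature subsets (scikit-learn trees); prediction is a strict
per-tree majority vote with the same fixed-order tie-break. The number of
trees is selected by a seeded 2/3–1/3 split, training forests with 1..50
trees and keeping the count with the best validation accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from .postures import CLASS_INDEX, CLASS_ORDER, PostureLabel
from .wrist_features import FeatureMatrix, FeatureVector, LabeledDataset

logger = logging.getLogger(__name__)

DEFAULT_C = 1.0
DEFAULT_MAX_TREES = 50
_ARCHIVE_FORMAT_VERSION = 1


class TrainingError(ValueError):
    """A classifier could not be trained on the given data."""


def oaa_relabel(
    labels: Sequence[PostureLabel], target: PostureLabel
) -> np.ndarray:
    """Map a label sequence to ±1: +1 where the label equals ``target``."""
    return np.array([1 if lab is target else -1 for lab in labels], dtype=np.int64)


def rbf_kernel(a: np.ndarray, b: np.ndarray, gamma: float) -> np.ndarray:
    """Radial basis similarity exp(−γ‖a−b‖²).

    ``a`` may be a single vector or a stack of vectors (rows); the squared
    Euclidean distance is taken row-wise against ``b``.
    """
    if gamma < 0:
        raise ValueError(f"gamma must be non-negative, got {gamma}")
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.asarray(b, dtype=np.float64).reshape(-1)
    d2 = np.sum((a - b) ** 2, axis=1)
    out = np.exp(-gamma * d2)
    return out if out.size > 1 else float(out[0])


def resolve_gamma(X: np.ndarray, gamma: float | None) -> float:
    """Default RBF width: 1 / (n_features · var(X)), the "scale" convention."""
    if gamma is not None:
        return float(gamma)
    var = float(X.var())
    if var == 0.0:
        var = 1.0
    return 1.0 / (X.shape[1] * var)


@dataclass
class BinarySvmModel:
    """Dual solution of one soft-margin RBF SVM separating one class.

    ``dual_coefs`` holds λ_i·ŷ_i for each support vector, so the decision
    value at z is Σ dual_coefs_i · K(sv_i, z) + bias.
    """

    support_vectors: np.ndarray  # (m, 3)
    dual_coefs: np.ndarray  # (m,)
    bias: float
    gamma: float
    C: float
    target_class: PostureLabel

    def decision_value(self, z: np.ndarray | FeatureVector) -> float:
        if isinstance(z, FeatureVector):
            z = z.as_array
        k = rbf_kernel(self.support_vectors, z, self.gamma)
        return float(np.dot(self.dual_coefs, np.atleast_1d(k)) + self.bias)


def svm_decision(model: BinarySvmModel, z: np.ndarray | FeatureVector) -> int:
    """Sign of the kernel expansion plus bias; sign(0) = +1 by convention."""
    return 1 if model.decision_value(z) >= 0.0 else -1


def train_binary_svm(
    X: np.ndarray | FeatureMatrix,
    y: Sequence[int] | np.ndarray,
    C: float = DEFAULT_C,
    gamma: float | None = None,
    target_class: PostureLabel | None = None,
    max_iter: int = 1_000_000,
    tol: float = 1e-8,
) -> BinarySvmModel:
    """Solve the soft-margin dual for one ±1 problem.

    The dual solution satisfies the box constraints 0 ≤ λ_i ≤ C and the
    equality constraint Σ λ_i ŷ_i = 0 within solver tolerance.

    Raises
    ------
    TrainingError
        If only one class is present, or the solver hits its iteration cap.
    """
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if C <= 0:
        raise ValueError(f"penalty C must be positive, got {C}")
    classes = np.unique(y)
    if not np.array_equal(np.sort(classes), [-1, 1]):
        raise TrainingError(
            f"binary SVM needs both +1 and -1 labels, got classes {classes.tolist()}"
        )
    g = resolve_gamma(X, gamma)
    svc = SVC(C=C, kernel="rbf", gamma=g, tol=tol, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            svc.fit(X, y)
        except ConvergenceWarning as exc:
            raise TrainingError(
                f"SMO did not converge within {max_iter} iterations "
                f"(n={len(y)}, C={C}, gamma={g}): {exc}"
            ) from exc
    # libsvm orders decision_function as (smaller class label) vs (larger);
    # with classes [-1, +1] dual_coef_ already carries λ_i·ŷ_i and
    # intercept_ the bias of the "+1 is positive" decision.
    return BinarySvmModel(
        support_vectors=np.asarray(svc.support_vectors_, dtype=np.float64),
        dual_coefs=np.asarray(svc.dual_coef_[0], dtype=np.float64),
        bias=float(svc.intercept_[0]),
        gamma=g,
        C=C,
        target_class=target_class if target_class is not None else PostureLabel.STAND,
    )


@dataclass
class OaaSvmModel:
    """One binary SVM per class present in the training data."""

    models: dict[PostureLabel, BinarySvmModel]

    @property
    def classes(self) -> list[PostureLabel]:
        return [c for c in CLASS_ORDER if c in self.models]


def train_oaa_svm(
    dataset: LabeledDataset,
    C: float = DEFAULT_C,
    gamma: float | None = None,
) -> OaaSvmModel:
    """Train one binary model per distinct label via ±1 relabeling.

    Raises
    ------
    TrainingError
        If fewer than two classes are present, or a per-class subproblem
        fails (the error names the class).
    """
    present = [c for c in CLASS_ORDER if c in set(dataset.labels)]
    if len(present) < 2:
        raise TrainingError(f"OAA-SVM needs >= 2 classes, got {len(present)}")
    g = resolve_gamma(dataset.X, gamma)
    models: dict[PostureLabel, BinarySvmModel] = {}
    for target in present:
        try:
            models[target] = train_binary_svm(
                dataset.X,
                oaa_relabel(dataset.labels, target),
                C=C,
                gamma=g,
                target_class=target,
            )
        except (TrainingError, ValueError) as exc:
            raise TrainingError(f"binary subproblem for class {target} failed: {exc}") from exc
    return OaaSvmModel(models=models)


def predict_oaa(
    model: OaaSvmModel,
    z: np.ndarray | FeatureVector,
    use_margin: bool = False,
) -> PostureLabel:
    """Classify one feature vector by literal vote tallying.

    Each binary model votes: a "+" decision adds one vote to its own
    class; a "−" decision adds one vote to every other class. The class
    with the most votes wins; ties are broken by the fixed class order and
    logged. With ``use_margin=True`` the argmax of the raw decision values
    is returned instead of the vote tally.
    """
    classes = model.classes
    if use_margin:
        values = [model.models[c].decision_value(z) for c in classes]
        return classes[int(np.argmax(values))]
    votes = {c: 0 for c in classes}
    for c in classes:
        if svm_decision(model.models[c], z) == 1:
            votes[c] += 1
        else:
            for other in classes:
                if other is not c:
                    votes[other] += 1
    best = max(votes.values())
    winners = [c for c in classes if votes[c] == best]
    if len(winners) > 1:
        logger.warning(
            "OAA vote tie among %s; fixed class order picks %s",
            [str(c) for c in winners], winners[0],
        )
    return winners[0]


def predict_oaa_batch(
    model: OaaSvmModel, X: np.ndarray, use_margin: bool = False
) -> list[PostureLabel]:
    return [predict_oaa(model, x, use_margin=use_margin) for x in np.atleast_2d(X)]


@dataclass
class RfModel:
    """Seeded bootstrap ensemble of decision trees."""

    n_trees: int
    forest: RandomForestClassifier
    seed: int

    @property
    def classes(self) -> list[PostureLabel]:
        return [PostureLabel.from_string(s) for s in self.forest.classes_]


def train_rf(dataset: LabeledDataset, n_trees: int, seed: int) -> RfModel:
    """Train a random forest: bootstrap resampling, random feature subsets,
    Gini splits. Fully reproducible for a given seed."""
    if n_trees < 1:
        raise ValueError(f"n_trees must be >= 1, got {n_trees}")
    if len(dataset) == 0:
        raise TrainingError("empty dataset")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
    )
    forest.fit(dataset.X, dataset.y)
    return RfModel(n_trees=n_trees, forest=forest, seed=seed)


def predict_rf(model: RfModel, z: np.ndarray | FeatureVector) -> PostureLabel:
    """Strict per-tree majority vote; ties go to the fixed class order."""
    return predict_rf_batch(model, np.atleast_2d(
        z.as_array if isinstance(z, FeatureVector) else z))[0]


def predict_rf_batch(model: RfModel, X: np.ndarray) -> list[PostureLabel]:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    classes = model.classes
    # trees predict encoded class indices into forest.classes_
    counts = np.zeros((X.shape[0], len(classes)), dtype=np.int64)
    for tree in model.forest.estimators_:
        pred = tree.predict(X).astype(np.int64)
        for row, k in enumerate(pred):
            counts[row, k] += 1
    out: list[PostureLabel] = []
    # resolve ties by fixed class order, not forest class order
    priority = np.array([CLASS_INDEX[c] for c in classes])
    for row in range(X.shape[0]):
        best = counts[row].max()
        winner_idx = [k for k in range(len(classes)) if counts[row, k] == best]
        if len(winner_idx) > 1:
            logger.warning("RF vote tie among %s; fixed class order applied",
                           [str(classes[k]) for k in winner_idx])
        k = min(winner_idx, key=lambda k: priority[k])
        out.append(classes[k])
    return out


def split_dataset(
    dataset: LabeledDataset, train_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded random split into train/validation subsets."""
    n = len(dataset)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    return _subset(dataset, perm[:n_train]), _subset(dataset, perm[n_train:])


def _subset(dataset: LabeledDataset, rows: np.ndarray) -> LabeledDataset:
    return LabeledDataset(
        features=FeatureMatrix(
            frame_indices=dataset.features.frame_indices[rows],
            values=dataset.features.values[rows],
        ),
        labels=[dataset.labels[int(r)] for r in rows],
    )


def tree_count_curve(
    dataset: LabeledDataset,
    max_trees: int = DEFAULT_MAX_TREES,
    train_fraction: float = 2 / 3,
    seed: int = 0,
) -> np.ndarray:
    """Validation accuracy of forests with 1..max_trees trees on one split.

    The split is drawn once (seeded) with the given training fraction; each
    candidate forest is trained with the same derived seed so the curve is
    reproducible.

    Raises
    ------
    TrainingError
        If the validation split does not contain every class of the dataset.
    """
    train, val = split_dataset(dataset, train_fraction, seed)
    if set(val.labels) != set(dataset.labels):
        missing = set(dataset.labels) - set(val.labels)
        raise TrainingError(
            f"validation split is missing class(es): {[str(c) for c in missing]}"
        )
    accs = np.empty(max_trees)
    truth = val.y
    for n in range(1, max_trees + 1):
        model = train_rf(train, n_trees=n, seed=seed)
        pred = np.array([lab.value for lab in predict_rf_batch(model, val.X)])
        accs[n - 1] = float(np.mean(pred == truth))
    return accs


def select_tree_count(
    dataset: LabeledDataset,
    max_trees: int = DEFAULT_MAX_TREES,
    train_fraction: float = 2 / 3,
    seed: int = 0,
) -> int:
    """Pick the tree count in [1, max_trees] with the best validation
    accuracy; ties go to the smallest count."""
    accs = tree_count_curve(dataset, max_trees, train_fraction, seed)
    return int(np.argmax(accs)) + 1


def save_model(model: OaaSvmModel | RfModel, path: str | Path) -> None:
    """Persist a trained model; ``load_model`` + predict is bit-exact."""
    if isinstance(model, OaaSvmModel):
        payload = {"format_version": _ARCHIVE_FORMAT_VERSION, "kind": "oaa_svm",
                   "class_order": [c.value for c in CLASS_ORDER], "model": model}
    elif isinstance(model, RfModel):
        payload = {"format_version": _ARCHIVE_FORMAT_VERSION, "kind": "rf",
                   "class_order": [c.value for c in CLASS_ORDER], "model": model}
    else:
        raise TypeError(f"cannot persist {type(model).__name__}")
    joblib.dump(payload, path)


def load_model(path: str | Path) -> OaaSvmModel | RfModel:
    payload = joblib.load(path)
    if payload.get("format_version") != _ARCHIVE_FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version: {payload.get('format_version')}")
    return payload["model"]


def predict_batch(model: OaaSvmModel | RfModel, X: np.ndarray) -> list[PostureLabel]:
    """Dispatch batch prediction on the model kind."""
    if isinstance(model, OaaSvmModel):
        return predict_oaa_batch(model, X)
    return predict_rf_batch(model, X)
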