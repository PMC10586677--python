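"""Two-level subgroup classifiers.

Level-0 (L0) classifiers — a radial-kernel SVM, a random forest and a
feed-forward neural network — are trained per feature set with
hyperparameters tuned by repeated stratified cross-validation. Their class
probabilities are then combined two ways:

* linear decision-level fusion  P_F = a*P_SVM + b*P_RF + g*P_FFNN with the
  weights scanned on a 0.01 grid under a + b + g = 1, picking the triple
  with the best accuracy on a selection set the L0s never trained on;
* nonlinear stacking — logistic regression or a small FFNN trained on the
  concatenated L0 probability vectors (3K inputs for K classes).

Two protocols are supported: without holdout (L0 and L1 share the training
samples) and with holdout (the training set is split 60/40, L0s on the 60%,
L1 on the remaining 40%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

L0_KINDS = ("SVM", "RF", "FFNN")
FFNN_LEARNING_RATES = (1e-3, 1e-4, 1e-5)


# ---------------------------------------------------------------- splits

@dataclass
class SplitPlan:
    """Train/validation/test partition settings.

    10% of samples are held out for testing; 10% of the remainder forms the
    validation set. Under `holdout`, the training set is further split
    60/40 into L0-train and L1-train. All splits stratify by label.
    """

    test_frac: float = 0.10
    val_frac: float = 0.10
    holdout: bool = False
    l0_frac: float = 0.60
    stratify: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.test_frac, self.val_frac, self.l0_frac):
            if not 0.0 < f < 1.0:
                raise ValueError("split fractions must lie in (0, 1)")


@dataclass
class Splits:
    """Disjoint index sets over the original sample axis."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    l0_train: np.ndarray
    l1_train: np.ndarray


def make_splits(labels: np.ndarray, plan: SplitPlan) -> Splits:
    """Stratified test / validation / training partition per the plan."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 3:
        small = classes[np.argmin(counts)]
        raise ValueError(f"class {small} has fewer than 3 samples; cannot stratify")
    idx = np.arange(len(labels))
    strat = labels if plan.stratify else None
    rest, test = train_test_split(
        idx, test_size=plan.test_frac, stratify=strat, random_state=plan.seed
    )
    strat_rest = labels[rest] if plan.stratify else None
    train, val = train_test_split(
        rest, test_size=plan.val_frac, stratify=strat_rest, random_state=plan.seed + 1
    )
    if plan.holdout:
        strat_train = labels[train] if plan.stratify else None
        l0_train, l1_train = train_test_split(
            train, test_size=1.0 - plan.l0_frac, stratify=strat_train,
            random_state=plan.seed + 2,
        )
    else:
        l0_train, l1_train = train, train
    return Splits(train=train, val=val, test=test, l0_train=l0_train, l1_train=l1_train)


# ---------------------------------------------------------------- L0 models

@dataclass
class L0Classifier:
    """A tuned probabilistic base classifier."""

    kind: str
    model: object
    best_params: dict
    classes: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(X, dtype=float))


def _hidden_width(n_in: int, n_out: int, cap: int = 256) -> int:
    return int(min(max(n_out, (n_in + n_out) // 2), cap))


def default_grids(n_features: int) -> dict[str, dict]:
    """Hyperparameter grids per L0 kind (desk-scale but standard)."""
    return {
        "SVM": {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.01]},
        "RF": {"n_estimators": [250, 500], "max_features": ["sqrt", 0.333]},
        "FFNN": {"learning_rate_init": list(FFNN_LEARNING_RATES)},
    }


def train_l0(
    X: np.ndarray,
    y: np.ndarray,
    model_kind: str,
    seed: int = 0,
    cv_folds: int = 5,
    cv_repeats: int = 10,
    param_grid: dict | None = None,
) -> L0Classifier:
    """Tune and fit one base classifier.

    Hyperparameters are chosen by `cv_folds`-fold cross-validation repeated
    `cv_repeats` times on mean accuracy, then the model is refit on the full
    training set. The SVM uses a radial kernel with probability outputs;
    the FFNN picks its learning rate from {1e-3, 1e-4, 1e-5}.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    if model_kind not in L0_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    grid = param_grid if param_grid is not None else default_grids(X.shape[1])[model_kind]

    if model_kind == "SVM":
        base = SVC(kernel="rbf", probability=True, random_state=seed)
    elif model_kind == "RF":
        base = RandomForestClassifier(random_state=seed)
    else:
        # training-loss convergence; a validation-based stop aborts on the
        # flat accuracy plateau small networks show in their first epochs
        base = MLPClassifier(
            hidden_layer_sizes=(_hidden_width(X.shape[1], len(np.unique(y))),),
            max_iter=800,
            random_state=seed,
        )
    cv = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed)
    search = GridSearchCV(base, grid, scoring="accuracy", cv=cv, refit=True, n_jobs=None)
    search.fit(X, y)
    return L0Classifier(
        kind=model_kind,
        model=search.best_estimator_,
        best_params=dict(search.best_params_),
        classes=np.asarray(search.best_estimator_.classes_),
    )


# ---------------------------------------------------------------- fusion

@dataclass
class StackedProbabilities:
    """Aligned class-probability matrices from the three L0 classifiers."""

    sample_ids: list[str]
    p_svm: np.ndarray
    p_rf: np.ndarray
    p_ffnn: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.p_svm, self.p_rf, self.p_ffnn)}
        if len(shapes) != 1:
            raise ValueError("probability matrices differ in shape")
        for m in (self.p_svm, self.p_rf, self.p_ffnn):
            if np.any(m < -1e-9) or np.any(m > 1 + 1e-9):
                raise ValueError("probabilities outside [0, 1]")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("probability rows must sum to 1")

    @property
    def n(self) -> int:
        return self.p_svm.shape[0]

    @property
    def n_classes(self) -> int:
        return self.p_svm.shape[1]

    def as_tensor(self) -> np.ndarray:
        return np.stack([self.p_svm, self.p_rf, self.p_ffnn])

    def stack(self) -> np.ndarray:
        """Concatenated (n, 3K) input for the nonlinear stackers."""
        return np.hstack([self.p_svm, self.p_rf, self.p_ffnn])


@dataclass
class FusionWeights:
    """Convex weights (alpha, beta, gamma) on the hundredths grid."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        vals = (self.alpha, self.beta, self.gamma)
        if any(v < -1e-12 for v in vals):
            raise ValueError("weights must be non-negative")
        ints = [round(v * 100) for v in vals]
        if any(abs(v * 100 - i) > 1e-6 for v, i in zip(vals, ints)):
            raise ValueError("weights must lie on the 0.01 grid")
        if sum(ints) != 100:
            raise ValueError("weights must sum to 1 on the hundredths grid")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])


def fused_predict(
    probs: StackedProbabilities, w: FusionWeights
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted fusion P_F = a*P_SVM + b*P_RF + g*P_FFNN and argmax labels.

    Ties in the argmax go to the lowest class index.
    """
    p_f = w.alpha * probs.p_svm + w.beta * probs.p_rf + w.gamma * probs.p_ffnn
    labels = probs.classes[np.argmax(p_f, axis=1)]
    return p_f, labels


def weight_grid(step: float = 0.01) -> np.ndarray:
    """All (alpha, beta, gamma) triples on the step grid summing to 1,
    in ascending lexicographic order (5151 triples at step 0.01)."""
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1 exactly")
    triples = [
        (a / n, b / n, (n - a - b) / n)
        for a in range(n + 1)
        for b in range(n + 1 - a)
    ]
    return np.asarray(triples)


def linear_fusion_search(
    probs: StackedProbabilities,
    y: np.ndarray,
    step: float = 0.01,
    chunk: int = 512,
) -> tuple[FusionWeights, float]:
    """Exhaustive grid search of the fusion weights on a selection set.

    Evaluates fused accuracy for every grid triple and returns the
    maximizer (first in lexicographic order on ties) and its accuracy.
    """
    y = np.asarray(y)
    grid = weight_grid(step)
    tensor = probs.as_tensor()  # (3, n, K)
    y_col = np.searchsorted(probs.classes, y)
    best_acc, best_idx = -1.0, 0
    for start in range(0, len(grid), chunk):
        w_block = grid[start : start + chunk]
        fused = np.tensordot(w_block, tensor, axes=([1], [0]))  # (m, n, K)
        preds = fused.argmax(axis=2)
        accs = (preds == y_col[None, :]).mean(axis=1)
        i = int(np.argmax(accs))
        if accs[i] > best_acc:
            best_acc = float(accs[i])
            best_idx = start + i
    a, b, g = grid[best_idx]
    return FusionWeights(round(a, 2), round(b, 2), round(g, 2)), best_acc


@dataclass
class L1Stacker:
    """A nonlinear decision-level fusion model over stacked L0 probabilities."""

    kind: str
    model: object
    classes: np.ndarray

    def predict_proba(self, probs: StackedProbabilities) -> np.ndarray:
        return self.model.predict_proba(probs.stack())

    def predict(self, probs: StackedProbabilities) -> np.ndarray:
        return self.model.predict(probs.stack())


def train_nonlinear_stacker(
    probs: StackedProbabilities, y: np.ndarray, kind: str = "LR", seed: int = 0
) -> L1Stacker:
    """Train a logistic-regression or FFNN meta-classifier on L0 probabilities."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    X = probs.stack()
    if kind == "LR":
        model = LogisticRegression(max_iter=2000, random_state=seed)
    elif kind == "FFNN":
        model = MLPClassifier(
            hidden_layer_sizes=(_hidden_width(X.shape[1], probs.n_classes, cap=64),),
            max_iter=800,
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown stacker kind {kind!r}")
    model.fit(X, y)
    return L1Stacker(kind=kind, model=model, classes=np.asarray(model.classes_))


# ---------------------------------------------------------------- feature fusion

def feature_level_fuse(
    layers: dict[str, pd.DataFrame], base: str = "F3", other: str = "F4"
) -> pd.DataFrame:
    """Column-concatenate the selected features of `base` and `other`.

    Both frames must be sample-indexed identically; fusing a datatype with
    itself is rejected.
    """
    if base == other:
        raise ValueError("cannot fuse a datatype with itself")
    left, right = layers[base], layers[other]
    if list(left.index) != list(right.index):
        raise ValueError("sample sets differ between the fused layers")
    return pd.concat([left, right], axis=1)


def align_features(
    new_X: pd.DataFrame,
    expected: list[str],
    fill_values: np.ndarray | None = None,
    min_present: float = 0.9,
) -> np.ndarray:
    """Reorder a new-sample frame to the training feature order.

    Features absent from `new_X` are filled from `fill_values` (training
    means); fewer than `min_present` of the expected features present is an
    error.
    """
    present = [f for f in expected if f in new_X.columns]
    if len(present) < min_present * len(expected):
        raise ValueError(
            f"only {len(present)}/{len(expected)} expected features present "
            f"(need at least {min_present:.0%})"
        )
    out = np.empty((len(new_X), len(expected)))
    for j, f in enumerate(expected):
        if f in new_X.columns:
            out[:, j] = new_X[f].to_numpy(dtype=float)
        else:
            if fill_values is None:
                raise ValueError(f"feature {f!r} absent and no fill values given")
            out[:, j] = fill_values[j]
    return out
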