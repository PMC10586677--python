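"""Model/Results surfaces tying the pipeline stages together.

Two fit-able models, in the estimator-returns-results idiom:

* :class:`SubgroupDiscovery` — from a stacked multi-omics matrix, learns a
  low-dimensional representation (autoencoder grid or PCA), scans K with
  consensus K-means and picks the K maximising RCSI. `fit` returns a
  :class:`SubgroupDiscoveryResults` holding the latent matrix, the per-K
  stability table, the final labels and a `summary()`.

* :class:`SubgroupClassifier` — from a feature matrix and subgroup labels,
  trains the L0 classifiers (SVM / RF / FFNN), the linear decision-level
  fusion (0.01-grid weight search) and the nonlinear stackers (LR / FFNN),
  under the with- or without-holdout protocol. `fit` returns a
  :class:`SubgroupClassifierResults` with test accuracies, the fusion
  weights and a `predict()` for new samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify, consensus, integration
from .characterize import logrank_test
from .datatypes import LatentRepresentation, MultiOmicsMatrix, SurvivalTable


# ================================================================ discovery

class SubgroupDiscovery:
    """Discover molecular subgroups from a stacked multi-omics matrix.

    Parameters
    ----------
    data : MultiOmicsMatrix
        Imputed, stacked sample x feature matrix (raw scale; `fit`
        normalizes internally unless ``normalize=False``).
    reducer : {"ae", "pca", "none"}
        Dimensionality reduction before clustering.
    architectures : list of AEArchitecture, optional
        Autoencoder candidates; the least train/validation-gap fit is kept.
        Defaults to a single (512, 100) architecture.
    k_range : iterable of int
        Candidate cluster numbers (default 2..20).
    reps, subsample, B, ref_reps, n_init, u1, u2
        Consensus and PAC/RCSI settings (see :mod:`omicstack.consensus`).
    """

    def __init__(
        self,
        data: MultiOmicsMatrix,
        reducer: str = "ae",
        architectures=None,
        variance_fraction: float = 0.99,
        k_range=range(2, 21),
        reps: int = 1000,
        subsample: float = 0.8,
        B: int = 25,
        ref_reps: int | None = None,
        n_init: int = 10,
        u1: float = 0.1,
        u2: float = 0.9,
        normalize: bool | str = "auto",
    ) -> None:
        if reducer not in ("ae", "pca", "none"):
            raise ValueError("reducer must be 'ae', 'pca' or 'none'")
        self.data = data
        self.reducer = reducer
        self.architectures = architectures
        self.variance_fraction = variance_fraction
        self.k_range = list(k_range)
        self.reps = reps
        self.subsample = subsample
        self.B = B
        self.ref_reps = ref_reps
        self.n_init = n_init
        self.u1 = u1
        self.u2 = u2
        self.normalize = normalize

    def fit(self, seed: int = 0) -> "SubgroupDiscoveryResults":
        # the autoencoder needs z-scaled input to train on mixed-scale
        # concatenations; the PCA and no-reduction branches take the stacked
        # values as-is (pca_reduce centers internally)
        do_norm = self.reducer == "ae" if self.normalize == "auto" else bool(self.normalize)
        X = integration.normalize(self.data) if do_norm else self.data
        trained = None
        if self.reducer == "ae":
            archs = self.architectures or [
                integration.AEArchitecture(encoder_widths=(512, 100), seed=seed)
            ]
            candidates = []
            for i, arch in enumerate(archs):
                arch.seed = seed + i
                candidates.append(integration.train_autoencoder(X, arch))
            trained = integration.select_autoencoder(candidates)
            latent = integration.encode(X, trained)
        elif self.reducer == "pca":
            latent = integration.pca_reduce(X, self.variance_fraction)
        else:
            latent = LatentRepresentation(list(X.sample_ids), X.values, source="F_RAW")

        best_k, per_k = consensus.select_k(
            latent,
            k_range=self.k_range,
            reps=self.reps,
            subsample=self.subsample,
            B=self.B,
            seed=seed,
            ref_reps=self.ref_reps,
            n_init=self.n_init,
            u1=self.u1,
            u2=self.u2,
        )
        return SubgroupDiscoveryResults(
            model=self, latent=latent, best_k=best_k, per_k=per_k, trained_ae=trained,
            seed=seed,
        )


@dataclass
class SubgroupDiscoveryResults:
    """Fitted subgroup discovery: latent space, stability scan, labels."""

    model: SubgroupDiscovery
    latent: LatentRepresentation
    best_k: int
    per_k: list[consensus.RCSIResult]
    trained_ae: integration.TrainedAE | None
    seed: int

    @property
    def labels(self) -> np.ndarray:
        """Cluster labels at the selected K."""
        return self.result_at(self.best_k).consensus.labels

    def result_at(self, k: int) -> consensus.RCSIResult:
        for r in self.per_k:
            if r.K == k:
                return r
        raise KeyError(f"K={k} was not scanned")

    @property
    def silhouette(self) -> float:
        return self.result_at(self.best_k).silhouette

    def rcsi_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": [r.K for r in self.per_k],
                "pac": [r.p_real for r in self.per_k],
                "mean_ref_pac": [float(np.mean(r.ref_pacs)) for r in self.per_k],
                "rcsi": [r.rcsi for r in self.per_k],
                "silhouette": [r.silhouette for r in self.per_k],
            }
        )

    def logrank(self, survival: SurvivalTable):
        """Log-rank test of the discovered subgroups on a survival endpoint."""
        return logrank_test(survival.with_clusters(self.labels))

    def summary(self) -> str:
        lines = [
            "Subgroup discovery results",
            "==========================",
            f"samples: {self.latent.n}    latent dim: {self.latent.d} "
            f"({self.latent.source})",
            f"reducer: {self.model.reducer}    consensus reps: {self.model.reps} "
            f"at {self.model.subsample:.0%} subsample, B={self.model.B}",
            f"selected K: {self.best_k}    "
            f"RCSI: {self.result_at(self.best_k).rcsi:.3f}    "
            f"silhouette: {self.silhouette:.3f}",
            "",
            self.rcsi_table().to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        if self.trained_ae is not None:
            a = self.trained_ae
            lines.insert(
                4,
                f"autoencoder: widths {a.architecture.encoder_widths}, "
                f"train loss {a.train_loss:.4f}, val loss {a.val_loss:.4f}, "
                f"epochs {a.n_epochs}",
            )
        return "\n".join(lines)


# ================================================================ classification

L1_KINDS = ("linear", "LR", "FFNN")


class SubgroupClassifier:
    """Two-level subgroup classifier for one feature set.

    Parameters
    ----------
    features : DataFrame
        Sample x feature matrix (sample-ID index, feature-ID columns) —
        typically the differentially expressed features of one datatype, a
        feature-level fusion, or the autoencoder latent matrix.
    labels : array of int
        Subgroup label per sample (aligned with `features` rows).
    plan : SplitPlan, optional
        Split protocol; defaults to the no-holdout 90/10 protocol.
    cv_folds, cv_repeats : int
        Repeated stratified CV settings for L0 hyperparameter tuning.
    param_grids : dict, optional
        Overrides for the per-kind hyperparameter grids.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: np.ndarray,
        plan: classify.SplitPlan | None = None,
        cv_folds: int = 5,
        cv_repeats: int = 10,
        param_grids: dict | None = None,
    ) -> None:
        self.features = features
        self.labels = np.asarray(labels)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels differ in length")
        self.plan = plan or classify.SplitPlan()
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.param_grids = param_grids or {}

    def fit(self, seed: int | None = None) -> "SubgroupClassifierResults":
        seed = self.plan.seed if seed is None else seed
        self.plan.seed = seed
        X = self.features.to_numpy(dtype=float)
        y = self.labels
        splits = classify.make_splits(y, self.plan)

        l0: dict[str, classify.L0Classifier] = {}
        for kind in classify.L0_KINDS:
            l0[kind] = classify.train_l0(
                X[splits.l0_train],
                y[splits.l0_train],
                kind,
                seed=seed,
                cv_folds=self.cv_folds,
                cv_repeats=self.cv_repeats,
                param_grid=self.param_grids.get(kind),
            )

        def stacked(idx: np.ndarray) -> classify.StackedProbabilities:
            ids = [str(self.features.index[i]) for i in idx]
            return classify.StackedProbabilities(
                sample_ids=ids,
                p_svm=l0["SVM"].predict_proba(X[idx]),
                p_rf=l0["RF"].predict_proba(X[idx]),
                p_ffnn=l0["FFNN"].predict_proba(X[idx]),
                classes=l0["SVM"].classes,
            )

        # weight selection on data the L0s never trained on:
        # validation split (no holdout) or the L1 partition (holdout)
        sel_idx = splits.l1_train if self.plan.holdout else splits.val
        weights, sel_acc = classify.linear_fusion_search(stacked(sel_idx), y[sel_idx])

        stack_train = stacked(splits.l1_train)
        stackers = {
            kind: classify.train_nonlinear_stacker(
                stack_train, y[splits.l1_train], kind=kind, seed=seed
            )
            for kind in ("LR", "FFNN")
        }

        # test-set evaluation
        test_probs = stacked(splits.test)
        y_test = y[splits.test]
        accuracies: dict[str, float] = {}
        for kind, clf in l0.items():
            accuracies[kind] = float((clf.predict(X[splits.test]) == y_test).mean())
        _, fused_labels = classify.fused_predict(test_probs, weights)
        accuracies["linear"] = float((fused_labels == y_test).mean())
        for kind, st in stackers.items():
            key = "LR" if kind == "LR" else "FFNN_stack"
            accuracies[key] = float((st.predict(test_probs) == y_test).mean())

        return SubgroupClassifierResults(
            model=self,
            splits=splits,
            l0=l0,
            weights=weights,
            selection_accuracy=sel_acc,
            stackers=stackers,
            accuracies=accuracies,
            feature_ids=[str(c) for c in self.features.columns],
            feature_means=X[splits.train].mean(axis=0),
            seed=seed,
        )


@dataclass
class SubgroupClassifierResults:
    """Fitted two-level classifier: accuracies, weights, and prediction."""

    model: SubgroupClassifier
    splits: classify.Splits
    l0: dict[str, classify.L0Classifier]
    weights: classify.FusionWeights
    selection_accuracy: float
    stackers: dict[str, classify.L1Stacker]
    accuracies: dict[str, float]
    feature_ids: list[str]
    feature_means: np.ndarray
    seed: int

    def _align(self, new_X: pd.DataFrame, min_present: float = 0.9) -> np.ndarray:
        return classify.align_features(
            new_X, self.feature_ids, fill_values=self.feature_means,
            min_present=min_present,
        )

    def _stacked(self, X: np.ndarray, ids: list[str]) -> classify.StackedProbabilities:
        return classify.StackedProbabilities(
            sample_ids=ids,
            p_svm=self.l0["SVM"].predict_proba(X),
            p_rf=self.l0["RF"].predict_proba(X),
            p_ffnn=self.l0["FFNN"].predict_proba(X),
            classes=self.l0["SVM"].classes,
        )

    def predict(
        self, new_X: pd.DataFrame, model: str = "linear", min_present: float = 0.9
    ) -> np.ndarray:
        """Assign subgroups to new samples with the requested model.

        `model` is an L0 kind (``SVM``/``RF``/``FFNN``), ``linear`` for the
        weighted fusion, or ``LR``/``FFNN_stack`` for the nonlinear
        stackers. Features are aligned by ID; missing ones (up to
        1 - min_present) are filled with training means.
        """
        X = self._align(new_X, min_present)
        ids = [str(s) for s in new_X.index]
        if model in self.l0:
            return self.l0[model].predict(X)
        probs = self._stacked(X, ids)
        if model == "linear":
            return classify.fused_predict(probs, self.weights)[1]
        if model == "LR":
            return self.stackers["LR"].predict(probs)
        if model == "FFNN_stack":
            return self.stackers["FFNN"].predict(probs)
        raise ValueError(f"unknown model {model!r}")

    def predict_proba(
        self, new_X: pd.DataFrame, model: str = "linear", min_present: float = 0.9
    ) -> np.ndarray:
        X = self._align(new_X, min_present)
        ids = [str(s) for s in new_X.index]
        if model in self.l0:
            return self.l0[model].predict_proba(X)
        probs = self._stacked(X, ids)
        if model == "linear":
            return classify.fused_predict(probs, self.weights)[0]
        if model == "LR":
            return self.stackers["LR"].predict_proba(probs)
        if model == "FFNN_stack":
            return self.stackers["FFNN"].predict_proba(probs)
        raise ValueError(f"unknown model {model!r}")

    def summary(self) -> str:
        mode = "with holdout" if self.model.plan.holdout else "w/o holdout"
        rows = "\n".join(
            f"  {name:<12s} {acc:.4f}" for name, acc in self.accuracies.items()
        )
        return (
            "Subgroup classifier results\n"
            "===========================\n"
            f"features: {len(self.feature_ids)}    protocol: {mode}\n"
            f"splits: {len(self.splits.train)} train / {len(self.splits.val)} val / "
            f"{len(self.splits.test)} test "
            f"(L0 {len(self.splits.l0_train)}, L1 {len(self.splits.l1_train)})\n"
            f"fusion weights: alpha={self.weights.alpha:.2f} "
            f"beta={self.weights.beta:.2f} gamma={self.weights.gamma:.2f} "
            f"(selection accuracy {self.selection_accuracy:.4f})\n"
            "test accuracy:\n" + rows
        )


def predict_subgroup(
    new_X: pd.DataFrame,
    results: SubgroupClassifierResults,
    model: str = "linear",
    min_present: float = 0.9,
) -> np.ndarray:
    """Functional alias for :meth:`SubgroupClassifierResults.predict`."""
    return results.predict(new_X, model=model, min_present=min_present)


def evaluation_report(
    feature_sets: dict[str, pd.DataFrame],
    labels: np.ndarray,
    seed: int = 0,
    holdout_modes: tuple[bool, ...] = (False, True),
    cv_folds: int = 5,
    cv_repeats: int = 10,
    param_grids: dict | None = None,
) -> pd.DataFrame:
    """Accuracy table over feature sets x (model kind, holdout mode).

    Rows are feature sets (e.g. F1..F4, fusions, the latent matrix);
    columns are L0 and L1 model kinds under each split protocol — the
    standard layout for comparing levels of evidence.
    """
    records = []
    for name, frame in feature_sets.items():
        row: dict[str, object] = {"feature_set": name, "dimension": frame.shape[1]}
        for holdout in holdout_modes:
            plan = classify.SplitPlan(holdout=holdout, seed=seed)
            res = SubgroupClassifier(
                frame, labels, plan=plan, cv_folds=cv_folds,
                cv_repeats=cv_repeats, param_grids=param_grids,
            ).fit(seed)
            tag = "holdout" if holdout else "no_holdout"
            for kind, acc in res.accuracies.items():
                row[f"{tag}:{kind}"] = acc
        records.append(row)
    return pd.DataFrame(records)
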