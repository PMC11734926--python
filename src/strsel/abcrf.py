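"""Approximate Bayesian computation with random forests (ABC-RF).

Model choice is a five-way classification problem: a random forest is
trained on a reference table of simulated feature vectors labelled by the
generating evolutionary model, and a locus's posterior probability for each
model is the fraction of trees voting for it.  Out-of-bag (OOB)
predictions give an unbiased confusion matrix and error rates without
extra simulation.

Parameter estimation follows the regression-forest ABC approach: a
regression forest maps features to the selection coefficient s, and the
posterior for a query locus is the training-row distribution weighted by
how often each row shares a terminal leaf with the query.  The key allele
size alpha is treated as a categorical label (49 classes, 2-50) and
estimated with a classification forest whose vote fractions form the
posterior over alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold

from .selection import MODEL_ORDER, ModelKind
from .simulate import ReferenceTable, feature_names

__all__ = [
    "Hyperparams",
    "ModelPosterior",
    "ParamPosterior",
    "ConfusionMatrix",
    "ModelChoiceForest",
    "SelectionStrengthForest",
    "AlphaClassificationForest",
    "default_grid",
    "tune_hyperparams",
    "train_model_classifier",
    "classify_locus",
    "oob_confusion",
    "variable_importance",
    "estimate_s",
    "estimate_alpha",
]

N_FEATURES = 408
_ARTIFACT_VERSION = 1


@dataclass(frozen=True)
class Hyperparams:
    """Random-forest hyperparameters: ntree, nfeat (features per split),
    and minobs (minimum observations to split a node).

    The defaults are the tuned full-scale values (ntree=200, minobs=15,
    nfeat=20).
    """

    ntree: int = 200
    nfeat: int = 20
    minobs: int = 15

    def __post_init__(self) -> None:
        if min(self.ntree, self.nfeat, self.minobs) < 1:
            raise ValueError("all hyperparameters must be >= 1")
        if self.nfeat > N_FEATURES:
            raise ValueError(f"nfeat must be <= {N_FEATURES}")

    def classifier(self, seed: int, oob: bool = True) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.ntree,
            max_features=self.nfeat,
            min_samples_split=self.minobs,
            criterion="gini",
            oob_score=oob,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )

    def regressor(self, seed: int) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.ntree,
            max_features=self.nfeat,
            min_samples_split=self.minobs,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )


@dataclass
class ModelPosterior:
    """Posterior probabilities over the five models; ``chosen`` is the
    argmax, with ties broken in the canonical order NEUTRAL < ASO < DSO <
    APO < DPO."""

    probabilities: dict[ModelKind, float]
    chosen: ModelKind

    @classmethod
    def from_votes(cls, votes: dict[ModelKind, float]) -> "ModelPosterior":
        total = sum(votes.values())
        probs = {k: votes.get(k, 0.0) / total for k in MODEL_ORDER}
        chosen = MODEL_ORDER[0]
        for k in MODEL_ORDER:
            if probs[k] > probs[chosen]:
                chosen = k
        return cls(probabilities=probs, chosen=chosen)


@dataclass
class ParamPosterior:
    """Posterior summary for one selection parameter.

    For s: ``point`` is the leaf-weighted posterior mean and ``interval``
    the weighted (0.025, 0.975) quantiles, reported as the 95% credible
    interval.  For alpha: ``point`` is the argmax label,
    ``point_probability`` its vote fraction, and ``probabilities`` the full
    posterior over candidate alpha values.
    """

    name: str
    point: float
    interval: Optional[tuple[float, float]] = None
    point_probability: Optional[float] = None
    probabilities: Optional[dict[int, float]] = None


@dataclass
class ConfusionMatrix:
    """5x5 out-of-bag confusion counts (rows simulated, columns predicted)."""

    counts: np.ndarray
    order: tuple[ModelKind, ...] = tuple(MODEL_ORDER)

    def _sel_idx(self) -> list[int]:
        return [i for i, k in enumerate(self.order) if not k.is_neutral]

    @property
    def neutral_to_selection_rate(self) -> float:
        i = self.order.index(ModelKind.NEUTRAL)
        row = self.counts[i]
        return float(row[self._sel_idx()].sum() / row.sum())

    @property
    def selection_to_neutral_rate(self) -> float:
        j = self.order.index(ModelKind.NEUTRAL)
        sel = self._sel_idx()
        total = self.counts[sel].sum()
        return float(self.counts[sel, j].sum() / total)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_frame(self):
        import pandas as pd

        labels = [k.value for k in self.order]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


class ModelChoiceForest:
    """Trained five-way model-choice classifier with OOB diagnostics."""

    def __init__(
        self,
        clf: RandomForestClassifier,
        labels: np.ndarray,
        oob_pred: np.ndarray,
        metadata: dict,
    ):
        self.clf = clf
        self.labels = labels  # training labels, in row order
        self.oob_pred = oob_pred  # OOB-predicted labels, in row order
        self.metadata = metadata

    # -- inference --------------------------------------------------------

    def classify(self, features: np.ndarray) -> ModelPosterior:
        """Posterior model probabilities for one locus (tree vote fractions)."""
        return self.classify_batch(_check_features(features))[0]

    def classify_batch(self, X: np.ndarray) -> list[ModelPosterior]:
        """Vote-fraction posteriors for many loci at once."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ValueError(f"feature matrix must be (n, {N_FEATURES})")
        classes = self.clf.classes_
        counts = np.zeros((X.shape[0], len(classes)))
        for est in self.clf.estimators_:
            pred = est.predict(X).astype(int)  # encoded class indices
            for j in range(len(classes)):
                counts[:, j] += pred == j
        out = []
        for row in counts:
            votes = {ModelKind(classes[j]): float(row[j]) for j in range(len(classes))}
            out.append(ModelPosterior.from_votes(votes))
        return out

    def oob_confusion(self) -> ConfusionMatrix:
        order = [k.value for k in MODEL_ORDER]
        idx = {label: i for i, label in enumerate(order)}
        counts = np.zeros((len(order), len(order)), dtype=int)
        for true, pred in zip(self.labels, self.oob_pred):
            counts[idx[true], idx[pred]] += 1
        return ConfusionMatrix(counts=counts)

    def variable_importance(self) -> list[tuple[str, float]]:
        """Features ranked by mean Gini impurity decrease, descending."""
        names = self.metadata.get("feature_names", feature_names())
        imp = self.clf.feature_importances_
        order = np.argsort(imp)[::-1]
        return [(names[i], float(imp[i])) for i in order]

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        joblib.dump(
            {
                "version": _ARTIFACT_VERSION,
                "type": "model-choice",
                "clf": self.clf,
                "labels": self.labels,
                "oob_pred": self.oob_pred,
                "metadata": self.metadata,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "ModelChoiceForest":
        blob = joblib.load(path)
        if blob.get("version") != _ARTIFACT_VERSION or blob.get("type") != "model-choice":
            raise ValueError(f"unrecognized forest artifact at {path}")
        return cls(blob["clf"], blob["labels"], blob["oob_pred"], blob["metadata"])

    def check_metadata(self, motif_size=None, schedule_hash=None, force=False) -> None:
        if force:
            return
        if motif_size is not None and motif_size != self.metadata.get("motif_size"):
            raise ValueError(
                f"classifier was trained for motif size {self.metadata.get('motif_size')}, "
                f"queried with {motif_size} (use force to override)"
            )
        if schedule_hash is not None and schedule_hash != self.metadata.get("schedule_hash"):
            raise ValueError(
                "classifier schedule hash mismatch (use force to override)"
            )


def _check_features(features: np.ndarray) -> np.ndarray:
    x = np.asarray(features, dtype=float).reshape(1, -1)
    if x.shape[1] != N_FEATURES:
        raise ValueError(f"feature vector must have length {N_FEATURES}, got {x.shape[1]}")
    return x


def train_model_classifier(
    table: ReferenceTable, hp: Hyperparams, seed: int
) -> ModelChoiceForest:
    """Train the five-way model-choice forest and retain OOB predictions."""
    labels = table.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("reference table must contain at least two model labels")
    X = table.features
    clf = hp.classifier(seed)
    clf.fit(X, labels)
    oob = clf.oob_decision_function_
    covered = ~np.isnan(oob).any(axis=1)
    # with >= ~40 trees every row is OOB for some tree with near certainty;
    # rows never out of bag (possible in tiny forests) reuse their own label
    pred_idx = np.zeros(len(labels), dtype=int)
    pred_idx[covered] = np.argmax(oob[covered], axis=1)
    oob_pred = np.where(covered, clf.classes_[pred_idx], labels)
    metadata = dict(table.metadata)
    metadata.setdefault("feature_names", feature_names())
    metadata["hyperparams"] = vars(hp)
    metadata["seed"] = seed
    return ModelChoiceForest(clf=clf, labels=labels, oob_pred=oob_pred, metadata=metadata)


def classify_locus(classifier: ModelChoiceForest, features: np.ndarray) -> ModelPosterior:
    return classifier.classify(features)


def oob_confusion(classifier: ModelChoiceForest) -> ConfusionMatrix:
    return classifier.oob_confusion()


def variable_importance(classifier: ModelChoiceForest) -> list[tuple[str, float]]:
    return classifier.variable_importance()


# ---------------------------------------------------------------------------
# Hyperparameter tuning
# ---------------------------------------------------------------------------


def default_grid() -> list[Hyperparams]:
    return [
        Hyperparams(ntree=ntree, nfeat=nfeat, minobs=minobs)
        for ntree in (100, 200, 500)
        for nfeat in (10, 20, 30, 50)
        for minobs in (5, 15, 50)
    ]


def tune_hyperparams(
    table: ReferenceTable,
    grid: Sequence[Hyperparams],
    k: int = 5,
    seed: int = 0,
    task: str = "classify",
) -> Hyperparams:
    """Pick the grid member minimizing mean k-fold validation error.

    ``task="classify"`` scores misclassification of the model label;
    ``task="regress"`` scores squared error on s.  Ties go to the earlier
    grid member.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(table) < k:
        raise ValueError(f"table has {len(table)} rows, fewer than k={k}")
    X = table.features
    if task == "classify":
        y = table.labels
    elif task == "regress":
        y = table.df["s"].to_numpy()
    else:
        raise ValueError(f"unknown task {task!r}")
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(X))
    best_hp, best_err = None, np.inf
    for hp in grid:
        errs = []
        for train_idx, val_idx in folds:
            if task == "classify":
                est = hp.classifier(seed, oob=False)
                est.fit(X[train_idx], y[train_idx])
                errs.append(float(np.mean(est.predict(X[val_idx]) != y[val_idx])))
            else:
                est = hp.regressor(seed)
                est.fit(X[train_idx], y[train_idx])
                errs.append(float(np.mean((est.predict(X[val_idx]) - y[val_idx]) ** 2)))
        err = float(np.mean(errs))
        if err < best_err:
            best_hp, best_err = hp, err
    return best_hp


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------


def _require_single_kind(table: ReferenceTable) -> ModelKind:
    kinds = np.unique(table.labels)
    if len(kinds) != 1:
        raise ValueError(
            f"parameter-estimation table must hold a single model kind, got {list(kinds)}"
        )
    kind = ModelKind(kinds[0])
    if kind.is_neutral:
        raise ValueError("cannot estimate selection parameters under the neutral model")
    return kind


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, qs) -> np.ndarray:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    cum /= cum[-1]
    return np.interp(qs, cum, v)


class SelectionStrengthForest:
    """Leaf-weighted regression-forest posterior for the selection strength.

    A regression forest maps features to s on a single-kind reference
    table; for each query, every training row is weighted by the average
    frequency with which it shares a terminal leaf with the query across
    trees.  The posterior point estimate is the weighted mean of the
    training s values and the 95% interval the weighted 2.5%/97.5%
    quantiles.
    """

    def __init__(self, table_subset: ReferenceTable, hp: Hyperparams, seed: int = 0):
        if len(table_subset) == 0:
            raise ValueError("empty reference table subset")
        self.kind = _require_single_kind(table_subset)
        self.X = table_subset.features
        self.s_vals = table_subset.df["s"].to_numpy(dtype=float)
        self.forest = hp.regressor(seed)
        self.forest.fit(self.X, self.s_vals)
        self._train_leaves = self.forest.apply(self.X)  # (n, ntree)

    def _weights(self, Xq: np.ndarray) -> np.ndarray:
        """(n_query, n_train) leaf co-membership weight matrix."""
        query_leaves = self.forest.apply(Xq)  # (q, ntree)
        n, ntree = self._train_leaves.shape
        weights = np.zeros((Xq.shape[0], n))
        for t in range(ntree):
            tl = self._train_leaves[:, t]
            uniq, inv, cnt = np.unique(tl, return_inverse=True, return_counts=True)
            inv_size = 1.0 / cnt[inv]
            leaf_pos = {leaf: i for i, leaf in enumerate(uniq)}
            for q, leaf in enumerate(query_leaves[:, t]):
                pos = leaf_pos.get(leaf)
                if pos is None:  # pragma: no cover - queries land in known leaves
                    continue
                mask = inv == pos
                weights[q, mask] += inv_size[mask]
        weights /= ntree
        rowsum = weights.sum(axis=1, keepdims=True)
        rowsum[rowsum == 0] = 1.0
        return weights / rowsum

    def posterior(self, features: np.ndarray) -> ParamPosterior:
        return self.posterior_batch(_check_features(features))[0]

    def posterior_batch(self, Xq: np.ndarray) -> list[ParamPosterior]:
        Xq = np.asarray(Xq, dtype=float)
        W = self._weights(Xq)
        out = []
        for w in W:
            point = float(np.dot(w, self.s_vals))
            lo, hi = _weighted_quantile(self.s_vals, w, (0.025, 0.975))
            out.append(
                ParamPosterior(name="s", point=point, interval=(float(lo), float(hi)))
            )
        return out


class AlphaClassificationForest:
    """Classification-forest posterior over the key allele size alpha.

    alpha is a categorical label (integer allele sizes); the posterior is
    the per-label tree vote fraction and the point estimate the argmax
    (ties to the smallest alpha).
    """

    def __init__(self, table_subset: ReferenceTable, hp: Hyperparams, seed: int = 0):
        if len(table_subset) == 0:
            raise ValueError("empty reference table subset")
        self.kind = _require_single_kind(table_subset)
        X = table_subset.features
        alpha_vals = table_subset.df["alpha"].to_numpy(dtype=int)
        self.classes = np.unique(alpha_vals)
        if len(self.classes) == 1:
            self.clf = None
        else:
            self.clf = hp.classifier(seed, oob=False)
            self.clf.fit(X, alpha_vals)
            self.classes = self.clf.classes_

    def posterior(self, features: np.ndarray) -> ParamPosterior:
        return self.posterior_batch(_check_features(features))[0]

    def posterior_batch(self, Xq: np.ndarray) -> list[ParamPosterior]:
        Xq = np.asarray(Xq, dtype=float)
        if self.clf is None:
            only = int(self.classes[0])
            return [
                ParamPosterior(
                    name="alpha", point=float(only), point_probability=1.0,
                    probabilities={only: 1.0},
                )
                for _ in range(Xq.shape[0])
            ]
        votes = np.zeros((Xq.shape[0], len(self.classes)))
        for est in self.clf.estimators_:
            pred = est.predict(Xq).astype(int)
            for j in range(len(self.classes)):
                votes[:, j] += pred == j
        probs = votes / votes.sum(axis=1, keepdims=True)
        out = []
        for row in probs:
            best = int(np.argmax(row))  # first (smallest alpha) wins ties
            out.append(
                ParamPosterior(
                    name="alpha",
                    point=float(self.classes[best]),
                    point_probability=float(row[best]),
                    probabilities={int(c): float(p) for c, p in zip(self.classes, row)},
                )
            )
        return out


def estimate_s(
    table_subset: ReferenceTable,
    hp: Hyperparams,
    features: np.ndarray,
    seed: int = 0,
) -> ParamPosterior:
    """One-shot train-and-query wrapper around :class:`SelectionStrengthForest`."""
    return SelectionStrengthForest(table_subset, hp, seed).posterior(features)


def estimate_alpha(
    table_subset: ReferenceTable,
    hp: Hyperparams,
    features: np.ndarray,
    seed: int = 0,
) -> ParamPosterior:
    """One-shot train-and-query wrapper around :class:`AlphaClassificationForest`."""
    return AlphaClassificationForest(table_subset, hp, seed).posterior(features)
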