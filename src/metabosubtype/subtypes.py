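"""Metabolic subtyping: k-means clusters, survival-ordered labels, transfer MLP.

Samples are clustered on the z-scores of the signature genes with k-means
(Euclidean distance, k = 2 by default; silhouette widths for k = 2..6 are
reported to document the choice).  The two clusters are then labeled by
outcome: the cluster with the longer Kaplan-Meier median overall survival
is M1 (lower risk) and the other M2 (high risk).  A one-hidden-layer
multilayer perceptron trained on the same z-scores transfers the subtype
labels to external cohorts, which must be normalized and z-scored within
their own cohort before classification; internal validation is repeated
stratified 10-fold cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import silhouette_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neural_network import MLPClassifier

from .io_norm import ClinicalTable, ExpressionMatrix
from .survival_stats import TestResult, km_estimate, logrank_test

logger = logging.getLogger(__name__)

LOW_RISK, HIGH_RISK = "M1", "M2"


@dataclass
class SubtypeAssignment:
    """Per-sample cluster labels with the fitted centroids.

    Labels are ``C0..C{k-1}`` straight out of clustering and ``M1``/``M2``
    after survival ordering (:func:`label_by_survival`).
    """

    labels: pd.Series
    k: int
    centroids: pd.DataFrame  # gene x cluster-label
    inertia: float
    seed: int
    silhouette: dict[int, float] = field(default_factory=dict)
    degenerate: bool = False
    logrank: TestResult | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def proportions(self) -> pd.Series:
        return self.labels.value_counts(normalize=True).sort_index()


def cluster_subtypes(Z: ExpressionMatrix, k: int = 2, seed: int = 0,
                     n_init: int = 20, silhouette_range: tuple[int, int] = (2, 6)) -> SubtypeAssignment:
    """k-means clustering of samples on signature-gene z-scores.

    Raises when the number of distinct sample profiles is <= k (no valid
    k-partition); a matrix whose samples are all identical instead returns a
    degenerate single-cluster assignment with a flag.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    data = Z.values.to_numpy(dtype=float).T  # samples x genes
    n = data.shape[0]
    if n <= k:
        raise ValueError(f"need more samples ({n}) than clusters ({k})")
    n_distinct = np.unique(data, axis=0).shape[0]
    if n_distinct == 1:
        logger.warning("all samples identical: degenerate single-cluster assignment")
        return SubtypeAssignment(
            labels=pd.Series("C0", index=Z.sample_ids, name="subtype"),
            k=1, centroids=pd.DataFrame({"C0": data[0]}, index=Z.gene_ids),
            inertia=0.0, seed=seed, degenerate=True,
        )
    if n_distinct <= k:
        raise ValueError(f"only {n_distinct} distinct sample profiles for k={k}")

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(data)
    labels = pd.Series([f"C{i}" for i in km.labels_], index=Z.sample_ids, name="subtype")
    centroids = pd.DataFrame(km.cluster_centers_.T, index=Z.gene_ids,
                             columns=[f"C{i}" for i in range(k)])
    sil: dict[int, float] = {}
    lo, hi = silhouette_range
    for kk in range(lo, hi + 1):
        if kk >= min(n, n_distinct):
            break
        lab = KMeans(n_clusters=kk, n_init=n_init, random_state=seed).fit_predict(data)
        if len(np.unique(lab)) > 1:
            sil[kk] = float(silhouette_score(data, lab, metric="euclidean"))
    return SubtypeAssignment(labels=labels, k=k, centroids=centroids,
                             inertia=float(km.inertia_), seed=seed, silhouette=sil)


def label_by_survival(a: SubtypeAssignment, surv: ClinicalTable) -> SubtypeAssignment:
    """Order two clusters by outcome: longer KM median survival -> M1, other -> M2.

    When neither cluster's median survival is defined the clusters are
    ordered by mean observed time instead (logged); exact survival ties fall
    back to calling the smaller cluster M2 (warned).  Idempotent: relabeling
    an already-labeled assignment reproduces it.
    """
    if a.degenerate or a.labels.nunique() != 2:
        raise ValueError("survival labeling needs exactly 2 clusters")
    surv = ClinicalTable(surv.data.loc[a.sample_ids].copy())
    groups = sorted(a.labels.unique())
    med, mean_t, sizes = {}, {}, {}
    for gname in groups:
        mask = (a.labels == gname).to_numpy()
        sub = ClinicalTable(surv.data.loc[a.labels.index[mask]].copy())
        med[gname] = km_estimate(sub).median
        mean_t[gname] = float(sub.time.mean())
        sizes[gname] = int(mask.sum())
    g0, g1 = groups
    if not np.isfinite(med[g0]) and not np.isfinite(med[g1]):
        logger.warning("both KM medians undefined; ordering clusters by mean survival")
        key = mean_t
    else:
        key = med
    if key[g0] == key[g1]:
        warnings.warn("clusters have identical survival; smaller cluster labeled M2",
                      stacklevel=2)
        high = g0 if sizes[g0] <= sizes[g1] else g1
    else:
        high = g0 if key[g0] < key[g1] else g1
    low = g1 if high == g0 else g0
    mapping = {low: LOW_RISK, high: HIGH_RISK}
    labels = a.labels.map(mapping).rename("subtype")
    lr = logrank_test(surv, labels)
    centroids = a.centroids.rename(columns=mapping)
    centroids = centroids[[LOW_RISK, HIGH_RISK]]
    return SubtypeAssignment(labels=labels, k=a.k, centroids=centroids,
                             inertia=a.inertia, seed=a.seed,
                             silhouette=dict(a.silhouette), logrank=lr)


# ---------------------------------------------------------------------------
# Transfer classifier
# ---------------------------------------------------------------------------

@dataclass
class ClassifierModel:
    """One-hidden-layer MLP over signature-gene z-scores.

    Weights are stored explicitly so prediction and (de)serialization do not
    depend on the training backend: hidden layer ReLU, output logistic
    (binary) / softmax (multiclass).
    """

    genes: list[str]
    classes: list[str]
    layer_sizes: list[int]
    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]
    seed: int
    cv_accuracy_mean: float
    cv_accuracy_sd: float
    cv_skipped: bool = False

    def _forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        return h @ self.coefs[-1] + self.intercepts[-1]

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Predict labels for a samples x genes frame (columns = self.genes)."""
        z = self._forward(X[self.genes].to_numpy(dtype=float))
        if z.shape[1] == 1:
            idx = (1.0 / (1.0 + np.exp(-z[:, 0])) > 0.5).astype(int)
        else:
            idx = z.argmax(axis=1)
        return pd.Series([self.classes[i] for i in idx], index=X.index, name="subtype")

    def to_dict(self) -> dict:
        return {
            "genes": self.genes, "classes": self.classes,
            "layer_sizes": self.layer_sizes,
            "coefs": [w.tolist() for w in self.coefs],
            "intercepts": [b.tolist() for b in self.intercepts],
            "seed": self.seed,
            "cv_accuracy_mean": self.cv_accuracy_mean,
            "cv_accuracy_sd": self.cv_accuracy_sd,
            "cv_skipped": self.cv_skipped,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierModel":
        return cls(
            genes=list(d["genes"]), classes=list(d["classes"]),
            layer_sizes=list(d["layer_sizes"]),
            coefs=[np.asarray(w, dtype=float) for w in d["coefs"]],
            intercepts=[np.asarray(b, dtype=float) for b in d["intercepts"]],
            seed=int(d["seed"]),
            cv_accuracy_mean=float(d["cv_accuracy_mean"]),
            cv_accuracy_sd=float(d["cv_accuracy_sd"]),
            cv_skipped=bool(d["cv_skipped"]),
        )


def _make_mlp(hidden: int, seed: int, learning_rate: float, momentum: float,
              epochs: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(hidden,), solver="sgd", learning_rate="constant",
        learning_rate_init=learning_rate, momentum=momentum,
        nesterovs_momentum=False, max_iter=epochs, random_state=seed,
    )


def train_classifier(Z: ExpressionMatrix, labels: pd.Series, hidden: int | None = None,
                     seed: int = 0, learning_rate: float = 0.3, momentum: float = 0.2,
                     epochs: int = 500, cv_folds: int = 10, cv_repeats: int = 10) -> ClassifierModel:
    """Train the subtype transfer MLP and estimate internal-validation accuracy.

    Hidden-layer width defaults to ceil((n_genes + n_classes)/2).  Internal
    validation is repeated stratified ``cv_folds``-fold CV (``cv_repeats``
    repeats); when a class has fewer members than folds, CV is skipped
    (flagged) and the training accuracy is reported instead.
    """
    labels = labels.loc[Z.sample_ids]
    y = labels.to_numpy()
    classes = sorted(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    X = Z.values.to_numpy(dtype=float).T
    if hidden is None:
        hidden = ceil((Z.n_genes + len(classes)) / 2)

    min_class = int(pd.Series(y).value_counts().min())
    accs: list[float] = []
    cv_skipped = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if min_class >= cv_folds:
            cv = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=cv_repeats,
                                         random_state=seed)
            for tr, te in cv.split(X, y):
                clf = _make_mlp(hidden, seed, learning_rate, momentum, epochs)
                clf.fit(X[tr], y[tr])
                accs.append(float((clf.predict(X[te]) == y[te]).mean()))
        else:
            cv_skipped = True
            logger.warning("class with %d sample(s) < %d folds: CV skipped, "
                           "training accuracy reported", min_class, cv_folds)
        final = _make_mlp(hidden, seed, learning_rate, momentum, epochs)
        final.fit(X, y)
    if cv_skipped:
        accs = [float((final.predict(X) == y).mean())]
    model = ClassifierModel(
        genes=Z.gene_ids, classes=[str(c) for c in final.classes_],
        layer_sizes=[Z.n_genes, hidden, len(final.classes_)],
        coefs=[np.asarray(w) for w in final.coefs_],
        intercepts=[np.asarray(b) for b in final.intercepts_],
        seed=seed,
        cv_accuracy_mean=float(np.mean(accs)),
        cv_accuracy_sd=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        cv_skipped=cv_skipped,
    )
    return model


def classify_external(model: ClassifierModel, m: ExpressionMatrix) -> tuple[pd.Series, pd.Series]:
    """Apply a trained model to a cohort; returns labels and subtype proportions.

    The cohort must have been normalized and z-scored within itself; a matrix
    whose gene rows do not look standardized triggers a warning.  Missing
    model genes raise with the genes listed.
    """
    missing = [g for g in model.genes if g not in m.values.index]
    if missing:
        raise KeyError(f"model genes absent from matrix: {missing}")
    sub = m.values.loc[model.genes]
    sds = sub.std(axis=1, ddof=1).to_numpy()
    informative = sds[sds > 0]
    if m.mode != "zscore" or (informative.size and
                              not 0.5 < float(np.median(informative)) < 2.0):
        warnings.warn("input does not look z-scored per gene; classify on "
                      "within-cohort z-scores", stacklevel=2)
    labels = model.predict(sub.T)
    props = labels.value_counts(normalize=True).reindex(model.classes, fill_value=0.0)
    props.name = "proportion"
    return labels, props
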