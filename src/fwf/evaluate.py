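"""Imbalance-aware evaluation pipeline.

Stages, in the order the full experiment runs them:

1. robust-PCA outlier removal (score + orthogonal distance in a robust
   principal subspace, top fraction of rows dropped),
2. temporal 80/20 split (no shuffling — the test set is the season tail,
   keeping its natural injury prevalence),
3. SMOTE oversampling of the training minority class,
4. unstandardized PCA fit on the training set only, keeping the smallest
   number of components reaching 95% cumulative explained variance,
5. repeated stratified 2-fold cross-validation over eight classical
   classifier families,
6. six metrics suited to rare-positive problems: ROC-AUC, PR-AUC,
   G-mean, accuracy, Type I error (false-positive rate) and Type II
   error (false-negative rate), with t-based 95% confidence intervals,
7. optional permutation test and 0-1-loss bias-variance decomposition.

SMOTE is implemented here directly (convex interpolation between a
minority sample and one of its k minority-class nearest neighbors);
classifiers, PCA, the robust covariance estimate and the CV splitter
come from scikit-learn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.covariance import MinCovDet
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "MODEL_FAMILIES",
    "ModelSpec",
    "MetricSet",
    "EvalReport",
    "make_classifier",
    "detect_outliers_robust_pca",
    "temporal_split",
    "oversample_smote",
    "pca_reduce",
    "cross_validate",
    "compute_metrics",
    "pr_baseline",
    "confidence_interval_t",
    "permutation_test",
    "bias_variance_decompose",
]

MODEL_FAMILIES = ("LDA", "LR", "NB", "KNN", "SVM", "CART", "RF", "MLP")

METRIC_NAMES = ("roc_auc", "pr_auc", "gmean", "accuracy", "type1_error", "type2_error")


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family plus hyperparameter overrides and a seed."""

    family: str
    hyperparameters: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {MODEL_FAMILIES}")

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)


def make_classifier(spec: ModelSpec):
    """Instantiate the scikit-learn estimator for a model spec.

    SVM uses the bounded RBF kernel; every stochastic family gets the
    spec's seed.  Hyperparameters are library defaults unless overridden.
    """
    p = spec.params
    if spec.family == "LDA":
        return LinearDiscriminantAnalysis(**p)
    if spec.family == "LR":
        return LogisticRegression(max_iter=p.pop("max_iter", 1000), **p)
    if spec.family == "NB":
        return GaussianNB(**p)
    if spec.family == "KNN":
        return KNeighborsClassifier(**p)
    if spec.family == "SVM":
        return SVC(kernel=p.pop("kernel", "rbf"), random_state=spec.seed, **p)
    if spec.family == "CART":
        return DecisionTreeClassifier(random_state=spec.seed, **p)
    if spec.family == "RF":
        return RandomForestClassifier(random_state=spec.seed, **p)
    if spec.family == "MLP":
        return MLPClassifier(max_iter=p.pop("max_iter", 500),
                             random_state=spec.seed, **p)
    raise ValueError(spec.family)  # pragma: no cover


def _decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous scores in [0, 1] for ranking metrics; 0.5 is the
    decision threshold, consistent with the model's own predict."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    if hasattr(model, "decision_function"):
        # squash the signed margin through a logistic so 0 maps to 0.5
        return 1.0 / (1.0 + np.exp(-np.clip(model.decision_function(X), -500, 500)))
    return model.predict(X).astype(float)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricSet:
    """Six imbalance-aware metrics for one scored sample set.

    Type I error is the false-positive rate FP/(FP+TN) (predicted injury,
    none occurred); Type II error is the false-negative rate FN/(FN+TP)
    (predicted safe, the player got injured).  G-mean is the geometric
    mean of sensitivity and specificity.  AUC metrics are NaN when only
    one class is present.
    """

    roc_auc: float
    pr_auc: float
    gmean: float
    accuracy: float
    type1_error: float
    type2_error: float
    pr_baseline: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricSet:
    """Score a prediction vector against binary labels.

    ``scores`` are probability-like values in [0, 1]; the confusion
    matrix uses ``score >= threshold``; ROC-AUC and PR-AUC are
    threshold-free.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    type1 = fp / (fp + tn) if (fp + tn) else 0.0
    type2 = fn / (fn + tp) if (fn + tp) else 0.0
    gmean = math.sqrt((1.0 - type1) * (1.0 - type2))
    accuracy = (tp + tn) / len(labels)
    both = labels.min() == 0 and labels.max() == 1
    roc = float(roc_auc_score(labels, scores)) if both else float("nan")
    pr = float(average_precision_score(labels, scores)) if both else float("nan")
    base = float(labels.mean()) if labels.any() else float("nan")
    return MetricSet(roc_auc=roc, pr_auc=pr, gmean=gmean, accuracy=accuracy,
                     type1_error=type1, type2_error=type2, pr_baseline=base)


def pr_baseline(labels) -> float:
    """PR-AUC of a random classifier: the positive-class prevalence."""
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        raise ValueError("PR baseline undefined without positive samples")
    return float(labels.mean())


def confidence_interval_t(values, level: float = 0.95) -> tuple[float, float, float]:
    """(low, mean, high) Student-t confidence interval for the mean."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values for a t interval")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    half = stats.t.ppf(0.5 + level / 2.0, n - 1) * sd / math.sqrt(n)
    return (mean - half, mean, mean + half)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def detect_outliers_robust_pca(
    X, reduction_factor: float, seed: int = 0, subspace_variance: float = 0.90
) -> np.ndarray:
    """Robust-PCA outlier mask: True = retained.

    Rows are scored in a principal subspace by a robust (MinCovDet)
    Mahalanobis score distance combined with the orthogonal residual
    distance, each scaled by its median; the ``ceil(reduction_factor*n)``
    highest-scoring rows are removed.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if not 0.0 <= reduction_factor < 1.0:
        raise ValueError("reduction_factor must be in [0, 1)")
    if reduction_factor == 0.0:
        return np.ones(n, dtype=bool)
    n_remove = math.ceil(reduction_factor * n)

    # principal subspace capturing most variance, small enough for a
    # high-breakdown covariance fit
    max_k = max(1, min(X.shape[1], n // 4, 10))
    pca = PCA(n_components=min(X.shape[1], max_k), svd_solver="full")
    T = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, subspace_variance) + 1)
    k = min(k, T.shape[1])
    T = T[:, :k]

    try:
        mcd = MinCovDet(random_state=seed).fit(T)
        sd = np.sqrt(mcd.mahalanobis(T))
    except Exception:  # singular subspace: fall back to classical distance
        center = T.mean(axis=0)
        scale = T.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        sd = np.linalg.norm((T - center) / scale, axis=1)

    recon = T @ pca.components_[:k] + pca.mean_
    od = np.linalg.norm(X - recon, axis=1)

    def _norm(d: np.ndarray) -> np.ndarray:
        m = np.median(d)
        return d / m if m > 0 else d

    score = np.sqrt(_norm(sd) ** 2 + _norm(od) ** 2)
    worst = np.argsort(score)[::-1][:n_remove]
    mask = np.ones(n, dtype=bool)
    mask[worst] = False
    return mask


def temporal_split(table, train_fraction: float = 0.8):
    """Chronological split: first ``floor(train_fraction * n)`` rows by
    event order go to train, the remainder (the season tail, at natural
    prevalence) to test.  No shuffling.

    Accepts a :class:`~fwf.datasets.FeatureTable` (returns two tables) or
    an (X, y, event_order) triple of arrays.
    """
    from .datasets import FeatureTable

    if isinstance(table, FeatureTable):
        order = table.features.index.get_level_values("event_index").to_numpy()
        if np.any(np.diff(order) < 0):
            # rows grouped per player: reorder chronologically (stable)
            srt = np.argsort(order, kind="stable")
            feats = table.features.iloc[srt]
            labels = table.labels.iloc[srt]
        else:
            feats, labels = table.features, table.labels
        n_train = int(train_fraction * len(feats))
        train = FeatureTable(feats.iloc[:n_train], labels.iloc[:n_train], table.spec)
        test = FeatureTable(feats.iloc[n_train:], labels.iloc[n_train:], table.spec)
        return train, test

    X, y, order = table
    order = np.asarray(order)
    if np.any(np.diff(order) < 0):
        raise ValueError("rows must be ordered by event index")
    n_train = int(train_fraction * len(order))
    return (X[:n_train], y[:n_train]), (X[n_train:], y[n_train:])


def oversample_smote(X, y, k_neighbors: int = 5, seed: int = 0):
    """SMOTE: balance the classes by synthesizing minority samples.

    Each synthetic sample is x_i + t * (x_nb - x_i) for a random minority
    sample x_i, one of its ``k_neighbors`` minority-class nearest
    neighbors x_nb, and t ~ U(0, 1).  Originals are preserved; the output
    has equal class counts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    minority = int(np.argmin(counts))
    majority = 1 - minority
    n_min, n_maj = counts[minority], counts[majority]
    if n_min == n_maj:
        return X.copy(), y.copy()
    if n_min < k_neighbors + 1:
        raise ValueError(
            f"minority class has {n_min} samples but SMOTE with k={k_neighbors} "
            f"needs at least {k_neighbors + 1}; use a smaller k_neighbors"
        )
    rng = np.random.default_rng(seed)
    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)  # column 0 is the point itself
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    nb = idx[base, rng.integers(1, k_neighbors + 1, size=n_new)]
    t = rng.random(size=(n_new, 1))
    synth = Xm[base] + t * (Xm[nb] - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority)])
    return X_out, y_out


def pca_reduce(X_train, X_test, variance_threshold: float = 0.95):
    """Unstandardized PCA fit on train only; test is projected with the
    train transform.  Keeps the smallest m with cumulative explained
    variance >= threshold.  Returns (train_m, test_m, m)."""
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    pca = PCA(svd_solver="full").fit(X_train)
    cum = np.cumsum(pca.explained_variance_ratio_)
    m = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    m = min(m, len(cum))
    comp = pca.components_[:m]
    Z_train = (X_train - pca.mean_) @ comp.T
    Z_test = (X_test - pca.mean_) @ comp.T
    return Z_train, Z_test, m


# ---------------------------------------------------------------------------
# cross-validation and reporting
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-split metric distributions plus mean and t-based 95% CIs."""

    model: ModelSpec
    train_metrics: pd.DataFrame   # one row per (repeat, fold)
    val_metrics: pd.DataFrame
    n_repeats: int
    n_folds: int
    permutation_p: float | None = None
    bias_variance: tuple[float, float, float] | None = None

    def summary(self, split: str = "val", level: float = 0.95) -> pd.DataFrame:
        """mean / ci_low / ci_high per metric for one split."""
        df = self.val_metrics if split == "val" else self.train_metrics
        rows = {}
        for m in METRIC_NAMES:
            vals = df[m].dropna().to_numpy()
            if len(vals) >= 2:
                lo, mean, hi = confidence_interval_t(vals, level)
            elif len(vals) == 1:
                lo = mean = hi = float(vals[0])
            else:
                lo = mean = hi = float("nan")
            rows[m] = {"mean": mean, "ci_low": lo, "ci_high": hi}
        return pd.DataFrame(rows).T


def cross_validate(
    X, y, model_spec: ModelSpec, repeats: int = 10, folds: int = 2, seed: int = 0,
    estimator=None,
) -> EvalReport:
    """Repeated stratified k-fold CV recording all six metrics on both
    the fitted fold and the held-out fold of every split.

    ``estimator`` (any scikit-learn estimator, cloned per split)
    overrides the model built from ``model_spec``; pass it when the
    classifier is a composite pipeline rather than one of the eight
    standard families.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if y.sum() < folds:
        raise ValueError(
            f"need at least {folds} positive samples for {folds}-fold stratification"
        )
    splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                       random_state=seed)
    train_rows, val_rows = [], []
    for split_i, (tr, va) in enumerate(splitter.split(X, y)):
        if estimator is not None:
            model = clone(estimator)
        else:
            model = make_classifier(
                ModelSpec(model_spec.family, model_spec.hyperparameters,
                          seed=model_spec.seed + split_i)
            )
        model.fit(X[tr], y[tr])
        train_rows.append(compute_metrics(_decision_scores(model, X[tr]), y[tr]).as_dict())
        val_rows.append(compute_metrics(_decision_scores(model, X[va]), y[va]).as_dict())
    return EvalReport(
        model=model_spec,
        train_metrics=pd.DataFrame(train_rows),
        val_metrics=pd.DataFrame(val_rows),
        n_repeats=repeats,
        n_folds=folds,
    )


def permutation_test(
    pipeline, X, y, n_permutations: int = 1000, seed: int = 0
) -> tuple[float, np.ndarray, float]:
    """Label-permutation significance test for a scoring pipeline.

    ``pipeline(X, y) -> float`` must be deterministic given its own
    seeding.  Returns (p_value, null_distribution, observed) with the
    add-one estimator p = (1 + #{null >= observed}) / (n + 1), which can
    never report exactly zero.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    observed = float(pipeline(X, y))
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = pipeline(X, rng.permutation(y))
    p = (1.0 + float((null >= observed).sum())) / (n_permutations + 1.0)
    return p, null, observed


def bias_variance_decompose(
    model_spec: ModelSpec, X_train, y_train, X_test, y_test,
    n_bootstrap: int = 200, seed: int = 0, max_retries: int = 50,
) -> tuple[float, float, float]:
    """0-1-loss bias-variance decomposition over bootstrap resamples.

    The main prediction at each test point is the majority vote across
    resample fits; bias is the loss of the main prediction against the
    truth, variance the mean disagreement of individual fits with the
    main prediction, expected loss the mean 0-1 loss over resamples.
    Returns (expected_loss, bias, variance), all in [0, 1].
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=int)
    rng = np.random.default_rng(seed)
    n = len(y_train)
    preds = np.empty((n_bootstrap, len(y_test)), dtype=int)
    for b in range(n_bootstrap):
        for attempt in range(max_retries):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y_train[idx])) > 1:
                break
        else:
            raise RuntimeError("bootstrap resamples keep collapsing to one class")
        model = make_classifier(
            ModelSpec(model_spec.family, model_spec.hyperparameters,
                      seed=model_spec.seed + b)
        )
        model.fit(X_train[idx], y_train[idx])
        preds[b] = model.predict(X_test)
    main = (preds.mean(axis=0) >= 0.5).astype(int)
    expected_loss = float((preds != y_test[None, :]).mean())
    bias = float((main != y_test).mean())
    variance = float((preds != main[None, :]).mean())
    return expected_loss, bias, variance
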