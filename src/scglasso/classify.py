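"""Two-group discrimination from estimated precision networks.

The pipeline vectorizes each subject's precision matrix (strictly
upper-triangular entries), screens features by Mann-Whitney rank
comparison between groups, and classifies with one of four families:
regularized LDA (covariance shrunk toward its diagonal by ``gamma``),
k-nearest neighbours (Euclidean, ``k`` in 2..10), polynomial-kernel SVM
(``(1 + <x, x'>)^d``, ``d`` in 1..6) and RBF-kernel SVM (``sigma`` in
``10^-5 .. 10^5``).  Generalization is estimated by stratified 10-fold
cross-validation with the feature count and hyperparameters chosen by a
nested 10-fold loop on the training rows only — feature screening is
never allowed to see test subjects.  Fold results aggregate into a
single confusion matrix; by convention the *second* group (sorted label
order) is the positive class, so sensitivity is its correct-
classification rate and specificity the first group's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .glasso import sample_covariance, weights_for_mode, glasso_fit
from .matrices import ConnectivityMatrix
from .selection import SelectionConfig, crossval_compare, multichannel_ess, select_lambda

__all__ = [
    "FeatureTable",
    "FoldRecord",
    "CVResult",
    "vectorize_precision",
    "mann_whitney_rank",
    "select_features",
    "ShrunkenLDA",
    "knn_predict",
    "svm_fit",
    "nested_cv",
    "default_grids",
    "feature_stability",
    "subject_network",
    "cohort_feature_table",
]


@dataclass(frozen=True)
class FeatureTable:
    """Subjects-by-features design matrix with region-pair labels."""

    X: np.ndarray
    feature_labels: tuple[str, ...]
    y: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be n_subjects x n_features, matching y")
        if len(self.feature_labels) != X.shape[1]:
            raise ValueError("one label per feature required")
        if len(set(self.feature_labels)) != len(self.feature_labels):
            raise ValueError("feature labels must be unique")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "feature_labels", tuple(self.feature_labels))

    def rows(self, idx) -> "FeatureTable":
        return FeatureTable(self.X[idx], self.feature_labels, self.y[idx])


def vectorize_precision(theta: ConnectivityMatrix) -> tuple[np.ndarray, tuple[str, ...]]:
    """Strictly-upper-triangular entries in row-major label order.

    Returns the feature vector and matching ``"regionA--regionB"``
    region-pair labels; ``p`` regions yield ``p(p-1)/2`` features.
    """
    iu = np.triu_indices(theta.p, k=1)
    labels = tuple(
        f"{theta.labels[i]}--{theta.labels[j]}" for i, j in zip(*iu)
    )
    return theta.values[iu].copy(), labels


def mann_whitney_rank(x, y) -> tuple[float, float]:
    """Mann-Whitney U of group ``x`` vs group ``y`` with two-sided p.

    Midranks resolve ties; the p-value uses exact enumeration for group
    sizes up to 8 (tie-free data) and otherwise the normal approximation
    with continuity and tie correction.  Identical pooled values give
    ``p = 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _mann_whitney_pvalues(X: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Vectorized two-sided normal-approximation p-values per column."""
    n1 = int(mask_a.sum())
    n2 = X.shape[0] - n1
    n = n1 + n2
    ranks = stats.rankdata(X, axis=0)
    U = ranks[mask_a].sum(axis=0) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per column
    tie_term = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(U - mu) - 0.5) / np.sqrt(var)
    pvals = np.where(var > 0, 2.0 * stats.norm.sf(np.clip(z, 0.0, None)), 1.0)
    return np.minimum(pvals, 1.0)


def select_features(table: FeatureTable, m: int) -> np.ndarray:
    """Indices of the ``m`` smallest Mann-Whitney p-values.

    Screening uses only the rows supplied (the caller passes training
    rows); ties break by ascending feature index.
    """
    if m > table.X.shape[1]:
        raise ValueError("m exceeds the number of features")
    classes = np.unique(table.y)
    if classes.size != 2:
        raise ValueError("feature screening requires exactly two groups")
    pvals = _mann_whitney_pvalues(table.X, table.y == classes[0])
    return np.argsort(pvals, kind="stable")[:m]


class ShrunkenLDA:
    """LDA with the pooled covariance shrunk toward its diagonal.

    The pooled within-group covariance ``Sigma`` is replaced by
    ``(1 - gamma) * Sigma + gamma * diag(Sigma)``; ``gamma = 1`` gives
    the diagonal-covariance (naive Gaussian) discriminant.  Class priors
    are the training frequencies.
    """

    def __init__(self, gamma: float = 0.5):
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        self.gamma = gamma

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("two classes required")
        n, d = X.shape
        means, priors, scatter = [], [], np.zeros((d, d))
        for c in self.classes_:
            Xc = X[y == c]
            mu = Xc.mean(axis=0)
            means.append(mu)
            priors.append(Xc.shape[0] / n)
            R = Xc - mu
            scatter += R.T @ R
        self.means_ = np.asarray(means)
        self.priors_ = np.asarray(priors)
        sigma = scatter / max(n - 2, 1)
        # zero-variance features (e.g. precision entries that are exactly
        # zero in every subject) get a floor so the diagonal target stays PD
        diag = np.diag(sigma).copy()
        scale = diag.max() if diag.max() > 0 else 1.0
        diag[diag <= 1e-12 * scale] = 1e-8 * scale
        np.fill_diagonal(sigma, diag)
        sigma = (1.0 - self.gamma) * sigma + self.gamma * np.diag(diag)
        try:
            cho = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            cho = None
        # LAPACK tolerates near-zero pivots; demand genuine conditioning
        if cho is None or np.min(np.diag(cho)) ** 2 <= 1e-10 * np.max(np.diag(sigma)):
            raise ValueError(
                "shrunken pooled covariance is singular; increase gamma"
            )
        solve = lambda b: np.linalg.solve(cho.T, np.linalg.solve(cho, b))  # noqa: E731
        self._sigma_inv_means = np.column_stack([solve(mu) for mu in self.means_])
        # discriminant direction toward the second class
        self.weights_ = solve(self.means_[1] - self.means_[0])
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        scores = X @ self._sigma_inv_means
        scores -= 0.5 * np.sum(self.means_.T * self._sigma_inv_means, axis=0)
        scores += np.log(self.priors_)
        return scores

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def knn_predict(X_train, y_train, X_test, k: int):
    """k-nearest-neighbour majority vote with deterministic tie-breaks.

    Euclidean distances; vote ties go to the class with the smaller mean
    neighbour distance, then to the lower class index.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    out = []
    for x in X_test:
        dist = np.linalg.norm(X_train - x, axis=1)
        nn = np.argsort(dist, kind="stable")[:k]
        votes = np.array([np.sum(y_train[nn] == c) for c in classes])
        best = np.nonzero(votes == votes.max())[0]
        if best.size > 1:
            mean_d = np.array(
                [
                    dist[nn][y_train[nn] == classes[b]].mean() if votes[b] else np.inf
                    for b in best
                ]
            )
            best = best[np.argsort(mean_d, kind="stable")]
        out.append(classes[best[0]])
    return np.asarray(out)


def svm_fit(X, y, kernel: str, param: float) -> SVC:
    """Soft-margin SVM (cost 1) with the polynomial or RBF kernel.

    ``kernel="poly"``: ``(1 + <x, x'>)^d`` with degree ``param``;
    ``kernel="rbf"``: ``exp(-||x - x'||^2 / (2 sigma^2))`` with
    bandwidth ``param``.
    """
    if kernel == "poly":
        clf = SVC(C=1.0, kernel="poly", degree=int(param), gamma=1.0, coef0=1.0)
    elif kernel == "rbf":
        clf = SVC(C=1.0, kernel="rbf", gamma=1.0 / (2.0 * param**2))
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return clf.fit(X, y)


def default_grids(n_features: int) -> dict:
    """Hyperparameter grids: feature counts plus one grid per family."""
    counts = [m for m in (10, 25, 50, 100, 200, 310, 385) if m < n_features]
    counts.append(n_features)
    return {
        "m": counts,
        "LDA": [0.1, 0.3, 0.5, 0.7, 0.9, 1.0],
        "kNN": list(range(2, 11)),
        "SVM": list(range(1, 7)),
        "SVMrbf": [10.0**e for e in range(-5, 6)],
    }


@dataclass(frozen=True)
class FoldRecord:
    """What one outer fold selected and fitted."""

    features: np.ndarray
    hyperparam: float
    m: int
    weights: dict | None


@dataclass(frozen=True)
class CVResult:
    """Aggregated nested-CV outcome for one classifier family."""

    confusion: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    per_fold: list
    seed: int
    family: str
    classes: tuple
    feature_labels: tuple[str, ...] = field(default=())


def _standardize(train: np.ndarray, *others):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return tuple((arr - mu) / sd for arr in (train, *others))


def _fit_predict(family, hyper, Xtr, ytr, Xte):
    """Fit one classifier and predict; returns (predictions, weights)."""
    if family == "LDA":
        clf = ShrunkenLDA(gamma=hyper).fit(Xtr, ytr)
        return clf.predict(Xte), clf.weights_
    if family == "kNN":
        return knn_predict(Xtr, ytr, Xte, k=int(hyper)), None
    if family == "SVM":
        return svm_fit(Xtr, ytr, "poly", hyper).predict(Xte), None
    if family == "SVMrbf":
        return svm_fit(Xtr, ytr, "rbf", hyper).predict(Xte), None
    raise ValueError(f"unknown classifier family {family!r}")


def nested_cv(
    table: FeatureTable,
    family: str = "LDA",
    grids: dict | None = None,
    seed: int = 0,
    outer_k: int = 10,
    inner_k: int = 10,
    outer_splits: list | None = None,
) -> CVResult:
    """Nested stratified cross-validation of one classifier family.

    The outer ``outer_k``-fold split estimates generalization; for each
    outer fold an inner ``inner_k``-fold loop over the training rows
    jointly picks the Mann-Whitney feature count ``m`` and the family
    hyperparameter by mean inner validation accuracy (ties prefer fewer
    features, then the earlier grid value).  Screening, standardization
    and fitting always use training rows only.  Outer test predictions
    aggregate into one confusion matrix.  ``outer_splits`` may supply
    precomputed ``(train_idx, test_idx)`` pairs in place of the seeded
    stratified split.
    """
    X, y = table.X, table.y
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("nested_cv handles exactly two groups")
    if y.size < 20:
        warnings.warn("fewer than 20 subjects; estimates will be unstable",
                      RuntimeWarning, stacklevel=2)
    min_class = min(np.sum(y == c) for c in classes)
    if min_class < 2:
        raise ValueError("each group needs at least 2 subjects for stratification")
    outer_k = min(outer_k, min_class)
    grids = grids or default_grids(X.shape[1])
    m_grid = [m for m in grids["m"] if m <= X.shape[1]]
    hyper_grid = grids[family]

    if outer_splits is None:
        outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
        outer_splits = list(outer.split(X, y))
    confusion = np.zeros((2, 2), dtype=int)
    per_fold = []
    for tr, te in outer_splits:
        Xtr_full, ytr = X[tr], y[tr]
        inner_splits = min(inner_k, min(np.sum(ytr == c) for c in classes))
        inner = StratifiedKFold(n_splits=inner_splits, shuffle=True,
                                random_state=seed + 1)
        scores = np.zeros((len(m_grid), len(hyper_grid)))
        for itr, ite in inner.split(Xtr_full, ytr):
            sub = table.rows(tr).rows(itr)
            order = select_features(sub, min(max(m_grid), X.shape[1]))
            for mi, m in enumerate(m_grid):
                cols = order[:m]
                Ztr, Zte = _standardize(Xtr_full[itr][:, cols],
                                        Xtr_full[ite][:, cols])
                for hi, hyper in enumerate(hyper_grid):
                    try:
                        pred, _ = _fit_predict(family, hyper, Ztr, ytr[itr], Zte)
                    except ValueError:
                        scores[mi, hi] = -np.inf
                        continue
                    scores[mi, hi] += np.mean(pred == ytr[ite])
        best = np.unravel_index(np.argmax(scores), scores.shape)
        m_best, hyper_best = m_grid[best[0]], hyper_grid[best[1]]

        cols = select_features(table.rows(tr), m_best)
        Ztr, Zte = _standardize(X[tr][:, cols], X[te][:, cols])
        pred, w = _fit_predict(family, hyper_best, Ztr, ytr, Zte)
        for yi, pi in zip(y[te], pred):
            confusion[int(np.nonzero(classes == yi)[0][0]),
                      int(np.nonzero(classes == pi)[0][0])] += 1
        per_fold.append(
            FoldRecord(
                features=np.asarray(cols),
                hyperparam=hyper_best,
                m=m_best,
                weights=None if w is None else
                {int(c): float(wi) for c, wi in zip(cols, w)},
            )
        )

    n = confusion.sum()
    return CVResult(
        confusion=confusion,
        accuracy=float((confusion[0, 0] + confusion[1, 1]) / n),
        sensitivity=float(confusion[1, 1] / confusion[1].sum()),
        specificity=float(confusion[0, 0] / confusion[0].sum()),
        per_fold=per_fold,
        seed=seed,
        family=family,
        classes=tuple(classes.tolist()),
        feature_labels=table.feature_labels,
    )


def feature_stability(
    result: CVResult,
    top_fraction: float = 0.01,
    min_folds: int = 9,
) -> pd.DataFrame:
    """Fold-stability table of the selected features.

    For every feature: how many folds selected it and (for linear
    classifiers) the median absolute discriminant weight across the
    folds where it was selected.  Features selected in at least
    ``min_folds`` folds are flagged as stable; among those, the top
    ``top_fraction`` of all features by median weight (by selection
    count when no weights exist) are marked ``top``.
    """
    n_features = len(result.feature_labels)
    counts = np.zeros(n_features, dtype=int)
    weight_lists: dict[int, list[float]] = {}
    for rec in result.per_fold:
        for f in rec.features:
            counts[f] += 1
        if rec.weights is not None:
            for f, w in rec.weights.items():
                weight_lists.setdefault(f, []).append(abs(w))
    medians = np.full(n_features, np.nan)
    for f, ws in weight_lists.items():
        medians[f] = float(np.median(ws))
    flagged = counts >= min_folds

    df = pd.DataFrame(
        {
            "feature": np.arange(n_features),
            "label": list(result.feature_labels),
            "count": counts,
            "median_weight": medians,
            "flagged": flagged,
        }
    )
    k = max(1, int(np.ceil(top_fraction * n_features)))
    score = np.where(np.isnan(medians), -np.inf, medians) if weight_lists else counts
    order = df.index[flagged]
    order = order[np.argsort(-np.asarray(score)[order], kind="stable")]
    df["top"] = False
    df.loc[order[:k], "top"] = True
    return df


def subject_network(
    envelopes,
    mode: str,
    fd: ConnectivityMatrix | None = None,
    config: SelectionConfig = SelectionConfig(),
    labels=None,
    strategy: str = "bic",
    cv_k: int = 10,
) -> ConnectivityMatrix:
    """One subject's final precision network for a penalty variant.

    ``strategy="bic"`` selects lambda by BIC on the full recording;
    ``strategy="cv_mean_lambda"`` runs the k-fold likelihood CV and
    refits at the mean of the fold-selected lambdas.
    """
    S = sample_covariance(envelopes, labels)
    W = None if mode == "GL" else weights_for_mode(mode, S, fd)
    if strategy == "bic":
        n_eff = multichannel_ess(envelopes)
        return select_lambda(S, W, n_eff, config, weight_mode=mode).final.theta
    if strategy == "cv_mean_lambda":
        report = crossval_compare(envelopes, mode, fd, k=cv_k, config=config,
                                  labels=labels)
        return glasso_fit(S, report.mean_lam, W, tol=config.tol,
                          max_iter=config.max_iter, weight_mode=mode).theta
    raise ValueError(f"unknown strategy {strategy!r}")


def cohort_feature_table(
    records,
    mode: str,
    config: SelectionConfig = SelectionConfig(),
    strategy: str = "bic",
) -> FeatureTable:
    """Estimate every subject's network and assemble the feature table."""
    rows, labels, groups = [], None, []
    for rec in records:
        theta = subject_network(
            rec.envelopes, mode, fd=rec.fd, config=config,
            labels=rec.fd.labels, strategy=strategy,
        )
        vec, pair_labels = vectorize_precision(theta)
        rows.append(vec)
        labels = labels or pair_labels
        groups.append(rec.group)
    return FeatureTable(np.asarray(rows), labels, np.asarray(groups))
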