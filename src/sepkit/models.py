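"""Supervised and unsupervised provenance modelling of elemental profiles.

Stratified 80/20 splitting, grid-tuned random-forest classification with
k-fold cross-validation, linear discriminant analysis, and three ordination
views (PCA, non-metric MDS, canonical discriminant analysis). Model inputs
are the element concentration columns of a (preferably scaled) profile
table; the group label defaults to the ``site`` column.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial.distance import pdist, squareform
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.manifold import MDS
from sklearn.decomposition import PCA

from .io import LABEL_COLUMNS, concentrations

DEFAULT_GROUP_COL = "site"
DEFAULT_MTRY_GRID = (2, 3, 4)
DEFAULT_NTREE_GRID = (200, 600)


class SingularScatterError(np.linalg.LinAlgError):
    """Within-group scatter is singular; apply the correlation filter first."""


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0
    group_col: str = DEFAULT_GROUP_COL


@dataclass
class ModelReport:
    """Tuning grid, accuracies, confusion matrix, and importances for one run."""

    tuning: pd.DataFrame | None = None
    best_mtry: int | None = None
    best_ntree: int | None = None
    cv_accuracy_pct: float | None = None
    resub_accuracy_pct: float | None = None
    test_accuracy_pct: float | None = None
    confusion: pd.DataFrame | None = None
    misclassified: list[dict] = field(default_factory=list)
    importances: pd.DataFrame | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "tuning": None if self.tuning is None else self.tuning.to_dict("records"),
            "best_mtry": self.best_mtry,
            "best_ntree": self.best_ntree,
            "cv_accuracy_pct": self.cv_accuracy_pct,
            "resub_accuracy_pct": self.resub_accuracy_pct,
            "test_accuracy_pct": self.test_accuracy_pct,
            "confusion": None if self.confusion is None else {
                "labels": list(self.confusion.index),
                "matrix": self.confusion.values.tolist(),
            },
            "misclassified": self.misclassified,
            "importances": None
            if self.importances is None
            else self.importances.to_dict("records"),
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path


def features_and_labels(
    table: pd.DataFrame, group_col: str = DEFAULT_GROUP_COL
) -> tuple[pd.DataFrame, np.ndarray]:
    X = concentrations(table)
    y = table[group_col].to_numpy()
    return X, y


def stratified_split(
    table: pd.DataFrame, spec: SplitSpec | None = None, **kwargs
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group split: round(train_fraction * n) train rows, rest test.

    Rounds half up. If rounding leaves a group with no test sample, one
    random sample is moved to test, so every group is represented on both
    sides. Groups of size 1 are an error. Deterministic under a fixed seed.
    """
    spec = spec or SplitSpec(**kwargs)
    rng = np.random.default_rng([spec.seed, 11])
    train_idx: list[int] = []
    test_idx: list[int] = []
    groups = table[spec.group_col]
    for g in pd.unique(groups):
        idx = np.flatnonzero((groups == g).to_numpy())
        n = idx.size
        if n < 2:
            raise ValueError(f"group {g!r} has a single sample; cannot split")
        n_train = int(np.floor(spec.train_fraction * n + 0.5))
        if n_train >= n:
            n_train = n - 1  # guard: every group contributes >= 1 test sample
        if n_train < 1:
            n_train = 1
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return (
        table.iloc[sorted(train_idx)].reset_index(drop=True),
        table.iloc[sorted(test_idx)].reset_index(drop=True),
    )


def _stratified_fold_ids(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Deal each class's shuffled samples round-robin across k folds.

    Unlike strict stratification this tolerates classes with fewer than k
    members (a fold simply lacks that class in its held-out part), which is
    required for 5-fold CV on 4-per-class training sets.
    """
    fold = np.empty(len(y), dtype=int)
    for cls in pd.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        offset = int(rng.integers(k))
        fold[idx] = (offset + np.arange(idx.size)) % k
    return fold


def _cv_accuracy(
    X: pd.DataFrame, y: np.ndarray, mtry: int, ntree: int, k: int, seed: int
) -> float:
    rng = np.random.default_rng([seed, 13, mtry, ntree])
    fold = _stratified_fold_ids(y, k, rng)
    correct = 0
    for f in range(k):
        tr = fold != f
        te = fold == f
        if not te.any():
            continue
        clf = RandomForestClassifier(
            n_estimators=ntree, max_features=mtry, random_state=seed
        )
        clf.fit(X[tr], y[tr])
        correct += int((clf.predict(X[te]) == y[te]).sum())
    return 100.0 * correct / len(y)


def tune_random_forest(
    train: pd.DataFrame,
    mtry_grid: tuple[int, ...] = DEFAULT_MTRY_GRID,
    ntree_grid: tuple[int, ...] = DEFAULT_NTREE_GRID,
    k_folds: int = 5,
    seed: int = 0,
    group_col: str = DEFAULT_GROUP_COL,
) -> tuple[RandomForestClassifier, ModelReport]:
    """Grid-search (mtry, ntree) by k-fold CV accuracy on the training set.

    Ties are broken toward smaller ntree, then smaller mtry. Cells with
    mtry exceeding the number of elements are skipped with a warning. The
    best model is refit on the full training set; per-element importances
    report both mean decrease in Gini impurity and permutation (accuracy)
    importance.
    """
    if not mtry_grid or not ntree_grid:
        raise ValueError("tuning grid must be nonempty")
    X, y = features_and_labels(train, group_col)
    rows = []
    for ntree in sorted(ntree_grid):
        for mtry in sorted(mtry_grid):
            if mtry > X.shape[1]:
                warnings.warn(
                    f"skipping mtry={mtry}: only {X.shape[1]} elements", stacklevel=2
                )
                continue
            acc = _cv_accuracy(X, y, mtry, ntree, k_folds, seed)
            rows.append({"mtry": mtry, "ntree": ntree, "cv_accuracy_pct": acc})
    if not rows:
        raise ValueError("every grid cell was skipped")
    tuning = pd.DataFrame(rows)
    best = tuning.sort_values(
        ["cv_accuracy_pct", "ntree", "mtry"], ascending=[False, True, True]
    ).iloc[0]

    model = RandomForestClassifier(
        n_estimators=int(best["ntree"]), max_features=int(best["mtry"]), random_state=seed
    )
    model.fit(X, y)
    resub = 100.0 * float((model.predict(X) == y).mean())
    perm = permutation_importance(model, X, y, n_repeats=10, random_state=seed)
    importances = pd.DataFrame(
        {
            "element": X.columns,
            "mean_decrease_accuracy": perm.importances_mean,
            "mean_decrease_gini": model.feature_importances_,
        }
    )
    report = ModelReport(
        tuning=tuning,
        best_mtry=int(best["mtry"]),
        best_ntree=int(best["ntree"]),
        cv_accuracy_pct=float(best["cv_accuracy_pct"]),
        resub_accuracy_pct=resub,
        importances=importances,
        seed=seed,
    )
    return model, report


def evaluate_classifier(
    model, test: pd.DataFrame, group_col: str = DEFAULT_GROUP_COL
) -> tuple[float, pd.DataFrame, list[dict]]:
    """Test accuracy (%), labelled confusion matrix, misclassification list."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    X, y = features_and_labels(test, group_col)
    fitted_roster = list(getattr(model, "feature_names_in_", X.columns))
    if list(X.columns) != fitted_roster:
        raise ValueError(
            f"element roster mismatch: model fitted on {fitted_roster}, "
            f"test has {list(X.columns)}"
        )
    pred = model.predict(X)
    labels = sorted(set(y) | set(pred))
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, p in zip(y, pred):
        confusion.loc[t, p] += 1
    mis = [
        {"sample_id": sid, "true": t, "predicted": p}
        for sid, t, p in zip(test["sample_id"], y, pred)
        if t != p
    ]
    accuracy = 100.0 * float((pred == y).mean())
    return accuracy, confusion, mis


def fit_lda(
    train: pd.DataFrame, group_col: str = DEFAULT_GROUP_COL
) -> tuple[LinearDiscriminantAnalysis, float]:
    """Linear discriminant classifier; returns resubstitution accuracy (%)."""
    X, y = features_and_labels(train, group_col)
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        singles = list(counts.index[counts < 2])
        raise ValueError(f"each class needs > 1 sample; offending: {singles}")
    _check_within_scatter(X.to_numpy(dtype=float), y)
    model = LinearDiscriminantAnalysis()
    model.fit(X, y)
    resub = 100.0 * float((model.predict(X) == y).mean())
    return model, resub


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained_pct: np.ndarray


def pca(table: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Principal components of the (scaled) element matrix.

    Variance explained is reported in percent and sums to 100 over all
    components. Requests beyond the data rank are truncated with a warning.
    """
    X = concentrations(table)
    max_rank = min(len(X) - 1 if len(X) > 1 else 1, X.shape[1])
    if n_components is not None and n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {max_rank}; truncating",
            stacklevel=2,
        )
        n_components = max_rank
    fit = PCA(n_components=n_components).fit(X)
    scores = fit.transform(X)
    axes = [f"PC{i + 1}" for i in range(scores.shape[1])]
    score_df = pd.DataFrame(scores, columns=axes)
    for col in LABEL_COLUMNS:
        if col in table.columns:
            score_df.insert(0, col, table[col].to_numpy())
    loadings = pd.DataFrame(fit.components_.T, index=X.columns, columns=axes)
    return PCAResult(
        scores=score_df,
        loadings=loadings,
        variance_explained_pct=100.0 * fit.explained_variance_ratio_,
    )


@dataclass(frozen=True)
class NMDSResult:
    coordinates: pd.DataFrame
    stress: float
    distance: str
    k: int


def nmds(
    table: pd.DataFrame,
    distance: str = "euclidean",
    k: int = 2,
    seed: int = 0,
    n_init: int = 8,
) -> NMDSResult:
    """Non-metric MDS minimizing Kruskal stress-1 over multiple seeded starts."""
    X = concentrations(table).to_numpy(dtype=float)
    if len(X) < k + 1:
        raise ValueError(f"need at least {k + 1} samples for a {k}-d configuration")
    d = pdist(X, metric=distance)
    if np.ptp(d) == 0.0:
        raise ValueError("degenerate distances: all pairwise distances equal")
    kwargs: dict = dict(
        n_components=k,
        n_init=n_init,
        max_iter=500,
        eps=1e-9,
        random_state=seed,
        normalized_stress=True,
    )
    # sklearn >= 1.9 renamed metric= -> metric_mds= and dissimilarity= ->
    # metric=; support both API generations
    import inspect

    params = inspect.signature(MDS.__init__).parameters
    if "metric_mds" in params:
        kwargs["metric_mds"] = False
        kwargs["metric"] = "precomputed"
        if "init" in params:
            kwargs["init"] = "random"
    else:  # pragma: no cover - older sklearn
        kwargs["metric"] = False
        kwargs["dissimilarity"] = "precomputed"
    mds = MDS(**kwargs)
    coords = mds.fit_transform(squareform(d))
    axes = [f"NMDS{i + 1}" for i in range(k)]
    coord_df = pd.DataFrame(coords, columns=axes)
    for col in LABEL_COLUMNS:
        if col in table.columns:
            coord_df.insert(0, col, table[col].to_numpy())
    return NMDSResult(coordinates=coord_df, stress=float(mds.stress_), distance=distance, k=k)


@dataclass(frozen=True)
class CDAResult:
    scores: pd.DataFrame
    eigenvalues: np.ndarray
    structure: pd.DataFrame   # element x axis correlations
    centroids: pd.DataFrame


def _scatter_matrices(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    grand = X.mean(axis=0)
    p = X.shape[1]
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in pd.unique(y):
        Xg = X[y == g]
        mg = Xg.mean(axis=0)
        centered = Xg - mg
        W += centered.T @ centered
        dm = (mg - grand)[:, None]
        B += Xg.shape[0] * (dm @ dm.T)
    return W, B


def _check_within_scatter(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    W, _ = _scatter_matrices(X, y)
    eigvals = np.linalg.eigvalsh(W)
    if eigvals[-1] <= 0 or eigvals[0] / eigvals[-1] < 1e-10:
        raise SingularScatterError(
            "within-group scatter is singular; remove collinear elements "
            "(apply the correlation filter) before discriminant analysis"
        )
    return W


def cda(
    table: pd.DataFrame, group_col: str = DEFAULT_GROUP_COL, n_axes: int | None = None
) -> CDAResult:
    """Canonical variates of between- vs within-group scatter.

    At most min(groups - 1, elements) axes. Axes are scaled to unit pooled
    within-group variance. Structure coefficients are the correlations of
    each element with each canonical axis.
    """
    X_df, y = features_and_labels(table, group_col)
    X = X_df.to_numpy(dtype=float)
    groups = pd.unique(y)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    _check_within_scatter(X, y)
    W, B = _scatter_matrices(X, y)
    try:
        eigvals, eigvecs = linalg.eigh(B, W)
    except linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise SingularScatterError(str(exc)) from exc
    order = np.argsort(eigvals)[::-1]
    r = min(len(groups) - 1, X.shape[1])
    if n_axes is not None:
        r = min(r, n_axes)
    eigvals = np.maximum(eigvals[order][:r], 0.0)
    V = eigvecs[:, order][:, :r]
    # unit pooled within-group variance per axis
    n_minus_g = X.shape[0] - len(groups)
    for a in range(r):
        s = float(V[:, a] @ W @ V[:, a]) / max(n_minus_g, 1)
        if s > 0:
            V[:, a] = V[:, a] / np.sqrt(s)

    scores = (X - X.mean(axis=0)) @ V
    axes = [f"CAN{i + 1}" for i in range(r)]
    score_df = pd.DataFrame(scores, columns=axes)
    for col in LABEL_COLUMNS:
        if col in table.columns:
            score_df.insert(0, col, table[col].to_numpy())

    structure = np.zeros((X.shape[1], r))
    for j in range(X.shape[1]):
        xj = X[:, j]
        if np.ptp(xj) == 0:
            continue
        for a in range(r):
            structure[j, a] = float(np.corrcoef(xj, scores[:, a])[0, 1])
    structure_df = pd.DataFrame(structure, index=X_df.columns, columns=axes)
    centroids = score_df.groupby(group_col)[axes].mean()
    return CDAResult(
        scores=score_df, eigenvalues=eigvals, structure=structure_df, centroids=centroids
    )
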