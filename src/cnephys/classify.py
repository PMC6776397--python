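"""Standardization, LDA/PCA classification, cross-validation and effect sizes.

The discriminant axes are computed from the generalized eigenproblem
``Sb w = lambda Sw w`` on the between-class (Sb) and pooled within-class
(Sw) scatter matrices of the standardized feature table; with c classes at
most c - 1 components have nonzero separation.  Prediction is nearest class
centroid in discriminant space (equal priors by default; empirical priors
add a log-prior term).  The PCA comparison scores the same nearest-centroid
rule in the top principal-component space, under the identical
cross-validation protocol.

Conventions fixed repo-wide: z-scores and fold-accuracy SDs use the sample
convention (ddof=1); folds are stratified by class; the FDR correction is
Benjamini-Hochberg.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from statsmodels.stats.multitest import multipletests

from .tables import MEASURES, FeatureTable

DEFAULT_FOLDS = 10
SUBSET_SPLITS = 5
_SHRINKAGE = 1e-8


class ClassificationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# standardization and imputation


@dataclass
class Standardizer:
    """Per-column z-scoring with stored train statistics (sample SD)."""

    means: pd.Series | None = None
    sds: pd.Series | None = None

    def fit(self, values: pd.DataFrame) -> "Standardizer":
        for col in values.columns:
            if values[col].notna().sum() < 2:
                raise ClassificationError(f"column {col!r} has fewer than 2 non-missing values")
        self.means = values.mean(skipna=True)
        self.sds = values.std(ddof=1, skipna=True)
        zero = self.sds[self.sds == 0].index.tolist()
        if zero:
            raise ClassificationError(f"zero-variance column(s): {zero}")
        return self

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        if self.means is None:
            raise ClassificationError("Standardizer not fitted")
        return (values - self.means) / self.sds


def standardize(table: FeatureTable) -> tuple[FeatureTable, Standardizer]:
    """Z-score every measure column; missing values stay missing."""
    sc = Standardizer().fit(table.values)
    return FeatureTable(sc.transform(table.values), table.labels, table.meta), sc


IMPUTE_POLICIES = ("column-median", "fixed-value", "drop-cell")


@dataclass
class Imputer:
    """Missing-value policy with stored train fills and an imputation mask."""

    policy: str = "column-median"
    fill_value: float = 0.0
    fills: pd.Series | None = None
    mask: pd.DataFrame | None = None

    def fit(self, values: pd.DataFrame) -> "Imputer":
        if self.policy not in IMPUTE_POLICIES:
            raise ClassificationError(
                f"unknown imputation policy {self.policy!r}; expected one of {IMPUTE_POLICIES}"
            )
        if self.policy == "column-median":
            all_missing = [c for c in values.columns if values[c].isna().all()]
            if all_missing:
                raise ClassificationError(f"all-missing column(s): {all_missing}")
            self.fills = values.median(skipna=True)
        elif self.policy == "fixed-value":
            self.fills = pd.Series(self.fill_value, index=values.columns)
        return self

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        self.mask = values.isna()
        if self.policy == "drop-cell":
            return values.dropna(axis=0)
        return values.fillna(self.fills)


def impute_missing(table: FeatureTable, policy: str = "column-median", fill_value: float = 0.0):
    """Apply a missing-value policy; returns (table, fitted Imputer)."""
    imp = Imputer(policy=policy, fill_value=fill_value).fit(table.values)
    filled = imp.transform(table.values)
    return FeatureTable(filled, table.labels.loc[filled.index], table.meta.loc[filled.index]), imp


# ---------------------------------------------------------------------------
# models


@dataclass
class LDAModel:
    """Fisher discriminant axes with a nearest-centroid decision rule."""

    priors: str = "equal"  # or "empirical"
    classes_: np.ndarray | None = None
    scalings_: np.ndarray | None = None       # features x components
    variance_explained_: np.ndarray | None = None
    centroids_: np.ndarray | None = None      # classes x components
    log_priors_: np.ndarray | None = None
    xbar_: np.ndarray | None = None
    shrinkage_used_: bool = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LDAModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ClassificationError("LDA needs at least 2 classes")
        counts = np.bincount(y_idx)
        if counts.min() < 2:
            small = classes[counts < 2].tolist()
            raise ClassificationError(f"classes with fewer than 2 cells: {small}")
        n, p = X.shape
        xbar = X.mean(axis=0)
        Sw = np.zeros((p, p))
        Sb = np.zeros((p, p))
        for k in range(classes.size):
            Xk = X[y_idx == k]
            mk = Xk.mean(axis=0)
            d = Xk - mk
            Sw += d.T @ d
            m = (mk - xbar)[:, None]
            Sb += Xk.shape[0] * (m @ m.T)
        try:
            evals, evecs = scipy.linalg.eigh(Sb, Sw)
        except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
            self.shrinkage_used_ = True
            eps = _SHRINKAGE * max(np.trace(Sw) / p, 1.0)
            Sw = Sw + eps * np.eye(p)
            evals, evecs = scipy.linalg.eigh(Sb, Sw)
        order = np.argsort(evals)[::-1]
        m_comp = min(classes.size - 1, p)
        evals = np.clip(evals[order][:m_comp], 0.0, None)
        W = evecs[:, order][:, :m_comp]
        total = evals.sum()
        self.classes_ = classes
        self.scalings_ = W
        self.variance_explained_ = evals / total if total > 0 else evals
        self.xbar_ = xbar
        proj = (X - xbar) @ W
        self.centroids_ = np.vstack([proj[y_idx == k].mean(axis=0) for k in range(classes.size)])
        pri = counts / n if self.priors == "empirical" else np.full(classes.size, 1.0 / classes.size)
        self.log_priors_ = np.log(pri)
        return self

    @property
    def n_components(self) -> int:
        return self.scalings_.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.xbar_) @ self.scalings_

    def predict(self, X: np.ndarray) -> np.ndarray:
        proj = self.transform(X)
        d2 = ((proj[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        scores = -0.5 * d2 + self.log_priors_
        return self.classes_[np.argmax(scores, axis=1)]


@dataclass
class PCACentroidModel:
    """Unsupervised principal axes; nearest class centroid in PC score space."""

    n_components: int = 5
    pca_: PCA | None = None
    classes_: np.ndarray | None = None
    centroids_: np.ndarray | None = None
    variance_explained_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PCACentroidModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        m = min(self.n_components, X.shape[1], X.shape[0] - 1)
        self.pca_ = PCA(n_components=m).fit(X)
        self.variance_explained_ = self.pca_.explained_variance_ratio_
        scores = self.pca_.transform(X)
        self.classes_ = np.unique(y)
        self.centroids_ = np.vstack([scores[y == c].mean(axis=0) for c in self.classes_])
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca_.transform(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.transform(X)
        d2 = ((scores[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]


def _make_model(model: str, priors: str = "equal", n_components: int = 5):
    if model == "lda":
        return LDAModel(priors=priors)
    if model == "pca":
        return PCACentroidModel(n_components=n_components)
    raise ClassificationError(f"unknown model {model!r}; expected 'lda' or 'pca'")


# ---------------------------------------------------------------------------
# results containers


@dataclass
class ClassificationResult:
    """LDA (or PCA) summary for one cohort."""

    model: str
    classes: list[str]
    component_loadings: pd.DataFrame      # measures x components
    projections: pd.DataFrame             # cells x components
    variance_explained: np.ndarray
    cv_accuracy_mean: float
    cv_accuracy_sd: float
    confusion: pd.DataFrame               # row-normalized proportions
    per_measure_r2: pd.DataFrame | None = None

    def to_summary(self) -> dict:
        return {
            "model": self.model,
            "classes": self.classes,
            "n_components": int(self.component_loadings.shape[1]),
            "variance_explained": [float(v) for v in self.variance_explained],
            "cv_accuracy_mean": float(self.cv_accuracy_mean),
            "cv_accuracy_sd": float(self.cv_accuracy_sd),
        }


# ---------------------------------------------------------------------------
# fitting and validation


def _prepared(table: FeatureTable, impute: str = "column-median"):
    """standardize -> impute on the full table; returns (X, y, index, columns)."""
    std, _ = standardize(table)
    filled, _ = impute_missing(std, policy=impute)
    return filled.values.to_numpy(), filled.labels.to_numpy(), filled.values.index, filled.values.columns


def fit_lda(table: FeatureTable, priors: str = "equal", impute: str = "column-median") -> tuple[LDAModel, ClassificationResult]:
    """Fit the discriminant axes on the full (standardized, imputed) table."""
    X, y, index, columns = _prepared(table, impute)
    model = LDAModel(priors=priors).fit(X, y)
    comp_names = [f"LD{i + 1}" for i in range(model.n_components)]
    pred = model.predict(X)
    conf = confusion(y, pred, classes=list(model.classes_))
    result = ClassificationResult(
        model="lda",
        classes=list(model.classes_),
        component_loadings=pd.DataFrame(model.scalings_, index=columns, columns=comp_names),
        projections=pd.DataFrame(model.transform(X), index=index, columns=comp_names),
        variance_explained=model.variance_explained_,
        cv_accuracy_mean=float("nan"),
        cv_accuracy_sd=float("nan"),
        confusion=conf,
    )
    return model, result


def fit_pca(table: FeatureTable, n_components: int = 5, impute: str = "column-median") -> tuple[PCACentroidModel, ClassificationResult]:
    """Principal axes of the standardized measures, with centroid prediction."""
    X, y, index, columns = _prepared(table, impute)
    model = PCACentroidModel(n_components=n_components).fit(X, y)
    comp_names = [f"PC{i + 1}" for i in range(model.pca_.n_components_)]
    pred = model.predict(X)
    conf = confusion(y, pred, classes=list(model.classes_))
    result = ClassificationResult(
        model="pca",
        classes=list(model.classes_),
        component_loadings=pd.DataFrame(model.pca_.components_.T, index=columns, columns=comp_names),
        projections=pd.DataFrame(model.transform(X), index=index, columns=comp_names),
        variance_explained=model.variance_explained_,
        cv_accuracy_mean=float("nan"),
        cv_accuracy_sd=float("nan"),
        confusion=conf,
    )
    return model, result


def cross_validate(
    table: FeatureTable,
    k: int = DEFAULT_FOLDS,
    model: str = "lda",
    seed: int = 0,
    priors: str = "equal",
    impute: str = "column-median",
    n_components: int = 5,
    columns: list[str] | None = None,
    return_predictions: bool = False,
):
    """Stratified k-fold CV of standardize -> impute -> model.

    All statistics (z-score means/SDs, imputation fills, the model) are fit
    on the training split only and applied to the held-out split.  Returns
    (mean, sd) of fold accuracies, plus out-of-fold predictions when
    requested.
    """
    if k < 2:
        raise ClassificationError("k must be >= 2")
    values = table.values if columns is None else table.values[list(columns)]
    y = table.labels.to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        small = counts[counts < k]
        raise ClassificationError(
            f"stratified {k}-fold CV impossible; classes smaller than k: {small.to_dict()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    oof = pd.Series(index=values.index, dtype=object)
    for train_idx, test_idx in skf.split(values, y):
        tr, te = values.iloc[train_idx], values.iloc[test_idx]
        sc = Standardizer().fit(tr)
        imp = Imputer(policy=impute if impute != "drop-cell" else "column-median").fit(sc.transform(tr))
        Xtr = imp.transform(sc.transform(tr)).to_numpy()
        Xte = imp.transform(sc.transform(te)).to_numpy()
        clf = _make_model(model, priors=priors, n_components=n_components)
        clf.fit(Xtr, y[train_idx])
        pred = clf.predict(Xte)
        accs.append(float(np.mean(pred == y[test_idx])))
        oof.iloc[test_idx] = pred
    mean = float(np.mean(accs))
    sd = float(np.std(accs, ddof=1))
    if return_predictions:
        return mean, sd, oof
    return mean, sd


def confusion(y_true, y_pred, classes: list[str]) -> pd.DataFrame:
    """Row-normalized confusion matrix (rows = true class)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    mat = np.zeros((len(classes), len(classes)))
    pos = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        mat[pos[t], pos[p]] += 1
    sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        mat = np.where(sums > 0, mat / sums, np.nan)
    return pd.DataFrame(mat, index=classes, columns=classes)


def measure_r2(table: FeatureTable, impute: str = "column-median") -> pd.DataFrame:
    """Per-measure eta-squared effect size with BH-FDR-adjusted p-values.

    eta^2 = SS_between / SS_total on the standardized values; the p-value
    is from a one-way between-class F test; the FDR adjustment runs across
    all measures simultaneously.
    """
    std, _ = standardize(table)
    y = std.labels.to_numpy()
    classes = np.unique(y)
    if classes.size < 2:
        raise ClassificationError("need at least 2 classes")
    rows = []
    for m in std.values.columns:
        col = std.values[m]
        ok = col.notna().to_numpy()
        x, g = col.to_numpy()[ok], y[ok]
        groups = [x[g == c] for c in classes if (g == c).sum() > 0]
        grand = x.mean()
        ss_total = float(((x - grand) ** 2).sum())
        ss_between = float(sum(len(gr) * (gr.mean() - grand) ** 2 for gr in groups))
        if ss_total == 0:
            rows.append({"measure": m, "r2": np.nan, "p": np.nan, "flag": "constant"})
            continue
        f, p = stats.f_oneway(*groups)
        rows.append({"measure": m, "r2": ss_between / ss_total, "p": float(p), "flag": ""})
    df = pd.DataFrame(rows).set_index("measure")
    ok = df["p"].notna()
    adj = np.full(len(df), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    df["p_fdr"] = adj
    return df


# ---------------------------------------------------------------------------
# subset search


@dataclass
class SubsetSearchResult:
    """Exhaustive feature-subset accuracy search."""

    per_subset: pd.DataFrame   # columns: size, members, accuracy_mean, accuracy_sd
    per_size: pd.DataFrame     # columns: size, n_subsets, mean, best5_mean, worst


def combination_search(
    table: FeatureTable,
    sizes,
    seed: int = 0,
    n_splits: int = SUBSET_SPLITS,
    test_size: float = 0.2,
    impute: str = "column-median",
    measures: tuple[str, ...] | None = None,
    progress=None,
) -> SubsetSearchResult:
    """LDA accuracy for every measure subset of the requested sizes.

    Each subset is scored with ``n_splits`` repeated stratified train/test
    splits (the split pattern is shared across subsets of a run, so
    comparisons are paired).  ``measures`` restricts the pool being
    combined (default: all 12).
    """
    measures = tuple(measures) if measures is not None else MEASURES
    sizes = sorted(set(int(s) for s in sizes))
    if any(s < 1 or s > len(measures) for s in sizes):
        raise ClassificationError(f"sizes must lie in 1..{len(measures)}, got {sizes}")
    y = table.labels.to_numpy()
    sss = StratifiedShuffleSplit(n_splits=n_splits, test_size=test_size, random_state=seed)
    splits = list(sss.split(table.values, y))
    rows = []
    for size in sizes:
        for members in itertools.combinations(measures, size):
            vals = table.values[list(members)]
            accs = []
            for train_idx, test_idx in splits:
                tr, te = vals.iloc[train_idx], vals.iloc[test_idx]
                try:
                    sc = Standardizer().fit(tr)
                    imp = Imputer(policy="column-median").fit(sc.transform(tr))
                    clf = LDAModel().fit(imp.transform(sc.transform(tr)).to_numpy(), y[train_idx])
                except ClassificationError:
                    continue  # e.g. a constant column inside a split
                pred = clf.predict(imp.transform(sc.transform(te)).to_numpy())
                accs.append(float(np.mean(pred == y[test_idx])))
            rows.append(
                {
                    "size": size,
                    "members": "+".join(members),
                    "accuracy_mean": float(np.mean(accs)) if accs else np.nan,
                    "accuracy_sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else np.nan,
                }
            )
        if progress is not None:
            progress(size, len(rows))
    per_subset = pd.DataFrame(rows)
    size_rows = []
    for size, grp in per_subset.groupby("size"):
        accs = grp["accuracy_mean"].dropna().sort_values(ascending=False)
        best5 = accs.iloc[: min(5, len(accs))]
        size_rows.append(
            {
                "size": size,
                "n_subsets": len(grp),
                "mean": float(accs.mean()),
                "best5_mean": float(best5.mean()),
                "worst": float(accs.min()),
            }
        )
    return SubsetSearchResult(per_subset=per_subset, per_size=pd.DataFrame(size_rows))
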