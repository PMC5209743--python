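"""Statistical and machine-learning layer over descriptor datasets.

Implements the calibration analytics: per-descriptor t-test matrices,
3-component PCA of the standardized descriptors, a maximum-margin
classifier calibrated on chemically "opened" vs "closed" chromatin
cohorts, k-means centroids in score space, the phenotype parsing index,
the open chromatin index from immunogold counts, sensitized-emission
FRET efficiency, and min-max normalized condition heat maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import (
    BadKError,
    DegenerateAxisError,
    DegenerateMarginWarning,
    EmptyCohortError,
    TooFewConditionsError,
    TooFewSamplesError,
    ZeroAcceptorError,
    ZeroCountsError,
)
from .texture import descriptor_names

N_COMPONENTS = 3


@dataclass
class DescriptorDataset:
    """An n x 104 descriptor matrix with one condition label per nucleus."""

    features: pd.DataFrame
    condition: pd.Series
    timepoint: pd.Series | None = None

    def __post_init__(self):
        X = self.features.to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("descriptor matrix contains non-finite values")
        self.condition = pd.Series(
            np.asarray(self.condition), index=self.features.index
        )

    @classmethod
    def from_rows(
        cls, rows: list[pd.Series], conditions: list[str]
    ) -> "DescriptorDataset":
        return cls(pd.DataFrame(rows).reset_index(drop=True), pd.Series(conditions))

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def matrix(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    def subset(self, cond: str) -> "DescriptorDataset":
        keep = (self.condition == cond).to_numpy()
        return DescriptorDataset(
            self.features.loc[keep].reset_index(drop=True),
            self.condition.loc[keep].reset_index(drop=True),
        )

    def condition_means(self) -> pd.DataFrame:
        """Per-condition descriptor means, in first-appearance order."""
        order = list(dict.fromkeys(self.condition))
        grouped = self.features.groupby(self.condition, sort=False).mean()
        return grouped.loc[order]


def ttest_matrix(
    treated: DescriptorDataset,
    control: DescriptorDataset,
    welch: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Two-sided two-sample t-test p-value for every descriptor.

    Default is the equal-variance (pooled) Student form; ``welch`` selects
    the unequal-variance variant.  ``fdr`` adds a Benjamini-Hochberg
    adjusted column (raw p-values are always reported, matching how the
    treated-vs-untreated heat maps are drawn).
    """
    for ds in (treated, control):
        if ds.n < 2:
            raise TooFewSamplesError("each group needs >= 2 rows")
    t_stat, p = stats.ttest_ind(
        treated.matrix, control.matrix, axis=0, equal_var=not welch
    )
    p = np.where(np.isnan(p), 1.0, p)
    out = pd.DataFrame(
        {"t": t_stat, "p_value": p}, index=treated.features.columns
    )
    if fdr:
        out["p_adjusted"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out


@dataclass
class Embedding:
    """Standardization plus a 3-component PCA basis for descriptor data."""

    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray                 # 104 x 3, orthonormal columns
    scores: np.ndarray                   # n x 3 (training scores)
    explained_variance_fraction: np.ndarray
    feature_names: list[str] = field(default_factory=descriptor_names)

    def transform(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = np.asarray(
            X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=float
        )
        return (X - self.center) / self.scale @ self.loadings

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_fraction": self.explained_variance_fraction.tolist(),
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Embedding":
        return cls(
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            scores=np.empty((0, N_COMPONENTS)),
            explained_variance_fraction=np.asarray(
                d["explained_variance_fraction"], dtype=float
            ),
            feature_names=list(d["feature_names"]),
        )


def fit_pca3(data: DescriptorDataset) -> Embedding:
    """Standardize the descriptors and fit the top-3 principal components.

    Columns are z-scored (zero-variance columns get unit scale so they
    contribute nothing); loadings are eigenvectors of the correlation
    structure with each column's sign fixed so its largest-magnitude
    coefficient is positive; scores are the standardized data projected
    onto the loadings.
    """
    if data.n < 4:
        raise TooFewSamplesError("PCA needs at least 4 samples")
    X = data.matrix
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale = np.where(scale > 1e-12, scale, 1.0)
    Z = (X - center) / scale
    pca = PCA(n_components=N_COMPONENTS, svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.T.copy()
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
    scores = Z @ loadings
    return Embedding(
        center=center,
        scale=scale,
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        feature_names=list(data.features.columns),
    )


@dataclass
class ChromatinClassifier:
    """Open/closed chromatin decision rule over 3-D PC scores.

    The margin is positive on the "open" side (cells with suppressed
    repressive-mark deposition) and negative on the "closed" side.
    """

    svc: SVC
    embedding: Embedding
    mode: str                       # "pc3" or "feature104"
    calibration: dict

    def _space(self, data: DescriptorDataset) -> np.ndarray:
        if self.mode == "pc3":
            return self.embedding.transform(data.features)
        return (data.matrix - self.embedding.center) / self.embedding.scale

    def margin(self, data: DescriptorDataset) -> np.ndarray:
        return self.svc.decision_function(self._space(data))

    def predict(self, data: DescriptorDataset) -> np.ndarray:
        return self.svc.predict(self._space(data))


def train_classifier(
    open_set: DescriptorDataset,
    closed_set: DescriptorDataset,
    embedding: Embedding,
    seed: int = 0,
    mode: str = "pc3",
) -> ChromatinClassifier:
    """Fit the maximum-margin linear classifier on two calibration cohorts.

    ``open_set`` plays the role of the DZNep-like (opened chromatin)
    cohort and ``closed_set`` the MTA-like (closed chromatin) cohort.
    """
    if open_set.n == 0 or closed_set.n == 0:
        raise EmptyCohortError("both calibration cohorts must be non-empty")
    clf = ChromatinClassifier(
        svc=SVC(kernel="linear", C=1.0, random_state=seed),
        embedding=embedding,
        mode=mode,
        calibration={"open_n": open_set.n, "closed_n": closed_set.n, "seed": seed},
    )
    X = np.vstack([clf._space(closed_set), clf._space(open_set)])
    # label order: sorted classes are ('closed', 'open'), so the decision
    # function is positive on the open side
    y = np.array(["closed"] * closed_set.n + ["open"] * open_set.n)
    mean_gap = np.linalg.norm(
        clf._space(open_set).mean(axis=0) - clf._space(closed_set).mean(axis=0)
    )
    spread = max(X.std(), 1e-12)
    if mean_gap < 1e-9 * spread or mean_gap == 0.0:
        warnings.warn(
            "calibration cohorts coincide; margin is degenerate",
            DegenerateMarginWarning,
        )
    clf.svc.fit(X, y)
    return clf


@dataclass
class ClassifierEvaluation:
    """Per-class sensitivity/specificity from stratified cross-validation."""

    per_class: pd.DataFrame          # index = class, cols = sensitivity, specificity
    accuracy: float
    n_folds: int

    @property
    def macro_sensitivity(self) -> float:
        return float(self.per_class["sensitivity"].mean())

    @property
    def macro_specificity(self) -> float:
        return float(self.per_class["specificity"].mean())


def _make_pipeline(seed: int, mode: str) -> Pipeline:
    steps = [("scale", StandardScaler())]
    if mode == "pc3":
        steps.append(("pca", PCA(n_components=N_COMPONENTS, svd_solver="full")))
    steps.append(
        ("svm", SVC(kernel="linear", C=1.0, decision_function_shape="ovr",
                    random_state=seed))
    )
    return Pipeline(steps)


def evaluate_classifier(
    data: DescriptorDataset,
    labels: np.ndarray | pd.Series | None = None,
    seed: int = 0,
    n_folds: int = 5,
    mode: str = "pc3",
) -> ClassifierEvaluation:
    """Stratified k-fold cross-validation of the PCA+SVM pipeline.

    The standardization, PCA and SVM are refit inside every training fold.
    Sensitivity is TP/(TP+FN) and specificity TN/(TN+FP), one-vs-rest per
    class; macro averages are their unweighted means.
    """
    y = np.asarray(labels if labels is not None else data.condition)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise TooFewSamplesError("need >= 2 classes")
    if counts.min() < 4:
        raise TooFewSamplesError("every class needs >= 4 samples")
    X = data.matrix
    n_folds = min(n_folds, int(counts.min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    for train_idx, test_idx in skf.split(X, y):
        pipe = _make_pipeline(seed, mode)
        pipe.fit(X[train_idx], y[train_idx])
        y_pred[test_idx] = pipe.predict(X[test_idx])
    return ClassifierEvaluation(
        per_class=sensitivity_specificity(y, y_pred),
        accuracy=float(np.mean(y_pred == y)),
        n_folds=n_folds,
    )


def sensitivity_specificity(y_true, y_pred) -> pd.DataFrame:
    """One-vs-rest sensitivity TP/(TP+FN) and specificity TN/(TN+FP)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    rows = {}
    for cls_name in np.unique(y_true):
        tp = np.sum((y_true == cls_name) & (y_pred == cls_name))
        fn = np.sum((y_true == cls_name) & (y_pred != cls_name))
        tn = np.sum((y_true != cls_name) & (y_pred != cls_name))
        fp = np.sum((y_true != cls_name) & (y_pred == cls_name))
        rows[cls_name] = {
            "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
            "specificity": tn / (tn + fp) if tn + fp else 0.0,
        }
    return pd.DataFrame(rows).T


@dataclass
class ClusterResult:
    """K-means centroids, assignments and inertia in 3-D score space."""

    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float

    def centroid_distances(self) -> np.ndarray:
        """Pairwise Euclidean distances between centroids."""
        diff = self.centroids[:, None, :] - self.centroids[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))


def kmeans_centroids(scores: np.ndarray, k: int, seed: int = 0) -> ClusterResult:
    """Lloyd's k-means on PC scores, 10 seeded restarts, best inertia kept."""
    scores = np.asarray(scores, dtype=float)
    if k < 1 or k > len(scores):
        raise BadKError(f"k={k} with n={len(scores)}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assignments = km.fit_predict(scores)
    return ClusterResult(
        centroids=km.cluster_centers_.copy(),
        assignments=assignments,
        inertia=float(km.inertia_),
    )


def phenotype_parsing_index(
    centroid: np.ndarray,
    open_ref: np.ndarray,
    closed_ref: np.ndarray,
    mode: str = "axis",
) -> float:
    """Place a condition centroid on the closed-to-open calibration axis.

    Default "axis" mode: signed scalar projection of the centroid onto the
    unit axis from the closed reference to the open reference, scaled so
    the open reference maps to +1 and the closed reference to -1.  The
    "coordinate_mean" mode returns the plain mean of the three centroid
    coordinates (the literal eigencoefficient-averaging reading).
    """
    centroid = np.asarray(centroid, dtype=float)
    open_ref = np.asarray(open_ref, dtype=float)
    closed_ref = np.asarray(closed_ref, dtype=float)
    if mode == "coordinate_mean":
        return float(centroid.mean())
    axis = open_ref - closed_ref
    norm2 = float(axis @ axis)
    if norm2 == 0.0:
        raise DegenerateAxisError("open and closed references coincide")
    midpoint = (open_ref + closed_ref) / 2.0
    return float(2.0 * (centroid - midpoint) @ axis / norm2)


@dataclass(frozen=True)
class IEMCounts:
    """Gold-particle counts from immunoelectron micrographs.

    ``k4_*``/``k27_*`` count H3K4me3 / H3K27me3 particles, in euchromatic
    (``_eu``) and heterochromatic (``_het``) regions.
    """

    k4_eu: int
    k27_eu: int
    k4_het: int
    k27_het: int

    def __post_init__(self):
        for name in ("k4_eu", "k27_eu", "k4_het", "k27_het"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def open_chromatin_index(
    counts: IEMCounts, log_scale: bool = True, pseudocount: bool = False
) -> float:
    """Ratio-of-ratios chromatin openness from immunogold counts.

    raw OCI = (k4_eu / k27_eu) / (k27_het / k4_het); the default log2
    scale maps balanced chromatin to 0 and closed states to negative
    values.  ``pseudocount`` adds 0.5 to every count to tolerate zeros.
    """
    k4_eu, k27_eu = float(counts.k4_eu), float(counts.k27_eu)
    k4_het, k27_het = float(counts.k4_het), float(counts.k27_het)
    if pseudocount:
        k4_eu += 0.5
        k27_eu += 0.5
        k4_het += 0.5
        k27_het += 0.5
    if k27_eu == 0 or k4_het == 0:
        raise ZeroCountsError("k27_eu and k4_het must be positive")
    if log_scale and (k4_eu == 0 or k27_het == 0):
        raise ZeroCountsError("log scale needs all four counts positive")
    raw = (k4_eu / k27_eu) / (k27_het / k4_het)
    return float(np.log2(raw)) if log_scale else float(raw)


@dataclass(frozen=True)
class FRETSample:
    """Three-cube intensities and bleed-through factors for one FRET sample.

    A, B, C are the donor-, transfer- and acceptor-channel intensities;
    b = B/A and c = B/C are the donor and acceptor bleed-through factors
    measured on single-labeled references; a = A/C is recorded for
    completeness but unused by the default correction.
    """

    A: float
    B: float
    C: float
    b: float
    c: float
    a: float = 0.0

    def __post_init__(self):
        if self.A < 0 or self.B < 0 or self.C < 0:
            raise ValueError("intensities must be non-negative")
        if self.b < 0 or self.c < 0:
            raise ValueError("bleed-through factors must be non-negative")


def fret_efficiency(s: FRETSample) -> float:
    """Sensitized-emission FRET efficiency with bleed-through correction.

    Corrected transfer signal F = B - b*A - c*C; efficiency E = F/C,
    clipped at 0 when the corrected signal is negative.
    """
    if s.C == 0:
        raise ZeroAcceptorError("acceptor intensity must be positive")
    corrected = s.B - s.b * s.A - s.c * s.C
    return float(max(0.0, corrected) / s.C)


def normalize_heatmap(
    condition_means: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Min-max scale each descriptor across ordered conditions to [0, 1].

    A descriptor constant across conditions maps to 0.5 everywhere.  Also
    reports each descriptor's Spearman correlation against the condition
    order (monotone trend strength; NaN-free, 0 for constants).
    """
    if len(condition_means) < 2:
        raise TooFewConditionsError("need >= 2 conditions")
    X = condition_means.to_numpy(dtype=float)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    flat = span <= 0
    span_safe = np.where(flat, 1.0, span)
    norm = (X - lo) / span_safe
    norm[:, flat] = 0.5
    order = np.arange(len(condition_means))
    rho = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        if not flat[j]:
            rho[j] = stats.spearmanr(order, X[:, j]).statistic
    return (
        pd.DataFrame(norm, index=condition_means.index,
                     columns=condition_means.columns),
        pd.Series(rho, index=condition_means.columns, name="spearman_rho"),
    )
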