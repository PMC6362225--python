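"""Sparse linear discriminant analysis of nodal-strength profiles.

Characterises the clinical stages II/IIIa/IIIb/IIIc by sparse
discriminant directions (LDDs) over region-wise nodal strengths,
following the penalized optimal-scoring formulation of discriminant
analysis: each LDD solves an elastic-net regression of optimal class
scores on the standardized feature matrix, alternating between the
regression coefficients ``beta`` and the class score vector ``theta``
(kept unit-norm and orthogonal to previous scores and the constant in
the class-proportion inner product). The L1 end of the penalty is
driven along the LARS path until the requested number of nonzero
loadings is reached, so sparsity is controlled as a budget of m
loadings per LDD rather than a bare penalty weight.

Usage follows the Model/Results convention::

    model = SparseDiscriminantAnalysis(strengths, labels, ridge=1e-3, sparsity=15)
    res = model.fit()
    res.summary()
    scores = res.project(strengths)

Class separability is evaluated by leave-one-out cross-validated
nearest-centroid classification in LDD space, against the chance
(1 - 1/K) and naive majority-class baselines, plus the inter-class
Euclidean distance matrix between centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lars_path_gram

from .stats import pearson_correlation

__all__ = [
    "FeatureMatrix",
    "standardize_features",
    "SparseDiscriminantAnalysis",
    "SparseDiscriminantResults",
    "DiscriminantEvaluation",
    "nearest_centroid_classify",
    "loocv_evaluate",
    "baseline_errors",
    "interclass_distance_matrix",
    "ldd_clinical_correlations",
]

STAGE_CLASSES = ("II", "IIIa", "IIIb", "IIIc")


# ---------------------------------------------------------------------
# Feature standardization
# ---------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Column-standardized subjects x regions matrix with stored scaling.

    ``kept`` indexes the original columns that survived (constant
    columns are dropped with a warning and recorded there).
    """

    values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    labels: np.ndarray
    kept: np.ndarray
    n_original_columns: int

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Standardize new raw rows with the stored parameters."""
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        if raw.shape[1] != self.n_original_columns:
            raise ValueError(
                f"expected {self.n_original_columns} features, got {raw.shape[1]}"
            )
        return (raw[:, self.kept] - self.column_means) / self.column_sds


def standardize_features(
    nodal_strengths, labels, class_order=None, min_class_size: int = 2
) -> FeatureMatrix:
    """Z-score feature columns and validate stage labels.

    Constant columns carry no discriminative information and break the
    scaling; they are dropped (warning) and recorded in ``kept``.
    """
    X = np.asarray(nodal_strengths, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] != len(labels):
        raise ValueError("row count must match the label vector")
    order = list(class_order) if class_order is not None else sorted(set(labels))
    for cls_ in order:
        n = int((labels == cls_).sum())
        if n < min_class_size:
            raise ValueError(f"class {cls_!r} has {n} subjects (< {min_class_size})")
    sds = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(sds > 0)
    if kept.size < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - kept.size} constant feature column(s)",
            stacklevel=2,
        )
    means = X[:, kept].mean(axis=0)
    sds = sds[kept]
    return FeatureMatrix(
        values=(X[:, kept] - means) / sds,
        column_means=means,
        column_sds=sds,
        labels=labels,
        kept=kept,
        n_original_columns=X.shape[1],
    )


# ---------------------------------------------------------------------
# Elastic-net inner solver
# ---------------------------------------------------------------------

def _enet_direction(
    gram: np.ndarray, Xy: np.ndarray, n_aug: int, budget: int
) -> np.ndarray:
    """Elastic-net regression with at most ``budget`` nonzero coefficients.

    ``gram`` is the ridge-augmented Gram matrix X'X + n*ridge*I and
    ``Xy`` the covariance X'y; the ridge is thereby folded in by data
    augmentation, and the L1 penalty is relaxed along the LARS path
    until the active set would exceed the budget. With
    ``budget >= n_features`` the closed-form ridge solution is returned
    (no L1).
    """
    p = gram.shape[0]
    if budget >= p:
        return np.linalg.solve(gram, Xy)
    _, _, coefs = lars_path_gram(
        Xy=Xy, Gram=gram, n_samples=n_aug,
        method="lasso", max_iter=budget + 12, verbose=False,
    )
    best = coefs[:, 0]
    for k in range(coefs.shape[1]):
        if np.count_nonzero(coefs[:, k]) <= budget:
            best = coefs[:, k]
        else:
            break
    return best.copy()


# ---------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------

class SparseDiscriminantAnalysis:
    """Sparse discriminant model over nodal-strength profiles.

    Parameters
    ----------
    nodal_strengths : array (n_subjects, n_regions)
        Raw (unstandardized) features; standardization is internal and
        its parameters are stored for out-of-sample projection.
    labels : array of str
        Stage label per subject.
    ridge : float
        L2 penalty weight (per-sample scale), default 1e-3.
    sparsity : int
        Budget of nonzero loadings per discriminant direction,
        default 15. Use ``sparsity >= n_regions`` for a dense fit.
    class_order : sequence of str
        Fixed class ordering (defines tie-breaks and confusion layout);
        defaults to the stage order II < IIIa < IIIb < IIIc when the
        labels are stages, else sorted order.
    """

    def __init__(
        self,
        nodal_strengths,
        labels,
        ridge: float = 1e-3,
        sparsity: int = 15,
        class_order=None,
        min_class_size: int = 2,
    ):
        labels = np.asarray(labels)
        if class_order is None:
            lab_set = set(labels)
            if lab_set <= set(STAGE_CLASSES):
                class_order = [c for c in STAGE_CLASSES if c in lab_set]
            else:
                class_order = sorted(lab_set)
        self.class_order = list(class_order)
        self.ridge = float(ridge)
        self.sparsity = int(sparsity)
        self.features = standardize_features(
            nodal_strengths, labels, self.class_order, min_class_size
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_column: str = "group", **kwargs
    ) -> "SparseDiscriminantAnalysis":
        labels = df[label_column].to_numpy()
        X = df.drop(columns=[label_column]).to_numpy(dtype=float)
        return cls(X, labels, **kwargs)

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    @property
    def n_components(self) -> int:
        return self.n_classes - 1

    def _indicator(self) -> np.ndarray:
        lab = self.features.labels
        return np.column_stack([(lab == c).astype(float) for c in self.class_order])

    def fit(self, max_iter: int = 200, tol: float = 1e-6) -> "SparseDiscriminantResults":
        """Alternating optimal-scoring fit of all Q = K - 1 directions.

        Deterministic: scores are initialized from the left singular
        vectors of the class-mean matrix, so repeated runs on identical
        input give identical results.
        """
        X = self.features.values
        n, p = X.shape
        Y = self._indicator()
        K, Q = self.n_classes, self.n_components
        Dp = Y.sum(axis=0) / n  # class proportions
        gram = X.T @ X + self.ridge * n * np.eye(p)
        n_aug = n + p

        # deterministic init: left singular vectors of the class-mean matrix
        class_means = (Y.T @ X) / Y.sum(axis=0)[:, None]
        U, _, _ = np.linalg.svd(class_means - class_means.mean(axis=0), full_matrices=True)

        def d_orth(theta, prev):
            """Project out the constant and previous scores (D inner product)."""
            ones = np.ones(K)
            theta = theta - ones * (Dp @ theta) / (Dp @ ones)
            for t in prev:
                theta = theta - t * float(np.sum(Dp * t * theta))
            nrm = float(np.sqrt(np.sum(Dp * theta * theta)))
            return theta / nrm if nrm > 1e-12 else None

        betas = np.zeros((p, Q))
        thetas = np.zeros((K, Q))
        converged = np.zeros(Q, dtype=bool)
        n_iter = np.zeros(Q, dtype=int)
        prev_thetas: list[np.ndarray] = []
        for q in range(Q):
            theta = None
            for cand in list(U.T) + list(np.eye(K)):
                theta = d_orth(cand, prev_thetas)
                if theta is not None:
                    break
            if theta is None:  # pragma: no cover - degenerate K
                raise RuntimeError("could not initialize score vector")
            beta_old = np.zeros(p)
            for it in range(1, max_iter + 1):
                beta = _enet_direction(gram, X.T @ (Y @ theta), n_aug, self.sparsity)
                if np.isnan(beta).any():
                    raise FloatingPointError("NaN in discriminant fit")
                scores_cls = (Y.T @ (X @ beta)) / n
                theta_new = d_orth(scores_cls / Dp, prev_thetas)
                if theta_new is None:
                    break
                theta = theta_new
                denom = max(1.0, float(np.linalg.norm(beta_old)))
                if float(np.linalg.norm(beta - beta_old)) / denom < tol:
                    converged[q] = True
                    beta_old = beta
                    break
                beta_old = beta
            n_iter[q] = it
            betas[:, q] = beta_old
            thetas[:, q] = theta
            prev_thetas.append(theta)

        # sign convention: largest-magnitude loading positive per LDD
        for q in range(Q):
            col = betas[:, q]
            if col.any():
                j = int(np.argmax(np.abs(col)))
                if col[j] < 0:
                    betas[:, q] = -col
                    thetas[:, q] = -thetas[:, q]

        scores = X @ betas
        centroids = np.stack(
            [scores[self.features.labels == c].mean(axis=0) for c in self.class_order]
        )
        if not converged.all():
            warnings.warn(
                f"discriminant directions not fully converged: {np.flatnonzero(~converged).tolist()}",
                stacklevel=2,
            )
        return SparseDiscriminantResults(
            model=self,
            beta=betas,
            theta=thetas,
            centroids=centroids,
            converged=converged,
            n_iter=n_iter,
        )


@dataclass
class SparseDiscriminantResults:
    """Fitted sparse discriminant directions and class geometry.

    ``beta`` is (n_kept_features, Q) on the standardized feature scale;
    ``theta`` the (K, Q) optimal scores; ``centroids`` the (K, Q) class
    means of the training scores.
    """

    model: SparseDiscriminantAnalysis
    beta: np.ndarray
    theta: np.ndarray
    centroids: np.ndarray
    converged: np.ndarray
    n_iter: np.ndarray

    @property
    def class_order(self) -> list[str]:
        return self.model.class_order

    def project(self, raw_features) -> np.ndarray:
        """Scores (subjects x Q) of raw feature rows in LDD space."""
        Z = self.model.features.transform(raw_features)
        return Z @ self.beta

    def classify(self, raw_features) -> np.ndarray:
        scores = self.project(raw_features)
        return nearest_centroid_classify(scores, self.centroids, self.class_order)

    def training_scores(self) -> np.ndarray:
        return self.model.features.values @ self.beta

    def loadings_frame(self, labels: list[str] | None = None) -> pd.DataFrame:
        """Tidy loadings: one row per (region, LDD) nonzero loading."""
        kept = self.model.features.kept
        rows = []
        for q in range(self.beta.shape[1]):
            for i, b in zip(kept, self.beta[:, q]):
                if b != 0.0:
                    rows.append(
                        {
                            "region_id": int(i),
                            "label": labels[i] if labels is not None else "",
                            "ldd": q + 1,
                            "loading": float(b),
                        }
                    )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        K, Q = self.theta.shape
        nnz = [int(np.count_nonzero(self.beta[:, q])) for q in range(Q)]
        dist, avg = interclass_distance_matrix(self.centroids)
        lines = [
            "Sparse discriminant analysis (penalized optimal scoring)",
            "=" * 56,
            f"classes: {', '.join(self.class_order)}   (K={K}, Q={Q})",
            f"features: {self.model.features.values.shape[1]} kept of "
            f"{self.model.features.n_original_columns}",
            f"ridge={self.model.ridge:g}  sparsity budget={self.model.sparsity}",
            f"nonzero loadings per LDD: {nnz}",
            f"iterations per LDD: {self.n_iter.tolist()}  "
            f"converged: {self.converged.tolist()}",
            "",
            "Inter-class centroid distances:",
        ]
        hdr = "        " + "".join(f"{c:>8}" for c in self.class_order)
        lines.append(hdr)
        for i, c in enumerate(self.class_order):
            lines.append(
                f"{c:>8}" + "".join(f"{dist[i, j]:8.3f}" for j in range(K))
            )
        lines.append("")
        lines.append(
            "mean distance to other classes: "
            + "  ".join(f"{c}={v:.3f}" for c, v in zip(self.class_order, avg))
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------
# Classification and evaluation
# ---------------------------------------------------------------------

def nearest_centroid_classify(scores, centroids, class_order) -> np.ndarray:
    """Euclidean nearest centroid; ties break to the earlier class."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    centroids = np.asarray(centroids, dtype=float)
    d2 = ((scores[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)  # argmin takes the first minimum: tie rule
    return np.asarray(class_order)[idx]


def baseline_errors(labels, n_classes: int | None = None) -> tuple[float, float]:
    """Chance-level and naive (majority-class) LOOCV errors.

    Chance is 1 - 1/K. The naive error is computed by actually running
    leave-one-out on the majority-class rule: for each held-out subject
    the prediction is the majority label among the remaining n - 1
    (ties to the earlier class in sorted order).
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    classes = sorted(set(labels))
    K = n_classes if n_classes is not None else len(classes)
    chance = 1.0 - 1.0 / K
    errors = 0
    counts = pd.Series(labels).value_counts()
    for i, lab in enumerate(labels):
        c = counts.copy()
        c[lab] -= 1
        top = c.max()
        pred = sorted(c.index[c == top])[0]
        if pred != lab:
            errors += 1
    return chance, errors / len(labels)


def interclass_distance_matrix(centroids) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Euclidean centroid distances and per-class mean distance."""
    C = np.asarray(centroids, dtype=float)
    D = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(axis=2))
    K = C.shape[0]
    avg = (D.sum(axis=1)) / max(K - 1, 1)
    return D, avg


@dataclass
class DiscriminantEvaluation:
    """Leave-one-out separability summary of a sparse discriminant model."""

    loocv_error: float
    confusion: np.ndarray  # K x K percentages, rows = true class
    distance_matrix: np.ndarray
    avg_distance: np.ndarray
    baseline_chance: float
    baseline_naive: float
    class_order: list[str] = field(default_factory=list)
    predictions: np.ndarray | None = None

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=self.class_order,
                            columns=self.class_order)

    def to_dict(self) -> dict:
        return {
            "loocv_error": self.loocv_error,
            "baseline_chance": self.baseline_chance,
            "baseline_naive": self.baseline_naive,
            "class_order": list(self.class_order),
            "confusion_percent": self.confusion.tolist(),
            "distance_matrix": self.distance_matrix.tolist(),
            "avg_distance": self.avg_distance.tolist(),
        }


def loocv_evaluate(
    nodal_strengths,
    labels,
    ridge: float = 1e-3,
    sparsity: int = 15,
    class_order=None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> DiscriminantEvaluation:
    """Leave-one-out evaluation of the sparse discriminant model.

    Every fold re-standardizes and refits on the remaining n - 1
    subjects (no leakage of scaling or sparsity pattern) and classifies
    the held-out subject by nearest centroid. The confusion matrix is
    row-normalized to percentages of true class size. Centroid
    distances come from the full-data fit.
    """
    X = np.asarray(nodal_strengths, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]

    full_model = SparseDiscriminantAnalysis(
        X, labels, ridge=ridge, sparsity=sparsity, class_order=class_order
    )
    order = full_model.class_order
    full = full_model.fit(max_iter=max_iter, tol=tol)
    dist, avg = interclass_distance_matrix(full.centroids)

    preds = np.empty(n, dtype=object)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            try:
                m = SparseDiscriminantAnalysis(
                    X[keep], labels[keep], ridge=ridge, sparsity=sparsity,
                    class_order=order, min_class_size=1,
                )
                res = m.fit(max_iter=max_iter, tol=tol)
            except Exception as exc:
                raise RuntimeError(f"LOOCV fold {i} (subject index {i}) failed") from exc
            preds[i] = res.classify(X[i])[0]

    err = float(np.mean(preds != labels))
    K = len(order)
    confusion = np.zeros((K, K))
    for i, true in enumerate(order):
        sel = labels == true
        denom = max(int(sel.sum()), 1)
        for j, pred in enumerate(order):
            confusion[i, j] = 100.0 * np.sum(preds[sel] == pred) / denom
    chance, naive = baseline_errors(labels, K)
    return DiscriminantEvaluation(
        loocv_error=err,
        confusion=confusion,
        distance_matrix=dist,
        avg_distance=avg,
        baseline_chance=chance,
        baseline_naive=naive,
        class_order=order,
        predictions=preds,
    )


def ldd_clinical_correlations(
    scores, subjects_table: pd.DataFrame,
    clinical_columns=("doi", "processing_speed"),
) -> pd.DataFrame:
    """Pearson r/p of each LDD score against clinical variables.

    ``subjects_table`` rows must align with the score rows (patients
    only); missing clinical values are handled pairwise.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != len(subjects_table):
        raise ValueError("score rows must match the subject rows")
    rows = []
    for q in range(scores.shape[1]):
        x = scores[:, q]
        for cvar in clinical_columns:
            if cvar not in subjects_table.columns:
                continue
            y = pd.to_numeric(subjects_table[cvar], errors="coerce").to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                r = p = float("nan")
            else:
                r, p = pearson_correlation(x[ok], y[ok])
            rows.append({"ldd": q + 1, "variable": cvar, "n": int(ok.sum()),
                         "r": r, "p": p})
    return pd.DataFrame(rows)
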