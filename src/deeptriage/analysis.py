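"""Interpretation of the importance matrix B.

Three complementary views:

* **NMF** — B ~ W H with non-negative factors; the "discriminative factor"
  is the W column whose sample scores best separate the two classes
  (largest |rank-sum statistic|). Each factor's feature loadings, normalised
  to sum to one, give a relative-contribution profile.
* **PCA** — column-mean-centred ordination of B (no unit-variance scaling:
  importance rows already share a common scale because they sum to one);
  biplots overlay the top-q most variable features as arrows.
* **Stage association** — per ordination axis, an ordinary least-squares
  model of the axis scores on dummy-coded clinical T/N/M stages (nominal,
  lowest level as reference), restricted to one class, to test whether
  within-class importance structure tracks tumour severity.

Also provided: the linear baseline classifiers (L2 logistic regression and
linear soft-margin SVM) used for benchmarking, and per-feature Welch tests of
between-class expression differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.svm import SVC

from .containers import ExpressionMatrix
from .model import ImportanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FactorisationResult",
    "OrdinationResult",
    "StageAssociation",
    "nmf_factorise",
    "pca_ordinate",
    "stage_association",
    "run_baselines",
    "group_mean_difference",
    "plot_factor_contributions",
    "plot_factor_boxplot",
    "plot_biplot",
]


# ---------------------------------------------------------------------------
# NMF


@dataclass
class FactorisationResult:
    W: np.ndarray  # n x k sample-factor scores
    H: np.ndarray  # k x d factor-feature loadings
    k: int
    objective: list[float]  # 0.5 * ||B - WH||_F^2 per iteration
    reconstruction_error: float
    feature_ids: list[str]
    sample_ids: list[str]
    discriminative_factor: int | None = None
    separation_stat: float | None = None

    def contributions(self, factor: int | None = None) -> pd.Series:
        """Relative feature contributions of a factor (H row, sum-1 normalised)."""
        if factor is None:
            factor = self.discriminative_factor
        if factor is None:
            raise ValueError("no factor given and no discriminative factor recorded")
        row = self.H[factor]
        total = row.sum()
        if total <= 0:
            raise ValueError(f"factor {factor} has all-zero loadings")
        return pd.Series(row / total, index=self.feature_ids).sort_values(ascending=False)


def _as_matrix(B: ImportanceMatrix | np.ndarray) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(B, ImportanceMatrix):
        return np.asarray(B.B, float), list(B.sample_ids), list(B.feature_ids)
    arr = np.asarray(B, float)
    n, d = arr.shape
    return arr, [f"s{i}" for i in range(n)], [f"f{i}" for i in range(d)]


def nmf_factorise(
    B: ImportanceMatrix | np.ndarray,
    k: int = 2,
    seed: int = 0,
    class_labels: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> FactorisationResult:
    """Seeded non-negative matrix factorisation of B by multiplicative updates.

    Minimises the Frobenius objective 0.5*||B - WH||^2; the per-iteration
    objective is recorded (multiplicative updates never increase it). When
    ``class_labels`` is given (or carried by the ImportanceMatrix), the
    discriminative factor — the W column with the largest two-class
    |rank-sum| statistic — is identified.
    """
    X, sample_ids, feature_ids = _as_matrix(B)
    if class_labels is None and isinstance(B, ImportanceMatrix):
        class_labels = B.class_labels
    if np.any(X < 0):
        raise ValueError("NMF input must be non-negative")
    n, d = X.shape
    if k < 2:
        raise ValueError("rank k must be >= 2")
    if k > min(n, d):
        raise ValueError(f"rank k={k} exceeds min(n, d)={min(n, d)}")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X.mean(), 1e-12) / k)
    W = scale * np.abs(rng.standard_normal((n, k)))
    H = scale * np.abs(rng.standard_normal((k, d)))

    eps = 1e-12
    objective: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        W *= (X @ H.T) / (W @ (H @ H.T) + eps)
        H *= (W.T @ X) / ((W.T @ W) @ H + eps)
        obj = 0.5 * float(np.linalg.norm(X - W @ H) ** 2)
        objective.append(obj)
        if prev - obj < tol * max(prev, 1.0):
            break
        prev = obj

    result = FactorisationResult(
        W=W, H=H, k=k, objective=objective,
        reconstruction_error=float(np.linalg.norm(X - W @ H)),
        feature_ids=feature_ids, sample_ids=sample_ids,
    )
    if class_labels is not None:
        y = np.asarray(class_labels).ravel()
        stats_ = [
            abs(stats.ranksums(W[y == 1, j], W[y == 0, j]).statistic) for j in range(k)
        ]
        result.discriminative_factor = int(np.argmax(stats_))
        result.separation_stat = float(max(stats_))
    return result


# ---------------------------------------------------------------------------
# PCA


@dataclass
class OrdinationResult:
    scores: np.ndarray  # n x r sample coordinates
    loadings: np.ndarray  # d x r orthonormal feature axes
    explained_variance_ratio: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    mean: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.feature_ids, columns=cols)


def pca_ordinate(B: ImportanceMatrix | np.ndarray, r: int = 2, scale: bool = False) -> OrdinationResult:
    """Column-mean-centred PCA of B via SVD (unscaled by default)."""
    X, sample_ids, feature_ids = _as_matrix(B)
    n, d = X.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 samples")
    if r > min(n, d):
        raise ValueError(f"r={r} exceeds min(n, d)={min(n, d)}")
    if scale:
        sd = X.std(axis=0)
        sd[sd < 1e-12] = 1.0
        X = X / sd
    pca = PCA(n_components=r, svd_solver="full")
    scores = pca.fit_transform(X)
    return OrdinationResult(
        scores=scores,
        loadings=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        mean=pca.mean_,
    )


def top_variable_features(B: ImportanceMatrix | np.ndarray, q: int = 5) -> list[str]:
    X, _, feature_ids = _as_matrix(B)
    order = np.argsort(X.var(axis=0))[::-1][:q]
    return [feature_ids[i] for i in order]


# ---------------------------------------------------------------------------
# stage association


@dataclass
class StageAssociation:
    axis: int
    subset: str
    terms: list[tuple[str, float, float]]  # (level e.g. "T2", coefficient, p-value)
    dropped_factors: list[str]
    n: int

    def to_frame(self, bh: bool = False) -> pd.DataFrame:
        frame = pd.DataFrame(self.terms, columns=["term", "coefficient", "p_value"])
        if bh:
            from statsmodels.stats.multitest import multipletests

            frame["p_bh"] = multipletests(frame["p_value"], method="fdr_bh")[1]
        return frame


def stage_association(
    ordination: OrdinationResult,
    clinical: pd.DataFrame,
    axis: int = 0,
    subset_class: str | int | None = None,
    class_column: str = "subtype",
    factors: tuple[str, ...] = ("T", "N", "M"),
) -> StageAssociation:
    """OLS of one ordination axis on dummy-coded clinical stage factors.

    ``clinical`` must be indexed by (or contain a ``sample_id`` column of)
    sample ids and carry nominal T/N/M columns. The model is fit on the
    samples of ``subset_class`` only (all samples when None). Each factor is
    treatment-coded against its lowest level; factors constant within the
    subset are dropped with a warning.
    """
    import statsmodels.formula.api as smf

    clin = clinical.copy()
    if "sample_id" in clin.columns:
        clin = clin.set_index("sample_id")
    clin.index = clin.index.astype(str)

    scores = ordination.scores_frame()
    if axis >= scores.shape[1]:
        raise ValueError(f"axis {axis} not available (only {scores.shape[1]} computed)")
    data = clin.join(scores.iloc[:, axis].rename("score"), how="inner")
    if subset_class is not None:
        data = data[data[class_column].astype(str) == str(subset_class)]
    if data.empty:
        raise ValueError("no samples left after subsetting")

    usable, dropped = [], []
    for f in factors:
        if f not in data.columns:
            raise KeyError(f"clinical table lacks a {f!r} column")
        if data[f].astype(str).nunique() >= 2:
            usable.append(f)
        else:
            dropped.append(f)
            logger.warning("stage factor %r constant within subset; dropped from the model", f)
    if not usable:
        raise ValueError("all stage factors are constant within the subset")

    for f in usable:  # nominal coding, lowest level = reference
        data[f] = pd.Categorical(data[f].astype(str), categories=sorted(data[f].astype(str).unique()))
    formula = "score ~ " + " + ".join(f"C({f})" for f in usable)
    fit = smf.ols(formula, data=data).fit()

    terms: list[tuple[str, float, float]] = []
    for name, coef, pval in zip(fit.params.index, fit.params, fit.pvalues):
        if name == "Intercept":
            continue
        level = name.split("[T.")[-1].rstrip("]")
        terms.append((level, float(coef), float(pval)))
    return StageAssociation(
        axis=axis,
        subset=str(subset_class) if subset_class is not None else "all",
        terms=terms,
        dropped_factors=dropped,
        n=len(data),
    )


# ---------------------------------------------------------------------------
# baselines and per-feature tests


def run_baselines(
    train: ExpressionMatrix | np.ndarray,
    train_labels: np.ndarray,
    test: ExpressionMatrix | np.ndarray,
    test_labels: np.ndarray,
    log_zscore: bool = True,
    feature_space: str = "features",
) -> pd.DataFrame:
    """F1 of L2 logistic regression and a linear soft-margin SVM.

    Both models see the same preprocessing as the attention model
    (log1p + train-set z-scoring by default). Returned as a one-row table,
    rows = feature space, columns = model.
    """
    Xtr = train.values if isinstance(train, ExpressionMatrix) else np.asarray(train, float)
    Xte = test.values if isinstance(test, ExpressionMatrix) else np.asarray(test, float)
    ytr = np.asarray(train_labels).ravel()
    yte = np.asarray(test_labels).ravel()
    if len(np.unique(ytr)) < 2:
        raise ValueError("training labels are degenerate (single class)")
    if log_zscore:
        Ltr, Lte = np.log1p(Xtr), np.log1p(Xte)
        mu, sd = Ltr.mean(axis=0), Ltr.std(axis=0)
        sd[sd < 1e-8] = 1.0
        Xtr, Xte = (Ltr - mu) / sd, (Lte - mu) / sd

    scores = {}
    logreg = LogisticRegression(C=1.0, max_iter=5000)  # L2-penalised by default
    logreg.fit(Xtr, ytr)
    scores["logistic_regression"] = f1_score(yte, logreg.predict(Xte))
    svm = SVC(kernel="linear", C=1.0)
    svm.fit(Xtr, ytr)
    scores["linear_svm"] = f1_score(yte, svm.predict(Xte))
    return pd.DataFrame([scores], index=[feature_space])


def group_mean_difference(
    expr: ExpressionMatrix,
    labels: np.ndarray,
    feature_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature Welch t-test between the two classes.

    ``mean_difference`` is mean(class 0) - mean(class 1): positive values mean
    the feature is higher in class 0 (the "B"/severe class under the package's
    label convention).
    """
    y = np.asarray(labels).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if feature_ids is None:
        feature_ids = list(expr.feature_ids)
    pos = {f: i for i, f in enumerate(expr.feature_ids)}
    missing = [f for f in feature_ids if f not in pos]
    if missing:
        raise KeyError(f"features not found: {missing[:5]}")
    idx = [pos[f] for f in feature_ids]
    X0 = expr.values[y == 0][:, idx]
    X1 = expr.values[y == 1][:, idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant features -> nan p
        tres = stats.ttest_ind(X0, X1, axis=0, equal_var=False)
    diff = X0.mean(axis=0) - X1.mean(axis=0)
    pvals = np.where(np.isnan(tres.pvalue), 1.0, tres.pvalue)
    return pd.DataFrame(
        {
            "mean_difference": diff,
            "direction": np.where(diff > 0, "up_in_class0", np.where(diff < 0, "up_in_class1", "none")),
            "t_statistic": np.where(np.isnan(tres.statistic), 0.0, tres.statistic),
            "p_value": pvals,
        },
        index=feature_ids,
    )


# ---------------------------------------------------------------------------
# figure exports (simple matplotlib renderings of the three standard views)


def _agg_pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_factor_contributions(result: FactorisationResult, path, top: int = 15, label_top: int = 3) -> None:
    """Horizontal bar chart of the discriminative factor's top contributions."""
    plt = _agg_pyplot()
    contrib = result.contributions().head(top)[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.3 * top + 1))
    ax.barh(range(len(contrib)), contrib.values, color="#4878cf")
    ax.set_yticks(range(len(contrib)))
    ax.set_yticklabels(contrib.index, fontsize=7)
    ax.set_xlabel("relative contribution")
    ax.set_title(f"factor {result.discriminative_factor} contributions")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_factor_boxplot(result: FactorisationResult, labels: np.ndarray, path) -> None:
    """Per-class box plot of the discriminative factor's sample scores."""
    plt = _agg_pyplot()
    y = np.asarray(labels).ravel()
    col = result.W[:, result.discriminative_factor]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot([col[y == 1], col[y == 0]], tick_labels=["class A (y=1)", "class B (y=0)"])
    ax.set_ylabel("factor score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_biplot(
    ordination: OrdinationResult,
    B: ImportanceMatrix | np.ndarray,
    path,
    labels: np.ndarray | None = None,
    top_q: int = 5,
) -> None:
    """PC1/PC2 biplot with arrows for the top-q most variable features."""
    plt = _agg_pyplot()
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ordination.scores
    if labels is not None:
        y = np.asarray(labels).ravel()
        for cls, color in ((1, "#4878cf"), (0, "#d65f5f")):
            ax.scatter(sc[y == cls, 0], sc[y == cls, 1], s=12, color=color,
                       label=f"class {'A' if cls else 'B'}")
        ax.legend(fontsize=7)
    else:
        ax.scatter(sc[:, 0], sc[:, 1], s=12, color="#4878cf")
    arrow_scale = np.abs(sc[:, :2]).max() * 0.8
    feats = top_variable_features(B, q=top_q)
    pos = {f: i for i, f in enumerate(ordination.feature_ids)}
    for f in feats:
        lx, ly = ordination.loadings[pos[f], 0], ordination.loadings[pos[f], 1]
        ax.annotate("", xy=(lx * arrow_scale, ly * arrow_scale), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="black", lw=0.8))
        ax.text(lx * arrow_scale, ly * arrow_scale, f, fontsize=6)
    evr = ordination.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.1%})")
    ax.set_ylabel(f"PC2 ({evr[1]:.1%})" if len(evr) > 1 else "PC2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
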