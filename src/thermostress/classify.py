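"""Two-stage feature selection and subject-independent stress classification.

Stage 1 is a filter: keep features whose point-biserial correlation with the
class label is significant (p <= 0.05).  Stage 2 ranks the survivors with
nu-SVM (RBF kernel) recursive feature elimination: at each step the feature
whose removal least perturbs the kernel-space weight-vector magnitude

    W^2(alpha) = sum_ij alpha_i alpha_j y_i y_j K(x_i, x_j)

is eliminated (criterion c_f = |W^2 - W^2_{-f}| with the dual coefficients
held fixed).  Because highly correlated features share their influence and
would mutually suppress their criteria (correlation bias), criteria are
corrected before each elimination: features are clustered by single linkage
on |Pearson r| above a threshold, and under-ranked cluster members are
raised to the cluster's mean criterion.  Generalization is measured by
leave-one-subject-out (LOSO) cross-validation over the accuracy-vs-top-k
curve; both of a subject's sessions always share a fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.stats import pearsonr
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import NuSVC

from .errors import RankingError, TableAssemblyError
from .rois import thermal_feature_names

#: class coding, as conventional for this task: 1 = Stroop (stress, the
#: "positive" class for type-II error), 2 = Rest.
STRESS_LABEL, REST_LABEL = 1, 2

FEATURE_SETS = ("full", "thermo", "nothermo")


@dataclass
class FeatureTable:
    """Observations (subject x session) x named features with labels."""

    data: pd.DataFrame  # columns: subject, session, label, <features...>

    def __post_init__(self) -> None:
        required = {"subject", "session", "label"}
        if not required <= set(self.data.columns):
            raise TableAssemblyError(f"missing columns: {required - set(self.data.columns)}")
        dup = self.data.duplicated(subset=["subject", "session"])
        if dup.any():
            raise TableAssemblyError(
                f"duplicate subject-session rows: "
                f"{self.data.loc[dup, ['subject', 'session']].values.tolist()}"
            )
        per_subject = self.data.groupby("subject")["label"].agg(["size", "nunique"])
        bad = per_subject[(per_subject["size"] != 2) | (per_subject["nunique"] != 2)]
        if len(bad):
            raise TableAssemblyError(
                f"subjects without exactly 2 distinctly-labelled rows: {list(bad.index)}"
            )
        if self.data[self.feature_columns].isna().any().any():
            raise TableAssemblyError("feature table contains missing values")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("subject", "session", "label")]

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.feature_columns]

    @property
    def y(self) -> np.ndarray:
        return self.data["label"].to_numpy(int)

    @property
    def subjects(self) -> np.ndarray:
        return self.data["subject"].to_numpy()

    def view(self, feature_set: str) -> "FeatureTable":
        """Full / Thermo / No-Thermo column views."""
        feature_set = feature_set.lower()
        if feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {feature_set!r}")
        thermal = [c for c in thermal_feature_names() if c in self.data.columns]
        if feature_set == "full":
            cols = self.feature_columns
        elif feature_set == "thermo":
            cols = thermal
        else:
            cols = [c for c in self.feature_columns if c not in thermal]
        return FeatureTable(self.data[["subject", "session", "label"] + cols].copy())

    def with_features(self, cols: list[str]) -> "FeatureTable":
        return FeatureTable(self.data[["subject", "session", "label"] + list(cols)].copy())


# ---------------------------------------------------------------------------
# stage 1: correlation filter

def filter_select(table: FeatureTable, alpha: float = 0.05) -> FeatureTable:
    """Keep features significantly point-biserial-correlated with the label.

    Pearson correlation of each feature against the binary class coding;
    features with p <= alpha survive, in their original column order.
    Zero-variance features are excluded with a warning (their correlation is
    undefined).
    """
    y = table.y.astype(float)
    kept: list[str] = []
    for col in table.feature_columns:
        x = table.data[col].to_numpy(float)
        if np.ptp(x) == 0:
            warnings.warn(f"feature {col!r} has zero variance; excluded from filter")
            continue
        _, p = pearsonr(x, y)
        if p <= alpha:
            kept.append(col)
    return table.with_features(kept)


# ---------------------------------------------------------------------------
# stage 2: nu-SVM RBF RFE with correlation-bias reduction

@dataclass
class RankingResult:
    """RFE ranking: ``ranking[0]`` is the most important feature (rank 1)."""

    ranking: list[str]
    criteria: dict[str, float]               # criterion at elimination time
    clusters_per_step: list[list[list[str]]] = field(default_factory=list)


def _standardize(X: np.ndarray, mean=None, std=None):
    if mean is None:
        mean = X.mean(axis=0)
        std = X.std(axis=0, ddof=0)
    std = np.where(std == 0, 1.0, std)
    return (X - mean) / std, mean, std


def _correlation_clusters(X: np.ndarray, threshold: float) -> list[np.ndarray]:
    """Single-linkage clusters of features with |Pearson r| > threshold."""
    p = X.shape[1]
    if p == 1:
        return [np.array([0])]
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(X, rowvar=False))
    corr = np.nan_to_num(corr)
    adj = corr > threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(adj, directed=False)
    return [np.flatnonzero(labels == k) for k in range(n_comp)]


class _RFEState:
    """One fitted nu-SVM step: evaluates |W^2 - W^2_{-S}| for feature sets S."""

    def __init__(self, X: np.ndarray, y: np.ndarray, nu: float, step: int):
        p = X.shape[1]
        self.gamma = 1.0 / p
        try:
            svm = NuSVC(nu=nu, kernel="rbf", gamma=self.gamma)
            svm.fit(X, y)
        except Exception as exc:  # noqa: BLE001 - surfaced with context
            raise RankingError(
                f"SVM training failed at elimination step {step}: {exc}"
            ) from exc
        self.Xsv = X[svm.support_]
        self.a = svm.dual_coef_[0]  # alpha_i * y_i over support vectors
        self.K = rbf_kernel(self.Xsv, self.Xsv, gamma=self.gamma)
        self.w2 = self.a @ self.K @ self.a

    def removal_criterion(self, features: np.ndarray) -> float:
        """Criterion for removing ``features`` jointly, duals held fixed."""
        d2 = np.zeros_like(self.K)
        for f in np.atleast_1d(features):
            d = self.Xsv[:, f][:, None] - self.Xsv[None, :, f]
            d2 += d**2
        K_minus = self.K * np.exp(self.gamma * d2)
        return abs(self.w2 - self.a @ K_minus @ self.a)


def _rfe_criteria(X: np.ndarray, y: np.ndarray, nu: float, step: int):
    """Per-feature |W^2 - W^2_{-f}|, plus the fitted state for CBR."""
    state = _RFEState(X, y, nu, step)
    crit = np.array([state.removal_criterion(f) for f in range(X.shape[1])])
    return crit, state


def svm_rfe_cbr_rank(
    table: FeatureTable,
    nu: float = 0.5,
    cbr_threshold: float = 0.7,
    use_cbr: bool = True,
    standardize: bool = True,
) -> RankingResult:
    """Rank features by nu-SVM-RBF recursive elimination with CBR.

    One feature is eliminated per step (criterion ties broken by column
    order); the last surviving feature gets rank 1.  The RBF width follows
    the LIBSVM default gamma = 1/p for the current feature count p.
    """
    cols = list(table.feature_columns)
    X_all = table.X.to_numpy(float)
    if standardize:
        X_all, _, _ = _standardize(X_all)
    y = table.y

    surviving = list(range(len(cols)))
    eliminated: list[str] = []
    criteria: dict[str, float] = {}
    clusters_per_step: list[list[list[str]]] = []

    step = 0
    while len(surviving) > 1:
        step += 1
        X = X_all[:, surviving]
        crit, state = _rfe_criteria(X, y, nu, step)
        clusters = _correlation_clusters(X, cbr_threshold)
        clusters_per_step.append([[cols[surviving[i]] for i in cl] for cl in clusters])
        if use_cbr:
            # correlated features share their influence, so their individual
            # removal criteria are mutually suppressed; the cluster's joint
            # removal criterion, spread evenly over its members, restores the
            # under-ranked ones
            for cl in clusters:
                if len(cl) >= 2:
                    c_cluster = state.removal_criterion(cl)
                    crit[cl] = np.maximum(crit[cl], c_cluster)
        worst = int(np.argmin(crit))  # first index wins ties -> column order
        name = cols[surviving[worst]]
        criteria[name] = float(crit[worst])
        eliminated.append(name)
        surviving.pop(worst)

    last = cols[surviving[0]]
    criteria.setdefault(last, float("inf"))
    eliminated.append(last)
    return RankingResult(
        ranking=eliminated[::-1],
        criteria=criteria,
        clusters_per_step=clusters_per_step,
    )


# ---------------------------------------------------------------------------
# LOSO evaluation

@dataclass
class LOSOResult:
    ks: np.ndarray
    accuracies: np.ndarray
    best_k: int
    ranking: list[str] | None
    confusion: dict[int, np.ndarray]     # k -> 2x2 row-% matrix [[S...],[NS...]]
    predictions: pd.DataFrame            # subject, session, label, k, predicted

    @property
    def max_accuracy(self) -> float:
        return float(self.accuracies.max())


def _confusion_percent(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """2x2 confusion matrix in % per actual class; rows = (Stress, Rest),
    columns = (predicted Stress, predicted Rest)."""
    out = np.zeros((2, 2))
    for i, actual in enumerate((STRESS_LABEL, REST_LABEL)):
        sel = y_true == actual
        n = sel.sum()
        for j, pred in enumerate((STRESS_LABEL, REST_LABEL)):
            out[i, j] = 100.0 * np.sum(y_pred[sel] == pred) / n if n else 0.0
    return out


def _fit_predict(X_tr, y_tr, X_te, nu: float) -> np.ndarray:
    X_tr, mean, std = _standardize(X_tr)
    X_te, _, _ = _standardize(X_te, mean, std)
    svm = NuSVC(nu=nu, kernel="rbf", gamma=1.0 / X_tr.shape[1])
    try:
        svm.fit(X_tr, y_tr)
    except ValueError:
        # degenerate fold (e.g. a quantized feature collapsing to point
        # masses with conflicting labels makes the nu-SVM dual non-finite):
        # no decision boundary exists, fall back to the majority class
        labels, counts = np.unique(y_tr, return_counts=True)
        return np.full(len(X_te), labels[np.argmax(counts)])
    return svm.predict(X_te)


def loso_accuracy_curve(
    table: FeatureTable,
    mode: str = "pooled",
    nu: float = 0.5,
    cbr_threshold: float = 0.7,
    filter_alpha: float = 0.05,
    use_cbr: bool = True,
) -> LOSOResult:
    """Accuracy as a function of the top-k ranked features, under LOSO CV.

    ``mode='pooled'`` filters and ranks once on the pooled table, then
    cross-validates each top-k subset (matching the construction of a single
    global ranked axis and accuracy curve).  ``mode='strict'`` refits the filter and the
    ranking inside every training fold (leakage-free); the curve is indexed
    by per-fold rank and truncated to each fold's retained feature count.
    """
    if mode not in ("pooled", "strict"):
        raise ValueError("mode must be 'pooled' or 'strict'")
    subjects = np.unique(table.subjects)
    if len(subjects) < 4:
        raise ValueError("need at least 4 subjects for LOSO")

    y_all = table.y
    subj_col = table.subjects
    global_ranking: list[str] | None = None

    if mode == "pooled":
        filtered = filter_select(table, alpha=filter_alpha)
        if not filtered.feature_columns:
            raise RankingError("no features survived the correlation filter")
        global_ranking = svm_rfe_cbr_rank(
            filtered, nu=nu, cbr_threshold=cbr_threshold, use_cbr=use_cbr
        ).ranking
        fold_rankings = {s: global_ranking for s in subjects}
    else:
        fold_rankings = {}
        for s in subjects:
            tr = FeatureTable(table.data[subj_col != s].copy())
            filt = filter_select(tr, alpha=filter_alpha)
            if not filt.feature_columns:
                fold_rankings[s] = []
                continue
            fold_rankings[s] = svm_rfe_cbr_rank(
                filt, nu=nu, cbr_threshold=cbr_threshold, use_cbr=use_cbr
            ).ranking

    max_k = max((len(r) for r in fold_rankings.values()), default=0)
    if max_k == 0:
        raise RankingError("no features available in any fold")

    ks = np.arange(1, max_k + 1)
    accuracies = np.zeros(max_k)
    confusion: dict[int, np.ndarray] = {}
    pred_rows = []
    X_df = table.data
    for k in ks:
        y_true_all, y_pred_all = [], []
        for s in subjects:
            ranking = fold_rankings[s]
            if not ranking:
                continue
            cols = ranking[: min(k, len(ranking))]
            tr_mask = subj_col != s
            X_tr = X_df.loc[tr_mask, cols].to_numpy(float)
            X_te = X_df.loc[~tr_mask, cols].to_numpy(float)
            y_pred = _fit_predict(X_tr, y_all[tr_mask], X_te, nu)
            y_true = y_all[~tr_mask]
            y_true_all.append(y_true)
            y_pred_all.append(y_pred)
            for sess, t_lbl, p_lbl in zip(
                X_df.loc[~tr_mask, "session"], y_true, y_pred
            ):
                pred_rows.append((s, sess, int(t_lbl), int(k), int(p_lbl)))
        y_true_all = np.concatenate(y_true_all)
        y_pred_all = np.concatenate(y_pred_all)
        accuracies[k - 1] = np.mean(y_true_all == y_pred_all)
        confusion[int(k)] = _confusion_percent(y_true_all, y_pred_all)

    best_k = int(ks[np.argmax(accuracies)])
    predictions = pd.DataFrame(
        pred_rows, columns=["subject", "session", "label", "k", "predicted"]
    )
    return LOSOResult(
        ks=ks,
        accuracies=accuracies,
        best_k=best_k,
        ranking=global_ranking,
        confusion=confusion,
        predictions=predictions,
    )


# ---------------------------------------------------------------------------
# confusion-matrix arithmetic

def evaluate_confusion(
    matrix: np.ndarray,
    class_sizes: tuple[int, int],
    as_percent: bool = True,
) -> dict[str, float]:
    """Accuracy and per-class error rates from a confusion matrix.

    ``matrix`` rows are actual classes (Stress, Rest) given either as row
    percentages (``as_percent=True``, rows must sum to 100) or as counts
    (rows must sum to their class size).  With equal class sizes the overall
    accuracy equals the mean of the diagonal percentages.  The type-II error
    is the stress-row false-negative percentage.
    """
    M = np.asarray(matrix, dtype=float)
    if M.shape != (2, 2) or np.any(M < 0):
        raise ValueError("confusion matrix must be 2x2 and nonnegative")
    n_s, n_r = class_sizes
    if n_s <= 0 or n_r <= 0:
        raise ValueError("class sizes must be positive")
    if as_percent:
        if not np.allclose(M.sum(axis=1), 100.0, atol=0.02):
            raise ValueError("percentage rows must sum to 100")
        counts = M * np.array([[n_s], [n_r]]) / 100.0
    else:
        if not np.allclose(M.sum(axis=1), [n_s, n_r]):
            raise ValueError("count rows must sum to the class sizes")
        counts = M
        M = 100.0 * counts / counts.sum(axis=1, keepdims=True)
    accuracy = 100.0 * (counts[0, 0] + counts[1, 1]) / (n_s + n_r)
    return {
        "accuracy_pct": float(accuracy),
        "type2_error_pct": float(M[0, 1]),  # stress misread as rest
        "type1_error_pct": float(M[1, 0]),  # rest misread as stress
    }
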