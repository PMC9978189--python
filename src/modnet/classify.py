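"""Network-based classification protocol.

The evaluation pipeline mirrors the standard connectome-classification
recipe: each scan's symmetric network is flattened to its strict upper
triangle (``n(n-1)/2`` edge-weight features; 6,670 for 116 ROIs), the most
informative features are selected by a two-sample t-test at a fixed p-value
threshold on the training portion only, and a linear support-vector machine
(fixed ``C = 1``) is trained on the selected features.  Performance is
measured by repeated 5-fold *subject-level* cross-validation: folds
partition subjects, never scans, so multiple scans of one person can never
straddle train and test.  Hyperparameters of the network estimator are
chosen by an inner 5-fold CV on the training subjects only.

Reported metrics: ACC = (TP+TN)/(TP+FP+TN+FN), SEN = TP/(TP+FN),
SPE = TN/(TN+FP), and AUC (area under the ROC curve).  The positive class
(label 1) is the patient group, so SEN is the detection rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .estimators import AmpcConfig, TimeSeries, ampc_estimate, estimate_network
from .graph import validate_adjacency

logger = logging.getLogger(__name__)

__all__ = [
    "Metrics",
    "CVReport",
    "vectorize_upper_triangle",
    "unvectorize_upper_triangle",
    "upper_triangle_index",
    "networks_to_features",
    "ttest_select",
    "compute_metrics",
    "subject_folds",
    "run_cv",
    "rank_edges",
    "cohort_feature_sets",
    "classify_cohort",
    "k_sweep",
]


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def upper_triangle_index(n: int) -> list[tuple[int, int]]:
    """ROI-pair ``(i, j)`` with ``i < j`` for each feature, row-major order."""
    iu, ju = np.triu_indices(n, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def vectorize_upper_triangle(W: np.ndarray) -> np.ndarray:
    """Strict upper triangle of a symmetric matrix as a length n(n-1)/2 vector."""
    W = validate_adjacency(W)
    iu, ju = np.triu_indices(W.shape[0], k=1)
    return W[iu, ju]


def unvectorize_upper_triangle(v: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper_triangle` (zero diagonal)."""
    v = np.asarray(v, dtype=float)
    if v.size != n * (n - 1) // 2:
        raise ValueError(f"vector length {v.size} does not match n = {n}")
    W = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    W[iu, ju] = v
    return W + W.T


def networks_to_features(networks: Sequence[np.ndarray]) -> np.ndarray:
    """Stack per-scan networks into a scans x features matrix."""
    return np.vstack([vectorize_upper_triangle(W) for W in networks])


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------


def ttest_select(
    features: np.ndarray,
    labels: np.ndarray,
    p_threshold: float = 0.05,
    *,
    equal_var: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-sample t-test feature selection (fit on training data only).

    Returns ``(selected_indices, p_values, t_statistics)``.  The default is
    the pooled-variance Student's t; ``equal_var=False`` gives Welch's t.
    Features with zero variance in both classes and equal means are
    assigned ``p = 1`` (never selected).  If no feature passes the
    threshold, the single smallest-p feature is kept so a classifier can
    always be trained (logged prominently).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes in training labels, got {classes}")
    a = features[labels == classes[1]]
    b = features[labels == classes[0]]
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant features trigger a catastrophic-cancellation warning;
        # they are handled explicitly below (p = 1, never selected)
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    selected = np.flatnonzero(p < p_threshold)
    if selected.size == 0:
        selected = np.array([int(np.argmin(p))])
        logger.warning(
            "no feature passed p < %g; falling back to the single smallest-p feature",
            p_threshold,
        )
    return selected, p, t


def rank_edges(
    features: np.ndarray,
    labels: np.ndarray,
    n_rois: int,
    roi_names: Sequence[str] | None = None,
    *,
    p_cutoff: float | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Rank edge features by discriminative power (ascending p-value).

    Returns a DataFrame with columns ``roi_i, roi_j, t, p``; with
    ``p_cutoff`` given only edges below the cutoff are kept.
    """
    _, p, t = ttest_select(features, labels, p_threshold=0.999999, equal_var=equal_var)
    pairs = upper_triangle_index(n_rois)
    if roi_names is None:
        roi_names = [f"ROI{i + 1}" for i in range(n_rois)]
    df = pd.DataFrame(
        {
            "roi_i": [roi_names[i] for i, _ in pairs],
            "roi_j": [roi_names[j] for _, j in pairs],
            "t": t,
            "p": p,
        }
    ).sort_values("p", kind="stable", ignore_index=True)
    if p_cutoff is not None:
        df = df[df["p"] < p_cutoff].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metrics:
    """ACC/SEN/SPE/AUC for one evaluation; AUC is NaN if undefined."""

    acc: float
    sen: float
    spe: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "sen": self.sen, "spe": self.spe, "auc": self.auc}


def compute_metrics(
    labels: np.ndarray, predictions: np.ndarray, scores: np.ndarray | None = None
) -> Metrics:
    """Accuracy, sensitivity, specificity and AUC for binary predictions.

    Label 1 is the positive class.  AUC uses the rank construction over
    decision scores; with a single-class truth it is undefined and reported
    as NaN with a warning.
    """
    y = np.asarray(labels).astype(int)
    yhat = np.asarray(predictions).astype(int)
    tp = int(np.sum((y == 1) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    acc = (tp + tn) / max(tp + tn + fp + fn, 1)
    sen = tp / (tp + fn) if (tp + fn) else float("nan")
    spe = tn / (tn + fp) if (tn + fp) else float("nan")
    if scores is None:
        scores = yhat.astype(float)
    if np.unique(y).size < 2:
        warnings.warn("AUC undefined: only one class present in the truth labels")
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y, np.asarray(scores, dtype=float)))
    return Metrics(acc=float(acc), sen=float(sen), spe=float(spe), auc=auc)


# ---------------------------------------------------------------------------
# Subject-level cross-validation
# ---------------------------------------------------------------------------


def _subject_table(subjects: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame({"subject": subjects, "label": labels})
    per = df.groupby("subject")["label"].nunique()
    bad = per[per > 1]
    if len(bad):
        raise ValueError(f"subject(s) with inconsistent labels: {list(bad.index)}")
    return df.groupby("subject", sort=True)["label"].first().reset_index()


def subject_folds(
    subjects: np.ndarray,
    labels: np.ndarray,
    n_folds: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Class-stratified partition of *subjects* into ``n_folds`` folds.

    Subjects are shuffled within each class and dealt round-robin, so every
    fold contains both classes whenever each class has at least ``n_folds``
    subjects (enforced).  Returns the subject ids per fold.
    """
    table = _subject_table(subjects, labels)
    folds: list[list] = [[] for _ in range(n_folds)]
    for cls in np.unique(table["label"]):
        subj = table.loc[table["label"] == cls, "subject"].to_numpy()
        if subj.size < n_folds:
            raise ValueError(
                f"class {cls} has {subj.size} subjects, fewer than {n_folds} folds"
            )
        subj = subj[rng.permutation(subj.size)]
        for i, s in enumerate(subj):
            folds[i % n_folds].append(s)
    return [np.asarray(f) for f in folds]


@dataclass
class CVReport:
    """Repeated-CV results: per-fold records plus aggregate mean ± sd.

    ``fold_records`` has one row per (repeat, fold) with metrics, the chosen
    hyperparameter key and the test-subject set; ``summary`` aggregates the
    per-repeat means into overall mean and standard deviation.
    """

    fold_records: pd.DataFrame
    seed: int
    folds: int
    repeats: int

    @property
    def repeat_means(self) -> pd.DataFrame:
        return self.fold_records.groupby("repeat")[["acc", "sen", "spe", "auc"]].mean()

    @property
    def summary(self) -> pd.DataFrame:
        rm = self.repeat_means
        return pd.DataFrame({"mean": rm.mean(), "sd": rm.std(ddof=1 if len(rm) > 1 else 0)})

    def as_dict(self) -> dict:
        s = self.summary
        return {
            "seed": self.seed,
            "folds": self.folds,
            "repeats": self.repeats,
            "mean": s["mean"].to_dict(),
            "sd": s["sd"].to_dict(),
        }


def _fit_eval(
    features: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    p_threshold: float,
    C: float,
) -> Metrics:
    sel, _, _ = ttest_select(features[train_idx], labels[train_idx], p_threshold)
    clf = SVC(kernel="linear", C=C)
    clf.fit(features[np.ix_(train_idx, sel)], labels[train_idx])
    Xte = features[np.ix_(test_idx, sel)]
    return compute_metrics(labels[test_idx], clf.predict(Xte), clf.decision_function(Xte))


def run_cv(
    feature_sets: Mapping[Hashable, np.ndarray] | np.ndarray,
    labels: np.ndarray,
    subjects: np.ndarray,
    *,
    folds: int = 5,
    repeats: int = 100,
    seed: int = 0,
    p_threshold: float = 0.05,
    C: float = 1.0,
    inner_folds: int = 5,
) -> CVReport:
    """Repeated subject-level nested cross-validation.

    ``feature_sets`` maps each hyperparameter grid point to its scans x
    features matrix (all computed from the same scans; network estimation is
    label-free, so the grid can be precomputed once).  A bare array is
    treated as a single grid point.  Per outer fold the grid point is chosen
    by inner ``inner_folds``-fold subject-level CV on the training subjects
    only (best mean accuracy; ties go to the earliest grid point); feature
    selection is refit on each training portion.  Outer folds and inner
    folds are re-randomized every repeat from ``seed``.
    """
    if isinstance(feature_sets, np.ndarray):
        feature_sets = {None: feature_sets}
    keys = list(feature_sets)
    labels = np.asarray(labels).astype(int)
    subjects = np.asarray(subjects)
    if np.unique(labels).size != 2:
        raise ValueError("both classes must be present")
    n_scans = labels.size
    for key, f in feature_sets.items():
        if f.shape[0] != n_scans:
            raise ValueError(f"feature set {key!r} has {f.shape[0]} rows, expected {n_scans}")
    _subject_table(subjects, labels)  # label-consistency check

    records: list[dict] = []
    for r in range(repeats):
        rng = np.random.default_rng(seed + r)
        outer = subject_folds(subjects, labels, folds, rng)
        for f_id, test_subjects in enumerate(outer):
            test_mask = np.isin(subjects, test_subjects)
            train_idx = np.flatnonzero(~test_mask)
            test_idx = np.flatnonzero(test_mask)

            if len(keys) > 1:
                best_key, best_score = keys[0], -np.inf
                tr_subj = subjects[train_idx]
                tr_lab = labels[train_idx]
                inner = subject_folds(tr_subj, tr_lab, inner_folds, rng)
                for key in keys:
                    feats = feature_sets[key]
                    scores = []
                    for val_subjects in inner:
                        val_mask = np.isin(tr_subj, val_subjects)
                        it_idx = train_idx[~val_mask]
                        iv_idx = train_idx[val_mask]
                        m = _fit_eval(feats, labels, it_idx, iv_idx, p_threshold, C)
                        scores.append(m.acc)
                    score = float(np.mean(scores))
                    if score > best_score + 1e-12:
                        best_key, best_score = key, score
            else:
                best_key = keys[0]

            m = _fit_eval(feature_sets[best_key], labels, train_idx, test_idx, p_threshold, C)
            records.append(
                {
                    "repeat": r,
                    "fold": f_id,
                    "param": best_key,
                    "test_subjects": tuple(np.sort(test_subjects).tolist()),
                    **m.as_dict(),
                }
            )
    return CVReport(
        fold_records=pd.DataFrame.from_records(records),
        seed=seed,
        folds=folds,
        repeats=repeats,
    )


# ---------------------------------------------------------------------------
# Cohort-level pipeline
# ---------------------------------------------------------------------------


def cohort_feature_sets(
    scans: Sequence[TimeSeries],
    method: str,
    grid: Mapping[Hashable, dict] | None = None,
) -> dict[Hashable, np.ndarray]:
    """Estimate networks for every scan at every grid point, vectorized.

    ``grid`` maps a grid-point key (e.g. a λ value) to the keyword
    parameters of :func:`modnet.estimators.estimate_network`; ``None`` means
    a single parameter-free fit.
    """
    if grid is None:
        grid = {None: {}}
    out: dict[Hashable, np.ndarray] = {}
    for key, params in grid.items():
        nets = [estimate_network(ts, method, **dict(params)) for ts in scans]
        out[key] = networks_to_features(nets)
    return out


def classify_cohort(
    scans: Sequence[TimeSeries],
    labels: np.ndarray,
    subjects: np.ndarray,
    method: str,
    grid: Mapping[Hashable, dict] | None = None,
    **cv_kwargs,
) -> CVReport:
    """End-to-end: estimate networks, extract features, run nested CV."""
    feature_sets = cohort_feature_sets(scans, method, grid)
    return run_cv(feature_sets, labels, subjects, **cv_kwargs)


def k_sweep(
    scans: Sequence[TimeSeries],
    labels: np.ndarray,
    subjects: np.ndarray,
    k_values: Sequence[int],
    *,
    lam_grid: Sequence[float] = (0.0,),
    normalized_laplacian: bool = True,
    **cv_kwargs,
) -> pd.DataFrame:
    """Classification performance of AM-PC as a function of the module count k.

    Runs the full pipeline per ``k`` and returns a tidy table with columns
    ``k, acc, sen, spe, auc`` (aggregate means) plus their sds.
    """
    n = scans[0].n
    rows = []
    for k in k_values:
        if not 1 <= k < n:
            raise ValueError(f"k must be in [1, {n}), got {k}")
        grid = {
            lam: {"k": k, "lam": lam, "normalized_laplacian": normalized_laplacian}
            for lam in lam_grid
        }
        report = classify_cohort(scans, labels, subjects, "am-pc", grid, **cv_kwargs)
        s = report.summary
        row = {"k": k}
        for metric in ("acc", "sen", "spe", "auc"):
            row[metric] = s.loc[metric, "mean"]
            row[f"{metric}_sd"] = s.loc[metric, "sd"]
        rows.append(row)
    return pd.DataFrame(rows)
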