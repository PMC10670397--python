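"""Classification and evaluation: SMOTE, extra-trees, LOSO CV, metrics.

The evaluation protocol mirrors how such classifiers are validated on small
clinical cohorts:

* **Leave-one-subject-out (LOSO)** cross-validation — each subject's epochs
  form the test set exactly once; training data never contain test-subject
  rows, so performance reflects generalization to an unseen infant.
* **Split before oversampling** — SMOTE runs inside each fold on the
  training partition only.  This is enforced structurally: the oversampler
  is invoked by the fold loop after the subject split, and synthetic rows
  never enter a test partition.
* **Median imputation** of missing features is fitted on the training
  partition and applied to both partitions.
* The classifier is an **extremely-randomized-trees** ensemble
  (scikit-learn's ``ExtraTreesClassifier``: random split thresholds, Gini
  impurity), exposing impurity-based feature importances.

Tasks: the 3-class problem (AS / QS / CTW) and the four pairwise problems
AS vs QS, QS vs CTW, AS vs CTW and Sleep vs CTW (Sleep = AS + QS).  Feature
sets: Motion, ECG-Resp-CRI, and all four families combined.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.neighbors import NearestNeighbors

from .config import STATES
from .features.registry import feature_names

__all__ = [
    "FEATURE_SETS",
    "TASKS",
    "loso_folds",
    "smote_oversample",
    "train_classifier",
    "cohen_kappa",
    "confusion_matrix",
    "classification_metrics",
    "auc_mann_whitney",
    "gini_importance",
    "EvalReport",
    "run_task",
    "run_experiment",
    "null_calibration",
]

#: Named feature sets (family combinations) used throughout.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "Motion": ("motion",),
    "ECG-Resp-CRI": ("cardiac", "respiratory", "cri"),
    "ECG-Resp-CRI-Motion": ("cardiac", "respiratory", "cri", "motion"),
}

#: Task name -> class labels; None entries in the map mean "drop the row".
TASKS: dict[str, dict[str, str | None]] = {
    "3class": {"AS": "AS", "QS": "QS", "CTW": "CTW"},
    "AS_vs_QS": {"AS": "AS", "QS": "QS", "CTW": None},
    "QS_vs_CTW": {"AS": None, "QS": "QS", "CTW": "CTW"},
    "AS_vs_CTW": {"AS": "AS", "QS": None, "CTW": "CTW"},
    "Sleep_vs_CTW": {"AS": "Sleep", "QS": "Sleep", "CTW": "CTW"},
}

_TASK_CLASS_ORDER: dict[str, list[str]] = {
    "3class": ["AS", "QS", "CTW"],
    "AS_vs_QS": ["AS", "QS"],
    "QS_vs_CTW": ["QS", "CTW"],
    "AS_vs_CTW": ["AS", "CTW"],
    "Sleep_vs_CTW": ["Sleep", "CTW"],
}


def feature_set_columns(name: str) -> list[str]:
    families = FEATURE_SETS[name]
    return [c for fam in families for c in feature_names(fam)]


# ---------------------------------------------------------------------------
# cross-validation structure


def loso_folds(matrix: pd.DataFrame) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (train_idx, test_idx) pair per subject; positional indices."""
    subjects = pd.unique(matrix["subject_id"])
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    sid = matrix["subject_id"].to_numpy()
    folds = []
    for s in subjects:
        test = np.flatnonzero(sid == s)
        train = np.flatnonzero(sid != s)
        folds.append((train, test))
    return folds


# ---------------------------------------------------------------------------
# SMOTE


def smote_oversample(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthetic-minority oversampling.

    Every class is raised to the majority count.  Each synthetic sample is
    ``x + u * (x_nn - x)`` with ``u ~ U[0, 1]``, ``x`` a random minority row
    and ``x_nn`` one of its ``k`` nearest same-class neighbors (Euclidean
    distance on per-feature standardized values).  ``k`` is reduced to
    ``class size - 1`` for tiny classes; a singleton class falls back to
    duplication with a warning.  Deterministic under ``seed``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    if np.all(counts == n_max):
        return X, y
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs_all = (X - mu) / sd
    new_X, new_y = [X], [y]
    for cls, cnt in zip(classes, counts):
        n_extra = int(n_max - cnt)
        if n_extra == 0:
            continue
        rows = np.flatnonzero(y == cls)
        if cnt == 1:
            warnings.warn(
                f"class {cls!r} has a single member; duplicating instead of SMOTE",
                stacklevel=2,
            )
            new_X.append(np.repeat(X[rows], n_extra, axis=0))
            new_y.append(np.repeat(y[rows], n_extra))
            continue
        k_eff = min(k, cnt - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xs_all[rows])
        _, nbr = nn.kneighbors(Xs_all[rows])  # col 0 is self
        base = rng.integers(0, cnt, size=n_extra)
        pick = rng.integers(1, k_eff + 1, size=n_extra)
        u = rng.random(size=(n_extra, 1))
        x0 = X[rows[base]]
        x1 = X[rows[nbr[base, pick]]]
        new_X.append(x0 + u * (x1 - x0))
        new_y.append(np.full(n_extra, cls, dtype=y.dtype))
    return np.vstack(new_X), np.concatenate(new_y)


# ---------------------------------------------------------------------------
# classifier


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    n_estimators: int = 100,
    seed: int = 0,
    **kwargs,
) -> ExtraTreesClassifier:
    """Fit an extremely-randomized-trees ensemble (Gini impurity)."""
    if len(X) == 0:
        raise ValueError("empty training set")
    model = ExtraTreesClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1, **kwargs
    )
    model.fit(X, y)
    return model


def gini_importance(
    fold_importances: list[np.ndarray], names: list[str]
) -> pd.DataFrame:
    """Rank features by mean impurity importance across folds.

    Returns a DataFrame (one row per feature, ranked) with the mean, SD and
    the per-fold importance distribution, mirroring a box-plot-ready layout.
    """
    arr = np.vstack(fold_importances)  # folds x features
    df = pd.DataFrame(
        {
            "feature": names,
            "importance_mean": arr.mean(axis=0),
            "importance_sd": arr.std(axis=0),
        }
    )
    for i in range(arr.shape[0]):
        df[f"fold_{i}"] = arr[i]
    return df.sort_values("importance_mean", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# metrics


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, classes: list[str]
) -> np.ndarray:
    """Count matrix with fixed class order; rows = true, cols = predicted."""
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return cm


def cohen_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement from a confusion matrix.

    ``kappa = (p_o - p_e) / (1 - p_e)``; by convention 0 when expected
    agreement is 1 (degenerate single-class case).
    """
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / total
    p_e = float(np.sum(cm.sum(axis=1) * cm.sum(axis=0)) / total**2)
    if p_e == 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def auc_mann_whitney(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """ROC AUC as the normalized Mann-Whitney U statistic (midranks for ties)."""
    pos = np.asarray(scores_pos, dtype=np.float64)
    neg = np.asarray(scores_neg, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        return np.nan
    combined = np.concatenate([pos, neg])
    order = np.argsort(combined, kind="mergesort")
    ranks = np.empty_like(combined)
    ranks[order] = np.arange(1, combined.size + 1, dtype=np.float64)
    # midranks for ties
    sorted_vals = combined[order]
    i = 0
    while i < sorted_vals.size:
        j = i
        while j + 1 < sorted_vals.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        if j > i:
            ranks[order[i : j + 1]] = 0.5 * (i + 1 + j + 1)
        i = j + 1
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def classification_metrics(cm: np.ndarray, classes: list[str]) -> dict[str, float]:
    """Accuracy plus one-vs-rest sensitivity/precision/specificity per class.

    A class absent from the test partition (or never predicted, for
    precision) yields NaN for the affected metric.
    """
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    out: dict[str, float] = {"accuracy": float(np.trace(cm) / total) if total else np.nan}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        out[f"sensitivity_{c}"] = float(tp / (tp + fn)) if tp + fn > 0 else np.nan
        out[f"precision_{c}"] = float(tp / (tp + fp)) if tp + fp > 0 else np.nan
        out[f"specificity_{c}"] = float(tn / (tn + fp)) if tn + fp > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# experiment driver


@dataclass
class EvalReport:
    """Evaluation artifacts of one feature set x task combination."""

    task: str
    feature_set: str
    classes: list[str]
    per_fold_kappa: dict[str, float]
    per_fold_auc: dict[str, float]
    pooled_cm: np.ndarray
    pooled_metrics: dict[str, float]
    pooled_kappa: float
    pooled_auc: float
    mean_kappa: float
    sd_kappa: float
    importance: pd.DataFrame
    seed: int
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        imp = self.importance[["feature", "importance_mean", "importance_sd"]]
        return {
            "task": self.task,
            "feature_set": self.feature_set,
            "classes": self.classes,
            "per_fold_kappa": self.per_fold_kappa,
            "per_fold_auc": self.per_fold_auc,
            "pooled_confusion_matrix": self.pooled_cm.tolist(),
            "pooled_metrics": self.pooled_metrics,
            "pooled_kappa": self.pooled_kappa,
            "pooled_auc": self.pooled_auc,
            "mean_kappa": self.mean_kappa,
            "sd_kappa": self.sd_kappa,
            "top_features": imp.head(10).to_dict(orient="records"),
            "seed": self.seed,
            "config": self.config,
        }


def _prepare_task(matrix: pd.DataFrame, task: str) -> pd.DataFrame:
    label_map = TASKS[task]
    mapped = matrix["label"].map(label_map)
    df = matrix.loc[mapped.notna()].copy()
    df["label"] = mapped[mapped.notna()]
    return df


def _impute_medians(train: np.ndarray) -> np.ndarray:
    med = np.nanmedian(train, axis=0)
    return np.where(np.isnan(med), 0.0, med)


def run_task(
    matrix: pd.DataFrame,
    feature_set: str,
    task: str,
    seed: int = 0,
    n_estimators: int = 100,
    smote_k: int = 5,
) -> EvalReport:
    """LOSO evaluation of one feature set on one task.

    Per fold: median-impute (train-fitted), SMOTE the training partition to
    balance, fit extra trees, predict the held-out subject.  Pooled metrics
    aggregate epochs over folds; per-fold kappa/AUC give the between-subject
    spread.  Binary-task AUC uses the positive-class (second class) score.
    """
    cols = feature_set_columns(feature_set)
    classes = _TASK_CLASS_ORDER[task]
    df = _prepare_task(matrix, task)
    folds = loso_folds(df)
    X_all = df[cols].to_numpy(dtype=np.float64)
    y_all = df["label"].to_numpy()
    subjects = df["subject_id"].to_numpy()

    per_fold_kappa: dict[str, float] = {}
    per_fold_auc: dict[str, float] = {}
    fold_importances: list[np.ndarray] = []
    pooled_cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    pooled_scores: list[np.ndarray] = []
    pooled_true: list[np.ndarray] = []

    for f_i, (tr, te) in enumerate(folds):
        assert not set(subjects[tr]) & set(subjects[te])  # subject exclusivity
        med = _impute_medians(X_all[tr])
        X_tr = np.where(np.isnan(X_all[tr]), med, X_all[tr])
        X_te = np.where(np.isnan(X_all[te]), med, X_all[te])
        X_bal, y_bal = smote_oversample(X_tr, y_all[tr], k=smote_k, seed=seed + f_i)
        model = train_classifier(X_bal, y_bal, n_estimators=n_estimators, seed=seed + f_i)
        y_pred = model.predict(X_te)
        subj = str(subjects[te][0])
        cm = confusion_matrix(y_all[te], y_pred, classes)
        pooled_cm += cm
        per_fold_kappa[subj] = cohen_kappa(cm)
        fold_importances.append(model.feature_importances_)
        if len(classes) == 2:
            pos = classes[1]
            pos_col = list(model.classes_).index(pos) if pos in model.classes_ else None
            if pos_col is not None:
                sc = model.predict_proba(X_te)[:, pos_col]
                pooled_scores.append(sc)
                pooled_true.append(y_all[te])
                per_fold_auc[subj] = auc_mann_whitney(
                    sc[y_all[te] == pos], sc[y_all[te] != pos]
                )
            else:  # pragma: no cover
                per_fold_auc[subj] = np.nan

    kappas = np.array(list(per_fold_kappa.values()))
    pooled_auc = np.nan
    if pooled_scores:
        sc = np.concatenate(pooled_scores)
        yt = np.concatenate(pooled_true)
        pooled_auc = auc_mann_whitney(sc[yt == classes[1]], sc[yt != classes[1]])
    return EvalReport(
        task=task,
        feature_set=feature_set,
        classes=classes,
        per_fold_kappa=per_fold_kappa,
        per_fold_auc=per_fold_auc,
        pooled_cm=pooled_cm,
        pooled_metrics=classification_metrics(pooled_cm, classes),
        pooled_kappa=cohen_kappa(pooled_cm),
        pooled_auc=pooled_auc,
        mean_kappa=float(kappas.mean()),
        sd_kappa=float(kappas.std(ddof=1)) if kappas.size > 1 else 0.0,
        importance=gini_importance(fold_importances, cols),
        seed=seed,
        config={"n_estimators": n_estimators, "smote_k": smote_k},
    )


def run_experiment(
    matrix: pd.DataFrame,
    feature_sets: list[str] | None = None,
    tasks: list[str] | None = None,
    seed: int = 0,
    n_estimators: int = 100,
    out_dir: str | Path | None = None,
) -> dict[tuple[str, str], EvalReport]:
    """Evaluate every feature set x task combination under LOSO.

    Returns ``{(feature_set, task): EvalReport}``; when ``out_dir`` is given,
    each report is written as JSON (``<feature_set>__<task>.json``).
    """
    feature_sets = list(FEATURE_SETS) if feature_sets is None else feature_sets
    tasks = list(TASKS) if tasks is None else tasks
    reports: dict[tuple[str, str], EvalReport] = {}
    for fs in feature_sets:
        for task in tasks:
            reports[(fs, task)] = run_task(
                matrix, fs, task, seed=seed, n_estimators=n_estimators
            )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (fs, task), rep in reports.items():
            name = f"{fs.replace(' ', '_')}__{task}.json"
            (out / name).write_text(json.dumps(rep.to_dict(), indent=1, sort_keys=True))
    return reports


def null_calibration(
    matrix: pd.DataFrame,
    feature_set: str = "ECG-Resp-CRI-Motion",
    task: str = "3class",
    seed: int = 0,
    n_estimators: int = 100,
) -> float:
    """Mean LOSO kappa after shuffling labels — should sit near 0.

    Labels are permuted over all rows (seeded), destroying any
    feature-label association while preserving the class mix.
    """
    rng = np.random.default_rng(seed)
    shuffled = matrix.copy()
    shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
    rep = run_task(shuffled, feature_set, task, seed=seed, n_estimators=n_estimators)
    return rep.mean_kappa


def state_class_order() -> list[str]:
    return list(STATES)
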