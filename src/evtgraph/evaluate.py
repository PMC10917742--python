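"""Cross-validation design, metrics, model comparison and uncertainty sweeps.

Folds are stratified so each test fold preserves the cohort's class mix to
within one patient; a stratified 20% of each fold's training portion serves
as validation split, and rows sharing a patient id always land in the same
fold. AUC / accuracy / balanced accuracy are the reported metrics; paired
t-tests compare algorithms across folds; per-variable chi-square / t-tests
with Benjamini-Hochberg adjustment reproduce the univariate cohort table;
the threshold sweep evaluates selective prediction at increasing uncertainty
cutoffs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, balanced_accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .cohort import CohortTable
from .preprocess import binarize_outcome

__all__ = [
    "FoldPlan",
    "MetricSet",
    "make_fold_plan",
    "compute_metrics",
    "paired_ttest_models",
    "univariate_table",
    "uncertainty_sweep",
    "DEFAULT_THRESHOLDS",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.1, 0.75, 0.1), 10))


@dataclass(frozen=True)
class MetricSet:
    auc: float
    accuracy: float
    balanced_accuracy: float

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
        }


@dataclass
class FoldPlan:
    """Per-patient fold id plus per-fold train/validation/test role masks."""

    n_folds: int
    fold_id: np.ndarray  # test-fold index per patient
    val_id: np.ndarray   # (n_folds, n) bool: validation rows of each fold
    seed: int

    @property
    def n_patients(self) -> int:
        return self.fold_id.size

    def masks(self, fold: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(train, validation, test) boolean masks for one fold."""
        test = self.fold_id == fold
        val = self.val_id[fold]
        train = ~test & ~val
        return train, val, test


def make_fold_plan(
    labels: np.ndarray,
    n_folds: int = 5,
    val_frac: float = 0.20,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> FoldPlan:
    """Stratified k-fold plan with a nested stratified validation split.

    ``groups`` (patient ids) forces repeated acquisitions of one patient into
    the same fold; with unique ids plain stratification is used. The
    validation split is drawn from the training rows of each fold only.
    """
    labels = np.asarray(labels)
    n = labels.size
    counts = np.bincount(labels.astype(int))
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members < {n_folds} folds"
        )
    grouped = groups is not None and np.unique(np.asarray(groups)).size < n
    if grouped:
        splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True,
                                        random_state=seed)
        split_iter = splitter.split(np.zeros(n), labels, groups=np.asarray(groups))
    else:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n), labels)

    fold_id = np.full(n, -1, dtype=int)
    val_id = np.zeros((n_folds, n), dtype=bool)
    rng = np.random.default_rng(seed)
    for f, (train_idx, test_idx) in enumerate(split_iter):
        fold_id[test_idx] = f
        val_id[f] = _stratified_subset(
            labels, train_idx, val_frac, rng,
            groups=np.asarray(groups) if grouped else None,
        )
    return FoldPlan(n_folds=n_folds, fold_id=fold_id, val_id=val_id, seed=seed)


def _stratified_subset(labels, train_idx, frac, rng, groups=None):
    """Boolean mask marking a stratified ``frac`` of ``train_idx`` as
    validation rows, keeping patient groups intact."""
    mask = np.zeros(labels.size, dtype=bool)
    if groups is None:
        for c in np.unique(labels[train_idx]):
            idx = train_idx[labels[train_idx] == c]
            k = max(1, int(round(frac * idx.size)))
            mask[rng.choice(idx, size=k, replace=False)] = True
        return mask
    # group-aware: pick whole patient groups, stratified by group label
    train_groups = np.unique(groups[train_idx])
    glabel = {g: labels[groups == g].max() for g in train_groups}
    for c in np.unique([glabel[g] for g in train_groups]):
        gs = np.array([g for g in train_groups if glabel[g] == c])
        k = max(1, int(round(frac * gs.size)))
        chosen = rng.choice(gs, size=k, replace=False)
        mask[np.isin(groups, chosen) & np.isin(np.arange(labels.size), train_idx)] = True
    return mask


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricSet:
    """AUC plus accuracy and balanced accuracy at the probability threshold.

    AUC is the probability that a random positive outranks a random negative
    (ties counted 1/2); balanced accuracy averages sensitivity and
    specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined with a single class")
    pred = (scores >= threshold).astype(int)
    return MetricSet(
        auc=float(roc_auc_score(labels, scores)),
        accuracy=float(accuracy_score(labels, pred)),
        balanced_accuracy=float(balanced_accuracy_score(labels, pred)),
    )


def paired_ttest_models(
    per_fold_auc: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sided paired t-tests on per-fold AUC for each algorithm pair.

    ``per_fold_auc``: rows = folds, columns = algorithms. Zero-variance
    difference vectors (identical fold-wise results) report p = 1 with a
    warning. Returns a symmetric p-value matrix with 1s on the diagonal.
    """
    if per_fold_auc.shape[0] < 2:
        raise ValueError("need at least 2 folds for a paired t-test")
    algos = list(per_fold_auc.columns)
    P = pd.DataFrame(np.ones((len(algos), len(algos))), index=algos, columns=algos)
    for i, a in enumerate(algos):
        for j in range(i + 1, len(algos)):
            b = algos[j]
            diff = per_fold_auc[a].to_numpy() - per_fold_auc[b].to_numpy()
            if np.allclose(diff, diff[0]) and np.isclose(diff.std(), 0.0):
                logger.warning(
                    "zero-variance AUC differences for (%s, %s); p set to 1", a, b
                )
                p = 1.0
            else:
                p = float(stats.ttest_rel(per_fold_auc[a], per_fold_auc[b]).pvalue)
            P.loc[a, b] = P.loc[b, a] = p
    return P


def _describe(values: np.ndarray, kind: str) -> str:
    if kind == "continuous":
        return f"{np.mean(values):.2f} ± {np.std(values, ddof=1):.2f}"
    if kind == "binary":
        n_pos = int(np.sum(values == 1))
        return f"{n_pos} ({100 * n_pos / values.size:.1f}%)"
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:g} [{q1:g}–{q3:g}]"


def univariate_table(table: CohortTable, task: str) -> pd.DataFrame:
    """Per-variable group comparison for one binarized outcome.

    Continuous variables: two-sample t-test. Categorical/binary: Pearson
    chi-square without continuity correction; Fisher's exact test replaces it
    for 2x2 tables with any expected count below 5. Missing cells are dropped
    per variable. P-values are Benjamini-Hochberg adjusted across variables.
    """
    y = binarize_outcome(table.data["mrs_3month"], task)
    rows = []
    for v in table.variables:
        col = table.data[v.name].to_numpy(dtype=float)
        ok = ~np.isnan(col)
        x, yy = col[ok], y[ok]
        g1, g0 = x[yy == 1], x[yy == 0]
        entry = {
            "variable": v.name,
            "kind": v.kind,
            "block": v.block,
            "group1_summary": _describe(g1, v.kind) if g1.size else "",
            "group0_summary": _describe(g0, v.kind) if g0.size else "",
        }
        if v.kind == "continuous":
            if np.std(x) == 0:
                entry.update(test="none", p_value=np.nan,
                             flag="zero-variance; no test")
            else:
                t = stats.ttest_ind(g1, g0)
                entry.update(test="t-test", p_value=float(t.pvalue), flag="")
        else:
            values = np.unique(x)
            if values.size < 2:
                entry.update(test="none", p_value=np.nan,
                             flag="single level; no test")
            else:
                contingency = np.array(
                    [[np.sum((x == val) & (yy == g)) for val in values]
                     for g in (0, 1)]
                )
                expected = stats.contingency.expected_freq(contingency)
                if contingency.shape == (2, 2) and (expected < 5).any():
                    _, p = stats.fisher_exact(contingency)
                    entry.update(test="fisher", p_value=float(p),
                                 flag="low expected count")
                else:
                    chi2 = stats.chi2_contingency(contingency, correction=False)
                    flag = "low expected count" if (expected < 5).any() else ""
                    entry.update(test="chi2", p_value=float(chi2.pvalue), flag=flag)
        rows.append(entry)
    df = pd.DataFrame(rows)
    tested = df["p_value"].notna()
    adjusted = np.full(len(df), np.nan)
    if tested.any():
        adjusted[tested.to_numpy()] = multipletests(
            df.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    df["p_adjusted"] = adjusted
    return df


def uncertainty_sweep(
    scores: np.ndarray,
    u_pred: np.ndarray,
    labels: np.ndarray,
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Selective-prediction table: for each threshold, patients with
    uncertainty strictly below it count as certain and the metrics are
    recomputed on that subset (NaN where the subset is single-class)."""
    scores = np.asarray(scores, float)
    u_pred = np.asarray(u_pred, float)
    labels = np.asarray(labels)
    if not (scores.size == u_pred.size == labels.size):
        raise ValueError("scores, u_pred and labels must be aligned")
    rows = []
    for th in thresholds:
        certain = u_pred < th
        row = {"threshold": float(th), "n_certain": int(certain.sum())}
        if certain.any() and np.unique(labels[certain]).size == 2:
            m = compute_metrics(scores[certain], labels[certain])
            row.update(m.as_dict())
        else:
            row.update(auc=np.nan, accuracy=np.nan, balanced_accuracy=np.nan)
            if certain.any():
                pred = (scores[certain] >= 0.5).astype(int)
                row["accuracy"] = float(np.mean(pred == labels[certain]))
        rows.append(row)
    return pd.DataFrame(rows)
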