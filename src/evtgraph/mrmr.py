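"""Greedy minimum-redundancy maximum-relevance (mRMR) feature selection.

Relevance is the one-way ANOVA F statistic of a feature against the binary
label; redundancy is the mean absolute Pearson correlation with the already
selected set. The first feature maximizes relevance alone; each later step
adds the candidate maximizing ``relevance - redundancy`` after min-max
scaling both terms to [0, 1] over the remaining candidates (the additive MID
scheme; a quotient variant is available). Ties break lexicographically by
feature name so selection is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import FeatureMatrix

__all__ = [
    "SelectionResult",
    "relevance_fscore",
    "redundancy_pearson",
    "mrmr_select",
]

logger = logging.getLogger(__name__)

F_CAP = 1e12  # cap for degenerate (zero within-group variance) F statistics
DUPLICATE_CORR = 0.999  # |Pearson r| above this marks a near-exact duplicate


@dataclass
class SelectionResult:
    """Ordered selection with the per-step score decomposition."""

    selected: list[str]
    scores: list[dict]  # per step: name, relevance, redundancy, combined
    k: int
    fold_id: int | None = None


def relevance_fscore(x: np.ndarray, y: np.ndarray) -> float:
    """One-way ANOVA F statistic of ``x`` between the two label groups.

    Columns whose group means coincide (including constant columns) score 0;
    a zero within-group variance with distinct means (perfectly separating
    feature) is capped at a large finite value with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("relevance needs both classes present")
    groups = [x[y == c] for c in classes]
    grand = x.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    scale = max(float((x - grand) @ (x - grand)), 1.0)
    if ssb <= 1e-12 * scale:
        return 0.0
    if ssw <= 1e-12 * scale:
        logger.warning("degenerate F statistic (zero within-group variance); "
                       "capping at %.0e", F_CAP)
        return F_CAP
    df1, df2 = classes.size - 1, x.size - classes.size
    return float((ssb / df1) / (ssw / df2))


def redundancy_pearson(x: np.ndarray, selected: np.ndarray | None) -> float:
    """Mean absolute Pearson correlation between ``x`` and each selected
    column; 0 for an empty set. Constant columns correlate as 0 (warned)."""
    if selected is None or selected.size == 0:
        return 0.0
    x = np.asarray(x, dtype=float)
    S = np.atleast_2d(np.asarray(selected, dtype=float))
    if S.shape[0] == x.size and S.ndim == 2 and S.shape[1] != x.size:
        S = S.T  # accept columns-as-features layout
    xs = x - x.mean()
    xn = np.linalg.norm(xs)
    vals = []
    for row in S:
        rs = row - row.mean()
        rn = np.linalg.norm(rs)
        if xn == 0.0 or rn == 0.0:
            logger.warning("constant column in redundancy computation; using 0")
            vals.append(0.0)
        else:
            vals.append(abs(float(xs @ rs) / (xn * rn)))
    return float(np.mean(vals))


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi - lo <= 0:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def mrmr_select(
    matrix: FeatureMatrix,
    k: int = 10,
    rows: np.ndarray | None = None,
    scheme: str = "difference",
    fold_id: int | None = None,
) -> SelectionResult:
    """Greedy mRMR selection of ``k`` feature columns.

    ``rows`` restricts the computation to a subset of patients (pass the
    train+validation mask so test patients never influence selection).
    """
    if k > matrix.n_features:
        raise ValueError(f"k={k} exceeds feature count {matrix.n_features}")
    if scheme not in ("difference", "quotient"):
        raise ValueError(f"unknown scheme {scheme!r}")
    X = matrix.X if rows is None else matrix.X[np.asarray(rows)]
    y = matrix.y if rows is None else matrix.y[np.asarray(rows)]
    names = list(matrix.feature_names)

    # constant columns carry no class information; keep them out of the pool
    usable = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    if k > len(usable):
        raise ValueError(
            f"k={k} exceeds the {len(usable)} non-constant candidate columns"
        )
    relevance = np.full(X.shape[1], -np.inf)
    for j in usable:
        relevance[j] = relevance_fscore(X[:, j], y)

    selected_idx: list[int] = []
    steps: list[dict] = []
    for _ in range(k):
        candidates = [j for j in usable if j not in selected_idx]
        rel = relevance[candidates]
        if not selected_idx:
            red = np.zeros(len(candidates))
            combined = rel.copy()
        else:
            S = X[:, selected_idx].T
            red = np.array([redundancy_pearson(X[:, j], S) for j in candidates])
            max_corr = np.array([
                max(abs(float(np.corrcoef(X[:, j], X[:, s])[0, 1]))
                    for s in selected_idx)
                for j in candidates
            ])
            rel_s, red_s = _minmax(rel), _minmax(red)
            if scheme == "difference":
                combined = rel_s - red_s
            else:
                combined = rel_s / (red_s + 1e-12)
            # near-exact copies of an already-selected feature add no
            # information; push them behind every genuine candidate
            degenerate = max_corr > DUPLICATE_CORR
            if degenerate.any() and not degenerate.all():
                combined = np.where(degenerate, -np.inf, combined)
        # argmax with lexicographic-name tie-break
        best = max(
            range(len(candidates)),
            key=lambda i: (combined[i], _NegStr(names[candidates[i]])),
        )
        j = candidates[best]
        selected_idx.append(j)
        steps.append(
            {
                "name": names[j],
                "relevance": float(relevance[j]),
                "redundancy": float(red[best]),
                "combined": float(combined[best]),
            }
        )
    return SelectionResult(
        selected=[names[j] for j in selected_idx],
        scores=steps,
        k=k,
        fold_id=fold_id,
    )


class _NegStr(str):
    """String with reversed ordering, so max() prefers the lexicographically
    smallest name on score ties."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)
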