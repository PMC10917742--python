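"""Cleaning, encoding, normalization and timepoint restriction.

The pipeline order is fixed: drop sparse variables -> impute (training-only
medians) -> encode -> restrict to a timepoint -> normalize (training-only
z-scores). Outcomes are binarized per task: ``good_outcome`` (mRS <= 2 vs
mRS > 2) or ``mortality`` (mRS = 6 vs mRS < 6).

Ordinal variables are encoded as cumulative "thermometer" vectors (level k of
L sets the first k+1 positions to 1) which preserves the ordering under any
monotone weighting; nominal variables are one-hot encoded; encoded 0/1
columns are left unscaled while continuous columns are z-scored with
statistics fitted on the training rows only (sample sd, ddof = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import BLOCKS, CohortTable, VariableSpec

__all__ = [
    "TASKS",
    "FeatureMatrix",
    "binarize_outcome",
    "drop_sparse_variables",
    "impute_median",
    "encode",
    "restrict_to_blocks",
    "normalize",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)

TASKS = ("good_outcome", "mortality")

# cumulative information design: each timepoint sees all earlier blocks
_CUMULATIVE_BLOCKS = {
    "admission": ("admission",),
    "post_evt": ("admission", "post_evt"),
    "followup": ("admission", "post_evt", "followup"),
}


@dataclass
class FeatureMatrix:
    """Encoded design matrix for one prediction task.

    ``feature_kinds`` distinguishes ``continuous`` columns (z-scored during
    normalization) from ``encoded`` 0/1 columns (passed through).
    ``norm_mean``/``norm_scale`` hold the fitted normalization statistics.
    """

    X: np.ndarray
    feature_names: list[str]
    feature_blocks: list[str]
    feature_kinds: list[str]
    y: np.ndarray
    task: str
    block_set: tuple[str, ...]
    normalized: bool = False
    norm_mean: np.ndarray | None = None
    norm_scale: np.ndarray | None = None

    @property
    def n_patients(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select_columns(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return replace(
            self,
            X=self.X[:, idx].copy(),
            feature_names=[self.feature_names[i] for i in idx],
            feature_blocks=[self.feature_blocks[i] for i in idx],
            feature_kinds=[self.feature_kinds[i] for i in idx],
            norm_mean=None if self.norm_mean is None else self.norm_mean[idx],
            norm_scale=None if self.norm_scale is None else self.norm_scale[idx],
        )


def binarize_outcome(mrs: np.ndarray | pd.Series, task: str) -> np.ndarray:
    """Binary labels from 3-month mRS: good outcome = mRS <= 2, death = mRS 6."""
    mrs = np.asarray(mrs)
    if task == "good_outcome":
        return (mrs <= 2).astype(int)
    if task == "mortality":
        return (mrs == 6).astype(int)
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def drop_sparse_variables(
    table: CohortTable, max_missing: float = 0.10
) -> tuple[CohortTable, list[str]]:
    """Remove variables missing in strictly more than ``max_missing`` of rows.

    A variable missing in exactly ``max_missing`` is retained (the cleaning
    rule is "over 10% missing").
    """
    removed = [
        v.name for v in table.variables if table.missing_fraction(v.name) > max_missing
    ]
    if removed:
        logger.info("dropping %d sparse variables: %s", len(removed), removed)
    kept = tuple(v for v in table.variables if v.name not in removed)
    data = table.data.drop(columns=removed)
    return CohortTable(data, kept), removed


def _fit_imputation(table: CohortTable, fit_rows: np.ndarray) -> dict[str, float]:
    """Per-variable imputation value from the fit (training) rows only:
    median for continuous/ordinal, mode for binary/nominal (ties -> smaller)."""
    stats: dict[str, float] = {}
    sub = table.data.iloc[np.flatnonzero(np.asarray(fit_rows))]
    for v in table.variables:
        observed = sub[v.name].dropna().to_numpy()
        if observed.size == 0:
            raise ValueError(
                f"variable {v.name!r} has no observed value among the fit rows"
            )
        if v.kind in ("binary", "nominal"):
            vals, counts = np.unique(observed, return_counts=True)
            stats[v.name] = float(vals[np.argmax(counts)])
        elif v.kind == "ordinal":
            med = float(np.median(observed))
            levels = np.asarray(v.levels, dtype=float)
            stats[v.name] = float(levels[np.argmin(np.abs(levels - med))])
        else:
            stats[v.name] = float(np.median(observed))
    return stats


def impute_median(
    table: CohortTable,
    fit_rows: np.ndarray | None = None,
    return_stats: bool = False,
):
    """Fill missing cells with medians (modes for binary/nominal) computed on
    ``fit_rows`` only and applied to all rows. ``fit_rows`` defaults to all
    rows; pass the training mask to keep test statistics out of the fit."""
    n = table.n_patients
    fit_rows = np.ones(n, dtype=bool) if fit_rows is None else np.asarray(fit_rows)
    if fit_rows.dtype != bool:
        mask = np.zeros(n, dtype=bool)
        mask[fit_rows] = True
        fit_rows = mask
    if not fit_rows.any():
        raise ValueError("fit_rows is empty")
    stats = _fit_imputation(table, fit_rows)
    data = table.data.copy()
    for name, value in stats.items():
        data[name] = data[name].fillna(value)
    out = CohortTable(data, table.variables)
    return (out, stats) if return_stats else out


def _encode_variable(v: VariableSpec, col: np.ndarray):
    """Columns, names and kinds for one variable."""
    if v.kind == "continuous":
        return [col.astype(float)], [v.name], ["continuous"]
    if v.kind == "binary":
        return [col.astype(float)], [v.name], ["encoded"]
    levels = np.asarray(v.levels, dtype=float)
    idx = np.searchsorted(levels, col.astype(float))
    if np.any(idx >= len(levels)) or np.any(levels[idx.clip(max=len(levels) - 1)] != col):
        bad = col[(idx >= len(levels)) | (levels[idx.clip(max=len(levels) - 1)] != col)]
        raise ValueError(f"{v.name}: value {bad[0]!r} outside declared levels")
    L = len(levels)
    if v.kind == "nominal":
        mat = np.zeros((col.size, L))
        mat[np.arange(col.size), idx] = 1.0
    else:  # ordinal thermometer: level k -> positions 0..k set to 1
        mat = (np.arange(L)[None, :] <= idx[:, None]).astype(float)
    names = [f"{v.name}={int(l) if float(l).is_integer() else l}" for l in levels]
    if v.kind == "ordinal":
        names = [f"{v.name}>={int(l) if float(l).is_integer() else l}" for l in levels]
    return list(mat.T), names, ["encoded"] * L


def encode(table: CohortTable, task: str) -> FeatureMatrix:
    """Encode a missing-free cohort table into a numeric design matrix."""
    if table.data[table.variable_names].isna().any().any():
        missing = [n for n in table.variable_names if table.data[n].isna().any()]
        raise ValueError(f"table still has missing values in {missing}; impute first")
    cols, names, blocks, kinds = [], [], [], []
    for v in table.variables:
        c, nm, kd = _encode_variable(v, table.data[v.name].to_numpy())
        cols.extend(c)
        names.extend(nm)
        blocks.extend([v.block] * len(nm))
        kinds.extend(kd)
    X = np.column_stack(cols)
    y = binarize_outcome(table.data["mrs_3month"], task)
    return FeatureMatrix(
        X=X, feature_names=names, feature_blocks=blocks, feature_kinds=kinds,
        y=y, task=task, block_set=BLOCKS,
    )


def restrict_to_blocks(matrix: FeatureMatrix, timepoint: str) -> FeatureMatrix:
    """Keep the cumulative union of blocks up to ``timepoint``
    (admission < post_evt < followup): information available at that time."""
    if timepoint not in _CUMULATIVE_BLOCKS:
        raise ValueError(
            f"unknown timepoint {timepoint!r}; expected one of {list(_CUMULATIVE_BLOCKS)}"
        )
    keep_blocks = _CUMULATIVE_BLOCKS[timepoint]
    idx = [i for i, b in enumerate(matrix.feature_blocks) if b in keep_blocks]
    return replace(
        matrix,
        X=matrix.X[:, idx].copy(),
        feature_names=[matrix.feature_names[i] for i in idx],
        feature_blocks=[matrix.feature_blocks[i] for i in idx],
        feature_kinds=[matrix.feature_kinds[i] for i in idx],
        block_set=keep_blocks,
    )


def normalize(
    matrix: FeatureMatrix,
    fit_rows: np.ndarray | None = None,
    scale_encoded: bool = False,
) -> FeatureMatrix:
    """Z-score continuous columns using mean/sd (ddof=1) of the fit rows only.

    Encoded 0/1 columns pass through unscaled unless ``scale_encoded``.
    Columns constant on the fit rows are dropped with a logged warning.
    """
    n = matrix.n_patients
    fit_rows = np.ones(n, dtype=bool) if fit_rows is None else np.asarray(fit_rows)
    if fit_rows.dtype != bool:
        mask = np.zeros(n, dtype=bool)
        mask[fit_rows] = True
        fit_rows = mask
    if not fit_rows.any():
        raise ValueError("fit_rows is empty")

    X = matrix.X.copy()
    mean = np.zeros(matrix.n_features)
    scale = np.ones(matrix.n_features)
    drop: list[int] = []
    for j in range(matrix.n_features):
        if matrix.feature_kinds[j] != "continuous" and not scale_encoded:
            continue
        col = X[fit_rows, j]
        sd = col.std(ddof=1) if col.size > 1 else 0.0
        if sd == 0.0:
            logger.warning(
                "dropping constant column %r (zero variance on fit rows)",
                matrix.feature_names[j],
            )
            drop.append(j)
            continue
        mean[j], scale[j] = col.mean(), sd
        X[:, j] = (X[:, j] - mean[j]) / scale[j]
    keep = [j for j in range(matrix.n_features) if j not in drop]
    return replace(
        matrix,
        X=X[:, keep],
        feature_names=[matrix.feature_names[j] for j in keep],
        feature_blocks=[matrix.feature_blocks[j] for j in keep],
        feature_kinds=[matrix.feature_kinds[j] for j in keep],
        normalized=True,
        norm_mean=mean[keep],
        norm_scale=scale[keep],
    )


def preprocess_pipeline(
    table: CohortTable,
    task: str,
    timepoint: str,
    fit_rows: np.ndarray | None = None,
    max_missing: float = 0.10,
) -> FeatureMatrix:
    """Full fixed-order pipeline: drop sparse -> impute -> encode -> restrict
    -> normalize, with imputation and normalization fitted on ``fit_rows``."""
    table, _ = drop_sparse_variables(table, max_missing)
    table = impute_median(table, fit_rows)
    matrix = encode(table, task)
    matrix = restrict_to_blocks(matrix, timepoint)
    return normalize(matrix, fit_rows)
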