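"""Patient population graphs gated by phenotype similarity.

Nodes are patients; the edge weight between patients i and j is

    W(i, j) = sim(m_i, m_j) * delta(i, j)

where m is the 4-entry meta vector (age, sex, NIHSS, pre-stroke mRS),
``sim`` maps the correlation distance between the cohort-standardized meta
vectors into [0, 1] (sim = 1 - d_corr/2 = (1 + r)/2, so correlated patients
get heavy edges), and ``delta`` is a task-specific binary gate:

* functional outcome: equal pre-stroke mRS and age difference < 3 years;
* mortality: same sex and age difference < 4 years.

Both inequalities are strict. Gates are conjunctions over the four meta
fields and can be re-derived by a validation-AUC grid search.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .cohort import CohortTable
from .preprocess import impute_median

__all__ = [
    "META_FIELDS",
    "MetaVector",
    "GatingRule",
    "PopulationGraph",
    "GOOD_OUTCOME_RULE",
    "MORTALITY_RULE",
    "rule_for_task",
    "meta_from_cohort",
    "standardize_meta",
    "meta_similarity",
    "delta_mrs",
    "delta_mortality",
    "build_graph",
    "default_gating_grid",
    "neighbor_vote_auc",
    "gating_grid_search",
]

logger = logging.getLogger(__name__)

META_FIELDS = ("age", "sex", "nihss", "prev_mrs")


@dataclass(frozen=True)
class MetaVector:
    """Admission phenotype used for graph construction."""

    age: float
    sex: int
    nihss: int
    prev_mrs: int

    def __post_init__(self) -> None:
        if self.prev_mrs > 2:
            raise ValueError("pre-stroke mRS > 2 violates the inclusion criterion")
        if self.nihss < 0:
            raise ValueError("NIHSS must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.age, self.sex, self.nihss, self.prev_mrs], dtype=float)


@dataclass(frozen=True)
class GatingRule:
    """Conjunction of conditions over meta fields deciding edge existence.

    Each condition is ``(field, comparator, threshold)`` with comparator
    ``"absdiff_lt"`` (|x_i - x_j| < threshold, strict) or ``"equal"``
    (threshold ignored).
    """

    task: str
    conditions: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        # canonical conjunct order: rules differing only in condition order
        # are the same rule
        ordered = tuple(sorted(self.conditions,
                               key=lambda c: META_FIELDS.index(c[0])))
        object.__setattr__(self, "conditions", ordered)
        for fieldname, comparator, threshold in self.conditions:
            if fieldname not in META_FIELDS:
                raise ValueError(f"unknown meta field {fieldname!r}")
            if comparator not in ("absdiff_lt", "equal"):
                raise ValueError(f"unknown comparator {comparator!r}")
            if comparator == "absdiff_lt" and not threshold > 0:
                raise ValueError("absdiff_lt threshold must be strictly positive")

    def gate_matrix(self, meta_raw: np.ndarray) -> np.ndarray:
        """n x n binary gate from raw (unstandardized) meta values."""
        n = meta_raw.shape[0]
        gate = np.ones((n, n), dtype=bool)
        for fieldname, comparator, threshold in self.conditions:
            col = meta_raw[:, META_FIELDS.index(fieldname)]
            diff = np.abs(col[:, None] - col[None, :])
            gate &= (diff == 0) if comparator == "equal" else (diff < threshold)
        np.fill_diagonal(gate, False)  # no self loops
        return gate

    def describe(self) -> str:
        parts = [
            f"{f} == {f}'" if c == "equal" else f"|d{f}| < {t:g}"
            for f, c, t in self.conditions
        ]
        return " and ".join(parts) if parts else "always connected"


GOOD_OUTCOME_RULE = GatingRule(
    "good_outcome",
    (("prev_mrs", "absdiff_lt", 1.0), ("age", "absdiff_lt", 3.0)),
)
MORTALITY_RULE = GatingRule(
    "mortality",
    (("sex", "equal", 0.0), ("age", "absdiff_lt", 4.0)),
)


def rule_for_task(task: str) -> GatingRule:
    if task == "good_outcome":
        return GOOD_OUTCOME_RULE
    if task == "mortality":
        return MORTALITY_RULE
    raise ValueError(f"unknown task {task!r}")


@dataclass
class PopulationGraph:
    """Symmetric non-negative weighted patient graph (no self loops)."""

    weights: sp.csr_matrix
    gating: GatingRule | None = None

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.weights.nnz // 2)

    @property
    def isolated_nodes(self) -> np.ndarray:
        degree = np.asarray(self.weights.sum(axis=1)).ravel()
        return np.flatnonzero(degree == 0)

    @property
    def edge_list(self) -> list[tuple[int, int, float]]:
        coo = sp.triu(self.weights, k=1).tocoo()
        return list(zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist()))


def meta_from_cohort(table: CohortTable) -> np.ndarray:
    """Raw n x 4 meta matrix (age, sex, NIHSS, pre-stroke mRS); missing meta
    cells are filled with cohort medians — graph construction is transductive
    and uses only admission phenotype, never labels."""
    needed = [f for f in META_FIELDS if f in table.variable_names]
    if len(needed) != 4:
        missing = set(META_FIELDS) - set(needed)
        raise ValueError(f"cohort lacks meta variables {sorted(missing)}")
    if table.data[list(META_FIELDS)].isna().any().any():
        table = impute_median(table)
    return table.data[list(META_FIELDS)].to_numpy(dtype=float)


def standardize_meta(meta_raw: np.ndarray) -> np.ndarray:
    """Cohort-wide z-scoring of each meta field so no field dominates the
    correlation (age is in years, the others are small scores)."""
    meta_raw = np.asarray(meta_raw, dtype=float)
    sd = meta_raw.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (meta_raw - meta_raw.mean(axis=0)) / sd


def _pairwise_similarity(meta_std: np.ndarray, mode: str = "affinity") -> np.ndarray:
    A = meta_std - meta_std.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(A, axis=1)
    degenerate = norms == 0
    if degenerate.any():
        logger.warning(
            "%d zero-variance meta vectors; their similarities set to 0",
            int(degenerate.sum()),
        )
    safe = np.where(degenerate, 1.0, norms)
    corr = (A @ A.T) / np.outer(safe, safe)
    corr = np.clip(corr, -1.0, 1.0)
    sim = (1.0 + corr) / 2.0 if mode == "affinity" else (1.0 - corr)  # d_corr
    sim[degenerate, :] = 0.0
    sim[:, degenerate] = 0.0
    return sim


def meta_similarity(
    m_i: MetaVector | np.ndarray,
    m_j: MetaVector | np.ndarray,
    mode: str = "affinity",
) -> float:
    """Similarity between two standardized meta vectors.

    ``affinity`` (default) returns 1 - d_corr/2 = (1 + r)/2 in [0, 1]; the
    raw correlation distance is available with ``mode="distance"``. Inputs
    are assumed already standardized cohort-wide.
    """
    a = m_i.as_array() if isinstance(m_i, MetaVector) else np.asarray(m_i, float)
    b = m_j.as_array() if isinstance(m_j, MetaVector) else np.asarray(m_j, float)
    sim = _pairwise_similarity(np.vstack([a, b]), mode=mode)
    return float(sim[0, 1])


def delta_mrs(m_i, m_j) -> int:
    """Gate for functional-outcome graphs: equal pre-stroke mRS (the integer
    reading of |diff| < 1) and age difference strictly below 3 years."""
    a = m_i if isinstance(m_i, MetaVector) else MetaVector(*np.asarray(m_i, float))
    b = m_j if isinstance(m_j, MetaVector) else MetaVector(*np.asarray(m_j, float))
    return int(abs(a.prev_mrs - b.prev_mrs) < 1 and abs(a.age - b.age) < 3)


def delta_mortality(m_i, m_j) -> int:
    """Gate for mortality graphs: same sex and age difference strictly below
    4 years."""
    a = m_i if isinstance(m_i, MetaVector) else MetaVector(*np.asarray(m_i, float))
    b = m_j if isinstance(m_j, MetaVector) else MetaVector(*np.asarray(m_j, float))
    return int(a.sex == b.sex and abs(a.age - b.age) < 4)


def build_graph(
    meta_raw: np.ndarray,
    rule: GatingRule,
    mode: str = "affinity",
) -> PopulationGraph:
    """Dense gate + similarity product, stored sparse.

    Gating thresholds apply to the raw meta values (age in years); the
    similarity uses the cohort-standardized vectors.
    """
    meta_raw = np.asarray(meta_raw, dtype=float)
    if meta_raw.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    gate = rule.gate_matrix(meta_raw)
    sim = _pairwise_similarity(standardize_meta(meta_raw), mode=mode)
    W = np.where(gate, sim, 0.0)
    np.fill_diagonal(W, 0.0)
    graph = PopulationGraph(sp.csr_matrix(W), gating=rule)
    logger.info(
        "built graph: %d nodes, %d edges, %d isolated (%s)",
        graph.n_nodes, graph.n_edges, graph.isolated_nodes.size, rule.describe(),
    )
    return graph


# ---------------------------------------------------------------------------
# Gating grid search
# ---------------------------------------------------------------------------

def default_gating_grid(task: str, max_conjuncts: int = 2) -> list[GatingRule]:
    """Conjunctive candidate rules over the 4 meta variables.

    Threshold windows: age 1-10 years, pre-stroke mRS 1-3 levels, NIHSS
    2-10 points, sex equality. All non-empty conjunctions of at most
    ``max_conjuncts`` conditions (one per variable).
    """
    per_var: dict[str, list[tuple[str, str, float]]] = {
        "age": [("age", "absdiff_lt", float(t)) for t in range(1, 11)],
        "prev_mrs": [("prev_mrs", "absdiff_lt", float(t)) for t in (1, 2, 3)],
        "nihss": [("nihss", "absdiff_lt", float(t)) for t in range(2, 11)],
        "sex": [("sex", "equal", 0.0)],
    }
    rules: list[GatingRule] = []
    for r in range(1, max_conjuncts + 1):
        for combo in itertools.combinations(META_FIELDS, r):
            for conds in itertools.product(*(per_var[v] for v in combo)):
                rules.append(GatingRule(task, tuple(conds)))
    return rules


def neighbor_vote_auc(
    graph: PopulationGraph,
    y: np.ndarray,
    train_mask: np.ndarray,
    val_mask: np.ndarray,
) -> float:
    """Validation AUC of a weighted neighbor-vote scorer: each validation
    node is scored by the weight-averaged label of its training neighbors
    (prevalence for nodes without any). A cheap downstream model for rating
    candidate graphs."""
    from sklearn.metrics import roc_auc_score

    y = np.asarray(y)
    train_mask = np.asarray(train_mask, bool)
    val_mask = np.asarray(val_mask, bool)
    W = graph.weights
    num = W[:, train_mask] @ y[train_mask]
    den = np.asarray(W[:, train_mask].sum(axis=1)).ravel()
    prevalence = float(y[train_mask].mean())
    scores = np.where(den > 0, num / np.where(den == 0, 1.0, den), prevalence)
    if np.unique(y[val_mask]).size < 2:
        raise ValueError("validation mask holds a single class")
    return float(roc_auc_score(y[val_mask], scores[val_mask]))


def gating_grid_search(
    meta_raw: np.ndarray,
    y: np.ndarray,
    splits: list[tuple[np.ndarray, np.ndarray]],
    grid: list[GatingRule] | None = None,
    trainer=neighbor_vote_auc,
    task: str = "good_outcome",
):
    """Pick the gating rule maximizing mean validation AUC over ``splits``.

    ``trainer(graph, y, train_mask, val_mask) -> AUC`` rates each candidate
    graph; ties (and duplicates) resolve to the first rule in the grid.
    Returns ``(best_rule, results)`` with the full grid table. Raises if every
    candidate yields an edgeless graph.
    """
    grid = default_gating_grid(task) if grid is None else list(grid)
    if not grid:
        raise ValueError("empty gating grid")
    results = []
    degenerate = []
    best_rule, best_score = None, -np.inf
    for rule in grid:
        graph = build_graph(meta_raw, rule)
        if graph.n_edges == 0:
            degenerate.append(rule.describe())
            results.append({"rule": rule.describe(), "mean_val_auc": np.nan,
                            "n_edges": 0})
            continue
        aucs = [trainer(graph, y, tr, va) for tr, va in splits]
        score = float(np.mean(aucs))
        results.append({"rule": rule.describe(), "mean_val_auc": score,
                        "n_edges": graph.n_edges})
        if score > best_score:  # strict: first-in-grid wins ties
            best_rule, best_score = rule, score
    if best_rule is None:
        raise ValueError(
            "every candidate rule produced an edgeless graph: "
            + "; ".join(degenerate)
        )
    return best_rule, results
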