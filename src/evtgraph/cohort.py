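"""Synthetic cohorts of endovascular-thrombectomy patients.

The real study cohort (220 anterior-circulation stroke patients treated with
mechanical thrombectomy at a single center) is private, so this module
generates seedable stand-ins with the same group-conditional structure: each
clinical variable is sampled conditionally on the patient's 3-month outcome
group, with group parameters transcribed from the published univariate
summaries (mean +/- SD for continuous variables, median [IQR] for ordinal
scores, event frequencies for binary variables).

Three outcome groups are distinguished so that both prediction tasks carry
signal: ``good`` (mRS <= 2), ``poor_alive`` (2 < mRS < 6) and ``dead``
(mRS = 6). Death is a sub-event of poor outcome, matching the semantics of
the modified Rankin Scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "GROUPS",
    "BLOCKS",
    "VariableSpec",
    "CohortSpec",
    "PatientRecord",
    "CohortTable",
    "ordinal_probs_from_median_iqr",
    "default_spec",
    "planted_spec",
    "generate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

GROUPS = ("good", "poor_alive", "dead")
BLOCKS = ("admission", "post_evt", "followup")
KINDS = ("continuous", "ordinal", "binary", "nominal")

MISSING = np.nan


class CohortSpecError(ValueError):
    """Raised when a cohort or variable specification violates its invariants."""


class CohortParseError(ValueError):
    """Raised when a cohort CSV / schema file cannot be parsed."""


@dataclass(frozen=True)
class VariableSpec:
    """Distributional description of one clinical variable.

    ``params_by_group`` maps each outcome group to
      - ``(mean, sd)`` for continuous variables,
      - a probability vector over ``levels`` for ordinal/nominal variables,
      - a positive-event probability for binary variables.
    """

    name: str
    kind: str
    block: str
    params_by_group: dict
    levels: tuple | None = None
    missing_rate: float = 0.0

    def validate(self) -> None:
        if self.kind not in KINDS:
            raise CohortSpecError(f"{self.name}: unknown kind {self.kind!r}")
        if self.block not in BLOCKS:
            raise CohortSpecError(f"{self.name}: unknown block {self.block!r}")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise CohortSpecError(
                f"{self.name}: missing_rate {self.missing_rate} outside [0, 0.5]"
            )
        if set(self.params_by_group) != set(GROUPS):
            raise CohortSpecError(
                f"{self.name}: params_by_group must cover groups {GROUPS}"
            )
        for g, p in self.params_by_group.items():
            if self.kind == "continuous":
                mean, sd = p
                if not sd > 0:
                    raise CohortSpecError(f"{self.name}/{g}: sd must be > 0, got {sd}")
            elif self.kind == "binary":
                if not 0.0 <= p <= 1.0:
                    raise CohortSpecError(f"{self.name}/{g}: probability {p} outside [0,1]")
            else:
                if self.levels is None:
                    raise CohortSpecError(f"{self.name}: {self.kind} variable needs levels")
                probs = np.asarray(p, dtype=float)
                if probs.shape != (len(self.levels),):
                    raise CohortSpecError(
                        f"{self.name}/{g}: {len(probs)} probabilities for "
                        f"{len(self.levels)} levels"
                    )
                if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
                    raise CohortSpecError(f"{self.name}/{g}: probabilities must sum to 1")


@dataclass(frozen=True)
class CohortSpec:
    """Full generative description of a synthetic cohort."""

    variables: tuple[VariableSpec, ...]
    n_patients: int = 220
    p_good: float = 81 / 220
    p_dead: float = 42 / 220
    mrs_level_probs: tuple[float, ...] = ()
    seed: int = 0
    severity_corr: float = 0.0  # latent shared-severity factor; 0 disables

    def validate(self) -> None:
        if not self.variables:
            raise CohortSpecError("spec has no variables")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise CohortSpecError("duplicate variable names")
        for v in self.variables:
            v.validate()
        if not 0.0 < self.p_good < 1.0:
            raise CohortSpecError("p_good must lie in (0, 1)")
        if not 0.0 <= self.p_dead <= 1.0 - self.p_good + 1e-12:
            raise CohortSpecError("p_dead must not exceed 1 - p_good")
        probs = np.asarray(self.mrs_level_probs, dtype=float)
        if probs.shape != (7,):
            raise CohortSpecError("mrs_level_probs must have 7 entries (mRS 0..6)")
        if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise CohortSpecError("mrs_level_probs must sum to 1")
        if not math.isclose(probs[:3].sum(), self.p_good, abs_tol=1e-9):
            raise CohortSpecError("P(mRS<=2) must equal p_good")
        if not math.isclose(probs[6], self.p_dead, abs_tol=1e-9):
            raise CohortSpecError("P(mRS=6) must equal p_dead")
        if not 0.0 <= self.severity_corr < 1.0:
            raise CohortSpecError("severity_corr must lie in [0, 1)")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    mrs_3month: int
    values: dict

    def __post_init__(self) -> None:
        if self.mrs_3month not in range(7):
            raise CohortSpecError(f"mRS {self.mrs_3month} outside 0..6")


@dataclass
class CohortTable:
    """Patient x variable table plus per-variable metadata.

    ``data`` holds one row per patient with columns ``patient_id``,
    ``mrs_3month`` and one column per variable; NaN marks a missing cell.
    ``variables`` carries the metadata (name, kind, block, levels) needed by
    the preprocessing stages; generative parameters are not retained.
    """

    data: pd.DataFrame
    variables: tuple[VariableSpec, ...]

    def __post_init__(self) -> None:
        expected = {"patient_id", "mrs_3month"} | {v.name for v in self.variables}
        if set(self.data.columns) != expected:
            raise CohortSpecError(
                "table columns do not match variable metadata: "
                f"{sorted(set(self.data.columns) ^ expected)}"
            )

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def records(self) -> list[PatientRecord]:
        out = []
        for _, row in self.data.iterrows():
            values = {v.name: row[v.name] for v in self.variables}
            out.append(
                PatientRecord(str(row["patient_id"]), int(row["mrs_3month"]), values)
            )
        return out

    def missing_fraction(self, name: str) -> float:
        return float(self.data[name].isna().mean())

    def equals(self, other: "CohortTable") -> bool:
        return self.variables == other.variables and self.data.equals(other.data)


def ordinal_probs_from_median_iqr(
    levels: Sequence[int], median: float, q1: float, q3: float
) -> tuple[float, ...]:
    """Level probabilities of a discretized normal matching a printed median [IQR].

    The latent normal has mu = median and sigma = IQR / 1.349 (floored at 0.5
    so degenerate IQRs like 0 [0-0] stay proper); mass is integrated between
    midpoints of adjacent levels, with open-ended tails.
    """
    levels = np.asarray(levels, dtype=float)
    sigma = max((q3 - q1) / 1.349, 0.5)
    edges = np.concatenate(([-np.inf], (levels[:-1] + levels[1:]) / 2.0, [np.inf]))
    cdf = norm.cdf(edges, loc=median, scale=sigma)
    probs = np.diff(cdf)
    probs = probs / probs.sum()
    return tuple(float(p) for p in probs)


def _three_group(good, poor_alive, dead) -> dict:
    return {"good": good, "poor_alive": poor_alive, "dead": dead}


def _uniform_group(params) -> dict:
    return {g: params for g in GROUPS}


def _ord(levels, good, poor, dead) -> dict:
    """Ordinal params from per-group (median, q1, q3); poor column reused for
    poor-alive (mixture inversion of medians is not well posed)."""
    return _three_group(
        ordinal_probs_from_median_iqr(levels, *good),
        ordinal_probs_from_median_iqr(levels, *poor),
        ordinal_probs_from_median_iqr(levels, *dead),
    )


# Default class mix: 81/220 good, 97/220 poor-alive, 42/220 dead, with the
# good and poor mass spread over the individual mRS levels.
_DEFAULT_MRS_PROBS = tuple(c / 220 for c in (20, 28, 33, 36, 33, 28, 42))


def default_spec() -> CohortSpec:
    """Cohort spec transcribing the published group-conditional summaries.

    Continuous poor-alive means are recovered from the mixture identity
    178 * alive_mean = 81 * good_mean + 97 * poor_alive_mean, so that both the
    good/poor and the alive/dead marginal splits are respected. Binary dead
    counts likewise follow good + poor = alive + dead where the printed cells
    are inconsistent.
    """
    mrs_levels = tuple(range(7))
    v = [
        # --- admission: metadata & clinical information ---
        VariableSpec(
            "age", "continuous", "admission",
            _three_group((65.48, 12.38), (73.70, 11.18), (77.14, 10.50)),
        ),
        VariableSpec("sex", "binary", "admission", _uniform_group(0.47)),
        VariableSpec(
            "nihss", "ordinal", "admission",
            _ord(range(43), (12, 7, 14), (17, 12, 20), (19, 14, 24)),
            levels=tuple(range(43)),
        ),
        VariableSpec(
            "prev_mrs", "ordinal", "admission",
            _ord(range(3), (0, 0, 0), (0, 0, 1), (1, 0, 2)),
            levels=(0, 1, 2),
        ),
        VariableSpec(
            "diabetes", "binary", "admission",
            _three_group(10 / 81, 26 / 97, 11 / 42),
        ),
        VariableSpec(
            "atrial_fibrillation", "binary", "admission",
            _three_group(26 / 81, 48 / 97, 23 / 42),
        ),
        VariableSpec(
            "doac", "binary", "admission",
            _three_group(3 / 81, 11 / 97, 8 / 42),
            missing_rate=0.03,
        ),
        # --- admission: CT / CT-perfusion imaging biomarkers ---
        VariableSpec(
            "e_aspects", "ordinal", "admission",
            _ord(range(11), (9, 8, 10), (8, 6, 10), (8, 6, 10)),
            levels=tuple(range(11)),
        ),
        VariableSpec(
            "tan_score", "ordinal", "admission",
            _ord(range(4), (2, 2, 3), (2, 1, 2), (1, 1, 2)),
            levels=(0, 1, 2, 3),
            missing_rate=0.04,
        ),
        VariableSpec(
            "coves_score", "ordinal", "admission",
            _ord(range(6), (2, 1, 3), (1, 0, 2), (0, 0, 2)),
            levels=tuple(range(6)),
            missing_rate=0.05,
        ),
        VariableSpec(
            "clot_burden_score", "ordinal", "admission",
            _ord(range(11), (7, 6, 8), (7, 6, 8), (6, 6, 8)),
            levels=tuple(range(11)),
            missing_rate=0.04,
        ),
        VariableSpec(
            "cbf30_volume", "continuous", "admission",
            _three_group((8.69, 17.78), (21.15, 41.11), (34.02, 47.83)),
            missing_rate=0.02,
        ),
        VariableSpec(
            "tmax6_volume", "continuous", "admission",
            _three_group((125.2, 85.6), (140.8, 94.1), (173.1, 110.5)),
            missing_rate=0.02,
        ),
        VariableSpec(
            "hypoperfusion_index", "continuous", "admission",
            _three_group((0.38, 0.23), (0.47, 0.24), (0.50, 0.27)),
            missing_rate=0.02,
        ),
        VariableSpec(
            "cbv_index", "continuous", "admission",
            _three_group((0.78, 0.13), (0.74, 0.15), (0.68, 0.18)),
            missing_rate=0.02,
        ),
        VariableSpec(
            "unknown_onset", "binary", "admission",
            _three_group(25 / 81, 46 / 97, 19 / 42),
        ),
        # --- admission filler (identically distributed across groups) ---
        VariableSpec(
            "glucose_admission", "continuous", "admission",
            _uniform_group((132.0, 38.0)),
        ),
        VariableSpec("smoking", "binary", "admission", _uniform_group(0.24)),
        VariableSpec("hypertension", "binary", "admission", _uniform_group(0.66)),
        VariableSpec(
            "crp_admission", "continuous", "admission",
            _uniform_group((9.0, 14.0)),
            missing_rate=0.15,  # above the 10% cleaning cut, as in the real table
        ),
        # --- post-EVT: treatment / reperfusion information ---
        VariableSpec(
            "tici", "ordinal", "post_evt",
            # grades 0, 1, 2a, 2b, 3 coded 0..4
            _ord(range(5), (4, 3, 4), (4, 3, 4), (4, 3, 4)),
            levels=tuple(range(5)),
        ),
        VariableSpec(
            "sae", "binary", "post_evt",
            _three_group(9 / 81, 11 / 97, 16 / 42),
        ),
        VariableSpec(
            "time_to_intervention", "continuous", "post_evt",
            _three_group((59.6, 22.5), (66.94, 28.9), (48.23, 32.02)),
            missing_rate=0.05,
        ),
        VariableSpec(
            "n_maneuvers", "ordinal", "post_evt",
            _uniform_group(ordinal_probs_from_median_iqr(range(1, 7), 2, 1, 3)),
            levels=tuple(range(1, 7)),
        ),
        VariableSpec(
            "device", "nominal", "post_evt",
            _uniform_group((0.5, 0.3, 0.2)),
            levels=(0, 1, 2),
        ),
        VariableSpec(
            "general_anesthesia", "binary", "post_evt", _uniform_group(0.41)
        ),
        # --- follow-up CT after 24 h ---
        VariableSpec(
            "infarct_volume_followup", "continuous", "followup",
            _three_group((27.01, 26.03), (50.74, 49.74), (74.34, 60.55)),
            missing_rate=0.03,
        ),
        VariableSpec(
            "aspects_followup", "ordinal", "followup",
            _ord(range(11), (10, 9, 10), (8, 5, 10), (8, 4, 9)),
            levels=tuple(range(11)),
            missing_rate=0.03,
        ),
        VariableSpec(
            "hemorrhagic_transformation", "binary", "followup",
            _uniform_group(0.15),
            missing_rate=0.05,
        ),
    ]
    spec = CohortSpec(
        variables=tuple(v),
        n_patients=220,
        p_good=81 / 220,
        p_dead=42 / 220,
        mrs_level_probs=_DEFAULT_MRS_PROBS,
        seed=0,
    )
    spec.validate()
    return spec


def planted_spec(
    effects_by_block: dict | None = None,
    n_signal_per_block: int = 3,
    n_noise_per_block: int = 3,
    sd: float = 1.0,
) -> CohortSpec:
    """Cohort spec with a controllable planted effect per timepoint block.

    Each block gets ``n_signal_per_block`` continuous variables whose
    good-vs-poor mean gap equals ``effects_by_block[block] * sd`` (dead group
    shifted half a gap further), plus identically distributed noise variables.
    Useful for testing that later-timepoint information helps exactly when it
    carries more signal.
    """
    effects_by_block = effects_by_block or {
        "admission": 0.3, "post_evt": 0.8, "followup": 1.5
    }
    variables = [
        VariableSpec("age", "continuous", "admission", _uniform_group((70.0, 12.0))),
        VariableSpec("sex", "binary", "admission", _uniform_group(0.5)),
        VariableSpec(
            "nihss", "ordinal", "admission",
            _uniform_group(ordinal_probs_from_median_iqr(range(43), 15, 10, 19)),
            levels=tuple(range(43)),
        ),
        VariableSpec(
            "prev_mrs", "ordinal", "admission",
            _uniform_group(ordinal_probs_from_median_iqr(range(3), 0, 0, 1)),
            levels=(0, 1, 2),
        ),
    ]
    for block in BLOCKS:
        gap = effects_by_block.get(block, 0.0) * sd
        for i in range(n_signal_per_block):
            variables.append(
                VariableSpec(
                    f"{block}_signal_{i}", "continuous", block,
                    _three_group((0.0, sd), (gap, sd), (1.5 * gap, sd)),
                )
            )
        for i in range(n_noise_per_block):
            variables.append(
                VariableSpec(
                    f"{block}_noise_{i}", "continuous", block,
                    _uniform_group((0.0, sd)),
                )
            )
    spec = CohortSpec(
        variables=tuple(variables),
        mrs_level_probs=_DEFAULT_MRS_PROBS,
    )
    spec.validate()
    return spec


def _group_of_mrs(mrs: int) -> str:
    if mrs <= 2:
        return "good"
    return "dead" if mrs == 6 else "poor_alive"


def generate_cohort(
    spec: CohortSpec, n: int | None = None, seed: int | None = None
) -> CohortTable:
    """Sample a cohort table from ``spec``.

    Outcome (mRS level, hence group) is drawn first; every variable is then
    drawn from its group-conditional distribution, conditionally independently
    given the group unless ``spec.severity_corr > 0``, in which case a shared
    latent severity factor induces within-patient correlation across the
    continuous and ordinal variables. Missingness is applied independently per
    cell (missing completely at random). Fully deterministic in (spec, n, seed).
    """
    spec.validate()
    n = spec.n_patients if n is None else int(n)
    if n < 10:
        raise CohortSpecError(f"need n >= 10 patients, got {n}")
    seed = spec.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)

    mrs = rng.choice(7, size=n, p=np.asarray(spec.mrs_level_probs))
    groups = np.array([_group_of_mrs(int(m)) for m in mrs])
    rho = spec.severity_corr
    z = rng.standard_normal(n)  # latent severity, used only when rho > 0

    columns: dict[str, np.ndarray] = {
        "patient_id": np.array([f"P{i:04d}" for i in range(n)], dtype=object),
        "mrs_3month": mrs.astype(int),
    }
    for var in spec.variables:
        eps = rng.standard_normal(n)
        u = rho * z + math.sqrt(1.0 - rho * rho) * eps
        values = np.empty(n, dtype=float)
        for g in GROUPS:
            idx = groups == g
            if not idx.any():
                continue
            params = var.params_by_group[g]
            if var.kind == "continuous":
                mean, sd = params
                values[idx] = mean + sd * u[idx]
            elif var.kind == "binary":
                # independent of the severity factor; uses its own draws
                values[idx] = (norm.cdf(eps[idx]) < params).astype(float)
            else:
                probs = np.asarray(params, dtype=float)
                cum = np.cumsum(probs)
                q = norm.cdf(u[idx])
                lev = np.searchsorted(cum, q, side="right").clip(0, len(probs) - 1)
                values[idx] = np.asarray(var.levels, dtype=float)[lev]
        if var.missing_rate > 0:
            mask = rng.random(n) < var.missing_rate
            values = values.copy()
            values[mask] = MISSING
        columns[var.name] = values

    return CohortTable(pd.DataFrame(columns), spec.variables)


# ---------------------------------------------------------------------------
# CSV round trip (data in a flat CSV, variable metadata in a JSON sidecar)
# ---------------------------------------------------------------------------

def _schema_path(path: Path) -> Path:
    return path.with_name(path.name + ".schema.json")


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    """Write a cohort to ``path`` (CSV, empty cell = missing) plus a
    ``<path>.schema.json`` sidecar with the variable metadata."""
    path = Path(path)
    table.data.to_csv(path, index=False)
    schema = [
        {
            "name": v.name,
            "kind": v.kind,
            "block": v.block,
            "levels": list(v.levels) if v.levels is not None else None,
            "missing_rate": v.missing_rate,
        }
        for v in table.variables
    ]
    _schema_path(path).write_text(json.dumps(schema, indent=1))


def read_cohort_csv(path: str | Path) -> CohortTable:
    """Read a cohort written by :func:`write_cohort_csv`.

    Metadata (kind/block/levels) is restored from the sidecar; generative
    parameters are not stored, so placeholder group parameters are attached.
    """
    path = Path(path)
    schema_file = _schema_path(path)
    if not schema_file.exists():
        raise CohortParseError(f"missing schema sidecar {schema_file}")
    try:
        schema = json.loads(schema_file.read_text())
    except json.JSONDecodeError as exc:
        raise CohortParseError(f"malformed schema {schema_file}: {exc}") from exc
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("patient_id", "mrs_3month"):
        if col not in df.columns:
            raise CohortParseError(f"{path}: required column {col!r} absent")
    for entry in schema:
        name = entry["name"]
        if name not in df.columns:
            raise CohortParseError(f"{path}: schema variable {name!r} not in CSV")
    known = {e["name"] for e in schema} | {"patient_id", "mrs_3month"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        raise CohortParseError(f"{path}: columns {extra} not described by schema")

    variables = []
    for entry in schema:
        name, kind = entry["name"], entry["kind"]
        levels = tuple(entry["levels"]) if entry.get("levels") else None
        col = df[name]
        bad = col[~col.isna() & pd.to_numeric(col, errors="coerce").isna()]
        if len(bad):
            raise CohortParseError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in column {name!r}, "
                f"row {bad.index[0]}"
            )
        df[name] = pd.to_numeric(col, errors="coerce").astype(float)
        if kind == "continuous":
            params = _uniform_group((0.0, 1.0))
        elif kind == "binary":
            params = _uniform_group(0.5)
        else:
            if levels is None:
                raise CohortParseError(f"{path}: {name!r} ({kind}) lacks levels")
            flat = tuple(1.0 / len(levels) for _ in levels)
            params = _uniform_group(flat)
        variables.append(
            VariableSpec(name, kind, entry["block"], params, levels,
                         float(entry.get("missing_rate", 0.0)))
        )
    df["mrs_3month"] = df["mrs_3month"].astype(int)
    df["patient_id"] = df["patient_id"].astype(str).astype(object)
    return CohortTable(df, tuple(variables))
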