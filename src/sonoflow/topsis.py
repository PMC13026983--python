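"""TOPSIS multi-criteria ranking of scenarios from a KPI decision matrix.

Technique for Order of Preference by Similarity to Ideal Solution, the
classical Hwang-Yoon procedure:

1. decision matrix ``a_ij`` (m alternatives x n criteria),
2. vector normalization ``n_ij = a_ij / sqrt(sum_i a_ij²)``,
3. weighting ``v_ij = w_j * n_ij`` with ``sum w_j = 1``,
4. ideal point A+ (per column: max for benefit criteria, min for cost
   criteria) and negative-ideal point A− (the reverse),
5. Euclidean separations ``S_i+ = sqrt(sum_j (v_ij − v_j+)²)`` and ``S_i−``,
6. relative closeness ``C_i = S_i− / (S_i− + S_i+)``,
7. rank alternatives by descending ``C_i``.

For the department study the alternatives are scenarios S1-S6 and the
criteria are AWT, WIP, PST (minimized) and UtilADC (maximized).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DecisionMatrix",
    "WeightVector",
    "TopsisResult",
    "normalize",
    "ideal_points",
    "topsis_rank",
    "read_decision_matrix",
]


@dataclass(frozen=True)
class DecisionMatrix:
    """m x n KPI values with a min/max direction per criterion."""

    values: np.ndarray
    alternatives: tuple[str, ...]
    criteria: tuple[str, ...]
    directions: tuple[str, ...]  # "min" (cost) or "max" (benefit) per criterion

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", a)
        object.__setattr__(self, "alternatives", tuple(self.alternatives))
        object.__setattr__(self, "criteria", tuple(self.criteria))
        object.__setattr__(self, "directions", tuple(self.directions))
        m, n = a.shape
        if m < 2 or n < 1:
            raise ValueError(f"need >= 2 alternatives and >= 1 criterion, got {a.shape}")
        if len(self.alternatives) != m or len(self.criteria) != n:
            raise ValueError("label lengths do not match the matrix shape")
        if len(self.directions) != n:
            raise ValueError("one direction per criterion required")
        if any(d not in ("min", "max") for d in self.directions):
            raise ValueError("directions must be 'min' or 'max'")
        if not np.all(np.isfinite(a)):
            raise ValueError("decision matrix values must be finite")
        if np.any((a == 0).all(axis=0)):
            raise ValueError("decision matrix has an all-zero criterion column")


@dataclass(frozen=True)
class WeightVector:
    """Criterion weights in [0, 1] summing to 1."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.ndim != 1:
            raise ValueError("weights must be a vector")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        if abs(float(w.sum()) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()}")


@dataclass(frozen=True)
class TopsisResult:
    """All intermediate matrices and the final ranking."""

    n_matrix: np.ndarray
    v_matrix: np.ndarray
    ideal: np.ndarray
    neg_ideal: np.ndarray
    s_plus: np.ndarray
    s_minus: np.ndarray
    closeness: np.ndarray
    ranks: np.ndarray  # rank of each alternative, 1 = best, aligned with input order
    alternatives: tuple[str, ...]
    degenerate: bool = False  # all alternatives identical -> Ci fixed at 0.5

    @property
    def ordering(self) -> tuple[str, ...]:
        """Alternative labels from best to worst."""
        order = np.argsort(self.ranks, kind="stable")
        return tuple(self.alternatives[i] for i in order)

    def to_dataframe(self) -> pd.DataFrame:
        """Table mirroring the usual report layout: Si+, Si−, Ci, Rank."""
        return pd.DataFrame(
            {
                "Si+": self.s_plus,
                "Si-": self.s_minus,
                "Ci": self.closeness,
                "Rank": self.ranks,
            },
            index=list(self.alternatives),
        )


def normalize(matrix: DecisionMatrix) -> np.ndarray:
    """Vector-normalize each column to unit Euclidean norm."""
    a = matrix.values
    norms = np.sqrt((a**2).sum(axis=0))
    return a / norms


def ideal_points(v_matrix: np.ndarray, directions) -> tuple[np.ndarray, np.ndarray]:
    """Ideal (A+) and negative-ideal (A−) points of a weighted matrix."""
    is_max = np.array([d == "max" for d in directions])
    a_plus = np.where(is_max, v_matrix.max(axis=0), v_matrix.min(axis=0))
    a_minus = np.where(is_max, v_matrix.min(axis=0), v_matrix.max(axis=0))
    return a_plus, a_minus


def topsis_rank(matrix: DecisionMatrix, weights) -> TopsisResult:
    """Run the full TOPSIS procedure and rank the alternatives.

    ``weights`` may be a :class:`WeightVector` or any sequence summing to 1.
    Ties in closeness keep input order; if every alternative coincides with
    both ideal points (all rows identical) the closeness is defined as 0.5
    and the result is flagged degenerate.
    """
    if not isinstance(weights, WeightVector):
        weights = WeightVector(np.asarray(weights, dtype=float))
    if weights.w.size != len(matrix.criteria):
        raise ValueError(
            f"{weights.w.size} weights for {len(matrix.criteria)} criteria"
        )
    n = normalize(matrix)
    v = n * weights.w
    a_plus, a_minus = ideal_points(v, matrix.directions)
    s_plus = np.sqrt(((v - a_plus) ** 2).sum(axis=1))
    s_minus = np.sqrt(((v - a_minus) ** 2).sum(axis=1))
    denom = s_plus + s_minus
    degenerate = bool(np.any(denom == 0.0))
    closeness = np.where(denom > 0.0, s_minus / np.where(denom == 0, 1.0, denom), 0.5)
    order = np.argsort(-closeness, kind="stable")  # stable: ties keep input order
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    return TopsisResult(
        n_matrix=n, v_matrix=v, ideal=a_plus, neg_ideal=a_minus,
        s_plus=s_plus, s_minus=s_minus, closeness=closeness, ranks=ranks,
        alternatives=matrix.alternatives, degenerate=degenerate,
    )


def read_decision_matrix(path) -> DecisionMatrix:
    """Read an alternatives x criteria CSV whose first row gives directions.

    Layout::

        alternative,AWT,WIP,PST,UtilADC
        direction,min,min,min,max
        S1,40.87,13.55,62.17,0.43
        ...
    """
    df = pd.read_csv(path, index_col=0)
    if "direction" not in df.index:
        raise ValueError("decision-matrix CSV needs a 'direction' row")
    directions = tuple(str(d).strip().lower() for d in df.loc["direction"])
    body = df.drop(index="direction").astype(float)
    return DecisionMatrix(
        values=body.to_numpy(),
        alternatives=tuple(str(i) for i in body.index),
        criteria=tuple(str(c) for c in body.columns),
        directions=directions,
    )
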