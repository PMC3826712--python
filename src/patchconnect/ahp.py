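"""Analytic Hierarchy Process (AHP) criterion weighting.

Saaty's eigenvector method: expert judgments enter as a positive reciprocal
pairwise-comparison matrix on a 1-9 scale (1 = equal importance); the weight
vector is the normalized principal right eigenvector, computed here by power
iteration.  Judgment consistency is summarized by

    CI = (lambda_max - n) / (n - 1),     CR = CI / RI(n),

where RI(n) are Saaty's published random-index constants.  A CR below 0.1 is
conventionally accepted as consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ComparisonMatrix", "WeightSet", "ConsistencyReport", "compute_weights", "check_consistency", "RANDOM_INDEX"]

# Saaty's random consistency indices for n = 1..10.
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

_RECIPROCAL_RTOL = 1e-9


@dataclass(frozen=True)
class ComparisonMatrix:
    """A positive reciprocal pairwise-comparison matrix with criterion labels."""

    entries: np.ndarray
    criteria_names: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", a)
        object.__setattr__(self, "criteria_names", tuple(self.criteria_names))
        n = len(self.criteria_names)
        if a.ndim != 2 or a.shape != (n, n):
            raise ValueError(f"matrix shape {a.shape} does not match {n} criteria")
        if n < 2:
            raise ValueError("a comparison matrix needs at least 2 criteria")
        if not np.all(a > 0):
            raise ValueError("comparison matrix entries must be positive")
        if not np.allclose(np.diag(a), 1.0, rtol=_RECIPROCAL_RTOL):
            raise ValueError("comparison matrix diagonal must be 1")
        if not np.allclose(a * a.T, 1.0, rtol=1e-6):
            raise ValueError("comparison matrix must be reciprocal (a_ji = 1/a_ij)")

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    @classmethod
    def from_dict(cls, obj: dict) -> "ComparisonMatrix":
        return cls(np.array(obj["entries"], dtype=float), tuple(obj["criteria"]))

    def to_dict(self) -> dict:
        return {"criteria": list(self.criteria_names), "entries": self.entries.tolist()}


@dataclass(frozen=True)
class WeightSet:
    """Normalized criterion weights plus AHP consistency diagnostics.

    ``weights`` always sums to exactly 1 (renormalized after the eigenvector
    solve, and after loading externally supplied weight vectors whose printed
    values may carry rounding residue).
    """

    weights: dict[str, float]
    lambda_max: float = float("nan")
    consistency_index: float = float("nan")
    consistency_ratio: float = float("nan")

    def __post_init__(self) -> None:
        total = float(sum(self.weights.values()))
        if not np.isfinite(total) or total <= 0:
            raise ValueError("weights must be positive and finite")
        object.__setattr__(self, "weights", {k: v / total for k, v in self.weights.items()})

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.weights)

    def as_array(self, order: tuple[str, ...] | list[str] | None = None) -> np.ndarray:
        order = tuple(order) if order is not None else self.names
        return np.array([self.weights[name] for name in order])

    @classmethod
    def from_weights(cls, weights: dict[str, float]) -> "WeightSet":
        """Wrap an externally supplied weight vector (no consistency info)."""
        return cls(dict(weights))

    def to_dict(self) -> dict:
        return {
            "weights": dict(self.weights),
            "lambda_max": self.lambda_max,
            "consistency_index": self.consistency_index,
            "consistency_ratio": self.consistency_ratio,
        }


@dataclass(frozen=True)
class ConsistencyReport:
    passed: bool
    consistency_ratio: float
    consistency_index: float
    lambda_max: float
    threshold: float


def _principal_eigenvector(a: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000) -> tuple[np.ndarray, float]:
    """Power iteration for the principal right eigenpair of a positive matrix.

    Converges when successive L1-normalized vectors differ by < ``tol`` in max
    norm.  For a positive matrix the Perron eigenpair is unique, so the
    iteration always converges from the uniform start.
    """
    n = a.shape[0]
    v = np.full(n, 1.0 / n)
    lam = float("nan")
    for _ in range(max_iter):
        w = a @ v
        s = w.sum()
        w /= s
        if np.max(np.abs(w - v)) < tol:
            v = w
            break
        v = w
    # Rayleigh-style estimate: with v normalized to sum 1, sum(A v) = lambda.
    lam = float((a @ v).sum())
    return v, lam


def compute_weights(matrix: ComparisonMatrix) -> WeightSet:
    """Criterion weights = normalized principal eigenvector of ``matrix``.

    Also reports lambda_max, CI = (lambda_max - n)/(n - 1), and CR = CI/RI(n).
    CR is defined as 0 for n <= 2 (2x2 reciprocal matrices are always
    consistent, and RI(2) = 0).
    """
    n = matrix.n
    v, lam = _principal_eigenvector(matrix.entries)
    ci = (lam - n) / (n - 1)
    if n <= 2:
        cr = 0.0
    else:
        ri = RANDOM_INDEX.get(n)
        if ri is None:
            raise ValueError(f"no random-index constant for n={n} (supported: 1..10)")
        cr = ci / ri
    return WeightSet(
        weights=dict(zip(matrix.criteria_names, v.tolist())),
        lambda_max=lam,
        consistency_index=ci,
        consistency_ratio=max(cr, 0.0),
    )


def check_consistency(weightset: WeightSet, threshold: float = 0.1) -> ConsistencyReport:
    """Pass iff the consistency ratio is strictly below ``threshold``."""
    cr = weightset.consistency_ratio
    if not np.isfinite(cr):
        raise ValueError("weight set carries no consistency ratio (not produced by compute_weights)")
    return ConsistencyReport(
        passed=bool(cr < threshold),
        consistency_ratio=cr,
        consistency_index=weightset.consistency_index,
        lambda_max=weightset.lambda_max,
        threshold=threshold,
    )
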