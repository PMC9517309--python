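"""Analytic hierarchy process: criterion weights and consistency checking.

Given a reciprocal pairwise-comparison matrix, the criterion weights are the
principal eigenvector (computed by power iteration), the maximum eigenvalue
λmax is its Rayleigh-type quotient, and consistency is judged by

    CI = (λmax − n) / (n − 1),      CR = CI / RI(n),

with RI the tabulated random index for the matrix order; the matrix passes
when CR < 0.1.  A feature-vector path reproduces weight percentages from a
published priority vector directly.  Survey descriptive rates round out the
questionnaire bookkeeping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Random consistency index per matrix order (orders 1–2 are defined as 0;
#: the published table covers orders 3–30).
RI_TABLE: dict[int, float] = {
    1: 0.0, 2: 0.0,
    3: 0.52, 4: 0.89, 5: 1.12, 6: 1.26, 7: 1.36, 8: 1.41, 9: 1.46,
    10: 1.49, 11: 1.52, 12: 1.54, 13: 1.56, 14: 1.58, 15: 1.59, 16: 1.5943,
    17: 1.6064, 18: 1.6133, 19: 1.6207, 20: 1.6292, 21: 1.6383, 22: 1.6403,
    23: 1.6462, 24: 1.6497, 25: 1.6556, 26: 1.6587, 27: 1.6631, 28: 1.6670,
    29: 1.6693, 30: 1.6724,
}

CONSISTENCY_LIMIT = 0.1


class AHPValidationError(ValueError):
    """The pairwise matrix is not a valid positive reciprocal matrix."""


def validate_pairwise_matrix(m) -> np.ndarray:
    """Check square shape, positivity, unit diagonal and reciprocity (1e-9)."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise AHPValidationError(f"matrix must be square, got shape {m.shape}")
    if not np.all(np.isfinite(m)) or np.any(m <= 0):
        raise AHPValidationError("all entries must be positive finite reals")
    if not np.allclose(np.diag(m), 1.0, atol=1e-9):
        raise AHPValidationError("diagonal entries must all equal 1")
    if not np.allclose(m * m.T, 1.0, atol=1e-9):
        raise AHPValidationError("reciprocal symmetry a_ij = 1/a_ji violated")
    return m


@dataclass
class AHPResult:
    """Weights, eigenvalue and consistency diagnostics for one matrix."""

    weights: np.ndarray
    feature_vector: np.ndarray
    lambda_max: float
    ci: float
    ri: float
    cr: float
    consistent: bool
    n: int

    def weights_percent(self) -> np.ndarray:
        return np.round(self.weights * 100.0, 3)

    def summary(self) -> str:
        lines = ["AHP result", "-" * 40,
                 f"order n = {self.n}",
                 f"lambda_max = {self.lambda_max:.6f}",
                 f"CI = {self.ci:.3f}   RI = {self.ri:.3g}   CR = {self.cr:.3f}",
                 f"consistent (CR < {CONSISTENCY_LIMIT}): {self.consistent}",
                 "weights (%): " + ", ".join(
                     f"{w:.3f}" for w in self.weights_percent())]
        return "\n".join(lines)


def power_iteration(m: np.ndarray, tol: float = 1e-12, max_iter: int = 10000
                    ) -> tuple[np.ndarray, float]:
    """Principal eigenvector (L1-normalized) and eigenvalue of a positive matrix.

    Convergence is guaranteed for positive matrices (Perron–Frobenius);
    λmax is recovered as the mean of the component-wise Rayleigh ratios
    (Mw)_i / w_i, the standard AHP estimator.
    """
    n = m.shape[0]
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        w_new = m @ w
        w_new /= w_new.sum()
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    lam = float(np.mean((m @ w) / w))
    return w, lam


def ahp_solve(m) -> AHPResult:
    """Solve a reciprocal pairwise matrix for weights and consistency."""
    m = validate_pairwise_matrix(m)
    n = m.shape[0]
    w, lam = power_iteration(m)
    ci = consistency_index(lam, n) if n >= 2 else 0.0
    ri = RI_TABLE.get(n)
    if ri is None:
        raise ValueError(f"no random index tabulated for order {n}")
    cr = consistency_ratio(ci, n) if n >= 1 else 0.0
    return AHPResult(weights=w, feature_vector=w * n, lambda_max=lam,
                     ci=ci, ri=ri, cr=cr,
                     consistent=cr < CONSISTENCY_LIMIT, n=n)


def consistent_matrix(weights) -> np.ndarray:
    """The perfectly consistent matrix a_ij = w_i / w_j for given weights."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return np.outer(w, 1.0 / w)


def weights_from_feature_vector(v) -> np.ndarray:
    """Percent weights from a priority (feature) vector: v_i / Σv × 100.

    Rounded to 3 decimals, matching the published presentation.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("feature vector must be a non-empty 1-D array")
    if not np.all(np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("feature-vector entries must be positive")
    return np.round(v / v.sum() * 100.0, 3)


def consistency_index(lambda_max: float, n: int) -> float:
    """CI = (λmax − n)/(n − 1); requires order n ≥ 2."""
    if n < 2:
        raise ValueError("consistency index requires order n >= 2")
    return (lambda_max - n) / (n - 1)


def consistency_ratio(ci: float, n: int, ri_table: dict[int, float] | None = None
                      ) -> float:
    """CR = CI / RI(n).  Orders 1–2 have RI = 0 and return CR = 0."""
    table = RI_TABLE if ri_table is None else ri_table
    if n not in table:
        raise ValueError(f"no random index tabulated for order {n}")
    if n < 3:
        logger.info("order %d matrix is consistent by construction; CR = 0", n)
        return 0.0
    return ci / table[n]


def response_rates(sent: int, returned: int, valid: int) -> tuple[float, float]:
    """Questionnaire (recovery %, effective %) rounded to 1 decimal.

    Recovery = returned/sent, effective = valid/sent; requires
    0 ≤ valid ≤ returned ≤ sent and sent > 0.
    """
    if sent <= 0:
        raise ValueError("sent must be positive")
    if not (0 <= valid <= returned <= sent):
        raise ValueError("counts must satisfy 0 <= valid <= returned <= sent")
    return (round(returned / sent * 100.0, 1), round(valid / sent * 100.0, 1))
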