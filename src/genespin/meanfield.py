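"""Mean-field theory of the gene-spin model on a fixed degree sequence.

Replacing each neighbour state by the global mean M decouples the model
into independent nodes in an effective field ``h + J M k_i`` and yields
the self-consistency equation

    M = (1/N) sum_i 1 / (1 + exp(-beta (h + J M k_i)))

(the antiferromagnetic variant is obtained by passing a negative J).
The right-hand side maps [0, 1] into (0, 1), so a damped fixed-point
iteration converges; starting the iteration from M = 0 and M = 1
exposes the two branches of the bistable (first-order) regime.  The
high-temperature expansion gives ``M ≈ (1/2)(2 + beta h)/(2 -/+ beta J m)``
(minus for ferromagnetic coupling), and the vanishing of the average
mapped local field predicts the critical field ``h_c ≈ J m``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import InvalidParameterError, SingularApproximationError

__all__ = [
    "MeanFieldSolution",
    "BranchScan",
    "mf_fixed_point",
    "mf_high_T_approx",
    "critical_field",
    "mf_branch_scan",
]


@dataclass(frozen=True)
class MeanFieldSolution:
    """Converged order parameter and diagnostics of the damped iteration."""

    M: float
    start_M: float
    n_iterations: int
    converged: bool
    residual: float


def _compress_degrees(degree_sequence) -> tuple[np.ndarray, np.ndarray]:
    k = np.asarray(degree_sequence, dtype=np.float64).ravel()
    if k.size == 0:
        raise InvalidParameterError("degree sequence must be nonempty")
    uniq, counts = np.unique(k, return_counts=True)
    return uniq, counts / k.size


def mf_fixed_point(degree_sequence, J: float, h: float, T: float,
                   start_M: float = 0.5, damping: float = 0.5,
                   tol: float = 1e-10, max_iter: int = 100_000) -> MeanFieldSolution:
    """Solve the self-consistency equation by damped fixed-point iteration.

    ``M <- (1 - damping) M + damping f(M)`` until ``|f(M) - M| < tol``.
    When successive residuals change sign (the map slope exceeds one in
    magnitude, which happens at very large beta) the damping factor is
    halved, which restores local stability without affecting the
    fixed point.  ``T`` must be positive; ``T = inf`` (beta = 0) is the
    exact high-temperature limit where every logistic term is 1/2.
    """
    if not T > 0:
        raise InvalidParameterError(
            f"mean-field iteration requires T > 0 (got T={T}); "
            "use the analytic limits for T = 0")
    if not 0.0 <= start_M <= 1.0:
        raise InvalidParameterError("start_M must lie in [0, 1]")
    uniq_k, weights = _compress_degrees(degree_sequence)
    beta = 0.0 if math.isinf(T) else 1.0 / T
    if beta == 0.0:
        return MeanFieldSolution(M=0.5, start_M=start_M, n_iterations=0,
                                 converged=True, residual=0.0)

    def f(m: float) -> float:
        return float(weights @ expit(beta * (h + J * m * uniq_k)))

    m = float(start_M)
    lam = float(damping)
    prev_diff = 0.0
    for it in range(1, max_iter + 1):
        fm = f(m)
        assert 0.0 <= fm <= 1.0  # f maps [0,1] into (0,1)
        diff = fm - m
        if abs(diff) < tol:
            return MeanFieldSolution(M=fm, start_M=start_M, n_iterations=it,
                                     converged=True, residual=abs(diff))
        if diff * prev_diff < 0.0:
            lam *= 0.5  # overshoot: the damped map is locally unstable
        prev_diff = diff
        m += lam * diff
    return MeanFieldSolution(M=m, start_M=start_M, n_iterations=max_iter,
                             converged=False, residual=abs(f(m) - m))


def mf_high_T_approx(J: float, m: int, h: float, T: float,
                     coupling_sign: str = "ferro") -> float:
    """Closed-form high-temperature order parameter.

    ``M ≈ (1/2) (2 + beta h) / (2 - beta J m)`` for ferromagnetic
    coupling and ``(2 + beta J m)`` in the denominator for
    antiferromagnetic coupling; valid for ``T >> 1``.
    """
    if not T > 0:
        raise InvalidParameterError("T must be positive")
    if coupling_sign not in ("ferro", "antiferro"):
        raise InvalidParameterError("coupling_sign must be 'ferro' or 'antiferro'")
    beta = 0.0 if math.isinf(T) else 1.0 / T
    sign = -1.0 if coupling_sign == "ferro" else 1.0
    denom = 2.0 + sign * beta * J * m
    if abs(denom) < 1e-12:
        raise SingularApproximationError(
            "high-temperature closed form is singular at 2 = -/+ beta J m")
    return 0.5 * (2.0 + beta * h) / denom


def critical_field(J: float, m: int) -> float:
    """Mean-field critical external field ``h_c = J m``.

    Follows from the vanishing of the average intrinsic local field of
    the mapped classical model: ``h/2 = (J/4) k_bar`` with
    ``k_bar ≈ 2m`` on a BA network.
    """
    if m < 1:
        raise InvalidParameterError("m must be >= 1")
    return float(J) * float(m)


@dataclass
class BranchScan:
    """Low-start and high-start mean-field branches over a field grid.

    ``jump_h_low`` / ``jump_h_high`` locate each branch's largest
    adjacent-point discontinuity (grid midpoint); ``None`` if the branch
    nowhere jumps by more than 0.5.
    """

    table: pd.DataFrame
    jump_h_low: float | None
    jump_h_high: float | None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _jump_location(h: np.ndarray, m_vals: np.ndarray) -> float | None:
    if m_vals.size < 2:
        return None
    d = np.abs(np.diff(m_vals))
    i = int(np.argmax(d))
    if d[i] <= 0.5:
        return None
    return float(0.5 * (h[i] + h[i + 1]))


def mf_branch_scan(degree_sequence, J: float, T: float, h_grid) -> BranchScan:
    """Run the fixed-point solver from M = 0 and M = 1 at each field value.

    A point is flagged bistable when the two branches differ by more
    than 0.5 — the signature of the first-order transition.
    """
    h_grid = np.asarray(h_grid, dtype=np.float64)
    if h_grid.ndim != 1 or h_grid.size < 1:
        raise InvalidParameterError("h_grid must be a nonempty 1-D grid")
    if np.any(np.diff(h_grid) < 0):
        raise InvalidParameterError("h_grid must be sorted ascending")
    rows = []
    for h in h_grid:
        low = mf_fixed_point(degree_sequence, J, float(h), T, start_M=0.0)
        high = mf_fixed_point(degree_sequence, J, float(h), T, start_M=1.0)
        rows.append((float(h), low.M, high.M, abs(high.M - low.M) > 0.5))
    table = pd.DataFrame(rows, columns=["h", "M_low_branch", "M_high_branch",
                                        "bistable"])
    return BranchScan(
        table=table,
        jump_h_low=_jump_location(h_grid, table["M_low_branch"].to_numpy()),
        jump_h_high=_jump_location(h_grid, table["M_high_branch"].to_numpy()),
    )
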