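"""Ensemble experiments: temperature/field sweeps, hysteresis, h_c scans.

Each sweep runs independent equilibrium chains for every (network
realization, control value) pair — no state is carried between control
values — and reports the across-realization mean and standard error of
the order parameter.  The hysteresis protocol is the one exception: the
final configuration at each field value seeds the chain at the next one,
which is what makes the first-order memory visible.

Critical-field estimation follows the activation transition: chains
start from the all-inactive state with antiferromagnetic coupling and
the field grid ascends; the estimate is the field at which the ensemble
mean first crosses 1/2, linearly interpolated between grid points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, NoTransitionError
from .mcmc import ChainSchedule, run_chain
from .network import BAParams, Network, generate_ba_network
from .spin_model import ModelParams, SpinConfiguration

__all__ = [
    "SweepResult",
    "HysteresisLoop",
    "temperature_sweep",
    "field_sweep",
    "hysteresis_loop",
    "estimate_critical_field",
    "critical_field_scan",
    "default_temperature_grid",
    "default_field_grid",
]

_SEED_MASK = 0x7FFFFFFF


def default_temperature_grid(n_points: int = 25) -> np.ndarray:
    return np.logspace(np.log10(0.1), np.log10(100.0), n_points)


def default_field_grid(n_points: int = 81) -> np.ndarray:
    return np.linspace(-10.0, 10.0, n_points)


def _network_seed(master_seed: int, r: int) -> int:
    return (int(master_seed) ^ r) & _SEED_MASK


def _chain_seeds(master_seed: int, r: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(entropy=(int(master_seed) & _SEED_MASK, r))
    return ss.generate_state(n) & _SEED_MASK


def _resolve_init(init: str | None, network: Network,
                  params: ModelParams) -> SpinConfiguration | None:
    if init is None:
        return None  # run_chain applies the convention default
    if init == "active":
        return SpinConfiguration.all_active(network.n_nodes)
    if init == "inactive":
        return SpinConfiguration.all_inactive(network.n_nodes)
    raise InvalidParameterError("init must be 'active', 'inactive', or None")


@dataclass
class SweepResult:
    """Ensemble order-parameter statistics over a control-parameter grid."""

    control_name: str  # "temperature" or "field"
    control_values: np.ndarray
    M_per_realization: np.ndarray  # (n_realizations, n_control)
    M_mean: np.ndarray
    M_stderr: np.ndarray
    n_realizations: int
    params: dict = dc_field(default_factory=dict)

    def tidy_df(self) -> pd.DataFrame:
        r_idx, c_idx = np.meshgrid(np.arange(self.n_realizations),
                                   np.arange(self.control_values.size),
                                   indexing="ij")
        return pd.DataFrame({
            "realization": r_idx.ravel(),
            self.control_name: self.control_values[c_idx.ravel()],
            "M": self.M_per_realization.ravel(),
        })

    def summary_df(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.control_name: self.control_values,
            "M_mean": self.M_mean,
            "M_stderr": self.M_stderr,
        })


def _ensemble_sweep(control_name: str, control_values, net_params: BAParams,
                    make_params, n_realizations: int, schedule: ChainSchedule | None,
                    master_seed: int, init: str | None,
                    network: Network | None, meta: dict) -> SweepResult:
    values = np.asarray(control_values, dtype=np.float64)
    if values.ndim != 1 or values.size < 1:
        raise InvalidParameterError("control grid must be a nonempty 1-D vector")
    if np.any(np.diff(values) < 0):
        raise InvalidParameterError("control grid must be sorted ascending")
    if n_realizations < 1:
        raise InvalidParameterError("n_realizations must be >= 1")
    schedule = schedule or ChainSchedule()
    M = np.empty((n_realizations, values.size))
    for r in range(n_realizations):
        net = network if network is not None else generate_ba_network(
            net_params.n_nodes, net_params.m, net_params.m0,
            seed=_network_seed(master_seed, r))
        seeds = _chain_seeds(master_seed, r, values.size)
        for c, v in enumerate(values):
            params = make_params(float(v))
            result = run_chain(net, params, schedule.with_seed(int(seeds[c])),
                               init=_resolve_init(init, net, params))
            M[r, c] = result.mean_M
    mean = M.mean(axis=0)
    stderr = (M.std(axis=0, ddof=1) / math.sqrt(n_realizations)
              if n_realizations > 1 else np.zeros(values.size))
    return SweepResult(control_name=control_name, control_values=values,
                       M_per_realization=M, M_mean=mean, M_stderr=stderr,
                       n_realizations=n_realizations, params=meta)


def temperature_sweep(net_params: BAParams, J: float, h: float, T_grid=None,
                      n_realizations: int = 20, schedule: ChainSchedule | None = None,
                      master_seed: int = 0, init: str | None = None,
                      network: Network | None = None) -> SweepResult:
    """Equilibrium M versus temperature over an ensemble of BA realizations."""
    T_grid = default_temperature_grid() if T_grid is None else T_grid
    if np.any(np.asarray(T_grid) <= 0):
        raise InvalidParameterError("temperature grid must be positive")
    meta = {"J": J, "h": h, "net_params": net_params, "master_seed": master_seed}
    return _ensemble_sweep("temperature", T_grid, net_params,
                           lambda T: ModelParams(J=J, h=h, T=T),
                           n_realizations, schedule, master_seed, init, network, meta)


def field_sweep(net_params: BAParams, J: float, T_fixed: float, h_grid=None,
                n_realizations: int = 20, schedule: ChainSchedule | None = None,
                master_seed: int = 0, init: str | None = None,
                network: Network | None = None) -> SweepResult:
    """Equilibrium M versus external field at fixed temperature.

    Every (realization, h) pair gets a fresh, independent chain — use
    :func:`hysteresis_loop` to carry state along the field sweep.
    """
    h_grid = default_field_grid() if h_grid is None else h_grid
    meta = {"J": J, "T": T_fixed, "net_params": net_params,
            "master_seed": master_seed}
    return _ensemble_sweep("field", h_grid, net_params,
                           lambda h: ModelParams(J=J, h=h, T=T_fixed),
                           n_realizations, schedule, master_seed, init, network, meta)


@dataclass
class HysteresisLoop:
    """Forward and backward field branches of a state-carrying sweep."""

    h_values_forward: np.ndarray
    M_forward: np.ndarray
    h_values_backward: np.ndarray
    M_backward: np.ndarray
    loop_area: float

    def summary_df(self) -> pd.DataFrame:
        return pd.DataFrame({
            "h": np.concatenate([self.h_values_forward, self.h_values_backward]),
            "M": np.concatenate([self.M_forward, self.M_backward]),
            "branch": ["forward"] * self.h_values_forward.size
                      + ["backward"] * self.h_values_backward.size,
        })

    def branch_crossing(self, branch: str, level: float = 0.5) -> float | None:
        """Field at which a branch first crosses ``level`` along its own direction."""
        h = self.h_values_forward if branch == "forward" else self.h_values_backward
        m = self.M_forward if branch == "forward" else self.M_backward
        for i in range(len(h) - 1):
            lo, hi = sorted((m[i], m[i + 1]))
            if lo <= level <= hi and m[i] != m[i + 1]:
                return float(h[i] + (level - m[i]) * (h[i + 1] - h[i])
                             / (m[i + 1] - m[i]))
            if m[i] == level:
                return float(h[i])
        return None


def hysteresis_loop(network: Network, J: float, T: float, h_start: float = 10.0,
                    h_end: float = -10.0, n_points: int = 81,
                    schedule: ChainSchedule | None = None,
                    seed: int = 0) -> HysteresisLoop:
    """Drive the field from h_start to h_end and back, carrying state.

    At each field value the chain thermalises from the final
    configuration of the previous one; the loop area is the trapezoidal
    ``|closed integral of M dh|``.
    """
    if n_points < 2:
        raise InvalidParameterError("n_points must be >= 2")
    schedule = schedule or ChainSchedule()
    h_f = np.linspace(h_start, h_end, n_points)
    h_b = h_f[::-1].copy()
    if h_start > 0:
        config = SpinConfiguration.all_active(network.n_nodes)
    elif h_start < 0:
        config = SpinConfiguration.all_inactive(network.n_nodes)
    else:
        config = (SpinConfiguration.all_active(network.n_nodes) if J > 0
                  else SpinConfiguration.all_inactive(network.n_nodes))
    seeds = _chain_seeds(seed, 0, 2 * n_points)
    m_f = np.empty(n_points)
    m_b = np.empty(n_points)
    for idx, h in enumerate(h_f):
        res = run_chain(network, ModelParams(J=J, h=float(h), T=T),
                        schedule.with_seed(int(seeds[idx])), init=config)
        m_f[idx] = res.mean_M
        config = res.final_config
    for idx, h in enumerate(h_b):
        res = run_chain(network, ModelParams(J=J, h=float(h), T=T),
                        schedule.with_seed(int(seeds[n_points + idx])), init=config)
        m_b[idx] = res.mean_M
        config = res.final_config
    area = abs(np.trapezoid(m_f, h_f) + np.trapezoid(m_b, h_b))
    return HysteresisLoop(h_values_forward=h_f, M_forward=m_f,
                          h_values_backward=h_b, M_backward=m_b,
                          loop_area=float(area))


def estimate_critical_field(sweep: SweepResult) -> float:
    """Field at which the ensemble mean M first crosses 1/2 from below.

    Linearly interpolates between the bracketing grid points; an exact
    grid hit resolves to that grid point (ties toward lower h).
    """
    if sweep.control_name != "field":
        raise InvalidParameterError("estimate_critical_field requires a field sweep")
    h = sweep.control_values
    m = sweep.M_mean
    idx = None
    for i in range(m.size):
        if m[i] >= 0.5:
            idx = i
            break
    if idx is None or idx == 0:
        raise NoTransitionError(
            "sweep mean never crosses 0.5 from below; no transition to locate")
    if m[idx] == 0.5:
        return float(h[idx])
    m0, m1 = m[idx - 1], m[idx]
    return float(h[idx - 1] + (0.5 - m0) * (h[idx] - h[idx - 1]) / (m1 - m0))


def _hc_field_grid(J: float, m: int) -> np.ndarray:
    """Default ascending grid bracketing the activation transition."""
    top = 2.0 * abs(J) * m + 1.0
    return np.linspace(-1.0, top, 33)


def critical_field_scan(vary: str, values, fixed: dict | None = None,
                        n_realizations: int = 20,
                        schedule: ChainSchedule | None = None,
                        master_seed: int = 0,
                        h_grid=None) -> pd.DataFrame:
    """Measured versus analytic critical field across J, m, or N.

    For each value of the varied parameter, runs an ascending field
    sweep with antiferromagnetic coupling (-|J|) from the all-inactive
    state and locates the 1/2 crossing; the analytic column is the
    mean-field line ``J * m``.
    """
    if vary not in ("J", "m", "N"):
        raise InvalidParameterError("vary must be one of 'J', 'm', 'N'")
    values = np.asarray(values, dtype=np.float64)
    if np.any(np.diff(values) < 0):
        raise InvalidParameterError("values must be ascending")
    fixed = dict(fixed or {})
    base = {"J": 1.0, "m": 5, "N": 5000, "T": 0.1, "m0": None}
    base.update(fixed)
    rows = []
    for v in values:
        J = float(v) if vary == "J" else float(base["J"])
        m = int(v) if vary == "m" else int(base["m"])
        n = int(v) if vary == "N" else int(base["N"])
        grid = _hc_field_grid(J, m) if h_grid is None else np.asarray(h_grid, float)
        sweep = field_sweep(BAParams(n_nodes=n, m=m, m0=base["m0"]), J=-abs(J),
                            T_fixed=float(base["T"]), h_grid=grid,
                            n_realizations=n_realizations, schedule=schedule,
                            master_seed=master_seed, init="inactive")
        rows.append((float(v), estimate_critical_field(sweep),
                     critical_field_line(J, m)))
    return pd.DataFrame(rows, columns=["value", "h_c_hat_MC", "h_c_analytic"])


def critical_field_line(J: float, m: int) -> float:
    """Analytic mean-field line h_c = J m (re-exported for the scan table)."""
    from .meanfield import critical_field

    return critical_field(abs(J), m)
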