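"""DII-VENUS reporter forward model.

Auxin degrades the DII-VENUS reporter through a small interaction network:
auxin binds its receptor (TIR1/AFB) to form a complex, and the complex
targets the reporter for degradation on top of a slow basal turnover.  With
auxin held fixed in a cell the network has a unique steady state that is
strictly decreasing in auxin, so the predicted reporter map is the
elementwise image of the cellular auxin field: high DII-VENUS means low
auxin and vice versa.

Network (per cell, auxin a treated as a fixed input):

    receptor binding   a + r  <-> c        (k_on, k_off)
    reporter           dv/dt = delta - mu_basal v - k_deg c v

At steady state c* = r_tot a / (a + K_D) with K_D = k_off/k_on, and

    v*(a) = delta / (mu_basal + k_deg c*(a))

normalized so v*(0) = ``normalization`` (default 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AuxinState, ODESystem


class DIIError(ValueError):
    pass


@dataclass(frozen=True)
class DIIParams:
    """Reporter-network parameters (s, uM units)."""

    production: float = 1.0  # delta: reporter production rate
    k_on: float = 1.0  # auxin-receptor association, 1/(uM s)
    k_off: float = 1.2  # auxin-receptor dissociation, 1/s
    r_tot: float = 1.0  # total receptor pool, uM
    k_deg: float = 0.03  # complex-mediated reporter degradation, 1/(uM s)
    basal_turnover: float = 3e-4  # 1/s
    normalization: float = 1.0

    def __post_init__(self):
        if min(
            self.production,
            self.k_on,
            self.k_off,
            self.r_tot,
            self.k_deg,
            self.basal_turnover,
            self.normalization,
        ) <= 0:
            raise DIIError("all DII network rates must be > 0")

    @property
    def kd(self) -> float:
        return self.k_off / self.k_on


def dii_steady_state(auxin, params: DIIParams = DIIParams()):
    """Steady-state normalized DII-VENUS level at fixed auxin (uM).

    Accepts scalars or arrays; strictly decreasing and continuous in auxin,
    equal to ``params.normalization`` at auxin = 0 and approaching the
    basal-turnover-limited minimum as auxin grows.
    """
    a = np.asarray(auxin, float)
    if np.any(a < 0):
        raise DIIError("auxin must be >= 0")
    complex_ss = params.r_tot * a / (a + params.kd)
    v = params.production / (params.basal_turnover + params.k_deg * complex_ss)
    v0 = params.production / params.basal_turnover
    out = params.normalization * v / v0
    return float(out) if np.isscalar(auxin) else out


@dataclass
class DIIState:
    """Predicted normalized DII-VENUS level per cell."""

    level: dict[int, float]

    def array(self, cell_ids=None) -> np.ndarray:
        ids = sorted(self.level) if cell_ids is None else list(cell_ids)
        return np.array([self.level[i] for i in ids])


def predict_dii(state: AuxinState, params: DIIParams = DIIParams()) -> DIIState:
    """Map a cellular auxin field to the predicted DII-VENUS field.

    Wall compartments are excluded: the reporter is nuclear.
    """
    return DIIState(
        level={cid: dii_steady_state(a, params) for cid, a in state.cell.items()}
    )


def dii_trajectory(
    times: np.ndarray,
    auxin_series: np.ndarray,
    params: DIIParams = DIIParams(),
    v0: np.ndarray | None = None,
) -> np.ndarray:
    """Co-integrate the reporter ODE against a time-varying auxin input.

    ``auxin_series`` has shape (n_times, n_cells); auxin is interpolated
    linearly between frames and the receptor binding is taken at quasi-steady
    state (it equilibrates in seconds).  Returns reporter levels of the same
    shape, normalized like :func:`dii_steady_state`.  This mode exists for
    deposition experiments; steady-state mapping is the default elsewhere.
    """
    from scipy.integrate import solve_ivp

    times = np.asarray(times, float)
    a = np.asarray(auxin_series, float)
    v_init = (
        np.full(a.shape[1], params.normalization) if v0 is None else np.asarray(v0, float)
    )
    scale = params.production / params.basal_turnover / params.normalization

    def rhs(t, v):
        at = np.array(
            [np.interp(t, times, a[:, j]) for j in range(a.shape[1])]
        )
        c = params.r_tot * at / (at + params.kd)
        return (
            params.production / scale
            - (params.basal_turnover + params.k_deg * c) * v
        )

    sol = solve_ivp(rhs, (times[0], times[-1]), v_init, t_eval=times, method="LSODA")
    if not sol.success:
        raise DIIError(f"reporter integration failed: {sol.message}")
    return sol.y.T
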