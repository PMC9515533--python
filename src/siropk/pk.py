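"""Closed-form one-compartment, first-order-absorption kinetics.

All quantities use a fixed internal unit system chosen so that trough
predictions land directly in the therapeutic-window units without conversion
factors: dose in micrograms, volume in litres, clearance in L/h, time in
hours, concentration in ng/ml (micrograms per litre).

The drug is given as an oral bolus into a depot (gut) compartment at the
start of each dosing interval; "trough" means the concentration at
``t = tau`` immediately before the next dose.  Steady state under repeated
dosing is evaluated with the closed-form superposition (accumulation)
formula, never by long simulation; :func:`ode_oracle` exists purely as an
independent numerical cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DegenerateKineticsError, EstimationError, InvalidParameterError

#: Relative tolerance below which |Ka - ke| is treated as the degenerate
#: flip-flop case.  The final-model parameter ranges never approach it, so a
#: loud error is safer than silently switching to the L'Hopital limit.
DEGENERACY_RTOL = 1e-10


@dataclass(frozen=True)
class StructuralParams:
    """Individual structural parameters of the one-compartment oral model.

    Attributes
    ----------
    cl : float
        Apparent oral clearance CL/F, L/h.
    v : float
        Apparent volume of distribution V/F, L.
    ka : float
        First-order absorption rate constant, 1/h.
    """

    cl: float
    v: float
    ka: float

    def __post_init__(self) -> None:
        for name in ("cl", "v", "ka"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise InvalidParameterError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )
        if abs(self.ka - self.ke) < DEGENERACY_RTOL * self.ka:
            raise DegenerateKineticsError(
                f"ka ({self.ka}) coincides with ke ({self.ke}); "
                "the Bateman solution is degenerate"
            )

    @property
    def ke(self) -> float:
        """Elimination rate constant CL/V, 1/h."""
        return self.cl / self.v


@dataclass(frozen=True)
class Regimen:
    """Repeated oral dosing: ``n_doses`` boluses of ``dose`` ug every ``tau`` h."""

    dose: float
    tau: float = 24.0
    n_doses: int = 1

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise InvalidParameterError(f"dose must be >= 0, got {self.dose!r}")
        if self.tau <= 0:
            raise InvalidParameterError(f"tau must be > 0, got {self.tau!r}")
        if self.n_doses < 1:
            raise InvalidParameterError(f"n_doses must be >= 1, got {self.n_doses!r}")


def bateman(dose, cl, v, ka, t):
    """Vectorized single-dose Bateman concentration (ng/ml).

    Low-level array routine shared with the estimation and simulation
    modules; inputs are broadcast.  No degeneracy guard — callers that accept
    arbitrary parameters must validate via :class:`StructuralParams` first.
    """
    dose, cl, v, ka, t = np.broadcast_arrays(dose, cl, v, ka, t)
    ke = cl / v
    coef = dose * ka / (v * (ka - ke))
    return coef * (np.exp(-ke * t) - np.exp(-ka * t))


def steady_state_trough_array(dose, cl, v, ka, tau):
    """Vectorized steady-state trough (concentration at ``tau`` post-dose)."""
    dose, cl, v, ka, tau = np.broadcast_arrays(dose, cl, v, ka, tau)
    ke = cl / v
    coef = dose * ka / (v * (ka - ke))
    ek = np.exp(-ke * tau)
    ea = np.exp(-ka * tau)
    return coef * (ek / (1.0 - ek) - ea / (1.0 - ea))


def conc_single_dose(params: StructuralParams, dose: float, t: float) -> float:
    """Concentration ``t`` hours after a single oral dose of ``dose`` ug."""
    if dose < 0:
        raise InvalidParameterError(f"dose must be >= 0, got {dose!r}")
    if t < 0:
        raise InvalidParameterError(f"t must be >= 0, got {t!r}")
    return float(bateman(dose, params.cl, params.v, params.ka, t))


def steady_state_trough(params: StructuralParams, dose: float, tau: float = 24.0) -> float:
    """Steady-state trough under repeated dosing of ``dose`` ug every ``tau`` h.

    Superposition of the Bateman solution over infinitely many past doses;
    the geometric-series closed form is exact for linear kinetics.  The
    result is homogeneous of degree 1 in ``dose``.
    """
    if dose < 0:
        raise InvalidParameterError(f"dose must be >= 0, got {dose!r}")
    if tau <= 0:
        raise InvalidParameterError(f"tau must be > 0, got {tau!r}")
    return float(steady_state_trough_array(dose, params.cl, params.v, params.ka, tau))


def ode_oracle(
    params: StructuralParams,
    regimen: Regimen,
    time_grid,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Numerically integrate the depot/central ODE system along ``time_grid``.

    dA_gut/dt = -ka * A_gut;  dA_central/dt = ka * A_gut - ke * A_central,
    with a bolus of ``regimen.dose`` into the gut at each dosing time.
    Returns A_central / V (ng/ml).  Grid points that coincide with a dosing
    time are evaluated immediately *before* the bolus (trough convention).

    This routine is an independent test oracle for the closed forms; it is
    deliberately not used anywhere in the analysis path.
    """
    grid = np.asarray(time_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise InvalidParameterError("time_grid must be a non-empty 1-D array")
    if np.any(np.diff(grid) < 0) or grid[0] < 0:
        raise InvalidParameterError("time_grid must be non-negative and non-decreasing")

    dose_times = [i * regimen.tau for i in range(regimen.n_doses)]
    t_end = max(grid[-1], dose_times[-1])
    breakpoints = sorted(set(dose_times) | {0.0, t_end})

    ke = params.ke
    ka = params.ka

    def rhs(_t, y):
        return [-ka * y[0], ka * y[0] - ke * y[1]]

    out = np.empty_like(grid)
    out.fill(np.nan)
    state = np.zeros(2)
    pos = np.searchsorted(grid, 0.0, side="left")
    # grid points exactly at t=0 are pre-dose: nothing absorbed yet
    while pos < grid.size and grid[pos] == 0.0:
        out[pos] = 0.0
        pos += 1

    for left, right in zip(breakpoints, breakpoints[1:] + [t_end]):
        if left in dose_times:
            state[0] += regimen.dose
        if right <= left:
            continue
        # evaluate at grid points in (left, right]; always include the right
        # endpoint so the state can be carried into the next segment
        mask = (grid > left) & (grid <= right)
        t_eval = np.unique(np.concatenate([grid[mask], [right]]))
        sol = solve_ivp(
            rhs,
            (left, right),
            state,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise EstimationError(f"ODE integrator failed on [{left}, {right}]: {sol.message}")
        conc = sol.y[1] / params.v
        out[mask] = np.interp(grid[mask], sol.t, conc)
        state = sol.y[:, -1].copy()

    return out
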