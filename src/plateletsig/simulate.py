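"""Numerical integration, steady-state solving and analytic budget
calculations for the platelet cyclic-nucleotide model.

The analytic helpers implement the resting-platelet bookkeeping: given
measured or fitted PDE pools, how fast is cAMP hydrolyzed, how often
does the pool turn over per minute, and which active enzyme
concentrations are compatible with stable basal nucleotide levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .model import (
    AC_INHIBITOR as AC_INHIBITOR_NAME,
    EMPTY_PROTOCOL,
    H0,
    BasalConstants,
    DomainError,
    DrugParameters,
    ModelVariant,
    ParameterError,
    PlateletState,
    StimulusProtocol,
    camp_rhs,
    ode_rhs,
)

__all__ = [
    "IntegrationError",
    "SteadyStateError",
    "Trajectory",
    "QuantificationContext",
    "HydrolysisBudget",
    "integrate",
    "steady_state",
    "steady_state_camp",
    "simulate_camp_batch",
    "calibrated_basal_state",
    "hydrolysis_budget",
    "solve_active_pde5",
    "solve_active_concentrations",
    "solve_active_pde5",
    "mass_concentration",
]


class IntegrationError(RuntimeError):
    """The ODE integrator failed; carries the last successful time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last successful time: {last_time:g} min)")
        self.last_time = last_time


class SteadyStateError(RuntimeError):
    """Steady-state search did not converge; carries the best residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (best residual: {residual:.3g} uM/min)")
        self.residual = residual


@dataclass
class Trajectory:
    """A solved time course: time grid (min) and one state per point."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 10)
    protocol: StimulusProtocol = EMPTY_PROTOCOL
    rtol: float = 0.0
    atol: float = 0.0
    n_rhs_evaluations: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.states = np.asarray(self.states, float)
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("trajectory times must be strictly increasing")

    @property
    def camp(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def cgmp(self) -> np.ndarray:
        return self.states[:, 1]

    def state_at(self, index: int) -> PlateletState:
        return PlateletState.from_array(self.states[index])

    def to_dataframe(self, protocol_id: str | None = None):
        """Tidy long-format table (time_min, variable, value, protocol_id)."""
        import pandas as pd
        from .model import _STATE_FIELDS

        pid = protocol_id if protocol_id is not None else self.protocol.describe()
        frames = []
        for j, name in enumerate(_STATE_FIELDS):
            frames.append(pd.DataFrame({
                "time_min": self.times,
                "variable": name,
                "value": self.states[:, j],
                "protocol_id": pid,
            }))
        return pd.concat(frames, ignore_index=True)


@dataclass
class QuantificationContext:
    """Conversion context between measured enzyme mass and
    intracellular mass concentration: platelet volume in femtoliters
    (default 5.2 fl) and optional measured masses in ng per 1e7
    platelets."""

    volume_fl: float = 5.2
    measured_ng_per_1e7: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.volume_fl <= 0:
            raise ParameterError("platelet volume must be > 0")
        for name, mass in self.measured_ng_per_1e7.items():
            if mass < 0:
                raise ParameterError(f"measured mass for {name!r} must be >= 0")


@dataclass
class HydrolysisBudget:
    """Per-isoform cAMP hydrolysis rates (uM/min), their total, and the
    turnover of the cAMP pool (1/min)."""

    pde2_rate: float
    pde3_rate: float
    total_rate: float
    turnover: float | None


def integrate(
    initial: PlateletState,
    constants: BasalConstants,
    drugs: DrugParameters | None = None,
    variant: ModelVariant = H0,
    protocol: StimulusProtocol = EMPTY_PROTOCOL,
    t_end: float = 10.0,
    grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the full ten-state system over ``[0, t_end]`` minutes.

    The timeline is split at stimulus onsets so step inputs never fall
    inside an adaptive integrator step.  Returns states at ``grid``
    (default: 201 evenly spaced points).
    """
    if t_end <= 0:
        raise ParameterError("t_end must be > 0")
    if drugs is None:
        drugs = DrugParameters()
    if grid is None:
        grid = np.linspace(0.0, t_end, 201)
    grid = np.asarray(grid, float)
    if grid.min() < 0 or grid.max() > t_end:
        raise ParameterError("grid must lie within [0, t_end]")

    breaks = sorted({0.0, t_end, *(o for o in protocol.onsets if 0.0 < o < t_end)})
    y = initial.to_array()
    out_times = [grid[0]] if grid[0] == 0.0 else []
    out_states = [y.copy()] if grid[0] == 0.0 else []
    nfev = 0

    def rhs(t, x):
        return ode_rhs(t, x, constants, drugs, variant, protocol)

    for a, b in zip(breaks[:-1], breaks[1:]):
        seg = grid[(grid > a) & (grid <= b)]
        t_eval = np.unique(np.concatenate([seg, [b]]))
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol)
        nfev += sol.nfev
        if not sol.success:
            raise IntegrationError(f"integrator failed: {sol.message}",
                                   sol.t[-1] if sol.t.size else a)
        for tt, col in zip(sol.t, sol.y.T):
            if tt in seg:
                out_times.append(tt)
                out_states.append(col)
        y = sol.y[:, -1]

    states = np.clip(np.array(out_states), 0.0, None)
    return Trajectory(np.array(out_times), states, protocol,
                      rtol=rtol, atol=atol, n_rhs_evaluations=nfev)


def steady_state(
    constants: BasalConstants,
    drugs: DrugParameters | None = None,
    variant: ModelVariant = H0,
    protocol: StimulusProtocol = EMPTY_PROTOCOL,
    initial: PlateletState | None = None,
    tol: float = 1e-6,
) -> PlateletState:
    """Plateau state under a sustained (step) protocol.

    The hydrolysis products AMP and GMP accumulate without bound and
    are excluded from the stationarity condition; the returned state
    carries them at their initial values.  The residual is the
    infinity-norm of the remaining eight derivatives (uM/min resp.
    mg/l/min), required to be below ``tol``.
    """
    if drugs is None:
        drugs = DrugParameters()
    for entry in protocol.entries:
        if entry.profile != "step":
            raise ParameterError("steady_state requires step profiles only")
    if initial is None:
        initial = PlateletState()
    x0 = initial.to_array()
    t_late = max([1.0, *(e.onset + 1.0 for e in protocol.entries)])

    def resid(x8):
        x = np.concatenate([np.abs(x8), x0[8:]])
        return ode_rhs(t_late, x, constants, drugs, variant, protocol)[:8]

    sol = root(resid, x0[:8], method="hybr", tol=1e-12)
    best = np.abs(np.asarray(sol.x))
    residual = float(np.max(np.abs(resid(best))))
    if residual > tol:
        # fall back to long-time integration, then refine
        traj = integrate(initial, constants, drugs, variant, protocol,
                         t_end=t_late + 500.0, grid=np.array([t_late + 500.0]),
                         rtol=1e-10, atol=1e-12)
        sol = root(resid, traj.states[-1][:8], method="hybr", tol=1e-12)
        best = np.abs(np.asarray(sol.x))
        residual = float(np.max(np.abs(resid(best))))
        if residual > tol:
            raise SteadyStateError("steady-state search did not converge", residual)
    x = np.concatenate([best, x0[8:]])
    return PlateletState.from_array(x)


def steady_state_camp(
    constants: BasalConstants,
    drugs: DrugParameters | None = None,
    variant: ModelVariant = H0,
    protocol: StimulusProtocol = EMPTY_PROTOCOL,
    pde2_active: float = 0.05,
    pde3_active: float = 2.3,
    camp_max: float = 1e5,
) -> float:
    """Scalar cAMP plateau for constant enzyme pools (zero
    (de)activation rates), solved by bracketing the autonomous cAMP
    balance.  Much faster than the full-system solver and exact for the
    fitted model structure."""
    if drugs is None:
        drugs = DrugParameters()
    t_late = max([1.0, *(e.onset + 1.0 for e in protocol.entries)])

    def f(c):
        return float(camp_rhs(t_late, c, constants, drugs, variant, protocol,
                              pde2_active, pde3_active))

    lo = 0.0
    if f(lo) <= 0.0:
        return 0.0
    hi = 8.0
    while f(hi) > 0.0:
        hi *= 2.0
        if hi > camp_max:
            raise SteadyStateError("no cAMP plateau below bracket limit", f(camp_max))
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def hydrolysis_budget(
    camp: float,
    pde2_conc: float,
    pde3_conc: float,
    constants: BasalConstants | None = None,
    with_turnover: bool = True,
) -> HydrolysisBudget:
    """cAMP hydrolysis budget at a given cAMP level and enzyme pools.

    Evaluates the PDE2 (Hill) and PDE3 (Michaelis-Menten) rate laws,
    sums them, and divides by the cAMP pool for the per-minute turnover
    number.
    """
    if constants is None:
        constants = BasalConstants()
    if camp < 0 or pde2_conc < 0 or pde3_conc < 0:
        raise DomainError("cAMP and enzyme concentrations must be >= 0")
    k = constants
    ch = camp ** k.hill_pde2
    pde2 = k.vmax_pde2_camp * ch * pde2_conc / (k.km_pde2_camp + ch)
    pde3 = k.vmax_pde3_camp * pde3_conc * camp / (k.km_pde3_camp + camp)
    total = pde2 + pde3
    turnover = None
    if with_turnover:
        if camp == 0:
            raise DomainError("turnover is undefined at zero cAMP")
        turnover = total / camp
    return HydrolysisBudget(pde2, pde3, total, turnover)


def solve_active_concentrations(
    target_camp: float = 4.0,
    influx: float = 8.0,
    pde3_share: float = 0.8,
    constants: BasalConstants | None = None,
) -> tuple[float, float]:
    """Active (PDE2, PDE3) concentrations (mg/l) that balance the basal
    cAMP influx at the target basal level.

    Closed-form inversion of the rate laws: ``c = v (Km + S^h) /
    (Vmax S^h)`` with the influx split ``pde3_share`` to PDE3 and the
    remainder to PDE2.  By construction the resulting basal cAMP level
    is exactly stationary.
    """
    if constants is None:
        constants = BasalConstants()
    if not 0.0 < pde3_share < 1.0:
        raise ParameterError("pde3_share must lie strictly between 0 and 1")
    if target_camp <= 0 or influx <= 0:
        raise ParameterError("target cAMP and influx must be > 0")
    k = constants
    ch = target_camp ** k.hill_pde2
    v2 = (1.0 - pde3_share) * influx
    v3 = pde3_share * influx
    pde2 = v2 * (k.km_pde2_camp + ch) / (k.vmax_pde2_camp * ch)
    pde3 = v3 * (k.km_pde3_camp + target_camp) / (k.vmax_pde3_camp * target_camp)
    return pde2, pde3


def solve_active_pde5(
    pde2_active: float,
    pde3_active: float,
    target_cgmp: float = 0.4,
    influx: float | None = None,
    constants: BasalConstants | None = None,
) -> float:
    """Active PDE5 concentration (mg/l) balancing the basal cGMP influx
    at the target basal cGMP level, given the cAMP-side active pools
    (PDE2 and PDE3 also hydrolyze cGMP)."""
    if constants is None:
        constants = BasalConstants()
    k = constants
    if influx is None:
        influx = k.cgmp_influx
    if target_cgmp <= 0 or influx <= 0:
        raise ParameterError("target cGMP and influx must be > 0")
    g = target_cgmp
    v_pde2 = k.vmax_pde2_cgmp * pde2_active * g / (k.km_pde2_cgmp + g)
    v_pde3 = k.vmax_pde3_cgmp * pde3_active * g / (k.km_pde3_cgmp + g)
    v5 = influx - v_pde2 - v_pde3
    if v5 <= 0:
        raise ParameterError(
            "infeasible: PDE2/PDE3 alone already exceed the cGMP influx")
    return v5 * (k.km_pde5_cgmp + g) / (k.vmax_pde5_cgmp * g)


def calibrated_basal_state(
    constants: BasalConstants | None = None,
    target_camp: float = 4.0,
    target_cgmp: float = 0.4,
    pde3_share: float = 0.8,
) -> PlateletState:
    """Resting state whose active pools are calibrated so the basal
    nucleotide levels are exactly stationary (the model set-up
    procedure: constrain basal cAMP and cGMP, solve for active pools)."""
    if constants is None:
        constants = BasalConstants()
    pde2, pde3 = solve_active_concentrations(
        target_camp, constants.camp_influx, pde3_share, constants)
    pde5 = solve_active_pde5(pde2, pde3, target_cgmp,
                             constants.cgmp_influx, constants)
    from .model import basal_state
    return basal_state(constants, pde2_active=pde2, pde3_active=pde3,
                       pde5_active=pde5, camp=target_camp, cgmp=target_cgmp)


def simulate_camp_batch(
    protocols: list,
    obs_times: list,
    constants: BasalConstants,
    drugs: DrugParameters,
    variant: ModelVariant,
    pde2_active: float = 0.05,
    pde3_active: float = 2.3,
    c0: float | np.ndarray | None = None,
    dt: float = 0.02,
) -> list:
    """Simulate the reduced cAMP equation for many protocols at once.

    A classic fourth-order Runge-Kutta scheme with a fixed step (default
    0.02 min) advances all series simultaneously as one numpy vector;
    observation values are linearly interpolated from the dense grid.
    Valid for constant enzyme pools and protocols whose entries all
    start at t = 0 (step or transient).  Agreement with the adaptive
    full-system integrator is covered by tests.

    Returns one array of cAMP values per protocol, evaluated at the
    corresponding ``obs_times`` entry.
    """
    n = len(protocols)
    if n != len(obs_times):
        raise ParameterError("one observation-time vector per protocol required")
    k = constants
    h = k.hill_pde2
    kf1 = drugs.kf1 if variant.pde3_feedback else 0.0
    kf2 = drugs.kf2 if variant.ac_feedback else 0.0

    inhibition = np.zeros(n)
    xac = np.zeros(n)
    has_ac = np.zeros(n, bool)
    lam = np.zeros(n)
    basal_factor = np.ones(n)
    for i, protocol in enumerate(protocols):
        synergy = drugs.k_syn if protocol.has_pde_inhibitor else 1.0
        for entry in protocol.entries:
            if entry.onset != 0.0:
                raise ParameterError(
                    "batch cAMP simulation supports onset-0 entries only")
            if entry.drug in ("Milrinone", "Cilostamide"):
                if entry.profile != "step":
                    raise ParameterError(
                        "batch simulation supports step inhibitor profiles only")
                inhibition[i] += entry.dose / drugs.ki[entry.drug]
            elif entry.drug in ("Iloprost", "Forskolin"):
                if has_ac[i]:
                    raise ParameterError(
                        "batch simulation supports one AC stimulator per series")
                xac[i] = synergy * drugs.influx_for(entry.drug, entry.dose)
                has_ac[i] = entry.dose > 0
                if entry.profile == "transient":
                    lam[i] = np.log(2.0) / entry.half_life
            elif entry.drug == AC_INHIBITOR_NAME:
                basal_factor[i] *= drugs.ac_inhibitor_khalf / (
                    drugs.ac_inhibitor_khalf + entry.dose)
    b = basal_factor * k.camp_influx
    A2 = k.vmax_pde2_camp * pde2_active
    C3 = pde3_active
    km_eff = (1.0 + inhibition) * k.km_pde3_camp
    any_transient = bool(np.any(lam > 0))

    def f(t, c):
        x = xac * np.exp(-lam * t) if any_transient else xac
        net = np.where(has_ac, np.maximum(x - kf2 * c, 0.0), 0.0)
        ch = c ** h
        v3 = A2 * ch / (k.km_pde2_camp + ch)
        v4 = np.maximum(k.vmax_pde3_camp + kf1 * c, 0.0) * C3 * c / (km_eff + c)
        return b + net - v3 - v4

    t_max = max(float(np.max(t)) for t in obs_times)
    n_steps = max(int(np.ceil(t_max / dt)), 1)
    tgrid = np.arange(n_steps + 1) * (t_max / n_steps) if t_max > 0 else np.array([0.0, dt])
    step = tgrid[1] - tgrid[0]

    if c0 is None:
        # pre-stimulus resting level under the same variant (the PDE3
        # feedback acts at basal cAMP too; the AC feedback does not,
        # since it only modifies drug-induced influx)
        c0 = steady_state_camp(constants, drugs, variant, EMPTY_PROTOCOL,
                               pde2_active, pde3_active)
    c = np.full(n, c0, float) if np.isscalar(c0) else np.asarray(c0, float).copy()
    history = np.empty((tgrid.size, n))
    history[0] = c
    for i in range(tgrid.size - 1):
        t = tgrid[i]
        k1 = f(t, c)
        k2 = f(t + step / 2.0, c + step / 2.0 * k1)
        k3 = f(t + step / 2.0, c + step / 2.0 * k2)
        k4 = f(t + step, c + step * k3)
        c = np.maximum(c + step / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4), 0.0)
        history[i + 1] = c

    return [np.interp(np.asarray(t, float), tgrid, history[:, i])
            for i, t in enumerate(obs_times)]


def mass_concentration(
    ng_per_1e7_platelets: float,
    context: QuantificationContext | None = None,
) -> float:
    """Convert a measured enzyme mass (ng per 1e7 platelets) to an
    intracellular mass concentration (mg/l) using the platelet volume:
    mass / (1e7 * volume)."""
    if context is None:
        context = QuantificationContext()
    if ng_per_1e7_platelets < 0:
        raise ParameterError("measured mass must be >= 0")
    grams = ng_per_1e7_platelets * 1e-9
    liters = 1e7 * context.volume_fl * 1e-15
    return grams / liters * 1e3  # g/l -> mg/l
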