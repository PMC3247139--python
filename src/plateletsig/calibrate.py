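"""Multi-experiment chi-square fitting.

Several dose-series experiments are fitted simultaneously: global
parameters (inhibition constants, feedback constants, basal influx,
active pools) are shared across all series while each administered
AC-stimulator dose carries its own local influx rate.  The merit
function is the standard weighted sum of squares

    chi2(p) = sum_i ((y_i - y(t_i, p)) / sigma_i)**2,

a maximum-likelihood estimator under Gaussian errors.  Measurement
uncertainty follows the error model ``sigma = 0.1 y + 0.05 max(y)``
per series; fitted points are per-time means of replicates with
SEM-style sigma (error model divided by sqrt(n_replicates)).

Optimization uses a bounded trust-region least-squares solver on
internally transformed coordinates (log scale for positive-constrained
parameters, whose fitting ranges span decades), optionally preceded by
perturb-and-refit restarts with multiplicative lognormal noise.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model import (
    AC_STIMULATORS,
    PDE3_INHIBITORS,
    BasalConstants,
    ConfigurationError,
    DomainError,
    DrugParameters,
    ModelVariant,
    ParameterError,
    StimulusProtocol,
)
from .params import ParameterContext, influx_name
from .simulate import hydrolysis_budget, integrate, simulate_camp_batch

__all__ = [
    "SIGMA_FLOOR",
    "ExperimentSeries",
    "ParameterSpec",
    "FitResult",
    "FitError",
    "error_sigma",
    "chi2_merit",
    "multi_experiment_fit",
    "build_default_specs",
    "fit_variants",
]

SIGMA_FLOOR = 1e-6  # observable units; avoids division by zero on degenerate series

OBSERVABLES = ("cAMP", "cGMP", "VASP_pS157_ratio", "VASP_pS239_ratio")


class FitError(RuntimeError):
    """All restarts of a fit failed; carries per-restart diagnostics."""

    def __init__(self, message: str, diagnostics: list):
        super().__init__(message)
        self.diagnostics = diagnostics


def error_sigma(values, floor: float = SIGMA_FLOOR, n_replicates: int = 1) -> np.ndarray:
    """Per-point standard deviation from the study's error model:
    ``0.1 y + 0.05 max(y)`` over the series, divided by
    ``sqrt(n_replicates)`` when applied to replicate means."""
    y = np.asarray(values, float)
    if y.size == 0:
        raise DomainError("error model needs a non-empty series")
    sigma = (0.1 * np.abs(y) + 0.05 * np.max(np.abs(y))) / np.sqrt(n_replicates)
    return np.maximum(sigma, floor)


@dataclass
class ExperimentSeries:
    """One dose's observed time course.

    ``values`` are the fitted per-time-point means; ``sigma`` their
    uncertainties; ``replicates`` (optional, shape ``(n_rep, n_times)``)
    retains the raw draws for bookkeeping.
    """

    experiment_id: str
    protocol: StimulusProtocol
    observable: str
    times: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.observable not in OBSERVABLES:
            raise ConfigurationError(f"unknown observable {self.observable!r}")
        if self.times.size < 1 or self.times.size != self.values.size:
            raise DomainError("need >= 1 time point with matching values")
        if self.sigma is None:
            n_rep = self.replicates.shape[0] if self.replicates is not None else 1
            self.sigma = error_sigma(self.values, n_replicates=n_rep)
        self.sigma = np.asarray(self.sigma, float)
        if np.any(self.sigma <= 0):
            raise DomainError("sigma must be > 0 for every fitted point")
        if self.replicates is not None:
            self.replicates = np.asarray(self.replicates, float)
            if self.replicates.shape[1] != self.times.size:
                raise DomainError("replicate matrix must be (n_rep, n_times)")

    @classmethod
    def from_replicates(cls, experiment_id, protocol, observable, times,
                        replicates) -> "ExperimentSeries":
        """Build a series from raw replicates: fitted values are the
        per-time means, sigma the error model of the means scaled by
        1/sqrt(n_replicates) (SEM-style)."""
        replicates = np.atleast_2d(np.asarray(replicates, float))
        mean = replicates.mean(axis=0)
        return cls(experiment_id, protocol, observable, times, mean,
                   error_sigma(mean, n_replicates=replicates.shape[0]),
                   replicates)

    @property
    def n_points(self) -> int:
        return int(self.times.size)


@dataclass
class ParameterSpec:
    """One fitted (or fixed) parameter.

    ``role`` is ``"shared"`` (global across experiments) or ``"local"``
    (specific to one administered dose, e.g. an AC influx rate).
    Positive-constrained parameters are fitted on a log scale
    (``log=True``); sign-free parameters (the feedback constants in
    hypothesis tests, where the null must be interior) use a linear
    scale with bounds spanning zero.
    """

    name: str
    value: float
    lower: float
    upper: float
    role: str = "shared"
    fixed: bool = False
    log: bool = True

    def __post_init__(self) -> None:
        if not self.fixed:
            if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
                raise ParameterError(f"{self.name}: bounds must be finite")
            if not self.lower < self.upper:
                raise ParameterError(f"{self.name}: lower bound must be < upper")
            if not self.lower <= self.value <= self.upper:
                raise ParameterError(f"{self.name}: initial value outside bounds")
            if self.log and self.lower <= 0:
                raise ParameterError(f"{self.name}: log scale needs lower > 0")
        if self.role not in ("shared", "local"):
            raise ParameterError(f"{self.name}: unknown role {self.role!r}")

    def to_internal(self, value: float) -> float:
        return np.log(value) if self.log else value

    def from_internal(self, z: float) -> float:
        return float(np.exp(z)) if self.log else float(z)


@dataclass
class FitResult:
    """Outcome of one multi-experiment fit: the unit of model selection."""

    parameters: dict
    chi2: float
    n_points: int
    n_free: int
    trajectories: list
    variant_name: str
    diagnostics: dict = field(default_factory=dict)
    seed: int | None = None
    data_hash: str = ""

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise DomainError("chi2 must be >= 0")
        if self.n_points < self.n_free:
            raise DomainError("need at least as many data points as free parameters")

    @property
    def chi2_per_point(self) -> float:
        return self.chi2 / self.n_points


def data_fingerprint(experiments: list) -> str:
    """Stable hash of the fitted data (ids, times, values, sigmas)."""
    digest = hashlib.sha256()
    for e in experiments:
        digest.update(e.experiment_id.encode())
        digest.update(e.observable.encode())
        for arr in (e.times, e.values, e.sigma):
            digest.update(np.ascontiguousarray(arr, float).tobytes())
    return digest.hexdigest()[:16]


def evaluate_model_curves(experiments, ctx: ParameterContext,
                          variant: ModelVariant, rk_step: float = 0.02) -> list:
    """Model value at every data time point, one array per experiment.

    cAMP series go through the batched reduced integrator; VASP series
    chain a dense cAMP course into the phospho-ODE; anything else falls
    back to the full ten-state system.
    """
    from .downstream import VaspParameters, vasp_phosphorylation
    from .model import basal_state

    pools = ctx.pools
    curves: list = [None] * len(experiments)
    camp_idx = [i for i, e in enumerate(experiments) if e.observable == "cAMP"]
    if camp_idx:
        batch = simulate_camp_batch(
            [experiments[i].protocol for i in camp_idx],
            [experiments[i].times for i in camp_idx],
            ctx.constants, ctx.drugs, variant,
            pools["pde2_active"], pools["pde3_active"], dt=rk_step)
        for i, curve in zip(camp_idx, batch):
            curves[i] = curve
    for i, series in enumerate(experiments):
        if curves[i] is not None:
            continue
        if series.observable.startswith("VASP"):
            t_end = float(series.times.max()) or 1.0
            dense_t = np.linspace(0.0, t_end, 201)
            camp = simulate_camp_batch(
                [series.protocol], [dense_t], ctx.constants, ctx.drugs,
                variant, pools["pde2_active"], pools["pde3_active"],
                dt=rk_step)[0]
            vp = VaspParameters(
                site_preference=ctx.vasp.get("vasp_r", 15.0),
                k239=ctx.vasp.get("vasp_k239", 0.05),
                kd=ctx.vasp.get("vasp_kd", 0.5),
                ka_camp=ctx.vasp.get("vasp_ka", 10.0))
            f157, f239 = vasp_phosphorylation(dense_t, camp, vp)
            dense = f157 if series.observable == "VASP_pS157_ratio" else f239
            curves[i] = np.interp(series.times, dense_t, dense)
        else:  # cGMP: integrate the full system
            state0 = basal_state(ctx.constants,
                                 pde2_active=pools["pde2_active"],
                                 pde3_active=pools["pde3_active"],
                                 pde5_active=pools["pde5_active"])
            t_end = float(series.times.max()) or 1.0
            traj = integrate(state0, ctx.constants, ctx.drugs, variant,
                             series.protocol, t_end=t_end,
                             grid=np.union1d(series.times, [t_end]))
            curves[i] = np.interp(series.times, traj.times, traj.states[:, 1])
    return curves


class MultiExperimentProblem:
    """Shared/local parameter structure over a list of experiments.

    Responsible for mapping the free-parameter vector to model
    parameters, evaluating model curves per experiment, and producing
    weighted residuals for the trust-region solver.
    """

    def __init__(self, experiments, specs, variant,
                 constants=None, drugs=None, pools=None, vasp=None,
                 rk_step: float = 0.02):
        if not experiments:
            raise ConfigurationError("need at least one experiment")
        self.experiments = list(experiments)
        self.specs = list(specs)
        self.variant = variant
        self.base = ParameterContext(
            constants or BasalConstants(), drugs or DrugParameters(),
            pools, vasp)
        self.rk_step = rk_step
        self.free = [s for s in self.specs if not s.fixed]
        if not self.free:
            raise ConfigurationError("need at least one free parameter")
        self.n_points = sum(e.n_points for e in self.experiments)
        if self.n_points < len(self.free):
            raise ConfigurationError(
                "fewer data points than free parameters (N < p)")
        for spec in self.specs:
            self.base.set(spec.name, spec.value)  # fixed specs pin the context

    # -- parameter bookkeeping -------------------------------------------
    def initial_internal(self) -> np.ndarray:
        return np.array([s.to_internal(s.value) for s in self.free])

    def internal_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([s.to_internal(s.lower) for s in self.free])
        hi = np.array([s.to_internal(s.upper) for s in self.free])
        return lo, hi

    def context_for(self, z: np.ndarray) -> ParameterContext:
        ctx = self.base.copy()
        for spec, zi in zip(self.free, z):
            ctx.set(spec.name, spec.from_internal(zi))
        return ctx

    def parameters_from(self, z: np.ndarray) -> dict:
        return {s.name: s.from_internal(zi) for s, zi in zip(self.free, z)}

    # -- model evaluation -------------------------------------------------
    def model_curves(self, ctx: ParameterContext) -> list:
        return evaluate_model_curves(self.experiments, ctx, self.variant,
                                     self.rk_step)

    def residuals(self, z: np.ndarray) -> np.ndarray:
        ctx = self.context_for(z)
        curves = self.model_curves(ctx)
        parts = [(curve - e.values) / e.sigma
                 for curve, e in zip(curves, self.experiments)]
        return np.concatenate(parts)

    def chi2(self, z: np.ndarray) -> float:
        return float(np.sum(self.residuals(z) ** 2))

    def jac_sparsity(self) -> np.ndarray:
        """Residual-block/parameter dependence mask: local parameters
        touch only the experiments administering their dose, which lets
        the solver group finite-difference columns."""
        mask = np.zeros((self.n_points, len(self.free)), bool)
        offsets = np.cumsum([0] + [e.n_points for e in self.experiments])
        for j, spec in enumerate(self.free):
            if spec.role == "local" and spec.name.startswith("influx:"):
                _, drug, dose = spec.name.split(":")
                for i, e in enumerate(self.experiments):
                    hit = any(en.drug == drug and f"{en.dose:g}" == dose
                              for en in e.protocol.entries)
                    if hit:
                        mask[offsets[i]:offsets[i + 1], j] = True
            else:
                mask[:, j] = True
        return mask


def chi2_merit(params: dict, experiments, variant: ModelVariant,
               constants=None, drugs=None, pools=None, vasp=None) -> float:
    """Chi-square of the model against a set of experiments for an
    explicit parameter assignment (names as in :mod:`plateletsig.params`).

    Additive over experiments and zero iff the model passes through all
    fitted means.
    """
    experiments = list(experiments)
    for e in experiments:
        if np.any(np.asarray(e.sigma) <= 0):
            raise DomainError(f"experiment {e.experiment_id}: sigma must be > 0")
    ctx = ParameterContext(constants or BasalConstants(),
                           drugs or DrugParameters(), pools, vasp)
    for name, value in params.items():
        ctx.set(name, value)
    curves = evaluate_model_curves(experiments, ctx, variant)
    return float(sum(np.sum(((c - e.values) / e.sigma) ** 2)
                     for c, e in zip(curves, experiments)))


def multi_experiment_fit(
    experiments,
    specs,
    variant: ModelVariant,
    constants: BasalConstants | None = None,
    drugs: DrugParameters | None = None,
    pools: dict | None = None,
    vasp: dict | None = None,
    n_restarts: int = 0,
    perturbation_scale: float = 0.2,
    seed: int = 0,
    ftol: float = 1e-9,
    xtol: float = 1e-9,
    rk_step: float = 0.02,
) -> FitResult:
    """Fit all experiments simultaneously and return the best of
    ``1 + n_restarts`` trust-region runs.

    Restarts perturb the internal (log) coordinates with Gaussian noise
    of ``perturbation_scale`` (multiplicative lognormal on positive
    parameters) before re-optimizing; given the same seed the result is
    deterministic.
    """
    problem = MultiExperimentProblem(experiments, specs, variant,
                                     constants, drugs, pools, vasp, rk_step)
    z0 = problem.initial_internal()
    lo, hi = problem.internal_bounds()
    sparsity = problem.jac_sparsity()
    rng = np.random.default_rng(seed)

    starts = [z0]
    for _ in range(n_restarts):
        sigma = np.where([s.log for s in problem.free], perturbation_scale,
                         perturbation_scale * (hi - lo) / 10.0)
        starts.append(np.clip(z0 + rng.normal(0.0, 1.0, z0.size) * sigma, lo, hi))

    best = None
    diagnostics = []
    for z_start in starts:
        try:
            sol = least_squares(problem.residuals, z_start, bounds=(lo, hi),
                                jac_sparsity=sparsity, method="trf",
                                ftol=ftol, xtol=xtol, gtol=1e-10)
            chi2 = float(2.0 * sol.cost)
            diagnostics.append({"status": int(sol.status), "nfev": int(sol.nfev),
                                "chi2": chi2, "message": sol.message})
            if sol.status > 0 and (best is None or chi2 < best[0]):
                best = (chi2, sol)
        except Exception as exc:  # noqa: BLE001 - recorded per restart
            diagnostics.append({"status": -1, "error": repr(exc)})
    if best is None:
        raise FitError("no restart converged", diagnostics)

    chi2, sol = best
    chi2_init = problem.chi2(z0)
    if chi2 > chi2_init + 1e-9:  # never worse than the initial guess
        chi2, z_best = chi2_init, z0
    else:
        z_best = sol.x
    ctx = problem.context_for(z_best)
    return FitResult(
        parameters=problem.parameters_from(z_best),
        chi2=chi2,
        n_points=problem.n_points,
        n_free=len(problem.free),
        trajectories=problem.model_curves(ctx),
        variant_name=variant.name,
        diagnostics={"restarts": diagnostics, "chi2_initial": chi2_init},
        seed=seed,
        data_hash=data_fingerprint(problem.experiments),
    )


def build_default_specs(
    experiments,
    variant: ModelVariant,
    constants: BasalConstants | None = None,
    pools: dict | None = None,
    two_sided_feedback: bool = True,
    fit_basal_influx: bool = False,
    fit_pools: bool = False,
) -> list:
    """Default free-parameter ledger for a drug study fit.

    One local AC influx rate per administered (stimulator, dose); one
    inhibition constant per PDE3 inhibitor present; the feedback
    constants demanded by the variant (sign-free by default so nested
    hypothesis tests have an interior null); optionally the basal cAMP
    influx and the active PDE2/PDE3 pools.  Initial influx guesses are
    read off the late data points via the hydrolysis balance.
    """
    constants = constants or BasalConstants()
    pools = pools or {"pde2_active": 0.05, "pde3_active": 2.3, "pde5_active": 1.0}
    specs: list = []
    seen_influx: set = set()
    seen_ki: set = set()
    for e in experiments:
        for entry in e.protocol.entries:
            if entry.drug in AC_STIMULATORS and entry.dose > 0:
                name = influx_name(entry.drug, entry.dose)
                if name in seen_influx:
                    continue
                seen_influx.add(name)
                c_end = float(np.max(e.values)) if e.observable == "cAMP" else 10.0
                guess = hydrolysis_budget(
                    max(c_end, 4.5), pools["pde2_active"], pools["pde3_active"],
                    constants, with_turnover=False).total_rate - constants.camp_influx
                specs.append(ParameterSpec(name, float(np.clip(guess, 0.5, 5e3)),
                                           lower=1e-3, upper=1e4, role="local"))
            elif entry.drug in PDE3_INHIBITORS:
                if entry.drug in seen_ki:
                    continue
                seen_ki.add(entry.drug)
                specs.append(ParameterSpec(f"ki:{entry.drug}", 10.0,
                                           lower=1e-2, upper=1e4))
    if variant.pde3_feedback:
        if two_sided_feedback:
            specs.append(ParameterSpec("kf1", 0.0, lower=-1.0, upper=10.0, log=False))
        else:
            specs.append(ParameterSpec("kf1", 1e-3, lower=1e-6, upper=10.0))
    if variant.ac_feedback:
        if two_sided_feedback:
            specs.append(ParameterSpec("kf2", 0.0, lower=-2.0, upper=20.0, log=False))
        else:
            specs.append(ParameterSpec("kf2", 1e-3, lower=1e-6, upper=20.0))
    if fit_basal_influx:
        specs.append(ParameterSpec("k11", constants.camp_influx,
                                   lower=1.0, upper=64.0))
    if fit_pools:
        specs.append(ParameterSpec("pde2_active", pools["pde2_active"],
                                   lower=1e-3, upper=63.46))
        specs.append(ParameterSpec("pde3_active", pools["pde3_active"],
                                   lower=1e-2, upper=225.0))
    return specs


def fit_variants(
    experiments,
    variants=("H0", "H1", "H2", "H3"),
    seed: int = 0,
    n_restarts: int = 0,
    **kwargs,
) -> dict:
    """Fit every feedback hypothesis to the same data; returns
    ``{variant name: FitResult}`` ready for model selection."""
    results = {}
    for name in variants:
        variant = ModelVariant.from_name(name)
        specs = build_default_specs(
            experiments, variant,
            constants=kwargs.get("constants"), pools=kwargs.get("pools"))
        results[name] = multi_experiment_fit(
            experiments, specs, variant, seed=seed, n_restarts=n_restarts,
            **kwargs)
    return results
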