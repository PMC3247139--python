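"""Drug-combination plateau surfaces and VASP phosphorylation.

Combination surfaces evaluate the steady-state cAMP level over a grid
of dose pairs.  When an adenylyl-cyclase stimulator is combined with a
PDE3 inhibitor the drug-induced AC influx is multiplied by the synergy
constant ``k_syn`` (fitted to 1.443 for the Iloprost + Cilostamide
combination; 1 for purely mechanistic, non-synergistic pairs), so
single-drug limits are preserved exactly.

Downstream of cAMP, the two VASP phosphosites Ser157 and Ser239 follow
two-state kinetics driven by a saturating PKA-activity proxy
``A(cAMP) = cAMP / (cAMP + Ka)``:

    df/dt = k_site * A(cAMP(t)) * (1 - f) - k_d * f

with Ser157 a 15-fold better PKA substrate than Ser239
(``k_157 = r * k_239``, default r = 15) and a shared dephosphorylation
rate.  Phospho-fractions are ratios of total VASP and stay in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    AC_INHIBITOR,
    AC_STIMULATORS,
    EMPTY_PROTOCOL,
    H3,
    PDE3_INHIBITORS,
    BasalConstants,
    ConfigurationError,
    DomainError,
    DrugParameters,
    ModelVariant,
    ParameterError,
    StimulusEntry,
    StimulusProtocol,
)
from .simulate import steady_state_camp

__all__ = [
    "CombinationGrid",
    "VaspParameters",
    "combination_surface",
    "vasp_phosphorylation",
    "vasp_steady_fraction",
]


@dataclass
class CombinationGrid:
    """Plateau cAMP (uM) over a two-drug dose grid.

    ``plateaus[i, j]`` is the steady-state cAMP at ``doses_a[i]`` of
    drug A combined with ``doses_b[j]`` of drug B; a zero dose on either
    axis reduces to the single-drug plateau.
    """

    drug_a: str
    doses_a: np.ndarray
    drug_b: str
    doses_b: np.ndarray
    k_syn: float
    plateaus: np.ndarray
    basal: float

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, float)
        self.doses_b = np.asarray(self.doses_b, float)
        self.plateaus = np.asarray(self.plateaus, float)
        if self.plateaus.shape != (self.doses_a.size, self.doses_b.size):
            raise DomainError("plateau matrix shape must match the dose lists")

    def to_dataframe(self):
        """Long-format table (dose_a, dose_b, camp_plateau)."""
        import pandas as pd

        rows = [
            {f"dose_{self.drug_a}": da, f"dose_{self.drug_b}": db,
             "camp_plateau": self.plateaus[i, j]}
            for i, da in enumerate(self.doses_a)
            for j, db in enumerate(self.doses_b)
        ]
        return pd.DataFrame(rows)


def combination_surface(
    drug_a: str,
    doses_a,
    drug_b: str,
    doses_b,
    constants: BasalConstants | None = None,
    drugs: DrugParameters | None = None,
    variant: ModelVariant = H3,
    k_syn: float | None = None,
    pde2_active: float = 0.05,
    pde3_active: float = 2.3,
) -> CombinationGrid:
    """Steady-state cAMP surface for a two-drug combination.

    Supported drugs: the PDE3 inhibitors, the AC stimulators (each
    administered dose must carry a configured local influx rate) and the
    generic AC inhibitor.  ``k_syn`` overrides the synergy constant in
    ``drugs`` for this surface; it only acts on cells where an AC
    stimulator meets a PDE inhibitor.
    """
    if constants is None:
        constants = BasalConstants()
    if drugs is None:
        drugs = DrugParameters()
    supported = set(PDE3_INHIBITORS) | set(AC_STIMULATORS) | {AC_INHIBITOR}
    for drug in (drug_a, drug_b):
        if drug not in supported:
            raise ConfigurationError(f"unsupported drug {drug!r}")
    if k_syn is not None:
        if k_syn < 0:
            raise ParameterError("k_syn must be >= 0")
        drugs = DrugParameters(
            ki=dict(drugs.ki), ac_influx=dict(drugs.ac_influx),
            kf1=drugs.kf1, kf2=drugs.kf2, k_syn=k_syn,
            ac_inhibitor_khalf=drugs.ac_inhibitor_khalf)

    doses_a = np.asarray(doses_a, float)
    doses_b = np.asarray(doses_b, float)
    plateaus = np.empty((doses_a.size, doses_b.size))
    for i, da in enumerate(doses_a):
        for j, db in enumerate(doses_b):
            entries = []
            if da > 0:
                entries.append(StimulusEntry(drug_a, float(da)))
            if db > 0:
                entries.append(StimulusEntry(drug_b, float(db)))
            protocol = StimulusProtocol(tuple(entries))
            plateaus[i, j] = steady_state_camp(
                constants, drugs, variant, protocol, pde2_active, pde3_active)
    basal = steady_state_camp(constants, drugs, variant, EMPTY_PROTOCOL,
                              pde2_active, pde3_active)
    return CombinationGrid(drug_a, doses_a, drug_b, doses_b,
                           drugs.k_syn, plateaus, basal)


@dataclass
class VaspParameters:
    """Kinetics of PKA-mediated VASP phosphorylation.

    ``site_preference`` is the Ser157 : Ser239 substrate-preference
    ratio (default 15); ``k239`` the Ser239 phosphorylation rate
    constant (1/min at full PKA activity); ``kd`` the shared
    dephosphorylation rate (1/min); ``ka_camp`` the half-saturation of
    the PKA-activity proxy (uM cAMP).
    """

    site_preference: float = 15.0
    k239: float = 0.05
    kd: float = 0.5
    ka_camp: float = 10.0

    def __post_init__(self) -> None:
        if self.site_preference <= 0:
            raise ParameterError("site preference ratio must be > 0")
        if self.k239 <= 0 or self.kd <= 0 or self.ka_camp <= 0:
            raise ParameterError("VASP rate constants must be > 0")

    @property
    def k157(self) -> float:
        return self.site_preference * self.k239

    def activity(self, camp) -> np.ndarray:
        """Saturating PKA-activity proxy in [0, 1)."""
        c = np.asarray(camp, float)
        return c / (c + self.ka_camp)


def vasp_steady_fraction(camp: float, k_site: float, params: VaspParameters) -> float:
    """Closed-form stationary phospho-fraction at constant cAMP:
    f* = kA / (kA + kd)."""
    ka = k_site * float(params.activity(camp))
    return ka / (ka + params.kd)


def vasp_phosphorylation(
    times,
    camp,
    params: VaspParameters | None = None,
    initial: tuple | None = None,
    dt: float = 0.005,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site phospho-fraction trajectories driven by a cAMP course.

    The cAMP input (uM, on a strictly increasing time grid) is linearly
    interpolated; both site ODEs are advanced jointly with a fixed-step
    fourth-order Runge-Kutta scheme and the fractions are returned at
    the input time points.  ``initial`` defaults to the stationary
    fractions at the first cAMP value (resting platelets carry a
    baseline phosphorylation).
    """
    if params is None:
        params = VaspParameters()
    times = np.asarray(times, float)
    camp = np.asarray(camp, float)
    if times.size != camp.size or times.size < 2:
        raise DomainError("times and cAMP must be equal-length vectors (>= 2)")
    if np.any(np.diff(times) <= 0):
        raise DomainError("time grid must be strictly increasing")
    if np.any(camp < 0):
        raise DomainError("cAMP course must be non-negative")

    if initial is None:
        f = np.array([vasp_steady_fraction(camp[0], params.k157, params),
                      vasp_steady_fraction(camp[0], params.k239, params)])
    else:
        f = np.asarray(initial, float).copy()
        if np.any(f < 0) or np.any(f > 1):
            raise DomainError("initial phospho-fractions must lie in [0, 1]")

    k_site = np.array([params.k157, params.k239])
    span = times[-1] - times[0]
    n_steps = max(int(np.ceil(span / dt)), 1)
    tgrid = times[0] + np.arange(n_steps + 1) * (span / n_steps)
    c_dense = np.interp(tgrid, times, camp)
    a_dense = params.activity(c_dense)
    step = tgrid[1] - tgrid[0]

    out = np.empty((times.size, 2))
    out[0] = f
    next_obs = 1
    for i in range(n_steps):
        a0 = a_dense[i]
        a1 = a_dense[i + 1]
        am = 0.5 * (a0 + a1)

        def rhs(a, ff):
            return k_site * a * (1.0 - ff) - params.kd * ff

        k1 = rhs(a0, f)
        k2 = rhs(am, f + step / 2.0 * k1)
        k3 = rhs(am, f + step / 2.0 * k2)
        k4 = rhs(a1, f + step * k3)
        f = np.clip(f + step / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0, 1.0)
        t_now = tgrid[i + 1]
        while next_obs < times.size and times[next_obs] <= t_now + 1e-12:
            out[next_obs] = f
            next_obs += 1
    while next_obs < times.size:  # guard against float round-off at the end
        out[next_obs] = f
        next_obs += 1
    return out[:, 0], out[:, 1]
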